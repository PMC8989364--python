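"""Parameter containers and validation for the Moran-lottery models.

Both the two-species and the diverse-community models share the same
environmental machinery: the community holds exactly ``N`` individuals at
all times (zero-sum competition), time advances in elementary birth-death
events of duration ``1/N`` generations, and the environment dwells in one
state for a characteristic time ``delta`` (in generations) before switching.
Fitness of an individual with log-fitness (selection parameter) ``s`` is
``exp(s)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Any


class Competition(str, enum.Enum):
    """How individuals compete for the slot opened by a death.

    ``LOCAL``: pairwise duels between two randomly chosen individuals; the
    winner's offspring replaces the loser.  No covariance between environment
    and competition can build up, so fluctuating selection cannot stabilize
    coexistence (no storage effect).

    ``GLOBAL``: a random individual dies and the whole community competes
    for the open slot in a fitness-weighted lottery.  Rare species then
    experience negative environment-competition covariance, which is the
    storage effect.
    """

    LOCAL = "local"
    GLOBAL = "global"


class EnvironmentMode(str, enum.Enum):
    """Temporal structure of the environmental state.

    ``PERIODIC``: deterministic (seasonal) switching every ``N*delta``
    elementary steps.  ``STOCHASTIC``: memoryless switching with mean dwell
    time ``delta`` generations.
    """

    PERIODIC = "periodic"
    STOCHASTIC = "stochastic"


def _as_competition(value: Any) -> Competition:
    if isinstance(value, Competition):
        return value
    return Competition(str(value).lower())


def _as_environment(value: Any) -> EnvironmentMode:
    if isinstance(value, EnvironmentMode):
        return value
    return EnvironmentMode(str(value).lower())


@dataclass
class TwoSpeciesConfig:
    """Parameters of the two-species zero-sum Moran-lottery chain.

    The selection difference between the focal and the rival species is
    dichotomous: ``delta_s`` is either ``s0 + gamma`` or ``s0 - gamma``,
    depending on the current environmental state.  The model's intended
    regime is weak mean selection, ``|s0| << gamma``; the engine runs for
    any ``s0`` but results outside that regime should be interpreted with
    care.

    Parameters
    ----------
    N : int
        Community size (total number of individuals), >= 2.
    s0 : float
        Mean log-fitness advantage of the focal species (dimensionless).
    gamma : float
        Amplitude of fitness fluctuations, >= 0.
    delta : float
        Environmental dwell time in generations, > 0.  The periodic switch
        period is ``round(N * delta)`` elementary steps, which must be >= 1.
    competition, environment
        Scenario selectors, see :class:`Competition` and
        :class:`EnvironmentMode`.
    seed : int
        Base RNG seed; replicate ``r`` uses ``seed + r``.
    """

    N: int
    gamma: float = 0.0
    delta: float = 1.0
    s0: float = 0.0
    competition: Competition = Competition.LOCAL
    environment: EnvironmentMode = EnvironmentMode.PERIODIC
    seed: int = 0

    def __post_init__(self) -> None:
        self.competition = _as_competition(self.competition)
        self.environment = _as_environment(self.environment)
        if not (isinstance(self.N, (int,)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be > 0, got {self.delta!r}")
        if not (self.gamma >= 0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        if not math.isfinite(self.s0):
            raise ValueError("s0 must be finite")
        if self.switch_period < 1:
            raise ValueError(
                "N * delta must be >= 1: environmental dwell shorter than one "
                f"elementary step is outside the model (N={self.N}, delta={self.delta})"
            )

    @property
    def g(self) -> float:
        """Strength of environmental fluctuations, ``g = delta * gamma**2 / 2``."""
        return self.delta * self.gamma**2 / 2.0

    @property
    def switch_period(self) -> int:
        """Periodic switch period in elementary steps, ``round(N * delta)``."""
        return int(round(self.N * self.delta))

    @property
    def scenario(self) -> str:
        """Two-letter scenario tag: LP, GP, LS or GS."""
        c = "L" if self.competition is Competition.LOCAL else "G"
        e = "P" if self.environment is EnvironmentMode.PERIODIC else "S"
        return c + e

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["competition"] = self.competition.value
        d["environment"] = self.environment.value
        d["g"] = self.g
        return d


@dataclass
class CommunityConfig:
    """Parameters of the diverse-community model with Q temporal niches.

    Each species ``i`` carries a vector of selection parameters
    ``s_i^1 .. s_i^Q``, one per temporal niche, drawn uniformly on
    ``[-gamma/2, gamma/2]`` and centered so every species has zero mean
    log-fitness across niches.  New species enter on a per-death
    colonization probability ``nu`` (speciation, mutation or immigration
    from a regional pool).

    Unlike the two-species chain, the stochastic environment here keeps a
    fixed dwell of ``round(N*delta)`` elementary steps and resamples the
    niche index uniformly (the current niche may repeat); the periodic
    environment cycles 1, 2, ..., Q deterministically.
    """

    N: int
    nu: float = 0.0
    Q: int = 1
    gamma: float = 0.0
    delta: float = 1.0
    competition: Competition = Competition.GLOBAL
    environment: EnvironmentMode = EnvironmentMode.PERIODIC
    seed: int = 0
    burn_in: int = 1000
    horizon: int = 5000

    def __post_init__(self) -> None:
        self.competition = _as_competition(self.competition)
        self.environment = _as_environment(self.environment)
        if not (isinstance(self.N, int) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError(f"nu must lie in [0, 1], got {self.nu!r}")
        if not (isinstance(self.Q, int) and self.Q >= 1):
            raise ValueError(f"Q must be an integer >= 1, got {self.Q!r}")
        if not (self.gamma >= 0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be > 0, got {self.delta!r}")
        if self.switch_period < 1:
            raise ValueError(
                "N * delta must be >= 1: environmental dwell shorter than one "
                f"elementary step is outside the model (N={self.N}, delta={self.delta})"
            )
        if not (self.horizon > self.burn_in >= 0):
            raise ValueError(
                f"horizon ({self.horizon}) must exceed burn_in ({self.burn_in})"
            )

    @property
    def g(self) -> float:
        """Strength of environmental fluctuations, ``g = delta * gamma**2 / 2``."""
        return self.delta * self.gamma**2 / 2.0

    @property
    def switch_period(self) -> int:
        """Environmental dwell in elementary steps, ``round(N * delta)``."""
        return int(round(self.N * self.delta))

    @property
    def scenario(self) -> str:
        c = "L" if self.competition is Competition.LOCAL else "G"
        e = "P" if self.environment is EnvironmentMode.PERIODIC else "S"
        return c + e

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["competition"] = self.competition.value
        d["environment"] = self.environment.value
        d["g"] = self.g
        return d
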