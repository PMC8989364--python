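"""Diffusion approximation for the two-species mean time to extinction.

In the annealed regime (environmental switching much faster than fixation)
the frequency ``x`` of the focal species obeys a one-dimensional diffusion
with scenario-specific drift ``mu(x)`` and variance rate ``sigma2(x)``, both
per elementary step.  The mean time to absorption ``T(x)`` then satisfies
the backward equation

    sigma2(x)/2 * T''(x) + mu(x) * T'(x) = -1,    T(0) = T(1) = 0,

solved here by the integrating-factor double quadrature.  ``T`` is returned
in generations (the elementary-step result divided by ``N``).

The four scenarios (local/global competition x periodic/stochastic
environment) differ only in their coefficients:

    LP:  mu = s0 x(1-x)/N                         sigma2 = 2x(1-x)/N^2
    GP:  mu = x(1-x)/N [s0 + (gamma^2/2)(1-2x)]   sigma2 = 2x(1-x)/N^2
    LS:  mu = x(1-x)/N [s0 + g(1-2x)]             sigma2 = 2x(1-x)/N^2 [1 + gN x(1-x)]
    GS:  mu = x(1-x)/N [s0 + (g+gamma^2/2)(1-2x)] sigma2 as LS

with ``g = delta gamma^2 / 2``.  Under periodic forcing the environmental
contribution averages out of the variance entirely, and under local
competition the stabilizing-looking drift term is exactly cancelled by
diffusive trapping — which is why only the global-stochastic and
global-periodic scenarios support long coexistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import Competition, EnvironmentMode, TwoSpeciesConfig

__all__ = ["DriftDiffusionSpec", "MTESolution", "build_coefficients", "solve_mte", "mte_profile"]


@dataclass
class DriftDiffusionSpec:
    """Scenario-tagged drift/variance coefficient pair of the frequency diffusion.

    ``mu`` and ``sigma2`` map interior frequencies ``x`` in (0,1) to the
    per-elementary-step drift and variance rate; both vanish at the
    absorbing boundaries.
    """

    scenario: str
    mu: Callable[[np.ndarray], np.ndarray]
    sigma2: Callable[[np.ndarray], np.ndarray]
    params: TwoSpeciesConfig

    def drift_over_var(self, x: np.ndarray) -> np.ndarray:
        """The ratio ``2 mu(x) / sigma2(x)`` entering the integrating factor."""
        return 2.0 * self.mu(x) / self.sigma2(x)


@dataclass
class MTESolution:
    """Mean time to absorption on a frequency grid, in generations."""

    grid: np.ndarray
    T: np.ndarray
    scenario: str
    grid_size: int
    convergence_estimate: float

    def at(self, x: float | np.ndarray) -> float | np.ndarray:
        """Interpolate T(x); T -> 0 at the boundaries."""
        return np.interp(x, self.grid, self.T, left=0.0, right=0.0)

    @property
    def T_half(self) -> float:
        return float(self.at(0.5))

    @property
    def argmax_x(self) -> float:
        """Grid location of the maximum of T."""
        return float(self.grid[int(np.argmax(self.T))])


def build_coefficients(config: TwoSpeciesConfig) -> DriftDiffusionSpec:
    """Drift and variance rate of the frequency diffusion for one scenario.

    The periodic coefficients carry no environmental term in ``sigma2``;
    for local-periodic dynamics ``gamma`` and ``delta`` drop out entirely
    and the coefficients are those of a fixed environment.
    """
    N = config.N
    s0 = config.s0
    gam2_half = config.gamma**2 / 2.0
    g = config.g
    is_global = config.competition is Competition.GLOBAL
    is_stoch = config.environment is EnvironmentMode.STOCHASTIC

    # Effective strength of the (1-2x) restoring term in the drift.
    kappa = (g if is_stoch else 0.0) + (gam2_half if is_global else 0.0)

    def mu(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x * (1.0 - x) / N * (s0 + kappa * (1.0 - 2.0 * x))

    if is_stoch:

        def sigma2(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return 2.0 * x * (1.0 - x) / N**2 * (1.0 + g * N * x * (1.0 - x))

    else:

        def sigma2(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return 2.0 * x * (1.0 - x) / N**2

    return DriftDiffusionSpec(
        scenario=config.scenario, mu=mu, sigma2=sigma2, params=config
    )


def _solve_on_grid(spec: DriftDiffusionSpec, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Integrating-factor solution of the backward equation on M cell centers.

    The grid is offset half a cell from the absorbing endpoints (first node at
    1/(2M)), because 2/sigma2 diverges like 1/x there; the divergence is
    integrable and trapezoidal quadrature on the offset grid converges under
    refinement.  The integrating-factor reference point is x = 1/2 so the
    exponentials stay bounded even when the drift term is strong (large N).
    """
    h = 1.0 / M
    x = (np.arange(M) + 0.5) * h

    r = spec.drift_over_var(x)  # 2 mu / sigma2
    phi = cumulative_trapezoid(r, x, initial=0.0)
    # re-reference phi to x = 1/2 (mean of the two central nodes for even M)
    phi -= np.interp(0.5, x, phi)

    w = np.exp(-phi)  # integrating factor e^{-phi}
    v = (2.0 / spec.sigma2(x)) * np.exp(phi)

    inner = cumulative_trapezoid(v, x, initial=0.0)
    inner -= np.interp(0.5, x, inner)

    # Outer integrals from 0, including the half-cell strip [0, h/2]
    # approximated by the first-node value (w is finite at the endpoints).
    def outer(f: np.ndarray) -> tuple[np.ndarray, float]:
        cum = cumulative_trapezoid(f, x, initial=0.0) + f[0] * (h / 2.0)
        total = cum[-1] + f[-1] * (h / 2.0)
        return cum, total

    A, A_tot = outer(w)
    B, B_tot = outer(w * inner)

    C1 = B_tot / A_tot
    T_steps = C1 * A - B
    return x, T_steps / spec.params.N


def solve_mte(
    spec: DriftDiffusionSpec,
    grid_size: int = 2048,
    rtol: float = 1e-2,
    max_refinements: int = 6,
) -> MTESolution:
    """Solve the backward equation for the mean time to absorption.

    Refines the grid (doubling) until the interior solution changes by less
    than ``rtol`` in relative terms, then returns the finer solution.

    Raises
    ------
    ValueError
        if ``grid_size`` < 64.
    RuntimeError
        if the refinement loop fails to converge.
    """
    if grid_size < 64:
        raise ValueError(f"grid_size must be >= 64, got {grid_size}")

    M = int(grid_size)
    x_c, T_c = _solve_on_grid(spec, M)
    for _ in range(max_refinements):
        M2 = 2 * M
        x_f, T_f = _solve_on_grid(spec, M2)
        T_f_on_c = np.interp(x_c, x_f, T_f)
        scale = float(np.max(T_f))
        if scale <= 0 or not np.isfinite(scale):
            raise RuntimeError(
                f"backward-equation solver produced a degenerate solution "
                f"(max T = {scale}) for scenario {spec.scenario}"
            )
        # Convergence is judged on the physical interior, one individual away
        # from the boundaries: below x = 1/N the continuum T has no discrete
        # counterpart and the quadrature error there is self-similar.
        lo = 1.0 / spec.params.N
        mask = (x_c >= lo) & (x_c <= 1.0 - lo) & (T_f_on_c > 1e-9 * scale)
        rel = float(np.max(np.abs(T_f_on_c[mask] - T_c[mask]) / T_f_on_c[mask]))
        if rel < rtol:
            return MTESolution(
                grid=x_f, T=T_f, scenario=spec.scenario,
                grid_size=M2, convergence_estimate=rel,
            )
        M, x_c, T_c = M2, x_f, T_f
    raise RuntimeError(
        f"mean-time-to-extinction solver did not converge to rtol={rtol} "
        f"after {max_refinements} grid doublings (last grid {M}, scenario "
        f"{spec.scenario}); the coefficients may be too stiff for this N"
    )


def mte_profile(config: TwoSpeciesConfig, grid_size: int = 2048) -> MTESolution:
    """Convenience composition: coefficients for ``config``, then solve."""
    return solve_mte(build_coefficients(config), grid_size=grid_size)
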