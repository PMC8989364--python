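"""Numba kernels for the individual-based simulations.

These are the hot loops only; all bookkeeping, validation and statistics
live in :mod:`two_species` and :mod:`community`.  Each kernel (re)seeds
numba's global NumPy-compatible RNG itself, so a replicate is fully
reproducible from its integer seed.

Conventions shared with the pure-Python reference implementations:

* one elementary birth-death event per step, ``1/N`` generations each;
* local competition: with probability ``2x(1-x)`` the step is an
  interspecific duel, decided by the fitness ratio; otherwise nothing
  happens to the abundances;
* global competition: a uniformly chosen individual dies and the slot is
  filled by an abundance- and fitness-weighted lottery evaluated at
  pre-death abundances;
* the environment advances *after* the birth-death event.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# two-species chain
# ---------------------------------------------------------------------------


@njit(cache=True)
def two_species_absorb(
    N: int,
    s0: float,
    gamma: float,
    period: int,          # round(N * delta), >= 1
    is_local: bool,
    is_periodic: bool,
    n0: int,
    seed: int,
    init_phase: int,      # periodic: -1 -> draw uniform phase; else fixed phase in [0, 2*period)
) -> tuple[int, int, int]:
    """Run one replicate to absorption.

    Returns ``(elapsed_steps, final_n, env_switches)``; time in generations
    is ``elapsed_steps / N``.
    """
    np.random.seed(seed)
    n = n0
    steps = 0
    switches = 0

    # environment state: eps = +1 -> delta_s = s0 + gamma, -1 -> s0 - gamma
    if is_periodic:
        phase = init_phase
        if phase < 0:
            phase = np.random.randint(0, 2 * period)
        eps = 1 if phase < period else -1
        # steps remaining in the current dwell
        left = period - (phase % period)
    else:
        eps = 1 if np.random.random() < 0.5 else -1
        # geometric dwell: per-step flip probability 1/period in expectation
        p_flip = 1.0 / period
        left = np.random.geometric(p_flip)

    while 0 < n < N:
        ds = s0 + gamma * eps
        eds = np.exp(ds)
        p_win = eds / (eds + 1.0)  # focal's chance in an interspecific duel
        # run out the current environmental dwell (or until absorption)
        m = left
        if is_local:
            while m > 0 and 0 < n < N:
                x = n / N
                if np.random.random() < 2.0 * x * (1.0 - x):
                    if np.random.random() < p_win:
                        n += 1
                    else:
                        n -= 1
                steps += 1
                m -= 1
        else:
            while m > 0 and 0 < n < N:
                x = n / N
                w = x * eds
                p1 = w / (w + (1.0 - x))  # focal captures the slot
                u = np.random.random()
                up = (1.0 - x) * p1
                if u < up:
                    n += 1
                elif u < up + x * (1.0 - p1):
                    n -= 1
                steps += 1
                m -= 1
        if m == 0:
            # two environmental states in both modes: a switch is a toggle
            eps = -eps
            switches += 1
            if is_periodic:
                left = period
            else:
                left = np.random.geometric(1.0 / period)
        else:
            left = m
    return steps, n, switches


# ---------------------------------------------------------------------------
# diverse community with Q temporal niches
# ---------------------------------------------------------------------------


@njit(cache=True)
def seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def draw_centered_fitness(Q: int, gamma: float, out: np.ndarray) -> None:
    """Q uniforms on [-gamma/2, gamma/2], centered to zero mean."""
    mean = 0.0
    for q in range(Q):
        out[q] = (np.random.random() - 0.5) * gamma
        mean += out[q]
    mean /= Q
    for q in range(Q):
        out[q] -= mean


@njit(cache=True)
def community_generations(
    n: np.ndarray,        # int64[cap] abundances
    ew: np.ndarray,       # float64[cap, Q] exp(s_i^q), per-niche fitness weights
    ids: np.ndarray,      # int64[cap] species identifiers
    state: np.ndarray,    # int64[4]: m (extant count), q, dwell_left, next_id
    N: int,
    nu: float,
    gamma: float,
    Q: int,
    period: int,
    is_local: bool,
    is_periodic: bool,
    n_generations: int,
) -> None:
    """Advance the community by ``n_generations * N`` elementary events in place.

    ``state`` carries the scalars that must persist across calls.  The RNG is
    numba's global state: call :func:`seed_rng` once per run before the first
    call.
    """
    m = int(state[0])
    q = int(state[1])
    left = int(state[2])
    next_id = int(state[3])
    svec = np.empty(Q, dtype=np.float64)

    for _ in range(n_generations * N):
        if is_local:
            # two distinct individuals: first by abundance, second from the
            # remaining N-1 individuals
            r = np.random.randint(0, N)
            i = 0
            acc = n[0]
            while r >= acc:
                i += 1
                acc += n[i]
            r = np.random.randint(0, N - 1)
            j = 0
            nj = n[0] - (1 if i == 0 else 0)
            acc = nj
            while r >= acc:
                j += 1
                acc += n[j] - (1 if i == j else 0)
            if i == j:
                # conspecific duel: winner and loser belong to the same species
                winner = i
                loser = i
            else:
                wi = ew[i, q]
                wj = ew[j, q]
                if np.random.random() < wi / (wi + wj):
                    winner, loser = i, j
                else:
                    winner, loser = j, i
            if nu > 0.0 and np.random.random() < nu:
                # the loser is replaced by a brand-new species
                n[loser] -= 1
                if n[loser] == 0:
                    m -= 1
                    n[loser] = n[m]
                    ids[loser] = ids[m]
                    ew[loser, :] = ew[m, :]
                draw_centered_fitness(Q, gamma, svec)
                n[m] = 1
                ids[m] = next_id
                next_id += 1
                for k in range(Q):
                    ew[m, k] = np.exp(svec[k])
                m += 1
            elif winner != loser:
                n[loser] -= 1
                n[winner] += 1
                if n[loser] == 0:
                    m -= 1
                    n[loser] = n[m]
                    ids[loser] = ids[m]
                    ew[loser, :] = ew[m, :]
        else:
            # global competition: uniform death, lottery at pre-death abundances
            r = np.random.randint(0, N)
            v = 0
            acc = n[0]
            while r >= acc:
                v += 1
                acc += n[v]
            if nu > 0.0 and np.random.random() < nu:
                n[v] -= 1
                if n[v] == 0:
                    m -= 1
                    n[v] = n[m]
                    ids[v] = ids[m]
                    ew[v, :] = ew[m, :]
                draw_centered_fitness(Q, gamma, svec)
                n[m] = 1
                ids[m] = next_id
                next_id += 1
                for k in range(Q):
                    ew[m, k] = np.exp(svec[k])
                m += 1
            else:
                tot = 0.0
                for k in range(m):
                    tot += n[k] * ew[k, q]
                u = np.random.random() * tot
                w = 0
                acc_f = n[0] * ew[0, q]
                while u >= acc_f and w < m - 1:
                    w += 1
                    acc_f += n[w] * ew[w, q]
                if w != v:
                    n[v] -= 1
                    n[w] += 1
                    if n[v] == 0:
                        m -= 1
                        n[v] = n[m]
                        ids[v] = ids[m]
                        ew[v, :] = ew[m, :]

        # environment advances after the birth-death event
        left -= 1
        if left == 0:
            left = period
            if is_periodic:
                q = (q + 1) % Q
            else:
                q = np.random.randint(0, Q)

    state[0] = m
    state[1] = q
    state[2] = left
    state[3] = next_id
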