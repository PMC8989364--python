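"""Brute-force mean absorption times for small two-species chains.

Independent oracle for the Monte-Carlo engine and the diffusion solver:
builds the full transition structure of the product chain (abundance x
environmental state) directly from the model's defining probabilities and
solves the fundamental-matrix linear system for the expected number of
elementary steps to absorption.  Feasible only for small N (and, in the
periodic case, modest switch periods), which is exactly its role.
"""

from __future__ import annotations

import math

import numpy as np


def _move_probs(n: int, N: int, ds: float, local: bool) -> tuple[float, float]:
    """(p_up, p_down) for one birth-death event at abundance n, selection ds."""
    x = n / N
    if local:
        p1 = math.exp(ds) / (math.exp(ds) + 1.0)
        p_duel = 2.0 * x * (1.0 - x)
        return p_duel * p1, p_duel * (1.0 - p1)
    w = x * math.exp(ds)
    p1 = w / (w + 1.0 - x)
    return (1.0 - x) * p1, x * (1.0 - p1)


def exact_mean_absorption_stochastic(
    N: int, s0: float, gamma: float, delta: float, local: bool, n0: int
) -> float:
    """Mean absorption time in generations, stochastic (geometric-dwell) environment.

    States are (n, e) with e = +/-1 the environmental sign; after each
    elementary event the environment toggles with probability 1/(N*delta).
    The initial environment is +/-1 with probability 1/2 each.
    """
    period = round(N * delta)
    pf = 1.0 / period
    interior = list(range(1, N))
    idx = {(n, e): i for i, (n, e) in enumerate(
        (n, e) for n in interior for e in (1, -1))}
    dim = len(idx)
    A = np.zeros((dim, dim))
    b = np.ones(dim)
    for (n, e), i in idx.items():
        A[i, i] = 1.0
        up, down = _move_probs(n, N, s0 + gamma * e, local)
        stay = 1.0 - up - down
        for n2, p in ((n + 1, up), (n - 1, down), (n, stay)):
            if p == 0.0 or not (0 < n2 < N):
                continue
            A[i, idx[(n2, e)]] -= p * (1.0 - pf)
            A[i, idx[(n2, -e)]] -= p * pf
    t = np.linalg.solve(A, b)
    return 0.5 * (t[idx[(n0, 1)]] + t[idx[(n0, -1)]]) / N


def exact_mean_absorption_periodic(
    N: int, s0: float, gamma: float, delta: float, local: bool, n0: int
) -> float:
    """Mean absorption time in generations, periodic environment.

    States are (n, c) with phase c in [0, 2P): the selection sign is +1 for
    c < P and -1 otherwise, and c advances deterministically after every
    elementary event.  The result is averaged over a uniform initial phase.
    """
    P = round(N * delta)
    C = 2 * P
    interior = list(range(1, N))
    idx = {(n, c): i for i, (n, c) in enumerate(
        (n, c) for n in interior for c in range(C))}
    dim = len(idx)
    A = np.zeros((dim, dim))
    b = np.ones(dim)
    for (n, c), i in idx.items():
        A[i, i] = 1.0
        e = 1 if c < P else -1
        c2 = (c + 1) % C
        up, down = _move_probs(n, N, s0 + gamma * e, local)
        stay = 1.0 - up - down
        for n2, p in ((n + 1, up), (n - 1, down), (n, stay)):
            if p == 0.0 or not (0 < n2 < N):
                continue
            A[i, idx[(n2, c2)]] -= p
    t = np.linalg.solve(A, b)
    return float(np.mean([t[idx[(n0, c)]] for c in range(C)])) / N


def exact_mean_absorption(
    N: int, s0: float, gamma: float, delta: float,
    competition: str, environment: str, n0: int,
) -> float:
    local = competition == "local"
    if environment == "periodic":
        return exact_mean_absorption_periodic(N, s0, gamma, delta, local, n0)
    return exact_mean_absorption_stochastic(N, s0, gamma, delta, local, n0)
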