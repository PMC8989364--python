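"""Tests of the Q-niche community engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moranlottery import (
    CommunityConfig,
    CommunityState,
    SpeciesRecord,
    TrajectoryRecord,
    draw_species_fitness,
    dominance_profile,
    equilibration_generation,
    recruit_probs,
    run_community,
    shannon_entropy,
)
from moranlottery import _kernels


class TestFitnessVectors:
    def test_single_niche_vector_is_zero(self):
        rng = np.random.default_rng(0)
        assert draw_species_fitness(1, 0.7, rng)[0] == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 12), st.floats(0.0, 2.0))
    def test_vectors_are_centered_and_bounded(self, Q, gamma):
        rng = np.random.default_rng(7)
        s = draw_species_fitness(Q, gamma, rng)
        assert abs(s.mean()) < 1e-12
        assert np.all(np.abs(s) <= gamma)

    def test_entry_variance_of_centered_uniforms(self):
        # Var[s_q] = gamma^2/12 * (1 - 1/Q)
        rng = np.random.default_rng(123)
        Q, gamma = 3, 0.4
        draws = np.stack([draw_species_fitness(Q, gamma, rng) for _ in range(100_000)])
        expected = gamma**2 / 12 * (1 - 1 / Q)
        assert np.var(draws) == pytest.approx(expected, rel=0.05)

    def test_kernel_draw_matches_contract(self):
        _kernels.seed_rng(5)
        out = np.empty(6)
        _kernels.draw_centered_fitness(6, 0.8, out)
        assert abs(out.mean()) < 1e-12 and np.all(np.abs(out) <= 0.8)


class TestRecruitProbs:
    def test_neutral_lottery_is_abundance_weighted(self):
        state = CommunityState(
            species=[SpeciesRecord(0, 30, [0.1, 0.1]), SpeciesRecord(1, 70, [0.1, 0.1])]
        )
        assert np.allclose(recruit_probs(state), [0.3, 0.7])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        species = [
            SpeciesRecord(i, 10 + i, draw_species_fitness(4, 0.6, rng))
            for i in range(8)
        ]
        assert recruit_probs(CommunityState(species=species, q=2)).sum() == pytest.approx(1.0)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            recruit_probs(CommunityState(species=[]))

    def test_generalist_invader_recruit_fraction(self):
        # two resident specialists at N/2 each (s=1 in their own season) plus
        # one generalist individual with s=1/2 in both seasons: its recruit
        # fraction is 2 e^{1/2} / (N (1+e)) in either season
        N = 10_000
        state = CommunityState(
            species=[
                SpeciesRecord(0, N // 2, [1.0, 0.0]),
                SpeciesRecord(1, N // 2, [0.0, 1.0]),
                SpeciesRecord(2, 1, [0.5, 0.5]),
            ],
            q=0,
        )
        f = recruit_probs(state)[2]
        assert f == pytest.approx(2 * math.e**0.5 / (N * (1 + math.e)), rel=1e-3)


class TestShannonEntropy:
    def test_monodominant_community(self):
        assert shannon_entropy([50], 50) == 0.0

    def test_perfectly_even_community(self):
        assert shannon_entropy([25, 25, 25, 25], 100) == pytest.approx(math.log(4))

    def test_direct_evaluation(self):
        assert shannon_entropy([2, 2, 4], 8) == pytest.approx(1.0397, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([], 10)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=40))
    def test_bounded_by_log_richness(self, counts):
        se = shannon_entropy(counts, sum(counts))
        assert -1e-12 <= se <= math.log(len(counts)) + 1e-12


class TestDynamics:
    def test_zero_sum_and_entropy_bound_along_trajectory(self):
        cfg = CommunityConfig(N=300, nu=0.01, Q=3, gamma=0.4, delta=0.2,
                              competition="global", environment="stochastic",
                              seed=2, burn_in=10, horizon=200)
        tr = run_community(cfg, snapshot_every=20)
        assert np.all(tr.se <= np.log(np.maximum(tr.sr, 1)) + 1e-12)
        assert np.all(tr.sr >= 1)
        for _, _ids, counts in tr.snapshots:
            assert counts.sum() == 300 and np.all(counts >= 1)

    def test_maximal_colonization_fills_community_with_singletons(self):
        cfg = CommunityConfig(N=100, nu=1.0, Q=2, gamma=0.3, delta=0.5,
                              competition="global", environment="periodic",
                              seed=0, burn_in=5, horizon=20)
        tr = run_community(cfg)
        assert tr.sr[-1] > 80  # every death spawns a new species

    def test_no_colonization_no_innovation(self):
        cfg = CommunityConfig(N=200, nu=0.0, Q=3, gamma=0.4, delta=0.5,
                              competition="local", environment="periodic",
                              seed=1, burn_in=1, horizon=50)
        tr = run_community(cfg)
        assert np.all(tr.sr == 1) and np.all(tr.se == 0.0)

    def test_neutral_abundance_is_a_martingale(self):
        # gamma=0, nu=0, two species at 50/50: one-generation mean change ~ 0
        N, reps = 200, 1500
        deltas = []
        for seed in range(reps):
            _kernels.seed_rng(seed)
            n = np.zeros(N + 1, dtype=np.int64)
            ew = np.ones((N + 1, 1))
            ids = np.arange(N + 1, dtype=np.int64)
            n[0] = n[1] = N // 2
            state = np.array([2, 0, 100, 2], dtype=np.int64)
            _kernels.community_generations(
                n, ew, ids, state, N, 0.0, 0.0, 1, 100, False, True, 1)
            first = n[0] if ids[0] == 0 else n[1]
            deltas.append(first - N // 2)
        se = np.std(deltas) / math.sqrt(reps)
        assert abs(np.mean(deltas)) < 3 * se

    def test_determinism(self):
        cfg = CommunityConfig(N=400, nu=0.005, Q=4, gamma=0.4, delta=0.25,
                              competition="local", environment="stochastic",
                              seed=9, burn_in=10, horizon=120)
        a, b = run_community(cfg), run_community(cfg)
        assert np.array_equal(a.sr, b.sr) and np.array_equal(a.se, b.se)

    def test_periodic_niche_cycle(self):
        # environment advances q -> q+1 -> ... -> 1 every round(N*delta) steps
        _kernels.seed_rng(0)
        N, Q = 50, 3
        n = np.zeros(N + 1, dtype=np.int64); n[0] = N
        ew = np.ones((N + 1, Q)); ids = np.zeros(N + 1, dtype=np.int64)
        state = np.array([1, 0, 25, 1], dtype=np.int64)  # period 25 steps
        seen = []
        for _ in range(6):  # 6 generations = 300 steps = 12 dwells
            _kernels.community_generations(
                n, ew, ids, state, N, 0.0, 0.0, Q, 25, False, True, 1)
            seen.append(int(state[1]))
        # after g generations, 2g dwells have elapsed: q = 2g mod 3
        assert seen == [(2 * g) % 3 for g in range(1, 7)]

    def test_stochastic_niche_resampling_is_uniform(self):
        _kernels.seed_rng(11)
        N, Q = 50, 3
        n = np.zeros(N + 1, dtype=np.int64); n[0] = N
        ew = np.ones((N + 1, Q)); ids = np.zeros(N + 1, dtype=np.int64)
        state = np.array([1, 0, 1, 1], dtype=np.int64)  # resample every step
        counts = np.zeros(Q)
        for _ in range(300):
            _kernels.community_generations(
                n, ew, ids, state, N, 0.0, 0.0, Q, 1, False, False, 1)
            counts[int(state[1])] += 1
        # 300 generations x 50 resamples each; per-generation endpoint uniform
        assert np.all(np.abs(counts / 300 - 1 / Q) < 0.1)


class TestSummaries:
    def test_equilibration_detects_ramp_end(self):
        rng = np.random.default_rng(0)
        ramp = np.linspace(0, 10, 800)
        flat = 10 + rng.normal(0, 0.5, 4200)
        gen = equilibration_generation(np.concatenate([ramp, flat]), window=200)
        assert 600 <= gen <= 1200

    def test_dominance_profile_monodominant(self):
        cfg = CommunityConfig(N=200, nu=0.0, Q=3, gamma=0.4, delta=0.5,
                              seed=1, burn_in=1, horizon=30)
        tr = run_community(cfg, snapshot_every=10)
        dp = dominance_profile(tr)
        assert np.allclose(dp.top_Q_share, 1.0)

    def test_dominance_requires_snapshots(self):
        cfg = CommunityConfig(N=200, nu=0.0, Q=3, gamma=0.4, delta=0.5,
                              seed=1, burn_in=1, horizon=30)
        with pytest.raises(ValueError):
            dominance_profile(run_community(cfg))

    def test_many_niches_and_fast_colonization_neutralize_the_dynamics(self):
        # Q=30 >> SR-relevant niche count: the differential response of many
        # species buffers the environment and all four scenarios approach the
        # neutral (gamma=0) richness
        results = {}
        for label, comp, env, gamma, Q in [
            ("GP", "global", "periodic", 0.4, 30),
            ("GS", "global", "stochastic", 0.4, 30),
            ("LP", "local", "periodic", 0.4, 30),
            ("LS", "local", "stochastic", 0.4, 30),
            ("neutral", "global", "periodic", 0.0, 1),
        ]:
            cfg = CommunityConfig(N=2000, nu=0.01, Q=Q, gamma=gamma, delta=0.2,
                                  competition=comp, environment=env, seed=8,
                                  burn_in=500, horizon=3000)
            results[label] = run_community(cfg).sr_mean
        for scen in ("GP", "GS", "LP", "LS"):
            assert results[scen] == pytest.approx(results["neutral"], rel=0.06)

    def test_global_competition_concentrates_dominance_in_specialists(self):
        # Q=3 niches, high colonization pressure: under global competition
        # one specialist per niche dominates (large top-3 share); under local
        # competition many species coexist with no abundance gap
        shares = {}
        for comp in ("global", "local"):
            cfg = CommunityConfig(N=10_000, nu=0.005, Q=3, gamma=0.4,
                                  delta=0.2, competition=comp,
                                  environment="periodic", seed=4,
                                  burn_in=1000, horizon=3000)
            tr = run_community(cfg, snapshot_every=200)
            dp = dominance_profile(tr)
            shares[comp] = dp[dp.generation > 1000].top_Q_share.mean()
        assert shares["global"] > 1.3 * shares["local"]

    def test_neutral_runs_are_dwell_time_invariant(self):
        # gamma=0 removes the environment: periodic runs with different delta
        # consume the identical random stream, hence identical trajectories
        kw = dict(N=300, nu=0.01, Q=3, gamma=0.0, competition="global",
                  environment="periodic", seed=6, burn_in=10, horizon=150)
        a = run_community(CommunityConfig(delta=0.2, **kw))
        b = run_community(CommunityConfig(delta=0.7, **kw))
        assert np.array_equal(a.sr, b.sr) and np.array_equal(a.se, b.se)
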