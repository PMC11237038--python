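import numpy as np
import pytest

from gwalign import (
    TransportPlan,
    entropic_gw,
    gw_cost,
    matching_rate,
    normalize,
    random_coupling,
    select_optimum,
    sweep,
)
from gwalign.alignment import SweepRecord, SweepResult, trial_seed
from gwalign.synthetic import make_pair, sample_structure

from reference_gw import gw_cost_loop, permutation_minimum


def _uniform_plan(n, m):
    return TransportPlan(
        np.full((n, m), 1.0 / (n * m)), np.full(n, 1.0 / n), np.full(m, 1.0 / m)
    )


def _identity_plan(n):
    return TransportPlan(
        np.eye(n) / n, np.full(n, 1.0 / n), np.full(n, 1.0 / n)
    )


class TestTransportPlan:
    def test_rejects_bad_marginals(self):
        p = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="mass"):
            TransportPlan(np.eye(3) / 3 * 1.01, p, p)
        skew = np.eye(3) / 3
        skew[0, 1] += 1e-4
        skew[1, 1] -= 1e-4
        with pytest.raises(ValueError, match="marginal"):
            TransportPlan(skew, p, p)
        with pytest.raises(ValueError, match="shape"):
            TransportPlan(np.eye(3) / 3, p, np.full(4, 0.25))

    def test_accepts_valid_coupling(self):
        plan = _uniform_plan(4, 6)
        assert plan.shape == (4, 6)
        assert plan.values.sum() == pytest.approx(1.0)


class TestGwCost:
    def test_self_alignment_is_exactly_zero(self, random_dissimilarity):
        D = random_dissimilarity(7, seed=0)
        assert gw_cost(D, D, _identity_plan(7)) == 0.0

    def test_uniform_outer_product_matches_quadruple_loop(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (4, 4)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.uniform(0, 1, (4, 4)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        plan = _uniform_plan(4, 4)
        assert gw_cost(A, B, plan) == pytest.approx(
            gw_cost_loop(A, B, plan.values), abs=1e-12
        )

    def test_cyclic_relabeling_costs_zero(self):
        # 3 items, off-diagonals (1, 2, 3); target is a cyclic relabeling
        A = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        sigma = [1, 2, 0]
        B = A[np.ix_(sigma, sigma)]  # B position k holds item sigma[k]
        G = np.zeros((3, 3))
        for k, s in enumerate(sigma):
            G[s, k] = 1 / 3
        plan = TransportPlan(G, np.full(3, 1 / 3), np.full(3, 1 / 3))
        cost = gw_cost(A, B, plan)
        assert cost == pytest.approx(gw_cost_loop(A, B, G), abs=1e-12)
        assert cost < 1e-12

    @pytest.mark.parametrize("n,m,seed", [(4, 4, 0), (5, 3, 1), (6, 6, 2), (3, 6, 3)])
    def test_factored_contraction_equals_loop(self, n, m, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 2, (n, n)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.uniform(0, 2, (m, m)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        plan = random_coupling(n, m, seed)
        assert gw_cost(A, B, plan) == pytest.approx(
            gw_cost_loop(A, B, plan.values), abs=1e-10
        )

    def test_dimension_mismatch_rejected(self, random_dissimilarity):
        with pytest.raises(ValueError, match="mismatch"):
            gw_cost(
                random_dissimilarity(4), random_dissimilarity(5), _identity_plan(4)
            )


class TestEntropicGw:
    def test_self_alignment_recovers_identity(self, random_dissimilarity):
        D = normalize(random_dissimilarity(8, seed=5))
        n = 8
        init_vals = 0.6 * np.eye(n) / n + 0.4 / n**2
        init = TransportPlan(init_vals, np.full(n, 1 / n), np.full(n, 1 / n))
        rec = entropic_gw(D, D, epsilon=1e-3, init=init)
        report = matching_rate(rec.plan, D.labels, D.labels)
        assert report.matching_rate == 100.0
        assert rec.gwd_plain < 1e-5

    def test_sweep_reaches_permutation_optimum(self):
        # n=5 metric structure vs a permuted copy: exhaustive enumeration
        # of all 120 permutation couplings gives the exact optimum; a
        # single fixed temperature is not reliable at this size, which is
        # precisely why the protocol sweeps (eps, init) pairs
        _, D = sample_structure(5, dim=3, seed=7)
        D = normalize(D)
        pair = make_pair(D, noise_sd=0.0, seed=8)
        A, B = pair.source.values, pair.target.values
        result = sweep(A, B, n_trials=12, seed=0)
        best = select_optimum(result).gwd_plain
        assert best <= permutation_minimum(A, B) + 1e-6

    def test_entropy_dominated_limit_is_uniform(self, random_dissimilarity):
        D = normalize(random_dissimilarity(6, seed=6))
        rec = entropic_gw(D, D, epsilon=10.0, init=random_coupling(6, 6, 0))
        assert np.abs(rec.plan.values - 1.0 / 36).max() < 1e-3

    def test_non_positive_epsilon_rejected(self, random_dissimilarity):
        D = random_dissimilarity(4)
        with pytest.raises(ValueError, match="epsilon"):
            entropic_gw(D, D, 0.0, _identity_plan(4))


class TestRandomCoupling:
    def test_uniform_marginals(self):
        plan = random_coupling(3, 3, seed=42)
        assert np.abs(plan.values.sum(axis=1) - 1 / 3).max() < 1e-8
        assert np.abs(plan.values.sum(axis=0) - 1 / 3).max() < 1e-8

    def test_deterministic_given_seed(self):
        a = random_coupling(5, 4, seed=7)
        b = random_coupling(5, 4, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = random_coupling(5, 4, seed=7)
        b = random_coupling(5, 4, seed=8)
        assert np.abs(a.values - b.values).max() > 1e-6

    def test_trial_seed_splitting_is_deterministic_and_spread(self):
        assert trial_seed(3, 5) == trial_seed(3, 5)
        seeds = {trial_seed(3, t) for t in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)


class TestSweep:
    def test_self_alignment_sweep(self):
        _, D = sample_structure(10, dim=3, seed=2)
        D = normalize(D)
        result = sweep(
            D, D, eps_min=1e-4, eps_max=1e-1, n_trials=20, seed=0,
            labels_for_eval=(D.labels, D.labels),
        )
        opt = select_optimum(result)
        assert opt.gwd_plain < 1e-6
        assert opt.matching_rate == 100.0

    def test_all_returned_plans_satisfy_marginals(self, random_dissimilarity):
        D = normalize(random_dissimilarity(6, seed=3))
        result = sweep(D, D, n_trials=8, seed=1)
        for rec in result.records:
            G = rec.plan.values
            assert np.abs(G.sum(axis=1) - 1 / 6).max() < 1e-6
            assert np.abs(G.sum(axis=0) - 1 / 6).max() < 1e-6

    def test_single_trial_sweep(self, random_dissimilarity):
        D = normalize(random_dissimilarity(5, seed=4))
        result = sweep(D, D, n_trials=1, seed=0)
        assert len(result.records) == 1
        assert result.optimal_index == 0

    def test_invalid_ranges_rejected(self, random_dissimilarity):
        D = random_dissimilarity(4)
        with pytest.raises(ValueError):
            sweep(D, D, eps_min=0.1, eps_max=0.01)
        with pytest.raises(ValueError):
            sweep(D, D, n_trials=0)


class TestNoiseDegradation:
    def test_matching_rate_degrades_monotonically_with_noise(self):
        # mean matching rate over seeds is non-increasing in noise amplitude
        # (one inversion between adjacent levels tolerated)
        noise_levels = [0.0, 0.1, 0.3, 1.0]
        means = []
        for noise in noise_levels:
            rates = []
            for seed in range(20):
                _, base = sample_structure(8, dim=3, seed=seed)
                base = normalize(base)
                pair = make_pair(base, noise_sd=noise, seed=seed + 50)
                result = sweep(
                    pair.source, pair.target, n_trials=4, seed=seed,
                    labels_for_eval=(pair.source.labels, pair.target.labels),
                )
                rates.append(select_optimum(result).matching_rate)
            means.append(np.mean(rates))
        inversions = sum(
            means[k + 1] > means[k] for k in range(len(means) - 1)
        )
        assert inversions <= 1, means


class TestSelectOptimum:
    def _record(self, eps, gwd, converged=True):
        plan = _uniform_plan(2, 2)
        return SweepRecord(
            epsilon=eps, seed=0, plan=plan, gwd_entropic=gwd, gwd_plain=gwd,
            n_iterations=1, converged=converged,
        )

    def test_argmin_of_plain_gwd(self):
        records = tuple(self._record(0.01, g) for g in (0.3, 0.1, 0.2))
        assert select_optimum(SweepResult(records, 1)) is records[1]

    def test_tie_breaks_toward_smaller_epsilon(self):
        records = (self._record(0.05, 0.1), self._record(0.01, 0.1))
        assert select_optimum(SweepResult(records, 0)) is records[1]

    def test_unconverged_records_excluded(self):
        records = (
            self._record(0.01, 0.05, converged=False),
            self._record(0.02, 0.1),
        )
        assert select_optimum(SweepResult(records, 0)) is records[1]

    def test_single_record(self):
        records = (self._record(0.01, 0.5),)
        assert select_optimum(SweepResult(records, 0)) is records[0]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            select_optimum(SweepResult((), 0))
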