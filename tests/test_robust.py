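"""Effective processes, uncertainty classes, robust clusterers."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import invgamma

from ibrcluster.cost import partition_error
from ibrcluster.gaussian import FixedCovGaussianState, GaussianRLPPSpec
from ibrcluster.partitions import Partition, SizeSpec, enumerate_partitions
from ibrcluster.robust import (DiscreteUncertaintyClass, ExactIBREngine,
                               effective_label_posterior,
                               expected_error_identity_check, ibr_partition,
                               label_posterior, mcbr_partition,
                               minimax_partition, partition_posterior,
                               state_partition_errors)


def _state(sigma2, sizes=(2, 2), nu=1.0):
    d = 1
    return FixedCovGaussianState(
        sigmas=(np.eye(d) * sigma2, np.eye(d) * sigma2),
        means=(np.zeros(d), np.zeros(d)), nus=(nu, nu),
        label_prior=SizeSpec.fixed(sizes))


@pytest.fixture
def two_state():
    return DiscreteUncertaintyClass((_state(1.0), _state(9.0)),
                                    np.array([0.5, 0.5]))


class TestEffectivePosterior:
    def test_single_state_reduces_to_state_posterior(self, rng):
        s = _state(2.0)
        U = DiscreteUncertaintyClass((s,), np.array([1.0]))
        X = rng.normal(size=(4, 1))
        np.testing.assert_allclose(
            effective_label_posterior(X, U).probs,
            label_posterior(X, s).probs, atol=1e-12)

    def test_two_state_mixture_is_half_sum(self, two_state, rng):
        """The effective unnormalized weights are exactly the weighted sum
        of per-state unnormalized weights (mixture linearity, log domain)."""
        X = rng.normal(size=(4, 1))
        post = effective_label_posterior(X, two_state)
        for lab, lw in zip(post.labelings, post.log_weights):
            parts = [s.log_label_weight(X, lab) for s in two_state.states]
            expected = logsumexp(np.array(parts) + np.log(0.5))
            assert lw == pytest.approx(expected, rel=1e-10)

    def test_discretized_variance_grid_converges_to_closed_form(self, rng):
        """A discretized variance prior (product grid over the two
        clusters' independent variances, density-weighted log-spaced
        nodes spanning the inverse-Wishart mass) converges in total
        variation over labelings to the closed-form NIW posterior as the
        grid refines."""
        import itertools
        kappa, psi = 3.0, 1.0
        X = rng.normal(scale=1.5, size=(4, 1))
        niw = GaussianRLPPSpec.symmetric(1, SizeSpec.fixed((2, 2)),
                                         kappa=kappa)
        target = label_posterior(X, niw).probs
        ig = dict(a=kappa / 2, scale=psi / 2)
        lo = np.log(invgamma.ppf(1e-7, **ig))
        hi = np.log(invgamma.ppf(1 - 1e-7, **ig))
        tvs = []
        for g in (6, 12, 24):
            sig2s = np.exp(np.linspace(lo, hi, g))
            w = invgamma.pdf(sig2s, **ig) * sig2s
            w = w / w.sum()
            states, weights = [], []
            for (a, wa), (b, wb) in itertools.product(zip(sig2s, w),
                                                      repeat=2):
                states.append(FixedCovGaussianState(
                    sigmas=(np.eye(1) * a, np.eye(1) * b),
                    means=(np.zeros(1),) * 2, nus=(1.0, 1.0),
                    label_prior=SizeSpec.fixed((2, 2))))
                weights.append(wa * wb)
            U = DiscreteUncertaintyClass(tuple(states), np.array(weights))
            probs = effective_label_posterior(X, U).probs
            tvs.append(0.5 * np.abs(probs - target).sum())
        assert tvs[0] > tvs[1] > tvs[2]
        assert tvs[2] < 1e-4

    def test_empty_state_list_rejected(self):
        with pytest.raises(ValueError):
            DiscreteUncertaintyClass((), np.array([]))

    def test_mismatched_label_priors_rejected(self):
        with pytest.raises(ValueError):
            DiscreteUncertaintyClass(
                (_state(1.0, sizes=(2, 2)), _state(1.0, sizes=(3, 1))),
                np.array([0.5, 0.5]))


class TestIBR:
    def test_single_state_equals_state_bayes(self, rng):
        s = _state(1.0)
        U = DiscreteUncertaintyClass((s,), np.array([1.0]))
        X = rng.normal(size=(4, 1))
        assert ibr_partition(X, U)[0] == ibr_partition(X, s)[0]

    def test_per_point_set_optimality_exhaustive(self, rng):
        """The IBR partition error is minimal over every candidate."""
        spec = GaussianRLPPSpec.symmetric(2, SizeSpec.fixed((4, 4)))
        for _ in range(10):
            X, _, _ = spec.sample(rng)
            dist = partition_posterior(X, spec)
            cands = enumerate_partitions(8, 2)
            best, risk = ibr_partition(X, spec, candidates=cands)
            errs = [partition_error(p, dist) for p in cands]
            assert risk == pytest.approx(min(errs), abs=1e-12)
            assert partition_error(best, dist) == pytest.approx(risk,
                                                                abs=1e-12)

    def test_recovers_well_separated_clusters(self, rng):
        spec = GaussianRLPPSpec.symmetric(1, SizeSpec.fixed((5, 5)))
        mu = np.array([[0.0], [10.0]])  # 10 sigma separation
        X = np.vstack([rng.normal(mu[0], 1.0, size=(5, 1)),
                       rng.normal(mu[1], 1.0, size=(5, 1))])
        best, _ = ibr_partition(X, spec)
        assert best == Partition.from_blocks([range(1, 6), range(6, 11)])

    def test_engine_matches_function_path(self, rng, spec_1d,
                                          well_separated_1d):
        eng = ExactIBREngine(4, spec_1d.label_prior)
        p1, r1, _ = eng.solve(well_separated_1d, spec_1d)
        p2, r2 = ibr_partition(well_separated_1d, spec_1d)
        assert p1 == p2 and r1 == pytest.approx(r2, abs=1e-12)


class TestEffectiveIdentity:
    def test_single_state_exact(self, rng):
        U = DiscreteUncertaintyClass((_state(1.0),), np.array([1.0]))
        q = Partition.from_blocks([[1, 2], [3, 4]])
        chk = expected_error_identity_check(lambda X: q, U, 40, rng)
        assert chk.lhs_exact == chk.rhs_exact

    def test_two_state_shared_draws_exact(self, two_state, rng):
        q = Partition.from_blocks([[1, 3], [2, 4]])
        chk = expected_error_identity_check(lambda X: q, two_state, 100, rng)
        assert chk.lhs_exact == chk.rhs_exact

    def test_two_state_independent_draws_within_3se(self, two_state, rng):
        q = Partition.from_blocks([[1, 2], [3, 4]])
        chk = expected_error_identity_check(lambda X: q, two_state, 3000,
                                            rng, shared=False)
        assert abs(chk.lhs - chk.rhs) < 3 * chk.se


class TestReferenceOperators:
    def test_all_coincide_for_single_state(self, rng):
        s = _state(1.0)
        U = DiscreteUncertaintyClass((s,), np.array([1.0]))
        X = rng.normal(size=(4, 1))
        cands = enumerate_partitions(4, 2)
        bayes = ibr_partition(X, s, candidates=cands)[0]
        assert mcbr_partition(X, U, cands) == bayes
        assert minimax_partition(X, U, cands) == bayes

    def test_minimax_optimizes_worst_state(self, rng):
        """On a two-state toy the minimax output's worst-state error is
        the best achievable in the state-optimal pool."""
        U = DiscreteUncertaintyClass(
            (_state(0.5, nu=4.0), _state(16.0, nu=0.25)),
            np.array([0.5, 0.5]))
        found = 0
        for _ in range(20):
            X = rng.normal(size=(4, 1)) * np.array([[0.4], [0.4], [3.0], [3.0]])
            cands = enumerate_partitions(4, 2)
            mm = minimax_partition(X, U, cands)
            pool = sorted({ibr_partition(X, s, candidates=cands)[0]
                           for s in U.states}, key=lambda p: p.rgs)
            errs = state_partition_errors(X, U, pool)
            worst = errs.max(axis=0)
            mm_worst = errs.max(axis=0)[pool.index(mm)]
            assert mm_worst == pytest.approx(worst.min(), abs=1e-12)
            found += len(pool) > 1
        assert found > 0  # the toy really produced disagreeing states

    def test_mcbr_never_beats_ibr_per_point_set(self, two_state, rng):
        """IBR minimizes the effective-posterior partition error over all
        partitions; the MCBR output is one of them (nested optimization)."""
        for _ in range(10):
            X, _, _ = two_state.sample(rng)
            cands = enumerate_partitions(4, 2)
            p_ibr, risk = ibr_partition(X, two_state, candidates=cands)
            p_mcbr = mcbr_partition(X, two_state, cands)
            dist_eff = partition_posterior(X, two_state)
            assert risk <= partition_error(p_mcbr, dist_eff) + 1e-12

    def test_expected_error_ordering_ibr_mcbr_single_state(self, two_state,
                                                           rng):
        """E_theta-averaged error ordering: IBR <= MCBR <= a single-state
        Bayes clusterer applied across the whole class (within Monte-Carlo
        noise; per-state posterior errors are used instead of sampled
        labels to cut the variance)."""
        cands = enumerate_partitions(4, 2)
        zetas = {
            "ibr": lambda X: ibr_partition(X, two_state, candidates=cands)[0],
            "mcbr": lambda X: mcbr_partition(X, two_state, cands),
            "single": lambda X: ibr_partition(X, two_state.states[0],
                                              candidates=cands)[0],
        }
        per = {k: [] for k in zetas}
        for _ in range(120):
            k = int(rng.choice(2, p=two_state.weights))
            X, _ = two_state.states[k].sample(rng)
            for name, zeta in zetas.items():
                errs = state_partition_errors(X, two_state, [zeta(X)])
                per[name].append(errs[k, 0])
        means = {k: np.mean(v) for k, v in per.items()}
        def se_diff(a, b):
            d = np.asarray(per[a]) - np.asarray(per[b])
            return d.std(ddof=1) / np.sqrt(d.size)
        assert means["ibr"] <= means["mcbr"] + 2 * se_diff("ibr", "mcbr") + 1e-12
        assert means["mcbr"] <= means["single"] + 2 * se_diff("mcbr", "single") + 1e-12

    def test_state_guard(self):
        states = tuple(_state(1.0 + k) for k in range(9))
        U = DiscreteUncertaintyClass(states, np.full(9, 1.0 / 9))
        with pytest.raises(ValueError):
            mcbr_partition(np.zeros((4, 1)), U)
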