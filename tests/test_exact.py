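import math

import numpy as np
import pytest
import scipy.linalg

from sisqsd import (
    build_subgenerator,
    complete_network,
    compute_qsd,
    conditioned_prevalence,
    invasion_probability_exact,
    qsd_event_probability,
    survival_ratio,
    transient_event_probability,
    transpose,
)
from sisqsd.exact import SISStateSpace, _dominant_pair
from sisqsd.networks import ContactNetwork

from conftest import nonempty_subsets, random_net

SQRT2 = math.sqrt(2.0)


def single_node_net():
    import scipy.sparse as sp

    return ContactNetwork(weights=sp.csr_array((1, 1), dtype=float), recovery=np.ones(1))


class TestStateSpace:
    def test_bijection(self):
        sp_ = SISStateSpace(4)
        seen = set()
        for idx in range(sp_.size):
            s = sp_.subset(idx)
            assert sp_.index(s) == idx
            seen.add(s)
        assert len(seen) == 15

    def test_full_set_is_last(self):
        sp_ = SISStateSpace(3)
        assert sp_.index(range(3)) == sp_.size - 1

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            SISStateSpace(3).index([])


class TestSubGenerator:
    def test_single_node(self):
        sub = build_subgenerator(single_node_net())
        assert np.allclose(sub.Q.toarray(), [[-1.0]])
        assert sub.exit == pytest.approx([1.0])

    def test_two_node_symmetric(self, two_node_symmetric):
        sub = build_subgenerator(two_node_symmetric)
        expected = np.array([[-2, 0, 1], [0, -2, 1], [1, 1, -2]], dtype=float)
        assert np.allclose(sub.Q.toarray(), expected)
        assert np.allclose(sub.exit, [1, 1, 0])

    def test_two_node_asymmetric(self, two_node_asymmetric):
        sub = build_subgenerator(two_node_asymmetric)
        expected = np.array([[-3, 0, 2], [0, -2, 1], [1, 1, -2]], dtype=float)
        assert np.allclose(sub.Q.toarray(), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_exit_structure(self, seed):
        net = random_net(5, seed, recovery=(0.5, 2.0))
        sub = build_subgenerator(net)
        rowsum = np.asarray(sub.Q.sum(axis=1)).ravel()
        assert np.allclose(rowsum + sub.exit, 0.0, atol=1e-12)
        # exit possible exactly from singleton states
        singletons = {(1 << i) - 1 for i in range(net.n)}
        for s in range(sub.size):
            if s in singletons:
                assert sub.exit[s] > 0
            else:
                assert sub.exit[s] == 0

    def test_rejects_disconnected(self):
        import scipy.sparse as sp

        net = ContactNetwork(
            weights=sp.csr_array(np.array([[0.0, 1.0], [0.0, 0.0]])),
            recovery=np.ones(2),
        )
        with pytest.raises(ValueError, match="strongly connected"):
            build_subgenerator(net)

    def test_population_cap(self):
        net = random_net(13, 0)
        with pytest.raises(ValueError, match="cap"):
            build_subgenerator(net)


class TestQSD:
    def test_single_node_trivial(self):
        res = compute_qsd(build_subgenerator(single_node_net()))
        assert res.alpha == pytest.approx(1.0, abs=1e-12)
        assert res.nu == pytest.approx([1.0])
        assert res.w == pytest.approx([1.0])

    def test_two_node_closed_form(self, two_node_symmetric):
        res = compute_qsd(build_subgenerator(two_node_symmetric))
        a = 1 / (2 + SQRT2)
        assert res.alpha == pytest.approx(2 - SQRT2, abs=1e-10)
        assert res.nu == pytest.approx([a, a, SQRT2 * a], abs=1e-10)
        assert res.w == pytest.approx([1 / SQRT2, 1 / SQRT2, 1.0], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigen_invariants(self, seed):
        net = random_net(5, seed, recovery=(0.5, 2.0))
        sub = build_subgenerator(net)
        res = compute_qsd(sub)
        assert res.nu.sum() == pytest.approx(1.0, abs=1e-12)
        assert (res.nu > 0).all() and (res.w > 0).all()
        assert res.w[-1] == 1.0
        assert np.abs(res.nu @ sub.Q.toarray() + res.alpha * res.nu).max() < 1e-10
        assert np.abs(sub.Q @ res.w + res.alpha * res.w).max() < 1e-10

    def test_alpha_is_simple(self):
        net = random_net(4, 11)
        sub = build_subgenerator(net)
        lam = np.linalg.eigvals(sub.Q.toarray())
        lam = np.sort(lam.real)[::-1]
        assert lam[0] - lam[1] > 1e-8  # spectral gap

    def test_dense_and_sparse_solvers_agree(self):
        net = random_net(8, 2)
        sub = build_subgenerator(net)
        l_dense, vl_d, vr_d = _dominant_pair(sub.Q, dense_threshold=300)
        l_sparse, vl_s, vr_s = _dominant_pair(sub.Q, dense_threshold=10)
        assert l_dense == pytest.approx(l_sparse, abs=1e-10)
        for a, b in ((vl_d, vl_s), (vr_d, vr_s)):
            a = a / a.sum()
            b = b / b.sum()
            assert np.abs(a - b).max() < 1e-9


class TestEventProbability:
    def test_whole_population_has_probability_one(self):
        net = random_net(4, 3)
        res = compute_qsd(build_subgenerator(net))
        assert qsd_event_probability(res, range(4)) == pytest.approx(1.0, abs=1e-12)

    def test_two_node_marginal(self, two_node_symmetric):
        res = compute_qsd(build_subgenerator(two_node_symmetric))
        assert qsd_event_probability(res, {0}) == pytest.approx(SQRT2 / 2, abs=1e-10)

    def test_empty_subset_rejected(self, two_node_symmetric):
        res = compute_qsd(build_subgenerator(two_node_symmetric))
        with pytest.raises(ValueError):
            qsd_event_probability(res, [])


class TestInvasion:
    def test_full_set_certain(self):
        net = random_net(5, 4)
        res = compute_qsd(build_subgenerator(net))
        assert invasion_probability_exact(res, range(5)) == pytest.approx(1.0)

    def test_single_node_case(self):
        res = compute_qsd(build_subgenerator(single_node_net()))
        assert invasion_probability_exact(res, {0}) == pytest.approx(1.0)

    def test_two_node_closed_form(self, two_node_symmetric):
        res = compute_qsd(build_subgenerator(two_node_symmetric))
        assert invasion_probability_exact(res, {0}) == pytest.approx(
            SQRT2 / 2, abs=1e-10
        )

    def test_values_in_unit_interval(self):
        net = random_net(5, 9, recovery=(0.5, 2.0))
        res = compute_qsd(build_subgenerator(net))
        for A in nonempty_subsets(5):
            v = invasion_probability_exact(res, A)
            assert 0 < v <= 1 + 1e-12


class TestTransientProbability:
    def test_time_zero_initial_condition(self, two_node_symmetric):
        assert transient_event_probability(two_node_symmetric, {0}, {0}, 0.0) == 1.0
        assert transient_event_probability(two_node_symmetric, {0}, {1}, 0.0) == 0.0

    def test_pure_death_closed_form(self):
        net = single_node_net()
        for t in (0.5, 1.0, 2.0):
            assert transient_event_probability(net, {0}, {0}, t) == pytest.approx(
                math.exp(-t), abs=1e-10
            )

    def test_negative_time_rejected(self, two_node_symmetric):
        with pytest.raises(ValueError):
            transient_event_probability(two_node_symmetric, {0}, {0}, -1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dense_expm_oracle(self, seed):
        net = random_net(4, seed, recovery=(0.5, 2.0))
        sub = build_subgenerator(net)
        Qd = sub.Q.toarray()
        sp_ = sub.space
        for t in (0.3, 1.0, 2.5):
            P = scipy.linalg.expm(Qd * t)
            for A in ({0}, {1, 2}, set(range(4))):
                for W in ({0}, {3}, {1, 2}):
                    f = np.array(
                        [bool(sp_.mask(W) & (i + 1)) for i in range(sp_.size)],
                        dtype=float,
                    )
                    expected = P[sp_.index(A)] @ f
                    got = transient_event_probability(net, A, W, t, sub=sub)
                    assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_finite_time_duality(self, seed):
        """P_T(A at 0 -> W at t) equals P_{T^T}(W at 0 -> A at t)."""
        net = random_net(5, 100 + seed, recovery=(0.5, 2.0))
        tnet = transpose(net)
        sub, tsub = build_subgenerator(net), build_subgenerator(tnet)
        for t in (0.5, 1.0, 2.0):
            for A in ({0}, {1, 3}, {2}):
                for W in ({4}, {0, 2}):
                    lhs = transient_event_probability(net, A, W, t, sub=sub)
                    rhs = transient_event_probability(tnet, W, A, t, sub=tsub)
                    assert lhs == pytest.approx(rhs, abs=1e-10)


class TestLimits:
    def test_conditioned_prevalence_at_zero_is_one(self, two_node_symmetric):
        assert conditioned_prevalence(two_node_symmetric, {0}, 0.0) == 1.0

    def test_single_node_ratio_is_one(self):
        net = single_node_net()
        for t in (0.5, 3.0):
            assert conditioned_prevalence(net, {0}, t) == pytest.approx(1.0)
            assert survival_ratio(net, {0}, t) == pytest.approx(1.0)

    def test_conditioned_prevalence_converges_to_qsd(self, two_node_symmetric):
        got = conditioned_prevalence(two_node_symmetric, {0}, 50.0)
        assert got == pytest.approx(SQRT2 / 2, abs=1e-6)

    def test_survival_ratio_converges_to_invasion(self, two_node_symmetric):
        got = survival_ratio(two_node_symmetric, {0}, 50.0)
        assert got == pytest.approx(SQRT2 / 2, abs=1e-6)

    def test_survival_ratio_full_is_identically_one(self):
        net = random_net(4, 6)
        for t in (0.0, 1.0, 10.0):
            assert survival_ratio(net, range(4), t) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_spectral_limit_matches_finite_time_ratio(self, seed):
        """The eigenvector realisation of the survival-ratio limit agrees
        with the ratio computed at large finite time."""
        net = random_net(4, 50 + seed, recovery=(0.5, 2.0))
        sub = build_subgenerator(net)
        res = compute_qsd(sub)
        for A in ({0}, {1, 2}):
            lim = invasion_probability_exact(res, A)
            fin = survival_ratio(net, A, 60.0, sub=sub)
            assert fin == pytest.approx(lim, abs=1e-6)


class TestPrevalenceInvasionIdentity:
    @pytest.mark.parametrize("seed", range(10))
    def test_directed_identity_all_subsets(self, seed):
        """invasion(A; T) = prevalence(A; T^T) for every nonempty subset."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        net = random_net(n, 1000 + seed, recovery=(0.5, 2.0))
        res = compute_qsd(build_subgenerator(net))
        tres = compute_qsd(build_subgenerator(transpose(net)))
        for A in nonempty_subsets(n):
            inv = invasion_probability_exact(res, A)
            prev = qsd_event_probability(tres, A)
            assert abs(inv - prev) < 1e-8

    def test_alpha_equal_on_transpose(self):
        net = random_net(6, 77, recovery=(0.5, 2.0))
        a1 = compute_qsd(build_subgenerator(net)).alpha
        a2 = compute_qsd(build_subgenerator(transpose(net))).alpha
        assert a1 == pytest.approx(a2, abs=1e-10)
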