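"""Rate estimation, time calibration, BM covariance, phylogenetic signal and
ancestral states."""

import numpy as np
import pytest

from otomorph.phylo import (
    RateEstimates,
    ancestral_states_bm,
    blomberg_k_mult,
    bm_covariance,
    consensus_tree,
    estimate_rates,
    time_calibrate,
)
from otomorph.types import EstimationError, OccurrenceRecord, ValidationError
from tests.conftest import make_timetree


class TestRates:
    def test_recovers_exponential_extinction_rate(self):
        rng = np.random.default_rng(1)
        durations = rng.exponential(scale=2.0, size=500)  # q = 0.5
        est = estimate_rates(durations, interval_length=0.01)
        assert abs(est.extinction_rate - 0.5) / 0.5 < 0.15

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(scale=3.0, size=200) + 0.5
        a = estimate_rates(d, interval_length=0.01)
        b = estimate_rates(2 * d, interval_length=0.01)
        assert b.extinction_rate == pytest.approx(a.extinction_rate / 2.0, rel=1e-9)

    def test_speciation_equals_extinction(self):
        est = estimate_rates([1.0, 2.0, 3.0, 0.5])
        assert est.speciation_rate == est.extinction_rate

    def test_all_zero_durations_error(self):
        with pytest.raises(EstimationError):
            estimate_rates([0.0, 0.0, 0.0])


class TestTimeCalibrate:
    @pytest.fixture()
    def fixture(self):
        tt = make_timetree("((A:1,B:1):1,(C:1,D:1):1);")
        occ = [
            OccurrenceRecord("A", 80.0, 70.0),
            OccurrenceRecord("B", 70.0, 60.0),
            OccurrenceRecord("C", 50.0, 40.0),
            OccurrenceRecord("D", 10.0, 0.0),
        ]
        return tt.tree, occ

    def test_stratigraphic_consistency(self, fixture):
        topo, occ = fixture
        rates = RateEstimates(sampling_rate=0.5, extinction_rate=0.2)
        for tt in time_calibrate(topo, occ, rates, n_trees=10, seed=0):
            tt.validate()
            assert tt.root_age >= 80.0
            ages = tt.node_ages()
            for nd in tt.tree.preorder_node_iter():
                for ch in nd.child_nodes():
                    assert ages[nd] >= ages[ch] - 1e-9

    def test_dense_sampling_shrinks_extensions(self, fixture):
        topo, occ = fixture
        lo = time_calibrate(topo, occ, RateEstimates(0.01, 0.2), n_trees=40, seed=1)
        hi = time_calibrate(topo, occ, RateEstimates(100.0, 0.2), n_trees=40, seed=1)
        mean_lo = np.mean([t.root_age for t in lo])
        mean_hi = np.mean([t.root_age for t in hi])
        assert mean_hi < mean_lo
        assert mean_hi == pytest.approx(80.0, abs=0.5)  # collapses to oldest FAD

    def test_seed_determinism(self, fixture):
        topo, occ = fixture
        rates = RateEstimates(0.5, 0.2)
        a = time_calibrate(topo, occ, rates, n_trees=5, seed=42)
        b = time_calibrate(topo, occ, rates, n_trees=5, seed=42)
        for x, y in zip(a, b):
            assert x.node_depths().keys() is not None
            assert np.allclose(
                sorted(v for v in x.node_ages().values()),
                sorted(v for v in y.node_ages().values()),
            )

    def test_missing_occurrence_errors(self, fixture):
        topo, occ = fixture
        with pytest.raises(ValidationError):
            time_calibrate(topo, occ[:-1], RateEstimates(0.5, 0.2), n_trees=1, seed=0)

    def test_fossil_tips_break_ultrametricity(self, fixture):
        topo, occ = fixture
        tt = time_calibrate(topo, occ, RateEstimates(0.5, 0.2), n_trees=1, seed=0)[0]
        assert not tt.is_ultrametric()


class TestConsensus:
    def test_identical_trees_are_returned(self, small_timetree):
        trees = [small_timetree] * 5
        cons = consensus_tree(trees)
        assert cons.root_age == pytest.approx(small_timetree.root_age)

    def test_two_tip_mean_root_age(self):
        a = make_timetree("(A:80,B:80);", tip_ages={"A": 0.0, "B": 0.0})
        b = make_timetree("(A:100,B:100);", tip_ages={"A": 0.0, "B": 0.0})
        cons = consensus_tree([a, b])
        assert cons.root_age == pytest.approx(90.0)

    def test_mean_node_ages_match_bruteforce(self, sim_tree20):
        tt, occ = sim_tree20
        rates = RateEstimates(0.5, 0.2)
        trees = time_calibrate(tt.tree, occ, rates, n_trees=8, seed=5)
        cons = consensus_tree(trees)
        # brute-force: average ages per clade key
        from otomorph.phylo import _clade_key

        acc = {}
        for t in trees:
            for nd, age in t.node_ages().items():
                acc.setdefault(_clade_key(nd), []).append(age)
        cons_ages = {_clade_key(nd): a for nd, a in cons.node_ages().items()}
        for k, ages in acc.items():
            assert cons_ages[k] == pytest.approx(np.mean(ages), abs=1e-9)


class TestBMCovariance:
    def test_star_tree(self):
        tt = make_timetree("(A:5,B:5,C:5);", tip_ages={"A": 0, "B": 0, "C": 0})
        C = bm_covariance(tt)
        assert np.allclose(C, 5.0 * np.eye(3))

    def test_two_tip(self):
        tt = make_timetree("(A:7,B:7);", tip_ages={"A": 0, "B": 0})
        assert np.allclose(bm_covariance(tt), 7.0 * np.eye(2))

    def test_balanced_tree_matches_path_enumeration(self, small_timetree):
        C = bm_covariance(small_timetree)
        expected = np.array(
            [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]], dtype=float
        )
        assert np.allclose(C, expected, atol=1e-12)

    def test_tip_order_permutation(self, small_timetree):
        taxa = ["D", "B", "A", "C"]
        C1 = bm_covariance(small_timetree)
        C2 = bm_covariance(small_timetree, taxa=taxa)
        ref = small_timetree.taxa
        perm = [ref.index(t) for t in taxa]
        assert np.allclose(C2, C1[np.ix_(perm, perm)])

    def test_subset_restriction(self, small_timetree):
        C = bm_covariance(small_timetree)
        Csub = bm_covariance(small_timetree, taxa=["A", "C"])
        assert np.allclose(Csub, np.array([[2.0, 0.0], [0.0, 2.0]]))


def univariate_k_oracle(x, C):
    """Direct textbook formula for Blomberg's K (univariate)."""
    n = len(x)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    d = x - a
    mse0 = d @ d / (n - 1)
    mse = d @ Cinv @ d / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


class TestBlombergK:
    def test_univariate_matches_direct_formula(self, small_timetree):
        x = np.array([1.2, 0.8, -1.4, 2.0])
        C = bm_covariance(small_timetree)
        res = blomberg_k_mult(x[:, None], small_timetree, n_perm=10, seed=0)
        assert res.K == pytest.approx(univariate_k_oracle(x, C), abs=1e-10)

    def test_invariances(self, small_timetree, rng):
        X = rng.normal(size=(4, 5))
        k0 = blomberg_k_mult(X, small_timetree, n_perm=1, seed=0).K
        k_scaled = blomberg_k_mult(3.7 * X, small_timetree, n_perm=1, seed=0).K
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        k_rot = blomberg_k_mult(X @ q, small_timetree, n_perm=1, seed=0).K
        assert k_scaled == pytest.approx(k0, rel=1e-9)
        assert k_rot == pytest.approx(k0, rel=1e-9)

    def test_p_value_bounds(self, small_timetree, rng):
        X = rng.normal(size=(4, 3))
        res = blomberg_k_mult(X, small_timetree, n_perm=99, seed=1)
        assert 1.0 / 100.0 <= res.p_value <= 1.0

    def test_constant_data_errors(self, small_timetree):
        with pytest.raises(EstimationError):
            blomberg_k_mult(np.ones((4, 2)), small_timetree, n_perm=9, seed=0)


class TestAncestralStates:
    def test_star_tree_root_is_mean(self):
        tt = make_timetree("(A:3,B:3,C:3,D:3);", tip_ages={t: 0 for t in "ABCD"})
        X = np.array([[1.0], [2.0], [3.0], [6.0]])
        anc, nodes = ancestral_states_bm(X, tt)
        assert anc.shape == (1, 1)
        assert anc[0, 0] == pytest.approx(3.0)

    def test_two_tip_closed_form(self):
        tt = make_timetree("(A:2,B:5);", tip_ages={"A": 3.0, "B": 0.0})
        x, y = 1.0, 7.0
        a, b = 2.0, 5.0
        anc, _ = ancestral_states_bm(np.array([[x], [y]]), tt)
        assert anc[0, 0] == pytest.approx((x / a + y / b) / (1 / a + 1 / b))

    def test_matches_gls_normal_equations_oracle(self):
        tt = make_timetree("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 2))
        C = bm_covariance(tt)
        Cinv = np.linalg.inv(C)
        ones = np.ones(5)
        a = (ones @ Cinv @ X) / (ones @ Cinv @ ones)
        anc, nodes = ancestral_states_bm(X, tt)
        # root estimate equals the GLS root state
        root_row = [i for i, nd in enumerate(nodes) if nd.parent_node is None][0]
        assert np.allclose(anc[root_row], a, atol=1e-10)
        # every internal estimate solves the GLS projection with the
        # tip-ancestor shared-path covariance vector
        depths = tt.node_depths()
        taxa = tt.taxa
        for i, nd in enumerate(nodes):
            leaves_below = {l.taxon.label for l in nd.leaf_iter()}
            c_v = np.zeros(5)
            for j, t in enumerate(taxa):
                # brute force MRCA of nd and tip t
                anc_chain = []
                cur = nd
                while cur is not None:
                    anc_chain.append(cur)
                    cur = cur.parent_node
                if t in leaves_below:
                    mrca = nd
                else:
                    mrca = next(
                        x for x in anc_chain
                        if t in {l.taxon.label for l in x.leaf_iter()}
                    )
                c_v[j] = depths[mrca]
            expected = a + c_v @ Cinv @ (X - a)
            assert np.allclose(anc[i], expected, atol=1e-10)
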