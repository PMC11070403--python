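import logging

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import funcsignal as fs
from funcsignal import BipartiteNetwork
from funcsignal.signal_test import CurveballSampler, _has_trade
from oracles import enumerate_fixed_margin_matrices, pearson_lower_triangle


def _dm(values, ids):
    return DistanceMatrix(np.asarray(values, float), ids=ids)


class TestMantel:
    def test_identity_is_one(self):
        d = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abc"))
        assert fs.mantel_r(d, d) == pytest.approx(1.0)

    def test_affine_invariance(self):
        d1 = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abc"))
        shifted = 3 + 2 * np.asarray(d1.data)
        np.fill_diagonal(shifted, 0.0)
        assert fs.mantel_r(d1, _dm(shifted, list("abc"))) == \
            pytest.approx(1.0)

    def test_hand_example_matches_direct_formula(self):
        a = np.zeros((4, 4))
        a[np.tril_indices(4, k=-1)] = [1, 2, 3, 4, 5, 6]
        a = a + a.T
        b = np.zeros((4, 4))
        b[np.tril_indices(4, k=-1)] = [2, 1, 4, 3, 6, 5]
        b = b + b.T
        r = fs.mantel_r(_dm(a, list("abcd")), _dm(b, list("abcd")))
        assert r == pytest.approx(pearson_lower_triangle(a, b))
        assert r == pytest.approx(0.8286, abs=5e-5)

    def test_id_mismatch_raises(self):
        d1 = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abc"))
        d2 = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abd"))
        with pytest.raises(ValueError, match="ids"):
            fs.mantel_r(d1, d2)

    def test_zero_variance_is_nan(self):
        d1 = _dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abc"))
        flat = _dm([[0, 1, 1], [1, 0, 1], [1, 1, 0]], list("abc"))
        assert np.isnan(fs.mantel_r(d1, flat))

    def test_p_floor_at_ten_thousand_permutations(self):
        assert fs.permutation_p(0, 10_000) == pytest.approx(1 / 10_001)
        assert round(fs.permutation_p(0, 10_000), 4) == 0.0001


class TestDegreePreservingNulls:
    def test_margins_preserved_in_every_sample(self):
        net = fs.generate_network(fs.generate_traits(10, seed=1, prefix="f"),
                                  fs.generate_traits(8, seed=2, prefix="h"),
                                  target_connectance=0.3, seed=3)
        ens = fs.degree_preserving_nulls(net, n_perm=50, seed=4)
        m = net.matrix()
        for null in ens.matrices:
            np.testing.assert_array_equal(null.sum(axis=1), m.sum(axis=1))
            np.testing.assert_array_equal(null.sum(axis=0), m.sum(axis=0))

    def test_two_by_two_support_is_exactly_two_states(self):
        net = BipartiteNetwork(pd.DataFrame([[1, 0], [0, 1]],
                                            index=["f0", "f1"],
                                            columns=["h0", "h1"]))
        states = enumerate_fixed_margin_matrices([1, 1], [1, 1])
        assert len(states) == 2
        ens = fs.degree_preserving_nulls(net, n_perm=200, seed=0)
        seen = {tuple(m.ravel()) for m in ens.matrices}
        assert seen == {tuple(s.ravel()) for s in states}

    def test_sampler_visits_all_enumerable_states(self):
        # complement of a 3x3 permutation matrix: margins (2,2,2)/(2,2,2)
        inc = pd.DataFrame([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                           index=["f0", "f1", "f2"],
                           columns=["h0", "h1", "h2"])
        net = BipartiteNetwork(inc)
        states = enumerate_fixed_margin_matrices([2, 2, 2], [2, 2, 2])
        assert len(states) == 6
        ens = fs.degree_preserving_nulls(net, n_perm=400, seed=1)
        seen = {tuple(m.ravel()) for m in ens.matrices}
        assert seen == {tuple(s.ravel()) for s in states}

    def test_sampling_close_to_uniform_on_enumerable_set(self):
        inc = pd.DataFrame([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                           index=["f0", "f1", "f2"],
                           columns=["h0", "h1", "h2"])
        ens = fs.degree_preserving_nulls(BipartiteNetwork(inc),
                                         n_perm=3000, seed=2)
        counts = {}
        for m in ens.matrices:
            counts[tuple(m.ravel())] = counts.get(tuple(m.ravel()), 0) + 1
        freqs = np.array(list(counts.values())) / 3000
        assert len(freqs) == 6
        # chi-square against uniform 1/6 at alpha=0.001
        chi2 = 3000 * ((freqs - 1 / 6) ** 2 / (1 / 6)).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, df=5)

    def test_degenerate_network_yields_identical_copies(self, caplog):
        # full row: the unique matrix with margins (2,1),(1,2)... use a
        # matrix with no checkerboard
        inc = pd.DataFrame([[1, 1], [0, 1]], index=["f0", "f1"],
                           columns=["h0", "h1"])
        net = BipartiteNetwork(inc)
        assert not _has_trade(net.matrix())
        with caplog.at_level(logging.WARNING):
            ens = fs.degree_preserving_nulls(net, n_perm=10, seed=0)
        assert ens.degenerate
        for m in ens.matrices:
            np.testing.assert_array_equal(m, net.matrix())

    def test_seed_reproducibility(self):
        net = fs.generate_network(fs.generate_traits(8, seed=1, prefix="f"),
                                  fs.generate_traits(8, seed=2, prefix="h"),
                                  target_connectance=0.3, seed=3)
        e1 = fs.degree_preserving_nulls(net, n_perm=20, seed=9)
        e2 = fs.degree_preserving_nulls(net, n_perm=20, seed=9)
        for a, b in zip(e1.matrices, e2.matrices):
            np.testing.assert_array_equal(a, b)


def _toy_system(seed=0):
    """4x4 network plus functional trees for both sides."""
    rng = np.random.default_rng(seed)
    inc = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1],
                        [0, 0, 1, 1]],
                       index=["f0", "f1", "f2", "f3"],
                       columns=["h0", "h1", "h2", "h3"])
    net = BipartiteNetwork(inc)
    def tree(prefix):
        d = rng.random((4, 4)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        return fs.upgma(DistanceMatrix(d, ids=[f"{prefix}{i}"
                                               for i in range(4)]))
    return net, tree("f"), tree("h")


class TestFunctionalSignalTest:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """The MC permutation p converges to the exact p computed by
        enumerating every matrix with the observed margins."""
        net, flea_tree, host_tree = _toy_system(3)
        focal = fs.patristic_distances(flea_tree)
        states = enumerate_fixed_margin_matrices(
            net.matrix().sum(axis=1), net.matrix().sum(axis=0))
        # exact p: fraction of fixed-margin matrices with r >= r_obs
        tri = np.tril_indices(4, k=-1)
        x = np.asarray(focal.filter(net.row_ids).data)
        def r_of(matrix):
            m = BipartiteNetwork(pd.DataFrame(
                matrix, index=net.row_ids, columns=net.col_ids))
            y = np.asarray(fs.partner_matrix(m, host_tree, "rows").data)
            if y[tri].std() == 0:
                return np.nan
            return np.corrcoef(x[tri], y[tri])[0, 1]
        r_obs = r_of(net.matrix())
        r_all = np.array([r_of(s) for s in states])
        exact = float(np.mean(np.isnan(r_all) | (r_all >= r_obs - 1e-12)))
        n_perm = 4000
        res = fs.functional_signal_test(net, focal, host_tree, side="rows",
                                        n_perm=n_perm, seed=11)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_value - exact) <= 2 * se + 2 / n_perm

    def test_p_value_floor_and_bounds(self):
        net, flea_tree, host_tree = _toy_system(1)
        res = fs.functional_signal_test(net, fs.patristic_distances(flea_tree),
                                        host_tree, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100
        assert -1 <= res.mantel_r <= 1

    def test_relabeling_invariance(self):
        net, flea_tree, host_tree = _toy_system(2)
        focal = fs.patristic_distances(flea_tree)
        res1 = fs.functional_signal_test(net, focal, host_tree,
                                         n_perm=200, seed=5)
        mapping = {old: f"X{old}" for old in
                   net.row_ids + net.col_ids}
        inc2 = net.incidence.copy()
        inc2.index = [mapping[i] for i in inc2.index]
        inc2.columns = [mapping[c] for c in inc2.columns]
        net2 = BipartiteNetwork(inc2)
        focal2 = DistanceMatrix(np.asarray(focal.data),
                                ids=[mapping[i] for i in focal.ids])
        host2 = host_tree.copy()
        for tip in host2.tips():
            tip.name = mapping[tip.name]
        res2 = fs.functional_signal_test(net2, focal2, host2,
                                         n_perm=200, seed=5)
        assert res1.mantel_r == pytest.approx(res2.mantel_r, abs=1e-12)
        assert res1.p_value == res2.p_value

    def test_shared_partner_set_reports_p_one(self):
        inc = pd.DataFrame([[1, 1], [1, 1], [1, 1]],
                           index=["f0", "f1", "f2"], columns=["h0", "h1"])
        net = BipartiteNetwork(inc)
        rng = np.random.default_rng(0)
        d = rng.random((3, 3)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        focal = DistanceMatrix(d, ids=["f0", "f1", "f2"])
        host_tree = fs.from_newick("(h0:1,h1:1);")
        res = fs.functional_signal_test(net, focal, host_tree, n_perm=99,
                                        seed=0)
        assert np.isnan(res.mantel_r)
        assert res.p_value == 1.0
        assert "partner set" in res.note


class TestCladeScan:
    def _system(self, n_fleas=12, seed=0):
        fleas = fs.generate_traits(n_fleas, seed=seed, prefix="f")
        hosts = fs.generate_traits(8, seed=seed + 1, prefix="h")
        net = fs.generate_network(fleas, hosts, signal_strength=2.0,
                                  target_connectance=0.25, seed=seed + 2)
        return (net, fs.functional_tree(fleas, seed=1),
                fs.functional_tree(hosts, seed=2))

    def test_root_only_scan_equals_whole_network_test(self):
        net, flea_tree, host_tree = self._system()
        results = fs.clade_signal_scan(net, flea_tree, host_tree,
                                       side="rows", min_clade_size=12,
                                       n_perm=200, seed=3)
        assert len(results) == 1
        whole = fs.functional_signal_test(
            net, fs.patristic_distances(flea_tree), host_tree,
            side="rows", n_perm=200, seed=3)
        assert results[0].n_species == len(net.row_ids)
        assert results[0].mantel_r == pytest.approx(whole.mantel_r,
                                                    abs=1e-12)
        assert results[0].p_adjusted == results[0].p_value  # m = 1

    def test_bonferroni_arithmetic(self):
        net, flea_tree, host_tree = self._system()
        results = fs.clade_signal_scan(net, flea_tree, host_tree,
                                       side="rows", min_clade_size=4,
                                       n_perm=99, seed=3)
        m = len(results)
        assert m > 1
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * m))

    def test_min_clade_size_respected(self):
        net, flea_tree, host_tree = self._system()
        results = fs.clade_signal_scan(net, flea_tree, host_tree,
                                       side="rows", min_clade_size=6,
                                       n_perm=49, seed=3)
        assert all(r.n_species >= 6 for r in results)

    def test_scan_on_host_side(self):
        net, flea_tree, host_tree = self._system()
        results = fs.clade_signal_scan(net, host_tree, flea_tree,
                                       side="cols", min_clade_size=4,
                                       n_perm=49, seed=3)
        assert results
        assert all(r.side == "cols" for r in results)
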