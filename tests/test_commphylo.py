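"""MPD, the independent-swap null, NRI, and group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phylocomm as pc
from phylocomm.commphylo import _mpd_matrix
from phylocomm.io import ValidationError


def brute_force_mpd(abund, dists, weighted):
    """O(T^2) oracle over explicit taxon pairs."""
    present = [t for t in dists.index if abund.get(t, 0) > 0]
    if len(present) < 2:
        return np.nan
    if not weighted:
        vals = [dists.loc[i, j] for i, j in itertools.combinations(present, 2)]
        return float(np.mean(vals))
    total = sum(abund[t] for t in present)
    p = {t: abund[t] / total for t in present}
    num = sum(p[i] * p[j] * dists.loc[i, j] for i, j in itertools.combinations(present, 2))
    den = sum(p[i] * p[j] for i, j in itertools.combinations(present, 2))
    return num / den


class TestCophenetic:
    def test_hand_path_sums(self, tree3):
        d = pc.cophenetic(tree3)
        assert d.loc["A", "B"] == 2
        assert d.loc["A", "C"] == 4
        assert d.loc["B", "C"] == 4
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0)

    def test_ultrametric_tips_equidistant_through_root(self):
        tree = pc.simulate_tree(16, seed=2)
        d = pc.cophenetic(tree)
        left, right = tree.skbio.children
        lt = [t.name for t in ([left] if left.is_tip() else left.tips())]
        rt = [t.name for t in ([right] if right.is_tip() else right.tips())]
        cross = d.loc[lt, rt].to_numpy()
        assert np.allclose(cross, 2.0, atol=1e-9)


class TestMpd:
    def test_unweighted_example(self, tree3):
        d = pc.cophenetic(tree3)
        val = pc.mpd(pd.Series({"A": 1, "B": 1, "C": 1}), d)
        assert val == pytest.approx(10 / 3, abs=1e-10)

    def test_weighted_example(self, tree3):
        d = pc.cophenetic(tree3)
        val = pc.mpd(pd.Series({"A": 0.5, "B": 0.25, "C": 0.25}), d, abundance_weighted=True)
        assert val == pytest.approx(3.2, abs=1e-10)

    def test_single_pair_ignores_weights(self, tree3):
        d = pc.cophenetic(tree3)
        for w in (False, True):
            assert pc.mpd(pd.Series({"A": 5, "C": 1}), d, w) == pytest.approx(4.0)

    def test_fewer_than_two_taxa_is_missing(self, tree3):
        d = pc.cophenetic(tree3)
        assert math.isnan(pc.mpd(pd.Series({"A": 3}), d))

    def test_matches_brute_force_on_30_taxon_fixture(self):
        tree = pc.simulate_tree(30, seed=8)
        d = pc.cophenetic(tree)
        rng = np.random.default_rng(8)
        mat = rng.integers(0, 20, size=(12, 30)) * (rng.random((12, 30)) < 0.4)
        for weighted in (False, True):
            fast = _mpd_matrix(mat.astype(float), d.to_numpy(), weighted)
            for i in range(12):
                abund = dict(zip(d.index, mat[i]))
                slow = brute_force_mpd(abund, d, weighted)
                if math.isnan(slow):
                    assert math.isnan(fast[i])
                else:
                    assert fast[i] == pytest.approx(slow, abs=1e-10)

    def test_weighted_equals_unweighted_for_equal_abundances(self):
        tree = pc.simulate_tree(20, seed=9)
        d = pc.cophenetic(tree)
        abund = pd.Series(0.0, index=d.index)
        abund.iloc[[1, 4, 9, 15]] = 7.0
        assert pc.mpd(abund, d, True) == pytest.approx(pc.mpd(abund, d, False), abs=1e-12)


class TestIndependentSwap:
    def test_single_checkerboard_swap(self):
        m = np.array([[5, 0], [0, 7]])
        out = pc.independent_swap(m, n_swaps=1, seed=0)
        assert out.tolist() == [[0, 5], [7, 0]]

    def test_all_positive_matrix_unchanged(self):
        m = np.ones((4, 5))
        with pytest.warns(UserWarning, match="no swappable"):
            out = pc.independent_swap(m, n_swaps=3, seed=0)
        assert np.array_equal(out, m)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_margins_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 30, size=(20, 30)) * (rng.random((20, 30)) < 0.3)
        out = pc.independent_swap(m, n_swaps=200, seed=seed)
        assert np.array_equal((out > 0).sum(0), (m > 0).sum(0))
        assert np.array_equal((out > 0).sum(1), (m > 0).sum(1))
        for i in range(m.shape[0]):
            assert sorted(out[i][out[i] > 0]) == sorted(m[i][m[i] > 0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            pc.independent_swap(np.array([[-1, 2], [3, 4]]), seed=0)


class TestNri:
    def test_null_centered_sample_has_zero_ses(self, tree3):
        """A sample whose observed MPD equals the null mean gets SES=NRI=0:
        with only one occupied pattern possible, the null is degenerate and
        flagged; with symmetric swaps the statistic is finite and small."""
        tree = pc.simulate_tree(12, seed=3)
        rng = np.random.default_rng(0)
        mat = (rng.random((8, 12)) < 0.5).astype(float)
        counts = pd.DataFrame(mat, index=[f"S{i}" for i in range(8)], columns=tree.tip_names)
        res = pc.nri(counts=counts, dists=pc.cophenetic(tree), n_null=199, n_swaps=300, seed=1)
        assert np.allclose(res["nri"].dropna(), -res["ses"].dropna(), atol=0)
        ok = res["p"].dropna()
        assert ((ok > 0) & (ok <= 1)).all()

    def test_filtered_assembly_recovers_clustering(self, neutral_sigma):
        """One hard-filtered site against a neutral pool: positive mean NRI."""
        sigma = dict(neutral_sigma, MM=0.5)
        design = pc.SyntheticDesign(
            n_taxa=64, samples_per_cell=3, controls_per_cell=0,
            tissues=("leaf",), timepoints=(1,), filtering_sigma=sigma,
            n_planted=0, baseline_log_sigma=0.0, tissue_shift_sigma=0.0, seed=11,
        )
        bundle, truth = pc.simulate_communities(design)
        res = pc.nri(bundle, n_null=49, n_swaps=500, seed=2)
        vals = res.loc[bundle.metadata["destination_site"] == "MM", "nri"].dropna()
        assert truth.expected_nri_sign["MM"] == 1
        assert vals.mean() > 0

    def test_degenerate_null_sd_flagged(self, tree3):
        counts = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["s1", "s2"], columns=["A", "B", "C"]
        )
        # 2x3 with these margins has swaps, but make a case with none:
        counts2 = pd.DataFrame(
            [[1, 1, 1], [1, 1, 1]], index=["s1", "s2"], columns=["A", "B", "C"]
        )
        with pytest.warns(UserWarning):
            res = pc.nri(counts=counts2, dists=pc.cophenetic(tree3), n_null=9, n_swaps=10, seed=0)
        assert res["ses"].isna().all()


class TestGroupTests:
    def _fake_nri(self, values_by_group):
        rows, groups = [], []
        for g, vals in values_by_group.items():
            for v in vals:
                rows.append(v)
                groups.append(g)
        idx = [f"S{i}" for i in range(len(rows))]
        res = pd.DataFrame({"nri": rows, "ses": [-v for v in rows]}, index=idx)
        return res, pd.Series(groups, index=idx)

    def test_all_zero_group_not_significant(self):
        rng = np.random.default_rng(1)
        res, groups = self._fake_nri({"a": [0.0] * 10, "b": list(rng.normal(0, 1, 10))})
        out = pc.nri_group_tests(res, groups)
        assert out.per_group.loc["a", "p_t"] > 0.9

    def test_shifted_group_detected_with_power(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            res, groups = self._fake_nri(
                {"a": rng.normal(0, 1, 15), "b": rng.normal(2, 1, 15)}
            )
            out = pc.nri_group_tests(res, groups)
            hits += out.among_p < 0.05
        assert hits >= 95

    def test_skewed_residuals_choose_kruskal(self):
        rng = np.random.default_rng(3)
        skewed = np.exp(rng.normal(0, 1.5, 40))
        res, groups = self._fake_nri({"a": skewed, "b": rng.normal(0, 1, 40)})
        out = pc.nri_group_tests(res, groups)
        assert out.among_test == "kruskal"
        assert out.shapiro_p < 0.05

    def test_singleton_group_skipped(self):
        rng = np.random.default_rng(4)
        res, groups = self._fake_nri({"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8), "c": [1.0]})
        with pytest.warns(UserWarning, match="skipped"):
            out = pc.nri_group_tests(res, groups)
        assert "c" not in out.per_group.index
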