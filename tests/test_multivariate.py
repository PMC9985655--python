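"""Distances, ordination, PERMANOVA and dispersion tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import phylocomm as pc
from phylocomm.io import ValidationError


def anova_seq_ss_oracle(X, metadata, terms):
    """Independent oracle: sequential ANOVA sums of squares summed over
    coordinate columns, via least-squares fits of cumulative designs."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    total = (Xc**2).sum()
    design = [np.ones((n, 1))]
    rss_prev = None
    out = []
    for term in terms:
        for part in [term]:
            blocks = [pd.get_dummies(metadata[p.strip()].astype(str)).to_numpy(float)
                      for p in part.split(":")]
            z = blocks[0]
            for b in blocks[1:]:
                z = np.einsum("ij,ik->ijk", z, b).reshape(n, -1)
            design.append(z)
        D = np.hstack(design)
        fit, rss, *_ = np.linalg.lstsq(D, Xc, rcond=None)
        resid = Xc - D @ fit
        rss_now = (resid**2).sum()
        prev = total if rss_prev is None else rss_prev
        out.append(prev - rss_now)
        rss_prev = rss_now
    return np.array(out), rss_prev


class TestDistances:
    def test_three_four_five(self):
        y = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        dm = pc.euclidean_distances(y)
        assert dm["a", "b"] == pytest.approx(5.0)

    def test_identical_rows_distance_zero(self):
        y = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert pc.euclidean_distances(y)["a", "b"] == 0.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        y = pd.DataFrame(rng.normal(size=(20, 4)))
        d = pc.euclidean_distances(y).data
        for i, j, k in itertools.permutations(range(20), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestPcoa:
    def test_planar_points_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        dm = pc.euclidean_distances(pd.DataFrame(pts))
        ordn = pc.pcoa(dm)
        ev = ordn.eigenvalues
        assert (ev[:2] > 1e-8).all()
        assert np.abs(ev[2:]).max() < 1e-8
        # distances between recovered coordinates reproduce the input
        rec = ordn.coordinates.to_numpy()
        d2 = pc.euclidean_distances(pd.DataFrame(rec, index=ordn.sample_ids))
        assert np.allclose(d2.data, dm.data, atol=1e-6)

    def test_identical_samples_coincide(self):
        y = pd.DataFrame([[0.0, 0], [0, 0], [1, 1]], index=list("abc"))
        ordn = pc.pcoa(pc.euclidean_distances(y))
        c = ordn.coordinates.to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-9)

    def test_non_euclidean_matrix_reports_negative_eigenvalue(self):
        # violates 4-point embeddability
        d = np.array(
            [[0, 1, 1, 1.9], [1, 0, 1, 1], [1, 1, 0, 1], [1.9, 1, 1, 0]]
        )
        ordn = pc.pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert ordn.eigenvalues.min() < -1e-8
        assert ordn.imaginary_coordinates.shape[1] >= 1

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(Exception):
            pc.pcoa(DistanceMatrix(d, ids=["a", "b"]))


class TestPermanova:
    def test_exact_two_group_example(self):
        """1-D data {0,1} vs {2,3}: F = 8 exactly; exhaustive p = 1/3."""
        y = pd.DataFrame({"b": [0.0, 1.0, 2.0, 3.0]}, index=list("wxyz"))
        md = pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=list("wxyz"))
        res = pc.permanova(pc.euclidean_distances(y), md, ["g"], n_perm=999)
        assert res.loc["g", "F"] == pytest.approx(8.0, abs=1e-10)
        assert res.loc["g", "p"] == pytest.approx(1 / 3, abs=1e-12)
        assert res.loc["g", "df"] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_ss_matches_coordinatewise_anova(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 25))
        X = rng.normal(size=(n, 3))
        md = pd.DataFrame(
            {
                "f1": rng.choice(["a", "b", "c"], n),
                "f2": rng.choice(["u", "v"], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        terms = ["f1", "f2", "f1:f2"]
        y = pd.DataFrame(X, index=md.index)
        try:
            res = pc.permanova(pc.euclidean_distances(y), md, terms, n_perm=9, seed=0)
        except ValidationError:
            return  # aliased random design: correctly refused
        ss_oracle, rss = anova_seq_ss_oracle(X, md, terms)
        for t, ss in zip(terms, ss_oracle):
            assert res.loc[t, "SumOfSquares"] == pytest.approx(ss, abs=1e-8)
        assert res.loc["Residual", "SumOfSquares"] == pytest.approx(rss, abs=1e-8)

    def test_ss_additivity_and_r2_closure(self):
        rng = np.random.default_rng(3)
        y = pd.DataFrame(rng.normal(size=(24, 5)))
        y.index = [f"S{i}" for i in range(24)]
        md = pd.DataFrame(
            {"f1": rng.choice(list("ab"), 24), "f2": rng.choice(list("uvw"), 24)},
            index=y.index,
        )
        res = pc.permanova(pc.euclidean_distances(y), md, ["f1", "f2"], n_perm=49, seed=1)
        terms_ss = res.drop(index=["Residual", "Total"])["SumOfSquares"].sum()
        assert terms_ss + res.loc["Residual", "SumOfSquares"] == pytest.approx(
            res.loc["Total", "SumOfSquares"], abs=1e-8
        )
        assert res["R2"].drop(index="Total").sum() == pytest.approx(1.0, abs=1e-10)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(size=(16, 3)), index=[f"S{i}" for i in range(16)])
        md = pd.DataFrame({"g": rng.choice(list("ab"), 16)}, index=y.index)
        dm = pc.euclidean_distances(y)
        perm = rng.permutation(16)
        y2 = y.iloc[perm]
        res1 = pc.permanova(dm, md, ["g"], n_perm=99, seed=11)
        res2 = pc.permanova(pc.euclidean_distances(y2), md, ["g"], n_perm=99, seed=11)
        assert res1.loc["g", "F"] == pytest.approx(res2.loc["g", "F"], abs=1e-10)
        assert res1.loc["g", "SumOfSquares"] == pytest.approx(
            res2.loc["g", "SumOfSquares"], abs=1e-10
        )

    def test_aliased_term_rejected(self):
        y = pd.DataFrame(np.arange(8.0)[:, None], index=[f"S{i}" for i in range(8)])
        md = pd.DataFrame(
            {"f1": list("aabbccdd"), "f2": list("aabbccdd")}, index=y.index
        )
        with pytest.raises(ValidationError, match="aliased"):
            pc.permanova(pc.euclidean_distances(y), md, ["f1", "f2"], n_perm=9)


class TestPairwise:
    def test_four_levels_give_six_comparisons(self):
        rng = np.random.default_rng(5)
        y = pd.DataFrame(rng.normal(size=(24, 3)), index=[f"S{i}" for i in range(24)])
        md = pd.DataFrame({"g": [l for l in "abcd" for _ in range(6)]}, index=y.index)
        out = pc.pairwise_permanova(pc.euclidean_distances(y), md, "g", n_perm=39, seed=0)
        assert len(out) == 6

    def test_separated_level_hits_permutation_floor(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 3))
        base[10:] += 100.0
        y = pd.DataFrame(base, index=[f"S{i}" for i in range(20)])
        md = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=y.index)
        out = pc.pairwise_permanova(pc.euclidean_distances(y), md, "g", n_perm=199, seed=0)
        assert out.loc[0, "p"] == pytest.approx(1 / 200, abs=1e-12)

    def test_small_level_skipped_with_warning(self):
        rng = np.random.default_rng(7)
        y = pd.DataFrame(rng.normal(size=(9, 2)), index=[f"S{i}" for i in range(9)])
        md = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4 + ["c"]}, index=y.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = pc.pairwise_permanova(pc.euclidean_distances(y), md, "g", n_perm=19, seed=0)
        assert len(out) == 1  # only (a, b) runs


class TestDispersion:
    def test_scaled_group_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(25, 3))
        b = rng.normal(size=(25, 3)) * 3.0
        y = pd.DataFrame(np.vstack([a, b]), index=[f"S{i}" for i in range(50)])
        groups = pd.Series(["a"] * 25 + ["b"] * 25, index=y.index)
        res = pc.dispersion_test(pc.euclidean_distances(y), groups)
        assert res.anova_p < 0.01
        assert res.distances[groups == "b"].mean() > res.distances[groups == "a"].mean()

    def test_identical_samples_zero_distances(self):
        y = pd.DataFrame(np.zeros((6, 2)), index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=y.index)
        res = pc.dispersion_test(pc.euclidean_distances(y), groups)
        assert np.allclose(res.distances, 0.0)

    def test_singleton_group_rejected(self):
        y = pd.DataFrame(np.arange(8.0).reshape(4, 2), index=list("abcd"))
        groups = pd.Series(["g1", "g1", "g1", "g2"], index=y.index)
        with pytest.raises(ValidationError):
            pc.dispersion_test(pc.euclidean_distances(y), groups)

    def test_spatial_median_runs(self):
        rng = np.random.default_rng(9)
        y = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"S{i}" for i in range(20)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=y.index)
        res = pc.dispersion_test(pc.euclidean_distances(y), groups, center="spatial_median")
        assert (res.distances >= 0).all()
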