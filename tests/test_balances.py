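"""Sparse multinomial balance selection and node characterization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import phylocomm as pc
from phylocomm.balances import (
    cv_lambda_min,
    lambda_grid,
    node_depth_test,
    sparse_multinomial_path,
    stability_select,
)
from phylocomm.io import ValidationError


def make_table(n, p, rng, index_prefix="S"):
    y = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"{index_prefix}{i}" for i in range(n)],
        columns=[f"n{j+1}" for j in range(p)],
    )
    return y


class TestPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(0)
        y = make_table(40, 10, rng)
        labels = pd.Series(["a", "b"] * 20, index=y.index)
        path = sparse_multinomial_path(y, labels)
        assert np.abs(path.coefficients[0]).max() < 1e-8  # top of the grid

    def test_perfect_separator_enters_first(self):
        rng = np.random.default_rng(1)
        y = make_table(60, 8, rng)
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=y.index)
        y["n3"] = np.where(labels == "a", -2.0, 2.0) + rng.normal(0, 0.05, 60)
        path = sparse_multinomial_path(y, labels)
        first = None
        for i in range(len(path.lambdas)):
            nz = np.abs(path.coefficients[i]).max(axis=0) > 1e-8
            if nz.any():
                first = set(np.array(path.node_labels)[nz])
                break
        assert first == {"n3"}

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        y = make_table(10, 4, rng)
        with pytest.raises(ValidationError):
            sparse_multinomial_path(y, pd.Series(["a"] * 10, index=y.index))

    def test_unpenalized_limit_matches_reference_fit(self):
        """At a negligible penalty, coefficients agree with an unpenalized
        multinomial fit (sklearn lbfgs, two classes) on a well-conditioned
        fixture."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        y = make_table(200, 3, rng)
        logits = 0.8 * y["n1"].to_numpy() - 0.5 * y["n2"].to_numpy()
        labels = pd.Series(
            np.where(rng.random(200) < 1 / (1 + np.exp(-logits)), "a", "b"), index=y.index
        )
        path = sparse_multinomial_path(y, labels, lambdas=[1e-7])
        ref = LogisticRegression(C=np.inf, max_iter=2000).fit(
            (y - y.mean()) / y.std(ddof=0), labels
        )
        # sklearn two-class coef is the "b"-vs-"a" logit; multinomial output
        # spreads it symmetrically over the two class rows
        mine = path.coefficients[0]
        contrast = (mine[1] - mine[0]) * y.std(ddof=0).to_numpy()
        assert np.allclose(contrast, ref.coef_[0], atol=0.05)


class TestStabilitySelect:
    def test_null_labels_select_little(self):
        rng = np.random.default_rng(4)
        y = make_table(60, 20, rng)
        labels = pd.Series(rng.choice(["a", "b", "c"], 60), index=y.index)
        sel = stability_select(y, labels, reps=8, folds=4, seed=0, n_lambda=15)
        assert sel.freq_overall.median() <= 0.25

    def test_fold_reduction_warns(self):
        rng = np.random.default_rng(5)
        y = make_table(12, 5, rng)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=y.index)
        with pytest.warns(UserWarning, match="reducing folds"):
            stability_select(y, labels, reps=2, folds=10, seed=0, n_lambda=8)

    def test_planted_balance_recovered(self):
        rng = np.random.default_rng(6)
        y = make_table(80, 15, rng)
        labels = pd.Series(["a", "b", "c", "d"] * 20, index=y.index)
        y["n5"] += np.where(labels == "b", 3.0, 0.0)
        sel = stability_select(y, labels, reps=6, folds=5, seed=1, n_lambda=15)
        assert sel.freq_overall["n5"] >= 0.8
        assert sel.freq_by_class.loc["n5", "b"] >= 0.8
        assert sel.mean_sign.loc["n5", "b"] == 1.0

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(7)
        y = make_table(40, 8, rng)
        labels = pd.Series(["a", "b"] * 20, index=y.index)
        y["n2"] += np.where(labels == "a", 2.0, 0.0)
        s1 = stability_select(y, labels, reps=4, folds=4, seed=3, n_lambda=10)
        s2 = stability_select(y, labels, reps=4, folds=4, seed=3, n_lambda=10)
        pd.testing.assert_series_equal(s1.freq_overall, s2.freq_overall)


class TestAnnotation:
    @pytest.fixture(scope="class")
    def annotated_tree(self):
        tree = pc.simulate_tree(24, seed=10)
        from phylocomm.synthdata import synthetic_taxonomy

        return tree, synthetic_taxonomy(tree)

    def test_cherry_node(self, annotated_tree):
        tree, tax = annotated_tree
        cherry = next(
            lab for lab in tree.internal_labels if len(tree.tips_under(lab)) == 2
        )
        ann = pc.node_annotation(cherry, tree, tax)
        assert ann["size"] == 2
        tips = tree.tips_under(cherry)
        if len(set(tax.loc[tips, "family"])) == 1:
            assert ann["taxon_rank"] in ("family", "genus", "species")

    def test_root_node_spans_all_tips(self, annotated_tree):
        tree, tax = annotated_tree
        ann = pc.node_annotation("n1", tree, tax)
        assert ann["size"] == tree.n_tips
        assert ann["taxon_rank"] == "domain"

    def test_lca_rank_scan(self):
        tree = pc.read_tree("(((A:1,B:1):1,C:2):1,D:3);")
        tax = pd.DataFrame(
            {
                "domain": ["Bacteria"] * 4,
                "phylum": ["P1"] * 4,
                "class": ["C1"] * 4,
                "order": ["O1", "O1", "O1", "O2"],
                "family": ["F1", "F1", "F2", "F3"],
                "genus": [""] * 4,
                "species": list("ABCD"),
            },
            index=list("ABCD"),
        )
        ann = pc.node_annotation("n2", tree, tax)  # tips A, B, C
        assert ann["taxon_rank"] == "order"
        assert ann["taxon_label"] == "O1"


class TestDepthTest:
    def _selection(self, tree, freqs):
        import phylocomm.balances as bal

        labels = tree.internal_labels
        f = pd.Series(freqs, index=labels)
        return bal.BalanceSelection(
            freq_overall=f,
            freq_by_class=pd.DataFrame({"a": f}),
            mean_sign=pd.DataFrame({"a": np.sign(f)}),
            reps=10,
            folds=5,
            lambda_mins=[],
            classes=["a"],
        )

    def test_cherries_only_is_less_basal(self):
        tree = pc.simulate_tree(64, seed=11)
        sizes = {lab: len(tree.tips_under(lab)) for lab in tree.internal_labels}
        freqs = [1.0 if sizes[lab] == 2 else 0.0 for lab in tree.internal_labels]
        res = node_depth_test(self._selection(tree, freqs), tree)
        assert res.direction == "less basal"
        assert res.p < 1e-6

    def test_random_subset_null_p_uniform(self):
        tree = pc.simulate_tree(48, seed=12)
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(200):
            freqs = (rng.random(len(tree.internal_labels)) < 0.3).astype(float)
            if 2 <= freqs.sum() <= len(freqs) - 2:
                pvals.append(node_depth_test(self._selection(tree, freqs), tree).p)
        pvals = np.array(pvals)
        assert 0.35 < pvals.mean() < 0.65

    def test_everything_selected_errors(self):
        tree = pc.simulate_tree(16, seed=13)
        with pytest.raises(ValidationError):
            node_depth_test(self._selection(tree, [1.0] * len(tree.internal_labels)), tree)


class TestFisher:
    def test_balanced_table(self):
        res = pc.tissue_family_overlap(
            leaf_families={"f1", "f2", "f3", "f4"},
            root_families={"f1", "f2", "f3", "f5"},
            universe={f"f{i}" for i in range(1, 9)},
        )
        assert res.table.tolist() == [[3, 1], [1, 3]]
        assert res.p == pytest.approx(34 / 70, abs=1e-10)

    def test_disjoint_sets_small_p(self):
        leaf = {f"L{i}" for i in range(5)}
        root = {f"R{i}" for i in range(5)}
        res = pc.tissue_family_overlap(leaf, root, leaf | root)
        assert res.table.tolist() == [[0, 5], [5, 0]]
        assert res.p == pytest.approx(2 / comb(10, 5), abs=1e-10)

    def test_identical_sets_associated(self):
        fams = {f"f{i}" for i in range(6)}
        universe = {f"f{i}" for i in range(30)}
        res = pc.tissue_family_overlap(fams, fams, universe)
        assert res.p < 1e-4

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            pc.tissue_family_overlap(set(), set(), set())
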