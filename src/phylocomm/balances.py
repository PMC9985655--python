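"""Discriminating balances via L1-penalized multinomial regression.

Which internal nodes of the phylogeny distinguish destination sites is
assessed with lasso-penalized multinomial logistic regression of site
labels on the balance table.  Because a single cross-validated fit is
unstable at amplicon sample sizes, the cross-validation (fresh fold
assignment, deviance curve, lambda at minimum deviance, refit) is repeated
many times (default 100) and each balance's *selection frequency* — the
fraction of repetitions in which it receives a nonzero coefficient — is
reported, per site class and overall.

Selected nodes are then characterized: clade size (descendant tips),
depth (tip count and root-to-node path length), and the most specific
taxonomic rank shared by all descendant tips; a Welch t-test asks whether
selected nodes sit closer to the tips than unselected ones, and Fisher's
exact test compares the families implicated in the two tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import PhyloTree, TAXONOMY_RANKS, ValidationError

__all__ = [
    "BalancePath",
    "sparse_multinomial_path",
    "BalanceSelection",
    "stability_select",
    "node_annotation",
    "annotate_selection",
    "NodeDepthTest",
    "node_depth_test",
    "FisherResult",
    "tissue_family_overlap",
]

_COEF_TOL = 1e-8


def _standardize(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x - mu) / sd, mu, sd


def lambda_grid(y: pd.DataFrame, labels: pd.Series, n_lambda: int = 25, ratio: float = 1e-3):
    """Log-spaced penalty grid from the smallest lambda that zeroes all
    coefficients (largest absolute score-equation gradient at the null fit)."""
    x, _, _ = _standardize(np.asarray(y, dtype=float))
    lab = pd.Series(labels).astype(str)
    classes = sorted(lab.unique())
    onehot = np.column_stack([(lab == c).to_numpy(float) for c in classes])
    p0 = onehot.mean(axis=0)
    grad = x.T @ (onehot - p0) / len(lab)
    lam_max = float(np.abs(grad).max()) * 1.05
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


@dataclass
class BalancePath:
    lambdas: np.ndarray
    classes: list
    node_labels: list
    coefficients: np.ndarray  # n_lambda x n_classes x n_nodes, original scale
    intercepts: np.ndarray  # n_lambda x n_classes


def _fit_path(x_std, lab, lambdas, tol=1e-4, max_iter=500):
    """Warm-started lasso multinomial fits along a descending-penalty path.

    sklearn's objective C * sum(loss) + |w|_1 matches the glmnet-style
    (1/n) sum(loss) + lambda |w|_1 at C = 1 / (n * lambda).
    """
    n = x_std.shape[0]
    clf = LogisticRegression(
        solver="saga", l1_ratio=1.0, warm_start=True, tol=tol, max_iter=max_iter,
        C=1.0, random_state=0,  # saga shuffles internally; pin it
    )
    coefs, intercepts = [], []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(x_std, lab)
        coef, intercept = clf.coef_, clf.intercept_
        if coef.shape[0] == 1 and len(clf.classes_) == 2:
            # binary fit returns the class-1 logit; spread it symmetrically
            # over two class rows (multinomial parameterization)
            coef = np.vstack([-coef[0] / 2.0, coef[0] / 2.0])
            intercept = np.array([-intercept[0] / 2.0, intercept[0] / 2.0])
        coefs.append(coef.copy())
        intercepts.append(intercept.copy())
    return np.array(coefs), np.array(intercepts), list(clf.classes_)


def sparse_multinomial_path(
    y: pd.DataFrame, labels, lambdas=None, n_lambda: int = 25
) -> BalancePath:
    """Coefficient paths of the penalized multinomial fit over a lambda grid.

    Predictors are standardized before penalization; coefficients are
    reported on the original balance scale.  At the top of the grid (the
    all-zero lambda) every coefficient is exactly 0.
    """
    lab = pd.Series(labels, index=y.index).astype(str)
    if lab.nunique() < 2:
        raise ValidationError("need >= 2 classes")
    sizes = lab.value_counts()
    if (sizes < 2).any():
        raise ValidationError(f"classes with < 2 samples: {sizes[sizes < 2].index.tolist()}")
    if lambdas is None:
        lambdas = lambda_grid(y, lab, n_lambda=n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    x = np.asarray(y, dtype=float)
    x_std, _, sd = _standardize(x)
    coefs, intercepts, classes = _fit_path(x_std, lab.to_numpy(), lambdas)
    coefs = coefs / sd[None, None, :]
    return BalancePath(
        lambdas=lambdas,
        classes=classes,
        node_labels=list(y.columns),
        coefficients=coefs,
        intercepts=intercepts,
    )


def _cv_deviance(x, lab, lambdas, folds, rng):
    """Held-out multinomial deviance per lambda over stratified folds."""
    classes = np.array(sorted(np.unique(lab)))
    dev = np.zeros(len(lambdas))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    for train, test in skf.split(x, lab):
        x_tr, mu, sd = _standardize(x[train])
        x_te = (x[test] - mu) / sd
        coefs, intercepts, cls = _fit_path(x_tr, lab[train], lambdas, tol=1e-3, max_iter=300)
        pos = {c: k for k, c in enumerate(cls)}
        true_idx = np.array([pos[c] for c in lab[test]])
        for i in range(len(lambdas)):
            scores = x_te @ coefs[i].T + intercepts[i]
            scores -= scores.max(axis=1, keepdims=True)
            logp = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
            dev[i] += -2.0 * logp[np.arange(len(test)), true_idx].sum()
    return dev


def cv_lambda_min(y: pd.DataFrame, labels, lambdas=None, folds: int = 10, seed=None, n_lambda: int = 25) -> float:
    """Penalty minimizing cross-validated multinomial deviance."""
    lab = pd.Series(labels, index=y.index).astype(str).to_numpy()
    if lambdas is None:
        lambdas = lambda_grid(y, lab, n_lambda=n_lambda)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dev = _cv_deviance(np.asarray(y, float), lab, np.asarray(lambdas, float), folds, rng)
    return float(np.asarray(lambdas)[int(np.argmin(dev))])


@dataclass
class BalanceSelection:
    freq_overall: pd.Series  # fraction of repetitions a node was selected for any class
    freq_by_class: pd.DataFrame  # node x class selection frequency
    mean_sign: pd.DataFrame  # node x class mean coefficient sign over selecting reps
    reps: int
    folds: int
    lambda_mins: list
    classes: list


def stability_select(
    y: pd.DataFrame,
    labels,
    reps: int = 100,
    folds: int = 10,
    seed=None,
    n_lambda: int = 25,
) -> BalanceSelection:
    """Selection frequency of each balance over repeated cross-validated fits.

    Each repetition draws a fresh stratified fold assignment, finds the
    deviance-minimizing lambda, refits on all samples at that lambda, and
    records which balances have nonzero coefficients for each class.  If
    the smallest class is smaller than ``folds`` the fold count is reduced
    with a warning.  Deterministic given ``seed``.
    """
    lab = pd.Series(labels, index=y.index).astype(str)
    if lab.nunique() < 2:
        raise ValidationError("need >= 2 classes")
    min_class = int(lab.value_counts().min())
    if min_class < 2:
        raise ValidationError("every class needs >= 2 samples")
    if folds > min_class:
        warnings.warn(f"reducing folds from {folds} to {min_class} (smallest class)")
        folds = min_class
    if folds < 2:
        raise ValidationError("degenerate folds (< 2)")
    rng = np.random.default_rng(seed)
    lambdas = lambda_grid(y, lab, n_lambda=n_lambda)
    x = np.asarray(y, dtype=float)
    x_std, _, _ = _standardize(x)
    classes = sorted(lab.unique())
    nodes = list(y.columns)
    hit = np.zeros((len(nodes), len(classes)))
    sign_sum = np.zeros((len(nodes), len(classes)))
    hit_any = np.zeros(len(nodes))
    lam_mins = []
    lab_arr = lab.to_numpy()
    for _ in range(reps):
        dev = _cv_deviance(x, lab_arr, lambdas, folds, rng)
        lam = lambdas[int(np.argmin(dev))]
        lam_mins.append(float(lam))
        coefs, _, cls = _fit_path(x_std, lab_arr, np.array([lam]))
        coef = coefs[0]  # n_classes x n_nodes (standardized scale)
        order = [cls.index(c) for c in classes]
        coef = coef[order]
        nz = np.abs(coef) > _COEF_TOL
        hit += nz.T
        sign_sum += np.sign(coef).T * nz.T
        hit_any += nz.any(axis=0)
    with np.errstate(invalid="ignore"):
        mean_sign = np.where(hit > 0, np.sign(sign_sum), 0.0)
    return BalanceSelection(
        freq_overall=pd.Series(hit_any / reps, index=nodes, name="frequency"),
        freq_by_class=pd.DataFrame(hit / reps, index=nodes, columns=classes),
        mean_sign=pd.DataFrame(mean_sign, index=nodes, columns=classes),
        reps=reps,
        folds=folds,
        lambda_mins=lam_mins,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Node characterization
# ---------------------------------------------------------------------------


def node_annotation(node: str, tree: PhyloTree, taxonomy: pd.DataFrame) -> dict:
    """Size, depth and lowest shared taxonomic rank of an internal node.

    Size and the primary depth metric are the number of descendant tips;
    the secondary depth metric is the root-to-node path length.  The taxon
    label is the most specific rank value shared (nonempty) by all
    descendant tips, else ``"mixed above domain"``.
    """
    tips = tree.tips_under(node)
    lineages = taxonomy.loc[tips]
    label, rank = "mixed above domain", None
    for r in reversed(TAXONOMY_RANKS):
        vals = lineages[r].unique()
        if len(vals) == 1 and vals[0] != "":
            label, rank = str(vals[0]), r
            break
    return {
        "node": node,
        "size": len(tips),
        "depth_tips": len(tips),
        "depth_path": tree.node_depth(node),
        "taxon_rank": rank,
        "taxon_label": label,
    }


def annotate_selection(
    selection: BalanceSelection, tree: PhyloTree, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Selection frequencies joined with per-node annotations, one row per
    node x class, sorted by overall frequency."""
    ann = pd.DataFrame(
        [node_annotation(n, tree, taxonomy) for n in selection.freq_overall.index]
    ).set_index("node")
    rows = []
    for node in selection.freq_overall.index:
        for cls in selection.classes:
            rows.append(
                {
                    "node": node,
                    "class": cls,
                    "frequency": selection.freq_by_class.loc[node, cls],
                    "frequency_overall": selection.freq_overall[node],
                    "mean_sign": selection.mean_sign.loc[node, cls],
                    **ann.loc[node].to_dict(),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["frequency_overall", "node", "class"], ascending=[False, True, True]).reset_index(drop=True)


@dataclass
class NodeDepthTest:
    metric: str
    n_selected: int
    n_unselected: int
    mean_selected: float  # mean log descendant-tip count
    mean_unselected: float
    t: float
    p: float
    direction: str  # "less basal" when selected nodes have fewer tips


def node_depth_test(selection: BalanceSelection, tree: PhyloTree, threshold: float = 0.5) -> NodeDepthTest:
    """Welch t-test of log(descendant-tip count): nodes selected at
    frequency >= threshold vs the unselected complement."""
    freq = selection.freq_overall
    sizes = np.array([len(tree.tips_under(n)) for n in freq.index], dtype=float)
    sel = freq.to_numpy() >= threshold
    if sel.sum() < 2 or (~sel).sum() < 2:
        raise ValidationError(
            "node depth test needs >= 2 selected and >= 2 unselected nodes"
        )
    a = np.log(sizes[sel])
    b = np.log(sizes[~sel])
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return NodeDepthTest(
        metric="log_descendant_tip_count",
        n_selected=int(sel.sum()),
        n_unselected=int((~sel).sum()),
        mean_selected=float(a.mean()),
        mean_unselected=float(b.mean()),
        t=float(t),
        p=float(p),
        direction="less basal" if a.mean() < b.mean() else "more basal",
    )


@dataclass
class FisherResult:
    table: np.ndarray  # [[both, leaf_only], [root_only, neither]]
    odds_ratio: float
    p: float


def tissue_family_overlap(leaf_families, root_families, universe) -> FisherResult:
    """Fisher's exact test of association between the family sets implicated
    in the two tissues, over a stated universe of candidate families."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty family universe")
    leaf = set(leaf_families) & universe
    root = set(root_families) & universe
    if (set(leaf_families) | set(root_families)) - universe:
        raise ValidationError("family sets must be subsets of the universe")
    a = len(leaf & root)
    b = len(leaf - root)
    c = len(root - leaf)
    d = len(universe - leaf - root)
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(table=table, odds_ratio=float(odds), p=float(p))
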