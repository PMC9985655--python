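"""Distance-based multivariate analysis of balance coordinates.

Implements the McArdle–Anderson trace formulation of permutational
multivariate ANOVA with sequential (Type-I) sums of squares for crossed
factor designs (e.g. destination site, origin site and their interaction),
principal coordinate analysis that reports negative eigenvalues instead of
clipping them, and a betadisper-style homogeneity-of-dispersion test with
the standard negative-axis correction of distances to group centroids.

For a distance matrix D with Gower-centered inner-product matrix
G = -(1/2) J D^2 J, the sequential sum of squares of term m with hat
matrix H_m (cumulative design up to m) is tr((H_m - H_{m-1}) G); the
pseudo-F is the usual ratio of term to residual mean squares.  P-values
come from free permutation of sample labels, with the (count+1)/(n_perm+1)
convention, or from exhaustive enumeration when the design is small enough
that all n! permutations fit in the requested budget.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "euclidean_distances",
    "Ordination",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "DispersionResult",
    "dispersion_test",
]

_RANK_TOL = 1e-8


def euclidean_distances(y: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows of a balance table."""
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("balance table contains non-finite values")
    return DistanceMatrix(squareform(pdist(arr)), ids=[str(i) for i in y.index])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """Principal coordinates with explicit negative-eigenvalue axes.

    ``coordinates`` holds the real axes (positive eigenvalues);
    ``imaginary_coordinates`` the axes of negative eigenvalues (their
    squared contribution is *subtracted* from squared distances).  Axes are
    ordered by descending eigenvalue and centered.
    """

    sample_ids: list
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    imaginary_coordinates: pd.DataFrame
    proportion_explained: np.ndarray


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> Ordination:
    """Classical metric multidimensional scaling of a distance matrix.

    Eigenvalues below ``-eig_tol * max(|eig|)`` indicate a non-Euclidean
    matrix and are reported (with coordinates on imaginary axes), never
    silently clipped.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    g = _gower_center(d**2)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = np.max(np.abs(eigval)) if eigval.size else 1.0
    cutoff = eig_tol * max(scale, 1.0)
    pos = eigval > cutoff
    neg = eigval < -cutoff
    ids = list(dm.ids)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    pos_sum = eigval[pos].sum()
    prop = np.where(eigval > 0, eigval, 0.0) / pos_sum if pos_sum > 0 else eigval * 0.0
    return Ordination(
        sample_ids=ids,
        eigenvalues=eigval,
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
        ),
        imaginary_coordinates=pd.DataFrame(
            imag, index=ids, columns=[f"PCoNeg{i+1}" for i in range(imag.shape[1])]
        ),
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _term_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Full-rank-agnostic dummy block for a main factor or ':' interaction."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        p = p.strip()
        if p not in metadata.columns:
            raise ValidationError(f"unknown factor in terms: {p!r}")
        dummies = pd.get_dummies(metadata[p].astype(str)).to_numpy(dtype=float)
        blocks.append(dummies)
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


def _orthonormal_increment(basis: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Orthonormal columns spanning the part of ``block`` outside ``basis``."""
    resid = block - basis @ (basis.T @ block)
    u, sv, _ = np.linalg.svd(resid, full_matrices=False)
    keep = sv > _RANK_TOL * max(1.0, sv[0] if sv.size else 1.0)
    return u[:, keep]


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a distance matrix on crossed factors.

    ``terms`` is an ordered list of factor names or ``a:b`` interactions;
    sums of squares are attributed in that order.  Returns a table with one
    row per term plus ``Residual`` and ``Total`` rows and columns
    ``df, SumOfSquares, R2, F, p``.  When n! <= n_perm the permutation
    distribution is enumerated exhaustively and the p-value is exact.
    """
    if isinstance(terms, str):
        terms = [terms]
    terms = list(terms)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(dm.ids)
    md = metadata.loc[ids]
    n = len(ids)
    g = _gower_center(np.asarray(dm.data, dtype=float) ** 2)

    basis = np.ones((n, 1)) / np.sqrt(n)
    term_bases = []
    for term in terms:
        q = _orthonormal_increment(basis, _term_matrix(md, term))
        if q.shape[1] == 0:
            raise ValidationError(
                f"term {term!r} is aliased with preceding terms (rank deficient)"
            )
        term_bases.append(q)
        basis = np.hstack([basis, q])

    df_terms = np.array([q.shape[1] for q in term_bases])
    df_resid = n - 1 - df_terms.sum()
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    def _term_ss(gmat):
        # tr(Q' G Q) per term: the sequential SS attributed to that term
        return np.array([float(np.sum(q * (gmat @ q))) for q in term_bases])

    ss_total = float(np.trace(g))
    ss_terms = _term_ss(g)
    ss_resid = ss_total - ss_terms.sum()
    f_obs = (ss_terms / df_terms) / (ss_resid / df_resid)

    def _perm_f(p):
        gp = g[np.ix_(p, p)]
        ss_t = _term_ss(gp)
        ss_r = ss_total - ss_t.sum()
        return (ss_t / df_terms) / (ss_r / df_resid)

    n_total = math.factorial(n) if n <= 12 else None
    if n_total is not None and n_total <= n_perm:
        count = np.zeros(len(terms))
        for p in itertools.permutations(range(n)):
            count += _perm_f(np.array(p)) >= f_obs - 1e-12
        pvals = count / n_total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            count += _perm_f(rng.permutation(n)) >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            (term, df_terms[i], ss_terms[i], ss_terms[i] / ss_total, f_obs[i], pvals[i])
        )
    rows.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["term", "df", "SumOfSquares", "R2", "F", "p"]
    ).set_index("term")
    return out


def pairwise_permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    within=None,
    n_perm: int = 999,
    seed=None,
    p_adjust: str = "BH",
) -> pd.DataFrame:
    """One-factor PERMANOVA for every unordered pair of factor levels.

    ``within=(column, level)`` restricts the comparison to samples at that
    level first (e.g. origins within one destination site).  Pairs in which
    a level has fewer than 2 samples are skipped with a warning.  Adjusted
    p-values use Benjamini–Hochberg (``BH``), ``holm`` or ``none`` across
    the family of comparisons.
    """
    if p_adjust not in ("none", "BH", "holm"):
        raise ValueError(f"unknown p_adjust: {p_adjust!r}")
    ids = list(dm.ids)
    md = metadata.loc[ids]
    if within is not None:
        col, level = within
        keep = [i for i in ids if md.loc[i, col] == level]
        dm = dm.filter(keep)
        ids = keep
        md = md.loc[ids]
    levels = sorted(md[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        sel = [i for i in ids if str(md.loc[i, factor]) in (a, b)]
        sub_md = md.loc[sel]
        sizes = sub_md[factor].astype(str).value_counts()
        if sizes.get(a, 0) < 2 or sizes.get(b, 0) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: a level has < 2 samples")
            continue
        res = permanova(
            dm.filter(sel), sub_md, [factor], n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            (a, b, res.loc[factor, "R2"], res.loc[factor, "F"], res.loc[factor, "p"])
        )
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "R2", "F", "p"])
    if len(out) and p_adjust != "none":
        method = {"BH": "fdr_bh", "holm": "holm"}[p_adjust]
        out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    else:
        out["p_adjusted"] = out["p"] if len(out) else []
    return out


# ---------------------------------------------------------------------------
# Dispersion (betadisper-style)
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to its group center
    groups: pd.Series
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise group contrasts on the distances
    center: str


def _corrected_distance(real_diff, imag_diff):
    """Squared real-axis distance minus imaginary-axis contribution,
    clipped at zero before the square root (standard correction for
    non-Euclidean distance matrices)."""
    d2 = (real_diff**2).sum(axis=1) - (imag_diff**2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def dispersion_test(
    dm: DistanceMatrix, groups: pd.Series, center: str = "centroid"
) -> DispersionResult:
    """Homogeneity of group dispersions: distances to group centers in
    principal-coordinate space, one-way ANOVA on the distances, Tukey HSD
    pairwise contrasts.

    ``center='spatial_median'`` uses the geometric median of the real-axis
    coordinates (Weiszfeld iteration); the negative-axis correction is then
    taken around the imaginary-axis centroid.
    """
    if center not in ("centroid", "spatial_median"):
        raise ValueError(f"unknown center: {center!r}")
    ord_ = pcoa(dm)
    groups = groups.loc[ord_.sample_ids].astype(str)
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValidationError(f"groups of size 1 not allowed: {small}")
    if len(counts) < 2:
        raise ValidationError("dispersion test needs >= 2 groups")
    real = ord_.coordinates.to_numpy()
    imag = ord_.imaginary_coordinates.to_numpy()
    dist = pd.Series(np.nan, index=ord_.sample_ids, name="distance_to_center")
    for level, idx in groups.groupby(groups).groups.items():
        pos = [ord_.sample_ids.index(i) for i in idx]
        r = real[pos]
        m = imag[pos]
        if center == "centroid":
            rc = r.mean(axis=0)
        else:
            rc = _geometric_median(r)
        mc = m.mean(axis=0) if m.size else np.zeros(m.shape[1])
        dist.iloc[pos] = _corrected_distance(r - rc, m - mc)
    by_group = [dist[groups == lv].to_numpy() for lv in counts.index]
    if all(np.allclose(v, 0) for v in by_group):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*by_group)
    tukey = _tukey_hsd(dist, groups)
    return DispersionResult(
        distances=dist,
        groups=groups,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
        center=center,
    )


def _geometric_median(x: np.ndarray, n_iter: int = 256, tol: float = 1e-10) -> np.ndarray:
    m = x.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(x - m, axis=1)
        if np.any(d < tol):
            return m
        w = 1.0 / d
        new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def _tukey_hsd(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    levels = sorted(groups.unique())
    samples = [values[groups == lv].to_numpy() for lv in levels]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append(
            (
                levels[i],
                levels[j],
                samples[i].mean() - samples[j].mean(),
                res.pvalue[i, j],
            )
        )
    return pd.DataFrame(rows, columns=["level_a", "level_b", "mean_diff", "p_adjusted"])
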