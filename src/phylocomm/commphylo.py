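"""Community phylogenetics: MPD, independent-swap null model, and NRI.

The mean pairwise distance (MPD) of a sample is the average patristic
distance among all pairs of taxa present in it; the abundance-weighted
form weights each pair by the product of relative abundances.  The null
model is the independent swap: repeated exchanges of 2x2 checkerboard
submatrices of the community matrix, which preserve per-sample richness
and per-taxon occurrence frequency exactly.  The standardized effect size
SES = (MPD_obs - mean(MPD_null)) / sd(MPD_null); the net relatedness index
NRI = -SES, so positive NRI means phylogenetic clustering (environmental
filtering) and negative NRI overdispersion.

Group-level inference follows the field convention: a one-sample t-test
of NRI against zero per site x timepoint group, and an among-group ANOVA
on SES when its residuals pass a Shapiro–Wilk normality gate, otherwise
Kruskal–Wallis; post-hoc pairwise tests on the chosen scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnalysisBundle, PhyloTree, ValidationError

__all__ = [
    "cophenetic",
    "mpd",
    "independent_swap",
    "nri",
    "NriGroupTests",
    "nri_group_tests",
]


def cophenetic(tree: PhyloTree) -> pd.DataFrame:
    """Patristic (path-length) distances between all tip pairs."""
    dm = tree.skbio.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def _mpd_matrix(abund: np.ndarray, d: np.ndarray, weighted: bool) -> np.ndarray:
    """MPD for every row of a samples x taxa abundance matrix.

    Both forms reduce to p' D p / (1 - sum p^2) with p the relative
    abundances (weighted) or the uniform distribution on present taxa
    (unweighted) — the unordered-pair mean in the unweighted case.
    """
    a = np.asarray(abund, dtype=float)
    if weighted:
        w = a
    else:
        w = (a > 0).astype(float)
    tot = w.sum(axis=1, keepdims=True)
    present = (a > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, w / np.where(tot == 0, 1.0, tot), 0.0)
        num = np.einsum("it,ts,is->i", p, d, p)
        den = 1.0 - (p**2).sum(axis=1)
        out = num / den
    out[present < 2] = np.nan
    return out


def mpd(abundances, dists: pd.DataFrame, abundance_weighted: bool = False) -> float:
    """Mean pairwise phylogenetic distance of one sample.

    Returns NaN (flagged missing) when fewer than 2 taxa are present.
    """
    if isinstance(abundances, pd.Series):
        abundances = abundances.reindex(dists.index).fillna(0.0)
        vec = abundances.to_numpy(dtype=float)
    else:
        vec = np.asarray(abundances, dtype=float)
        if vec.shape[0] != dists.shape[0]:
            raise ValidationError("abundance vector does not match distance matrix")
    return float(_mpd_matrix(vec[None, :], dists.to_numpy(), abundance_weighted)[0])


def _has_checkerboard(m: np.ndarray) -> bool:
    pos = m > 0
    n = m.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(pos[i] & ~pos[j]) and np.any(~pos[i] & pos[j]):
                return True
    return False


def independent_swap(matrix, n_swaps: int = 1000, seed=None) -> np.ndarray:
    """Randomize a community matrix by ``n_swaps`` accepted checkerboard swaps.

    A swap finds a 2x2 submatrix with pattern (a>0, 0 / 0, b>0) and moves
    the values across the diagonal, preserving row and column nonzero
    counts exactly and the multiset of values within each row.  A matrix
    with no swappable checkerboard is returned unchanged with a warning.
    """
    m = np.array(matrix, copy=True)
    if np.any(m < 0):
        raise ValidationError("community matrix must be nonnegative")
    nr, nc = m.shape
    if nr < 2 or nc < 2:
        warnings.warn("matrix too small to swap; returned unchanged")
        return m
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    done = 0
    attempts = 0
    max_attempts = 500 * n_swaps + 10_000
    batch = 4096
    while done < n_swaps:
        if attempts >= max_attempts:
            if not _has_checkerboard(m):
                warnings.warn("no swappable checkerboard; matrix returned unchanged")
                return np.array(matrix, copy=True)
            max_attempts *= 2  # checkerboards exist but are rare; keep going
        r = rng.integers(0, nr, size=(batch, 2))
        c = rng.integers(0, nc, size=(batch, 2))
        for k in range(batch):
            r1, r2 = r[k]
            c1, c2 = c[k]
            if r1 == r2 or c1 == c2:
                continue
            attempts += 1
            a = m[r1, c1]
            b = m[r2, c2]
            if a > 0 and b > 0 and m[r1, c2] == 0 and m[r2, c1] == 0:
                m[r1, c2] = a
                m[r2, c1] = b
                m[r1, c1] = 0
                m[r2, c2] = 0
                done += 1
                if done >= n_swaps:
                    break
    return m


def nri(
    bundle: AnalysisBundle = None,
    *,
    counts: pd.DataFrame = None,
    dists: pd.DataFrame = None,
    abundance_weighted: bool = True,
    n_null: int = 999,
    n_swaps: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Per-sample NRI against an independent-swap null.

    Each of the ``n_null`` null matrices is generated from the observed
    community matrix by ``n_swaps`` accepted swaps (the whole matrix is
    randomized at once, so sample richness and taxon occurrence frequency
    are held fixed across the community).  Two-sided empirical p-values use
    the rank of the observed MPD in the null distribution with the
    (count+1)/(n_null+1) convention.  Returns a table with columns
    ``mpd_obs, null_mean, null_sd, ses, nri, p``; run parameters are in
    ``DataFrame.attrs``.
    """
    if bundle is not None:
        counts = bundle.counts.values
        dists = cophenetic(bundle.tree)
    if counts is None or dists is None:
        raise ValueError("provide a bundle or counts and dists")
    dists = dists.loc[counts.columns, counts.columns]
    mat = counts.to_numpy(dtype=float)
    d = dists.to_numpy()
    rng = np.random.default_rng(seed)
    obs = _mpd_matrix(mat, d, abundance_weighted)
    null = np.empty((n_null, mat.shape[0]))
    for k in range(n_null):
        swapped = independent_swap(mat, n_swaps=n_swaps, seed=rng)
        null[k] = _mpd_matrix(swapped, d, abundance_weighted)
    null_mean = np.nanmean(null, axis=0)
    null_sd = np.nanstd(null, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (obs - null_mean) / null_sd
    degenerate = null_sd <= 1e-12 * np.maximum(1.0, np.abs(null_mean))
    ses[degenerate] = np.nan  # degenerate null: SES undefined
    lo = (null <= obs[None, :]).sum(axis=0) + 1
    hi = (null >= obs[None, :]).sum(axis=0) + 1
    p = np.minimum(1.0, 2.0 * np.minimum(lo, hi) / (n_null + 1))
    out = pd.DataFrame(
        {
            "mpd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "nri": -ses,
            "p": p,
        },
        index=counts.index,
    )
    out.attrs.update(
        n_null=n_null, n_swaps=n_swaps, abundance_weighted=abundance_weighted, seed=seed
    )
    return out


@dataclass
class NriGroupTests:
    per_group: pd.DataFrame  # one-sample tests of NRI against 0
    among_test: str  # "anova" or "kruskal"
    among_statistic: float
    among_p: float
    shapiro_p: float
    posthoc: pd.DataFrame


def nri_group_tests(res: pd.DataFrame, groups: pd.Series) -> NriGroupTests:
    """Per-group one-sample tests of NRI vs 0 and an among-group comparison.

    The among-group test runs on SES: ANOVA (with Tukey HSD post hoc) when
    Shapiro–Wilk on the group-centered residuals gives p >= 0.05, otherwise
    Kruskal–Wallis (with pairwise Mann–Whitney, Benjamini–Hochberg).
    Groups with fewer than 2 finite values are skipped with a warning.
    """
    groups = groups.loc[res.index].astype(str)
    rows = []
    usable = {}
    for level in sorted(groups.unique()):
        vals = res.loc[groups == level, "nri"].dropna().to_numpy()
        if len(vals) < 2:
            warnings.warn(f"group {level!r} has < 2 samples; skipped")
            continue
        t, p_t = stats.ttest_1samp(vals, 0.0)
        if np.allclose(vals, vals[0]):
            w_p = 1.0 if np.allclose(vals, 0) else 0.0
            if np.allclose(vals, 0):
                t, p_t = 0.0, 1.0
        else:
            try:
                w_p = stats.wilcoxon(vals)[1]
            except ValueError:
                w_p = np.nan
        rows.append((level, len(vals), vals.mean(), vals.std(ddof=1), t, p_t, w_p))
        usable[level] = -vals  # SES scale for the among-group test
    per_group = pd.DataFrame(
        rows, columns=["group", "n", "mean_nri", "sd_nri", "t", "p_t", "p_wilcoxon"]
    ).set_index("group")
    if len(usable) < 2:
        raise ValidationError("among-group test needs >= 2 usable groups")
    resid = np.concatenate([v - v.mean() for v in usable.values()])
    if np.allclose(resid, 0):
        shapiro_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(resid)[1])
    levels = list(usable)
    if shapiro_p >= 0.05:
        test = "anova"
        stat, p = stats.f_oneway(*usable.values())
        hsd = stats.tukey_hsd(*usable.values())
        ph = [
            (levels[i], levels[j], hsd.pvalue[i, j])
            for i, j in itertools.combinations(range(len(levels)), 2)
        ]
        posthoc = pd.DataFrame(ph, columns=["level_a", "level_b", "p_adjusted"])
    else:
        test = "kruskal"
        stat, p = stats.kruskal(*usable.values())
        ph = []
        for i, j in itertools.combinations(range(len(levels)), 2):
            ph.append(
                (levels[i], levels[j], stats.mannwhitneyu(usable[levels[i]], usable[levels[j]])[1])
            )
        posthoc = pd.DataFrame(ph, columns=["level_a", "level_b", "p"])
        posthoc["p_adjusted"] = multipletests(posthoc["p"], method="fdr_bh")[1]
    return NriGroupTests(
        per_group=per_group,
        among_test=test,
        among_statistic=float(stat),
        among_p=float(p),
        shapiro_p=shapiro_p,
        posthoc=posthoc,
    )
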