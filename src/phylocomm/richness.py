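"""Repeated-rarefaction ASV richness and negative-binomial modelling.

Richness per sample is the number of taxa observed in a without-replacement
subsample of fixed depth (default 1980 reads), averaged over repeated draws
(default 200).  Differences in mean richness among groups are modelled with
a negative-binomial GLM (log link) whose dispersion is profiled out by
maximum likelihood; the mean richness is rounded to the nearest integer for
the count likelihood.  Per-term Wald tests and all pairwise level contrasts
(single-step max-|z| adjustment, Tukey-style) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .io import CountTable, ValidationError

__all__ = ["rarefied_richness", "NBRichnessModel", "nb_richness_model"]


def rarefied_richness(
    counts: CountTable,
    depth: int = 1980,
    reps: int = 200,
    seed=None,
    strict: bool = False,
) -> pd.DataFrame:
    """Mean observed-taxon richness over repeated rarefactions.

    Each repetition draws exactly ``depth`` reads without replacement
    (multivariate hypergeometric) and counts taxa with >= 1 read.  Samples
    shallower than ``depth`` are dropped with a warning (or raise under
    ``strict``).  Returns a table with ``mean_richness``, ``se``, ``reps``
    and ``depth`` per retained sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    df = counts.values
    totals = df.sum(axis=1)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        if strict:
            raise ValidationError(f"samples shallower than depth {depth}: {shallow}")
        warnings.warn(
            f"dropping {len(shallow)} samples shallower than depth {depth}: {shallow}"
        )
    rows = []
    for sample in df.index:
        if sample in shallow:
            continue
        vec = df.loc[sample].to_numpy()
        draws = rng.multivariate_hypergeometric(vec, depth, size=reps)
        rich = (draws > 0).sum(axis=1)
        se = rich.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
        rows.append((sample, rich.mean(), se))
    if not rows:
        raise ValidationError("no samples deep enough to rarefy")
    out = pd.DataFrame(rows, columns=["sample_id", "mean_richness", "se"]).set_index(
        "sample_id"
    )
    out["reps"] = reps
    out["depth"] = depth
    return out


@dataclass
class NBRichnessModel:
    params: pd.Series
    alpha: float  # NB dispersion (variance = mu + alpha mu^2)
    loglik: float
    term_tests: pd.DataFrame  # per-term Wald chi-square tests
    contrasts: pd.DataFrame  # pairwise level contrasts per factor
    design_columns: list


def _design(metadata: pd.DataFrame, terms) -> tuple[np.ndarray, list, dict]:
    """Treatment-coded design matrix for main effects and ':' interactions."""
    cols = [np.ones(len(metadata))]
    names = ["Intercept"]
    term_cols: dict = {}
    level_cols: dict = {}
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        blocks, blocknames = [], []
        for p in parts:
            if p not in metadata.columns:
                raise ValidationError(f"unknown factor in terms: {p!r}")
            f = metadata[p].astype(str)
            levels = sorted(f.unique())
            if len(levels) < 2:
                raise ValidationError(f"factor {p!r} has < 2 levels")
            d = pd.get_dummies(f)[levels[1:]]  # drop first level (reference)
            blocks.append(d.to_numpy(dtype=float))
            blocknames.append([f"{p}[{lv}]" for lv in levels[1:]])
            if ":" not in term:
                level_cols[p] = levels
        x = blocks[0]
        nm = blocknames[0]
        for b, bn in zip(blocks[1:], blocknames[1:]):
            x = np.einsum("ij,ik->ijk", x, b).reshape(len(metadata), -1)
            nm = [f"{a}:{c}" for a in nm for c in bn]
        term_cols[term] = list(range(len(names), len(names) + x.shape[1]))
        cols.append(x)
        names.extend(nm)
    X = np.column_stack(cols)
    return X, names, {"terms": term_cols, "levels": level_cols}


def _nb_profile_fit(y: np.ndarray, X: np.ndarray):
    """Profile the NB2 dispersion alpha by ML over GLM fits."""

    def fit_at(alpha):
        fam = sm.families.NegativeBinomial(alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=fam).fit(maxiter=200)

    def negll(log_alpha):
        try:
            return -fit_at(np.exp(log_alpha)).llf
        except Exception:
            return np.inf

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(1e-8), np.log(1e3)), method="bounded",
        options={"xatol": 1e-6},
    )
    alpha = float(np.exp(res.x))
    fit = fit_at(alpha)
    if not np.all(np.isfinite(fit.params)):
        raise ValidationError("negative-binomial fit did not converge")
    return fit, alpha


def _single_step_adjust(z: np.ndarray, corr: np.ndarray, seed: int = 0, n_mc: int = 100_000):
    """Single-step max-|z| adjusted p-values (Tukey-style joint adjustment)
    from the multivariate-normal reference of the contrast statistics."""
    rng = np.random.default_rng(seed)
    corr = (corr + corr.T) / 2.0 + 1e-10 * np.eye(len(z))
    draws = rng.multivariate_normal(np.zeros(len(z)), corr, size=n_mc, method="cholesky")
    maxabs = np.abs(draws).max(axis=1)
    return np.array([(maxabs >= abs(zi)).mean() for zi in z])


def nb_richness_model(
    richness: pd.DataFrame,
    metadata: pd.DataFrame,
    terms,
    seed: int = 0,
) -> NBRichnessModel:
    """Negative-binomial regression of mean rarefied richness on design factors.

    ``terms`` may be empty (intercept-only).  A response with zero variance
    is only accepted for the intercept-only model (there is nothing to
    contrast otherwise).
    """
    if isinstance(terms, str):
        terms = [terms]
    terms = list(terms)
    samples = list(richness.index)
    md = metadata.loc[samples]
    y = np.round(richness["mean_richness"].to_numpy()).astype(int)
    if np.ptp(y) == 0 and terms:
        raise ValidationError("richness response has zero variance")
    X, names, info = _design(md, terms)
    fit, alpha = _nb_profile_fit(y, X)
    params = pd.Series(fit.params, index=names)
    cov = np.asarray(fit.cov_params())

    term_rows = []
    for term, cols in info["terms"].items():
        sel = np.zeros((len(cols), len(names)))
        for k, c in enumerate(cols):
            sel[k, c] = 1.0
        wt = fit.wald_test(sel, scalar=True)
        term_rows.append((term, len(cols), float(wt.statistic), float(wt.pvalue)))
    term_tests = pd.DataFrame(
        term_rows, columns=["term", "df", "wald_chi2", "p"]
    ).set_index("term")

    contrast_rows = []
    rng = np.random.default_rng(seed)
    for factor, levels in info["levels"].items():
        C, pairs = [], []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                c = np.zeros(len(names))
                if i > 0:
                    c[names.index(f"{factor}[{levels[i]}]")] = 1.0
                c[names.index(f"{factor}[{levels[j]}]")] -= 1.0
                C.append(c)
                pairs.append((levels[i], levels[j]))
        C = np.array(C)
        est = C @ params.to_numpy()
        var = np.einsum("ij,jk,ik->i", C, cov, C)
        se = np.sqrt(var)
        zstat = est / se
        p_raw = 2 * stats.norm.sf(np.abs(zstat))
        vcc = C @ cov @ C.T
        corr = vcc / np.sqrt(np.outer(var, var))
        p_adj = _single_step_adjust(zstat, corr, seed=int(rng.integers(2**31)))
        for k, (a, b) in enumerate(pairs):
            contrast_rows.append(
                (factor, a, b, est[k], se[k], zstat[k], p_raw[k], p_adj[k])
            )
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["factor", "level_a", "level_b", "estimate", "se", "z", "p_raw", "p_adjusted"],
    )
    return NBRichnessModel(
        params=params,
        alpha=alpha,
        loglik=float(fit.llf),
        term_tests=term_tests,
        contrasts=contrasts,
        design_columns=names,
    )
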