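"""Canonical end-to-end validation experiments.

Each function runs one of the package's parameter-recovery or calibration
experiments from scratch — generating synthetic data, executing the method,
and measuring the result — and returns plain numbers.  They back both the
acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are scaled for a single desktop CPU: 64–128 taxa, 20–40
samples per group, 99 null draws and 20 selection repetitions (where the
full analysis defaults are 999 and 100); docs/methods.md discusses the
scaling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .balances import stability_select, tissue_family_overlap
from .commphylo import cophenetic, mpd, nri
from .io import read_tree
from .multivariate import dispersion_test, euclidean_distances, permanova
from .richness import nb_richness_model, rarefied_richness
from .synthdata import SyntheticDesign, simulate_communities
from .transform import build_balance_basis, close_with_pseudocount, philr

NEUTRAL_SIGMA = {s: math.inf for s in ("CC", "MM", "WP", "DB")}


def ilr_worked_example() -> dict:
    """Three-tip balance values plus basis/isometry errors on a random
    32-tip fixture."""
    tree3 = read_tree("((A:1,B:1):1,C:2);")
    basis3 = build_balance_basis(tree3)
    comp = pd.DataFrame([[0.5, 0.25, 0.25]], columns=["A", "B", "C"])
    y = philr(comp, basis3)

    from .synthdata import simulate_tree

    tree32 = simulate_tree(32, seed=7)
    basis = build_balance_basis(tree32)
    V = basis.V.to_numpy()
    ortho_err = float(np.abs(V.T @ V - np.eye(V.shape[1])).max())
    rng = np.random.default_rng(7)
    comps = pd.DataFrame(rng.dirichlet(np.ones(32), size=10), columns=tree32.tip_names)
    yy = philr(comps, basis).to_numpy()
    lx = np.log(comps.to_numpy())
    clr = lx - lx.mean(axis=1, keepdims=True)
    iso_err = 0.0
    for i in range(10):
        for j in range(i + 1, 10):
            iso_err = max(
                iso_err,
                abs(np.linalg.norm(yy[i] - yy[j]) - np.linalg.norm(clr[i] - clr[j])),
            )
    return {
        "balance_n1": float(y.iloc[0, 0]),
        "balance_n2": float(y.iloc[0, 1]),
        "orthonormality_error": ortho_err,
        "isometry_error": float(iso_err),
    }


def permanova_exact_example() -> dict:
    """Two groups {0,1} vs {2,3} in one dimension: F is exactly 8 and the
    exhaustive permutation p is exactly 1/3."""
    y = pd.DataFrame({"b": [0.0, 1.0, 2.0, 3.0]}, index=list("wxyz"))
    md = pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=y.index)
    res = permanova(euclidean_distances(y), md, ["g"], n_perm=999)
    return {"F": float(res.loc["g", "F"]), "p": float(res.loc["g", "p"])}


def type1_error_rates(n_sim: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rates of PERMANOVA and the dispersion test on null
    Gaussian data (two groups of 10, 199 permutations)."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(20)]
    labels = ["a"] * 10 + ["b"] * 10
    md = pd.DataFrame({"g": labels}, index=ids)
    groups = pd.Series(labels, index=ids)
    rej_perm = rej_disp = 0
    for _ in range(n_sim):
        y = pd.DataFrame(rng.normal(size=(20, 3)), index=ids)
        dm = euclidean_distances(y)
        res = permanova(dm, md, ["g"], n_perm=199, seed=int(rng.integers(2**31)))
        rej_perm += res.loc["g", "p"] <= alpha
        rej_disp += dispersion_test(dm, groups).anova_p <= alpha
    return {
        "permanova_rate": rej_perm / n_sim,
        "dispersion_rate": rej_disp / n_sim,
        "n_sim": n_sim,
    }


def mpd_worked_example() -> dict:
    tree3 = read_tree("((A:1,B:1):1,C:2);")
    d = cophenetic(tree3)
    return {
        "unweighted": mpd(pd.Series({"A": 1, "B": 1, "C": 1}), d),
        "weighted": mpd(pd.Series({"A": 0.5, "B": 0.25, "C": 0.25}), d, True),
    }


def nri_recovery(seed: int = 11, n_null: int = 99, n_swaps: int = 1000) -> dict:
    """Filtered-vs-neutral NRI experiment.

    Filtered: one site (MM) assembles under a hard trait filter
    (sigma_f = 0.5) within a pool of three neutral sites; its 20 samples
    should be phylogenetically clustered (mean NRI > 0).  Neutral: fully
    exchangeable samples; the group mean NRI should sit within 2 SE of 0.
    """
    sigma = dict(NEUTRAL_SIGMA, MM=0.5)
    design = SyntheticDesign(
        n_taxa=64, samples_per_cell=5, controls_per_cell=0,
        tissues=("leaf",), timepoints=(1,), filtering_sigma=sigma,
        n_planted=0, baseline_log_sigma=0.0, tissue_shift_sigma=0.0, seed=seed,
    )
    bundle, _ = simulate_communities(design)
    res = nri(bundle, n_null=n_null, n_swaps=n_swaps, seed=seed + 100)
    vals = res.loc[bundle.metadata["destination_site"] == "MM", "nri"].dropna()
    t_stat, p_one = stats.ttest_1samp(vals, 0.0)

    design0 = SyntheticDesign(
        n_taxa=64, samples_per_cell=5, controls_per_cell=0,
        tissues=("leaf",), timepoints=(1,), filtering_sigma=dict(NEUTRAL_SIGMA),
        n_planted=0, baseline_log_sigma=0.0, tissue_shift_sigma=0.0, seed=seed + 1,
    )
    bundle0, _ = simulate_communities(design0)
    sub = bundle0.counts.values.iloc[:20]
    res0 = nri(counts=sub, dists=cophenetic(bundle0.tree), n_null=n_null,
               n_swaps=n_swaps, seed=seed + 101)
    v0 = res0["nri"].dropna()
    return {
        "filtered_mean_nri": float(vals.mean()),
        "filtered_p": float(p_one),
        "filtered_n": int(len(vals)),
        "neutral_mean_nri": float(v0.mean()),
        "neutral_se": float(v0.std(ddof=1) / np.sqrt(len(v0))),
        "neutral_n": int(len(v0)),
    }


def planted_balance_recovery(seed: int = 21, reps: int = 20, folds: int = 10) -> dict:
    """128-tip tree, 4 sites x 40 samples, 3 planted clades at fold-change 4:
    selection frequency of planted vs other balances."""
    design = SyntheticDesign(
        n_taxa=128, samples_per_cell=10, controls_per_cell=0,
        tissues=("leaf",), timepoints=(1,), filtering_sigma=dict(NEUTRAL_SIGMA),
        seed=seed,
    )
    bundle, truth = simulate_communities(design)
    basis = build_balance_basis(bundle.tree)
    y = philr(close_with_pseudocount(bundle.counts), basis)
    sel = stability_select(
        y, bundle.metadata["destination_site"], reps=reps, folds=folds, seed=seed + 50
    )
    planted = list(truth.planted_nodes)
    others = sel.freq_overall.drop(planted)
    return {
        "planted_min_frequency": float(sel.freq_overall[planted].min()),
        "others_median_frequency": float(others.median()),
        "planted_nodes": planted,
        "n_samples": int(len(y)),
        "reps": reps,
    }


def closed_form_checks(seed: int = 1) -> dict:
    """Rarefaction vs its hypergeometric expectation, the Fisher exact
    worked table, and the NB intercept on constant data."""
    from .io import CountTable

    counts = CountTable(pd.DataFrame([[2, 2]], index=["S0"], columns=["A", "B"]))
    reps = 20000
    rar = rarefied_richness(counts, depth=2, reps=reps, seed=seed)
    rich = pd.DataFrame(
        {"mean_richness": [10.0] * 12, "se": 0.0, "reps": 1, "depth": 1},
        index=pd.Index([f"S{i}" for i in range(12)], name="sample_id"),
    )
    nb = nb_richness_model(rich, pd.DataFrame(index=rich.index), [])
    fisher = tissue_family_overlap(
        {"f1", "f2", "f3", "f4"}, {"f1", "f2", "f3", "f5"},
        {f"f{i}" for i in range(1, 9)},
    )
    return {
        "rarefied_mean": float(rar.loc["S0", "mean_richness"]),
        "rarefied_expected": 5 / 3,
        "rarefied_mc_se": float(np.sqrt((5 / 6) * (1 / 6) / reps)),
        "fisher_p": fisher.p,
        "nb_intercept": float(nb.params["Intercept"]),
    }


def synthetic_study(seed: int = 0, n_perm: int = 199) -> dict:
    """Scaled end-to-end synthetic transplant study under the standing
    design: destination/origin PERMANOVA on leaf balances at month one
    plus the origin effect at month three (the fading-origin contrast)."""
    design = SyntheticDesign(n_taxa=64, samples_per_cell=6, controls_per_cell=0, seed=seed)
    bundle, _ = simulate_communities(design)
    basis = build_balance_basis(bundle.tree)
    y = philr(close_with_pseudocount(bundle.counts), basis)
    md = bundle.metadata
    out = {}
    for tp in (1, 3):
        ids = md.index[(md["tissue"] == "leaf") & (md["timepoint"] == tp)]
        res = permanova(
            euclidean_distances(y.loc[ids]), md.loc[ids],
            ["destination_site", "origin_site"], n_perm=n_perm, seed=seed + tp,
        )
        out[f"destination_R2_month{tp}"] = float(res.loc["destination_site", "R2"])
        out[f"destination_p_month{tp}"] = float(res.loc["destination_site", "p"])
        out[f"origin_R2_month{tp}"] = float(res.loc["origin_site", "R2"])
        out[f"origin_p_month{tp}"] = float(res.loc["origin_site", "p"])
    out["n_samples_per_stratum"] = int(len(ids))
    return out
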