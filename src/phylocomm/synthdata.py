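"""Synthetic communities with known structure for end-to-end testing.

The generator emulates the reciprocal-transplant design the pipeline is
built for: four sites (CC, MM, WP, DB) crossed as origins and destinations,
three monthly timepoints, two tissues (leaf, root), plus back-transplant
controls.  Ground truth is planted at three levels so every downstream
stage has a recovery target:

* **Phylogenetic clustering** — a Brownian "environmental tolerance" trait
  on an ultrametric Yule tree; each site has a one-dimensional optimum and
  a filtering strength sigma_f, and taxa enter a sample with probability
  proportional to a Gaussian kernel of trait distance to the destination
  optimum.  Small sigma_f concentrates occupancy in clades near the
  optimum (positive NRI); sigma_f = inf recovers neutral assembly.
* **Differential clades** — selected internal nodes whose descendant tips
  get a multiplicative fold-change at one destination site; these are the
  balances the lasso stage should re-discover.
* **Origin memory** — each origin's fold-change pattern applied attenuated
  as fold^(decay^timepoint), so the origin signal fades over months, like
  the transplant experiment's fading origin effect.

Relative abundances are Dirichlet around a shared (tissue-shifted)
log-normal baseline; reads are multinomial at a log-normal depth within
bounds, mirroring amplicon libraries' uneven depths.  Everything is
deterministic given the seed, including the Newick string.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    AnalysisBundle,
    CountTable,
    PhyloTree,
    TAXONOMY_RANKS,
    ValidationError,
    write_biom_json,
    write_count_tsv,
    write_metadata_tsv,
    write_taxonomy_tsv,
)

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_trait",
    "synthetic_taxonomy",
    "simulate_communities",
    "write_fixture",
]

_SITE_OPTIMA = {"CC": -1.0, "WP": -1.0 / 3.0, "DB": 1.0 / 3.0, "MM": 1.0}
# Filtering strength per site: ordered along the gradient narrative
# (CC most oceanic, weakest filtering; MM warm/low-flow, strongest).
_SITE_SIGMA_F = {"CC": 2.0, "WP": 1.0, "DB": 0.7, "MM": 0.5}


@dataclass
class SyntheticDesign:
    """Generative parameters of the synthetic transplant study.

    Defaults are the standing study conditions: 4x4 origins x destinations,
    3 timepoints, 2 tissues, log-normal read depths bounded to
    [2000, 80000], site-graded filtering strength, 3 planted differential
    clades at fold-change 4, and an origin effect that decays with time.
    """

    n_taxa: int = 128
    sites: tuple = ("CC", "MM", "WP", "DB")
    timepoints: tuple = (1, 2, 3)
    tissues: tuple = ("leaf", "root")
    samples_per_cell: int = 2
    controls_per_cell: int = 2  # per destination x timepoint x tissue
    depth_median: float = 10_000.0
    depth_log_sigma: float = 0.7
    depth_bounds: tuple = (2000, 80_000)
    site_optima: dict = field(default_factory=lambda: dict(_SITE_OPTIMA))
    filtering_sigma: dict = field(default_factory=lambda: dict(_SITE_SIGMA_F))
    base_occupancy: float = 0.8
    trait_sigma: float = 1.0
    n_planted: int = 3
    planted_fold_change: float = 4.0
    planted_size_range: tuple = (3, 10)
    origin_decay: float = 0.3
    dirichlet_concentration: float = 300.0
    baseline_log_sigma: float = 1.0
    tissue_shift_sigma: float = 0.3
    transplant_effect_sigma: dict = field(
        default_factory=lambda: {"leaf": 0.0, "root": 0.3}
    )
    plots_per_site: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValidationError("n_taxa must be >= 3")
        if self.planted_fold_change <= 0:
            raise ValidationError("fold-changes must be > 0")
        for s, v in self.filtering_sigma.items():
            if v < 0:
                raise ValidationError(f"filtering sigma for {s} must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything planted: the recovery target for tests."""

    planted_nodes: dict  # node label -> {"site": ..., "fold_change": ...}
    filtering_sigma: dict  # site -> sigma_f
    expected_nri_sign: dict  # site -> +1 (clustered) or 0 (neutral)
    site_optima: dict
    origin_decay: float
    traits: dict  # tip -> trait value
    tree_newick: str
    design: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed=None) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with unit root-to-tip depth.

    Lineages split at exponential waiting times (rate = current lineage
    count); all branches extend to the present, then the whole tree is
    rescaled so every root-to-tip path length is exactly 1.
    """
    if n_tips < 3:
        raise ValidationError("n_tips must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    a = TreeNode(length=0.0)
    b = TreeNode(length=0.0)
    root.append(a)
    root.append(b)
    active = [(a, 0.0), (b, 0.0)]  # (node, birth time)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.length = t - born
        c1 = TreeNode(length=0.0)
        c2 = TreeNode(length=0.0)
        node.append(c1)
        node.append(c2)
        active.extend([(c1, t), (c2, t)])
    t_end = t + rng.exponential(1.0 / n_tips)
    if t_end <= 0:
        t_end = 1.0
    for node, born in active:
        node.length = t_end - born
    for node in root.traverse(include_self=False):
        node.length /= t_end
    width = len(str(n_tips))
    for i, tip in enumerate(root.tips()):
        tip.name = f"ASV{i + 1:0{width}d}"
    return PhyloTree(root)


def simulate_trait(tree: PhyloTree, sigma: float, seed=None) -> pd.Series:
    """Brownian-motion trait from root value 0: each branch adds a Gaussian
    increment with variance sigma^2 * branch length, so the variance of a
    tip trait is sigma^2 times its root-to-tip depth."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {}
    root = tree.skbio
    values[id(root)] = 0.0
    out = {}
    for node in root.preorder(include_self=False):
        step = rng.normal(0.0, sigma * math.sqrt(max(node.length, 0.0))) if sigma > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait").loc[tree.tip_names]


_RANK_FRACTIONS = {
    "phylum": 0.15,
    "class": 0.30,
    "order": 0.45,
    "family": 0.60,
    "genus": 0.80,
}


def synthetic_taxonomy(tree: PhyloTree, fractions: dict = None) -> pd.DataFrame:
    """Seven-rank lineages cut from the tree itself: each rank groups tips by
    the maximal clades at a fixed depth fraction of tree height (family at
    0.6 by default), giving realistic shared-lineage structure without an
    external database."""
    fractions = dict(_RANK_FRACTIONS if fractions is None else fractions)
    height = tree.height()
    root = tree.skbio
    # root-to-node start depth for every node
    start = {id(root): 0.0}
    for node in root.preorder(include_self=False):
        start[id(node)] = start[id(node.parent)] + (node.length or 0.0)
    rows = {}
    prefix = {"phylum": "p", "class": "c", "order": "o", "family": "Family_", "genus": "g"}
    for rank, frac in fractions.items():
        cutoff = frac * height
        clade_of = {}
        counter = 0
        names = {}
        for node in root.preorder(include_self=True):
            parent_start = start[id(node.parent)] if node.parent is not None else 0.0
            if start[id(node)] >= cutoff and parent_start < cutoff:
                counter += 1
                names[id(node)] = f"{prefix[rank]}{counter:03d}"
                for tip in ([node] if node.is_tip() else node.tips()):
                    clade_of[tip.name] = names[id(node)]
        rows[rank] = clade_of
    out = pd.DataFrame(index=tree.tip_names, columns=list(TAXONOMY_RANKS), dtype=object)
    out["domain"] = "Bacteria"
    for rank in fractions:
        out[rank] = pd.Series(rows[rank]).reindex(tree.tip_names).fillna("")
    out["species"] = list(tree.tip_names)
    return out.fillna("")


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------


def _pick_planted(design: SyntheticDesign, tree: PhyloTree, rng) -> dict:
    if design.n_planted == 0:
        return {}
    lo, hi = design.planted_size_range
    # require >= 2 tips on both sides of the planted balance: a side carried
    # by a single taxon is dominated by that taxon's detection noise
    def _min_child_tips(lab):
        return min(
            1 if c.is_tip() else c.count(tips=True) for c in tree.node(lab).children
        )

    chosen: list = []
    hi_eff = hi
    while True:
        candidates = [
            lab
            for lab in tree.internal_labels
            if lo <= len(tree.tips_under(lab)) <= hi_eff and _min_child_tips(lab) >= 2
        ]
        # avoid nested planted clades so the targets are independent
        chosen = []
        rng.shuffle(candidates)
        for lab in candidates:
            tips = set(tree.tips_under(lab))
            if all(tips.isdisjoint(tree.tips_under(c)) for c in chosen):
                chosen.append(lab)
            if len(chosen) == design.n_planted:
                break
        if len(chosen) == design.n_planted:
            break
        if hi_eff >= tree.n_tips // 2:  # relaxed as far as reasonable
            raise ValidationError(
                f"tree has too few disjoint clades in size range {design.planted_size_range}"
            )
        hi_eff = min(hi_eff * 2, tree.n_tips // 2)
    sites = list(design.sites)
    assigned = {}
    for k, lab in enumerate(sorted(chosen)):
        assigned[lab] = {
            "site": sites[k % len(sites)],
            "fold_change": design.planted_fold_change,
        }
    return assigned


def _site_fold_pattern(planted: dict, tree: PhyloTree, taxa: list) -> dict:
    """Per-site multiplicative fold-change vector over taxa.

    The fold-change is applied to the tips under the *first* (numerator)
    child of the planted node, i.e. one of the node's two daughter clades
    shifts against its sister — so the balance at the planted node itself
    moves by k * ln(fold_change) and is the recovery target.  (Scaling the
    whole clade would cancel inside the node's own log-ratio.)
    """
    pos = {t: i for i, t in enumerate(taxa)}
    patterns = {}
    for node, info in planted.items():
        site = info["site"]
        vec = patterns.setdefault(site, np.ones(len(taxa)))
        child = tree.node(node).children[0]
        tips = [child.name] if child.is_tip() else [t.name for t in child.tips()]
        for t in tips:
            vec[pos[t]] *= info["fold_change"]
    return patterns


def simulate_communities(
    design: SyntheticDesign, tree: PhyloTree = None, traits: pd.Series = None
) -> tuple[AnalysisBundle, SyntheticTruth]:
    """Generate a full synthetic transplant dataset plus its ground truth."""
    rng = np.random.default_rng(design.seed)
    if tree is None:
        tree = simulate_tree(design.n_taxa, seed=rng)
    if traits is None:
        traits = simulate_trait(tree, design.trait_sigma, seed=rng)
    taxa = tree.tip_names
    n_taxa = len(taxa)
    trait_vec = traits.loc[taxa].to_numpy()

    planted = _pick_planted(design, tree, rng)
    for node in planted:
        if node not in tree.internal_labels:
            raise ValidationError(f"planted node {node} not in tree")
    fold_patterns = _site_fold_pattern(planted, tree, taxa)

    baseline = np.exp(rng.normal(0.0, design.baseline_log_sigma, n_taxa))
    tissue_shift = {
        u: np.exp(rng.normal(0.0, design.tissue_shift_sigma, n_taxa))
        for u in design.tissues
    }
    transplant_pattern = {
        u: np.exp(rng.normal(0.0, design.transplant_effect_sigma.get(u, 0.0), n_taxa))
        for u in design.tissues
    }

    occupancy_p = {}
    for site in design.sites:
        sig = design.filtering_sigma.get(site, math.inf)
        if math.isinf(sig):
            w = np.ones(n_taxa)
        else:
            sig_eff = max(sig, 1e-6)  # sigma_f = 0 means a point filter
            w = np.exp(-((trait_vec - design.site_optima[site]) ** 2) / (2.0 * sig_eff**2))
        p = design.base_occupancy * w / w.mean()
        occupancy_p[site] = np.clip(p, 1e-6, 1.0)

    lo, hi = design.depth_bounds
    meta_rows = []
    count_rows = []
    sample_ids = []

    def _one_sample(dest, origin, tp, tissue, status, idx):
        mean = baseline * tissue_shift[tissue]
        fold = np.ones(n_taxa)
        if dest in fold_patterns:
            fold = fold * fold_patterns[dest]
        if status == "transplant":
            if origin in fold_patterns and design.origin_decay > 0:
                expo = design.origin_decay ** tp
                fold = fold * fold_patterns[origin] ** expo
            mean = mean * transplant_pattern[tissue]
        mean = mean * fold
        alpha = design.dirichlet_concentration * mean / mean.sum()
        rel = rng.dirichlet(alpha)
        # differential clades shift in prevalence as well as abundance:
        # the fold-change multiplies the odds of ecological presence
        p_occ = occupancy_p[dest]
        if np.any(fold != 1.0):
            odds = p_occ / (1.0 - p_occ + 1e-12) * fold
            p_occ = odds / (1.0 + odds)
        occ = rng.random(n_taxa) < p_occ
        if occ.sum() < 2:
            occ[np.argsort(alpha)[-2:]] = True
        rel = rel * occ
        rel /= rel.sum()
        depth = int(np.clip(rng.lognormal(math.log(design.depth_median), design.depth_log_sigma), lo, hi))
        counts = rng.multinomial(depth, rel)
        sid = f"S{idx:04d}"
        sample_ids.append(sid)
        count_rows.append(counts)
        meta_rows.append(
            {
                "sample_id": sid,
                "origin_site": origin,
                "destination_site": dest,
                "timepoint": tp,
                "tissue": tissue,
                "transplant_status": status,
                "plot_id": f"{dest}-plot{1 + int(rng.integers(design.plots_per_site))}",
            }
        )

    idx = 0
    for tp in design.timepoints:
        for tissue in design.tissues:
            for dest in design.sites:
                for origin in design.sites:
                    for _ in range(design.samples_per_cell):
                        idx += 1
                        _one_sample(dest, origin, tp, tissue, "transplant", idx)
                for _ in range(design.controls_per_cell):
                    idx += 1
                    _one_sample(dest, dest, tp, tissue, "control", idx)

    counts = CountTable(
        pd.DataFrame(np.array(count_rows), index=sample_ids, columns=taxa)
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    taxonomy = synthetic_taxonomy(tree)
    bundle = AnalysisBundle(
        counts=counts,
        tree=tree,
        taxonomy=taxonomy,
        metadata=metadata,
        log=[f"synthetic dataset (seed={design.seed})"],
    )
    truth = SyntheticTruth(
        planted_nodes=planted,
        filtering_sigma={s: design.filtering_sigma.get(s, math.inf) for s in design.sites},
        expected_nri_sign={
            s: (1 if math.isfinite(design.filtering_sigma.get(s, math.inf)) else 0)
            for s in design.sites
        },
        site_optima=dict(design.site_optima),
        origin_decay=design.origin_decay,
        traits={t: float(v) for t, v in traits.items()},
        tree_newick=tree.to_newick(),
        design={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(design).items()
        },
    )
    return bundle, truth


def write_fixture(bundle: AnalysisBundle, truth: SyntheticTruth, directory) -> dict:
    """Write the five fixture files (counts TSV + BIOM JSON, Newick tree,
    metadata TSV, taxonomy TSV, truth JSON), re-readable by the IO layer."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts_tsv": os.path.join(directory, "counts.tsv"),
        "counts_biom": os.path.join(directory, "counts.biom"),
        "tree": os.path.join(directory, "tree.nwk"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "taxonomy": os.path.join(directory, "taxonomy.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_count_tsv(bundle.counts, paths["counts_tsv"])
    write_biom_json(bundle.counts, paths["counts_biom"])
    with open(paths["tree"], "w") as fh:
        fh.write(bundle.tree.to_newick() + "\n")
    write_metadata_tsv(bundle.metadata, paths["metadata"])
    write_taxonomy_tsv(bundle.taxonomy, paths["taxonomy"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
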