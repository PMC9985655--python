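"""End-to-end orchestration: validate -> transform -> per-stratum multivariate
tests -> richness -> NRI -> discriminating balances.

Analyses are stratified by tissue x timepoint, mirroring the structure of a
reciprocal-transplant study report: the destination/origin PERMANOVA runs
on transplanted samples, and a separate transplant-vs-control comparison
runs on home-site transplants plus undisturbed controls.  Every output
table carries a provenance header (package version, stage parameters, the
derived stage seed) so a run is auditable and byte-reproducible from its
config and master seed alone.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .balances import (
    annotate_selection,
    node_depth_test,
    stability_select,
    tissue_family_overlap,
)
from .commphylo import cophenetic, nri, nri_group_tests
from .config import RunConfig
from .io import (
    AnalysisBundle,
    ValidationError,
    align_and_filter,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)
from .multivariate import dispersion_test, euclidean_distances, pairwise_permanova, permanova
from .transform import build_balance_basis, close_with_pseudocount, philr

__all__ = ["run_all", "stratify", "load_bundle", "write_table", "StageError"]

logger = logging.getLogger("phylocomm")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def write_table(df: pd.DataFrame, path, stage: str, params: dict, index=True) -> None:
    """TSV with a provenance header of parameters and seeds (no timestamps,
    so identical runs are byte-identical)."""
    with open(path, "w") as fh:
        fh.write(f"# phylocomm {__version__}\n")
        fh.write(f"# stage={stage}\n")
        for k in sorted(params):
            fh.write(f"# {k}={params[k]}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def stratify(bundle: AnalysisBundle, status_filter: str = "transplant"):
    """Split a bundle into tissue x timepoint strata.

    ``status_filter='transplant'`` keeps transplanted samples only (the
    destination/origin analyses); ``'control_comparison'`` keeps home-site
    transplants (destination == origin) plus undisturbed controls (the
    transplant-effect analyses); ``'all'`` keeps everything.  Returns a
    list of ``((tissue, timepoint), sub_bundle_or_None)`` with ``None`` for
    empty strata.
    """
    md = bundle.metadata
    if status_filter == "transplant":
        keep = md["transplant_status"] == "transplant"
    elif status_filter == "control_comparison":
        keep = (md["transplant_status"] == "control") | (
            (md["transplant_status"] == "transplant")
            & (md["origin_site"] == md["destination_site"])
        )
    elif status_filter == "all":
        keep = pd.Series(True, index=md.index)
    else:
        raise ValueError(f"unknown status_filter: {status_filter!r}")
    out = []
    tissues = sorted(md["tissue"].unique())
    timepoints = sorted(md["timepoint"].astype(int).unique())
    for tissue in tissues:
        for tp in timepoints:
            sel = keep & (md["tissue"] == tissue) & (md["timepoint"].astype(int) == tp)
            ids = md.index[sel].tolist()
            out.append(((tissue, tp), bundle.subset_samples(ids) if ids else None))
    return out


def load_bundle(config: RunConfig) -> AnalysisBundle:
    inp = config.sections["input"]
    for key in ("counts", "tree", "metadata", "taxonomy"):
        if not inp[key]:
            raise StageError("validate", f"missing input path: {key}")
    metadata = read_metadata(inp["metadata"])
    table = read_count_table(inp["counts"], format=inp["counts_format"], sample_ids=metadata.index)
    tree = read_tree(inp["tree"])
    taxonomy = read_taxonomy(inp["taxonomy"])
    return align_and_filter(
        table,
        tree,
        taxonomy,
        metadata,
        min_sample_depth=int(config.get("filter", "min_sample_depth")),
        min_prevalence=int(config.get("filter", "min_prevalence")),
    )


@dataclass
class RunReport:
    out_dir: str
    tables: list
    decisions: list


def run_all(config: RunConfig, bundle: AnalysisBundle = None) -> RunReport:
    """Execute the enabled stages end to end, writing one report bundle.

    ``bundle`` may be passed directly (e.g. a synthetic dataset); otherwise
    the inputs named in the config are loaded and filtered.  Stage errors
    abort with the stage name; tables already written are left in place.
    """
    config.validate()
    stages = config.stages
    out_dir = str(config.get("run", "out_dir"))
    os.makedirs(out_dir, exist_ok=True)
    config.to_file(os.path.join(out_dir, "effective_config.ini"))
    tables: list = []
    decisions = [
        "pseudocount added before closure (zero replacement is a modelling choice): "
        f"{config.get('transform', 'pseudocount')}",
        "ILR taxon weighting: " + str(config.get("transform", "weighting")),
        "PERMANOVA: sequential (Type-I) SS, free permutation of sample labels",
        "pairwise PERMANOVA p adjustment: Benjamini-Hochberg (raw p also reported)",
        "NRI null: independent swap of the full community matrix, "
        f"{config.get('nri', 'n_swaps')} accepted swaps per draw",
        "balance selection: lambda at minimum CV deviance, chosen per repetition",
    ]

    def _write(df, name, stage, params, index=True):
        path = os.path.join(out_dir, name)
        write_table(df, path, stage, params, index=index)
        tables.append(path)

    def _need(stage, *required):
        for r in required:
            if r not in stages:
                raise StageError(stage, f"requires stage {r!r}, which is not enabled")

    # ---- validate -------------------------------------------------------
    if "validate" not in stages:
        raise StageError(stages[0] if stages else "run", "requires stage 'validate'")
    if bundle is None:
        bundle = load_bundle(config)
    logger.info("validated bundle: %s samples x %s taxa", *bundle.counts.shape)
    with open(os.path.join(out_dir, "filter_log.txt"), "w") as fh:
        fh.write("\n".join(bundle.log) + ("\n" if bundle.log else ""))

    balance_table = None
    if "transform" in stages:
        basis = build_balance_basis(bundle.tree, weighting=str(config.get("transform", "weighting")))
        comp = close_with_pseudocount(bundle.counts, float(config.get("transform", "pseudocount")))
        balance_table = philr(comp, basis)
        tparams = {
            "pseudocount": config.get("transform", "pseudocount"),
            "weighting": config.get("transform", "weighting"),
        }
        _write(balance_table, "balances.tsv", "transform", tparams)
        _write(basis.sign_matrix(), "balance_basis_signs.tsv", "transform", tparams)

    md = bundle.metadata
    strata = stratify(bundle, "transplant")
    control_strata = stratify(bundle, "control_comparison")

    if "permanova" in stages or "dispersion" in stages:
        _need("permanova" if "permanova" in stages else "dispersion", "transform")
        terms = str(config.get("permanova", "terms")).split()
        n_perm = int(config.get("permanova", "n_perm"))
        seed = config.stage_seed("permanova")
        rng = np.random.default_rng(seed)
        perm_rows, pair_rows, disp_rows = [], [], []
        for (tissue, tp), sub in strata:
            if sub is None:
                logger.warning("stratum %s t%s empty; skipped", tissue, tp)
                continue
            y = balance_table.loc[sub.sample_ids]
            dm = euclidean_distances(y)
            smd = sub.metadata
            usable_terms = [
                t for t in terms
                if all(smd[p.strip()].nunique() > 1 for p in t.split(":"))
            ]
            if "permanova" in stages and usable_terms:
                try:
                    res = permanova(dm, smd, usable_terms, n_perm=n_perm, seed=int(rng.integers(2**31)))
                except ValidationError as exc:
                    # saturated or aliased design in this stratum: drop the
                    # interaction, then give up with a warning
                    mains = [t for t in usable_terms if ":" not in t]
                    try:
                        res = permanova(dm, smd, mains, n_perm=n_perm, seed=int(rng.integers(2**31)))
                    except ValidationError:
                        logger.warning("permanova skipped for %s t%s: %s", tissue, tp, exc)
                        continue
                res = res.reset_index()
                res.insert(0, "timepoint", tp)
                res.insert(0, "tissue", tissue)
                perm_rows.append(res)
                pw = pairwise_permanova(
                    dm, smd, "destination_site", n_perm=n_perm,
                    seed=int(rng.integers(2**31)), p_adjust="BH",
                )
                pw.insert(0, "timepoint", tp)
                pw.insert(0, "tissue", tissue)
                pair_rows.append(pw)
            if "dispersion" in stages and smd["destination_site"].nunique() > 1:
                try:
                    disp = dispersion_test(dm, smd["destination_site"])
                except ValidationError as exc:
                    logger.warning("dispersion skipped for %s t%s: %s", tissue, tp, exc)
                    continue
                disp_rows.append(
                    pd.DataFrame(
                        [(tissue, tp, disp.anova_f, disp.anova_p)],
                        columns=["tissue", "timepoint", "anova_F", "anova_p"],
                    )
                )
        pparams = {"terms": " ".join(terms), "n_perm": n_perm, "seed": seed}
        if "permanova" in stages:
            if perm_rows:
                _write(pd.concat(perm_rows, ignore_index=True), "permanova.tsv", "permanova", pparams, index=False)
            if pair_rows:
                _write(pd.concat(pair_rows, ignore_index=True), "pairwise_permanova.tsv", "permanova", pparams, index=False)
            # transplant-vs-control comparison (home-site transplants + controls)
            ctl_rows = []
            for (tissue, tp), sub in control_strata:
                if sub is None or sub.metadata["transplant_status"].nunique() < 2:
                    continue
                y = balance_table.loc[sub.sample_ids]
                dm = euclidean_distances(y)
                smd = sub.metadata
                tms = ["destination_site", "transplant_status"]
                tms = [t for t in tms if smd[t].nunique() > 1]
                if smd["destination_site"].nunique() > 1 and smd["transplant_status"].nunique() > 1:
                    tms.append("destination_site:transplant_status")
                try:
                    res = permanova(dm, smd, tms, n_perm=n_perm, seed=int(rng.integers(2**31)))
                except ValidationError as exc:
                    logger.warning("control comparison skipped for %s t%s: %s", tissue, tp, exc)
                    continue
                res = res.reset_index()
                res.insert(0, "timepoint", tp)
                res.insert(0, "tissue", tissue)
                ctl_rows.append(res)
            if ctl_rows:
                _write(pd.concat(ctl_rows, ignore_index=True), "permanova_controls.tsv", "permanova", pparams, index=False)
        if "dispersion" in stages and disp_rows:
            _write(pd.concat(disp_rows, ignore_index=True), "dispersion.tsv", "dispersion", pparams, index=False)

    if "richness" in stages:
        from .richness import nb_richness_model, rarefied_richness

        seed = config.stage_seed("richness")
        depth = int(config.get("richness", "depth"))
        reps = int(config.get("richness", "reps"))
        rich = rarefied_richness(bundle.counts, depth=depth, reps=reps, seed=seed)
        rparams = {"depth": depth, "reps": reps, "seed": seed}
        out = rich.join(md[["tissue", "timepoint", "destination_site", "origin_site"]])
        _write(out, "richness.tsv", "richness", rparams)
        nb_rows = []
        for (tissue, tp), sub in strata:
            if sub is None:
                continue
            ids = [s for s in sub.sample_ids if s in rich.index]
            if len(ids) < 8 or md.loc[ids, "destination_site"].nunique() < 2:
                continue
            try:
                model = nb_richness_model(rich.loc[ids], md.loc[ids], ["destination_site"], seed=seed)
            except (ValidationError, ValueError) as exc:
                logger.warning("richness model skipped for %s t%s: %s", tissue, tp, exc)
                continue
            tt = model.term_tests.reset_index()
            tt.insert(0, "timepoint", tp)
            tt.insert(0, "tissue", tissue)
            nb_rows.append(tt)
        if nb_rows:
            _write(pd.concat(nb_rows, ignore_index=True), "richness_model.tsv", "richness", rparams, index=False)

    if "nri" in stages:
        seed = config.stage_seed("nri")
        n_null = int(config.get("nri", "n_null"))
        n_swaps = int(config.get("nri", "n_swaps"))
        weighted = bool(config.get("nri", "abundance_weighted"))
        dists = cophenetic(bundle.tree)
        nparams = {"n_null": n_null, "n_swaps": n_swaps, "abundance_weighted": weighted, "seed": seed}
        nri_rows, test_rows = [], []
        rng = np.random.default_rng(seed)
        for tissue in sorted(md["tissue"].unique()):
            ids = md.index[md["tissue"] == tissue].tolist()
            res = nri(
                counts=bundle.counts.values.loc[ids],
                dists=dists,
                abundance_weighted=weighted,
                n_null=n_null,
                n_swaps=n_swaps,
                seed=int(rng.integers(2**31)),
            )
            res = res.join(md.loc[ids, ["destination_site", "timepoint"]])
            res.insert(0, "tissue", tissue)
            nri_rows.append(res)
            groups = (
                md.loc[ids, "destination_site"].astype(str)
                + "_t"
                + md.loc[ids, "timepoint"].astype(int).astype(str)
            )
            try:
                gt = nri_group_tests(res, groups)
            except ValidationError as exc:
                logger.warning("NRI group tests skipped for %s: %s", tissue, exc)
                continue
            tab = gt.per_group.reset_index()
            tab.insert(0, "tissue", tissue)
            tab["among_test"] = gt.among_test
            tab["among_p"] = gt.among_p
            test_rows.append(tab)
        _write(pd.concat(nri_rows), "nri.tsv", "nri", nparams)
        if test_rows:
            _write(pd.concat(test_rows, ignore_index=True), "nri_tests.tsv", "nri", nparams, index=False)

    if "balances" in stages:
        _need("balances", "transform")
        seed = config.stage_seed("balances")
        reps = int(config.get("balances", "reps"))
        folds = int(config.get("balances", "folds"))
        n_lambda = int(config.get("balances", "n_lambda"))
        threshold = float(config.get("balances", "threshold"))
        bparams = {"reps": reps, "folds": folds, "n_lambda": n_lambda, "threshold": threshold, "seed": seed}
        rng = np.random.default_rng(seed)
        sel_rows = []
        families_by_tissue: dict = {}
        depth_rows = []
        for (tissue, tp), sub in strata:
            if sub is None or sub.metadata["destination_site"].nunique() < 2:
                continue
            y = balance_table.loc[sub.sample_ids]
            sel = stability_select(
                y,
                sub.metadata["destination_site"],
                reps=reps,
                folds=folds,
                seed=int(rng.integers(2**31)),
                n_lambda=n_lambda,
            )
            ann = annotate_selection(sel, bundle.tree, bundle.taxonomy)
            ann.insert(0, "timepoint", tp)
            ann.insert(0, "tissue", tissue)
            sel_rows.append(ann)
            chosen = ann[(ann["frequency_overall"] >= threshold)]
            fams = set(
                bundle.taxonomy.loc[
                    [t for n in chosen["node"].unique() for t in bundle.tree.tips_under(n)],
                    "family",
                ]
            ) - {""}
            families_by_tissue.setdefault(tissue, set()).update(fams)
            try:
                dt = node_depth_test(sel, bundle.tree, threshold=threshold)
                depth_rows.append(
                    (tissue, tp, dt.n_selected, dt.n_unselected, dt.t, dt.p, dt.direction)
                )
            except ValidationError as exc:
                logger.warning("node depth test skipped for %s t%s: %s", tissue, tp, exc)
        if sel_rows:
            _write(pd.concat(sel_rows, ignore_index=True), "balance_selection.tsv", "balances", bparams, index=False)
        if depth_rows:
            _write(
                pd.DataFrame(
                    depth_rows,
                    columns=["tissue", "timepoint", "n_selected", "n_unselected", "t", "p", "direction"],
                ),
                "node_depth_test.tsv", "balances", bparams, index=False,
            )
        if len(families_by_tissue) == 2:
            universe = set(bundle.taxonomy["family"]) - {""}
            fr = tissue_family_overlap(
                families_by_tissue.get("leaf", set()),
                families_by_tissue.get("root", set()),
                universe,
            )
            _write(
                pd.DataFrame(
                    [
                        (
                            fr.table[0, 0], fr.table[0, 1], fr.table[1, 0], fr.table[1, 1],
                            fr.odds_ratio, fr.p,
                        )
                    ],
                    columns=["both", "leaf_only", "root_only", "neither", "odds_ratio", "p"],
                ),
                "tissue_family_overlap.tsv", "balances", bparams, index=False,
            )

    with open(os.path.join(out_dir, "decisions_in_force.txt"), "w") as fh:
        fh.write("\n".join(decisions) + "\n")
    return RunReport(out_dir=out_dir, tables=tables, decisions=decisions)
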