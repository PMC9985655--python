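"""Data model and file I/O for the community-phylogenetics pipeline.

The pipeline consumes four artifacts produced upstream (denoising, taxonomy
assignment and tree inference are out of scope): an ASV count table
(samples x taxa, nonnegative integers), a rooted phylogeny over the same
taxa, a seven-rank taxonomy, and per-sample metadata describing the
reciprocal-transplant design (origin site, destination site, timepoint,
tissue, transplant status, plot).  ``align_and_filter`` intersects and
validates them into one :class:`AnalysisBundle` with a provenance log.

Counts are accepted as TSV (taxa in rows, samples in columns — the common
amplicon export orientation) or BIOM 1.0 JSON.  Trees are Newick; any
polytomy below the root is resolved deterministically (file order, left
grouping, zero-length branches) and internal nodes receive stable preorder
labels ``n1 .. n(T-1)`` that the balance machinery refers to.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "ValidationError",
    "FormatError",
    "CountTable",
    "PhyloTree",
    "AnalysisBundle",
    "SITES",
    "TISSUES",
    "TRANSPLANT_STATUSES",
    "TAXONOMY_RANKS",
    "read_count_table",
    "write_count_tsv",
    "write_biom_json",
    "read_tree",
    "read_metadata",
    "validate_metadata",
    "read_taxonomy",
    "align_and_filter",
]

SITES = ("CC", "MM", "WP", "DB")
TISSUES = ("leaf", "root")
TRANSPLANT_STATUSES = ("transplant", "control")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = (
    "origin_site",
    "destination_site",
    "timepoint",
    "tissue",
    "transplant_status",
    "plot_id",
)


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class FormatError(ValueError):
    """Input file does not parse in the declared dialect."""


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


class CountTable:
    """Samples x taxa matrix of nonnegative integer read counts.

    Invariants: no negative entries, unique sample and taxon identifiers,
    every sample row sum > 0.  The in-memory orientation is always samples
    in rows; on-disk TSV orientation is taxa in rows (transposed on read).
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count table contains non-numeric entries")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {values.index[i]!r}, taxon {values.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count at sample {values.index[i]!r}, taxon {values.columns[j]!r}"
            )
        df = values.astype(np.int64)
        empty = df.sum(axis=1) == 0
        if empty.any():
            raise ValidationError(
                f"samples with zero total reads: {df.index[empty].tolist()}"
            )
        self._df = df

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def depths(self) -> pd.Series:
        return self._df.sum(axis=1)

    def prevalence(self) -> pd.Series:
        """Number of samples in which each taxon has count > 0."""
        return (self._df > 0).sum(axis=0)

    def subset(self, samples=None, taxa=None) -> "CountTable":
        df = self._df
        if samples is not None:
            df = df.loc[list(samples)]
        if taxa is not None:
            df = df[list(taxa)]
        return CountTable(df)

    def __eq__(self, other):
        return isinstance(other, CountTable) and self._df.equals(other._df)

    def __repr__(self):
        n, t = self.shape
        return f"CountTable({n} samples x {t} taxa)"


def read_count_table(path, format: str = "tsv", sample_ids=None) -> CountTable:
    """Read a count table from ``tsv`` (taxa x samples) or BIOM 1.0 ``biom`` JSON.

    If ``sample_ids`` is given (e.g. from metadata), orientation of a TSV is
    auto-detected by matching identifiers, guarding against silent
    transposition; otherwise taxa-in-rows is assumed.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse TSV count table: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if sample_ids is not None:
            sample_ids = set(map(str, sample_ids))
            col_hits = len(sample_ids & set(df.columns))
            row_hits = len(sample_ids & set(df.index))
            if row_hits > col_hits:
                return CountTable(df)  # samples already in rows
        return CountTable(df.T)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        return _count_table_from_biom(doc)
    raise ValueError(f"unknown count-table format: {format!r}")


def _count_table_from_biom(doc: dict) -> CountTable:
    try:
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM 1.0 JSON table: missing {exc}") from exc
    mat = np.zeros(shape, dtype=float)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"unknown BIOM matrix_type: {mtype!r}")
    # BIOM rows are observations (taxa); transpose to samples x taxa
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CountTable(df)


def write_count_tsv(table: CountTable, path) -> None:
    """Write taxa-in-rows TSV (round-trips through :func:`read_count_table`)."""
    table.values.T.to_csv(path, sep="\t", index_label="taxon_id")


def write_biom_json(table: CountTable, path, table_id: str = "phylocomm") -> None:
    df = table.values
    rows, cols = np.nonzero(df.to_numpy())
    data = [[int(j), int(i), int(df.iat[i, j])] for i, j in zip(rows, cols)]
    data.sort()
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "phylocomm",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [df.shape[1], df.shape[0]],
        "rows": [{"id": t, "metadata": None} for t in df.columns],
        "columns": [{"id": s, "metadata": None} for s in df.index],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted, strictly bifurcating tree with stable internal labels.

    Construction resolves polytomies below the root deterministically
    (children grouped left-to-right in file order under zero-length
    branches), validates tip-label uniqueness and positive root-to-tip
    path lengths, and assigns internal labels ``n1 .. n(T-1)`` in preorder
    (``n1`` is the root).  Any original internal-node labels are preserved
    on the ``original_label`` node attribute.
    """

    def __init__(self, tree: TreeNode):
        t = tree.copy()
        if t.length is None:
            t.length = 0.0
        if len(t.children) > 2:
            raise ValidationError(
                f"tree is unrooted: root has degree {len(t.children)}"
            )
        for node in list(t.traverse(include_self=True)):
            if node.is_tip():
                continue
            while len(node.children) > 2:
                c1, c2 = node.children[0], node.children[1]
                node.remove(c1)
                node.remove(c2)
                grp = TreeNode(length=0.0)
                grp.append(c1)
                grp.append(c2)
                node.children.insert(0, grp)
                grp.parent = node
            if len(node.children) == 1 and node.parent is not None:
                # collapse unbranched internal node into its child
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                idx = parent.children.index(node)
                parent.remove(node)
                parent.children.insert(idx, child)
                child.parent = parent
        if len(t.children) == 1:  # root with single child: lift
            only = t.children[0]
            only.parent = None
            only.length = 0.0
            t = only
        tips = list(t.tips())
        names = [tip.name for tip in tips]
        if any(n is None for n in names):
            raise ValidationError("unnamed tip in tree")
        if len(set(names)) != len(names):
            seen, coll = set(), set()
            for n in names:
                (coll if n in seen else seen).add(n)
            raise ValidationError(f"tip label collision: {sorted(coll)}")
        for node in t.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        # preorder internal labels
        self._internal = {}
        counter = 0
        for node in t.preorder(include_self=True):
            if node.is_tip():
                continue
            counter += 1
            label = f"n{counter}"
            node.original_label = node.name
            node.name = label
            self._internal[label] = node
        for tip in t.tips():
            d = tip.accumulate_to_ancestor(t)
            if d <= 0:
                raise ValidationError(
                    f"tip {tip.name!r} has non-positive root-to-tip path length"
                )
        self._tree = t
        self._tip_names = [tip.name for tip in t.tips()]

    @property
    def skbio(self) -> TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return list(self._tip_names)

    @property
    def n_tips(self) -> int:
        return len(self._tip_names)

    @property
    def internal_labels(self) -> list[str]:
        return list(self._internal)

    def node(self, label: str) -> TreeNode:
        try:
            return self._internal[label]
        except KeyError:
            raise KeyError(f"unknown internal node: {label!r}") from None

    def tips_under(self, label: str) -> list[str]:
        return [tip.name for tip in self.node(label).tips()]

    def node_depth(self, label: str) -> float:
        """Root-to-node path length."""
        node = self.node(label)
        if node.parent is None:
            return 0.0
        return node.accumulate_to_ancestor(self._tree)

    def height(self) -> float:
        return max(tip.accumulate_to_ancestor(self._tree) for tip in self._tree.tips())

    def total_branch_length(self) -> float:
        return sum(
            node.length or 0.0 for node in self._tree.traverse(include_self=False)
        )

    def shear(self, taxa) -> "PhyloTree":
        """Prune to ``taxa`` and rebuild (labels are reassigned in preorder)."""
        taxa = list(taxa)
        if len(taxa) < 2:
            raise ValidationError("cannot shear tree below 2 tips")
        sub = self._tree.shear(set(taxa))
        sub.prune()
        return PhyloTree(sub)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def __repr__(self):
        return f"PhyloTree({self.n_tips} tips, {len(self._internal)} internal nodes)"


def read_tree(source) -> PhyloTree:
    """Read a rooted Newick tree from a path, file object or string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = _io.StringIO(source)
    t = TreeNode.read(source, format="newick", convert_underscores=False)
    return PhyloTree(t)


# ---------------------------------------------------------------------------
# Metadata and taxonomy
# ---------------------------------------------------------------------------


def validate_metadata(md: pd.DataFrame, sites=SITES, timepoints=(1, 2, 3)) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if md.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    md = md.copy()
    md["timepoint"] = md["timepoint"].astype(int)
    checks = {
        "origin_site": set(sites),
        "destination_site": set(sites),
        "timepoint": set(int(t) for t in timepoints),
        "tissue": set(TISSUES),
        "transplant_status": set(TRANSPLANT_STATUSES),
    }
    for col, allowed in checks.items():
        bad = set(md[col]) - allowed
        if bad:
            raise ValidationError(f"metadata column {col!r} has unknown levels: {sorted(map(str, bad))}")
    return md


def read_metadata(path, sites=SITES, timepoints=(1, 2, 3)) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    return validate_metadata(md, sites=sites, timepoints=timepoints)


_QIIME_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")


def _split_lineage(lineage: str) -> list[str]:
    parts = [p.strip() for p in str(lineage).split(";")]
    out = []
    for p in parts:
        for pref in _QIIME_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        out.append(p)
    out = out[: len(TAXONOMY_RANKS)]
    out += [""] * (len(TAXONOMY_RANKS) - len(out))
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: either 7 rank columns or a QIIME-style lineage column."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    lower = {c.lower(): c for c in df.columns}
    if all(r in lower for r in TAXONOMY_RANKS):
        out = df[[lower[r] for r in TAXONOMY_RANKS]]
        out.columns = list(TAXONOMY_RANKS)
        return out
    lineage_col = next(
        (lower[c] for c in ("taxon", "taxonomy", "lineage") if c in lower), None
    )
    if lineage_col is None:
        raise FormatError(
            "taxonomy TSV needs either 7 rank columns (domain..species) or a "
            "Taxon/taxonomy/lineage column"
        )
    rows = [_split_lineage(v) for v in df[lineage_col]]
    return pd.DataFrame(rows, index=df.index, columns=list(TAXONOMY_RANKS))


def write_taxonomy_tsv(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="taxon_id")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class AnalysisBundle:
    """Validated, aligned inputs plus a provenance log of everything dropped."""

    counts: CountTable
    tree: PhyloTree
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self):
        taxa = set(self.counts.taxon_ids)
        if taxa != set(self.tree.tip_names):
            raise ValidationError("taxon sets of count table and tree differ")
        if taxa - set(self.taxonomy.index):
            raise ValidationError("taxa missing from taxonomy")
        if set(self.counts.sample_ids) != set(self.metadata.index):
            raise ValidationError("sample sets of count table and metadata differ")
        # keep metadata in table order
        self.metadata = self.metadata.loc[self.counts.sample_ids]
        self.taxonomy = self.taxonomy.loc[self.counts.taxon_ids]

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids

    @property
    def taxon_ids(self) -> list[str]:
        return self.counts.taxon_ids

    def subset_samples(self, sample_ids) -> "AnalysisBundle":
        """Sample-subset bundle; taxa and tree are left untouched so balance
        coordinates stay comparable across strata."""
        sample_ids = list(sample_ids)
        return AnalysisBundle(
            counts=self.counts.subset(samples=sample_ids),
            tree=self.tree,
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[sample_ids],
            log=self.log + [f"subset to {len(sample_ids)} samples"],
        )


def align_and_filter(
    table: CountTable,
    tree: PhyloTree,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    min_sample_depth: int,
    min_prevalence: int = 2,
) -> AnalysisBundle:
    """Intersect inputs and apply the prevalence and depth filters.

    Taxa are restricted to the table/tree/taxonomy intersection and to taxa
    present (count > 0) in at least ``min_prevalence`` samples; samples
    shallower than ``min_sample_depth`` reads are dropped.  Filtering
    iterates to a fixed point (dropping taxa lowers depths, dropping samples
    lowers prevalence), which makes the operation idempotent.  Every dropped
    identifier is recorded in the provenance log.
    """
    log: list[str] = []
    df = table.values

    meta_samples = set(metadata.index)
    drop = [s for s in df.index if s not in meta_samples]
    if drop:
        log.append(f"dropped {len(drop)} samples without metadata: {drop}")
        df = df.drop(index=drop)

    taxa = [
        t
        for t in df.columns
        if t in set(tree.tip_names) and t in set(taxonomy.index)
    ]
    lost = [t for t in df.columns if t not in set(taxa)]
    if lost:
        log.append(
            f"dropped {len(lost)} taxa absent from tree and/or taxonomy: {lost[:20]}"
            + ("..." if len(lost) > 20 else "")
        )
    if not taxa:
        raise ValidationError("empty taxon intersection of table, tree and taxonomy")
    df = df[taxa]

    while True:
        changed = False
        depths = df.sum(axis=1)
        shallow = depths.index[depths < min_sample_depth].tolist()
        if shallow:
            log.append(
                f"dropped {len(shallow)} samples with depth < {min_sample_depth}: {shallow}"
            )
            df = df.drop(index=shallow)
            changed = True
        if df.shape[0] == 0:
            raise ValidationError("all samples dropped by depth filter")
        if min_prevalence > 0:
            prev = (df > 0).sum(axis=0)
            rare = prev.index[prev < min_prevalence].tolist()
            if rare:
                log.append(
                    f"dropped {len(rare)} taxa present in < {min_prevalence} samples: "
                    f"{rare[:20]}" + ("..." if len(rare) > 20 else "")
                )
                df = df.drop(columns=rare)
                changed = True
        if df.shape[1] == 0:
            raise ValidationError("all taxa dropped by prevalence filter")
        if not changed:
            break

    kept_taxa = list(df.columns)
    pruned = tree if set(kept_taxa) == set(tree.tip_names) else tree.shear(kept_taxa)
    if pruned is not tree:
        log.append(f"tree pruned to {len(kept_taxa)} tips and re-bifurcated")
    counts = CountTable(df)
    return AnalysisBundle(
        counts=counts,
        tree=pruned,
        taxonomy=taxonomy.loc[kept_taxa],
        metadata=metadata.loc[counts.sample_ids],
        log=log,
    )
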