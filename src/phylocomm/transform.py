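"""Phylogenetic isometric log-ratio (ILR) transform.

A strictly bifurcating rooted tree over the taxa defines a sequential
binary partition: each internal node ``i`` splits its descendant tips into
a numerator set ``R_i`` (tips under the first child, in preorder) and a
denominator set ``S_i`` (tips under the second child).  The balance
coordinate of a composition ``x`` at node ``i`` is

    y_i = k_i * ln( g(x_R) / g(x_S) ),    k_i = sqrt(r s / (r + s)),

with ``g`` the geometric mean and ``r = |R_i|``, ``s = |S_i|``.  With
uniform taxon weights the contrast matrix ``V`` is orthonormal and the
Euclidean distance between balance vectors equals the Aitchison
(clr-Euclidean) distance between compositions — the geometry PERMANOVA and
ordination operate in downstream.

Counts are made strictly positive by adding a pseudocount before closure;
the pseudocount (default 1) is an explicit, logged parameter because zero
replacement is a modelling choice, not a detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, PhyloTree, ValidationError

__all__ = [
    "BalanceBasis",
    "build_balance_basis",
    "close_with_pseudocount",
    "philr",
    "balance_subcomposition",
]


@dataclass
class BalanceBasis:
    """Sequential binary partition of a tree as an ILR contrast basis.

    ``V`` is the taxa x nodes matrix of orthonormal contrast vectors
    (uniform weights); ``node_weight`` is an optional per-balance scaling
    (identically 1 for uniform weighting).
    """

    tip_names: list
    node_labels: list
    numerator: dict
    denominator: dict
    scale: pd.Series  # k_i = sqrt(r s / (r + s))
    V: pd.DataFrame  # taxa x nodes
    node_weight: pd.Series
    weighting: str

    def sizes(self) -> pd.DataFrame:
        r = pd.Series({n: len(self.numerator[n]) for n in self.node_labels})
        s = pd.Series({n: len(self.denominator[n]) for n in self.node_labels})
        return pd.DataFrame({"r": r, "s": s, "size": r + s})

    def sign_matrix(self) -> pd.DataFrame:
        """Taxa x nodes membership signs (+1 numerator, -1 denominator, 0)."""
        sign = pd.DataFrame(0, index=self.tip_names, columns=self.node_labels, dtype=int)
        for n in self.node_labels:
            sign.loc[list(self.numerator[n]), n] = 1
            sign.loc[list(self.denominator[n]), n] = -1
        return sign


def build_balance_basis(tree: PhyloTree, weighting: str = "uniform") -> BalanceBasis:
    """Construct one balance per internal node of a bifurcating tree.

    The numerator is always the first child in preorder, fixing the sign
    convention across runs.  ``weighting='branch_length'`` additionally
    scales each balance by sqrt of the mean of its two child branch
    lengths (the basis is then no longer orthonormal; uniform is the
    default and the form all invariants are stated for).
    """
    if weighting not in ("uniform", "branch_length"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    tips = tree.tip_names
    tip_pos = {t: i for i, t in enumerate(tips)}
    labels = tree.internal_labels
    V = np.zeros((len(tips), len(labels)))
    num, den, scale, weight = {}, {}, {}, {}
    for j, label in enumerate(labels):
        node = tree.node(label)
        if len(node.children) != 2:
            raise ValidationError(f"node {label} is not bifurcating")
        left, right = node.children
        R = tuple(t.name for t in ([left] if left.is_tip() else left.tips()))
        S = tuple(t.name for t in ([right] if right.is_tip() else right.tips()))
        r, s = len(R), len(S)
        num[label], den[label] = R, S
        scale[label] = np.sqrt(r * s / (r + s))
        V[[tip_pos[t] for t in R], j] = np.sqrt(s / (r * (r + s)))
        V[[tip_pos[t] for t in S], j] = -np.sqrt(r / (s * (r + s)))
        if weighting == "branch_length":
            weight[label] = np.sqrt(((left.length or 0.0) + (right.length or 0.0)) / 2.0)
        else:
            weight[label] = 1.0
    return BalanceBasis(
        tip_names=list(tips),
        node_labels=list(labels),
        numerator=num,
        denominator=den,
        scale=pd.Series(scale, name="k").loc[labels],
        V=pd.DataFrame(V, index=tips, columns=labels),
        node_weight=pd.Series(weight, name="weight").loc[labels],
        weighting=weighting,
    )


def close_with_pseudocount(counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Add a pseudocount and close each sample to a strictly positive
    composition summing to 1."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    df = counts.values if isinstance(counts, CountTable) else pd.DataFrame(counts)
    x = df.to_numpy(dtype=float) + pseudocount
    x /= x.sum(axis=1, keepdims=True)
    return pd.DataFrame(x, index=df.index, columns=df.columns)


def philr(comp: pd.DataFrame, basis: BalanceBasis) -> pd.DataFrame:
    """Balance coordinates (samples x internal nodes) of compositions.

    Equivalent to ``clr(x) @ V`` since every contrast vector sums to zero;
    computed as ``ln(x) @ V`` directly.
    """
    if set(comp.columns) != set(basis.tip_names):
        raise ValidationError("composition taxa do not match basis tips")
    x = comp[basis.tip_names].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValidationError("composition must be strictly positive")
    y = np.log(x) @ basis.V.to_numpy()
    y *= basis.node_weight.to_numpy()[None, :]
    return pd.DataFrame(y, index=comp.index, columns=basis.node_labels)


def balance_subcomposition(node: str, comp: pd.DataFrame, basis: BalanceBasis) -> pd.Series:
    """Single-node balance: identical to the corresponding column of
    :func:`philr`, computed from the node's two tip sets alone."""
    if node not in basis.numerator:
        raise KeyError(f"unknown internal node: {node!r}")
    x = comp[basis.tip_names]
    if (x.to_numpy() <= 0).any():
        raise ValidationError("composition must be strictly positive")
    gm_num = np.log(x[list(basis.numerator[node])]).mean(axis=1)
    gm_den = np.log(x[list(basis.denominator[node])]).mean(axis=1)
    y = basis.scale[node] * basis.node_weight[node] * (gm_num - gm_den)
    y.name = node
    return y
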