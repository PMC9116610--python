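"""Tissue expression signatures of BM-zone genes.

Covers three analyses: hierarchical clustering of tissue expression
profiles on Spearman distance (d = 1 - rho), per-gene expression-variance
quartile binning (low / medium / high / very_high), and cross-species
overlap of variance classes through an orthology map.

Variance is computed on the values as provided (no log transform by
default; an optional log2(x+1) pre-transform is exposed).  Quartile
cutpoints use linear interpolation, and a gene falling exactly on a
cutpoint goes to the lower bin.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "read_expression_matrix",
    "spearman_distance",
    "hierarchical_cluster",
    "cut_clusters",
    "dendrogram_to_newick",
    "variance_bins",
    "cross_species_overlap",
    "BIN_LABELS",
]

BIN_LABELS = ("low", "medium", "high", "very_high")

Axis = Literal["genes", "tissues"]


def read_expression_matrix(path: str | Path, drop_missing: bool = True) -> pd.DataFrame:
    """Read a genes x tissues TSV; rows with missing values are dropped."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, encoding="utf-8")
    if drop_missing and df.isna().any().any():
        n = int(df.isna().any(axis=1).sum())
        warnings.warn(f"dropping {n} gene row(s) with missing values", stacklevel=2)
        df = df.dropna(axis=0)
    if (df.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    return df


def spearman_distance(matrix: pd.DataFrame, axis: Axis = "tissues") -> pd.DataFrame:
    """Pairwise Spearman distance d = 1 - rho along the chosen axis.

    ``axis='tissues'`` correlates tissue columns across genes;
    ``axis='genes'`` correlates gene rows across tissues.  A constant
    profile has undefined rank correlation; rho is defined as 0 there
    (distance 1) with a warning.
    """
    data = matrix.values.T if axis == "tissues" else matrix.values
    labels = list(matrix.columns if axis == "tissues" else matrix.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 items to compute distances")
    if data.shape[1] < 3:
        raise ValueError("need >= 3 observations along the correlated axis")

    ranks = np.apply_along_axis(rankdata, 1, data.astype(float))
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s); rho set to 0",
            stacklevel=2,
        )
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * data.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / denom
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


def hierarchical_cluster(
    distance: pd.DataFrame, method: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns a scipy linkage matrix.  Complete linkage is the default
    (matching hclust's default in R); 'average' and 'single' are accepted.
    """
    d = distance.values
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] == 1:
        return np.empty((0, 4))
    condensed = squareform(d, checks=False)
    return linkage(condensed, method=method)


def cut_clusters(z: np.ndarray, labels: Sequence[str], k: int) -> dict[str, int]:
    """Cut the merge tree into k flat clusters; labels map to cluster ids."""
    if len(labels) == 1:
        return {labels[0]: 0}
    assignment = cut_tree(z, n_clusters=k).ravel()
    return {lab: int(c) for lab, c in zip(labels, assignment)}


def dendrogram_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick string with merge heights."""
    if len(labels) == 1:
        return f"{labels[0]};"
    tree = to_tree(z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def variance_bins(
    matrix: pd.DataFrame, log_transform: bool = False
) -> pd.DataFrame:
    """Per-gene expression variance with quartile bin labels.

    Sample variance (ddof=1) across tissues; cutpoints at the empirical
    25/50/75 percentiles (linear interpolation).  Bin rule:
    low <= Q1 < medium <= Q2 < high <= Q3 < very_high, i.e. a gene exactly
    at a cutpoint takes the lower bin.  All-constant genes have variance 0
    and land in low.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variance needs >= 2 tissues")
    values = np.log2(matrix.values + 1.0) if log_transform else matrix.values
    var = values.astype(float).var(axis=1, ddof=1)
    q1, q2, q3 = np.percentile(var, [25, 50, 75], method="linear")
    labels = np.where(
        var <= q1, "low",
        np.where(var <= q2, "medium", np.where(var <= q3, "high", "very_high")),
    )
    return pd.DataFrame(
        {"variance": var, "bin": labels}, index=matrix.index
    ).rename_axis("gene")


def cross_species_overlap(
    bins_a: pd.DataFrame,
    bins_b: pd.DataFrame,
    orthology: Mapping[str, Sequence[str]],
    focus: Sequence[str] = ("low", "very_high"),
) -> pd.DataFrame:
    """Bin concordance between two species through an orthology map.

    For each focus bin, a species-A gene overlaps when ANY of its orthologs
    occupies the same bin in species B (permissive one-to-many policy).
    Reports the overlap count and the Jaccard index between the bin's
    species-A gene set (mapped) and species-B ortholog set.
    """
    if not orthology:
        warnings.warn("empty orthology map; all overlaps are 0", stacklevel=2)
    rows = []
    bin_b = bins_b["bin"]
    for b in focus:
        a_genes = set(bins_a.index[bins_a["bin"] == b])
        b_genes = set(bins_b.index[bins_b["bin"] == b])
        mapped = {
            g for g in a_genes
            for o in orthology.get(g, [])
        }
        shared = sum(
            1
            for g in a_genes
            if any(o in bin_b.index and bin_b[o] == b for o in orthology.get(g, []))
        )
        union = mapped | b_genes
        inter = mapped & b_genes
        rows.append(
            {
                "bin": b,
                "n_a": len(a_genes),
                "n_b": len(b_genes),
                "overlap": shared,
                "jaccard": (len(inter) / len(union)) if union else 0.0,
            }
        )
    return pd.DataFrame(rows)
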