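"""Interaction-confidence filtering and proteomic abundance composition.

STRING-style combined scores are binned on the published confidence scale
(lowest < 0.15 <= low < 0.4 <= medium < 0.7 <= high <= 0.9 < highest) and
the interaction network is rebuilt from high-confidence pairs only
(combined score > 0.7).  Tissue proteomic relative abundance is ranked per
tissue (dense ranks, descending) with log-transformed node sizes, and
proteins are called "common" (abundant in every tissue) or "variable"
(high coefficient of variation across tissues).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CONFIDENCE_BINS",
    "InteractionRecord",
    "bin_confidence",
    "read_interactions",
    "high_confidence_network",
    "read_abundance_table",
    "rank_abundance",
    "common_variable_components",
]

CONFIDENCE_BINS = ("lowest", "low", "medium", "high", "highest")


def bin_confidence(score: float) -> str:
    """Confidence bin for a combined score in [0, 1].

    Boundaries as published: lowest < 0.15; low 0.15-0.39; medium
    0.4-0.69; high 0.7-0.9 (inclusive of 0.9); highest > 0.9.
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"combined score out of range [0,1]: {score}")
    if score < 0.15:
        return "lowest"
    if score < 0.4:
        return "low"
    if score < 0.7:
        return "medium"
    if score <= 0.9:
        return "high"
    return "highest"


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction: {self.protein_a}")
        # canonical unordered pair
        if self.protein_a > self.protein_b:
            object.__setattr__(self, "protein_a", self.protein_b)
            object.__setattr__(self, "protein_b", self.protein_a)

    @property
    def bin(self) -> str:
        return bin_confidence(self.combined_score)


def read_interactions(
    path: str | Path, auto_scale: bool = True
) -> list[InteractionRecord]:
    """Read a STRING-style link table (protein1, protein2, combined_score).

    Scores on the 0-1000 integer scale are divided by 1000 when
    ``auto_scale`` and any score exceeds 1.  Self-interactions are dropped
    with a warning.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", encoding="utf-8")
    cols = {c.lower(): c for c in df.columns}
    try:
        a, b, s = cols["protein1"], cols["protein2"], cols["combined_score"]
    except KeyError as err:
        raise ValueError(f"missing column: {err}") from None
    scores = df[s].astype(float)
    if auto_scale and (scores > 1).any():
        scores = scores / 1000.0
    records = []
    n_self = 0
    for pa, pb, sc in zip(df[a], df[b], scores):
        if pa == pb:
            n_self += 1
            continue
        records.append(InteractionRecord(str(pa), str(pb), float(sc)))
    if n_self:
        warnings.warn(f"dropped {n_self} self-interaction(s)", stacklevel=2)
    return records


def high_confidence_network(
    interactions: Sequence[InteractionRecord],
    threshold: float = 0.7,
    registry_proteins: Iterable[str] | None = None,
) -> tuple[nx.Graph, dict]:
    """Graph of pairs with combined score > threshold, plus a coverage report.

    The report gives the fraction of input pairs falling in the high or
    highest confidence bins, per-bin counts, and — when registry proteins
    are supplied — the proteins excluded from the filtered network for
    lacking any retained interaction.
    """
    g = nx.Graph()
    bin_counts = {b: 0 for b in CONFIDENCE_BINS}
    for rec in interactions:
        bin_counts[rec.bin] += 1
        if rec.combined_score > threshold:
            g.add_edge(rec.protein_a, rec.protein_b, weight=rec.combined_score)
    total = len(interactions)
    high_frac = (
        (bin_counts["high"] + bin_counts["highest"]) / total if total else 0.0
    )
    report = {
        "n_interactions": total,
        "n_retained": g.number_of_edges(),
        "bin_counts": bin_counts,
        "high_confidence_fraction": high_frac,
    }
    if registry_proteins is not None:
        registry_proteins = sorted(set(registry_proteins))
        report["excluded_proteins"] = [
            p for p in registry_proteins if p not in g
        ]
        g.add_nodes_from(registry_proteins)
    return g, report


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Protein x tissue relative abundance TSV; zeros mean not detected."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, encoding="utf-8")
    if (df.values < 0).any():
        raise ValueError("abundance values must be nonnegative")
    return df


def rank_abundance(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue dense descending ranks and log node sizes.

    Tied abundances share a rank (dense ranking); output rows are
    symbol-sorted so ties resolve deterministically.  Node size is
    log(1 + abundance) — zero abundance (not detected) stays size zero.
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one tissue column")
    if (table.values < 0).any():
        raise ValueError("abundance values must be nonnegative")
    table = table.sort_index()
    ranks = table.rank(axis=0, method="dense", ascending=False).astype(int)
    sizes = np.log1p(table.astype(float))
    return ranks, sizes


def common_variable_components(
    table: pd.DataFrame,
    common_rank_quantile: float = 0.25,
    variable_cv_quantile: float = 0.9,
) -> tuple[set[str], set[str], pd.Series]:
    """Call common-core and variable BM-zone proteins from abundance.

    common: detected (abundance > 0) in every tissue AND within the top
    rank quantile (default top quartile) in each tissue.
    variable: coefficient of variation across detected tissues above the
    ``variable_cv_quantile`` quantile (default top decile) of CVs among
    proteins detected in >= 2 tissues.  A protein qualifying as common is
    by definition not variable, so the two sets are disjoint.

    Returns (common, variable, per-protein CV over detected tissues).
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    detected = table > 0
    ranks, _ = rank_abundance(table)
    table = table.sort_index()
    detected = detected.sort_index()

    common: set[str] = set()
    for protein in table.index:
        if not detected.loc[protein].all():
            continue
        ok = True
        for tissue in table.columns:
            n_ranks = ranks[tissue][detected[tissue]].max()
            cutoff = max(1, math.ceil(common_rank_quantile * n_ranks))
            if ranks.loc[protein, tissue] > cutoff:
                ok = False
                break
        if ok:
            common.add(protein)

    cvs = {}
    for protein in table.index:
        vals = table.loc[protein][detected.loc[protein]].astype(float)
        if len(vals) >= 2 and vals.mean() > 0:
            cvs[protein] = float(vals.std(ddof=1) / vals.mean())
    cv_series = pd.Series(cvs, dtype=float).sort_index()
    variable: set[str] = set()
    if len(cv_series):
        cutoff = cv_series.quantile(variable_cv_quantile)
        variable = {p for p, v in cv_series.items() if v > cutoff} - common
    return common, variable, cv_series
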