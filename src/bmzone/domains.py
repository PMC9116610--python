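"""Cross-species protein-domain enrichment for the BM-zone gene set.

For each species, every InterPro-style domain accession is tested for
over-representation among BM-zone genes relative to the whole proteome with
a one-sided hypergeometric test on gene-level presence/absence, followed by
Benjamini-Hochberg FDR control.  Domains enriched in human and in enough
other species form the conserved BM-enriched domain set that seeds the
domain-sharing network.

Copy counts (tandem repeats of a domain within one protein) are carried
through as descriptive output — the ``count_ratio`` used for dot sizing —
but the test itself is on presence/absence so repeat expansions do not
pseudo-replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DomainAnnotation",
    "EnrichedDomain",
    "read_domain_table",
    "write_enrichment_table",
    "count_domains",
    "enrich_domains",
    "conserved_domains",
]


@dataclass(frozen=True)
class DomainAnnotation:
    """One (protein, domain) assignment with its within-protein copy count."""

    protein: str
    domain: str
    copies: int = 1

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError(f"{self.protein}/{self.domain}: copies must be >= 1")


@dataclass(frozen=True)
class EnrichedDomain:
    domain: str
    species: str
    bm_gene_hits: int
    bm_copies: int
    proteome_gene_hits: int
    proteome_copies: int
    p_value: float
    q_value: float

    @property
    def count_ratio(self) -> float:
        """BM-set copies over proteome-wide copies (dot-sizing statistic)."""
        return self.bm_copies / self.proteome_copies


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a per-species ``protein<TAB>domain<TAB>copies`` table.

    A two-column protein2ipr-style file (repeated protein/accession pairs,
    no copies column) is also accepted: pairs are aggregated to copy counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if not {"protein", "domain"} <= set(df.columns):
        raise ValueError("domain table needs 'protein' and 'domain' columns")
    if "copies" in df.columns:
        out = [
            DomainAnnotation(p, d, int(c))
            for p, d, c in zip(df["protein"], df["domain"], df["copies"])
        ]
        pairs = {(a.protein, a.domain) for a in out}
        if len(pairs) != len(out):
            raise ValueError("duplicate (protein, domain) rows; aggregate first")
        return out
    agg = df.groupby(["protein", "domain"], sort=True).size().reset_index(name="copies")
    return [
        DomainAnnotation(p, d, int(c))
        for p, d, c in zip(agg["protein"], agg["domain"], agg["copies"])
    ]


def count_domains(
    annotations: Iterable[DomainAnnotation], gene_set: set[str]
) -> dict[str, tuple[int, int]]:
    """Per-domain (distinct gene hits, total copies) within ``gene_set``.

    Genes in the set but absent from the annotation table contribute nothing
    (a warning is emitted); an empty set yields an empty map.
    """
    annotations = list(annotations)
    if not gene_set:
        return {}
    annotated = {a.protein for a in annotations}
    orphans = sorted(gene_set - annotated)
    if orphans:
        warnings.warn(
            f"{len(orphans)} gene(s) in set lack domain annotations: "
            + ", ".join(orphans[:5]) + ("..." if len(orphans) > 5 else ""),
            stacklevel=2,
        )
    out: dict[str, tuple[int, int]] = {}
    for a in annotations:
        if a.protein in gene_set:
            hits, copies = out.get(a.domain, (0, 0))
            out[a.domain] = (hits + 1, copies + a.copies)
    return out


def enrich_domains(
    bm_set: set[str],
    proteome: Sequence[DomainAnnotation],
    alpha: float = 0.05,
    species: str = "human",
) -> list[EnrichedDomain]:
    """One-sided hypergeometric over-representation per domain, BH-adjusted.

    For a domain carried by K of the N proteome genes, with k of the n
    BM-set genes carrying it, p = P[X >= k], X ~ Hypergeom(N, K, n).
    Returns domains with q <= alpha, sorted by (q, accession).  A domain
    present in every proteome gene has p = 1 by construction and can never
    be called enriched.
    """
    if not bm_set:
        raise ValueError("bm_set must be nonempty")
    proteome = list(proteome)
    proteome_genes = {a.protein for a in proteome}
    n_universe = len(proteome_genes)
    bm_in_universe = bm_set & proteome_genes
    if len(bm_in_universe) < len(bm_set):
        warnings.warn(
            f"{len(bm_set) - len(bm_in_universe)} BM gene(s) not in proteome; ignored",
            stacklevel=2,
        )
    n_draw = len(bm_in_universe)

    prot_counts = count_domains(proteome, proteome_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bm genes missing annotations already noted
        bm_counts = count_domains(proteome, bm_in_universe)

    domains = sorted(prot_counts)
    pvals = []
    for d in domains:
        K, _ = prot_counts[d]
        k, _ = bm_counts.get(d, (0, 0))
        # survival function at k-1 gives P[X >= k]
        pvals.append(float(hypergeom.sf(k - 1, n_universe, K, n_draw)))
    if not domains:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = []
    for d, p, q in zip(domains, pvals, qvals):
        k, bm_copies = bm_counts.get(d, (0, 0))
        if q <= alpha and k > 0:
            K, prot_copies = prot_counts[d]
            results.append(
                EnrichedDomain(
                    domain=d, species=species,
                    bm_gene_hits=k, bm_copies=bm_copies,
                    proteome_gene_hits=K, proteome_copies=prot_copies,
                    p_value=p, q_value=float(q),
                )
            )
    results.sort(key=lambda e: (e.q_value, e.domain))
    return results


def conserved_domains(
    per_species: Mapping[str, Sequence[EnrichedDomain]],
    min_species: int = 3,
) -> set[str]:
    """Domains enriched in human AND in at least ``min_species - 1`` others.

    Human enrichment is mandatory; the default requires two additional
    species (3 of 5 total).
    """
    if "human" not in per_species:
        raise ValueError("per_species must include 'human'")
    if min_species > len(per_species):
        warnings.warn(
            f"min_species={min_species} exceeds {len(per_species)} species; empty set",
            stacklevel=2,
        )
        return set()
    human = {e.domain for e in per_species["human"]}
    out = set()
    for d in human:
        n_other = sum(
            1
            for sp, hits in per_species.items()
            if sp != "human" and d in {e.domain for e in hits}
        )
        if n_other >= min_species - 1:
            out.add(d)
    return out


def write_enrichment_table(
    results: Iterable[EnrichedDomain], path: str | Path
) -> None:
    rows = [
        {
            "domain": e.domain,
            "species": e.species,
            "bm_gene_hits": e.bm_gene_hits,
            "bm_copies": e.bm_copies,
            "proteome_gene_hits": e.proteome_gene_hits,
            "proteome_copies": e.proteome_copies,
            "count_ratio": e.count_ratio,
            "p_value": e.p_value,
            "q_value": e.q_value,
        }
        for e in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
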