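"""Rare-variant pLoF burden screen for a case-control cohort.

Implements the genomic arm of the BM-zone pipeline: variant consequence
classification against the seven predicted loss-of-function (pLoF) terms,
in-cohort minor allele frequency recomputed from genotypes (strict
MAF < 0.01 rarity filter), per-gene carrier 2x2 tables comparing affected
individuals to unaffected relatives with Fisher exact p-values and odds
ratios, stratification by prior disease-evidence tier, gnomAD constraint
flags (pLI > 0.9, LOEUF < 0.2), a high-penetrance homozygous-pLoF filter,
and compound-heterozygote candidate flagging.

The burden unit is the individual (carrier counts), not the allele:
a sample is a carrier when it holds at least one qualifying genotype in
the gene.  Missing genotypes never make a carrier and are excluded from
MAF denominators.  Kinship structure among relatives is not modeled.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

__all__ = [
    "PLOF_TERMS",
    "ConsequenceClass",
    "ZygosityMode",
    "CohortDataset",
    "classify_consequence",
    "cohort_maf",
    "fisher_burden_test",
    "gene_burden",
    "stratified_burden",
    "constraint_flags",
    "high_penetrance_filter",
    "compound_het_candidates",
    "read_cohort_vcf",
    "read_phenotypes",
    "read_tiers",
    "DEFAULT_INFO_MAP",
]

# The seven consequence terms counted as predicted loss-of-function.
PLOF_TERMS = frozenset(
    {
        "stop_lost",
        "start_lost",
        "stop_gained",
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "frameshift_variant",
    }
)

# genotype codes in the genotype matrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class ConsequenceClass(str, enum.Enum):
    pLoF = "pLoF"
    missense = "missense"
    synonymous = "synonymous"
    other = "other"


class ZygosityMode(str, enum.Enum):
    hom_pLoF = "hom_pLoF"
    het_pLoF = "het_pLoF"
    any_pLoF = "any_pLoF"


def classify_consequence(term: str) -> ConsequenceClass:
    """Classify a VEP-style consequence string.

    Multi-term annotations joined by ',' or '&' are allowed; any pLoF
    member wins, then missense, then synonymous; unknown terms fall back
    to 'other'.
    """
    if not term or not term.strip():
        raise ValueError("empty consequence term")
    parts = [p.strip() for p in term.replace("&", ",").split(",") if p.strip()]
    if any(p in PLOF_TERMS for p in parts):
        return ConsequenceClass.pLoF
    if "missense_variant" in parts:
        return ConsequenceClass.missense
    if "synonymous_variant" in parts:
        return ConsequenceClass.synonymous
    return ConsequenceClass.other


def cohort_maf(genotypes: np.ndarray) -> float:
    """Folded minor allele frequency from diploid genotype codes.

    alt allele count / (2 x non-missing samples), folded to min(f, 1-f).
    All-missing rows are undefined (NaN) — callers drop such variants.
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        return float("nan")
    alt = int(g[called].sum())  # het contributes 1, hom_alt 2
    f = alt / (2 * n)
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Annotated variants + genotype matrix + sample phenotypes.

    ``variants`` columns: gene, variant_id, consequence, canonical (bool),
    lof_confidence (HC/LC/NA), gnomad_hom_count (int).  ``genotypes`` is an
    int8 array of shape (n_variants, n_samples) with codes 0/1/2/-1.
    ``phenotype`` maps each sample to 'affected' or 'unaffected'.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    phenotype: pd.Series

    def __post_init__(self):
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        missing = [s for s in self.samples if s not in self.phenotype.index]
        if missing:
            raise ValueError(f"samples without phenotype: {missing[:5]}")
        bad = set(self.phenotype.unique()) - {"affected", "unaffected"}
        if bad:
            raise ValueError(f"unknown phenotype value(s): {sorted(bad)}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def affected_mask(self) -> np.ndarray:
        return np.array(
            [self.phenotype[s] == "affected" for s in self.samples], dtype=bool
        )

    def variant_classes(self) -> pd.Series:
        return self.variants["consequence"].map(lambda t: classify_consequence(t).value)

    def cohort_mafs(self) -> np.ndarray:
        return np.array([cohort_maf(row) for row in self.genotypes])

    def qualifying_mask(
        self,
        maf_max: float = 0.01,
        require_canonical: bool = True,
        require_hc: bool = False,
        classes: Sequence[str] = ("pLoF",),
    ) -> np.ndarray:
        """Boolean mask over variants passing class/canonical/rarity filters.

        The MAF bound is strict (< maf_max).  All-missing variants are
        dropped with a warning.
        """
        cls = self.variant_classes().isin(classes).values
        mask = cls.copy()
        if require_canonical:
            mask &= self.variants["canonical"].astype(bool).values
        if require_hc:
            mask &= (self.variants["lof_confidence"] == "HC").values
        mafs = self.cohort_mafs()
        undefined = np.isnan(mafs)
        if (undefined & mask).any():
            warnings.warn(
                f"{int((undefined & mask).sum())} variant(s) with no called "
                "genotypes dropped",
                stacklevel=2,
            )
        mask &= ~undefined
        mask &= mafs < maf_max
        return mask


# ---------------------------------------------------------------------------
# Fisher burden machinery
# ---------------------------------------------------------------------------


def _haldane_or_ci(table: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Cross-product OR with Haldane-Anscombe correction and Wald CI.

    +0.5 is added to all cells only when some cell is zero; the Wald CI on
    log OR uses the (possibly adjusted) cells.
    """
    t = np.asarray(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    return (
        float(or_point),
        float(np.exp(np.log(or_point) - z * se)),
        float(np.exp(np.log(or_point) + z * se)),
    )


def fisher_burden_test(
    table: Sequence[Sequence[int]], alternative: str = "two-sided",
    cmle: bool = True,
) -> dict:
    """Exact test and odds-ratio estimates for a 2x2 carrier table.

    ``table`` rows are (affected, unaffected), columns (carrier,
    non-carrier).  Returns the exact Fisher p, the cross-product OR with
    Haldane-Anscombe handling of zero cells and its Wald 95% CI (the
    reported interval), and — when ``cmle`` — the conditional-MLE OR with
    its exact CI.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    _, p = fisher_exact(t, alternative=alternative)
    or_point, lo, hi = _haldane_or_ci(t)
    out = {
        "or_point": or_point,
        "ci_low": lo,
        "ci_high": hi,
        "p_value": float(p),
    }
    if cmle:
        res = _cmle_odds_ratio(t, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        out["or_cmle"] = float(res.statistic)
        out["ci_cmle_low"] = float(ci.low)
        out["ci_cmle_high"] = float(ci.high)
    return out


def _carrier_matrix(
    dataset: CohortDataset, mask: np.ndarray, mode: ZygosityMode
) -> tuple[list[str], np.ndarray]:
    """Per-gene boolean carrier matrix (genes x samples) under a zygosity mode."""
    mode = ZygosityMode(mode)
    if mode is ZygosityMode.hom_pLoF:
        hit = dataset.genotypes == HOM_ALT
    elif mode is ZygosityMode.het_pLoF:
        hit = dataset.genotypes == HET
    else:
        hit = dataset.genotypes >= HET
    hit = hit & mask[:, None]
    genes = sorted(dataset.variants.loc[mask, "gene"].unique())
    carriers = np.zeros((len(genes), len(dataset.samples)), dtype=bool)
    gene_idx = {g: i for i, g in enumerate(genes)}
    var_genes = dataset.variants["gene"].values
    for vi in np.nonzero(mask)[0]:
        carriers[gene_idx[var_genes[vi]]] |= hit[vi]
    return genes, carriers


def _burden_row(
    carriers: np.ndarray, affected: np.ndarray, cmle: bool
) -> dict:
    aff_car = int((carriers & affected).sum())
    aff_non = int((~carriers & affected).sum())
    unaff_car = int((carriers & ~affected).sum())
    unaff_non = int((~carriers & ~affected).sum())
    stats = fisher_burden_test(
        [[aff_car, aff_non], [unaff_car, unaff_non]], cmle=cmle
    )
    return {
        "aff_carriers": aff_car,
        "aff_noncarriers": aff_non,
        "unaff_carriers": unaff_car,
        "unaff_noncarriers": unaff_non,
        **stats,
    }


def gene_burden(
    dataset: CohortDataset,
    mode: ZygosityMode | str = ZygosityMode.hom_pLoF,
    maf_max: float = 0.01,
    cmle: bool = True,
) -> pd.DataFrame:
    """Per-gene carrier burden: 2x2 table, Fisher exact p, OR with 95% CI.

    Qualifying variants are canonical rare pLoF (strict MAF < ``maf_max``);
    a sample is a carrier when it holds >= 1 qualifying genotype under
    ``mode`` anywhere in the gene.  Genes with no qualifying variants are
    omitted.
    """
    mask = dataset.qualifying_mask(maf_max=maf_max)
    genes, carriers = _carrier_matrix(dataset, mask, ZygosityMode(mode))
    affected = dataset.affected_mask
    rows = []
    for gi, gene in enumerate(genes):
        row = {"gene": gene, "zygosity_mode": ZygosityMode(mode).value}
        row.update(_burden_row(carriers[gi], affected, cmle))
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_burden(
    dataset: CohortDataset,
    tiers: Mapping[str, str],
    mode: ZygosityMode | str = ZygosityMode.hom_pLoF,
    maf_max: float = 0.01,
    cmle: bool = True,
) -> pd.DataFrame:
    """Burden pooled across genes within each disease-evidence tier.

    A sample is a tier carrier when it carries in any gene of that tier.
    An 'all' row pools every gene.  Every gene must carry a tier label.
    """
    mask = dataset.qualifying_mask(maf_max=maf_max)
    genes, carriers = _carrier_matrix(dataset, mask, ZygosityMode(mode))
    unknown = [g for g in genes if g not in tiers]
    if unknown:
        raise ValueError(f"genes without tier assignment: {unknown[:5]}")
    affected = dataset.affected_mask
    rows = []
    tier_order = ["high", "moderate_low", "none"]
    present = [t for t in tier_order if t in set(tiers[g] for g in genes)]
    for tier in present + ["all"]:
        idx = [
            i for i, g in enumerate(genes) if tier == "all" or tiers[g] == tier
        ]
        pooled = (
            carriers[idx].any(axis=0)
            if idx
            else np.zeros(len(dataset.samples), dtype=bool)
        )
        row = {"tier": tier, "n_genes": len(idx),
               "zygosity_mode": ZygosityMode(mode).value}
        row.update(_burden_row(pooled, affected, cmle))
        rows.append(row)
    return pd.DataFrame(rows)


def constraint_flags(records: pd.DataFrame) -> pd.DataFrame:
    """gnomAD constraint flags: pLI > 0.9 and LOEUF < 0.2 thresholds.

    Expects columns gene, pli, loeuf; missing metrics yield NA flags.
    """
    out = records.copy()
    if (out["loeuf"].dropna() <= 0).any():
        raise ValueError("LOEUF must be positive")
    if ((out["pli"].dropna() < 0) | (out["pli"].dropna() > 1)).any():
        raise ValueError("pLI must lie in [0, 1]")
    out["pli_intolerant"] = out["pli"].map(
        lambda v: bool(v > 0.9) if pd.notna(v) else pd.NA
    )
    out["loeuf_intolerant"] = out["loeuf"].map(
        lambda v: bool(v < 0.2) if pd.notna(v) else pd.NA
    )
    return out


@dataclass
class PenetranceVerdict:
    gene: str
    passes: bool
    reasons: list[str] = field(default_factory=list)
    n_affected_hom: int = 0
    prioritized: bool = False


def high_penetrance_filter(
    dataset: CohortDataset, maf_max: float = 0.01
) -> list[PenetranceVerdict]:
    """High-penetrance homozygous-pLoF gene filter.

    Qualifying variants are canonical, high-confidence (HC) pLoF, rare in
    the cohort.  A gene passes iff (a) every qualifying variant has at most
    1 homozygote in gnomAD, (b) no unaffected individual is homozygous for
    a qualifying variant, and (c) at least one affected individual is.
    Genes with >= 2 affected homozygotes are prioritized.
    """
    mask = dataset.qualifying_mask(maf_max=maf_max, require_hc=True)
    affected = dataset.affected_mask
    hom = dataset.genotypes == HOM_ALT
    verdicts = []
    for gene in sorted(dataset.variants["gene"].unique()):
        vidx = np.nonzero(mask & (dataset.variants["gene"] == gene).values)[0]
        if len(vidx) == 0:
            continue
        reasons = []
        gnomad = dataset.variants.loc[vidx, "gnomad_hom_count"].astype(int)
        if (gnomad > 1).any():
            reasons.append("gnomad_hom_count > 1 for a qualifying variant")
        gene_hom = hom[vidx].any(axis=0)
        n_unaff_hom = int((gene_hom & ~affected).sum())
        if n_unaff_hom > 0:
            reasons.append("unaffected hom present")
        n_aff_hom = int((gene_hom & affected).sum())
        if n_aff_hom == 0:
            reasons.append("no affected hom")
        verdicts.append(
            PenetranceVerdict(
                gene=gene,
                passes=not reasons,
                reasons=reasons,
                n_affected_hom=n_aff_hom,
                prioritized=(not reasons) and n_aff_hom >= 2,
            )
        )
    return verdicts


def compound_het_candidates(
    dataset: CohortDataset,
    phase: Mapping[tuple[str, str, str], str] | None = None,
    maf_max: float = 0.01,
) -> pd.DataFrame:
    """Samples het at >= 2 qualifying variants of one gene.

    Qualifying variants are canonical rare pLoF or missense; a candidate
    pair must include at least one pLoF.  With phase data — a map from
    (sample, variant_id_a, variant_id_b) to 'trans' or 'cis' — pairs are
    confirmed (trans) or excluded (cis); without phase the pair is flagged
    'possible' only, never asserted in trans.
    """
    mask = dataset.qualifying_mask(
        maf_max=maf_max, classes=("pLoF", "missense")
    )
    classes = dataset.variant_classes()
    het = (dataset.genotypes == HET) & mask[:, None]
    rows = []
    for gene in sorted(dataset.variants["gene"].unique()):
        vidx = np.nonzero(mask & (dataset.variants["gene"] == gene).values)[0]
        if len(vidx) < 2:
            continue
        for si, sample in enumerate(dataset.samples):
            carried = [vi for vi in vidx if het[vi, si]]
            if len(carried) < 2:
                continue
            for i in range(len(carried)):
                for j in range(i + 1, len(carried)):
                    va = dataset.variants.loc[carried[i], "variant_id"]
                    vb = dataset.variants.loc[carried[j], "variant_id"]
                    if classes[carried[i]] != "pLoF" and classes[carried[j]] != "pLoF":
                        continue
                    status = "possible"
                    if phase is not None:
                        ph = phase.get((sample, va, vb)) or phase.get(
                            (sample, vb, va)
                        )
                        if ph == "cis":
                            continue
                        if ph == "trans":
                            status = "confirmed"
                    rows.append(
                        {
                            "gene": gene,
                            "sample": sample,
                            "status": dataset.phenotype[sample],
                            "variant_a": va,
                            "variant_b": vb,
                            "phase": status,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "status", "variant_a", "variant_b", "phase"],
    )


# ---------------------------------------------------------------------------
# VCF / phenotype IO
# ---------------------------------------------------------------------------

DEFAULT_INFO_MAP = {
    "gene": "GENE",
    "consequence": "CSQ",
    "canonical": "CANON",
    "lof_confidence": "LOF",
    "gnomad_hom_count": "GNOMAD_HOM",
}


def read_phenotypes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    if not {"sample", "status"} <= set(df.columns):
        raise ValueError("phenotype table needs 'sample' and 'status' columns")
    return pd.Series(df["status"].values, index=df["sample"].values, name="status")


def read_tiers(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    if not {"gene", "tier"} <= set(df.columns):
        raise ValueError("tier table needs 'gene' and 'tier' columns")
    return dict(zip(df["gene"], df["tier"]))


def read_cohort_vcf(
    vcf_path: str | Path,
    phenotype_path: str | Path,
    info_map: Mapping[str, str] | None = None,
) -> CohortDataset:
    """Load an annotated VCF + phenotype table into a CohortDataset.

    INFO field names are mapped via ``info_map`` (defaults above).
    Multiallelic records must be pre-split.  cyvcf2 genotype codes are
    remapped to 0/1/2/-1 (hom_ref/het/hom_alt/missing).
    """
    from cyvcf2 import VCF

    info_map = dict(DEFAULT_INFO_MAP, **(info_map or {}))
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, gts = [], []
    code = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; pre-split required"
            )
        rows.append(
            {
                "gene": rec.INFO.get(info_map["gene"]),
                "variant_id": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                "consequence": rec.INFO.get(info_map["consequence"], ""),
                "canonical": str(
                    rec.INFO.get(info_map["canonical"], "0")
                ) in {"1", "YES", "True", "true"},
                "lof_confidence": str(rec.INFO.get(info_map["lof_confidence"], "NA")),
                "gnomad_hom_count": int(
                    rec.INFO.get(info_map["gnomad_hom_count"], 0)
                ),
            }
        )
        gts.append([code[int(t)] for t in rec.gt_types])
    variants = pd.DataFrame(rows)
    genotypes = np.array(gts, dtype=np.int8).reshape(len(rows), len(samples))
    phenotype = read_phenotypes(phenotype_path)
    return CohortDataset(
        variants=variants, genotypes=genotypes, samples=samples, phenotype=phenotype
    )
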