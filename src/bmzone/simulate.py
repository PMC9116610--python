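"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: per-species
protein-domain annotation tables with planted BM-enriched domains and a
planted hub/bridge topology, tissue expression matrices with planted
variance classes and tissue blocks, STRING-style interaction link tables
with a planted confidence-bin mixture, and a diploid case-control cohort
with planted per-gene carrier odds ratios plus high-penetrance pass/fail
gene roles.  Each generator is a pure function of (config, seed): the same
seed reproduces the same output byte for byte, and each generator draws
from its own substream so adding one call never perturbs another.

The planted truths are returned (and exported) in machine-readable form so
recovery tests never hard-code expected values.

Proteome topology.  The BM set contains five densely intra-connected
"hub-side" modules (each with its own core domain carried by every
member), one larger "bridge-side" module whose members carry nothing else,
a hub protein carrying one core domain from each hub-side module (top
degree by construction), and a bridge protein carrying the core domains of
hub-side module 0 and of the bridge-side module — the sole articulation
point between the two, hence the top betweenness score.  A ubiquitous
EGF-like domain and six planted accessory domains spread over hub-side
members provide enrichment signal and cross-module shortcuts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import HET, HOM_ALT, HOM_REF, CohortDataset
from .domains import DomainAnnotation

__all__ = [
    "ProteomeConfig",
    "ExpressionConfig",
    "CohortConfig",
    "InteractionConfig",
    "SyntheticConfig",
    "gen_proteome",
    "gen_expression",
    "gen_cohort",
    "gen_interactions",
    "write_cohort_vcf",
    "write_phenotypes",
]

# substream ids: one per generator, so streams are independent under a seed
_STREAMS = {"proteome": 1, "expression": 2, "cohort": 3, "interactions": 4}

SPECIES_ALL = ("human", "mouse", "zebrafish", "drosophila", "celegans")
_SP_CODE = {
    "human": "HS", "mouse": "MM", "zebrafish": "DR",
    "drosophila": "DM", "celegans": "CE",
}


def _rng(seed: int, component: str, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component], sub])


# ---------------------------------------------------------------------------
# Proteome / domain annotations
# ---------------------------------------------------------------------------


@dataclass
class ProteomeConfig:
    n_genes: int = 1000
    n_domains: int = 300
    zipf_exponent: float = 1.2
    n_hub_modules: int = 5          # modules the hub spans
    hub_module_size: int = 9
    bridge_module_size: int = 20    # module reachable only through the bridge
    p_ubiquitous: float = 0.3       # hub-side members carrying the EGF-like domain
    n_extra_domains: int = 6        # planted accessory enriched domains
    extra_carriers: int = 9         # BM carriers per accessory domain (<=2 per gene)
    bg_rate_core: float = 0.01      # background carrier rates of planted domains
    bg_rate_ubiquitous: float = 0.05
    bg_rate_extra: float = 0.02
    bg_domains_mean: float = 2.0    # Poisson mean of extra background domains/gene
    enrichment_fold: float = 8.0    # descriptive: BM vs background planted rate ratio

    @property
    def bm_set_size(self) -> int:
        return self.n_hub_modules * self.hub_module_size + self.bridge_module_size + 2

    def __post_init__(self):
        if self.bm_set_size >= self.n_genes:
            raise ValueError("bm_set_size must be smaller than n_genes")
        planted = self.n_hub_modules + 1 + 1 + self.n_extra_domains + 2
        if planted >= self.n_domains:
            raise ValueError("n_domains too small for planted structure")


@dataclass
class ProteomeTruth:
    bm_genes: dict[str, list[str]]
    enriched_domains: dict[str, list[str]]  # per species
    conserved_domains: list[str]
    hub: dict[str, str]
    bridge: dict[str, str]
    modules: dict[str, dict[str, list[str]]]


def _domain_name(i: int) -> str:
    return f"IPR{i:06d}"


def gen_proteome(
    config: ProteomeConfig | None = None,
    seed: int = 0,
    species: Sequence[str] = SPECIES_ALL,
) -> tuple[dict[str, list[DomainAnnotation]], ProteomeTruth]:
    """Per-species domain annotation tables with planted enrichment truth.

    The planted enriched domains (module cores, the ubiquitous domain, and
    the accessory domains) are over-represented in every generated
    species' BM set; two decoy domains are enriched only in C. elegans to
    exercise the human-anchor conservation rule.
    """
    cfg = config or ProteomeConfig()
    n_mod = cfg.n_hub_modules
    cores = [_domain_name(i + 1) for i in range(n_mod)]           # hub-side cores
    bridge_core = _domain_name(n_mod + 1)                         # bridge-side core
    ubiq = _domain_name(n_mod + 2)
    extras = [_domain_name(n_mod + 3 + i) for i in range(cfg.n_extra_domains)]
    worm_only = [
        _domain_name(n_mod + 3 + cfg.n_extra_domains + i) for i in range(2)
    ]
    n_reserved = n_mod + 2 + cfg.n_extra_domains + 2
    background = [
        _domain_name(i + 1) for i in range(n_reserved, cfg.n_domains)
    ]
    zipf_w = 1.0 / np.arange(1, len(background) + 1) ** cfg.zipf_exponent
    zipf_w /= zipf_w.sum()

    planted = cores + [bridge_core, ubiq] + extras
    tables: dict[str, list[DomainAnnotation]] = {}
    truth_bm: dict[str, list[str]] = {}
    truth_enriched: dict[str, list[str]] = {}
    truth_modules: dict[str, dict[str, list[str]]] = {}
    hub_ids: dict[str, str] = {}
    bridge_ids: dict[str, str] = {}

    for sp_i, sp in enumerate(species):
        rng = _rng(seed, "proteome", sub=10 + sp_i)
        code = _SP_CODE.get(sp, sp[:2].upper())
        genes = [f"{code}_G{i + 1:04d}" for i in range(cfg.n_genes)]
        hub_side = genes[: n_mod * cfg.hub_module_size]
        bridge_side = genes[
            n_mod * cfg.hub_module_size: n_mod * cfg.hub_module_size
            + cfg.bridge_module_size
        ]
        hub = genes[cfg.bm_set_size - 2]
        bridge = genes[cfg.bm_set_size - 1]
        bm = hub_side + bridge_side + [hub, bridge]
        bg_genes = genes[cfg.bm_set_size:]

        ann: dict[tuple[str, str], int] = {}

        def add(gene: str, domain: str, copies: int = 1):
            ann[(gene, domain)] = ann.get((gene, domain), 0) + copies

        modules: dict[str, list[str]] = {}
        for m in range(n_mod):
            members = hub_side[m * cfg.hub_module_size:(m + 1) * cfg.hub_module_size]
            modules[f"module_{m}"] = members
            for g in members:
                add(g, cores[m], int(rng.integers(1, 4)))
        modules["bridge_module"] = list(bridge_side)
        for g in bridge_side:
            add(g, bridge_core, int(rng.integers(1, 4)))
        for d in cores:
            add(hub, d)
        add(bridge, cores[0])
        add(bridge, bridge_core)

        # ubiquitous EGF-like domain on a fraction of hub-side members
        for g in hub_side:
            if rng.random() < cfg.p_ubiquitous:
                add(g, ubiq, int(rng.integers(1, 6)))
        # accessory enriched domains, dealt round-robin so no member carries
        # more than ~2 of them (keeps member degrees well below the hub's)
        deck = list(rng.permutation(hub_side))
        pos = 0
        for d in extras:
            for _ in range(cfg.extra_carriers):
                add(deck[pos % len(deck)], d)
                pos += 1
        # worm-only decoy enrichment
        if sp == "celegans":
            for d in worm_only:
                for g in rng.choice(bm, size=8, replace=False):
                    add(str(g), d)

        # background occurrences of planted domains
        for d, rate in (
            *((c, cfg.bg_rate_core) for c in cores + [bridge_core]),
            (ubiq, cfg.bg_rate_ubiquitous),
            *((e, cfg.bg_rate_extra) for e in extras),
            *((w, cfg.bg_rate_core) for w in worm_only),
        ):
            hits = np.asarray(bg_genes)[rng.random(len(bg_genes)) < rate]
            for g in hits:
                add(str(g), d)

        # background domain law (Zipf) for every gene
        n_bg = 1 + rng.poisson(cfg.bg_domains_mean, size=cfg.n_genes)
        for g, k in zip(genes, n_bg):
            for d in rng.choice(background, size=min(int(k), len(background)),
                                replace=False, p=zipf_w):
                add(g, str(d), 1 + int(rng.poisson(0.3)))

        tables[sp] = [
            DomainAnnotation(g, d, c) for (g, d), c in sorted(ann.items())
        ]
        truth_bm[sp] = bm
        truth_enriched[sp] = sorted(planted + (worm_only if sp == "celegans" else []))
        truth_modules[sp] = modules
        hub_ids[sp] = hub
        bridge_ids[sp] = bridge

    truth = ProteomeTruth(
        bm_genes=truth_bm,
        enriched_domains=truth_enriched,
        conserved_domains=sorted(planted),
        hub=hub_ids,
        bridge=bridge_ids,
        modules=truth_modules,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionConfig:
    n_genes: int = 400
    n_tissues: int = 12
    n_blocks: int = 2
    block_fold: float = 4.0       # expression fold between preferred/other block
    noise_sigma: float = 0.4      # log-normal multiplicative noise (log scale)
    inflation_fold: float = 20.0  # log-noise multiplier for planted very_high genes
    constant_sigma: float = 0.02  # residual noise of planted low-variance genes

    def __post_init__(self):
        if self.n_tissues < 4:
            raise ValueError("need n_tissues >= 4")
        if self.n_genes % 4:
            raise ValueError("n_genes must be divisible by 4")


@dataclass
class ExpressionTruth:
    gene_bins: dict[str, str]        # planted low / very_high (others 'mid')
    tissue_blocks: dict[str, int]


def gen_expression(
    config: ExpressionConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Tissue-blocked expression with planted variance classes.

    One quarter of genes is near-constant (truth 'low'); one quarter
    (truth 'very_high') has its tissue-block spread inflated by
    ``inflation_fold`` on the linear scale, so its cross-tissue standard
    deviation exceeds a mid gene's by construction, not just in
    expectation; the remaining half carries the default block signal that
    drives tissue clustering.  Baselines span a narrow range so baseline
    differences cannot reorder the variance classes.
    """
    cfg = config or ExpressionConfig()
    rng = _rng(seed, "expression")
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    tissues = [f"tissue_{t + 1:02d}" for t in range(cfg.n_tissues)]
    blocks = np.arange(cfg.n_tissues) * cfg.n_blocks // cfg.n_tissues

    q = cfg.n_genes // 4
    classes = np.array(["low"] * q + ["mid"] * (2 * q) + ["very_high"] * q)
    classes = classes[rng.permutation(cfg.n_genes)]

    base = rng.uniform(80.0, 120.0, size=cfg.n_genes)
    half_log_fold = np.log(cfg.block_fold) / 2.0
    values = np.empty((cfg.n_genes, cfg.n_tissues))
    for gi in range(cfg.n_genes):
        cls = classes[gi]
        if cls == "low":
            logx = rng.normal(0.0, cfg.constant_sigma, size=cfg.n_tissues)
        else:
            half = half_log_fold
            if cls == "very_high":
                half = half_log_fold + np.log(cfg.inflation_fold)
            pref = rng.integers(0, cfg.n_blocks)
            signal = np.where(blocks == pref, half, -half)
            logx = signal + rng.normal(0.0, cfg.noise_sigma, size=cfg.n_tissues)
        values[gi] = base[gi] * np.exp(logx)

    matrix = pd.DataFrame(values, index=genes, columns=tissues).rename_axis("gene")
    truth = ExpressionTruth(
        gene_bins={g: c for g, c in zip(genes, classes)},
        tissue_blocks={t: int(b) for t, b in zip(tissues, blocks)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    n_affected: int = 1000
    n_unaffected: int = 1000
    n_risk_genes: int = 3
    n_null_genes: int = 13
    planted_or: float = 5.0           # carrier odds ratio of risk genes
    background_carrier_rate: float = 0.05  # hom-carrier probability, unaffecteds
    n_plof_variants: int = 60         # qualifying variants per gene
    n_filler_variants: int = 6        # missense/synonymous variants per gene
    het_noise_rate: float = 0.001     # per-sample het probability at pLoF variants
    maf_beta: tuple[float, float] = (0.5, 50.0)  # filler allele-frequency law
    missingness: float = 0.002

    @property
    def n_genes(self) -> int:
        # risk + null + 2 high-penetrance passes + 2 planted decoys
        return self.n_risk_genes + self.n_null_genes + 4


def toy_cohort_config() -> CohortConfig:
    """Desk-size cohort used for the shipped filter-logic fixture.

    Small enough to store as plain text, large enough that a single
    homozygote at a variant stays below the MAF < 0.01 rarity bound
    (1 hom in 160 samples gives MAF 2/320 = 0.00625).
    """
    return CohortConfig(
        n_affected=80,
        n_unaffected=80,
        n_risk_genes=1,
        n_null_genes=1,
        n_plof_variants=6,
        n_filler_variants=2,
        background_carrier_rate=0.02,
        het_noise_rate=0.002,
        missingness=0.005,
    )


@dataclass
class CohortTruth:
    gene_roles: dict[str, str]
    true_or: dict[str, float]
    tiers: dict[str, str]
    penetrance_expected: dict[str, bool]
    phase: list[dict[str, str]]


def _carrier_probs(p0: float, oddsratio: float) -> tuple[float, float]:
    odds0 = p0 / (1 - p0)
    odds1 = oddsratio * odds0
    return odds1 / (1 + odds1), p0


def gen_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[CohortDataset, CohortTruth]:
    """Diploid case-control cohort with planted per-gene carrier odds ratios.

    Risk genes enrich homozygous-pLoF carriers among affecteds at the
    configured odds ratio; null genes carry equal rates in both groups.
    Two "novel" genes satisfy every high-penetrance criterion (one with
    multiple affected homozygotes, hence prioritized), one decoy violates
    the gnomAD <=1 homozygote rule, and one decoy plants an unaffected
    homozygote.  Carriers are spread over many distinct variants so each
    variant stays below the MAF < 0.01 rarity bound; common-pLoF,
    non-canonical and low-confidence decoy variants are planted to
    exercise the qualifying filters, and one null gene carries a phased
    compound-het pair (one trans, one cis).
    """
    cfg = config or CohortConfig()
    rng = _rng(seed, "cohort")
    n = cfg.n_affected + cfg.n_unaffected
    samples = [f"S{i + 1:05d}" for i in range(n)]
    affected = np.zeros(n, dtype=bool)
    affected[: cfg.n_affected] = True
    phenotype = pd.Series(
        np.where(affected, "affected", "unaffected"), index=samples, name="status"
    )

    roles = (
        ["risk"] * cfg.n_risk_genes
        + ["null"] * cfg.n_null_genes
        + ["novel_multi", "novel_single", "decoy_gnomad", "decoy_unaff_hom"]
    )
    genes = [f"BMG{i + 1:03d}" for i in range(cfg.n_genes)]
    gene_roles = dict(zip(genes, roles))

    plof_pool = [
        "frameshift_variant", "stop_gained", "splice_acceptor_variant",
        "splice_donor_variant", "stop_lost", "start_lost", "transcript_ablation",
    ]
    rows: list[dict] = []
    gts: list[np.ndarray] = []
    chrom_pos = 1000

    def new_variant(gene, consequence, canonical=True, lof="HC", gnomad=0):
        nonlocal chrom_pos
        chrom_pos += int(rng.integers(50, 500))
        return {
            "gene": gene,
            "chrom": "1",
            "pos": chrom_pos,
            "variant_id": f"1:{chrom_pos}:A:T",
            "consequence": consequence,
            "canonical": canonical,
            "lof_confidence": lof,
            "gnomad_hom_count": gnomad,
        }

    truth_or: dict[str, float] = {}
    tiers: dict[str, str] = {}
    phase: list[dict[str, str]] = []
    penetrance_expected: dict[str, bool] = {}

    for gi, (gene, role) in enumerate(zip(genes, roles)):
        # hom-carrier assignment per sample
        if role == "risk":
            p1, p0 = _carrier_probs(cfg.background_carrier_rate, cfg.planted_or)
            truth_or[gene] = cfg.planted_or
            tiers[gene] = "high"
        elif role == "null":
            p1 = p0 = cfg.background_carrier_rate
            truth_or[gene] = 1.0
            tiers[gene] = "moderate_low" if gi % 2 else "none"
        else:
            p1 = p0 = 0.0
            truth_or[gene] = 1.0
            tiers[gene] = "none"
        carrier = np.where(
            affected, rng.random(n) < p1, rng.random(n) < p0
        )

        # planted homozygotes for the penetrance-filter genes
        aff_idx = np.nonzero(affected)[0]
        unaff_idx = np.nonzero(~affected)[0]
        if role == "novel_multi":
            carrier[rng.choice(aff_idx, size=3, replace=False)] = True
        elif role == "novel_single":
            carrier[rng.choice(aff_idx, size=1, replace=False)] = True
        elif role == "decoy_gnomad":
            carrier[rng.choice(aff_idx, size=2, replace=False)] = True
        elif role == "decoy_unaff_hom":
            carrier[rng.choice(aff_idx, size=2, replace=False)] = True
            carrier[rng.choice(unaff_idx, size=1, replace=False)] = True

        variants = [
            new_variant(
                gene,
                plof_pool[int(rng.integers(0, len(plof_pool)))],
                gnomad=5 if role == "decoy_gnomad" else int(rng.integers(0, 2)),
            )
            for v in range(cfg.n_plof_variants)
        ]
        # genotype matrix for this gene's pLoF variants; planted homozygotes
        # for the special roles go to distinct variants so no single variant
        # accumulates enough alleles to breach the MAF rarity bound
        g = np.zeros((cfg.n_plof_variants, n), dtype=np.int8)
        carriers_idx = np.nonzero(carrier)[0]
        # the first null gene hosts the phased compound-het pair on its
        # first two variants; keep those variants free of other genotypes
        # so the pair cannot be pushed over the MAF rarity bound
        ch_gene = role == "null" and not phase
        lo = 2 if ch_gene else 0
        if role in ("risk", "null"):
            which = rng.integers(lo, cfg.n_plof_variants, size=len(carriers_idx))
        else:
            which = rng.choice(
                cfg.n_plof_variants, size=len(carriers_idx), replace=False
            )
        g[which, carriers_idx] = HOM_ALT
        het = (rng.random((cfg.n_plof_variants, n)) < cfg.het_noise_rate) & (g == 0)
        if ch_gene:
            het[:2] = False
        g[het] = HET

        # compound-het plant: first null gene, two affected non-carriers
        if ch_gene:
            free = [s for s in aff_idx if g[0, s] == 0 and g[1, s] == 0]
            s_trans, s_cis = free[0], free[1]
            g[0, s_trans] = g[1, s_trans] = HET
            g[0, s_cis] = g[1, s_cis] = HET
            phase.append(
                {"sample": samples[s_trans], "variant_a": variants[0]["variant_id"],
                 "variant_b": variants[1]["variant_id"], "phase": "trans"}
            )
            phase.append(
                {"sample": samples[s_cis], "variant_a": variants[0]["variant_id"],
                 "variant_b": variants[1]["variant_id"], "phase": "cis"}
            )

        # filter-exercise decoy variants: common pLoF, non-canonical, LC
        extra = [
            new_variant(gene, "frameshift_variant"),
            new_variant(gene, "stop_gained", canonical=False),
            new_variant(gene, "stop_gained", lof="LC"),
        ]
        g_extra = np.zeros((len(extra), n), dtype=np.int8)
        common_f = 0.08
        draws = rng.random((2, n))
        g_extra[0][draws[0] < common_f ** 2] = HOM_ALT
        g_extra[0][(draws[0] >= common_f ** 2)
                   & (draws[1] < 2 * common_f * (1 - common_f))] = HET
        for i in (1, 2):
            hets = rng.random(n) < 0.002
            g_extra[i][hets] = HET

        # missense/synonymous fillers with Beta-law allele frequencies
        fillers = []
        g_fill = np.zeros((cfg.n_filler_variants, n), dtype=np.int8)
        for v in range(cfg.n_filler_variants):
            csq = "missense_variant" if v % 2 else "synonymous_variant"
            fillers.append(new_variant(gene, csq, lof="NA"))
            f = float(rng.beta(*cfg.maf_beta))
            u = rng.random(n)
            g_fill[v][u < f * f] = HOM_ALT
            g_fill[v][(u >= f * f) & (u < f * f + 2 * f * (1 - f))] = HET

        gene_g = np.vstack([g, g_extra, g_fill])
        if cfg.missingness > 0:
            gene_g[rng.random(gene_g.shape) < cfg.missingness] = -1
            # planted genotypes must survive missingness: re-apply the
            # special-role homozygotes and the phased compound-het pair
            if role not in ("risk", "null"):
                gene_g[which, carriers_idx] = HOM_ALT
            if role == "null" and phase and phase[0]["variant_a"] == variants[0][
                "variant_id"
            ]:
                for entry in phase:
                    si = samples.index(entry["sample"])
                    gene_g[0, si] = gene_g[1, si] = HET
        rows.extend(variants + extra + fillers)
        gts.append(gene_g)

        if role not in ("risk", "null"):
            penetrance_expected[gene] = role.startswith("novel")

    variants_df = pd.DataFrame(rows)
    genotypes = np.vstack(gts)
    dataset = CohortDataset(
        variants=variants_df,
        genotypes=genotypes,
        samples=samples,
        phenotype=phenotype,
    )
    truth = CohortTruth(
        gene_roles=gene_roles,
        true_or=truth_or,
        tiers=tiers,
        penetrance_expected=penetrance_expected,
        phase=phase,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

_BIN_RANGES = {
    "lowest": (0.0, 0.15),
    "low": (0.15, 0.4),
    "medium": (0.4, 0.7),
    "high": (0.7, 0.9),
    "highest": (0.9, 1.0),
}


@dataclass
class InteractionConfig:
    n_pairs: int = 500
    n_proteins: int = 80
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "lowest": 0.30, "low": 0.25, "medium": 0.25,
            "high": 0.15, "highest": 0.05,
        }
    )

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("bin mixture proportions must sum to 1")


def gen_interactions(
    config: InteractionConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """STRING-style link table with a planted confidence-bin mixture.

    Returns (table with protein1/protein2/combined_score, truth bin
    fractions actually drawn).
    """
    cfg = config or InteractionConfig()
    rng = _rng(seed, "interactions")
    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    bins = list(cfg.proportions)
    probs = np.array([cfg.proportions[b] for b in bins])
    chosen = rng.choice(len(bins), size=cfg.n_pairs, p=probs)
    pairs = set()
    rows = []
    for b_i in chosen:
        while True:
            a, b = rng.choice(len(proteins), size=2, replace=False)
            key = (min(a, b), max(a, b))
            if key not in pairs:
                pairs.add(key)
                break
        lo, hi = _BIN_RANGES[bins[b_i]]
        score = float(rng.uniform(lo + 1e-9, hi))
        rows.append(
            {"protein1": proteins[key[0]], "protein2": proteins[key[1]],
             "combined_score": round(score, 4)}
        )
    table = pd.DataFrame(rows)
    counts = pd.Series([bins[i] for i in chosen]).value_counts()
    truth = {b: float(counts.get(b, 0)) / cfg.n_pairs for b in bins}
    return table, truth


# ---------------------------------------------------------------------------
# Top-level config + exports
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    seed: int = 0
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    interactions: InteractionConfig = field(default_factory=InteractionConfig)


def write_phenotypes(phenotype: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample": phenotype.index, "status": phenotype.values})
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_cohort_vcf(dataset: CohortDataset, path: str | Path) -> None:
    """Minimal VCFv4.2 export with the annotation INFO fields the screen reads."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", -1: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">',
        '##INFO=<ID=CANON,Number=1,Type=String,Description="Canonical transcript (1/0)">',
        '##INFO=<ID=LOF,Number=1,Type=String,Description="LoF confidence (HC/LC/NA)">',
        '##INFO=<ID=GNOMAD_HOM,Number=1,Type=Integer,Description="gnomAD homozygote count">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dataset.samples),
    ]
    has_pos = "pos" in dataset.variants.columns
    for vi, row in dataset.variants.iterrows():
        chrom = str(row["chrom"]) if has_pos else "1"
        pos = int(row["pos"]) if has_pos else vi + 1
        info = (
            f"GENE={row['gene']};CSQ={row['consequence']};"
            f"CANON={1 if row['canonical'] else 0};LOF={row['lof_confidence']};"
            f"GNOMAD_HOM={int(row['gnomad_hom_count'])}"
        )
        gts = "\t".join(gt_str[int(g)] for g in dataset.genotypes[vi])
        lines.append(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth(truth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
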