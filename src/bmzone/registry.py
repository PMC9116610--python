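"""Curated basement-membrane (BM) zone gene registry.

The BM zone comprises the BM matrix proteins themselves plus their cell
surface interactors (CSIs).  Candidate genes enter the registry from a GO
seed list or from a network-expansion step, and each carries a set of
localization-evidence flags.  Evidence is tiered into three categories:

* ``confirmed`` ("green") — vertebrate tissue immunolocalization places the
  protein in the BM zone.
* ``predicted`` ("magenta") — interaction with a verified BM/CSI protein,
  BM-substrate-cleaving protease activity, or an ortholog localized to the
  BM zone by endogenous fluorescent tagging in an animal model.
* ``insufficient`` ("gray") — none of the above.

The verified registry keeps confirmed and predicted genes only, after first
removing genes flagged as GO misannotations.
"""

from __future__ import annotations

import enum
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NetworkRole",
    "MatrisomeClass",
    "DiseaseTier",
    "EvidenceCategory",
    "GeneRecord",
    "VerifiedRegistry",
    "SchemaError",
    "ValidationError",
    "classify_evidence",
    "build_verified_registry",
    "summarize_registry",
    "read_gene_table",
    "write_gene_table",
    "read_registry",
    "write_registry",
]

SPECIES = ("mouse", "zebrafish", "drosophila", "celegans")

EVIDENCE_FLAGS = (
    "vertebrate_immunolocalization",
    "ortholog_tag_localized",
    "interacts_with_verified",
    "bm_cleaving_protease",
    "go_misannotated",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Row-level contract violation (duplicate symbols, bad enum values...)."""


class NetworkRole(str, enum.Enum):
    BM_matrix = "BM_matrix"
    CSI = "CSI"


class MatrisomeClass(str, enum.Enum):
    collagen = "collagen"
    glycoprotein = "glycoprotein"
    proteoglycan = "proteoglycan"
    ECM_regulator = "ECM_regulator"
    ECM_affiliated = "ECM_affiliated"
    secreted_factor = "secreted_factor"
    CSI_receptor = "CSI_receptor"


class DiseaseTier(str, enum.Enum):
    high = "high"
    moderate_low = "moderate_low"
    none = "none"


class EvidenceCategory(str, enum.Enum):
    """Localization-evidence tier with its display color alias."""

    confirmed = "confirmed"
    predicted = "predicted"
    insufficient = "insufficient"

    @property
    def color(self) -> str:
        return {"confirmed": "green", "predicted": "magenta", "insufficient": "gray"}[
            self.value
        ]


@dataclass
class GeneRecord:
    """One BM-zone candidate gene with its curation annotations."""

    symbol: str
    network_role: NetworkRole
    matrisome_class: MatrisomeClass
    source: str = "GO_seed"  # GO_seed | expansion
    evidence_flags: dict[str, bool] = field(default_factory=dict)
    orthologs: dict[str, list[str]] = field(default_factory=dict)
    disease_tier: DiseaseTier = DiseaseTier.none
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")
        self.symbol = self.symbol.upper()
        self.network_role = NetworkRole(self.network_role)
        self.matrisome_class = MatrisomeClass(self.matrisome_class)
        self.disease_tier = DiseaseTier(self.disease_tier)
        for flag in EVIDENCE_FLAGS:
            self.evidence_flags.setdefault(flag, False)
        # CSI role and receptor class are two views of the same fact
        is_csi = self.network_role is NetworkRole.CSI
        is_receptor = self.matrisome_class is MatrisomeClass.CSI_receptor
        if is_csi != is_receptor:
            raise ValidationError(
                f"{self.symbol}: network_role=CSI iff matrisome_class=CSI_receptor"
            )
        # ortholog lists: order-preserving dedup
        self.orthologs = {
            sp: list(dict.fromkeys(ids)) for sp, ids in self.orthologs.items()
        }

    def flag(self, name: str) -> bool:
        return bool(self.evidence_flags.get(name, False))


def classify_evidence(record: GeneRecord) -> EvidenceCategory:
    """Tier a gene's localization evidence.

    Vertebrate immunolocalization alone confers ``confirmed``.  Interaction
    with a verified BM/CSI protein, BM-cleaving protease activity, or an
    animal-model ortholog tagged and localized to the BM zone confer
    ``predicted`` — ortholog tagging never promotes to confirmed (an ortholog
    localizing in worm leaves the human gene a predicted candidate).
    Total and deterministic: depends on the evidence flags only.
    """
    if record.flag("vertebrate_immunolocalization"):
        return EvidenceCategory.confirmed
    if (
        record.flag("interacts_with_verified")
        or record.flag("bm_cleaving_protease")
        or record.flag("ortholog_tag_localized")
    ):
        return EvidenceCategory.predicted
    return EvidenceCategory.insufficient


@dataclass
class VerifiedRegistry:
    """Confirmed + predicted BM-zone genes, after misannotation removal."""

    genes: list[GeneRecord]
    counts: dict[str, dict[str, int]]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in set(self.symbols())


def build_verified_registry(records: Iterable[GeneRecord]) -> VerifiedRegistry:
    """Drop GO-misannotated records, then insufficient-evidence records.

    The two removals are applied in that order so a misannotated gene is
    excluded even when its evidence flags would classify it as confirmed.
    The surviving list is sorted by symbol for deterministic output.
    """
    records = list(records)
    seen: Counter[str] = Counter(r.symbol for r in records)
    dupes = sorted(s for s, n in seen.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate symbols: {', '.join(dupes)}")

    survivors = [r for r in records if not r.flag("go_misannotated")]
    survivors = [
        r for r in survivors if classify_evidence(r) is not EvidenceCategory.insufficient
    ]
    survivors.sort(key=lambda r: r.symbol)
    if not survivors:
        warnings.warn("verified registry is empty", stacklevel=2)

    counts = {
        "category": dict(
            Counter(classify_evidence(r).value for r in survivors)
        ),
        "role": dict(Counter(r.network_role.value for r in survivors)),
        "matrisome_class": dict(
            Counter(r.matrisome_class.value for r in survivors)
        ),
        "total": {"genes": len(survivors)},
    }
    return VerifiedRegistry(genes=survivors, counts=counts)


def summarize_registry(registry: VerifiedRegistry) -> pd.DataFrame:
    """Counts per (category, role, matrisome class); grand total = registry size."""
    rows = [
        {
            "category": classify_evidence(r).value,
            "network_role": r.network_role.value,
            "matrisome_class": r.matrisome_class.value,
        }
        for r in registry
    ]
    if not rows:
        return pd.DataFrame(
            columns=["category", "network_role", "matrisome_class", "n"]
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["category", "network_role", "matrisome_class"], sort=True)
        .size()
        .reset_index(name="n")
    )
    assert int(df["n"].sum()) == len(registry)
    return df


# ---------------------------------------------------------------------------
# Table IO.  All tables: UTF-8, tab-delimited, header required, '#' comments.
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("symbol", "network_role", "matrisome_class")

_BOOLISH = {"1": True, "0": False, "true": True, "false": False,
            "yes": True, "no": False, "": False, "nan": False}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, encoding="utf-8")


def _parse_bool(value: str, column: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOLISH:
        raise ValidationError(f"column {column!r}: cannot parse boolean {value!r}")
    return _BOOLISH[key]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a curated gene table into records.

    Required columns: symbol, network_role, matrisome_class.  Evidence flags
    and disease_tier are optional (default false / none).  Ortholog columns
    named ``orthologs_<species>`` hold comma-separated identifiers.  Unknown
    columns are preserved verbatim in ``record.annotations``.
    """
    df = _read_tsv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    known = set(_REQUIRED_COLUMNS) | set(EVIDENCE_FLAGS) | {"source", "disease_tier"}
    known |= {f"orthologs_{sp}" for sp in SPECIES}
    extra = [c for c in df.columns if c not in known]

    records: list[GeneRecord] = []
    for _, row in df.iterrows():
        flags = {
            f: _parse_bool(row[f], f) for f in EVIDENCE_FLAGS if f in df.columns
        }
        orth = {}
        for sp in SPECIES:
            col = f"orthologs_{sp}"
            if col in df.columns and str(row[col]).strip():
                orth[sp] = [x.strip() for x in str(row[col]).split(",") if x.strip()]
        records.append(
            GeneRecord(
                symbol=str(row["symbol"]).strip(),
                network_role=str(row["network_role"]).strip(),
                matrisome_class=str(row["matrisome_class"]).strip(),
                source=str(row.get("source", "GO_seed")).strip() or "GO_seed",
                evidence_flags=flags,
                orthologs=orth,
                disease_tier=str(row.get("disease_tier", "none")).strip() or "none",
                annotations={c: str(row[c]) for c in extra},
            )
        )
    symbols = Counter(r.symbol for r in records)
    dupes = sorted(s for s, n in symbols.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate symbols: {', '.join(dupes)}")
    return records


def _record_row(r: GeneRecord) -> dict[str, str]:
    row: dict[str, str] = {
        "symbol": r.symbol,
        "network_role": r.network_role.value,
        "matrisome_class": r.matrisome_class.value,
        "source": r.source,
        "disease_tier": r.disease_tier.value,
    }
    for f in EVIDENCE_FLAGS:
        row[f] = "1" if r.flag(f) else "0"
    for sp in SPECIES:
        row[f"orthologs_{sp}"] = ",".join(r.orthologs.get(sp, []))
    row.update(r.annotations)
    return row


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame([_record_row(r) for r in records])
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_registry(registry: VerifiedRegistry, path: str | Path,
                   summary_path: str | Path | None = None) -> None:
    """Export registry as TSV (one row per gene, with evidence category)."""
    rows = []
    for r in registry:
        row = _record_row(r)
        row["evidence_category"] = classify_evidence(r).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps(registry.counts, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def read_registry(path: str | Path) -> VerifiedRegistry:
    """Read a registry export back; re-derives counts from the rows."""
    records = read_gene_table(path)
    for r in records:
        r.annotations.pop("evidence_category", None)
    return build_verified_registry(records)
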