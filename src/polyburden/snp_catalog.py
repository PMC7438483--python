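"""Harmonize GWAS association records and classify the frequency spectrum.

Harmonization steps, in order:

1. reject malformed records (non-ACGT or identical alleles), logging a reason;
2. drop records above the genome-wide p-value threshold (default 5e-8);
3. drop strand-ambiguous (A/T, C/G) records reported on the reverse strand
   unless ``keep_ambiguous`` — complementing cannot orient them;
4. complement both alleles of reverse-strand records and mark them forward;
5. flip records with OR < 1 (swap alleles, invert the OR) so the effect
   allele is always the risk-increasing one;
6. collapse duplicate snp_ids keeping the smallest p-value;
7. flag the risk subset: OR >= 1.2.

The resulting catalog is a fixed point of ``harmonize``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
RISK_OR_FLOOR = 1.2
GWAS_P_THRESHOLD = 5e-8

_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class AssociationRecord:
    """One catalog SNP: the unit of harmonization."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    pvalue: float
    strand: str = "forward"
    gene: str = ""

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is well-formed."""
        if self.effect_allele not in COMPLEMENT or self.other_allele not in COMPLEMENT:
            return "non_acgt_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if self.odds_ratio <= 0:
            return "nonpositive_or"
        if not (0 < self.pvalue <= 1):
            return "invalid_pvalue"
        if self.pos < 1:
            return "invalid_position"
        if self.strand not in ("forward", "reverse"):
            return "invalid_strand"
        return None

    @property
    def is_ambiguous(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class HarmonizedCatalog:
    """Harmonized records plus the OR >= 1.2 risk subset and the exclusion log."""

    records: tuple[AssociationRecord, ...]
    risk_subset: tuple[AssociationRecord, ...]
    exclusions: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.records)


def complement_alleles(record: AssociationRecord) -> AssociationRecord:
    return replace(
        record,
        effect_allele=COMPLEMENT[record.effect_allele],
        other_allele=COMPLEMENT[record.other_allele],
        strand="forward",
    )


def harmonize(
    records,
    p_threshold: float = GWAS_P_THRESHOLD,
    keep_ambiguous: bool = False,
) -> HarmonizedCatalog:
    """Apply the harmonization pipeline (see module docstring)."""
    exclusions: list[tuple[str, str]] = []
    kept: list[AssociationRecord] = []
    for rec in records:
        reason = rec.validate()
        if reason is not None:
            exclusions.append((rec.snp_id, reason))
            continue
        if rec.pvalue > p_threshold:
            exclusions.append((rec.snp_id, "above_p_threshold"))
            continue
        if rec.strand == "reverse":
            if rec.is_ambiguous and not keep_ambiguous:
                exclusions.append((rec.snp_id, "strand_ambiguous"))
                continue
            rec = complement_alleles(rec)
        if rec.odds_ratio < 1.0:
            rec = replace(
                rec,
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
                odds_ratio=1.0 / rec.odds_ratio,
            )
        kept.append(rec)

    # duplicate snp_ids: keep smallest p-value (first occurrence on ties)
    best: dict[str, AssociationRecord] = {}
    for rec in kept:
        cur = best.get(rec.snp_id)
        if cur is None or rec.pvalue < cur.pvalue:
            best[rec.snp_id] = rec
    deduped = tuple(best.values())

    if not deduped:
        raise ValueError("no records survive harmonization")
    risk = tuple(r for r in deduped if r.odds_ratio >= RISK_OR_FLOOR)
    return HarmonizedCatalog(records=deduped, risk_subset=risk, exclusions=tuple(exclusions))


def classify_spectrum(freqs) -> dict[str, int]:
    """Bin effect-allele frequencies: rare < 0.01 <= low_frequency < 0.05 <= common."""
    f = np.asarray(freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    return {
        "rare": int((f < 0.01).sum()),
        "low_frequency": int(((f >= 0.01) & (f < 0.05)).sum()),
        "common": int((f >= 0.05).sum()),
    }


# ---------------------------------------------------------------------------
# I/O — the summary TSV dialect written by synthetic_data
# ---------------------------------------------------------------------------

def read_summary(path: str | Path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    required = {"snp_id", "chr", "pos", "effect_allele", "other_allele", "or", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary file missing columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        gene = row.get("gene", "")
        records.append(
            AssociationRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chr"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                odds_ratio=float(row["or"]),
                pvalue=float(row["pvalue"]),
                strand=str(row.get("strand", "forward")),
                gene="" if pd.isna(gene) else str(gene),
            )
        )
    return records


def catalog_frame(catalog: HarmonizedCatalog) -> pd.DataFrame:
    rows = [
        {
            "snp_id": r.snp_id,
            "chr": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "or": r.odds_ratio,
            "pvalue": r.pvalue,
            "strand": r.strand,
            "gene": r.gene,
            "is_risk": r.odds_ratio >= RISK_OR_FLOOR,
        }
        for r in catalog.records
    ]
    return pd.DataFrame(rows)


def write_catalog(catalog: HarmonizedCatalog, path: str | Path) -> Path:
    path = Path(path)
    catalog_frame(catalog).to_csv(path, sep="\t", index=False)
    return path


def write_exclusions(catalog: HarmonizedCatalog, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(catalog.exclusions, columns=["snp_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_catalog(path: str | Path) -> HarmonizedCatalog:
    """Load a previously written harmonized catalog TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    records = tuple(
        AssociationRecord(
            snp_id=str(r["snp_id"]),
            chrom=str(r["chr"]),
            pos=int(r["pos"]),
            effect_allele=str(r["effect_allele"]),
            other_allele=str(r["other_allele"]),
            odds_ratio=float(r["or"]),
            pvalue=float(r["pvalue"]),
            strand=str(r["strand"]),
            gene="" if pd.isna(r["gene"]) else str(r["gene"]),
        )
        for r in df.to_dict("records")
    )
    risk = tuple(r for r in records if r.odds_ratio >= RISK_OR_FLOOR)
    return HarmonizedCatalog(records=records, risk_subset=risk)
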