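"""Genotype container, VCF/panel ingestion, and per-population allele frequencies.

The frequency table is long-format with one row per (snp_id, population):
``effect_count`` is the number of effect alleles observed, ``total_count`` is
twice the number of non-missing genotypes, and ``frequency`` their ratio.
A pooled row set (population label ``GLOBAL``) is obtained by summing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLOBAL_POP = "GLOBAL"


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with a population panel.

    ``dosages`` is float with values {0, 1, 2} and NaN for missing.
    ``variants`` has columns snp_id, chrom, pos (1-based), ref, alt.
    ``panel`` maps sample_id -> population label; every panel sample must be
    present in the matrix.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    panel: pd.Series

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")
        missing = set(self.panel.index) - set(self.samples)
        if missing:
            raise KeyError(f"panel samples absent from genotype matrix: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        return sorted(self.panel.unique())

    def population_mask(self, population: str) -> np.ndarray:
        """Boolean row mask for one population (sample order preserved)."""
        members = set(self.panel.index[self.panel == population])
        if not members:
            raise KeyError(f"unknown population {population!r}")
        return np.array([s in members for s in self.samples])

    def variant_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.variants.snp_id.to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"variant {snp_id!r} not in matrix")
        return int(hits[0])


def read_panel(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("panel file needs columns sample_id, population")
    return df.set_index("sample_id")["population"]


def read_vcf(vcf_path, panel_path) -> GenotypeMatrix:
    """Load a multi-sample VCF (GT field) into a GenotypeMatrix.

    Multiallelic and non-SNP sites are skipped with a log entry; only
    biallelic SNPs enter the matrix.
    """
    from cyvcf2 import VCF

    panel = read_panel(panel_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    rows = []
    dosage_rows = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP site %s:%s", var.CHROM, var.POS)
            continue
        gt = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.vstack(dosage_rows).T if dosage_rows else np.empty((len(samples), 0))
    )
    panel = panel[panel.index.isin(samples)]
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples, panel=panel)


# ---------------------------------------------------------------------------
# frequency computation
# ---------------------------------------------------------------------------

def _resolve_catalog(genotypes: GenotypeMatrix, records) -> tuple[list, list]:
    """Match harmonized records to matrix variants by (chrom, pos, allele pair).

    Returns (matches, excluded): matches are (record, variant_row_index,
    effect_is_alt) triples; excluded are (snp_id, reason) pairs.
    """
    v = genotypes.variants
    by_coord: dict[tuple[str, int], list[int]] = {}
    for j, (c, p) in enumerate(zip(v.chrom, v.pos)):
        by_coord.setdefault((str(c), int(p)), []).append(j)

    matches, excluded = [], []
    for rec in records:
        cand = by_coord.get((str(rec.chrom), int(rec.pos)), [])
        if len(cand) > 1:
            # tie-break on snp_id
            cand = [j for j in cand if v.snp_id.iloc[j] == rec.snp_id] or cand
        if not cand:
            excluded.append((rec.snp_id, "not_in_genotypes"))
            continue
        j = cand[0]
        ref, alt = v.ref.iloc[j], v.alt.iloc[j]
        if {rec.effect_allele, rec.other_allele} != {ref, alt}:
            excluded.append((rec.snp_id, "allele_mismatch"))
            logger.warning("allele mismatch for %s: catalog %s/%s vs VCF %s/%s",
                           rec.snp_id, rec.effect_allele, rec.other_allele, ref, alt)
            continue
        matches.append((rec, j, rec.effect_allele == alt))
    return matches, excluded


def allele_frequencies(genotypes: GenotypeMatrix, catalog) -> pd.DataFrame:
    """Effect-allele frequency of each catalog SNP in each population.

    The effect-allele frequency is the alt-allele frequency when the effect
    allele is alt, and its complement when the effect allele is ref. Missing
    dosages are excluded from the denominator. Unresolvable or
    allele-mismatched SNPs are excluded and listed in ``df.attrs['excluded']``.
    """
    matches, excluded = _resolve_catalog(genotypes, catalog.records)
    pops = genotypes.populations
    masks = {p: genotypes.population_mask(p) for p in pops}

    out = []
    for rec, j, effect_is_alt in matches:
        col = genotypes.dosages[:, j]
        for p in pops:
            d = col[masks[p]]
            ok = ~np.isnan(d)
            total = int(2 * ok.sum())
            alt_count = int(d[ok].sum())
            eff = alt_count if effect_is_alt else total - alt_count
            out.append(
                {
                    "snp_id": rec.snp_id,
                    "population": p,
                    "effect_count": eff,
                    "total_count": total,
                    "frequency": eff / total if total else np.nan,
                }
            )
    df = pd.DataFrame(out, columns=["snp_id", "population", "effect_count", "total_count", "frequency"])
    df.attrs["excluded"] = excluded
    return df


def pooled_global(freqs: pd.DataFrame) -> pd.DataFrame:
    """Pooled-global rows (population = GLOBAL): counts summed over populations."""
    g = (
        freqs[freqs.population != GLOBAL_POP]
        .groupby("snp_id", sort=False)[["effect_count", "total_count"]]
        .sum()
        .reset_index()
    )
    g["population"] = GLOBAL_POP
    g["frequency"] = g.effect_count / g.total_count.where(g.total_count > 0)
    return g[["snp_id", "population", "effect_count", "total_count", "frequency"]]


def fold_differences(freqs: pd.DataFrame, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-SNP frequency ratio pop_a / pop_b.

    Zero denominator with nonzero numerator -> ratio inf, flag "infinite";
    0/0 -> ratio NaN, flag "undefined" (excluded from any maxima). No
    pseudo-counts are applied.
    """
    pops = set(freqs.population)
    for p in (pop_a, pop_b):
        if p not in pops:
            raise KeyError(f"unknown population {p!r}")
    a = freqs[freqs.population == pop_a].set_index("snp_id").frequency
    b = freqs[freqs.population == pop_b].set_index("snp_id").frequency
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    flag = np.where(
        (b == 0) & (a > 0), "infinite", np.where((b == 0) & (a == 0), "undefined", "")
    )
    ratio = ratio.where(~((a == 0) & (b == 0)), np.nan)
    return pd.DataFrame({"snp_id": common, "ratio": ratio.to_numpy(), "flag": flag})
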