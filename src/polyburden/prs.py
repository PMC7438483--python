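"""Greedy LD clumping and the log-OR-weighted polygenic risk score.

Clumping visits SNPs in ascending p-value (ties by position, then id); each
surviving SNP becomes an index and removes every other unvisited SNP on the
same chromosome within ``window_bp`` whose dosage r^2 with it exceeds
``r2_threshold``. r^2 is the squared Pearson correlation of (mean-imputed)
dosages in the reference panel — composite LD, no phasing needed.

The score is the raw sum of ln(OR) x effect-allele dosage; a missing dosage
is imputed as twice the cohort effect-allele frequency. Quintiles use the
linear-interpolation empirical quantile definition with boundary ties
assigned to the lower quintile; risk categories are low (quintile 1),
moderate (2–4) and high (5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popfreq import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpConfig:
    r2_threshold: float = 0.1
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def _imputed_dosages(genotypes: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    d = genotypes.dosages[:, cols].astype(float)
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
    return d


def ld_clump(
    summary: pd.DataFrame, reference: GenotypeMatrix, config: ClumpConfig = ClumpConfig()
) -> list[str]:
    """Greedy p-value clumping; returns index snp_ids in genomic order.

    ``summary`` needs columns snp_id, chrom, pos, pvalue. SNPs absent from
    the reference are excluded with a warning.
    """
    ref_ids = {sid: j for j, sid in enumerate(reference.variants.snp_id)}
    rows = []
    for row in summary.itertuples(index=False):
        j = ref_ids.get(row.snp_id)
        if j is None:
            logger.warning("clump: %s absent from reference, excluded", row.snp_id)
            continue
        rows.append((row.pvalue, int(row.pos), row.snp_id, str(row.chrom), j))
    if not rows:
        return []
    rows.sort(key=lambda t: (t[0], t[1], t[2]))

    cols = np.array([t[4] for t in rows])
    dos = _imputed_dosages(reference, cols)
    removed = [False] * len(rows)
    index_snps: list[int] = []
    for i, (_, pos_i, _, chrom_i, _) in enumerate(rows):
        if removed[i]:
            continue
        index_snps.append(i)
        for k, (_, pos_k, _, chrom_k, _) in enumerate(rows):
            if k == i or removed[k]:
                continue
            if chrom_k != chrom_i or abs(pos_k - pos_i) > config.window_bp:
                continue
            x, y = dos[:, i], dos[:, k]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > config.r2_threshold:
                removed[k] = True
    retained = [rows[i] for i in index_snps]
    retained.sort(key=lambda t: (t[3], t[1]))
    return [t[2] for t in retained]


@dataclass(frozen=True)
class PrsResult:
    sample_id: str
    score: float
    n_snps_used: int
    quintile: int | None = None
    risk_category: str | None = None


def compute_prs(genotypes: GenotypeMatrix, index_snps) -> pd.DataFrame:
    """Per-sample sum of ln(OR)-weighted effect-allele dosages.

    ``index_snps`` is an iterable of harmonized records (snp_id, chrom, pos,
    effect_allele, other_allele, odds_ratio). Missing dosages are replaced by
    twice the cohort effect-allele frequency at the SNP; ``n_snps_used``
    counts SNPs with an observed genotype per sample.
    """
    usable: list[tuple[int, float, bool]] = []  # (variant col, weight, effect_is_alt)
    v = genotypes.variants
    by_coord = {(str(c), int(p)): j for j, (c, p) in enumerate(zip(v.chrom, v.pos))}
    for rec in index_snps:
        j = by_coord.get((str(rec.chrom), int(rec.pos)))
        if j is None:
            try:
                j = genotypes.variant_index(rec.snp_id)
            except KeyError:
                logger.warning("PRS: %s absent from genotypes, skipped", rec.snp_id)
                continue
        ref, alt = v.ref.iloc[j], v.alt.iloc[j]
        if {rec.effect_allele, rec.other_allele} != {ref, alt}:
            logger.warning("PRS: allele mismatch at %s, skipped", rec.snp_id)
            continue
        usable.append((j, math.log(rec.odds_ratio), rec.effect_allele == alt))
    if not usable:
        raise ValueError("no usable index SNPs for scoring")

    cols = np.array([u[0] for u in usable])
    weights = np.array([u[1] for u in usable])
    is_alt = np.array([u[2] for u in usable])

    d = genotypes.dosages[:, cols].astype(float)
    eff = np.where(is_alt[None, :], d, 2.0 - d)
    observed = ~np.isnan(eff)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(eff, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    eff = np.where(observed, eff, 2.0 * freq[None, :])

    scores = eff @ weights
    return pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "score": scores,
            "n_snps_used": observed.sum(axis=1).astype(int),
        }
    )


_CATEGORY = {1: "low", 2: "moderate", 3: "moderate", 4: "moderate", 5: "high"}


def assign_quintiles(scores) -> pd.DataFrame:
    """Quintile (1–5) and risk category for each score.

    Cut points are the empirical 20/40/60/80 percentiles (linear
    interpolation); a score exactly at a boundary goes to the lower quintile.
    Requires >= 5 samples and >= 5 distinct score values.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 5:
        raise ValueError("need at least 5 samples to form quintiles")
    if np.unique(s).size < 5:
        raise ValueError("need at least 5 distinct score values to form quintiles")
    cuts = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    quintile = 1 + (s[:, None] > cuts[None, :]).sum(axis=1)
    category = [_CATEGORY[q] for q in quintile]
    return pd.DataFrame({"score": s, "quintile": quintile, "risk_category": category})


def score_cohort(genotypes: GenotypeMatrix, index_snps) -> pd.DataFrame:
    """compute_prs + quintile assignment in one call."""
    prs = compute_prs(genotypes, index_snps)
    q = assign_quintiles(prs.score.to_numpy())
    prs["quintile"] = q.quintile.to_numpy()
    prs["risk_category"] = q.risk_category.to_numpy()
    return prs
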