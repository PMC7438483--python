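"""Population differentiation: Weir–Cockerham Fst, selection test, genotype PCA.

The Fst estimator is the 1984 variance-components formulation for two
populations and one biallelic locus, computed from genotype counts (so the
observed heterozygosity enters directly). ``theta = a / (a + b + c)`` where
``a``, ``b`` and ``c`` are the among-population, among-individual and
within-individual components; the estimate is undefined when the denominator
is zero (both populations monomorphic for the same allele) or when either
population has fewer than two non-missing genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popfreq import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FstResult:
    snp_id: str
    pop_pair: tuple[str, str]
    theta: float
    a: float
    b: float
    c: float
    defined: bool


@dataclass(frozen=True)
class MeanFst:
    """Mean per-SNP theta (primary) and the ratio-of-sums variant (secondary)."""

    mean_of_ratios: float
    ratio_of_sums: float
    n_defined: int


@dataclass(frozen=True)
class SelectionTestResult:
    n_high_fst_t2d: int
    n_high_fst_random: int
    n_total: int
    chi2: float
    pvalue: float
    threshold: float


# ---------------------------------------------------------------------------
# Weir-Cockerham estimator
# ---------------------------------------------------------------------------

def _wc_components(n1, het1, p1, n2, het2, p2):
    """Vectorized variance components a, b, c for two populations (r = 2).

    Arguments are per-SNP arrays: sample sizes, observed heterozygote
    proportions and alt-allele frequencies.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * het1 + n2 * het2) / (r * n_bar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
    c = h_bar / 2.0
    return a, b, c


def wc_fst_counts(counts1, counts2, snp_id: str = "", pop_pair=("pop1", "pop2")) -> FstResult:
    """Weir–Cockerham theta for one SNP from genotype counts.

    ``counts1``/``counts2`` are (hom_ref, het, hom_alt) tuples for the two
    populations. Fewer than two genotypes in either population, or a zero
    variance-component denominator, yields an undefined (flagged) result.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != (3,) or c2.shape != (3,) or (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("genotype counts must be three nonnegative numbers")
    n1, n2 = c1.sum(), c2.sum()
    if n1 < 2 or n2 < 2:
        return FstResult(snp_id, tuple(pop_pair), np.nan, np.nan, np.nan, np.nan, False)
    p1 = (c1[1] + 2 * c1[2]) / (2 * n1)
    p2 = (c2[1] + 2 * c2[2]) / (2 * n2)
    a, b, c = _wc_components(
        np.array([n1]), np.array([c1[1] / n1]), np.array([p1]),
        np.array([n2]), np.array([c2[1] / n2]), np.array([p2]),
    )
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    if denom == 0 or not np.isfinite(denom):
        return FstResult(snp_id, tuple(pop_pair), np.nan, a, b, c, False)
    return FstResult(snp_id, tuple(pop_pair), a / denom, a, b, c, True)


def pairwise_fst(
    genotypes: GenotypeMatrix, pop_a: str, pop_b: str, snp_ids=None
) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham theta between two populations (vectorized).

    Columns: snp_id, pop_a, pop_b, theta, a, b, c, defined. Undefined SNPs
    (either population with < 2 genotypes, or zero denominator) carry NaN
    theta and defined = False.
    """
    mask_a = genotypes.population_mask(pop_a)
    mask_b = genotypes.population_mask(pop_b)
    dos = genotypes.dosages
    if snp_ids is not None:
        wanted = set(snp_ids)
        keep = genotypes.variants.snp_id.isin(wanted).to_numpy()
    else:
        keep = np.ones(genotypes.n_variants, dtype=bool)

    da, db = dos[mask_a][:, keep], dos[mask_b][:, keep]
    oka, okb = ~np.isnan(da), ~np.isnan(db)
    n1 = oka.sum(axis=0).astype(float)
    n2 = okb.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(da, axis=0) / (2 * n1)
        p2 = np.nansum(db, axis=0) / (2 * n2)
        het1 = np.nansum(da == 1, axis=0) / n1
        het2 = np.nansum(db == 1, axis=0) / n2
        a, b, c = _wc_components(n1, het1, p1, n2, het2, p2)
        denom = a + b + c
        theta = a / denom
    defined = (n1 >= 2) & (n2 >= 2) & np.isfinite(denom) & (denom != 0)
    theta = np.where(defined, theta, np.nan)
    return pd.DataFrame(
        {
            "snp_id": genotypes.variants.snp_id.to_numpy()[keep],
            "pop_a": pop_a,
            "pop_b": pop_b,
            "theta": theta,
            "a": a,
            "b": b,
            "c": c,
            "defined": defined,
        }
    )


def mean_fst(fst: pd.DataFrame) -> MeanFst:
    """Arithmetic mean of defined per-SNP theta values (+ ratio-of-sums)."""
    defined = fst[fst.defined]
    if defined.empty:
        raise ValueError("no defined Fst estimates")
    denom = (defined.a + defined.b + defined.c).sum()
    return MeanFst(
        mean_of_ratios=float(defined.theta.mean()),
        ratio_of_sums=float(defined.a.sum() / denom) if denom != 0 else np.nan,
        n_defined=int(len(defined)),
    )


# ---------------------------------------------------------------------------
# frequency-matched random SNP set
# ---------------------------------------------------------------------------

def sample_frequency_matched(
    target: pd.Series, pool: pd.Series, bin_width: float = 0.02, seed: int = 0
) -> list:
    """Draw, for each target SNP, one pool SNP from the same frequency bin.

    ``target`` and ``pool`` map snp_id -> frequency. Draws are without
    replacement; an exhausted bin falls back to the nearest non-empty bin with
    a warning; an empty pool raises. Returns the drawn pool snp_ids, one per
    target SNP, in target order.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    bins: dict[int, list] = {}
    for sid, f in pool.items():
        bins.setdefault(int(f / bin_width), []).append(sid)
    for b in bins.values():
        rng.shuffle(b)

    chosen = []
    for sid, f in target.items():
        want = int(f / bin_width)
        if bins.get(want):
            chosen.append(bins[want].pop())
            continue
        occupied = [b for b, members in bins.items() if members]
        if not occupied:
            raise ValueError("pool exhausted while matching frequencies")
        nearest = min(occupied, key=lambda b: (abs(b - want), b))
        warnings.warn(
            f"frequency bin {want} exhausted for {sid}; falling back to bin {nearest}",
            stacklevel=2,
        )
        chosen.append(bins[nearest].pop())
    return chosen


# ---------------------------------------------------------------------------
# high-Fst selection test
# ---------------------------------------------------------------------------

def chi2_upper_tail(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square probability (the selection test's p-value)."""
    return float(stats.chi2.sf(statistic, df))


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and 1-df upper-tail p."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, chi2_upper_tail(stat, 1)


def high_fst_selection_test(
    t2d_fst: pd.Series,
    random_fst: pd.Series,
    fst_floor: float = 0.05,
    top_quantile: float = 0.01,
) -> SelectionTestResult:
    """Compare high-Fst counts between the target SNP set and a matched set.

    Each series holds one summary Fst per SNP (max over its pairwise
    comparisons). "High" means above ``fst_floor`` AND above the
    (1 - top_quantile) quantile of the pooled summary distribution of both
    sets. Counts are compared by Pearson chi-square (1 df, no continuity
    correction).
    """
    t = np.asarray(t2d_fst, dtype=float)
    r = np.asarray(random_fst, dtype=float)
    if t.size != r.size:
        raise ValueError("the two SNP sets must have equal size")
    if t.size == 0:
        raise ValueError("empty SNP sets")
    pooled = np.concatenate([t, r])
    threshold = float(np.nanquantile(pooled, 1.0 - top_quantile))
    cut = max(threshold, fst_floor)
    n_t = int(np.nansum(t > cut))
    n_r = int(np.nansum(r > cut))
    n = t.size
    if n_t == n_r:
        stat, p = 0.0, 1.0
    else:
        stat, p = pearson_chi2_2x2([[n_t, n - n_t], [n_r, n - n_r]])
    return SelectionTestResult(
        n_high_fst_t2d=n_t,
        n_high_fst_random=n_r,
        n_total=n,
        chi2=stat,
        pvalue=p,
        threshold=cut,
    )


def max_fst_summary(fst_frames) -> pd.Series:
    """Per-SNP summary Fst: maximum defined theta over the supplied pair frames."""
    stacked = pd.concat(fst_frames, ignore_index=True)
    defined = stacked[stacked.defined]
    return defined.groupby("snp_id").theta.max()


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components, index sample_id
    explained_variance_ratio: np.ndarray
    n_snps_used: int


def genotype_pca(genotypes: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA on standardized dosages (center 2p, scale sqrt(2p(1-p))).

    Missing dosages are mean-imputed before scaling; monomorphic SNPs are
    dropped. Scores are U * S from the SVD of the standardized matrix.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least two samples")
    X = genotypes.dosages.astype(float).copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    p_hat = X.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than two polymorphic SNPs")
    X = X[:, poly]
    p_hat = p_hat[poly]
    Z = (X - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    k = min(n_components, min(Z.shape))
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    total = float((S**2).sum())
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=pd.Index(genotypes.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(
        scores=scores,
        explained_variance_ratio=S[:k] ** 2 / total,
        n_snps_used=int(poly.sum()),
    )
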