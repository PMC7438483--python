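"""Simulate multi-population genotypes, GWAS summary statistics and phenotypes.

The generative model is deliberately simple but exposes every statistical
handle the downstream analysis relies on:

* per-population allele frequencies diverge from a shared ancestral frequency
  under the Balding–Nichols Beta model, parameterized by an Fst-like ``c``;
* linkage disequilibrium is block-diagonal: within a block, haplotype alleles
  copy a shared anchor haplotype with probability ``ld_r2 ** 0.25``, which
  yields pairwise dosage correlation ``r^2 ≈ ld_r2`` when block members share
  an ancestral frequency (each block draws a single ancestral frequency);
* a GWAS-style summary table marks a subset of variants as genome-wide
  significant, with risk variants at OR >= 1.2;
* phenotypes follow a log-link prevalence model and an exponential
  proportional-hazards incidence model, both driven by the standardized true
  polygenic score.

All randomness flows from ``SimConfig.seed`` through named substreams
(frequencies, genotypes, phenotypes, summary), so a fixed seed reproduces the
VCF and phenotype table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .popfreq import GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, size and divergence from the ancestor."""

    name: str
    n_samples: int
    fst_to_ancestral: float  # Balding-Nichols c in [0, 1)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"population {self.name!r}: n_samples must be >= 1")
        if not (0.0 <= self.fst_to_ancestral < 1.0):
            raise ValueError(
                f"population {self.name!r}: divergence c must be in [0, 1), "
                f"got {self.fst_to_ancestral}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full simulation design.

    ``n_assoc_snps`` of the ``n_snps`` VCF variants appear in the GWAS summary
    table (the rest form the genome-wide pool for frequency-matched random-SNP
    draws); ``n_risk_snps`` of the associated variants carry OR in
    ``or_range`` (>= 1.2). ``n_planted`` (even) variants, all risk, are split
    into two groups with opposite frequency shifts of ``planted_shift`` across
    the two population halves and share the gene label ``planted_gene``.
    """

    n_snps: int
    populations: tuple[PopulationSpec, ...]
    n_risk_snps: int
    seed: int
    n_assoc_snps: int | None = None  # default: all SNPs associated
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    ld_block_size: int = 1
    ld_r2: float = 0.0
    or_range: tuple[float, float] = (1.2, 1.6)
    prevalence_beta: float = 0.0  # log-PR per PRS standard deviation
    hazard_beta: float = 0.0  # log-HR per PRS standard deviation
    prevalence_intercept: float = -2.0
    baseline_hazard: float = 0.02  # events per person-year at score 0
    censoring_rate: float = 0.1
    followup_years: float = 18.0
    missing_rate: float = 0.0
    reverse_strand_fraction: float = 0.1
    n_planted: int = 0
    planted_shift: float = 0.25
    planted_gene: str = "PLANTGENE"
    covariate_effects: bool = True
    spacing_bp: int = 2000
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not self.populations:
            raise ValueError("at least one population required")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        if self.n_assoc is not None and not (0 < self.n_assoc <= self.n_snps):
            raise ValueError("n_assoc_snps must be in (0, n_snps]")
        if self.n_risk_snps > self.n_assoc_effective:
            raise ValueError("n_risk_snps must not exceed the associated SNP count")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        if self.or_range[0] < 1.2:
            raise ValueError("or_range lower bound must be >= 1.2 for risk variants")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_planted % 2 != 0:
            raise ValueError("n_planted must be even (two equal groups)")
        if self.n_planted > self.n_risk_snps:
            raise ValueError("planted SNPs must be a subset of risk SNPs")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("censoring_rate must be in [0, 1]")

    @property
    def n_assoc(self) -> int | None:
        return self.n_assoc_snps

    @property
    def n_assoc_effective(self) -> int:
        return self.n_snps if self.n_assoc_snps is None else self.n_assoc_snps

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_snps / self.ld_block_size)


def beta_for_quintile_ratio(target_ratio: float) -> float:
    """Per-SD log coefficient giving a top-vs-bottom-quintile ratio of group means.

    For a standard-normal score the mean of the top (bottom) quintile is
    ``±phi(z_0.8)/0.2``; a log-linear effect ``b`` per SD then separates the
    expected outcome rates of the extreme quintiles by approximately
    ``exp(b * delta)``.
    """
    if target_ratio <= 0:
        raise ValueError("target ratio must be positive")
    z80 = stats.norm.ppf(0.8)
    delta = 2.0 * stats.norm.pdf(z80) / 0.2
    return math.log(target_ratio) / delta


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def draw_ancestral_frequencies(config: SimConfig) -> np.ndarray:
    """Ancestral frequencies, one value per LD block, repeated across the block.

    Sharing the ancestral frequency within a block keeps the latent-anchor LD
    construction calibrated (see module docstring).
    """
    rng = substream(config.seed, "frequencies")
    lo, hi = config.ancestral_freq_range
    per_block = rng.uniform(lo, hi, size=config.n_blocks)
    return np.repeat(per_block, config.ld_block_size)[: config.n_snps]


def simulate_population_frequencies(
    ancestral_freqs: np.ndarray, spec: PopulationSpec, seed: int
) -> np.ndarray:
    """Balding–Nichols draw of one population's allele frequencies.

    Frequency at SNP j is Beta(p_j(1-c)/c, (1-p_j)(1-c)/c) with
    c = ``spec.fst_to_ancestral``; c = 0 returns the ancestral frequencies
    unchanged. Results are clipped to [0, 1].
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must lie strictly inside (0, 1)")
    c = spec.fst_to_ancestral
    if not (0.0 <= c < 1.0):
        raise ValueError(f"divergence c must be in [0, 1), got {c}")
    if c == 0.0:
        return p.copy()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    scale = (1.0 - c) / c
    draws = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(draws, 0.0, 1.0)


def population_frequency_table(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-population frequency vectors for the whole design, with planting.

    Planted SNPs get frequency ``ancestral ± planted_shift``: group A is
    shifted up in the first half of the populations and down in the second,
    group B the opposite.
    """
    ancestral = draw_ancestral_frequencies(config)
    rng = substream(config.seed, "frequencies")
    # child seeds, one per population, drawn after the ancestral stream is used
    child_seeds = rng.integers(0, 2**31 - 1, size=len(config.populations))
    freqs: dict[str, np.ndarray] = {}
    planted_a, planted_b = planted_indices(config)
    half = len(config.populations) // 2
    block = config.ld_block_size
    # one Balding-Nichols draw per LD block (members share the realized
    # frequency) so the within-block anchor LD stays calibrated
    block_anchor = ancestral[::block] if block > 1 else ancestral
    for i, spec in enumerate(config.populations):
        f = simulate_population_frequencies(block_anchor, spec, int(child_seeds[i]))
        if block > 1:
            f = np.repeat(f, block)[: config.n_snps]
        if config.n_planted:
            up = i < half
            shift = config.planted_shift
            f[planted_a] = np.clip(ancestral[planted_a] + (shift if up else -shift), 0.01, 0.99)
            f[planted_b] = np.clip(ancestral[planted_b] + (-shift if up else shift), 0.01, 0.99)
        freqs[spec.name] = f
    return freqs


def planted_indices(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the two planted SNP groups (first SNP of distinct LD blocks)."""
    if config.n_planted == 0:
        empty = np.array([], dtype=int)
        return empty, empty
    if config.n_planted > config.n_blocks:
        raise ValueError("not enough LD blocks to place planted SNPs")
    starts = np.arange(config.n_planted) * config.ld_block_size
    k = config.n_planted // 2
    return starts[:k], starts[k:]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _variant_table(config: SimConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(21,)))
    ref_idx = rng.integers(0, 4, size=config.n_snps)
    alt_shift = rng.integers(1, 4, size=config.n_snps)
    alt_idx = (ref_idx + alt_shift) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"rs{100000 + j}" for j in range(config.n_snps)],
            "chrom": config.chrom,
            "pos": 1 + np.arange(config.n_snps) * config.spacing_bp,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def _haplotypes_for_block(
    rng: np.random.Generator, freqs_block: np.ndarray, n_hap: int, share_prob: float
) -> np.ndarray:
    """(n_hap, block_size) 0/1 alleles with anchor-copy LD."""
    m = freqs_block.shape[0]
    anchor_u = rng.uniform(size=(n_hap, 1))
    copy_mask = rng.uniform(size=(n_hap, m)) < share_prob
    independent = rng.uniform(size=(n_hap, m)) < freqs_block[None, :]
    anchored = anchor_u < freqs_block[None, :]
    return np.where(copy_mask, anchored, independent).astype(np.int8)


def simulate_genotypes(
    pop_freqs: dict[str, np.ndarray], config: SimConfig
) -> GenotypeMatrix:
    """Draw dosages for every population and assemble a GenotypeMatrix.

    Within an LD block dosages are built from two latent haplotypes that copy
    a per-individual anchor with probability ``ld_r2 ** 0.25``; outside blocks
    (block size 1) dosages are plain Binomial(2, freq). Missing genotypes are
    injected at ``missing_rate`` (NaN dosage).
    """
    if not pop_freqs:
        raise ValueError("no populations supplied")
    rng = substream(config.seed, "genotypes")
    variants = _variant_table(config)
    share = config.ld_r2**0.25 if config.ld_block_size > 1 else 0.0

    sample_ids: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    for spec in config.populations:
        freqs = np.asarray(pop_freqs[spec.name], dtype=float)
        if freqs.shape[0] != config.n_snps:
            raise ValueError("frequency vector length mismatch")
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        n = spec.n_samples
        if n < 1:
            raise ValueError("zero samples in a population")
        if config.ld_block_size > 1:
            dos = np.empty((n, config.n_snps), dtype=np.int8)
            for start in range(0, config.n_snps, config.ld_block_size):
                stop = min(start + config.ld_block_size, config.n_snps)
                fb = freqs[start:stop]
                h1 = _haplotypes_for_block(rng, fb, n, share)
                h2 = _haplotypes_for_block(rng, fb, n, share)
                dos[:, start:stop] = h1 + h2
        else:
            dos = rng.binomial(2, freqs[None, :], size=(n, config.n_snps)).astype(np.int8)
        blocks.append(dos)
        sample_ids.extend(f"{spec.name}_{i:05d}" for i in range(n))
        pops.extend([spec.name] * n)

    dosages = np.concatenate(blocks, axis=0).astype(float)
    if config.missing_rate > 0:
        miss_rng = substream(config.seed, "missingness")
        mask = miss_rng.uniform(size=dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    panel = pd.Series(pops, index=pd.Index(sample_ids, name="sample_id"), name="population")
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=list(sample_ids), panel=panel)


# ---------------------------------------------------------------------------
# GWAS summary table
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_summary(config: SimConfig, variants: pd.DataFrame) -> pd.DataFrame:
    """GWAS summary rows for the associated subset of variants.

    All rows pass genome-wide significance (p <= 5e-8, log-uniform down to
    1e-30). Risk rows draw OR from ``or_range``; non-risk rows draw OR in
    (0.85, 1.19) so they stay below the 1.2 risk floor even after flipping.
    A ``reverse_strand_fraction`` of non-ambiguous rows is reported on the
    reverse strand with complemented alleles, exercising harmonization.
    """
    rng = substream(config.seed, "summary")
    n_assoc = config.n_assoc_effective
    planted_a, planted_b = planted_indices(config)
    planted = np.concatenate([planted_a, planted_b])

    candidates = np.setdiff1d(np.arange(config.n_snps), planted)
    extra_assoc = rng.choice(candidates, size=n_assoc - planted.size, replace=False)
    assoc_idx = np.sort(np.concatenate([planted, extra_assoc]))

    non_planted_assoc = np.setdiff1d(assoc_idx, planted)
    extra_risk = rng.choice(
        non_planted_assoc, size=config.n_risk_snps - planted.size, replace=False
    )
    risk_idx = set(np.concatenate([planted, extra_risk]).tolist())

    rows = []
    block = config.ld_block_size
    planted_set = set(planted.tolist())
    for j in assoc_idx:
        v = variants.iloc[j]
        is_risk = j in risk_idx
        if is_risk:
            odds = rng.uniform(*config.or_range)
        else:
            odds = rng.uniform(0.85, 1.19)
        pval = 10 ** rng.uniform(-30, math.log10(5e-8))
        # planted SNPs keep effect = alt on the forward strand so their
        # frequency shifts translate directly into enrichment direction
        if j in planted_set:
            effect, other, strand = v.alt, v.ref, "forward"
        else:
            effect, other = (v.alt, v.ref) if rng.uniform() < 0.7 else (v.ref, v.alt)
            strand = "forward"
            ambiguous = _COMPLEMENT[effect] == other
            if not ambiguous and rng.uniform() < config.reverse_strand_fraction:
                strand = "reverse"
                effect, other = _COMPLEMENT[effect], _COMPLEMENT[other]
        if j in planted_set:
            gene = config.planted_gene
        else:
            gene = f"GENE{j // block:04d}"
        rows.append(
            {
                "snp_id": v.snp_id,
                "chr": v.chrom,
                "pos": int(v.pos),
                "effect_allele": effect,
                "other_allele": other,
                "or": round(float(odds), 6),
                "pvalue": float(pval),
                "strand": strand,
                "gene": gene,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def true_score(genotypes: GenotypeMatrix, weights: np.ndarray) -> np.ndarray:
    """Standardized latent polygenic score (missing dosages mean-imputed)."""
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != genotypes.n_variants:
        raise ValueError(
            f"weights length {w.shape[0]} != number of variants {genotypes.n_variants}"
        )
    dos = genotypes.dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    raw = dos @ w
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix, weights: np.ndarray, config: SimConfig
) -> pd.DataFrame:
    """Per-individual covariates, prevalent status and incident follow-up.

    Prevalence is log-linear in the standardized score (``prevalence_beta`` is
    the log prevalence-ratio per score SD, probabilities clipped at 0.95);
    incident times for everyone are exponential with rate
    ``baseline_hazard * exp(hazard_beta * s + covariate terms)``, censored
    administratively at ``followup_years`` and at random with probability
    ``censoring_rate``. Covariate and biomarker scales loosely follow a
    middle-aged cardio-metabolic cohort.
    """
    s = true_score(genotypes, weights)
    n = genotypes.n_samples
    rng = substream(config.seed, "phenotypes")

    sex = rng.binomial(1, 0.5, size=n)
    age = np.clip(rng.normal(45.0, 12.0, size=n), 20.0, 80.0)
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 15.0, 50.0)
    fpg = np.clip(rng.normal(88.0, 8.0, size=n), 50.0, None)
    g2h = np.clip(rng.normal(100.0, 25.0, size=n), 40.0, None)
    tc = np.clip(rng.normal(195.0, 42.0, size=n), 80.0, None)
    tg = np.clip(rng.normal(140.0, 70.0, size=n), 30.0, None)
    hdl = np.clip(rng.normal(41.0, 10.0, size=n), 15.0, None)
    ldl = np.clip(rng.normal(125.0, 34.0, size=n), 40.0, None)

    cov_scale = 1.0 if config.covariate_effects else 0.0
    lin_prev = (
        config.prevalence_intercept
        + config.prevalence_beta * s
        + cov_scale * (0.015 * (age - 45.0) + 0.02 * (bmi - 27.0))
    )
    prob = np.clip(np.exp(lin_prev), 0.0, 0.95)
    prevalent = rng.binomial(1, prob)

    rate = config.baseline_hazard * np.exp(
        config.hazard_beta * s + cov_scale * (0.01 * (age - 45.0) + 0.02 * (bmi - 27.0))
    )
    t_event = rng.exponential(1.0 / rate)
    censor = np.full(n, config.followup_years)
    random_censored = rng.uniform(size=n) < config.censoring_rate
    censor_times = rng.uniform(0.0, config.followup_years, size=n)
    censor = np.where(random_censored, np.minimum(censor, censor_times), censor)
    censor = np.maximum(censor, 1e-6)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    return pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "sex": sex,
            "age": np.round(age, 3),
            "bmi": np.round(bmi, 3),
            "fpg": np.round(fpg, 3),
            "g2h": np.round(g2h, 3),
            "tc": np.round(tc, 3),
            "tg": np.round(tg, 3),
            "hdl": np.round(hdl, 3),
            "ldl": np.round(ldl, 3),
            "prevalent_t2d": prevalent,
            "time_years": np.round(time, 6),
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal valid VCF 4.2 (GT only, 1-based positions)."""
    path = Path(path)
    dos = genotypes.dosages
    codes = np.where(np.isnan(dos), 3, dos).astype(np.int64)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(genotypes.variants.chrom):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        v = genotypes.variants
        for j in range(genotypes.n_variants):
            gts = _GT_STRINGS[codes[:, j]]
            fh.write(
                f"{v.chrom.iloc[j]}\t{v.pos.iloc[j]}\t{v.snp_id.iloc[j]}\t"
                f"{v.ref.iloc[j]}\t{v.alt.iloc[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def write_panel(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    genotypes.panel.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)
    return path


def write_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    summary.to_csv(path, sep="\t", index=False)
    return path


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    phenotypes.to_csv(path, index=False)
    return path


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulator and write VCF, panel, summary and phenotype files.

    Returns a mapping of logical input names to paths. The true per-SNP
    effect weights are ln(OR) for risk rows of the summary and 0 elsewhere.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freqs = population_frequency_table(config)
    genotypes = simulate_genotypes(freqs, config)
    summary = simulate_summary(config, genotypes.variants)

    # true weights act on alt-allele dosage: flip sign when the (forward-strand)
    # effect allele is the reference allele
    weights = np.zeros(config.n_snps)
    idx_by_id = {sid: j for j, sid in enumerate(genotypes.variants.snp_id)}
    alt_by_id = dict(zip(genotypes.variants.snp_id, genotypes.variants.alt))
    for _, row in summary.iterrows():
        if row["or"] >= 1.2:
            effect = row.effect_allele
            if row.strand == "reverse":
                effect = _COMPLEMENT[effect]
            sign = 1.0 if effect == alt_by_id[row.snp_id] else -1.0
            weights[idx_by_id[row.snp_id]] = sign * math.log(row["or"])
    phenotypes = simulate_phenotypes(genotypes, weights, config)

    return {
        "vcf": write_vcf(genotypes, outdir / "genotypes.vcf"),
        "panel": write_panel(genotypes, outdir / "panel.tsv"),
        "summary": write_summary(summary, outdir / "summary.tsv"),
        "phenotypes": write_phenotypes(phenotypes, outdir / "phenotypes.csv"),
    }
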