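"""Per-population risk-allele enrichment against the pooled global population.

For each risk SNP and population, a 2x2 allele-count table
``[[risk_pop, nonrisk_pop], [risk_global, nonrisk_global]]`` is tested with a
two-sided Fisher exact test. The global pool sums allele counts over all
populations and, by default, includes the tested population (a
leave-one-out pool is available behind a flag). Benjamini–Hochberg FDR is
applied within each population across its SNPs; significance is strict
(q < alpha). The signed heatmap score is -log10(q) for enriched alleles and
+log10(q) (negative) for depleted ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .popfreq import GLOBAL_POP

logger = logging.getLogger(__name__)

_Q_FLOOR = 1e-300  # avoid log10(0) for vanishing q-values


@dataclass(frozen=True)
class EnrichmentResult:
    snp_id: str
    population: str
    table: tuple[tuple[int, int], tuple[int, int]]
    direction: str  # "enriched" | "depleted"
    pvalue: float
    qvalue: float
    signed_score: float
    significant: bool


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Two-sided by the standard 'sum of tables no more probable than the
    observed one' rule on the hypergeometric distribution with fixed margins.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def test_enrichment(
    risk_catalog,
    freqs: pd.DataFrame,
    alpha: float = 0.05,
    leave_one_out: bool = False,
    pool_fdr: bool = False,
) -> list[EnrichmentResult]:
    """Fisher enrichment/depletion of every risk SNP in every population.

    ``risk_catalog`` is an iterable of harmonized risk records (or snp_ids);
    ``freqs`` the long-format frequency table (per-population rows; a GLOBAL
    row set is derived by summation, asserting count conservation).
    ``pool_fdr=True`` applies BH across all SNP x population tests at once
    instead of within each population.
    """
    wanted = {getattr(r, "snp_id", r) for r in risk_catalog}
    pop_rows = freqs[(freqs.population != GLOBAL_POP) & freqs.snp_id.isin(wanted)]
    populations = sorted(pop_rows.population.unique())

    raw: list[dict] = []
    for sid, grp in pop_rows.groupby("snp_id", sort=True):
        if set(grp.population) != set(populations):
            logger.warning("skipping %s: missing population frequencies", sid)
            continue
        g_eff = int(grp.effect_count.sum())
        g_tot = int(grp.total_count.sum())
        if g_tot == 0:
            logger.warning("skipping %s: no called genotypes", sid)
            continue
        for row in grp.itertuples(index=False):
            p_eff, p_tot = int(row.effect_count), int(row.total_count)
            if p_tot == 0:
                logger.warning("skipping %s in %s: no called genotypes", sid, row.population)
                continue
            if leave_one_out:
                o_eff, o_tot = g_eff - p_eff, g_tot - p_tot
            else:
                o_eff, o_tot = g_eff, g_tot  # pool includes the tested population
            assert o_eff <= g_eff and o_tot <= g_tot
            table = ((p_eff, p_tot - p_eff), (o_eff, o_tot - o_eff))
            pval = fisher_exact_2x2(table)
            direction = "enriched" if p_eff / p_tot > o_eff / o_tot else "depleted"
            raw.append(
                {
                    "snp_id": sid,
                    "population": row.population,
                    "table": table,
                    "direction": direction,
                    "pvalue": pval,
                }
            )

    if not raw:
        return []
    df = pd.DataFrame(raw)
    if pool_fdr:
        df["qvalue"] = bh_fdr(df.pvalue.to_numpy())
    else:
        df["qvalue"] = np.nan
        for pop, grp in df.groupby("population"):
            df.loc[grp.index, "qvalue"] = bh_fdr(grp.pvalue.to_numpy())

    results = []
    for row in df.itertuples(index=False):
        q = max(float(row.qvalue), _Q_FLOOR)
        score = -np.log10(q) if row.direction == "enriched" else np.log10(q)
        results.append(
            EnrichmentResult(
                snp_id=row.snp_id,
                population=row.population,
                table=row.table,
                direction=row.direction,
                pvalue=float(row.pvalue),
                qvalue=float(row.qvalue),
                signed_score=float(score),
                significant=bool(row.qvalue < alpha),
            )
        )
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "population": [r.population for r in results],
            "direction": [r.direction for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
            "signed_score": [r.signed_score for r in results],
            "significant": [r.significant for r in results],
        }
    )


def gene_level_counts(results, gene_map: dict) -> pd.DataFrame:
    """Significant enriched/depleted SNP counts per (gene, population).

    Unmapped SNPs count under "intergenic". Output is ranked by descending
    count within each (population, direction), ties broken alphabetically by
    gene.
    """
    rows = [
        {
            "gene": gene_map.get(r.snp_id) or "intergenic",
            "population": r.population,
            "direction": r.direction,
        }
        for r in results
        if r.significant
    ]
    if not rows:
        return pd.DataFrame(columns=["population", "direction", "gene", "count"])
    counts = (
        pd.DataFrame(rows)
        .groupby(["population", "direction", "gene"])
        .size()
        .reset_index(name="count")
        .sort_values(
            ["population", "direction", "count", "gene"],
            ascending=[True, True, False, True],
        )
        .reset_index(drop=True)
    )
    return counts


@dataclass(frozen=True)
class HeatmapResult:
    matrix: pd.DataFrame  # SNP x population signed scores, clustered row order
    row_order: list[str]
    cluster_labels: pd.Series  # two-cluster cut, index snp_id


def heatmap_matrix(results, significant_only: bool = True) -> HeatmapResult:
    """Signed SNP x population matrix, rows ordered by hierarchical clustering.

    Non-significant cells are 0 (when ``significant_only``). Rows are sorted
    by snp_id before clustering so the dendrogram is invariant to input
    order; agglomerative clustering uses Euclidean distance with complete
    linkage, and the two-cluster cut is reported.
    """
    df = results_frame(list(results))
    if df.empty:
        raise ValueError("no enrichment results")
    if significant_only:
        df = df.assign(signed_score=df.signed_score.where(df.significant, 0.0))
    mat = (
        df.pivot(index="snp_id", columns="population", values="signed_score")
        .fillna(0.0)
        .sort_index()
    )
    mat = mat[(mat != 0).any(axis=1)]
    if mat.empty:
        raise ValueError("all-zero heatmap matrix (nothing significant)")
    if len(mat) == 1:
        labels = pd.Series([1], index=mat.index, name="cluster")
        return HeatmapResult(matrix=mat, row_order=list(mat.index), cluster_labels=labels)
    link = hierarchy.linkage(pdist(mat.to_numpy(), metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(link)
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    ordered = mat.iloc[order]
    labels = pd.Series(cut, index=mat.index, name="cluster")
    return HeatmapResult(matrix=ordered, row_order=list(ordered.index), cluster_labels=labels)
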