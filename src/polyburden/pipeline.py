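"""Staged pipeline orchestration with a checksummed run manifest.

Stage order: simulate -> catalog -> freqs -> (fst, pca, enrich) -> clump ->
score -> assoc. Each stage reads only files recorded by earlier stages and
writes its outputs under the run directory; the manifest records the config,
the seed and a sha256 per output so a rerun with the same config is
verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import differentiation as diff_mod
from . import enrichment as enr_mod
from . import popfreq, prs, snp_catalog, synthetic_data
from .popfreq import GLOBAL_POP

logger = logging.getLogger(__name__)

STAGES = ("simulate", "catalog", "freqs", "fst", "pca", "enrich", "clump", "score", "assoc")

# file-level dependency contract: stage -> (required inputs, producing stage)
_REQUIRES = {
    "catalog": [("summary", "simulate")],
    "freqs": [("vcf", "simulate"), ("panel", "simulate"), ("harmonized", "catalog")],
    "fst": [("vcf", "simulate"), ("panel", "simulate"), ("harmonized", "catalog")],
    "pca": [("vcf", "simulate"), ("panel", "simulate"), ("harmonized", "catalog")],
    "enrich": [("frequencies", "freqs"), ("harmonized", "catalog")],
    "clump": [("vcf", "simulate"), ("harmonized", "catalog"), ("enrichment", "enrich")],
    "score": [("vcf", "simulate"), ("clumped", "clump"), ("harmonized", "catalog")],
    "assoc": [("scores", "score"), ("phenotypes", "simulate")],
}


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters (defaults follow the method)."""

    outdir: Path = Path("runs/out")
    seed: int = 0
    # input files; filled by the simulate stage when simulation is requested
    vcf: Path | None = None
    panel: Path | None = None
    summary: Path | None = None
    phenotypes: Path | None = None
    # stage parameters
    p_threshold: float = 5e-8
    or_floor: float = 1.2
    fdr_alpha: float = 0.05
    fst_floor: float = 0.05
    top_quantile: float = 0.01
    r2_threshold: float = 0.1
    window_bp: int = 250_000
    bin_width: float = 0.02
    n_components: int = 10
    target_population: str | None = None  # default: first population alphabetically
    score_all_risk: bool = False  # score all risk SNPs instead of enriched-only
    leave_one_out: bool = False
    sim: synthetic_data.SimConfig | None = None

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.paths: dict[str, Path] = {}
        for key in ("vcf", "panel", "summary", "phenotypes"):
            p = getattr(config, key)
            if p is not None:
                self.paths[key] = Path(p)
        self._genotypes = None
        self._catalog = None

    # -- helpers ------------------------------------------------------------

    def _need(self, stage: str) -> None:
        for key, producer in _REQUIRES.get(stage, []):
            p = self.paths.get(key)
            if p is None or not Path(p).exists():
                raise PipelineError(
                    f"stage '{stage}' is missing input '{key}'; run stage '{producer}' first"
                )

    def _register(self, key: str, path: Path) -> Path:
        self.paths[key] = Path(path)
        return Path(path)

    def _load_genotypes(self):
        if self._genotypes is None:
            self._genotypes = popfreq.read_vcf(self.paths["vcf"], self.paths["panel"])
        return self._genotypes

    def _load_catalog(self):
        if self._catalog is None:
            self._catalog = snp_catalog.read_catalog(self.paths["harmonized"])
        return self._catalog

    def _target_population(self, populations) -> str:
        if self.config.target_population is not None:
            if self.config.target_population not in populations:
                raise PipelineError(
                    f"target population {self.config.target_population!r} not in panel"
                )
            return self.config.target_population
        return sorted(populations)[0]

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        if self.config.sim is None:
            raise PipelineError("stage 'simulate' requires a sim config")
        written = synthetic_data.simulate_dataset(self.config.sim, self.outdir / "inputs")
        for key, path in written.items():
            self._register(key, path)

    def stage_catalog(self) -> None:
        self._need("catalog")
        records = snp_catalog.read_summary(self.paths["summary"])
        catalog = snp_catalog.harmonize(records, p_threshold=self.config.p_threshold)
        self._register("harmonized", snp_catalog.write_catalog(catalog, self.outdir / "harmonized.tsv"))
        self._register("exclusions", snp_catalog.write_exclusions(catalog, self.outdir / "exclusions.tsv"))
        self._catalog = catalog

    def stage_freqs(self) -> None:
        self._need("freqs")
        gt = self._load_genotypes()
        catalog = self._load_catalog()
        freqs = popfreq.allele_frequencies(gt, catalog)
        freqs = pd.concat([freqs, popfreq.pooled_global(freqs)], ignore_index=True)
        out = self.outdir / "frequencies.tsv"
        freqs.to_csv(out, sep="\t", index=False)
        self._register("frequencies", out)

    def stage_fst(self) -> None:
        self._need("fst")
        gt = self._load_genotypes()
        catalog = self._load_catalog()
        catalog_ids = [r.snp_id for r in catalog.records]
        pops = gt.populations
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]

        frames, mean_rows = [], []
        for a, b in pairs:
            f = diff_mod.pairwise_fst(gt, a, b, snp_ids=catalog_ids)
            frames.append(f)
            m = diff_mod.mean_fst(f)
            mean_rows.append(
                {"pop_a": a, "pop_b": b, "mean_fst": m.mean_of_ratios,
                 "ratio_of_sums": m.ratio_of_sums, "n_defined": m.n_defined}
            )
        all_fst = pd.concat(frames, ignore_index=True)
        out = self.outdir / "fst_pairs.tsv"
        all_fst.to_csv(out, sep="\t", index=False)
        self._register("fst_pairs", out)
        mean_out = self.outdir / "fst_means.tsv"
        pd.DataFrame(mean_rows).to_csv(mean_out, sep="\t", index=False)
        self._register("fst_means", mean_out)

        # frequency-matched random-SNP null from SNPs outside the catalog
        pool_ids = sorted(set(gt.variants.snp_id) - set(catalog_ids))
        selection = None
        if pool_ids and len(pool_ids) >= len(catalog_ids):
            alt_freq = np.nanmean(gt.dosages, axis=0) / 2.0
            freq_by_id = dict(zip(gt.variants.snp_id, alt_freq))
            target = pd.Series({s: freq_by_id[s] for s in catalog_ids})
            pool = pd.Series({s: freq_by_id[s] for s in pool_ids})
            matched = diff_mod.sample_frequency_matched(
                target, pool, bin_width=self.config.bin_width, seed=self.config.seed
            )
            rand_frames = [diff_mod.pairwise_fst(gt, a, b, snp_ids=matched) for a, b in pairs]
            t2d_summary = diff_mod.max_fst_summary(frames)
            rand_summary = diff_mod.max_fst_summary(rand_frames)
            n = min(len(t2d_summary), len(rand_summary))
            res = diff_mod.high_fst_selection_test(
                t2d_summary.iloc[:n], rand_summary.iloc[:n],
                fst_floor=self.config.fst_floor, top_quantile=self.config.top_quantile,
            )
            selection = dataclasses.asdict(res)
        else:
            logger.warning("no non-catalog SNP pool; selection test skipped")
        sel_out = self.outdir / "selection_test.json"
        sel_out.write_text(json.dumps(selection, indent=2, sort_keys=True) + "\n")
        self._register("selection_test", sel_out)

    def stage_pca(self) -> None:
        self._need("pca")
        gt = self._load_genotypes()
        catalog = self._load_catalog()
        keep = gt.variants.snp_id.isin({r.snp_id for r in catalog.records}).to_numpy()
        sub = popfreq.GenotypeMatrix(
            dosages=gt.dosages[:, keep],
            variants=gt.variants[keep].reset_index(drop=True),
            samples=gt.samples,
            panel=gt.panel,
        )
        res = diff_mod.genotype_pca(sub, n_components=self.config.n_components)
        scores = res.scores.copy()
        scores.insert(0, "population", gt.panel.reindex(scores.index))
        out = self.outdir / "pca_scores.tsv"
        scores.to_csv(out, sep="\t")
        self._register("pca_scores", out)
        ev_out = self.outdir / "pca_explained.tsv"
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(res.explained_variance_ratio))],
             "explained_variance_ratio": res.explained_variance_ratio}
        ).to_csv(ev_out, sep="\t", index=False)
        self._register("pca_explained", ev_out)

    def stage_enrich(self) -> None:
        self._need("enrich")
        catalog = self._load_catalog()
        freqs = pd.read_csv(self.paths["frequencies"], sep="\t")
        results = enr_mod.test_enrichment(
            catalog.risk_subset,
            freqs,
            alpha=self.config.fdr_alpha,
            leave_one_out=self.config.leave_one_out,
        )
        out = self.outdir / "enrichment.tsv"
        enr_mod.results_frame(results).to_csv(out, sep="\t", index=False)
        self._register("enrichment", out)

        gene_map = {r.snp_id: r.gene for r in catalog.records}
        gene_counts = enr_mod.gene_level_counts(results, gene_map)
        gout = self.outdir / "gene_counts.tsv"
        gene_counts.to_csv(gout, sep="\t", index=False)
        self._register("gene_counts", gout)

        # heatmap for the gene with the most enriched SNPs in the target population
        pops = sorted({r.population for r in results})
        if results and pops:
            target = self._target_population(pops)
            enr_target = gene_counts[
                (gene_counts.population == target) & (gene_counts.direction == "enriched")
            ]
            if not enr_target.empty:
                top_gene = enr_target.iloc[0].gene
                gene_snps = {sid for sid, g in gene_map.items() if g == top_gene}
                sub = [r for r in results if r.snp_id in gene_snps]
                try:
                    hm = enr_mod.heatmap_matrix(sub)
                except ValueError:
                    hm = None
                if hm is not None:
                    hout = self.outdir / "heatmap.tsv"
                    hm.matrix.to_csv(hout, sep="\t")
                    self._register("heatmap", hout)
                    cout = self.outdir / "heatmap_clusters.tsv"
                    hm.cluster_labels.rename_axis("snp_id").reset_index().to_csv(
                        cout, sep="\t", index=False
                    )
                    self._register("heatmap_clusters", cout)

    def stage_clump(self) -> None:
        self._need("clump")
        gt = self._load_genotypes()
        catalog = self._load_catalog()
        risk = {r.snp_id: r for r in catalog.risk_subset}

        if self.config.score_all_risk:
            selected = list(risk)
        else:
            enr = pd.read_csv(self.paths["enrichment"], sep="\t")
            target = self._target_population(sorted(enr.population.unique()))
            sig = enr[
                (enr.population == target)
                & enr.significant
                & (enr.direction == "enriched")
            ]
            selected = [s for s in sig.snp_id if s in risk]
            if not selected:
                logger.warning("no enriched risk SNPs in %s; falling back to all risk SNPs", target)
                selected = list(risk)

        summary = pd.DataFrame(
            {
                "snp_id": selected,
                "chrom": [risk[s].chrom for s in selected],
                "pos": [risk[s].pos for s in selected],
                "pvalue": [risk[s].pvalue for s in selected],
            }
        )
        cfg = prs.ClumpConfig(self.config.r2_threshold, self.config.window_bp)
        retained = prs.ld_clump(summary, gt, cfg)
        out = self.outdir / "clumped.tsv"
        pd.DataFrame({"snp_id": retained}).to_csv(out, sep="\t", index=False)
        self._register("clumped", out)

    def stage_score(self) -> None:
        self._need("score")
        gt = self._load_genotypes()
        catalog = self._load_catalog()
        retained = set(pd.read_csv(self.paths["clumped"], sep="\t").snp_id)
        index_snps = [r for r in catalog.risk_subset if r.snp_id in retained]
        scored = prs.score_cohort(gt, index_snps)
        out = self.outdir / "prs.tsv"
        scored.to_csv(out, sep="\t", index=False)
        self._register("scores", out)

    def stage_assoc(self) -> None:
        self._need("assoc")
        scores = pd.read_csv(self.paths["scores"], sep="\t")
        pheno = pd.read_csv(self.paths["phenotypes"])
        cohort = pheno.merge(scores, on="sample_id", how="inner")
        if cohort.empty:
            raise PipelineError("no overlap between scored samples and phenotypes")

        pr = assoc_mod.prevalence_ratios(cohort)
        pr_out = self.outdir / "prevalence_ratios.tsv"
        assoc_mod.estimates_frame(pr).to_csv(pr_out, sep="\t", index=False)
        self._register("prevalence_ratios", pr_out)

        hr_rows = []
        for full in (False, True):
            hr = assoc_mod.hazard_ratios(cohort, full_model=full)
            f = assoc_mod.estimates_frame(hr)
            f.insert(0, "model", "full" if full else "age_sex_bmi")
            hr_rows.append(f)
        hr_out = self.outdir / "hazard_ratios.tsv"
        pd.concat(hr_rows, ignore_index=True).to_csv(hr_out, sep="\t", index=False)
        self._register("hazard_ratios", hr_out)

        curves = assoc_mod.cumulative_incidence(cohort)
        ci_frames = []
        for label, frame in sorted(curves.items()):
            frame = frame.copy()
            frame.insert(0, "risk_category", label)
            ci_frames.append(frame)
        ci_out = self.outdir / "cumulative_incidence.tsv"
        pd.concat(ci_frames, ignore_index=True).to_csv(ci_out, sep="\t", index=False)
        self._register("cumulative_incidence", ci_out)

        bio_frames = []
        for b in assoc_mod.BIOMARKERS:
            f = assoc_mod.estimates_frame(assoc_mod.biomarker_associations(cohort, b))
            f.insert(0, "biomarker", b)
            bio_frames.append(f)
        bio_out = self.outdir / "biomarker_associations.tsv"
        pd.concat(bio_frames, ignore_index=True).to_csv(bio_out, sep="\t", index=False)
        self._register("biomarker_associations", bio_out)

    # -- driver -------------------------------------------------------------

    def run(self, stages=None) -> dict:
        """Execute the requested stages in dependency order; write the manifest."""
        selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
        unknown = set(stages or []) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for stage in selected:
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        manifest = self.write_manifest(selected)
        return manifest

    def write_manifest(self, stages_run) -> dict:
        from . import __version__

        checksums = {
            key: _sha256(path) for key, path in sorted(self.paths.items()) if Path(path).exists()
        }
        manifest = {
            "version": __version__,
            "seed": self.config.seed,
            "stages_run": list(stages_run),
            "config": self.config.to_jsonable(),
            "checksums": checksums,
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Convenience wrapper: build a Pipeline and run the selected stages."""
    return Pipeline(config).run(stages)
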