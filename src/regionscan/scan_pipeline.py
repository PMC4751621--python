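"""Significance thresholds and end-to-end orchestration of the scan.

Genome-wide thresholds are Bonferroni at family-wise level alpha over the
number of tests; for overlapping-window scans half the window count is used
as the effective number of tests (adjacent windows share half their SNPs).
The halved count may be fractional and is used as-is.  The suggestive level
is the p-value at which one false positive per whole-genome scan is expected,
i.e. -log10(1/m).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import genotype_io, kinship, phenotype_prep, ssgwas, synthetic_data, varcomp, windows

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSet", "bonferroni_threshold", "suggestive_threshold",
           "threshold_set", "PipelineConfig", "run_full_analysis"]


def bonferroni_threshold(n_tests: float, alpha: float = 0.05,
                         halve: bool = False) -> float:
    """Genome-wide -log10 p threshold: -log10(alpha / m), m = n_tests(/2)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    m = n_tests / 2.0 if halve else float(n_tests)
    return float(-np.log10(alpha / m))


def suggestive_threshold(n_tests: float, halve: bool = False) -> float:
    """-log10 p at which one false positive per scan is expected: -log10(1/m)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    m = n_tests / 2.0 if halve else float(n_tests)
    return float(np.log10(m))


@dataclass
class ThresholdSet:
    """Thresholds for one analysis class (ssgwas / window100 / window10)."""

    analysis_class: str
    n_tests_raw: int
    n_tests_effective: float
    genomewide_neg_log10_p: float
    suggestive_neg_log10_p: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.genomewide_neg_log10_p < self.suggestive_neg_log10_p:
            raise ValueError("genome-wide threshold below suggestive threshold")
        if self.n_tests_effective > self.n_tests_raw:
            raise ValueError("effective test count exceeds raw count")


def threshold_set(analysis_class: str, n_tests: int, alpha: float = 0.05,
                  halve: bool | None = None) -> ThresholdSet:
    """Build the threshold pair; overlapping-window classes halve by default."""
    if halve is None:
        halve = analysis_class in ("window100", "window10")
    return ThresholdSet(
        analysis_class=analysis_class,
        n_tests_raw=int(n_tests),
        n_tests_effective=n_tests / 2.0 if halve else float(n_tests),
        genomewide_neg_log10_p=bonferroni_threshold(n_tests, alpha, halve),
        suggestive_neg_log10_p=suggestive_threshold(n_tests, halve),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage parameters for one full run.

    Either ``bfile``+``pheno`` point at existing inputs, or ``simulate``
    holds a :class:`~regionscan.synthetic_data.SimulationConfig` mapping.
    """

    out_dir: str = "results/run"
    bfile: str | None = None
    pheno: str | None = None
    trait: str = "trait"
    simulate: dict | None = None
    seed: int = 0
    window_size: int = 100
    window_stride: int = 50
    fine_size: int = 10
    fine_stride: int = 5
    top_k: int = 100
    alpha: float = 0.05
    null_dist: str = "chi2_half"
    qc: dict = field(default_factory=dict)
    pinned_counts: dict | None = None  # optional pinned test counts per class

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run qc -> phenotype prep -> GRM -> regional scan -> fine mapping ->
    single-SNP scan -> thresholds, writing every stage's output under
    ``config.out_dir`` so stages are independently re-runnable.

    Returns a report bundle (paths, summaries, thresholds).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"out_dir": str(out), "seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
        return deco

    # ---- inputs -----------------------------------------------------------
    @stage("load")
    def _inputs():
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            cohort = synthetic_data.simulate_cohort(
                synthetic_data.SimulationConfig(**sim)
            )
            synthetic_data.write_cohort(cohort, out / "cohort")
            return cohort.genotypes, cohort.trait_table(config.trait), cohort.truth
        if config.bfile is None or config.pheno is None:
            raise ValueError("config needs either 'simulate' or 'bfile'+'pheno'")
        import pandas as pd
        genotypes = genotype_io.read_plink(config.bfile)
        table = pd.read_csv(config.pheno, sep="\t")
        return genotypes, table, None

    genotypes, trait_table, truth = _inputs

    # ---- QC ---------------------------------------------------------------
    @stage("qc")
    def _qc():
        thresholds = genotype_io.QCThresholds(**config.qc)
        filtered, qc_report = genotype_io.apply_qc(genotypes, thresholds)
        (out / "qc_report.json").write_text(json.dumps({
            "n_snps_in": qc_report.n_snps_in, "n_snps_out": qc_report.n_snps_out,
            "n_samples_in": qc_report.n_samples_in,
            "n_samples_out": qc_report.n_samples_out,
            "removed": qc_report.n_removed_per_criterion,
        }, indent=2))
        return filtered.sort_by_position(), qc_report

    clean, qc_report = _qc
    report["qc"] = {"n_snps": clean.m_snps, "n_samples": clean.n_samples}

    # ---- phenotype --------------------------------------------------------
    @stage("phenotype")
    def _pheno():
        sub = trait_table[trait_table["sample_id"].isin(clean.samples)]
        adjusted = phenotype_prep.prepare_phenotype(sub, trait=config.trait)
        frame = adjusted.to_frame().set_index("sample_id").loc[clean.samples]
        frame.to_csv(out / "phenotype.tsv", sep="\t")
        return frame["y"].to_numpy()

    y = _pheno

    # ---- whole-genome GRM -------------------------------------------------
    @stage("grm")
    def _grm():
        G_w = kinship.genomic_relationship(clean, role="whole_genome")
        kinship.write_gcta_grm(G_w, clean.samples, out / "whole_genome")
        return kinship.bend_psd(G_w)

    G_w = _grm

    # ---- regional scan ----------------------------------------------------
    @stage("rhm_scan")
    def _scan():
        specs = windows.make_windows(clean.variants, config.window_size,
                                     config.window_stride)
        results, summary = varcomp.scan_regions(y, clean, specs, G_w,
                                                null_dist=config.null_dist)
        varcomp.scan_to_frame(results).to_csv(out / "rhm_scan.tsv", sep="\t",
                                              index=False, float_format="%.10g")
        return specs, results, summary

    specs, scan_results, scan_summary = _scan
    report["rhm"] = scan_summary

    # ---- fine mapping -----------------------------------------------------
    @stage("fine_map")
    def _fine():
        selected, fine_specs = windows.select_fine_map_targets(
            scan_results, k=min(config.top_k, len(scan_results)),
            fine_size=config.fine_size, fine_stride=config.fine_stride,
            variants=clean.variants,
        )
        null_fit = varcomp.fit_reml(y, {"whole_genome": G_w})
        fine_results, fine_summary = varcomp.scan_regions(
            y, clean, fine_specs, G_w, null_fit=null_fit,
            null_dist=config.null_dist,
        )
        varcomp.scan_to_frame(fine_results).to_csv(
            out / "rhm_finemap.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return fine_results, fine_summary

    fine_results, fine_summary = _fine
    report["fine_map"] = fine_summary

    # ---- single-SNP scan --------------------------------------------------
    @stage("ssgwas")
    def _ssgwas():
        null_fit = ssgwas.fit_polygenic_null(y, G_w)
        assocs = ssgwas.scan_snps(null_fit, clean)
        ssgwas.associations_to_frame(assocs).to_csv(
            out / "ssgwas.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return assocs

    assocs = _ssgwas

    # ---- thresholds & significance calls ----------------------------------
    @stage("thresholds")
    def _thresholds():
        counts = {
            "ssgwas": clean.m_snps,
            "window100": len(specs),
            "window10": len(fine_results),
        }
        if config.pinned_counts:
            counts.update(config.pinned_counts)
        sets = {cls: threshold_set(cls, max(1, n), alpha=config.alpha)
                for cls, n in counts.items()}
        (out / "thresholds.json").write_text(
            json.dumps({cls: asdict(t) for cls, t in sets.items()}, indent=2)
        )
        return sets

    thresholds = _thresholds
    report["thresholds"] = {cls: asdict(t) for cls, t in thresholds.items()}

    report["hits"] = {
        "rhm_genomewide": [
            r.window.window_id for r in scan_results
            if r.neg_log10_p >= thresholds["window100"].genomewide_neg_log10_p
        ],
        "rhm_suggestive": [
            r.window.window_id for r in scan_results
            if r.neg_log10_p >= thresholds["window100"].suggestive_neg_log10_p
        ],
        "ssgwas_genomewide": [
            a.snp_id for a in assocs
            if a.neg_log10_p is not None
            and a.neg_log10_p >= thresholds["ssgwas"].genomewide_neg_log10_p
        ],
    }
    if truth is not None:
        report["truth"] = truth
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
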