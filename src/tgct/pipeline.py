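"""End-to-end orchestration: filter -> landscape statistics -> driver
statistics -> CNV calling -> CNV landscape -> QC, with a single-command
reproduction of the bundled paper fixture.

:func:`analyze_cohort` runs the whole analysis in memory on a
:class:`~tgct.synthetic.CohortBundle`; :func:`run_pipeline` adds the file
layer (writes the simulated inputs, per-stage output tables, a JSON cohort
report and a run manifest with checksums and timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnv import LohParams, SegmentationParams, call_loh, segment_sample
from .cnv_landscape import (
    LandscapeConfig,
    arm_and_chromosome_summary,
    artifact_region_filter,
    chromothripsis_flag,
    classify_scale,
    empirical_focal_background,
    exclude_unstable_samples,
    focal_recurrence_significance,
    genome_cnv_fraction,
    map_focal_to_genes,
    per_sample_focal_counts,
    rank_recurrent_genes,
)
from .drivers import (
    DriverTestConfig,
    binomial_recurrence_test,
    detection_power,
    gene_background_probability,
)
from .filters import FilterConfig, apply_filters
from .landscape import (
    age_rate_association,
    gene_recurrence,
    mutation_rate,
    round_percent,
    snv_spectrum,
)
from .models import CnvSegment
from .synthetic import CohortBundle, CohortConfig, generate_cohort, paper_fixture

__all__ = ["PipelineParams", "CoverageQc", "CohortReport", "coverage_qc",
           "analyze_cohort", "run_pipeline"]


@dataclass
class PipelineParams:
    filters: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    loh: LohParams = field(default_factory=LohParams)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    driver: DriverTestConfig = field(default_factory=DriverTestConfig)
    target_mb: float = 37.0
    power_frequencies: tuple[float, ...] = (0.05, 0.10, 0.15)
    age_cutoff: float = 40.0
    external_fsip2_p: float | None = None  # external-cohort p for meta-analysis


@dataclass(frozen=True)
class CoverageQc:
    """Length-weighted sequencing-depth QC for one side of the cohort.

    ``fraction_ge_10x`` is the fraction of target bases with depth
    strictly above 10; ``fraction_ge_20x`` the fraction at or above 20
    (matching how the two thresholds are conventionally reported)."""

    mean_coverage: float
    fraction_ge_10x: float
    fraction_ge_20x: float


def coverage_qc(coverage: pd.DataFrame, side: str = "tumour") -> CoverageQc:
    if side not in ("tumour", "normal"):
        raise ValueError("side must be 'tumour' or 'normal'")
    if len(coverage) == 0:
        raise ValueError("coverage_qc requires at least one bin")
    depth = coverage[f"{side}_depth"].to_numpy(dtype=float)
    lengths = (coverage["end"] - coverage["start"]).to_numpy(dtype=float)
    w = lengths / lengths.sum()
    return CoverageQc(
        mean_coverage=float((depth * w).sum()),
        fraction_ge_10x=float(w[depth > 10].sum()),
        fraction_ge_20x=float(w[depth >= 20].sum()),
    )


@dataclass
class CohortReport:
    """All stage outputs of one cohort analysis (in-memory)."""

    n_samples: int
    filter_report: object
    rates: object
    spectrum: object
    snv_recurrence: list
    association: object
    driver_pvalues: pd.DataFrame
    power: list
    segments: list[CnvSegment]
    het_sites: pd.DataFrame
    arm_summary: object
    cnv_fraction: dict[str, float]
    chromothripsis: dict[str, list[str]]
    focal_counts: dict[str, int]
    excluded_samples: list[str]
    retained_samples: list
    gene_events: list
    artifact_regions: list[dict]
    recurrence_rows: list
    focal_significance: pd.DataFrame
    qc_tumour: CoverageQc
    qc_normal: CoverageQc
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        """Headline cohort numbers as a JSON-able dict."""
        n = self.n_samples
        arm = self.arm_summary
        n_12p = len(arm.samples_with_arm("12p", "gain"))
        n_x = len(arm.samples_with_chrom("X", "gain"))
        n_y = len(arm.samples_with_chrom("Y", "loss"))
        n_7 = len(arm.samples_with_chrom("7", "gain"))
        n_21 = len(arm.samples_with_chrom("21", "gain"))
        n_22 = len(arm.samples_with_chrom("22", "gain"))
        large_samples = {s.sample_id for s in self.segments
                        if s.call != "neutral" and s.scale == "large"}
        n_ret = len(self.retained_samples)
        fsip2_row = next((r for r in self.recurrence_rows
                          if "FSIP2" in r.genes), None)
        fsip2_gain_samples = {e.sample_id for e in self.gene_events
                              if e.gene == "FSIP2" and e.direction == "gain"}
        gene_pct = {}
        for rec in self.snv_recurrence:
            if rec.gene in ("KIT", "CDC27", "KRAS", "PRKRIR", "XRCC2"):
                gene_pct[rec.gene] = {
                    "mutated_samples": rec.mutated_samples,
                    "mutations": rec.mutation_count,
                    "percent_samples": rec.percent_samples,
                    "percent_by_histology": rec.percent_by_histology,
                }
        fractions = list(self.cnv_fraction.values())
        return {
            "n_samples": n,
            "n_variants_pass": len(self.filter_report.passed),
            "n_common_snps_removed": self.filter_report.n_common_snps_removed,
            "mean_nonsyn_rate_per_mb": round(self.rates.cohort_mean, 4),
            "sd_nonsyn_rate_per_mb": (None if self.rates.cohort_sd is None
                                      else round(self.rates.cohort_sd, 4)),
            "spectrum": {k: (None if v is None else round(v, 4))
                         for k, v in self.spectrum.proportions.items()},
            "genes": gene_pct,
            "age_rate_r": (None if self.association is None
                           else self.association.r),
            "pct_12p_gain": round_percent(100.0 * n_12p / n),
            "n_12p_gain": n_12p,
            "n_isochromosome_12p": len(arm.isochromosome_12p),
            "pct_chrX_gain": round_percent(100.0 * n_x / n),
            "n_chrX_gain": n_x,
            "pct_chrY_loss": round_percent(100.0 * n_y / n),
            "n_chrY_loss": n_y,
            "pct_chr7_gain": round_percent(100.0 * n_7 / n),
            "n_chr7_gain": n_7,
            "n_chr21_gain": n_21,
            "n_chr22_gain": n_22,
            "n_large_scale_samples": len(large_samples),
            "mean_cnv_fraction_pct": (round(float(np.mean(fractions)), 2)
                                      if fractions else 0.0),
            "chromothriptic_samples": sorted(self.chromothripsis),
            "excluded_samples": self.excluded_samples,
            "n_retained": n_ret,
            "fsip2": None if fsip2_row is None else {
                "losses": fsip2_row.losses,
                "gains": fsip2_row.gains,
                "total": fsip2_row.total,
                "n_samples": fsip2_row.n_samples,
                "n_gain_samples": len(fsip2_gain_samples),
                # amplification recurrence is quoted as % of tumours
                # eligible for the recurrence analysis
                "pct_retained": round_percent(
                    100.0 * len(fsip2_gain_samples) / n_ret),
            },
            "recurrence_table": [
                {"genes": list(r.genes), "region": r.region,
                 "losses": r.losses, "gains": r.gains, "total": r.total,
                 "n_samples": r.n_samples}
                for r in self.recurrence_rows
            ],
            "qc": {
                "tumour_mean_coverage": round(self.qc_tumour.mean_coverage, 2),
                "normal_mean_coverage": round(self.qc_normal.mean_coverage, 2),
                "tumour_fraction_ge_10x": round(self.qc_tumour.fraction_ge_10x, 4),
                "tumour_fraction_ge_20x": round(self.qc_tumour.fraction_ge_20x, 4),
            },
        }


def analyze_cohort(bundle: CohortBundle,
                   params: PipelineParams | None = None,
                   seed: int = 0) -> CohortReport:
    """Run the full analysis on an in-memory bundle.

    ``seed`` drives the segmentation permutation tests (per-sample child
    seeds are spawned deterministically); all other stages are
    deterministic in their inputs.
    """
    params = params or PipelineParams()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    filt = apply_filters(bundle.variants, params.filters)
    timings["filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rates = mutation_rate(filt.passed, bundle.samples, params.target_mb)
    spectrum = snv_spectrum(filt.passed)
    snv_rec = gene_recurrence(filt.passed, bundle.samples)
    try:
        association = age_rate_association(bundle.samples, rates,
                                           params.age_cutoff)
    except ValueError:
        association = None
    timings["landscape"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    driver_cfg = dataclasses.replace(
        params.driver, background_rate_per_mb=max(rates.cohort_mean, 0.0))
    p_bg = gene_background_probability(driver_cfg)
    n = len(bundle.samples)
    driver_rows = []
    for rec in snv_rec:
        p = binomial_recurrence_test(rec.mutated_samples, n, p_bg)
        driver_rows.append({
            "gene": rec.gene, "mutated_samples": rec.mutated_samples,
            "mutations": rec.mutation_count, "p_value": p,
            "significant_nominal": p <= driver_cfg.alpha_nominal,
            "significant_genomewide": p <= driver_cfg.alpha_genomewide,
        })
    driver_pvalues = pd.DataFrame(
        driver_rows, columns=["gene", "mutated_samples", "mutations",
                              "p_value", "significant_nominal",
                              "significant_genomewide"])
    power = [detection_power(n, f, driver_cfg)
             for f in params.power_frequencies]
    timings["driver"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(seed).spawn(len(bundle.samples))
    segments: list[CnvSegment] = []
    loh_frames = []
    for child, sample in zip(seeds, bundle.samples):
        sid = sample.sample_id
        rng_seed = int(child.generate_state(1)[0] % (2 ** 31))
        _, segs = segment_sample(bundle.coverage[sid], params.segmentation,
                                 sample_id=sid, seed=rng_seed)
        het = bundle.het_sites[bundle.het_sites["sample_id"] == sid]
        if len(het):
            loh_frames.append(call_loh(het, segs, params.loh))
        segments.extend(segs)
    het_annotated = (pd.concat(loh_frames, ignore_index=True)
                     if loh_frames else bundle.het_sites.copy())
    timings["cnv"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    classify_scale(segments, params.landscape)
    arms = bundle.genome.arms()
    arm_summary = arm_and_chromosome_summary(segments, arms, params.landscape)
    genome_size = bundle.genome.size_bp
    fractions = {
        sid: genome_cnv_fraction([s for s in segments if s.sample_id == sid],
                                 genome_size)
        for sid in bundle.sample_ids
    }
    chromo = chromothripsis_flag(segments, arms, params.landscape)
    focal_counts = per_sample_focal_counts(segments, bundle.samples)
    retained, excluded = exclude_unstable_samples(bundle.samples, focal_counts,
                                                  params.landscape)
    retained_ids = {s.sample_id for s in retained}
    focal_segs = [s for s in segments
                  if s.scale == "focal" and s.sample_id in retained_ids]
    events = map_focal_to_genes(focal_segs, bundle.gene_models)
    events, artifact_regions = artifact_region_filter(events, params.landscape)
    rows = rank_recurrent_genes(events, retained, params.landscape)
    gene_by_name = {g.name: g for g in bundle.gene_models}
    sig_rows = []
    for row in rows:
        gene = gene_by_name[row.genes[0]]
        p_bg_focal = empirical_focal_background(events, retained, gene,
                                                genome_size)
        p = focal_recurrence_significance(row, len(retained), p_bg_focal)
        rec = {"genes": ";".join(row.genes), "region": row.region,
               "losses": row.losses, "gains": row.gains, "total": row.total,
               "n_samples": row.n_samples, "p_bg_focal": p_bg_focal,
               "p_value": p}
        if params.external_fsip2_p is not None and "FSIP2" in row.genes:
            from .cnv_landscape import meta_with_external
            rec["meta_p"] = meta_with_external(p, params.external_fsip2_p).combined_p
        sig_rows.append(rec)
    focal_significance = pd.DataFrame(
        sig_rows, columns=["genes", "region", "losses", "gains", "total",
                           "n_samples", "p_bg_focal", "p_value", "meta_p"])
    timings["cnv_landscape"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    all_cov = pd.concat(bundle.coverage.values(), ignore_index=True)
    qc_t = coverage_qc(all_cov, "tumour")
    qc_n = coverage_qc(all_cov, "normal")
    timings["qc"] = time.perf_counter() - t0

    return CohortReport(
        n_samples=n, filter_report=filt, rates=rates, spectrum=spectrum,
        snv_recurrence=snv_rec, association=association,
        driver_pvalues=driver_pvalues, power=power, segments=segments,
        het_sites=het_annotated, arm_summary=arm_summary,
        cnv_fraction=fractions, chromothripsis=chromo,
        focal_counts=focal_counts, excluded_samples=excluded,
        retained_samples=retained, gene_events=events,
        artifact_regions=artifact_regions, recurrence_rows=rows,
        focal_significance=focal_significance, qc_tumour=qc_t, qc_normal=qc_n,
        stage_seconds=timings,
    )


# ---------------------------------------------------------------------------
# file-level pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_report_tables(report: CohortReport, out: Path) -> list[str]:
    written = []

    def save(df: pd.DataFrame, name: str):
        df.to_csv(out / name, sep="\t", index=False)
        written.append(name)

    rates = report.rates
    save(pd.DataFrame(
        [{"sample_id": sid, "n_nonsyn": rates.per_sample_count[sid],
          "rate_per_mb": round(r, 6)}
         for sid, r in rates.per_sample_rate.items()]), "rates.tsv")
    save(pd.DataFrame(
        [{"class": k, "proportion": ("" if v is None else round(v, 6)),
          "count": report.spectrum.counts.get(k, 0)}
         for k, v in report.spectrum.proportions.items()]), "spectrum.tsv")
    save(pd.DataFrame(
        [{"gene": r.gene, "mutated_samples": r.mutated_samples,
          "mutations": r.mutation_count, "percent_samples": r.percent_samples}
         for r in report.snv_recurrence]), "recurrence_snv.tsv")
    save(report.driver_pvalues, "driver_pvalues.tsv")
    save(pd.DataFrame(
        [{"n": p.n, "frequency": p.f, "p_bg": p.p_bg, "k_min": p.k_min,
          "power": round(p.power, 6)} for p in report.power]), "power.tsv")
    from .io import write_segments
    write_segments(report.segments, out / "segments.tsv")
    written.append("segments.tsv")
    report.het_sites.to_csv(out / "loh.tsv", sep="\t", index=False)
    written.append("loh.tsv")
    arm_rows = []
    for sid, calls in sorted(report.arm_summary.arm_calls.items()):
        for arm_name, call in sorted(calls.items()):
            arm_rows.append({"sample_id": sid, "level": "arm",
                             "name": arm_name, "call": call})
    for sid, calls in sorted(report.arm_summary.chrom_calls.items()):
        for chrom, call in sorted(calls.items()):
            arm_rows.append({"sample_id": sid, "level": "chromosome",
                             "name": chrom, "call": call})
    for sid in sorted(report.arm_summary.isochromosome_12p):
        arm_rows.append({"sample_id": sid, "level": "isochromosome",
                         "name": "12p", "call": "gain"})
    save(pd.DataFrame(arm_rows, columns=["sample_id", "level", "name",
                                         "call"]), "arm_summary.tsv")
    save(pd.DataFrame(
        [{"sample_id": sid, "arms": ";".join(arms)}
         for sid, arms in sorted(report.chromothripsis.items())]),
        "chromothripsis.tsv")
    save(pd.DataFrame(
        [{"sample_id": sid, "cnv_fraction_pct": round(v, 4),
          "focal_cnvs": report.focal_counts.get(sid, 0)}
         for sid, v in report.cnv_fraction.items()]), "cnv_fraction.tsv")
    save(pd.DataFrame(
        [{"genes": ";".join(r.genes), "region": r.region, "losses": r.losses,
          "gains": r.gains, "total": r.total, "n_samples": r.n_samples}
         for r in report.recurrence_rows]), "focal_recurrence.tsv")
    save(report.focal_significance, "focal_significance.tsv")
    save(pd.DataFrame([
        {"side": "tumour", "mean_coverage": report.qc_tumour.mean_coverage,
         "fraction_ge_10x": report.qc_tumour.fraction_ge_10x,
         "fraction_ge_20x": report.qc_tumour.fraction_ge_20x},
        {"side": "normal", "mean_coverage": report.qc_normal.mean_coverage,
         "fraction_ge_10x": report.qc_normal.fraction_ge_10x,
         "fraction_ge_20x": report.qc_normal.fraction_ge_20x},
    ]), "qc.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)
    written.append("report.json")
    return written


def run_pipeline(out_dir, seed: int = 0, *, fixture: bool = False,
                 config: CohortConfig | None = None,
                 input_dir=None,
                 params: PipelineParams | None = None,
                 write_inputs: bool = True) -> tuple[dict, CohortReport]:
    """Run every stage in one pass and persist all outputs.

    Exactly one of ``fixture``, ``config`` (simulate) or ``input_dir``
    (pre-written cohort directory) selects the input source.  Returns the
    run manifest and the in-memory report.
    """
    sources = sum((fixture, config is not None, input_dir is not None))
    if sources != 1:
        raise ValueError("select exactly one of fixture / config / input_dir")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or PipelineParams()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if fixture:
        bundle = paper_fixture()
    elif config is not None:
        bundle = generate_cohort(config)
    else:
        from .io import read_cohort
        bundle = read_cohort(input_dir)
    timings["inputs"] = time.perf_counter() - t0

    input_manifest = None
    if write_inputs and input_dir is None:
        from .io import write_cohort
        t0 = time.perf_counter()
        input_manifest = write_cohort(bundle, out / "inputs")
        timings["write_inputs"] = time.perf_counter() - t0

    report = analyze_cohort(bundle, params, seed)
    timings.update(report.stage_seconds)

    t0 = time.perf_counter()
    results_dir = out / "results"
    results_dir.mkdir(exist_ok=True)
    written = _write_report_tables(report, results_dir)
    timings["write_outputs"] = time.perf_counter() - t0

    outputs = {name: _sha256(results_dir / name) for name in written}
    manifest = {
        "tool": "tgct",
        "version": __version__,
        "seed": seed,
        "mode": ("fixture" if fixture else
                 "simulate" if config is not None else "analyze"),
        "params": {
            "target_mb": params.target_mb,
            "segmentation": dataclasses.asdict(params.segmentation),
            "landscape": dataclasses.asdict(params.landscape),
            "filters": dataclasses.asdict(params.filters),
            "loh": dataclasses.asdict(params.loh),
        },
        "inputs": input_manifest,
        "outputs": outputs,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    for name in written:
        assert (results_dir / name).exists()
    return manifest, report
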