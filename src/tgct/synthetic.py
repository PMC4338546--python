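"""Synthetic matched tumour/normal exome cohorts.

Two entry points:

* :func:`generate_cohort` draws a cohort with the statistical structure the
  analysis assumes — per-sample non-synonymous counts around a configured
  rate, a six-class substitution spectrum, optional driver spikes at chosen
  VAFs, depth-perturbation CNV spikes, chromothriptic outlier samples,
  oxidation-artifact calls and common germline SNPs — all deterministic
  given the seed.
* :func:`paper_fixture` builds a fixed 42-tumour bundle whose hidden truth
  ledger transcribes the printed counts of the TGCT whole-exome study
  (histology split 16/18/4/4, 795 non-synonymous calls, KIT in 6 tumours
  with 5 seminomas, CDC27 at subclonal VAF in 5, the 12p/X/7/21/22/Y
  aneuploidies, FSIP2 and Xq28 focal amplifications, 3 chromothriptic
  outliers, 33 common SNPs), so that the full pipeline can be checked
  end-to-end against those summaries.

Depth model: per-exon Poisson around the configured mean coverage (negative
binomial behind ``overdispersion``); the normal genome is male, so X and Y
run at single copy and tumour/normal ratios keep their usual thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import SEX_CHROMOSOMES, Genome, default_genome
from .models import GeneModel, SampleRecord, VariantCall

__all__ = [
    "DriverSpike",
    "CnvSpike",
    "CohortConfig",
    "CohortBundle",
    "default_gene_models",
    "generate_cohort",
    "paper_fixture",
    "FIXTURE_SEED",
]

FIXTURE_SEED = 20150122

SPECTRUM_ORDER = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class DriverSpike:
    gene: str
    n_samples: int
    vaf_range: tuple[float, float] = (0.2, 0.45)
    histology_restriction: str | None = None
    mutations_per_sample: int = 1


@dataclass(frozen=True)
class CnvSpike:
    chrom: str
    start: int
    length_bp: int
    direction: str  # "gain" | "loss"
    n_samples: int
    ratio: float

    @property
    def end(self) -> int:
        return self.start + self.length_bp


@dataclass
class CohortConfig:
    """Cohort generator parameters.

    Defaults encode the study conditions: 37 Mb capture, mean
    non-synonymous rate 0.5/Mb, a spectrum dominated by C>A (31%), C>T
    (27%) and T>C (23%), 33 common SNPs across the cohort, and mean
    tumour/normal coverage 73.6x / 69.0x.  ``synonymous_ratio`` is the
    synonymous-per-non-synonymous call ratio and ``indel_fraction`` the
    indel share of non-synonymous calls.
    """

    n_samples: int = 42
    target_mb: float = 37.0
    mean_nonsyn_rate_per_mb: float = 0.5
    synonymous_ratio: float = 0.61
    indel_fraction: float = 0.14
    spectrum_weights: tuple[float, ...] = (
        0.31, 0.19 / 3, 0.27, 0.19 / 3, 0.23, 0.19 / 3)
    driver_spikes: tuple[DriverSpike, ...] = ()
    cnv_spikes: tuple[CnvSpike, ...] = ()
    chromothriptic_samples: int = 0
    chromothripsis_events: int | None = None
    focal_rate_multiplier_unstable: float = 19.0
    artifact_snv_rate: float = 1.0
    common_snp_count: int = 33
    mean_coverage_tumour: float = 73.6
    mean_coverage_normal: float = 69.0
    het_sites_per_sample: int = 300
    overdispersion: float | None = None
    seed: int = 0
    genome: Genome = field(default_factory=default_genome)

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("mean_nonsyn_rate_per_mb", "synonymous_ratio",
                     "indel_fraction", "artifact_snv_rate", "common_snp_count",
                     "chromothriptic_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        w = np.asarray(self.spectrum_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum_weights must be 6 nonnegative reals "
                             "summing to 1 within 1e-9")
        if self.chromothriptic_samples > self.n_samples:
            raise ValueError("more chromothriptic samples than samples")

    def n_chromothripsis_events(self, mean_focal_per_sample: float = 1.0) -> int:
        if self.chromothripsis_events is not None:
            return self.chromothripsis_events
        return max(21, int(np.ceil(self.focal_rate_multiplier_unstable
                                   * max(1.0, mean_focal_per_sample))))


@dataclass
class CohortBundle:
    samples: list[SampleRecord]
    variants: list[VariantCall]
    coverage: dict[str, pd.DataFrame]      # sample_id -> per-bin depths
    het_sites: pd.DataFrame
    gene_models: list[GeneModel]
    genome: Genome
    truth_events: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


# ---------------------------------------------------------------------------
# gene models

_RESERVED_GENES = [
    ("KIT", "6", 1_200_000, 1_283_000),
    ("KRAS", "12", 2_536_000, 2_582_000),
    ("CDC27", "14", 3_500_000, 3_570_000),
    ("PRKRIR", "7", 9_000_000, 9_030_000),
    ("XRCC2", "7", 15_234_000, 15_264_000),
    ("AKAP4", "X", 4_995_000, 5_005_000),
    ("FSIP2", "2", 18_660_000, 18_757_000),
]

XQ28_GENES = (
    "HCFC1", "TMEM187", "MIR3202-1", "IRAK1", "MIR718", "MECP2", "OPN1LW",
    "TEX28", "OPN1MW", "TKTL1", "FLNA", "EMD", "AK307233", "RPL10",
    "SNORA70", "DQ570720", "DNASE1L1", "TAZ",
)
XQ28_REGION = ("X", 15_048_000, 15_448_000)

_FILLER_SPACING = 250_000
_FILLER_OFFSET = 50_000
_FILLER_SPAN = 30_000
_RESERVED_MARGIN = 20_000


def default_gene_models(genome: Genome | None = None) -> list[GeneModel]:
    """Bundled gene set: named TGCT-relevant genes at fixed (scaled)
    coordinates, the 18-gene Xq28 cluster, and synthetic filler genes
    tiling the rest of the genome at ~250 kb spacing."""
    genome = genome or default_genome()
    genes: list[GeneModel] = []
    reserved_spans: dict[str, list[tuple[int, int]]] = {}
    for name, chrom, start, end in _RESERVED_GENES:
        if chrom not in genome:
            continue
        genes.append(GeneModel(name, chrom, start, end))
        reserved_spans.setdefault(chrom, []).append((start, end))
    if XQ28_REGION[0] in genome:
        chrom, rstart, rend = XQ28_REGION
        step, span = 20_800, 18_000
        for i, name in enumerate(XQ28_GENES):
            s = rstart + 12_000 + i * step
            genes.append(GeneModel(name, chrom, s, s + span))
        reserved_spans.setdefault(chrom, []).append((rstart, rend))
    k = 0
    for c in genome.chromosomes:
        spans = reserved_spans.get(c.name, [])
        for start in range(_FILLER_OFFSET, c.length - _FILLER_SPAN,
                           _FILLER_SPACING):
            end = start + _FILLER_SPAN
            if any(start < re + _RESERVED_MARGIN and rs - _RESERVED_MARGIN < end
                   for rs, re in spans):
                continue
            k += 1
            genes.append(GeneModel(f"SYNG{k:04d}", c.name, start, end))
    return genes


# ---------------------------------------------------------------------------
# variant synthesis helpers


def _display_substitution(cls: str, flip: bool) -> tuple[str, str]:
    ref, alt = cls.split(">")
    if flip:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _read_support(vaf: float, depth: float, rng: np.random.Generator
                  ) -> tuple[int, int]:
    total = max(2, int(round(vaf * depth)))
    fwd = max(1, min(total - 1, int(rng.binomial(total, 0.5))))
    return fwd, total - fwd


def _make_snv(sample_id: str, gene: GeneModel | None, cls: str,
              consequence: str, vaf: float, rng: np.random.Generator,
              truth: str, genome: Genome, pos: int | None = None,
              chrom: str | None = None, **quality) -> VariantCall:
    if gene is not None:
        chrom = gene.chrom
        if pos is None:
            pos = int(rng.integers(gene.start + 1, gene.end + 1))
    elif pos is None:
        c = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        chrom, pos = c.name, int(rng.integers(1, c.length))
    ref, alt = _display_substitution(cls, bool(rng.integers(2)))
    vaf = round(float(vaf), 4)
    fwd, rev = _read_support(vaf, 73.6, rng)
    q = {
        "alt_reads_fwd": fwd,
        "alt_reads_rev": rev,
        "mean_base_quality": round(float(rng.uniform(28, 38)), 1),
        "mean_mapq": round(float(rng.uniform(52, 60)), 1),
        "alignability": 1.0,
        "population_maf": None,
    }
    q.update(quality)
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_type="SNV", gene=gene.name if gene else None,
        consequence=consequence, vaf=vaf, truth=truth, **q,
    )


def _make_indel(sample_id: str, gene: GeneModel, vaf: float,
                rng: np.random.Generator, truth: str) -> VariantCall:
    pos = int(rng.integers(gene.start + 1, gene.end + 1))
    base = "ACGT"[int(rng.integers(4))]
    ins = "ACGT"[int(rng.integers(4))]
    if rng.integers(2):  # insertion
        ref, alt = base, base + ins
    else:  # deletion
        ref, alt = base + ins, base
    consequence = "frameshift" if rng.random() < 2 / 3 else "inframe"
    vaf = round(float(vaf), 4)
    fwd, rev = _read_support(vaf, 73.6, rng)
    return VariantCall(
        sample_id=sample_id, chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
        variant_type="indel", gene=gene.name, consequence=consequence,
        vaf=vaf, alt_reads_fwd=fwd, alt_reads_rev=rev,
        mean_base_quality=round(float(rng.uniform(28, 38)), 1),
        mean_mapq=round(float(rng.uniform(52, 60)), 1),
        alignability=1.0, truth=truth,
    )


_ARTIFACT_MODES = (
    {"alt_reads_fwd": 0},
    {"mean_base_quality": 24.0},
    {"mean_mapq": 45.0},
    {"alignability": 0.85},
    {"alt_reads_rev": 0, "mean_base_quality": 25.5},
)


def _make_artifact(sample_id: str, mode_idx: int, gene: GeneModel | None,
                   rng: np.random.Generator, genome: Genome) -> VariantCall:
    # oxidation artifacts present as C>A / G>T at modest VAF
    cls = "C>A"
    quality = dict(_ARTIFACT_MODES[mode_idx % len(_ARTIFACT_MODES)])
    return _make_snv(sample_id, gene, cls, "missense",
                     rng.uniform(0.05, 0.25), rng, "artifact:oxog", genome,
                     **quality)


def _make_common_snp(sample_id: str, gene: GeneModel,
                     rng: np.random.Generator, genome: Genome) -> VariantCall:
    cls = SPECTRUM_ORDER[int(rng.integers(6))]
    maf = round(float(rng.uniform(0.26, 0.45)), 3)
    return _make_snv(sample_id, gene, cls,
                     "synonymous" if rng.integers(2) else "missense",
                     rng.uniform(0.35, 0.65), rng, "common_snp", genome,
                     population_maf=maf)


# ---------------------------------------------------------------------------
# coverage synthesis


def _depth_draw(rng: np.random.Generator, mean: np.ndarray,
                overdispersion: float | None) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(mean)
    shape = overdispersion
    return rng.poisson(rng.gamma(shape, mean / shape))


def _simulate_coverage(genome: Genome, grid: pd.DataFrame,
                       multiplier: np.ndarray, rng: np.random.Generator,
                       mean_t: float, mean_n: float,
                       overdispersion: float | None) -> pd.DataFrame:
    sex = grid["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
    base = np.where(sex, 0.5, 1.0)
    out = grid.copy()
    out["tumour_depth"] = _depth_draw(rng, mean_t * base * multiplier,
                                      overdispersion)
    out["normal_depth"] = _depth_draw(rng, mean_n * base, overdispersion)
    return out


def _spike_multiplier(grid: pd.DataFrame, multiplier: np.ndarray,
                      chrom: str, start: int, end: int, ratio: float) -> int:
    """Multiply tumour depth over bins inside [start, end); returns the
    number of bins affected."""
    mask = ((grid["chrom"] == chrom) & (grid["start"] >= start)
            & (grid["end"] <= end)).to_numpy()
    multiplier[mask] *= ratio
    return int(mask.sum())


# ---------------------------------------------------------------------------
# generic generator


_HISTOLOGY_CYCLE = ("seminoma", "nonseminoma", "seminoma", "nonseminoma",
                    "mixed", "indeterminate")

_CHROMOTHRIPSIS_ARMS = ("1q", "2p", "6q", "7q", "1p", "2q")


def _arm_interval(genome: Genome, arm_name: str) -> tuple[str, int, int]:
    chrom, arm = arm_name[:-1], arm_name[-1]
    c = genome.chromosome(chrom)
    return (chrom, 0, c.centromere) if arm == "p" else (chrom, c.centromere, c.length)


def _chromothripsis_spikes(genome: Genome, arm_name: str, n_events: int,
                           ) -> list[tuple[int, int, float]]:
    """Deterministic alternating gain/loss spikes along one arm; each spike
    covers 4 probe bins."""
    chrom, a_start, a_end = _arm_interval(genome, arm_name)
    spacing = genome.bin_spacing
    first_bin = -(-a_start // spacing)  # ceil division
    n_bins = (a_end - a_start) // spacing
    step = max(8, (n_bins - 80) // n_events)
    spikes = []
    length = 3 * spacing + genome.bin_length  # 4 bins
    for i in range(n_events):
        start = (first_bin + 40 + i * step) * spacing
        if start + length > a_end:
            break
        ratio = 3.0 if i % 2 == 0 else 0.4
        spikes.append((start, length, ratio))
    return spikes


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a full cohort bundle from the configuration (deterministic
    given ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    genes = default_gene_models(genome)
    gene_by_name = {g.name: g for g in genes}
    fillers = [g for g in genes if g.name.startswith("SYNG")]
    if not fillers:
        raise ValueError("genome too small: no filler genes available")

    for spike in config.driver_spikes:
        if spike.gene not in gene_by_name:
            raise ValueError(f"driver spike gene {spike.gene!r} absent from "
                             "gene models")
        if spike.n_samples > config.n_samples:
            raise ValueError(f"driver spike {spike.gene!r} requests "
                             f"{spike.n_samples} samples but cohort has "
                             f"{config.n_samples}")
    for spike in config.cnv_spikes:
        if spike.n_samples > config.n_samples:
            raise ValueError(f"cnv spike {spike.chrom}:{spike.start} requests "
                             f"{spike.n_samples} samples but cohort has "
                             f"{config.n_samples}")

    # samples
    samples = [
        SampleRecord(
            sample_id=f"S{i + 1:03d}",
            histology=_HISTOLOGY_CYCLE[i % len(_HISTOLOGY_CYCLE)],
            age_years=round(float(np.clip(rng.normal(36, 9), 18, 65)), 1),
            treatment_response="sensitive",
        )
        for i in range(config.n_samples)
    ]
    sample_ids = [s.sample_id for s in samples]

    truth_rows: list[dict] = []
    variants: list[VariantCall] = []
    weights = np.asarray(config.spectrum_weights, dtype=float)

    # driver spike placement (distinct samples per spike)
    driver_assignment: dict[int, list[DriverSpike]] = {}
    for spike in config.driver_spikes:
        if spike.histology_restriction:
            pool = [i for i, s in enumerate(samples)
                    if s.histology == spike.histology_restriction]
        else:
            pool = list(range(config.n_samples))
        if len(pool) < spike.n_samples:
            raise ValueError(f"driver spike {spike.gene!r}: only {len(pool)} "
                             "eligible samples")
        chosen = rng.choice(pool, size=spike.n_samples, replace=False)
        for i in chosen:
            driver_assignment.setdefault(int(i), []).append(spike)

    mb = config.target_mb
    for i, sample in enumerate(samples):
        sid = sample.sample_id
        for spike in driver_assignment.get(i, []):
            gene = gene_by_name[spike.gene]
            for _ in range(spike.mutations_per_sample):
                vaf = rng.uniform(*spike.vaf_range)
                cls = SPECTRUM_ORDER[int(rng.choice(6, p=weights))]
                v = _make_snv(sid, gene, cls, "missense", vaf, rng,
                              f"driver:{spike.gene}", genome)
                variants.append(v)
                truth_rows.append({"sample_id": sid, "kind": "driver_variant",
                                   "name": spike.gene, "chrom": v.chrom,
                                   "start": v.pos, "end": v.pos,
                                   "direction": "", "ratio": np.nan,
                                   "detail": v.consequence})
        n_nonsyn = rng.poisson(config.mean_nonsyn_rate_per_mb * mb)
        n_indel = rng.binomial(n_nonsyn, config.indel_fraction) if n_nonsyn else 0
        n_syn = rng.poisson(config.mean_nonsyn_rate_per_mb
                            * config.synonymous_ratio * mb)
        for _ in range(n_nonsyn - n_indel):
            gene = fillers[int(rng.integers(len(fillers)))]
            cls = SPECTRUM_ORDER[int(rng.choice(6, p=weights))]
            cons = str(rng.choice(["missense", "nonsense", "splice", "other"],
                                  p=[0.8, 0.08, 0.06, 0.06]))
            variants.append(_make_snv(sid, gene, cls, cons,
                                      rng.uniform(0.2, 0.45), rng,
                                      "background", genome))
        for _ in range(n_indel):
            gene = fillers[int(rng.integers(len(fillers)))]
            variants.append(_make_indel(sid, gene, rng.uniform(0.2, 0.45),
                                        rng, "background"))
        for _ in range(n_syn):
            gene = fillers[int(rng.integers(len(fillers)))]
            cls = SPECTRUM_ORDER[int(rng.choice(6, p=weights))]
            variants.append(_make_snv(sid, gene, cls, "synonymous",
                                      rng.uniform(0.2, 0.45), rng,
                                      "background", genome))
        for k in range(rng.poisson(config.artifact_snv_rate)):
            gene = fillers[int(rng.integers(len(fillers)))]
            variants.append(_make_artifact(sid, int(rng.integers(5)), gene,
                                           rng, genome))
    for j in range(config.common_snp_count):
        sid = sample_ids[j % config.n_samples]
        gene = fillers[int(rng.integers(len(fillers)))]
        variants.append(_make_common_snp(sid, gene, rng, genome))

    # CNV spikes -> per-sample depth multipliers
    grid = genome.bin_grid()
    multipliers = {sid: np.ones(len(grid)) for sid in sample_ids}
    for spike in config.cnv_spikes:
        chosen = rng.choice(config.n_samples, size=spike.n_samples,
                            replace=False)
        for i in chosen:
            sid = sample_ids[int(i)]
            n_bins = _spike_multiplier(grid, multipliers[sid], spike.chrom,
                                       spike.start, spike.end, spike.ratio)
            if n_bins == 0:
                raise ValueError(f"cnv spike {spike.chrom}:{spike.start}-"
                                 f"{spike.end} covers no probe bins")
            kind = "cnv_large" if spike.length_bp >= 3_000_000 else "cnv_focal"
            truth_rows.append({"sample_id": sid, "kind": kind, "name": "",
                               "chrom": spike.chrom, "start": spike.start,
                               "end": spike.end, "direction": spike.direction,
                               "ratio": spike.ratio, "detail": f"bins={n_bins}"})

    mean_focal = max(
        1.0,
        sum(s.n_samples for s in config.cnv_spikes
            if s.length_bp < 3_000_000) / config.n_samples,
    )
    n_events = config.n_chromothripsis_events(mean_focal)
    unstable_idx = rng.choice(config.n_samples,
                              size=config.chromothriptic_samples,
                              replace=False)
    available_arms = [a for a in _CHROMOTHRIPSIS_ARMS if a[:-1] in genome]
    if not available_arms:
        # genome subset without the preferred arms: largest q arms instead
        available_arms = [f"{c.name}q" for c in sorted(
            genome.chromosomes, key=lambda c: c.centromere - c.length)]
    for k, i in enumerate(sorted(int(x) for x in unstable_idx)):
        sid = sample_ids[i]
        arm = available_arms[k % len(available_arms)]
        spikes = _chromothripsis_spikes(genome, arm, n_events)
        for start, length, ratio in spikes:
            _spike_multiplier(grid, multipliers[sid], arm[:-1], start,
                              start + length, ratio)
            truth_rows.append({"sample_id": sid, "kind": "cnv_focal",
                               "name": "chromothripsis", "chrom": arm[:-1],
                               "start": start, "end": start + length,
                               "direction": "gain" if ratio > 1 else "loss",
                               "ratio": ratio, "detail": f"arm={arm}"})
        truth_rows.append({"sample_id": sid, "kind": "chromothripsis_arm",
                           "name": arm, "chrom": arm[:-1], "start": 0,
                           "end": 0, "direction": "", "ratio": np.nan,
                           "detail": f"events={len(spikes)}"})
        truth_rows.append({"sample_id": sid, "kind": "unstable_sample",
                           "name": sid, "chrom": "", "start": 0, "end": 0,
                           "direction": "", "ratio": np.nan, "detail": ""})

    coverage = {
        sid: _simulate_coverage(genome, grid, multipliers[sid], rng,
                                config.mean_coverage_tumour,
                                config.mean_coverage_normal,
                                config.overdispersion)
        for sid in sample_ids
    }

    het_sites = _simulate_het_sites(genome, grid, multipliers, sample_ids,
                                    rng, config)

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "kind", "name", "chrom", "start", "end",
                 "direction", "ratio", "detail"],
    )
    return CohortBundle(samples=samples, variants=variants, coverage=coverage,
                        het_sites=het_sites, gene_models=genes, genome=genome,
                        truth_events=truth)


def _simulate_het_sites(genome: Genome, grid: pd.DataFrame,
                        multipliers: dict[str, np.ndarray],
                        sample_ids: list[str], rng: np.random.Generator,
                        config: CohortConfig) -> pd.DataFrame:
    autosomal = ~grid["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
    idx_pool = np.flatnonzero(autosomal)
    rows = []
    for sid in sample_ids:
        if config.het_sites_per_sample == 0 or idx_pool.size == 0:
            continue
        idx = np.sort(rng.choice(idx_pool,
                                 size=min(config.het_sites_per_sample,
                                          idx_pool.size),
                                 replace=False))
        chroms = grid["chrom"].to_numpy()[idx]
        pos = grid["start"].to_numpy()[idx] + 101  # 1-based, inside the exon
        ratio = multipliers[sid][idx]
        n_depth = rng.poisson(config.mean_coverage_normal, size=len(idx))
        n_alt = rng.binomial(np.maximum(n_depth, 1), 0.5)
        # germline sites are ascertained heterozygous: clamp normal BAF
        with np.errstate(invalid="ignore", divide="ignore"):
            baf = n_alt / np.maximum(n_depth, 1)
        bad = (baf < 0.2) | (baf > 0.8)
        n_alt = np.where(bad, n_depth // 2, n_alt)
        t_depth = rng.poisson(config.mean_coverage_tumour * ratio)
        # allelic imbalance where one copy is lost
        p_alt = np.where(ratio < 0.8, 0.15, 0.5)
        t_alt = rng.binomial(np.maximum(t_depth, 1), p_alt)
        t_alt = np.where(t_depth == 0, 0, t_alt)
        rows.append(pd.DataFrame({
            "sample_id": sid, "chrom": chroms, "pos": pos,
            "normal_ref_depth": n_depth - n_alt, "normal_alt_depth": n_alt,
            "tumour_ref_depth": t_depth - t_alt, "tumour_alt_depth": t_alt,
        }))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "chrom", "pos",
                                     "normal_ref_depth", "normal_alt_depth",
                                     "tumour_ref_depth", "tumour_alt_depth"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# the paper fixture


def _fixture_samples() -> list[SampleRecord]:
    rng = np.random.default_rng(FIXTURE_SEED)
    hist = (["seminoma"] * 16 + ["nonseminoma"] * 18 + ["mixed"] * 4
            + ["indeterminate"] * 4)
    ages = np.round(np.clip(rng.normal(36, 9, size=42), 18, 62), 1)
    out = []
    for i in range(42):
        response = "refractory" if i == 20 else (
            "unknown" if i >= 38 else "sensitive")
        out.append(SampleRecord(f"T{i + 1:02d}", hist[i], float(ages[i]),
                                response))
    return out


# large-scale event assignment (sample indices); the union of all lists is
# exactly 35 samples, matching the printed count of tumours with any
# large-scale CNV
_FIX_12P_ISO = list(range(25))           # 12p gain, q neutral
_FIX_12_WHOLE = list(range(25, 30))      # whole-chromosome 12 gain
_FIX_X_GAIN = list(range(0, 31, 2))      # 16 samples
_FIX_7_GAIN = list(range(1, 30, 2))      # 15 samples
_FIX_21_GAIN = [0, 3, 6, 9, 12, 15, 18, 21, 24, 27, 30, 34]
_FIX_22_GAIN = [1, 4, 7, 10, 13, 16, 19, 22, 25, 28, 33]
_FIX_Y_LOSS = [2, 5, 8, 11, 14, 17, 20, 23, 31, 32]

_FIX_FSIP2_AMP_A = [21, 9, 10, 22, 36, 38]   # 8.5 kb, exons 16-17 analogue
_FIX_FSIP2_AMP_B = [21]                      # second event in the same tumour
_FIX_FSIP2_DEL = [11, 23]
_FIX_XQ28_AMP = [12, 24, 25, 37, 39, 0]
_FIX_ARTIFACT_GAIN = [13, 26]
_FIX_ARTIFACT_LOSS = [14, 27]
_FIX_UNSTABLE = [31, 32, 33]

_FIX_KIT_EXON17 = [0, 1, 2, 3, 4]   # seminomas
_FIX_KIT_EXON11 = [16]              # one non-seminoma
_FIX_CDC27 = [5, 6, 17, 18, 34]
_FIX_PRKRIR = [7, 19]               # two mutations each
_FIX_KRAS = [8]
_FIX_XRCC2 = [20]                   # the refractory patient
_FIX_AKAP4 = [21]                   # co-occurs with an FSIP2 amplification

# exact six-class SNV counts over the 1,168 fixture SNVs: 31% / 27% / 23%
# for C>A / C>T / T>C and the remainder split over the other three classes
_FIX_CLASS_COUNTS = {"C>A": 362, "C>G": 74, "C>T": 315,
                     "T>A": 74, "T>C": 269, "T>G": 74}

FSIP2_AMP_A = ("2", 18_668_000, 8_500)
FSIP2_AMP_B = ("2", 18_700_000, 8_500)
FSIP2_DEL = ("2", 18_728_000, 12_000)
XQ28_AMP = ("X", 15_048_000, 400_000)
ARTIFACT_REGION = ("1", 5_052_000, 12_000)


def _fixture_variants(samples: list[SampleRecord], genes: list[GeneModel],
                      genome: Genome, rng: np.random.Generator,
                      ) -> tuple[list[VariantCall], list[dict]]:
    gene_by_name = {g.name: g for g in genes}
    fillers = [g for g in genes if g.name.startswith("SYNG")]
    # per-sample quotas reproducing the printed totals:
    # 795 non-synonymous calls (111 of them indels) + 484 synonymous SNVs
    nonsyn_quota = [19] * 39 + [18] * 3
    indel_quota = [3] * 27 + [2] * 15
    syn_quota = [12] * 22 + [11] * 20
    assert sum(nonsyn_quota) == 795 and sum(indel_quota) == 111
    assert sum(syn_quota) == 484

    drivers: dict[int, list[tuple[str, str, tuple[float, float], str]]] = {}

    def add(idxs, gene, vaf_range, detail, per_sample=1):
        for i in idxs:
            for _ in range(per_sample):
                drivers.setdefault(i, []).append(
                    (gene, "missense", vaf_range, detail))

    add(_FIX_KIT_EXON17, "KIT", (0.25, 0.45), "exon17")
    add(_FIX_KIT_EXON11, "KIT", (0.25, 0.45), "exon11")
    add(_FIX_CDC27, "CDC27", (0.08, 0.14), "subclonal")
    add(_FIX_PRKRIR, "PRKRIR", (0.2, 0.4), "", per_sample=2)
    add(_FIX_KRAS, "KRAS", (0.25, 0.45), "")
    add(_FIX_XRCC2, "XRCC2", (0.2, 0.4), "refractory")
    add(_FIX_AKAP4, "AKAP4", (0.2, 0.4), "")

    class_pool = [c for c, n in _FIX_CLASS_COUNTS.items() for _ in range(n)]
    assert len(class_pool) == 1168
    rng.shuffle(class_pool)
    pool_iter = iter(class_pool)

    kit = gene_by_name["KIT"]
    kit_exon_pos = {"exon17": 1_260_500, "exon11": 1_220_500}

    variants: list[VariantCall] = []
    truth_rows: list[dict] = []
    for i, sample in enumerate(samples):
        sid = sample.sample_id
        d = drivers.get(i, [])
        for gene_name, cons, vaf_range, detail in d:
            gene = gene_by_name[gene_name]
            pos = None
            if gene_name == "KIT":
                pos = kit_exon_pos[detail] + int(rng.integers(0, 120))
            v = _make_snv(sid, gene, next(pool_iter), cons,
                          rng.uniform(*vaf_range), rng,
                          f"driver:{gene_name}", genome, pos=pos)
            variants.append(v)
            truth_rows.append({"sample_id": sid, "kind": "driver_variant",
                               "name": gene_name, "chrom": v.chrom,
                               "start": v.pos, "end": v.pos, "direction": "",
                               "ratio": np.nan, "detail": detail})
        n_background = nonsyn_quota[i] - indel_quota[i] - len(d)
        assert n_background >= 0
        for _ in range(n_background):
            gene = fillers[int(rng.integers(len(fillers)))]
            cons = str(rng.choice(["missense", "nonsense", "splice", "other"],
                                  p=[0.8, 0.08, 0.06, 0.06]))
            variants.append(_make_snv(sid, gene, next(pool_iter), cons,
                                      rng.uniform(0.2, 0.45), rng,
                                      "background", genome))
        for _ in range(indel_quota[i]):
            gene = fillers[int(rng.integers(len(fillers)))]
            variants.append(_make_indel(sid, gene, rng.uniform(0.2, 0.45),
                                        rng, "background"))
        for _ in range(syn_quota[i]):
            gene = fillers[int(rng.integers(len(fillers)))]
            variants.append(_make_snv(sid, gene, next(pool_iter),
                                      "synonymous", rng.uniform(0.2, 0.45),
                                      rng, "background", genome))
        # one oxidation artifact per tumour, violating >= 1 filter criterion
        gene = fillers[int(rng.integers(len(fillers)))]
        variants.append(_make_artifact(sid, i, gene, rng, genome))
    # 33 common germline SNPs across the cohort
    for j in range(33):
        sid = samples[j % 42].sample_id
        gene = fillers[int(rng.integers(len(fillers)))]
        variants.append(_make_common_snp(sid, gene, rng, genome))
    assert next(pool_iter, None) is None  # the class pool is exactly consumed
    return variants, truth_rows


def paper_fixture() -> CohortBundle:
    """Deterministic 42-tumour bundle transcribing the study's printed
    cohort summaries into simulated inputs (see module docstring)."""
    genome = default_genome()
    rng = np.random.default_rng(FIXTURE_SEED)
    samples = _fixture_samples()
    genes = default_gene_models(genome)
    variants, truth_rows = _fixture_variants(samples, genes, genome, rng)

    grid = genome.bin_grid()
    sample_ids = [s.sample_id for s in samples]
    multipliers = {sid: np.ones(len(grid)) for sid in sample_ids}

    def spike(idxs, chrom, start, end, ratio, kind, name="", detail=""):
        direction = "gain" if ratio > 1 else "loss"
        for i in idxs:
            sid = sample_ids[i]
            n_bins = _spike_multiplier(grid, multipliers[sid], chrom, start,
                                       end, ratio)
            assert n_bins > 0
            truth_rows.append({"sample_id": sid, "kind": kind, "name": name,
                               "chrom": chrom, "start": start, "end": end,
                               "direction": direction, "ratio": ratio,
                               "detail": detail or f"bins={n_bins}"})

    c12 = genome.chromosome("12")
    spike(_FIX_12P_ISO, "12", 0, c12.centromere, 1.8, "cnv_large", "12p",
          "isochromosome")
    spike(_FIX_12_WHOLE, "12", 0, c12.length, 1.5, "cnv_large", "12",
          "whole-chromosome")
    cx = genome.chromosome("X")
    spike(_FIX_X_GAIN, "X", 0, cx.length, 1.5, "cnv_large", "X")
    c7 = genome.chromosome("7")
    spike(_FIX_7_GAIN, "7", 0, c7.length, 1.5, "cnv_large", "7")
    c21 = genome.chromosome("21")
    spike(_FIX_21_GAIN, "21", c21.centromere, c21.length, 1.5, "cnv_large",
          "21q", "acrocentric")
    c22 = genome.chromosome("22")
    spike(_FIX_22_GAIN, "22", c22.centromere, c22.length, 1.5, "cnv_large",
          "22q", "acrocentric")
    cy = genome.chromosome("Y")
    spike(_FIX_Y_LOSS, "Y", 0, cy.length, 0.5, "cnv_large", "Y")

    for idxs, (chrom, start, ln), ratio, name in (
        (_FIX_FSIP2_AMP_A, FSIP2_AMP_A, 3.0, "FSIP2"),
        (_FIX_FSIP2_AMP_B, FSIP2_AMP_B, 3.0, "FSIP2"),
        (_FIX_FSIP2_DEL, FSIP2_DEL, 0.4, "FSIP2"),
        (_FIX_XQ28_AMP, XQ28_AMP, 2.5, "Xq28"),
        (_FIX_ARTIFACT_GAIN, ARTIFACT_REGION, 3.0, "artifact-region"),
        (_FIX_ARTIFACT_LOSS, ARTIFACT_REGION, 0.4, "artifact-region"),
    ):
        spike(idxs, chrom, start, start + ln, ratio, "cnv_focal", name)

    for k, i in enumerate(_FIX_UNSTABLE):
        sid = sample_ids[i]
        arm = ("1q", "2p", "6q")[k]
        for start, length, ratio in _chromothripsis_spikes(genome, arm, 26):
            _spike_multiplier(grid, multipliers[sid], arm[:-1], start,
                              start + length, ratio)
            truth_rows.append({"sample_id": sid, "kind": "cnv_focal",
                               "name": "chromothripsis", "chrom": arm[:-1],
                               "start": start, "end": start + length,
                               "direction": "gain" if ratio > 1 else "loss",
                               "ratio": ratio, "detail": f"arm={arm}"})
        truth_rows.append({"sample_id": sid, "kind": "chromothripsis_arm",
                           "name": arm, "chrom": arm[:-1], "start": 0,
                           "end": 0, "direction": "", "ratio": np.nan,
                           "detail": "events=26"})
        truth_rows.append({"sample_id": sid, "kind": "unstable_sample",
                           "name": sid, "chrom": "", "start": 0, "end": 0,
                           "direction": "", "ratio": np.nan, "detail": ""})

    coverage = {
        sid: _simulate_coverage(genome, grid, multipliers[sid], rng,
                                73.6, 69.0, None)
        for sid in sample_ids
    }
    config = CohortConfig(seed=FIXTURE_SEED, het_sites_per_sample=300)
    het_sites = _simulate_het_sites(genome, grid, multipliers, sample_ids,
                                    rng, config)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "kind", "name", "chrom", "start", "end",
                 "direction", "ratio", "detail"],
    )
    return CohortBundle(samples=samples, variants=variants, coverage=coverage,
                        het_sites=het_sites, gene_models=genes, genome=genome,
                        truth_events=truth)
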