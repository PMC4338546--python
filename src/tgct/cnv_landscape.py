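"""Cohort-level CNV landscape analysis.

Post-processes per-sample CNV segments into the study-level results:
focal/large-scale classification (3 Mb boundary), arm- and chromosome-level
aneuploidy summaries with isochromosome-12p detection, per-genome CNV
fraction, chromothripsis flagging (>20 CNVs on a single arm), focal-event
to gene mapping with coverage-artifact removal, recurrence ranking,
binomial recurrence significance and Fisher meta-analysis against external
cohorts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .drivers import MetaResult, binomial_recurrence_test, fisher_combine
from .genome import ArmDefinition
from .models import CnvSegment, GeneCnvEvent, GeneModel, RecurrenceRow, SampleRecord

__all__ = [
    "LandscapeConfig",
    "ArmChromSummary",
    "classify_scale",
    "arm_and_chromosome_summary",
    "genome_cnv_fraction",
    "chromothripsis_flag",
    "map_focal_to_genes",
    "artifact_region_filter",
    "exclude_unstable_samples",
    "per_sample_focal_counts",
    "rank_recurrent_genes",
    "empirical_focal_background",
    "focal_recurrence_significance",
    "meta_with_external",
]


@dataclass(frozen=True)
class LandscapeConfig:
    focal_max_bp: int = 3_000_000          # >= boundary is large-scale
    chromothripsis_min_cnvs: int = 20      # strict >
    arm_event_min_coverage: float = 0.9    # fraction of arm length
    recurrence_min_total: int = 5
    unstable_exclusion_sd: float = 2.0
    artifact_min_samples: int = 3

    def __post_init__(self):
        for name in ("focal_max_bp", "chromothripsis_min_cnvs",
                     "arm_event_min_coverage", "recurrence_min_total",
                     "unstable_exclusion_sd", "artifact_min_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def classify_scale(segments: list[CnvSegment],
                   config: LandscapeConfig | None = None) -> list[CnvSegment]:
    """Assign ``scale`` in place: large when length >= ``focal_max_bp``,
    focal below; neutral segments get no scale.  Returns the input list."""
    config = config or LandscapeConfig()
    for seg in segments:
        if seg.call == "neutral":
            seg.scale = None
        else:
            seg.scale = "large" if seg.length >= config.focal_max_bp else "focal"
    return segments


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


@dataclass
class ArmChromSummary:
    """Per-sample arm and chromosome event calls.

    ``arm_calls[sample]["12p"] -> "gain" | "loss"`` (absent when neutral);
    ``chrom_calls`` likewise keyed by chromosome; ``isochromosome_12p`` is
    the set of samples whose 12p arm is gained without a 12q gain.
    """

    arm_calls: dict[str, dict[str, str]] = field(default_factory=dict)
    chrom_calls: dict[str, dict[str, str]] = field(default_factory=dict)
    isochromosome_12p: set[str] = field(default_factory=set)

    def samples_with_arm(self, arm: str, direction: str) -> list[str]:
        return sorted(s for s, calls in self.arm_calls.items()
                      if calls.get(arm) == direction)

    def samples_with_chrom(self, chrom: str, direction: str) -> list[str]:
        return sorted(s for s, calls in self.chrom_calls.items()
                      if calls.get(chrom) == direction)


def arm_and_chromosome_summary(segments: list[CnvSegment],
                               arms: list[ArmDefinition],
                               config: LandscapeConfig | None = None,
                               ) -> ArmChromSummary:
    """Arm- and chromosome-level aneuploidy calls.

    An arm is called gained (lost) when gain (loss) segments cover at least
    ``arm_event_min_coverage`` of its length.  A chromosome is called when
    both arms agree; for acrocentric chromosomes the q arm alone decides.
    Isochromosome 12p is flagged as a gained 12p without a gained 12q.
    """
    config = config or LandscapeConfig()
    arm_by_chrom: dict[str, list[ArmDefinition]] = defaultdict(list)
    for a in arms:
        arm_by_chrom[a.chrom].append(a)
    for seg in segments:
        if seg.chrom not in arm_by_chrom:
            raise ValueError(
                f"segment on chromosome {seg.chrom!r} absent from the arm table")
    by_sample: dict[str, list[CnvSegment]] = defaultdict(list)
    for seg in segments:
        if seg.call != "neutral":
            by_sample[seg.sample_id].append(seg)
    summary = ArmChromSummary()
    for sample, segs in by_sample.items():
        arm_calls: dict[str, str] = {}
        for arm in (a for chrom_arms in arm_by_chrom.values() for a in chrom_arms):
            for direction in ("gain", "loss"):
                cov = sum(
                    _overlap(s.start, s.end, arm.start, arm.end)
                    for s in segs
                    if s.chrom == arm.chrom and s.call == direction
                )
                if cov >= config.arm_event_min_coverage * arm.length:
                    arm_calls[arm.name] = direction
                    break
        chrom_calls: dict[str, str] = {}
        for chrom, chrom_arms in arm_by_chrom.items():
            p = next((a for a in chrom_arms if a.arm == "p"), None)
            q = next((a for a in chrom_arms if a.arm == "q"), None)
            q_call = arm_calls.get(q.name) if q else None
            if q_call is None:
                continue
            acro = q.acrocentric if q else False
            if acro or (p and arm_calls.get(p.name) == q_call):
                chrom_calls[chrom] = q_call
        if arm_calls:
            summary.arm_calls[sample] = arm_calls
        if chrom_calls:
            summary.chrom_calls[sample] = chrom_calls
        if arm_calls.get("12p") == "gain" and arm_calls.get("12q") != "gain":
            summary.isochromosome_12p.add(sample)
    return summary


def genome_cnv_fraction(segments: list[CnvSegment], genome_size_bp: int) -> float:
    """Percent of the genome covered by non-neutral segments (union length,
    overlapping segments counted once).  Intended per sample."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for seg in segments:
        if seg.call != "neutral":
            by_chrom[seg.chrom].append((seg.start, seg.end))
    union = 0
    for intervals in by_chrom.values():
        intervals.sort()
        cur_s, cur_e = None, None
        for s, e in intervals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    union += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            union += cur_e - cur_s
    return 100.0 * union / genome_size_bp


def chromothripsis_flag(segments: list[CnvSegment], arms: list[ArmDefinition],
                        config: LandscapeConfig | None = None,
                        ) -> dict[str, list[str]]:
    """Arms with more than ``chromothripsis_min_cnvs`` non-neutral segments
    fully contained in them, per sample.  Segments spanning the centromere
    count toward neither arm.  Samples with no flagged arm are absent."""
    config = config or LandscapeConfig()
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for seg in segments:
        if seg.call == "neutral":
            continue
        for arm in arms:
            if seg.chrom == arm.chrom and seg.start >= arm.start and \
                    seg.end <= arm.end:
                counts[(seg.sample_id, arm.name)] += 1
                break
    flags: dict[str, list[str]] = defaultdict(list)
    for (sample, arm_name), n in sorted(counts.items()):
        if n > config.chromothripsis_min_cnvs:
            flags[sample].append(arm_name)
    return dict(flags)


def map_focal_to_genes(focal_segments: list[CnvSegment],
                       gene_models: list[GeneModel]) -> list[GeneCnvEvent]:
    """One event per (gene, overlapping focal non-neutral segment); the
    overlap test is half-open intersection >= 1 bp against the gene's
    coding span."""
    events: list[GeneCnvEvent] = []
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in gene_models:
        by_chrom[g.chrom].append(g)
    for seg in focal_segments:
        if seg.call == "neutral" or seg.scale != "focal":
            continue
        for gene in by_chrom.get(seg.chrom, ()):
            ov = _overlap(seg.start, seg.end, gene.start, gene.end)
            if ov >= 1:
                events.append(
                    GeneCnvEvent(
                        gene=gene.name,
                        sample_id=seg.sample_id,
                        direction=seg.call,
                        segment=seg,
                        interval=(max(seg.start, gene.start),
                                  min(seg.end, gene.end)),
                    )
                )
    return events


def artifact_region_filter(events: list[GeneCnvEvent],
                           config: LandscapeConfig | None = None,
                           ) -> tuple[list[GeneCnvEvent], list[dict]]:
    """Drop events in coverage-artifact-prone regions.

    Events are grouped by their segment's exact interval across samples; a
    group is removed when it occurs in >= ``artifact_min_samples`` samples
    AND contains both gains and losses (the signature of a probe set whose
    coverage is unstable rather than truly altered).  Returns (retained
    events, removed-region report)."""
    config = config or LandscapeConfig()
    groups: dict[tuple[str, int, int], list[GeneCnvEvent]] = defaultdict(list)
    for ev in events:
        groups[ev.segment.interval].append(ev)
    removed_keys = set()
    report = []
    for key, evs in groups.items():
        n_samples = len({e.sample_id for e in evs})
        directions = {e.direction for e in evs}
        if n_samples >= config.artifact_min_samples and directions == {"gain", "loss"}:
            removed_keys.add(key)
            report.append(
                {"chrom": key[0], "start": key[1], "end": key[2],
                 "n_samples": n_samples, "n_events": len(evs)}
            )
    retained = [e for e in events if e.segment.interval not in removed_keys]
    return retained, report


def per_sample_focal_counts(segments: list[CnvSegment],
                            samples: list[SampleRecord]) -> dict[str, int]:
    counts = {s.sample_id: 0 for s in samples}
    for seg in segments:
        if seg.call != "neutral" and seg.scale == "focal":
            counts[seg.sample_id] = counts.get(seg.sample_id, 0) + 1
    return counts


def exclude_unstable_samples(samples: list[SampleRecord],
                             focal_counts: dict[str, int],
                             config: LandscapeConfig | None = None,
                             ) -> tuple[list[SampleRecord], list[str]]:
    """Single-pass outlier rule for chromosomally unstable tumours.

    Samples whose focal-CNV count exceeds mean + ``unstable_exclusion_sd``
    standard deviations of the cohort (computed once) are excluded from
    recurrence analysis.  Returns (retained samples, excluded sample ids).
    Cohorts of fewer than 3 samples are never filtered."""
    config = config or LandscapeConfig()
    if len(samples) < 3:
        return list(samples), []
    values = np.array([focal_counts.get(s.sample_id, 0) for s in samples],
                      dtype=float)
    cutoff = values.mean() + config.unstable_exclusion_sd * values.std(ddof=1)
    excluded = [s.sample_id for s, v in zip(samples, values) if v > cutoff]
    retained = [s for s in samples if s.sample_id not in set(excluded)]
    return retained, excluded


def rank_recurrent_genes(events: list[GeneCnvEvent],
                         samples_retained: list[SampleRecord],
                         config: LandscapeConfig | None = None,
                         ) -> list[RecurrenceRow]:
    """Gene-level focal-CNV recurrence table.

    Counts are events, not samples (a tumour with two separate gains in a
    gene contributes two).  Genes whose event sets have identical
    footprints (same sample/interval/direction multiset) are collapsed into
    a single row.  Rows with total >= ``recurrence_min_total`` are kept,
    sorted by total descending then region."""
    config = config or LandscapeConfig()
    retained_ids = {s.sample_id for s in samples_retained}
    per_gene: dict[str, list[GeneCnvEvent]] = defaultdict(list)
    for ev in events:
        if ev.sample_id in retained_ids:
            per_gene[ev.gene].append(ev)
    footprints: dict[frozenset, list[str]] = defaultdict(list)
    for gene, evs in per_gene.items():
        fp = frozenset(
            (e.sample_id, e.segment.interval, e.direction, i)
            for i, e in enumerate(sorted(
                evs, key=lambda e: (e.sample_id, e.segment.interval, e.direction)))
        )
        footprints[fp].append(gene)
    rows = []
    for fp, genes in footprints.items():
        evs = per_gene[genes[0]]
        losses = sum(1 for e in evs if e.direction == "loss")
        gains = sum(1 for e in evs if e.direction == "gain")
        if losses + gains < config.recurrence_min_total:
            continue
        chrom = evs[0].segment.chrom
        start = min(e.segment.start for e in evs)
        end = max(e.segment.end for e in evs)
        rows.append(
            RecurrenceRow(
                genes=tuple(sorted(genes)),
                region=f"{chrom}:{start}-{end}",
                losses=losses,
                gains=gains,
                samples=tuple(sorted({e.sample_id for e in evs})),
            )
        )
    rows.sort(key=lambda r: (-r.total, r.region))
    return rows


def empirical_focal_background(events: list[GeneCnvEvent],
                               samples_retained: list[SampleRecord],
                               gene: GeneModel, genome_size_bp: int) -> float:
    """Per-sample chance probability of a focal event overlapping ``gene``.

    Estimated from the cohort itself: mean focal events per retained sample
    times the probability that a random placement of an event of the
    cohort's mean length overlaps the gene's span, capped at 1."""
    n = len(samples_retained)
    if n == 0 or not events:
        return 0.0
    retained_ids = {s.sample_id for s in samples_retained}
    segs = {(e.sample_id, e.segment.interval) for e in events
            if e.sample_id in retained_ids}
    if not segs:
        return 0.0
    mean_len = float(np.mean([iv[2] - iv[1] for _, iv in segs]))
    events_per_sample = len(segs) / n
    p_hit = min(1.0, (mean_len + gene.length) / genome_size_bp)
    return min(1.0, events_per_sample * p_hit)


def focal_recurrence_significance(row: RecurrenceRow, n_samples: int,
                                  p_bg_focal: float) -> float:
    """Exact upper-tail binomial p-value on distinct affected samples."""
    if row.n_samples > n_samples:
        raise ValueError("affected samples exceed cohort size")
    return binomial_recurrence_test(row.n_samples, n_samples, p_bg_focal)


def meta_with_external(p_internal: float, p_external: float) -> MetaResult:
    """Fisher meta-analysis of this cohort's p-value with an external one."""
    return fisher_combine([p_internal, p_external])
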