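"""Core record types shared across the pipeline.

Per-exon coverage and germline heterozygous sites are carried as pandas
DataFrames (schemas below) because they number in the tens of thousands per
sample; individually meaningful records (variants, samples, genes, CNV
segments) are dataclasses.

Coverage frame schema (BED convention, 0-based half-open)::

    chrom  start  end  tumour_depth  normal_depth

Het-site frame schema (1-based positions)::

    sample_id  chrom  pos  normal_ref_depth  normal_alt_depth
    tumour_ref_depth  tumour_alt_depth
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

HISTOLOGIES = ("seminoma", "nonseminoma", "mixed", "indeterminate")
TREATMENT_RESPONSES = ("sensitive", "refractory", "unknown")

CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "inframe",
    "other",
)

#: consequence classes counted as non-synonymous by default
NON_SYNONYMOUS = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe", "other"}
)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    histology: str
    age_years: float
    treatment_response: str = "unknown"

    def __post_init__(self):
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.treatment_response not in TREATMENT_RESPONSES:
            raise ValueError(f"unknown treatment response {self.treatment_response!r}")
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding span, BED convention."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantCall:
    """One somatic call with the quality fields the oxidation filter consumes.

    ``pos`` is 1-based (VCF convention).  ``alt_reads_fwd``/``alt_reads_rev``
    are strand-split supporting read counts; ``mean_base_quality`` is a Phred
    score; ``alignability`` is the reference uniqueness score in [0, 1];
    ``population_maf`` is the population minor allele frequency, or None when
    the site is absent from every population panel.  ``truth`` is the hidden
    simulation label (None on real data).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str  # "SNV" | "indel"
    gene: str | None = None
    consequence: str = "missense"
    vaf: float = 0.0
    alt_reads_fwd: int | None = None
    alt_reads_rev: int | None = None
    mean_base_quality: float | None = None
    mean_mapq: float | None = None
    alignability: float | None = None
    population_maf: float | None = None
    truth: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.variant_type not in ("SNV", "indel"):
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if (self.variant_type == "SNV") != is_snv:
            raise ValueError(
                f"{self.sample_id} {self.chrom}:{self.pos} {self.ref}>{self.alt}: "
                "variant_type SNV requires single-base ref and alt (and vice versa)"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.sample_id} {self.chrom}:{self.pos} {self.ref}>{self.alt}"


@dataclass
class CnvSegment:
    """A segmented copy-number call (BED convention coordinates).

    ``mean_ratio`` is the linear tumour/normal depth ratio (2**mean log2
    ratio over the segment's bins).  ``specificity`` is the confidence that
    the segment mean is not a fluctuation of the sample's genome-wide null
    (1 - two-sided normal tail); non-neutral calls below the required
    specificity are downgraded to neutral with ``low_specificity`` set.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_ratio: float
    call: str = "neutral"  # "gain" | "loss" | "neutral"
    specificity: float | None = None
    scale: str | None = None  # "focal" | "large" | None
    low_specificity: bool = False
    loh: bool | None = None

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("segment must contain at least one bin")
        if self.call not in ("gain", "loss", "neutral"):
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneCnvEvent:
    """A focal CNV segment overlapping one gene's coding span."""

    gene: str
    sample_id: str
    direction: str  # "gain" | "loss"
    segment: CnvSegment
    interval: tuple[int, int]  # overlapping span within the gene


@dataclass(frozen=True)
class RecurrenceRow:
    """Gene-level focal-CNV recurrence record (one output table row).

    ``genes`` lists every gene sharing an identical event footprint;
    ``samples`` is the set of distinct affected samples.
    """

    genes: tuple[str, ...]
    region: str
    losses: int
    gains: int
    samples: tuple[str, ...]

    @property
    def total(self) -> int:
        return self.losses + self.gains

    @property
    def n_samples(self) -> int:
        return len(self.samples)
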