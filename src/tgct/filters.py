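"""Variant-level quality filters.

Two filters are applied to the raw somatic call set before any statistics:

* an oxidation-artifact (OxoG/"FoxoG") filter that requires SNVs to be
  supported on both strands with adequate base quality, mapping quality and
  reference alignability — 8-oxoguanine damage during library preparation
  produces strand-biased, low-quality C>A/G>T calls, and these four
  predicates remove them;
* a common-germline-SNP filter that removes calls present in population
  panels at a minor allele frequency above 25%, since such sites are almost
  always mis-subtracted germline polymorphism rather than somatic mutation.

Boundary semantics are deliberate: base quality is a strict ``> 26``,
mapping quality an inclusive ``>= 50``, alignability an exact ``1.0``
(within 1e-9), strand support ``>= 1`` per strand, and the MAF cut a strict
``> 0.25``.  Indels bypass the oxidation filter (the artifact mechanism is
SNV-specific) but remain subject to the MAF filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import VariantCall

__all__ = ["FilterConfig", "FilterReport", "foxog_filter", "germline_maf_filter",
           "apply_filters"]

_ALIGNABILITY_TOL = 1e-9


@dataclass(frozen=True)
class FilterConfig:
    min_alt_per_strand: int = 1
    min_mean_bq: float = 26.0        # strict >
    min_mean_mapq: float = 50.0      # inclusive >=
    required_alignability: float = 1.0  # exact equality (1e-9)
    max_population_maf: float = 0.25    # removal on strict >

    def __post_init__(self):
        for name in ("min_mean_bq", "min_mean_mapq", "required_alignability",
                     "max_population_maf"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")


@dataclass
class FilterReport:
    """Outcome of one filtering pass: ``passed`` and ``failed`` partition
    the input; every failed record carries at least one reason."""

    passed: list[VariantCall] = field(default_factory=list)
    failed: list[tuple[VariantCall, list[str]]] = field(default_factory=list)
    n_common_snps_removed: int = 0

    @property
    def n_input(self) -> int:
        return len(self.passed) + len(self.failed)


def _foxog_reasons(v: VariantCall, config: FilterConfig) -> list[str]:
    required = {
        "alt_reads_fwd": v.alt_reads_fwd,
        "alt_reads_rev": v.alt_reads_rev,
        "mean_base_quality": v.mean_base_quality,
        "mean_mapq": v.mean_mapq,
        "alignability": v.alignability,
    }
    missing = [k for k, val in required.items() if val is None]
    if missing:
        raise ValueError(
            f"SNV {v.label} is missing quality field(s) {missing}; "
            "the oxidation filter requires all five"
        )
    reasons = []
    if v.alt_reads_fwd < config.min_alt_per_strand or \
            v.alt_reads_rev < config.min_alt_per_strand:
        reasons.append("strand-support")
    if not v.mean_base_quality > config.min_mean_bq:
        reasons.append("base-quality")
    if not v.mean_mapq >= config.min_mean_mapq:
        reasons.append("mapping-quality")
    if abs(v.alignability - config.required_alignability) > _ALIGNABILITY_TOL:
        reasons.append("alignability")
    return reasons


def foxog_filter(variants: list[VariantCall],
                 config: FilterConfig | None = None) -> FilterReport:
    """Oxidation-artifact filter.

    An SNV passes iff it has >= ``min_alt_per_strand`` supporting reads on
    each strand, mean base quality strictly above ``min_mean_bq``, mean
    mapping quality >= ``min_mean_mapq`` and alignability exactly
    ``required_alignability``.  Failure reasons enumerate every violated
    criterion.  Indels pass through unfiltered.
    """
    config = config or FilterConfig()
    report = FilterReport()
    for v in variants:
        if v.variant_type != "SNV":
            report.passed.append(v)
            continue
        reasons = _foxog_reasons(v, config)
        if reasons:
            report.failed.append((v, reasons))
        else:
            report.passed.append(v)
    return report


def germline_maf_filter(variants: list[VariantCall],
                        config: FilterConfig | None = None) -> FilterReport:
    """Remove calls recorded in population panels at MAF > ``max_population_maf``.

    A variant with ``population_maf`` None (absent from every panel) is
    retained.  ``n_common_snps_removed`` counts removals across all samples.
    """
    config = config or FilterConfig()
    report = FilterReport()
    for v in variants:
        maf = v.population_maf
        if maf is not None and not 0.0 <= maf <= 1.0:
            raise ValueError(f"{v.label}: population_maf {maf} outside [0, 1]")
        if maf is not None and maf > config.max_population_maf:
            report.failed.append((v, ["common-germline-snp"]))
            report.n_common_snps_removed += 1
        else:
            report.passed.append(v)
    return report


def apply_filters(variants: list[VariantCall],
                  config: FilterConfig | None = None) -> FilterReport:
    """Full filtering pass: oxidation filter first, then the MAF filter.

    The two predicates commute; the order is fixed only so that reason lists
    are reproducible.
    """
    config = config or FilterConfig()
    fox = foxog_filter(variants, config)
    maf = germline_maf_filter(fox.passed, config)
    return FilterReport(
        passed=maf.passed,
        failed=fox.failed + maf.failed,
        n_common_snps_removed=maf.n_common_snps_removed,
    )
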