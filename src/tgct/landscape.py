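"""Mutational-landscape summaries.

Per-sample and cohort mutation rates (mutations per Mb of sequenced
target), the strand-collapsed six-class SNV spectrum, gene-level recurrence
tallies, and the age-versus-rate association.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import NON_SYNONYMOUS, SampleRecord, VariantCall

__all__ = [
    "SPECTRUM_CLASSES",
    "RateSummary",
    "SpectrumSummary",
    "GeneRecurrence",
    "AgeRateAssociation",
    "mutation_rate",
    "snv_spectrum",
    "gene_recurrence",
    "age_rate_association",
    "collapse_snv_class",
    "round_percent",
]

#: the six pyrimidine-reference substitution classes
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def round_percent(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (percentages are reported to 1 d.p.)."""
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def collapse_snv_class(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-reference class.

    Purine-reference changes are replaced by their reverse complement
    (G>A -> C>T, A>G -> T>C, ...), collapsing the 12 possible substitutions
    onto 6 strand-symmetric classes.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref}>{alt})")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class RateSummary:
    per_sample_rate: dict[str, float]
    cohort_mean: float
    cohort_sd: float | None
    target_mb: float
    per_sample_count: dict[str, int] = field(default_factory=dict)


def mutation_rate(variants: list[VariantCall], samples: list[SampleRecord],
                  target_mb: float = 37.0,
                  classes: frozenset[str] | set[str] = NON_SYNONYMOUS,
                  ) -> RateSummary:
    """Per-sample and cohort mutation rates over the given consequence classes.

    Every sample contributes (zero-variant samples at rate 0); the cohort
    mean is the arithmetic mean of per-sample rates and the s.d. uses the
    n-1 denominator (None for a single sample).
    """
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    if not classes:
        raise ValueError("classes must be a nonempty consequence set")
    counts = {s.sample_id: 0 for s in samples}
    for v in variants:
        if v.sample_id not in counts:
            raise ValueError(f"variant {v.label} references unknown sample")
        if v.consequence in classes:
            counts[v.sample_id] += 1
    rates = {sid: c / target_mb for sid, c in counts.items()}
    values = np.array(list(rates.values()), dtype=float)
    mean = float(values.mean()) if len(values) else 0.0
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return RateSummary(rates, mean, sd, target_mb, per_sample_count=counts)


@dataclass
class SpectrumSummary:
    """Proportions over the six strand-collapsed classes; all None when
    ``n_snvs`` is zero."""

    proportions: dict[str, float | None]
    n_snvs: int
    counts: dict[str, int] = field(default_factory=dict)


def snv_spectrum(variants: list[VariantCall]) -> SpectrumSummary:
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    n = 0
    for v in variants:
        if v.variant_type != "SNV":
            continue
        counts[collapse_snv_class(v.ref, v.alt)] += 1
        n += 1
    if n == 0:
        return SpectrumSummary({c: None for c in SPECTRUM_CLASSES}, 0, counts)
    return SpectrumSummary({c: counts[c] / n for c in SPECTRUM_CLASSES}, n, counts)


@dataclass
class GeneRecurrence:
    gene: str
    mutated_samples: int
    mutation_count: int
    percent_samples: float
    percent_by_histology: dict[str, float]


def gene_recurrence(variants: list[VariantCall], samples: list[SampleRecord],
                    classes: frozenset[str] | set[str] = NON_SYNONYMOUS,
                    ) -> list[GeneRecurrence]:
    """Per-gene recurrence: distinct mutated samples, total qualifying
    mutations, percent of cohort and per-histology percentages.

    Sorted by mutated samples descending, ties broken by gene name.
    """
    histology = {s.sample_id: s.histology for s in samples}
    strata: dict[str, int] = {}
    for s in samples:
        strata[s.histology] = strata.get(s.histology, 0) + 1
    per_gene: dict[str, dict] = {}
    for v in variants:
        if v.gene is None or v.consequence not in classes:
            continue
        if v.sample_id not in histology:
            raise ValueError(f"variant {v.label} references unknown sample")
        g = per_gene.setdefault(v.gene, {"samples": set(), "count": 0})
        g["samples"].add(v.sample_id)
        g["count"] += 1
    n = len(samples)
    out = []
    for gene, g in per_gene.items():
        by_hist = {}
        for hist, denom in strata.items():
            k = sum(1 for sid in g["samples"] if histology[sid] == hist)
            by_hist[hist] = round_percent(100.0 * k / denom) if denom else 0.0
        out.append(
            GeneRecurrence(
                gene=gene,
                mutated_samples=len(g["samples"]),
                mutation_count=g["count"],
                percent_samples=round_percent(100.0 * len(g["samples"]) / n),
                percent_by_histology=by_hist,
            )
        )
    out.sort(key=lambda r: (-r.mutated_samples, r.gene))
    return out


@dataclass
class AgeRateAssociation:
    r: float | None
    n: int
    age_cutoff: float
    mean_rate_older: float | None
    mean_rate_younger: float | None
    t_statistic: float | None
    p_value: float | None


def age_rate_association(samples: list[SampleRecord], rates: RateSummary,
                         age_cutoff: float = 40.0) -> AgeRateAssociation:
    """Pearson correlation of per-sample mutation rate with age, plus a
    two-sided equal-variance t-test of rates between patients above and at
    or below ``age_cutoff`` years."""
    pairs = [(s.age_years, rates.per_sample_rate[s.sample_id]) for s in samples
             if s.sample_id in rates.per_sample_rate]
    if len(pairs) < 3:
        raise ValueError("age-rate association requires >= 3 samples with ages")
    ages = np.array([p[0] for p in pairs])
    vals = np.array([p[1] for p in pairs])
    if np.ptp(ages) == 0 or np.ptp(vals) == 0:
        r = None
    else:
        r = float(stats.pearsonr(ages, vals).statistic)
    older = vals[ages > age_cutoff]
    younger = vals[ages <= age_cutoff]
    if len(older) >= 2 and len(younger) >= 2:
        with warnings.catch_warnings():
            # near-identical rates trip scipy's precision-loss warning;
            # the degenerate all-equal case is guarded above via r=None
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(older, younger, equal_var=True)
        t, p = float(t), float(p)
    else:
        t = p = None
    return AgeRateAssociation(
        r=r,
        n=len(pairs),
        age_cutoff=age_cutoff,
        mean_rate_older=float(older.mean()) if len(older) else None,
        mean_rate_younger=float(younger.mean()) if len(younger) else None,
        t_statistic=t,
        p_value=p,
    )
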