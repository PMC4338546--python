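"""Shared test helpers and independent oracles."""

import functools
import math

import numpy as np
import pandas as pd

from tgct.models import NON_SYNONYMOUS


def binomial_tail_oracle(k, n, p):
    """Upper-tail P(X >= k) by multiplicative pmf recurrence (no scipy,
    no log-sum-exp): the independent route for checking exact tails."""
    if k == 0:
        return 1.0
    log_pmf = (math.lgamma(n + 1) - math.lgamma(k + 1)
               - math.lgamma(n - k + 1)
               + k * math.log(p) + (n - k) * math.log1p(-p))
    pmf = math.exp(log_pmf)
    total = 0.0
    for i in range(k, n + 1):
        total += pmf
        if i < n:
            pmf *= (n - i) / (i + 1) * p / (1 - p)
    return min(1.0, total)


@functools.lru_cache(maxsize=1)
def spike_recovery_counts(n_runs=50):
    """Seeded recovery study: an 8.5 kb ratio-3 amplification at 70x on
    chromosome 21, chromosome 22 left unspiked.  Returns (recovered,
    false_positive) counts over ``n_runs`` simulations."""
    from tgct.cnv import SegmentationParams, segment_sample
    from tgct.genome import default_genome

    genome = default_genome(["21", "22"])
    grid = genome.bin_grid()
    spike_start, spike_len = 2_000_000, 8_500
    in_spike = ((grid["chrom"] == "21")
                & (grid["start"] >= spike_start)
                & (grid["end"] <= spike_start + spike_len)).to_numpy()
    assert in_spike.sum() == 3
    recovered = false_pos = 0
    for seed in range(n_runs):
        r = np.random.default_rng(1000 + seed)
        mult = np.where(in_spike, 3.0, 1.0)
        cov = grid.copy()
        cov["tumour_depth"] = r.poisson(70 * mult)
        cov["normal_depth"] = r.poisson(70, size=len(grid))
        _, segs = segment_sample(cov, SegmentationParams(seed=seed),
                                 sample_id="sim", seed=seed)
        hits = [s for s in segs if s.chrom == "21" and s.call == "gain"
                and s.start < spike_start + spike_len and s.end > spike_start]
        recovered += bool(hits)
        false_pos += any(s.chrom == "22" and s.call == "gain" for s in segs)
    return recovered, false_pos


def variant_key(v):
    return (v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.variant_type,
            v.gene, v.consequence, v.vaf, v.alt_reads_fwd, v.alt_reads_rev,
            v.mean_base_quality, v.mean_mapq, v.alignability,
            v.population_maf, v.truth)


def assert_bundles_equal(a, b):
    assert a.samples == b.samples
    assert sorted(map(variant_key, a.variants)) == \
        sorted(map(variant_key, b.variants))
    assert a.sample_ids == b.sample_ids
    for sid in a.sample_ids:
        pd.testing.assert_frame_equal(
            a.coverage[sid].reset_index(drop=True),
            b.coverage[sid].reset_index(drop=True), check_dtype=False)
    pd.testing.assert_frame_equal(
        a.het_sites.reset_index(drop=True),
        b.het_sites.reset_index(drop=True), check_dtype=False)
    assert sorted((g.name, g.chrom, g.start, g.end) for g in a.gene_models) \
        == sorted((g.name, g.chrom, g.start, g.end) for g in b.gene_models)
    assert a.genome == b.genome
    ta = a.truth_events.fillna("").astype(str).reset_index(drop=True)
    tb = b.truth_events.fillna("").astype(str).reset_index(drop=True)
    pd.testing.assert_frame_equal(ta, tb)


def nonsyn_count(variants, sample_id=None):
    return sum(
        1 for v in variants
        if v.consequence in NON_SYNONYMOUS
        and v.truth not in ("artifact:oxog", "common_snp")
        and (sample_id is None or v.sample_id == sample_id)
    )
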