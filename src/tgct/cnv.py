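"""Depth-ratio CNV calling from matched tumour/normal exon coverage.

The engine follows the classic exome depth-ratio recipe:

1. per-bin log2 tumour/normal coverage ratios after library-size
   normalization (tumour depths scaled by total-normal / total-tumour) with
   a pseudocount for zero-depth robustness;
2. segmentation of each chromosome's bin sequence by a simplified circular
   binary segmentation (CBS): recursively accept the maximal-|t| candidate
   change whenever it beats a permutation null;
3. thresholded gain/loss calls on the linear segment-mean ratio
   (gain > 1.3, loss < 0.7 by default) gated by a specificity confidence
   score measuring how far the segment mean sits from the sample's
   genome-wide null;
4. LOH calling at germline heterozygous sites from tumour B-allele
   frequencies via exact binomial tests.

Candidate family used by the segmentation statistic
---------------------------------------------------
On a segment of ``n`` bins the tested candidates are circular arcs
``[i, j)`` compared against their complement with a pooled two-sample
t-statistic, restricted to

* arcs of length ``min_bins <= (j - i) <= max_arc_bins`` at any interior
  anchor (``i == 0`` or ``i >= min_bins``, ``j <= n - min_bins``), and
* arcs anchored at the left boundary (``i == 0``) of any length
  (equivalently plain binary splits); arcs ending at the right boundary
  are redundant — each is the complement of a prefix split — and excluded,

so every resulting piece is empty or at least ``min_bins`` long.  Short interior arcs catch focal spikes (which a plain
binary split cannot see on a long chromosome); boundary-anchored arcs catch
large-scale level shifts, which recursion then refines.  ``max_arc_bins``
is a sensitivity/runtime trade-off exposed in the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import CnvSegment

__all__ = [
    "SegmentationParams",
    "LohParams",
    "compute_log_ratios",
    "cbs_segment",
    "call_segments",
    "segment_sample",
    "call_loh",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SegmentationParams:
    cbs_alpha: float = 0.01
    n_permutations: int = 1000
    min_bins: int = 3
    seed: int = 0
    gain_threshold: float = 1.3
    loss_threshold: float = 0.7
    specificity_required: float = 0.9999
    max_arc_bins: int = 20
    pseudocount: float = 0.5
    normalization: str = "library"  # "library" | "median"

    def __post_init__(self):
        if not 0 < self.loss_threshold < 1 < self.gain_threshold:
            raise ValueError("require 0 < loss_threshold < 1 < gain_threshold")
        if not 0 < self.cbs_alpha < 1:
            raise ValueError("cbs_alpha must be in (0, 1)")
        if self.min_bins < 1 or self.max_arc_bins < self.min_bins:
            raise ValueError("require 1 <= min_bins <= max_arc_bins")
        if self.normalization not in ("library", "median"):
            raise ValueError("normalization must be 'library' or 'median'")


def compute_log_ratios(coverage: pd.DataFrame,
                       params: SegmentationParams | None = None) -> pd.DataFrame:
    """Per-bin log2 tumour/normal ratios for one sample.

    Returns a copy of ``coverage`` with ``log2_ratio`` and ``usable``
    columns.  Bins with zero normal depth are flagged unusable (NaN ratio)
    and excluded from segmentation.
    """
    params = params or SegmentationParams()
    required = {"chrom", "start", "end", "tumour_depth", "normal_depth"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage frame missing columns {sorted(missing)}")
    tum = coverage["tumour_depth"].to_numpy(dtype=float)
    norm = coverage["normal_depth"].to_numpy(dtype=float)
    usable = norm > 0
    if not usable.any():
        raise ValueError("all normal depths are zero; cannot form ratios")
    if params.normalization == "library":
        scale = norm.sum() / max(tum.sum(), _EPS)
    else:
        ok = usable & (tum > 0)
        scale = float(np.median(norm[ok] / tum[ok]))
    c = params.pseudocount
    out = coverage.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2((tum * scale + c) / (norm + c))
    lr[~usable] = np.nan
    out["log2_ratio"] = lr
    out["usable"] = usable
    return out


# ---------------------------------------------------------------------------
# simplified CBS


def _candidate_stats(S: np.ndarray, Q: np.ndarray, n: int,
                     min_bins: int, max_arc: int):
    """|t| for every valid candidate arc, given cumsum/cumsq with leading 0.

    S and Q may be 1-D (length n+1) for the observed series or 2-D
    (B, n+1) for a block of permutations.  Yields (abs_t, i_starts, L) per
    arc length, then the boundary-anchored splits as L = None.
    """
    two_d = S.ndim == 2
    T = S[..., n:n + 1] if two_d else S[n]
    QT = Q[..., n:n + 1] if two_d else Q[n]

    def t_for(sa, qa, a):
        b = n - a
        ssa = qa - sa * sa / a
        ssb = (QT - qa) - (T - sa) * (T - sa) / b
        s2 = (ssa + ssb) / (n - 2)
        mdiff = sa / a - (T - sa) / b
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mdiff / np.sqrt(np.maximum(s2, 0.0) * (1.0 / a + 1.0 / b))
        # constant data: zero pooled variance and zero mean difference
        t = np.where(np.abs(mdiff) < _EPS, 0.0,
                     np.where(s2 < _EPS, np.inf * np.sign(mdiff), t))
        return np.abs(t)

    hi_arc = min(max_arc, n - min_bins)
    for L in range(min_bins, hi_arc + 1):
        sa = S[..., L:n + 1] - S[..., 0:n - L + 1]
        qa = Q[..., L:n + 1] - Q[..., 0:n - L + 1]
        starts = np.arange(0, n - L + 1)
        # suffix-anchored arcs are excluded: an arc ending at the boundary
        # is the complement of a prefix split already in the family
        valid = ((starts == 0) | (starts >= min_bins)) & \
                (starts + L <= n - min_bins)
        yield t_for(sa, qa, L)[..., valid], starts[valid], L
    # boundary-anchored splits of any length (arc = prefix [0, j))
    js = np.arange(min_bins, n - min_bins + 1)
    long_js = js[js > hi_arc]  # shorter prefixes already covered above
    if long_js.size:
        sa = S[..., long_js]
        qa = Q[..., long_js]
        b_t = t_for(sa, qa, long_js.astype(float))
        yield b_t, long_js, None


def _best_candidate(x: np.ndarray, min_bins: int, max_arc: int):
    """Best arc (i, j) and its |t| on the observed series; None if no
    candidate exists."""
    n = len(x)
    if n < 2 * min_bins:
        return None
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    best = (-1.0, None)
    for abs_t, starts, L in _candidate_stats(S, Q, n, min_bins, max_arc):
        if abs_t.size == 0:
            continue
        k = int(np.argmax(abs_t))
        if abs_t[k] > best[0]:
            i = int(starts[k])
            j = i + L if L is not None else int(starts[k])
            if L is None:
                i, j = 0, int(starts[k])
            best = (float(abs_t[k]), (i, j))
    if best[1] is None:
        return None
    return best


def _perm_max_stats(x: np.ndarray, rng: np.random.Generator, block: int,
                    min_bins: int, max_arc: int) -> np.ndarray:
    """Max candidate |t| for a block of permutations of x."""
    n = len(x)
    mat = np.tile(x, (block, 1))
    mat = rng.permuted(mat, axis=1)
    S = np.concatenate((np.zeros((block, 1)), np.cumsum(mat, axis=1)), axis=1)
    Q = np.concatenate((np.zeros((block, 1)), np.cumsum(mat * mat, axis=1)), axis=1)
    out = np.zeros(block)
    for abs_t, _, _ in _candidate_stats(S, Q, n, min_bins, max_arc):
        if abs_t.size:
            np.maximum(out, abs_t.max(axis=1), out=out)
    return out


def _accept_split(x: np.ndarray, params: SegmentationParams,
                  rng: np.random.Generator):
    """Permutation-test the best candidate on segment x.

    Returns the accepted arc (i, j) or None.  The candidate is accepted
    when fewer than ceil(alpha * n_permutations) permutation maxima reach
    the observed maximum; permutations run in blocks with early rejection.
    """
    best = _best_candidate(x, params.min_bins, params.max_arc_bins)
    if best is None:
        return None
    obs, arc = best
    if not math.isfinite(obs):
        return arc  # zero-variance step: no permutation can beat infinity
    threshold = max(1, math.ceil(params.cbs_alpha * params.n_permutations))
    exceed = 0
    done = 0
    block = 150
    # sequential shortcut: clear signals (zero exceedances after 2 blocks)
    # are accepted without exhausting the permutation budget
    early_accept_at = min(params.n_permutations, 2 * block)
    while done < params.n_permutations:
        b = min(block, params.n_permutations - done)
        maxima = _perm_max_stats(x, rng, b, params.min_bins, params.max_arc_bins)
        exceed += int(np.sum(maxima >= obs - 1e-9))
        done += b
        if exceed >= threshold:
            return None
        if exceed == 0 and done >= early_accept_at:
            return arc
    return arc


def cbs_segment(values: np.ndarray,
                params: SegmentationParams | None = None,
                rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Segment one chromosome's log-ratio sequence.

    Returns half-open index ranges partitioning ``[0, len(values))``,
    sorted.  Deterministic given ``params.seed`` (or a caller-supplied
    generator).  Sequences shorter than ``2 * min_bins`` come back as a
    single segment.
    """
    params = params or SegmentationParams()
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("values contain NaN; drop unusable bins first")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    segments: list[tuple[int, int]] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * params.min_bins:
            segments.append((lo, hi))
            continue
        arc = _accept_split(values[lo:hi], params, rng)
        if arc is None:
            segments.append((lo, hi))
            continue
        i, j = arc
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        # LIFO: push reversed so the leftmost piece is processed first
        for piece in reversed([p for p in pieces if p[1] > p[0]]):
            stack.append(piece)
    segments.sort()
    return segments


# ---------------------------------------------------------------------------
# calling


def call_segments(lr: pd.DataFrame,
                  segmentation: dict[str, list[tuple[int, int]]],
                  params: SegmentationParams | None = None,
                  sample_id: str = "") -> list[CnvSegment]:
    """Thresholded gain/loss calls with a specificity confidence score.

    ``lr`` is the output of :func:`compute_log_ratios`; ``segmentation``
    maps chromosome -> index ranges into that chromosome's usable bins.
    The specificity null is Normal(median, MAD-derived sigma / sqrt(n_bins))
    fitted on all usable bins genome-wide.
    """
    params = params or SegmentationParams()
    usable = lr[lr["usable"]]
    all_vals = usable["log2_ratio"].to_numpy()
    med = float(np.median(all_vals))
    mad = float(np.median(np.abs(all_vals - med)))
    sigma = 1.4826 * mad if mad > 0 else float(np.std(all_vals)) or _EPS
    out: list[CnvSegment] = []
    for chrom, ranges in segmentation.items():
        sub = usable[usable["chrom"] == chrom]
        vals = sub["log2_ratio"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for lo, hi in ranges:
            if hi <= lo:
                raise ValueError(f"empty segment {chrom}[{lo}:{hi})")
            seg_vals = vals[lo:hi]
            mean_lr = float(seg_vals.mean())
            ratio = 2.0 ** mean_lr
            n_bins = hi - lo
            z = (mean_lr - med) / (sigma / math.sqrt(n_bins))
            specificity = float(1.0 - 2.0 * stats.norm.sf(abs(z)))
            if ratio > params.gain_threshold:
                call = "gain"
            elif ratio < params.loss_threshold:
                call = "loss"
            else:
                call = "neutral"
            low = False
            if call != "neutral" and specificity < params.specificity_required:
                call, low = "neutral", True
            out.append(
                CnvSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_bins=n_bins,
                    mean_ratio=ratio,
                    call=call,
                    specificity=specificity,
                    low_specificity=low,
                )
            )
    return out


def segment_sample(coverage: pd.DataFrame, params: SegmentationParams | None = None,
                   sample_id: str = "", seed: int | None = None,
                   ) -> tuple[pd.DataFrame, list[CnvSegment]]:
    """Full per-sample pipeline: ratios -> CBS per chromosome -> calls."""
    params = params or SegmentationParams()
    lr = compute_log_ratios(coverage, params)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    segmentation: dict[str, list[tuple[int, int]]] = {}
    usable = lr[lr["usable"]]
    for chrom in usable["chrom"].unique():
        vals = usable.loc[usable["chrom"] == chrom, "log2_ratio"].to_numpy()
        segmentation[str(chrom)] = cbs_segment(vals, params, rng)
    return lr, call_segments(lr, segmentation, params, sample_id)


# ---------------------------------------------------------------------------
# LOH


@dataclass(frozen=True)
class LohParams:
    min_tumour_depth: int = 8
    max_p: float = 1e-3
    baf_band: tuple[float, float] = (0.3, 0.7)
    segment_majority: float = 0.5  # strict > fraction of covered sites


def call_loh(het_sites: pd.DataFrame, segments: list[CnvSegment],
             params: LohParams | None = None) -> pd.DataFrame:
    """Per-site and per-segment LOH calls for one sample.

    Each site with tumour depth >= ``min_tumour_depth`` gets an exact
    two-sided binomial test of the tumour alt depth against B-allele
    frequency 0.5; a site is LOH when the p-value is below ``max_p`` and
    the tumour BAF falls outside ``baf_band``.  A segment is flagged LOH
    when more than ``segment_majority`` of its covered sites are LOH.

    Returns a copy of ``het_sites`` with ``covered``, ``loh_p`` and
    ``loh_call`` columns; segment ``loh`` flags are set in place.
    """
    params = params or LohParams()
    out = het_sites.copy()
    alt = out["tumour_alt_depth"].to_numpy(dtype=int)
    depth = alt + out["tumour_ref_depth"].to_numpy(dtype=int)
    covered = depth >= params.min_tumour_depth
    k = np.minimum(alt, depth - alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(k, np.maximum(depth, 1), 0.5))
        baf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    lo, hi = params.baf_band
    loh = covered & (p < params.max_p) & ((baf < lo) | (baf > hi))
    out["covered"] = covered
    out["loh_p"] = np.where(covered, p, np.nan)
    out["loh_call"] = loh
    pos0 = out["pos"].to_numpy(dtype=int) - 1  # 1-based site vs BED segment
    chroms = out["chrom"].astype(str).to_numpy()
    for seg in segments:
        mask = covered & (chroms == seg.chrom) & (pos0 >= seg.start) & (pos0 < seg.end)
        n_cov = int(mask.sum())
        if n_cov == 0:
            seg.loh = None
            continue
        frac = float(loh[mask].sum()) / n_cov
        seg.loh = frac > params.segment_majority
    return out
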