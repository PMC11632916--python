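"""Stiffening-profile analysis of oscillatory-shear time sweeps.

The workflow mirrors how photo-rheology time sweeps are reduced to summary
statistics: a locally weighted regression (LOWESS) smooths each replicate's
G' trace, its first derivative gives the stiffening rate, and a 3 Pa/s
threshold splits the sweep into plateau and stiffening regions.  Plateau
means before and after light exposure give per-replicate fold change; the
total time above threshold is the time to stiffness plateau; post-stiffening
plateau means averaged across replicates give the group's maximum stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .simulate import TimeSweep

__all__ = [
    "RegionSegmentation",
    "StiffeningSummary",
    "GroupSummary",
    "smooth_curve",
    "rate_of_change",
    "segment_regions",
    "summarize_replicate",
    "aggregate_group",
    "analyze_sweep",
    "analyze_group",
    "DEFAULT_THRESHOLD",
    "DEFAULT_SPAN",
]

DEFAULT_THRESHOLD = 3.0  # Pa/s
DEFAULT_SPAN = 0.05      # LOWESS span as a fraction of the series
MIN_SAMPLES = 10
DEFAULT_MIN_RUN = 10.0   # s; shorter threshold runs are absorbed into neighbors


@dataclass
class RegionSegmentation:
    """Disjoint, ordered plateau/stiffening intervals covering a sweep."""

    intervals: list[tuple[float, float, str]]  # (start s, end s, label)
    rate: np.ndarray                           # Pa/s, aligned with t
    threshold: float

    def total_duration(self, label: str) -> float:
        return sum(e - s for s, e, lab in self.intervals if lab == label)


@dataclass
class StiffeningSummary:
    pre_mean: float        # Pa, raw G' over the pre-light plateau
    post_mean: float       # Pa, raw G' over the final plateau
    fold_change: float     # post_mean / pre_mean
    time_to_plateau: float  # s above threshold
    replicate_id: str = ""


@dataclass
class GroupSummary:
    max_stiffness_mean: float
    max_stiffness_sd: float
    fold_change_mean: float
    fold_change_sd: float
    time_to_plateau_mean: float
    n: int
    single_replicate: bool = False  # sd reported as 0 by convention


def smooth_curve(sweep: TimeSweep, span: float = DEFAULT_SPAN) -> np.ndarray:
    """LOWESS fit of G' evaluated at the sweep's own time points.

    Local linear weighted regression with one robustifying iteration; the
    small default span preserves the sharp light-onset transition.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = sweep.t.size
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    return sm.nonparametric.lowess(
        sweep.g_prime, sweep.t, frac=span, it=1, return_sorted=False
    )


def rate_of_change(t: np.ndarray, g_fit: np.ndarray) -> np.ndarray:
    """First derivative of the fitted stiffness: central differences in the
    interior, one-sided at the ends (same length as the input)."""
    t = np.asarray(t, dtype=float)
    g_fit = np.asarray(g_fit, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    return np.gradient(g_fit, t)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of a boolean array as (start idx, stop idx exclusive, value)."""
    out = []
    start = 0
    for i in range(1, mask.size + 1):
        if i == mask.size or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def segment_regions(
    t: np.ndarray,
    rate: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_run_duration: float = DEFAULT_MIN_RUN,
) -> RegionSegmentation:
    """Label the sweep as stiffening (rate > threshold) vs plateau.

    The comparison uses the signed rate — these gels only stiffen.  Runs
    shorter than ``min_run_duration`` are iteratively absorbed into their
    neighbors (shortest first) to suppress noise flicker at the threshold.
    """
    t = np.asarray(t, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if t.size != rate.size:
        raise ValueError("rate must be aligned with t")
    above = rate > threshold
    runs = _runs(above)

    def run_duration(run):
        s, e, _ = run
        return t[e - 1] - t[s]

    while len(runs) > 1:
        durations = [run_duration(r) for r in runs]
        shortest = int(np.argmin(durations))
        if durations[shortest] >= min_run_duration:
            break
        s, e, v = runs[shortest]
        runs[shortest] = (s, e, not v)
        merged = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1] = (merged[-1][0], r[1], r[2])
            else:
                merged.append(list(r) if isinstance(r, tuple) else r)
        runs = [tuple(r) for r in merged]

    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    intervals = []
    for s, e, v in runs:
        end = t[e - 1] + dt if e == t.size else t[e]
        intervals.append((float(t[s]), float(end), "stiffening" if v else "plateau"))
    return RegionSegmentation(intervals=intervals, rate=rate, threshold=threshold)


def summarize_replicate(sweep: TimeSweep, seg: RegionSegmentation) -> StiffeningSummary:
    """Per-replicate plateau means, fold change and time to plateau.

    Pre-light plateau = plateau samples with t < light_on; post plateau = the
    final plateau run.  Means are taken on the *raw* G' (unbiased under
    symmetric noise), not the smoothed fit.
    """
    t, g = sweep.t, sweep.g_prime
    pre_mask = np.zeros(t.size, dtype=bool)
    for s, e, lab in seg.intervals:
        if lab == "plateau":
            pre_mask |= (t >= s) & (t < e) & (t < sweep.light_on)
    if not pre_mask.any():
        raise ValueError("no pre-light plateau found (nothing before light_on)")
    last = seg.intervals[-1]
    if last[2] != "plateau":
        raise ValueError("no post-stiffening plateau found (sweep ends stiffening)")
    post_mask = (t >= last[0]) & (t < last[1])
    pre_mean = float(g[pre_mask].mean())
    post_mean = float(g[post_mask].mean())
    return StiffeningSummary(
        pre_mean=pre_mean,
        post_mean=post_mean,
        fold_change=post_mean / pre_mean,
        time_to_plateau=seg.total_duration("stiffening"),
        replicate_id=sweep.replicate_id,
    )


def aggregate_group(summaries: list[StiffeningSummary]) -> GroupSummary:
    """Means and sample SDs of the replicate summaries (n = 1 → sd 0, flagged)."""
    if not summaries:
        raise ValueError("no replicate summaries to aggregate")
    post = np.array([s.post_mean for s in summaries])
    fold = np.array([s.fold_change for s in summaries])
    ttp = np.array([s.time_to_plateau for s in summaries])
    single = post.size == 1
    sd = (lambda x: 0.0 if single else float(np.std(x, ddof=1)))
    return GroupSummary(
        max_stiffness_mean=float(post.mean()),
        max_stiffness_sd=sd(post),
        fold_change_mean=float(fold.mean()),
        fold_change_sd=sd(fold),
        time_to_plateau_mean=float(ttp.mean()),
        n=int(post.size),
        single_replicate=single,
    )


def analyze_sweep(
    sweep: TimeSweep,
    span: float = DEFAULT_SPAN,
    threshold: float = DEFAULT_THRESHOLD,
    min_run_duration: float = DEFAULT_MIN_RUN,
) -> StiffeningSummary:
    """Full per-replicate pipeline: smooth → derivative → segment → summarize."""
    fit = smooth_curve(sweep, span=span)
    rate = rate_of_change(sweep.t, fit)
    seg = segment_regions(sweep.t, rate, threshold=threshold,
                          min_run_duration=min_run_duration)
    return summarize_replicate(sweep, seg)


def analyze_group(sweeps: list[TimeSweep], **kwargs) -> GroupSummary:
    return aggregate_group([analyze_sweep(s, **kwargs) for s in sweeps])
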