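"""Change-point segmentation of extension traces into OS/CS dwells.

Transitions between the two tether levels are located by offline bottom-up
change-point detection with a least-absolute-deviation cost: the trace is
cut into a fine initial partition, and adjacent segments are merged
greedily, cheapest merge first, until the cost increase of the best
remaining merge exceeds a penalty.  The cost is computed on a
MAD-standardized copy of the signal so that the penalty is scale-free (a
useful range is roughly 0.2-5) and segmentation is invariant to offset and
gain.  Segments are then classified into the two levels by exact 1-D
2-means on their medians -- the lower-extension cluster is the open state,
since promoter opening shortens a supercoiled tether -- and dwell times are
read off the labeled segmentation.

Trace-quality metrics (overlapping Allan deviation and the autocorrelation
time) quantify tracking noise and the temporal resolution of the assay.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.stats import theilslopes

from .dwells import DwellSet

__all__ = [
    "Segmentation",
    "detect_changepoints",
    "label_segments",
    "extract_dwells",
    "segment_trace",
    "allan_deviation",
    "correlation_time",
    "detrend",
]


def _noise_sigma(z: np.ndarray) -> float:
    """Robust per-sample noise SD from first differences (level-shift proof)."""
    d = np.abs(np.diff(z))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(d)) / np.sqrt(2.0)


def _l1_cost(sorted_vals: np.ndarray) -> float:
    """Sum of absolute deviations from the median, given sorted values."""
    m = sorted_vals.size
    med = sorted_vals[(m - 1) // 2] if m % 2 else 0.5 * (
        sorted_vals[m // 2 - 1] + sorted_vals[m // 2])
    return float(np.sum(np.abs(sorted_vals - med)))


def detect_changepoints(z, penalty: float = 1.0, min_size: int = 2) -> np.ndarray:
    """Bottom-up change-point detection with L1 cost.

    Parameters
    ----------
    z : array
        Extension series (any units; the cost is computed on a
        MAD-standardized copy, so ``penalty`` is scale-free).
    penalty : float
        Merge-stopping threshold: merging continues while the smallest cost
        increase of any adjacent merge is below ``penalty``.
    min_size : int
        Size of the initial fine partition (samples); no returned segment is
        shorter than this.

    Returns
    -------
    ndarray of int
        Indices at which a new segment starts (0 < i < len(z)), sorted.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("empty series")
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    min_size = int(min_size)
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if n < 2 * min_size:
        return np.array([], dtype=int)

    sigma = _noise_sigma(z)
    zs = (z - np.median(z)) / sigma if sigma > 0 else z - np.median(z)
    # quantize so that the greedy merge order is stable under float-level
    # perturbations (e.g. adding a constant offset to z)
    zs = np.round(zs, 6)

    # initial fine partition; the last segment absorbs the remainder
    starts = list(range(0, n - n % min_size, min_size))
    ends = starts[1:] + [n]
    if len(starts) >= 2 and ends[-1] - starts[-1] < min_size:
        starts.pop()
        ends = starts[1:] + [n]

    nseg = len(starts)
    if nseg == 1:
        return np.array([], dtype=int)

    seg_start = list(starts)
    seg_end = list(ends)
    seg_sorted = [np.sort(zs[s:e]) for s, e in zip(starts, ends)]
    seg_cost = [_l1_cost(sv) for sv in seg_sorted]
    prev = list(range(-1, nseg - 1))
    nxt = list(range(1, nseg + 1))
    nxt[-1] = -1
    alive = [True] * nseg
    version = [0] * nseg

    def _merge_gain(i: int, j: int):
        merged = np.sort(np.concatenate((seg_sorted[i], seg_sorted[j])),
                         kind="stable")
        return _l1_cost(merged) - seg_cost[i] - seg_cost[j], merged

    heap = []
    for i in range(nseg - 1):
        gain, _ = _merge_gain(i, i + 1)
        heapq.heappush(heap, (gain, i, i + 1, 0, 0))

    while heap:
        gain, i, j, vi, vj = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or version[i] != vi or version[j] != vj:
            continue
        if gain > penalty:
            break
        # merge j into i
        merged_gain, merged = _merge_gain(i, j)
        seg_sorted[i] = merged
        seg_cost[i] += merged_gain
        seg_end[i] = seg_end[j]
        alive[j] = False
        version[i] += 1
        nxt[i] = nxt[j]
        if nxt[j] != -1:
            prev[nxt[j]] = i
        for a, b in ((prev[i], i), (i, nxt[i])):
            if a != -1 and b != -1:
                g, _ = _merge_gain(a, b)
                heapq.heappush(heap, (g, a, b, version[a], version[b]))

    bps = sorted(seg_start[k] for k in range(nseg) if alive[k] and seg_start[k] > 0)
    return np.array(bps, dtype=int)


@dataclass
class Segmentation:
    """Breakpoints, per-segment OS/CS labels and median levels of one trace."""

    n_samples: int
    breakpoints: np.ndarray   # internal segment-start indices, increasing
    labels: list              # per-segment "OS"/"CS"
    levels: np.ndarray        # per-segment median extension (nm)

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=int)
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one label per segment")

    @property
    def bounds(self) -> np.ndarray:
        return np.concatenate(([0], self.breakpoints, [self.n_samples]))


def _two_means_1d(values: np.ndarray, weights: np.ndarray):
    """Exact weighted 1-D 2-means: best split of the sorted values.

    Returns (assignment, centers) with assignment 1 for the upper cluster;
    centers ordered (lower, upper).  A single value yields one cluster.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    n = v.size
    if n == 1:
        return np.zeros(1, dtype=int), np.array([v[0], v[0]])
    cw = np.cumsum(w)
    cwv = np.cumsum(w * v)
    cwv2 = np.cumsum(w * v * v)
    best, best_k = np.inf, 1
    for k in range(1, n):  # lower cluster = v[:k]
        wl, wu = cw[k - 1], cw[-1] - cw[k - 1]
        sl, su = cwv[k - 1], cwv[-1] - cwv[k - 1]
        ql, qu = cwv2[k - 1], cwv2[-1] - cwv2[k - 1]
        ss = (ql - sl * sl / wl) + (qu - su * su / wu)
        if ss < best:
            best, best_k = ss, k
    lo = cwv[best_k - 1] / cw[best_k - 1]
    hi = (cwv[-1] - cwv[best_k - 1]) / (cw[-1] - cw[best_k - 1])
    assign = np.zeros(n, dtype=int)
    assign[order[best_k:]] = 1
    return assign, np.array([lo, hi])


def label_segments(z, breakpoints) -> Segmentation:
    """Classify segments into the two extension levels.

    Segment medians are split by exact (length-weighted) 1-D 2-means; the
    lower-extension cluster is labeled OS.  If the two cluster centers are
    closer than 3 noise SDs (no resolvable second level, e.g. a trace with
    no opening events) all segments are labeled CS.  Adjacent same-label
    segments are merged and their level recomputed.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("empty series")
    bounds = np.concatenate(([0], np.asarray(breakpoints, dtype=int), [n]))
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("invalid breakpoints")
    medians = np.array([np.median(z[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])
    lengths = np.diff(bounds).astype(float)

    sigma = _noise_sigma(z)
    if len(medians) == 1:
        labels = ["CS"]
    else:
        assign, centers = _two_means_1d(medians, lengths)
        if centers[1] - centers[0] <= 3.0 * sigma:
            labels = ["CS"] * len(medians)
        else:
            labels = ["OS" if a == 0 else "CS" for a in assign]

    # merge adjacent same-label segments
    keep_bounds = [0]
    keep_labels = [labels[0]]
    for i in range(1, len(labels)):
        if labels[i] != keep_labels[-1]:
            keep_bounds.append(int(bounds[i]))
            keep_labels.append(labels[i])
    keep_bounds.append(n)
    levels = np.array([np.median(z[a:b])
                       for a, b in zip(keep_bounds[:-1], keep_bounds[1:])])
    return Segmentation(n_samples=n, breakpoints=np.array(keep_bounds[1:-1], dtype=int),
                        labels=keep_labels, levels=levels)


def extract_dwells(seg: Segmentation, f_s_eff: float, t_min: float = 0.0) -> DwellSet:
    """Dwell durations from a labeled segmentation.

    Durations are segment lengths over the effective sampling rate.  The
    first and last dwell are flagged censored (window-truncated).  Interior
    dwells shorter than ``t_min`` are treated as undetectable excursions:
    the dwell is discarded and its two (same-label) neighbors merged,
    shortest first, until every interior dwell is >= t_min.
    """
    if f_s_eff <= 0:
        raise ValueError("f_s_eff must be > 0")
    durations = list(np.diff(seg.bounds) / f_s_eff)
    labels = list(seg.labels)
    m = len(durations)
    censored = [i == 0 or i == m - 1 for i in range(m)]

    if t_min > 0:
        while True:
            interior = [i for i in range(1, len(durations) - 1)
                        if durations[i] < t_min]
            if not interior:
                break
            i = min(interior, key=lambda k: durations[k])
            merged_dur = durations[i - 1] + durations[i] + durations[i + 1]
            merged_cens = censored[i - 1] or censored[i + 1]
            labels[i - 1: i + 2] = [labels[i - 1]]
            durations[i - 1: i + 2] = [merged_dur]
            censored[i - 1: i + 2] = [merged_cens]

    return DwellSet(labels=np.array(labels, dtype=object),
                    durations=np.array(durations),
                    censored=np.array(censored, dtype=bool),
                    t_min=t_min)


def detrend(z, f_s: float, max_drift: float = 0.5):
    """Remove linear drift by a robust (Theil-Sen) line fit.

    The correction is only applied when the fitted slope magnitude exceeds
    ``max_drift`` nm/s; below that the series is returned unchanged.
    Returns ``(z_corrected, slope_nm_per_s)``.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 3:
        return z, 0.0
    step = max(1, n // 500)  # Theil-Sen is O(m^2) in the point count
    idx = np.arange(0, n, step)
    t_sub = idx / f_s
    slope, _, _, _ = theilslopes(z[idx], t_sub)
    if abs(slope) > max_drift:
        return z - slope * (np.arange(n) / f_s), float(slope)
    return z, float(slope)


def segment_trace(trace, penalty: float = 1.0, min_size: int = 2,
                  t_min: float = 0.09, max_drift: float = 0.5):
    """Full segmentation of a trace: detrend, detect, label, extract.

    ``trace`` is an :class:`opencomplex.simulate.Trace` (or anything with
    ``z`` and ``f_s_eff``).  Returns ``(Segmentation, DwellSet)``.
    """
    f_s_eff = trace.f_s_eff
    z, _ = detrend(trace.z, f_s_eff, max_drift=max_drift)
    bps = detect_changepoints(z, penalty=penalty, min_size=min_size)
    seg = label_segments(z, bps)
    return seg, extract_dwells(seg, f_s_eff, t_min=t_min)


def allan_deviation(z, f_s: float):
    """Overlapping Allan deviation of an extension series.

    For octave-spaced averaging times ``tau = m / f_s``,
    ``sigma(tau) = sqrt(0.5 * mean[(ybar_{i+m} - ybar_i)^2])`` over
    overlapping block means ``ybar``.  White tracking noise gives the
    signature ``sigma ~ tau^{-1/2}``; correlated bead motion flattens the
    curve below the correlation time.  Returns ``(taus, deviations)``.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    c = np.concatenate(([0.0], np.cumsum(z)))
    taus, sigmas = [], []
    m = 1
    while 2 * m <= n:
        y = (c[m:] - c[:-m]) / m          # overlapping block means
        d = y[m:] - y[:-m]
        sigmas.append(np.sqrt(0.5 * np.mean(d * d)))
        taus.append(m / f_s)
        m *= 2
    return np.array(taus), np.array(sigmas)


def correlation_time(z, f_s: float, max_lag: int | None = None) -> float:
    """Lag at which the autocorrelation of ``z`` decays to 1/e, in seconds.

    Computed from the FFT-based autocorrelation with linear interpolation
    between lags; returns NaN if the autocorrelation never crosses 1/e
    within ``max_lag`` samples.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if max_lag is None:
        max_lag = n // 2
    x = z - z.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    ps = np.abs(np.fft.rfft(x, nfft)) ** 2
    acf = np.fft.irfft(ps)[: max_lag + 1]
    if acf[0] <= 0:
        return float("nan")
    acf = acf / acf[0]
    target = 1.0 / np.e
    below = np.flatnonzero(acf < target)
    if below.size == 0:
        return float("nan")
    k = below[0]
    if k == 0:
        return 0.0
    frac = (acf[k - 1] - target) / (acf[k - 1] - acf[k])
    return float((k - 1 + frac) / f_s)
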