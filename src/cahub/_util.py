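"""Internal numerical helpers shared across analysis stages."""

from __future__ import annotations

import numpy as np


def hist_percentile(counts: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of integer data given as a histogram.

    ``counts[v]`` is the number of observations equal to ``v``.  Matches
    ``np.percentile(values, q)`` (the default linear method) without
    materialising the pooled value vector, which for surrogate pooling
    can run to many millions of entries.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty histogram")
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    cum = np.cumsum(counts)
    v_lo = int(np.searchsorted(cum, lo + 1))
    if hi == lo:
        return float(v_lo)
    v_hi = int(np.searchsorted(cum, hi + 1))
    return v_lo + (pos - lo) * (v_hi - v_lo)


def circular_cross_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-offset circular cross-correlation ``c[m] = sum_t x[t] * y[(t+m) % T]``.

    Computed via FFT in O(T log T).  Both inputs must share the last-axis
    length; broadcasting over leading axes is supported.
    """
    T = x.shape[-1]
    if y.shape[-1] != T:
        raise ValueError("length mismatch in circular cross-correlation")
    fx = np.fft.rfft(x, axis=-1)
    fy = np.fft.rfft(y, axis=-1)
    return np.fft.irfft(np.conj(fx) * fy, n=T, axis=-1)


def greedy_separated_peaks(
    heights: np.ndarray,
    candidate_idx: np.ndarray,
    times_s: np.ndarray,
    min_sep_s: float,
) -> np.ndarray:
    """Keep the highest candidates subject to a minimal time separation.

    Candidates are visited in order of decreasing height (ties broken by
    earlier time); a candidate is kept if it lies at least ``min_sep_s``
    from every already-kept peak.  Returns kept indices sorted by time.
    This greedy rule makes the kept set at a high threshold a subset of
    the kept set at any lower threshold.
    """
    if len(candidate_idx) == 0:
        return np.asarray(candidate_idx, dtype=np.int64)
    h = heights[candidate_idx]
    order = np.lexsort((times_s[candidate_idx], -h))
    kept: list[int] = []
    kept_t: list[float] = []
    for k in order:
        idx = candidate_idx[k]
        t = times_s[idx]
        if all(abs(t - u) >= min_sep_s for u in kept_t):
            kept.append(idx)
            kept_t.append(t)
    return np.asarray(sorted(kept), dtype=np.int64)


def two_consecutive(mask: np.ndarray) -> bool:
    """True when at least two consecutive entries of ``mask`` are True."""
    mask = np.asarray(mask, dtype=bool)
    return bool(np.any(mask[1:] & mask[:-1]))


def poisson_times(
    rate_hz: float, t0_s: float, t1_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson event times (seconds) on ``[t0, t1)``."""
    if rate_hz <= 0 or t1_s <= t0_s:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1_s - t0_s))
    return np.sort(t0_s + rng.random(n) * (t1_s - t0_s))
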