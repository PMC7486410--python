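"""In vivo per-cell modulation: locomotion classification and SCE analysis.

Peri-event histograms are built at single-frame resolution (~101.5 ms at
9.85 Hz) and z-scored against a pre-event baseline:

    Z = (PSTH - mu_B) / sigma_B

with ``mu_B``/``sigma_B`` the mean and SD of the baseline bins.  For
locomotion the window is 10 s and baseline bins are those ending before
-200 ms relative to locomotion onset; a cell is onset-activated if at
least two consecutive bins from -200 ms onward exceed Z = 2.  A second,
rate-based test compares each cell's locomotion/rest spike-count ratio
with the 95th percentile of the same ratio under circular shifts of its
spike train; a cell is locomotion-ON if it passes either test.

SCEs (synchronous calcium events) are rest-restricted 200 ms bins whose
population spike count exceeds the pooled 99th percentile of
circular-shift surrogates, kept at >= 1 s separation.  A cell is SCE-ON
if the zero-lag bin of its 4 s SCE-aligned Z-PSTH exceeds Z = 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cahub._util import (
    circular_cross_correlation,
    greedy_separated_peaks,
    hist_percentile,
    two_consecutive,
)
from cahub.raster import ActivityRaster, EpochSet, bin_raster, random_row_shifts

logger = logging.getLogger(__name__)


@dataclass
class ZPSTH:
    """Event-aligned z-scored peri-stimulus time histogram of one cell."""

    event_type: str                 # "LOC" or "SCE"
    window_s: float
    bin_s: float
    offsets_s: np.ndarray           # bin-centre times relative to event
    psth: np.ndarray                # mean count per bin per event
    mu_b: float
    sigma_b: float
    z: np.ndarray                   # NaN-filled when sigma_b == 0
    n_events: int
    valid: bool = True              # False when sigma_b == 0


@dataclass
class SCECatalog:
    """Detected synchronous calcium events of one session."""

    bin_idx: np.ndarray             # indices into the rest-binned matrix
    frames: np.ndarray              # start frame of each SCE bin
    frame_rate_hz: float
    bin_s: float
    n_coactive: np.ndarray
    participants: list[np.ndarray] = field(default_factory=list)
    threshold: float = np.nan
    rest_duration_s: float = np.nan

    @property
    def n_sces(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames / self.frame_rate_hz

    @property
    def rate_hz(self) -> float:
        """SCE rate per second of rest."""
        if not np.isfinite(self.rest_duration_s) or self.rest_duration_s <= 0:
            return np.nan
        return self.n_sces / self.rest_duration_s


@dataclass
class LocomotionModulation:
    """Per-cell locomotion-modulation results of one session."""

    zpsths: list[ZPSTH]
    onset_sig: np.ndarray           # method 1 (onset Z-PSTH)
    ratio_sig: np.ndarray           # method 2 (shuffle ratio)
    locomotion_on: np.ndarray       # method 1 OR method 2
    ratios: np.ndarray
    ratio_thresholds: np.ndarray


@dataclass
class SCEModulation:
    """Per-cell SCE-modulation results of one session."""

    zpsths: list[ZPSTH]
    sce_on: np.ndarray
    indeterminate: np.ndarray       # sigma_B == 0


def _event_psths(
    onsets: np.ndarray, event_frames: np.ndarray, half: int
) -> tuple[np.ndarray, int]:
    """Per-cell event-aligned count matrix (frame bins from -half to +half).

    Only events with the full window inside the recording contribute, so
    every bin is normalised by the same event count.
    """
    n_cells, n_frames = onsets.shape
    width = 2 * half + 1
    ok = event_frames[(event_frames >= half) & (event_frames + half < n_frames)]
    acc = np.zeros((n_cells, width), dtype=np.int64)
    for f in ok:
        acc += onsets[:, f - half : f + half + 1]
    return acc, len(ok)


def _make_zpsth(
    event_type: str,
    counts: np.ndarray,
    n_events: int,
    half: int,
    frame_rate_hz: float,
    baseline_mask: np.ndarray,
) -> ZPSTH:
    bin_s = 1.0 / frame_rate_hz
    offsets = np.arange(-half, half + 1) * bin_s
    psth = counts / max(n_events, 1)
    mu = float(psth[baseline_mask].mean()) if baseline_mask.any() else np.nan
    sd = float(psth[baseline_mask].std()) if baseline_mask.any() else np.nan
    valid = bool(np.isfinite(sd) and sd > 0)
    z = (psth - mu) / sd if valid else np.full_like(psth, np.nan)
    return ZPSTH(
        event_type, 2 * half * bin_s, bin_s, offsets, psth, mu, sd, z,
        n_events, valid,
    )


def classify_locomotion(
    r: ActivityRaster,
    loco: EpochSet,
    rest: EpochSet,
    n_shuffles: int = 1000,
    window_s: float = 10.0,
    z_thresh: float = 2.0,
    baseline_edge_s: float = 0.2,
    ratio_pctile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> LocomotionModulation:
    """Classify locomotion-ON cells with the onset-PSTH and ratio methods.

    Method 1 aligns each cell's onsets on locomotion-bout starts
    (``window_s`` window, 1-frame bins), z-scores against bins ending
    before ``-baseline_edge_s``, and requires two consecutive bins above
    ``z_thresh`` from ``-baseline_edge_s`` onward.  Method 2 compares the
    locomotion/rest spike-count ratio against the per-cell
    ``ratio_pctile`` percentile of the same ratio under ``n_shuffles``
    circular shifts; both counts carry an additive half-count
    regulariser so cells silent at rest keep a finite ratio.
    """
    rng = np.random.default_rng(rng)
    if loco.n_epochs == 0:
        raise ValueError("no locomotion onset available")
    fs = r.frame_rate_hz
    half = int(round(window_s / 2 * fs))
    counts, n_events = _event_psths(r.onsets, loco.onset_frames(), half)
    offsets_s = np.arange(-half, half + 1) / fs
    baseline_mask = offsets_s < -baseline_edge_s
    test_mask = ~baseline_mask

    zpsths: list[ZPSTH] = []
    onset_sig = np.zeros(r.n_cells, dtype=bool)
    for c in range(r.n_cells):
        zp = _make_zpsth("LOC", counts[c], n_events, half, fs, baseline_mask)
        zpsths.append(zp)
        if zp.valid and n_events > 0:
            onset_sig[c] = two_consecutive(zp.z[test_mask] > z_thresh)

    loco_mask = loco.mask(r.n_frames).astype(float)
    rest_mask = rest.mask(r.n_frames).astype(float)
    x = r.onsets.astype(float)
    # Counts inside each epoch set for *every* circular shift at once:
    # shifting a spike train by s and counting within a mask equals the
    # circular cross-correlation of train and mask evaluated at s.
    c_loco = np.rint(circular_cross_correlation(x, loco_mask[None, :]))
    c_rest = np.rint(circular_cross_correlation(x, rest_mask[None, :]))
    real_ratio = (c_loco[:, 0] + 0.5) / (c_rest[:, 0] + 0.5)
    if np.any(c_rest[:, 0] == 0):
        logger.info(
            "%d cells without rest spikes: half-count regulariser active",
            int(np.sum(c_rest[:, 0] == 0)),
        )
    thresholds = np.empty(r.n_cells)
    for c in range(r.n_cells):
        shifts = random_row_shifts(n_shuffles, r.n_frames, rng)
        ratios = (c_loco[c, shifts] + 0.5) / (c_rest[c, shifts] + 0.5)
        thresholds[c] = np.percentile(ratios, ratio_pctile)
    ratio_sig = real_ratio > thresholds
    return LocomotionModulation(
        zpsths, onset_sig, ratio_sig, onset_sig | ratio_sig,
        real_ratio, thresholds,
    )


def detect_sces(
    r: ActivityRaster,
    rest: EpochSet,
    bin_ms: float = 200.0,
    n_surrogates: int = 1000,
    pctile: float = 99.0,
    min_sep_s: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> SCECatalog:
    """Detect SCEs in rest-restricted 200 ms bins.

    The population spike count per rest bin is thresholded at the
    ``pctile`` percentile of the pooled per-bin sums of ``n_surrogates``
    per-cell circular-shift surrogates of the binned matrix; bins
    strictly above threshold are kept greedily at >= ``min_sep_s``
    separation (highest first).  All SCEs lie inside rest epochs by
    construction.
    """
    rng = np.random.default_rng(rng)
    bin_s = bin_ms / 1000.0
    if rest.n_epochs == 0:
        return SCECatalog(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            r.frame_rate_hz, bin_s, np.empty(0, dtype=np.int64),
            rest_duration_s=0.0,
        )
    counts, bin_frames = bin_raster(r, bin_ms, rest)
    n_bins = counts.shape[1]
    if n_bins < 10:
        raise ValueError(f"rest epochs cover only {n_bins} bins (< 10)")
    sums = counts.sum(axis=0)
    total = counts.sum(axis=1)

    # Pool surrogate per-bin sums into an integer histogram.
    cells, bins = np.nonzero(counts)
    vals = counts[cells, bins]
    max_sum = int(total.sum())
    hist = np.zeros(max_sum + 1, dtype=np.int64)
    for _ in range(n_surrogates):
        shifts = random_row_shifts(r.n_cells, n_bins, rng)
        moved = (bins + shifts[cells]) % n_bins
        s = np.bincount(moved, weights=vals, minlength=n_bins).astype(np.int64)
        hist += np.bincount(s, minlength=max_sum + 1)
    threshold = hist_percentile(hist, pctile)

    candidates = np.flatnonzero(sums > threshold)
    times_s = bin_frames[:, 0] / r.frame_rate_hz
    kept = greedy_separated_peaks(sums.astype(float), candidates, times_s,
                                  min_sep_s)
    participants = [np.flatnonzero(counts[:, b] > 0) for b in kept]
    return SCECatalog(
        kept, bin_frames[kept, 0], r.frame_rate_hz, bin_s,
        sums[kept], participants, float(threshold),
        rest_duration_s=rest.duration_s(r.frame_rate_hz),
    )


def classify_sce_on(
    r: ActivityRaster,
    cat: SCECatalog,
    window_s: float = 4.0,
    z_thresh: float = 3.0,
) -> SCEModulation:
    """Classify SCE-ON cells from the zero-lag bin of the SCE Z-PSTH.

    PSTHs are aligned on SCE bin-start frames (``window_s`` window,
    1-frame bins) and z-scored against the pre-event half-window.  A
    cell is SCE-ON iff Z at zero lag strictly exceeds ``z_thresh``;
    cells whose baseline SD is zero are flagged indeterminate.
    """
    if cat.n_sces == 0:
        raise ValueError("no SCE available for alignment")
    fs = r.frame_rate_hz
    half = int(round(window_s / 2 * fs))
    counts, n_events = _event_psths(r.onsets, cat.frames, half)
    offsets_s = np.arange(-half, half + 1) / fs
    baseline_mask = offsets_s < 0
    zero_bin = half

    zpsths: list[ZPSTH] = []
    sce_on = np.zeros(r.n_cells, dtype=bool)
    indeterminate = np.zeros(r.n_cells, dtype=bool)
    for c in range(r.n_cells):
        zp = _make_zpsth("SCE", counts[c], n_events, half, fs, baseline_mask)
        zpsths.append(zp)
        if not zp.valid:
            indeterminate[c] = True
        else:
            sce_on[c] = bool(zp.z[zero_bin] > z_thresh)
    return SCEModulation(zpsths, sce_on, indeterminate)
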