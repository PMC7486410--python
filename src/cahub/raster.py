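"""Core raster data model, binning, circular-shift surrogates and epochs.

Conventions used throughout the package:

* frames are 0-based; all intervals are half-open ``[start, end)``;
* rasters are binary ``uint8`` matrices of shape ``(n_cells, n_frames)``
  holding event *onsets* (at most one per cell per frame);
* circular-shift surrogates rotate each cell's row by an independent
  uniform offset, preserving per-cell rates while destroying cross-cell
  timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ActivityRaster:
    """Binary onset raster with acquisition frame rate.

    Parameters
    ----------
    onsets
        ``(n_cells, n_frames)`` matrix with entries in {0, 1}.
    frame_rate_hz
        Acquisition rate in frames per second (> 0).
    cell_ids
        One label per cell; defaults to ``"cell000"``-style labels.
    tag
        Optional per-cell annotation (e.g. ``"ebGABA"`` vs ``"ctrl"``).
    """

    onsets: np.ndarray
    frame_rate_hz: float
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]
    tag: list[str] | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets)
        if self.onsets.ndim != 2:
            raise ValueError("onsets must be a 2-D (n_cells, n_frames) matrix")
        vals = np.unique(self.onsets)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("onset matrix entries must be 0 or 1")
        self.onsets = self.onsets.astype(np.uint8)
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:03d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("cell_ids length must equal n_cells")
        if self.tag is not None and len(self.tag) != self.n_cells:
            raise ValueError("tag length must equal n_cells")

    @property
    def n_cells(self) -> int:
        return self.onsets.shape[0]

    @property
    def n_frames(self) -> int:
        return self.onsets.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class EpochSet:
    """Labelled set of sorted, pairwise-disjoint half-open frame intervals."""

    label: str
    intervals: np.ndarray  # (n, 2) int array of [start, end)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if np.any(iv[:, 1] <= iv[:, 0]):
            raise ValueError("empty or inverted interval in EpochSet")
        if np.any(iv[:, 0] < 0):
            raise ValueError("negative frame index in EpochSet")
        order = np.argsort(iv[:, 0])
        iv = iv[order]
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("overlapping intervals in EpochSet")
        self.intervals = iv

    @property
    def n_epochs(self) -> int:
        return len(self.intervals)

    @property
    def total_frames(self) -> int:
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def duration_s(self, frame_rate_hz: float) -> float:
        return self.total_frames / frame_rate_hz

    def mask(self, n_frames: int) -> np.ndarray:
        """Boolean per-frame membership mask of length ``n_frames``."""
        m = np.zeros(n_frames, dtype=bool)
        for s, e in self.intervals:
            m[s:e] = True
        return m

    def onset_frames(self) -> np.ndarray:
        """Start frame of every epoch (e.g. locomotion onsets)."""
        return self.intervals[:, 0].copy()

    @classmethod
    def from_mask(cls, label: str, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return cls(label, np.column_stack([starts, ends]))

    def __iter__(self):
        return iter(tuple(iv) for iv in self.intervals)


@dataclass
class StimulationProtocol:
    """Single-cell phasic stimulation protocol for slice sessions.

    The recording is split into three contiguous epochs (pre / stim /
    post); stimulation pulses are delivered at ``stim_rate_hz`` during
    the stim epoch and each pulse is followed by a trial window of
    ``trial_len_frames`` frames.
    """

    stim_frames: np.ndarray
    trial_len_frames: int
    pre: tuple[int, int]
    stim: tuple[int, int]
    post: tuple[int, int]
    stim_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        self.stim_frames = np.asarray(self.stim_frames, dtype=np.int64)
        if np.any(np.diff(self.stim_frames) <= 0):
            raise ValueError("stim_frames must be strictly increasing")
        if self.trial_len_frames < 1:
            raise ValueError("trial_len_frames must be >= 1")
        s0, s1 = self.stim
        if len(self.stim_frames) and (
            self.stim_frames[0] < s0 or self.stim_frames[-1] >= s1
        ):
            raise ValueError("stim_frames must lie inside the stim epoch")
        if len(self.stim_frames) and (
            self.stim_frames[-1] + self.trial_len_frames > self.post[1]
        ):
            raise ValueError("trials must not extend past the recording end")

    @property
    def n_trials(self) -> int:
        return len(self.stim_frames)

    def trial_spacing_frames(self) -> int:
        if len(self.stim_frames) < 2:
            return self.trial_len_frames
        return int(np.median(np.diff(self.stim_frames)))


def bin_raster(
    r: ActivityRaster,
    bin_ms: float,
    restrict: EpochSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a raster into non-overlapping windows, optionally epoch-wise.

    Binning restarts at the beginning of each epoch so that no bin
    straddles two epochs; trailing partial bins are dropped.

    Parameters
    ----------
    r
        Input raster.
    bin_ms
        Bin width in milliseconds; must be at least one frame period.
    restrict
        Restrict binning to these epochs.  ``None`` bins the full
        recording as a single epoch.

    Returns
    -------
    counts : ``(n_cells, n_bins)`` int array
        Per-cell onset counts per bin.
    bin_frames : ``(n_bins, 2)`` int array
        Half-open frame interval ``[start, end)`` covered by each bin.
    """
    frames_per_bin = bin_ms * r.frame_rate_hz / 1000.0
    if frames_per_bin < 1.0 - 1e-9:
        raise ValueError(
            f"bin of {bin_ms} ms is smaller than one frame period "
            f"({1000.0 / r.frame_rate_hz:.2f} ms)"
        )
    bf = int(round(frames_per_bin))
    intervals = (
        restrict.intervals
        if restrict is not None
        else np.array([[0, r.n_frames]], dtype=np.int64)
    )
    counts_parts: list[np.ndarray] = []
    frame_parts: list[np.ndarray] = []
    for s, e in intervals:
        n_full = (e - s) // bf
        if n_full == 0:
            continue
        block = r.onsets[:, s : s + n_full * bf]
        counts_parts.append(
            block.reshape(r.n_cells, n_full, bf).sum(axis=2)
        )
        starts = s + bf * np.arange(n_full, dtype=np.int64)
        frame_parts.append(np.column_stack([starts, starts + bf]))
    if not counts_parts:
        return (
            np.zeros((r.n_cells, 0), dtype=np.int64),
            np.zeros((0, 2), dtype=np.int64),
        )
    return (
        np.concatenate(counts_parts, axis=1).astype(np.int64),
        np.concatenate(frame_parts, axis=0),
    )


def random_row_shifts(
    n_rows: int, n_cols: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent uniform circular offsets, one per row.

    Offset 0 is excluded whenever the row length permits, so surrogates
    always differ from the data (conservative null).
    """
    if n_cols > 1:
        return rng.integers(1, n_cols, size=n_rows)
    return np.zeros(n_rows, dtype=np.int64)


def roll_rows(mat: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Circularly shift each row of ``mat`` by its own offset."""
    n_rows, n_cols = mat.shape
    idx = (np.arange(n_cols)[None, :] - np.asarray(shifts)[:, None]) % n_cols
    return mat[np.arange(n_rows)[:, None], idx]


def circular_shift_surrogate(
    data: ActivityRaster | np.ndarray, rng: np.random.Generator
) -> ActivityRaster | np.ndarray:
    """Build one circular-shift surrogate of a raster or count matrix.

    Each row is rotated by an independent uniform offset, so per-cell
    totals (hence rates) are exactly conserved while the temporal
    relationship between cells is destroyed.
    """
    if isinstance(data, ActivityRaster):
        shifted = circular_shift_surrogate(data.onsets, rng)
        return ActivityRaster(
            shifted, data.frame_rate_hz, list(data.cell_ids),
            None if data.tag is None else list(data.tag),
        )
    mat = np.asarray(data)
    if mat.ndim != 2 or mat.shape[1] < 2:
        if mat.ndim == 2 and mat.shape[1] == 1:
            return mat.copy()
        raise ValueError("need a 2-D matrix with >= 2 time points")
    shifts = random_row_shifts(mat.shape[0], mat.shape[1], rng)
    return roll_rows(mat, shifts)


def derive_epochs(
    movement: np.ndarray,
    frame_rate_hz: float,
    n_frames: int | None = None,
    min_rest_s: float = 0.2,
) -> tuple[EpochSet, EpochSet]:
    """Split a recording into locomotion and rest epochs.

    Locomotion epochs are maximal runs of frames with treadmill
    photo-sensor deflection; rest epochs are maximal movement-free runs
    strictly longer than ``min_rest_s`` (movement-free gaps of at most
    ``min_rest_s`` belong to neither epoch set).

    Parameters
    ----------
    movement
        Per-frame boolean deflection flag, or a sensor deflection series
        (nonzero treated as movement).
    frame_rate_hz
        Acquisition rate.
    n_frames
        Expected signal length; a mismatch raises ``ValueError``.
    min_rest_s
        Minimal (exclusive) duration of a movement-free run to count as
        rest; default 0.2 s.
    """
    sig = np.asarray(movement)
    if sig.ndim != 1:
        raise ValueError("movement signal must be 1-D")
    if n_frames is not None and len(sig) != n_frames:
        raise ValueError(
            f"movement signal length {len(sig)} != n_frames {n_frames}"
        )
    moving = sig.astype(bool)
    loco = EpochSet.from_mask("locomotion", moving)
    still = EpochSet.from_mask("rest", ~moving)
    keep = (
        (still.intervals[:, 1] - still.intervals[:, 0]) / frame_rate_hz
        > min_rest_s
    )
    rest_iv = still.intervals[keep]
    rest = EpochSet("rest", rest_iv.reshape(-1, 2)) if len(rest_iv) else EpochSet(
        "rest", np.zeros((0, 2), dtype=np.int64)
    )
    return loco, rest
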