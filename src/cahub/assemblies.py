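"""ICA-based cell-assembly detection, activity tracking and modulation.

The detection pipeline (Lopes-dos-Santos-style PCA/ICA on binned spike
counts) runs on rest-restricted 200 ms bins:

1. bin, convolve each cell's counts with a Gaussian kernel (circular
   boundary), z-score per cell;
2. count significant patterns as the number of principal-component
   variances above the maximum eigenvalue observed across circularly
   shifted count matrices;
3. extract that many independent components from the PCA-projected data;
   assembly patterns are the back-projected, unit-norm mixing columns
   (sign-aligned so the largest-magnitude weight is positive).

Assembly activity is the quadratic projection
``R_k(t) = z(t)^T P_k z(t)`` with ``P_k = w_k w_k^T`` and a zeroed
diagonal, so a single cell never drives its own assembly's activity.

Per-cell assembly modulation cross-correlates raw spike counts with each
activity trace (8 s window), averages across assemblies, and compares
the five central bins with a per-cell 95th-percentile circular-shift
threshold (two consecutive suprathreshold bins required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import FastICA

from cahub._util import circular_cross_correlation, two_consecutive
from cahub.raster import ActivityRaster, EpochSet, bin_raster, random_row_shifts, roll_rows

logger = logging.getLogger(__name__)


@dataclass
class AssemblySet:
    """Significant co-activation patterns of one session."""

    patterns: np.ndarray            # (n_significant, n_cells), unit norm
    activities: np.ndarray          # (n_significant, n_bins)
    eigenvalues: np.ndarray         # PC variances, descending
    threshold: float                # max shuffled eigenvalue
    zcounts: np.ndarray             # (n_cells, n_bins) smoothed z-scored counts
    bin_frames: np.ndarray          # (n_bins, 2) frame intervals
    bin_s: float
    kept_cells: np.ndarray          # indices of non-zero-variance cells
    underdetermined: bool = False

    @property
    def n_significant(self) -> int:
        return len(self.patterns)

    def projection_matrix(self, k: int) -> np.ndarray:
        """Outer-product projector of pattern ``k`` with zeroed diagonal."""
        w = self.patterns[k]
        P = np.outer(w, w)
        np.fill_diagonal(P, 0.0)
        return P


@dataclass
class AssemblyModulation:
    """Per-cell modulation by assembly activity."""

    mean_correlogram: np.ndarray    # (n_cells, n_lags)
    lags_s: np.ndarray
    thresholds: np.ndarray          # per-cell 95th percentile
    significant: np.ndarray
    assessable: bool = True


def _preprocess(
    r: ActivityRaster,
    rest: EpochSet | None,
    bin_ms: float,
    kernel_sd_bins: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin, smooth (circular Gaussian) and z-score; drop flat cells."""
    counts, bin_frames = bin_raster(r, bin_ms, rest)
    smoothed = gaussian_filter1d(
        counts.astype(float), kernel_sd_bins, axis=1, mode="wrap"
    )
    sd = smoothed.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < r.n_cells:
        logger.info("dropping %d zero-variance cells", r.n_cells - len(kept))
    z = (smoothed[kept] - smoothed[kept].mean(axis=1, keepdims=True)) / sd[
        kept, None
    ]
    return z, bin_frames, kept


def detect_assemblies(
    r: ActivityRaster,
    rest: EpochSet | None,
    bin_ms: float = 200.0,
    kernel_sd_bins: float = 1.0,
    n_shuffles: int = 500,
    rng: np.random.Generator | int | None = None,
    ica_max_iter: int = 1000,
) -> AssemblySet:
    """Detect significant co-activation patterns during rest.

    The significance threshold for the pattern count is the maximum
    eigenvalue of the cell-correlation matrix over ``n_shuffles``
    circularly shifted count matrices (the smoothing kernel uses a
    circular boundary, so shifting commutes with smoothing and
    z-scoring and the shuffle can roll the preprocessed rows directly).
    """
    rng = np.random.default_rng(rng)
    if r.n_cells < 2:
        raise ValueError("need at least two cells")
    z, bin_frames, kept = _preprocess(r, rest, bin_ms, kernel_sd_bins)
    n_kept, n_bins = z.shape
    underdetermined = n_bins < n_kept
    if underdetermined:
        logger.warning(
            "fewer rest bins (%d) than cells (%d): eigenvalue threshold "
            "is under-determined", n_bins, n_kept,
        )
    corr = z @ z.T / n_bins
    eigvals, eigvecs = np.linalg.eigh(corr)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]

    lam_max = 0.0
    for _ in range(n_shuffles):
        shifts = random_row_shifts(n_kept, n_bins, rng)
        zs = roll_rows(z, shifts)
        lam = np.linalg.eigvalsh(zs @ zs.T / n_bins)[-1]
        lam_max = max(lam_max, float(lam))
    n_sig = int(np.sum(eigvals > lam_max))

    bin_s = bin_frames[0, 1] - bin_frames[0, 0] if len(bin_frames) else 0
    bin_s = bin_s / r.frame_rate_hz
    if n_sig == 0:
        return AssemblySet(
            np.zeros((0, r.n_cells)), np.zeros((0, n_bins)), eigvals,
            lam_max, z, bin_frames, bin_s, kept, underdetermined,
        )

    V = eigvecs[:, :n_sig]                       # (n_kept, k)
    zproj = V.T @ z                              # (k, n_bins)
    ica = FastICA(
        n_components=n_sig,
        whiten="unit-variance",
        max_iter=ica_max_iter,
        random_state=int(rng.integers(2**31)),
    )
    ica.fit(zproj.T)
    mixing = ica.mixing_                         # (k, k)
    pat_kept = V @ mixing                        # (n_kept, k)
    pat_kept /= np.linalg.norm(pat_kept, axis=0, keepdims=True)
    flip = np.sign(pat_kept[np.argmax(np.abs(pat_kept), axis=0),
                            np.arange(n_sig)])
    pat_kept *= flip
    patterns = np.zeros((n_sig, r.n_cells))
    patterns[:, kept] = pat_kept.T

    activities = compute_assembly_activity_kept(pat_kept.T, z)
    return AssemblySet(
        patterns, activities, eigvals, lam_max, z, bin_frames, bin_s, kept,
        underdetermined,
    )


def compute_assembly_activity_kept(
    patterns: np.ndarray, zcounts: np.ndarray
) -> np.ndarray:
    """Quadratic assembly activities for patterns over the same cell set.

    ``R_k(t) = (w_k . z(t))^2 - sum_i w_ki^2 z_i(t)^2`` — the quadratic
    form of the zero-diagonal projector, invariant to sign flips of
    ``w_k``.
    """
    if patterns.shape[1] != zcounts.shape[0]:
        raise ValueError(
            f"pattern length {patterns.shape[1]} != number of cells "
            f"{zcounts.shape[0]}"
        )
    proj = patterns @ zcounts                    # (k, n_bins)
    diag = (patterns**2) @ (zcounts**2)
    return proj**2 - diag


def compute_assembly_activity(
    aset: AssemblySet, zcounts: np.ndarray | None = None
) -> np.ndarray:
    """Activity time series of each assembly pattern.

    ``zcounts`` must come from the same preprocessing as detection
    (defaults to the stored matrix).  Rows correspond to the kept cells
    of the assembly set.
    """
    if zcounts is None:
        zcounts = aset.zcounts
    patterns = aset.patterns[:, aset.kept_cells]
    return compute_assembly_activity_kept(patterns, zcounts)


def test_assembly_modulation(
    r: ActivityRaster,
    aset: AssemblySet,
    rest: EpochSet | None,
    window_s: float = 8.0,
    bin_ms: float = 200.0,
    n_shuffles: int = 100,
    pctile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> AssemblyModulation:
    """Test which cells are modulated by assembly activity.

    Each cell's raw binned spike counts are cross-correlated with every
    assembly activity over ``+/- window_s / 2`` and averaged across
    assemblies.  The per-cell threshold is the ``pctile`` percentile of
    the pooled correlogram values obtained under circular shifts of the
    cell's counts; a cell is significant if at least two consecutive of
    the five bins around zero lag exceed it.  Circularly shifted
    correlograms are exact windows of the full circular
    cross-correlation, so the surrogate distribution is computed without
    re-correlating.
    """
    rng = np.random.default_rng(rng)
    if aset.n_significant == 0:
        return AssemblyModulation(
            np.zeros((r.n_cells, 0)), np.empty(0), np.full(r.n_cells, np.nan),
            np.zeros(r.n_cells, dtype=bool), assessable=False,
        )
    counts, bin_frames = bin_raster(r, bin_ms, rest)
    n_bins = counts.shape[1]
    if n_bins != aset.activities.shape[1]:
        raise ValueError("binning mismatch between counts and activities")
    L = int(round(window_s / 2 / aset.bin_s))
    lags = np.arange(-L, L + 1)
    lags_s = lags * aset.bin_s

    # full[c, m] = mean over assemblies of sum_t counts[c, t] * R[k, t+m] / B
    full = np.zeros((r.n_cells, n_bins))
    x = counts.astype(float)
    for k in range(aset.n_significant):
        full += circular_cross_correlation(x, aset.activities[k][None, :])
    full /= aset.n_significant * n_bins

    real = full[:, lags % n_bins]
    shifts = random_row_shifts(n_shuffles, n_bins, rng)
    # surrogate correlogram of cell c at shift s and lag m is full[c, (m+s) % B]
    surr_idx = (lags[None, :] + shifts[:, None]) % n_bins
    thresholds = np.empty(r.n_cells)
    for c in range(r.n_cells):
        thresholds[c] = np.percentile(full[c, surr_idx], pctile)

    centre = len(lags) // 2
    central = real[:, centre - 2 : centre + 3]
    above = central > thresholds[:, None]
    significant = np.array([two_consecutive(row) for row in above])
    return AssemblyModulation(real, lags_s, thresholds, significant)


# library operation, not a pytest case
test_assembly_modulation.__test__ = False   # type: ignore[attr-defined]
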