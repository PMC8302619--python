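"""Puncta segmentation by seeded radial growth around local intensity maxima.

The segmenter identifies local maxima above a per-image seed threshold,
derives a per-spot border intensity from the radial distribution of pixel
intensities around each maximum, then grows each spot outward accepting
pixels that are above the border, no brighter than the accepted neighbour
through which they are reached (monotone descent), and 4-adjacent to the
growing region.  Centroids are intensity-weighted and sub-pixel.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import local_maxima

from .core import CellMask, ImageStack


@dataclass
class Punctum:
    """One segmented spot (need not be circular)."""

    id: int
    frame: int
    centroid_x_nm: float
    centroid_y_nm: float
    pixel_set: np.ndarray               # (k, 2) of (y, x) indices, 4-connected
    integrated_intensity_fu: float      # sum of (I - border) over the pixel set
    peak_intensity_fu: float
    border_threshold_fu: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)


@dataclass
class SpotConfig:
    """Segmentation parameters.

    ``seed_threshold_fu`` overrides the adaptive per-image threshold
    (background median + ``k_sigma`` robust s.d.), mirroring per-image
    threshold selection.  ``smooth_sigma_px`` Gaussian-smooths the working
    image before detection and growth (0 disables); all punctum measurements
    are made on the working image.
    """

    seed_threshold_fu: float | None = None
    k_sigma: float = 5.0
    smooth_sigma_px: float = 1.0
    flatten_tol: float = 0.05
    r_max_px: int = 10
    max_spot_pixels: int = 10000
    localizer: str = "gaussian_fit"     # "gaussian_fit" | "region"
    localizer_radius_px: int = 4


@dataclass
class SegmentationResult:
    puncta: list[Punctum]
    n_frames: int
    pixel_size_nm: float
    params: dict = field(default_factory=dict)

    def frame_puncta(self, t: int) -> list[Punctum]:
        return [p for p in self.puncta if p.frame == t]

    def centroids_nm(self, frame: int | None = None) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in nm."""
        pts = self.puncta if frame is None else self.frame_puncta(frame)
        if not pts:
            return np.zeros((0, 2))
        return np.array([[p.centroid_x_nm, p.centroid_y_nm] for p in pts])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "frame": p.frame, "id": p.id,
                "x_nm": p.centroid_x_nm, "y_nm": p.centroid_y_nm,
                "n_pixels": p.n_pixels,
                "integrated_FU": p.integrated_intensity_fu,
                "peak_FU": p.peak_intensity_fu,
                "border_FU": p.border_threshold_fu,
            }
            for p in self.puncta
        ]
        return pd.DataFrame(
            rows, columns=["frame", "id", "x_nm", "y_nm", "n_pixels",
                           "integrated_FU", "peak_FU", "border_FU"])


def find_local_maxima(frame: np.ndarray, seed_threshold_fu: float) -> list[tuple[int, int]]:
    """Pixels strictly greater than all 8-neighbours and >= the seed threshold.

    Plateau maxima are reduced to their lexicographically smallest (y, x)
    pixel.  Returns seeds sorted by decreasing intensity (ties by (y, x)).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.max() == frame.min():
        return []
    peaks = local_maxima(frame, connectivity=2, allow_borders=True)
    peaks &= frame >= seed_threshold_fu
    if not peaks.any():
        return []
    # collapse plateaus: one seed per connected component of the maxima mask
    lab, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
    seeds = []
    for sl in ndimage.find_objects(lab):
        comp = np.argwhere(lab[sl] > 0)
        comp = comp + np.array([sl[0].start, sl[1].start])
        # lexicographic min of (y, x)
        k = np.lexsort((comp[:, 1], comp[:, 0]))[0]
        seeds.append((int(comp[k, 0]), int(comp[k, 1])))
    seeds.sort(key=lambda yx: (-frame[yx], yx))
    return seeds


def radial_border_threshold(frame: np.ndarray, seed: tuple[int, int],
                            r_max_px: int = 10, flatten_tol: float = 0.05) -> float:
    """Border intensity from the radial distribution around a local maximum.

    Mean intensities are computed in concentric 1-px-wide rings around the
    seed out to ``r_max_px`` (rings truncated at image edges).  The border is
    the ring mean at the first radius where the profile flattens — relative
    drop between successive rings below ``flatten_tol`` — i.e. the local
    background shoulder of the spot.  Falls back to the outermost ring mean
    if the profile never flattens.
    """
    frame = np.asarray(frame, dtype=np.float64)
    ny, nx = frame.shape
    sy, sx = seed
    y0, y1 = max(sy - r_max_px, 0), min(sy + r_max_px + 1, ny)
    x0, x1 = max(sx - r_max_px, 0), min(sx + r_max_px + 1, nx)
    win = frame[y0:y1, x0:x1]
    yy = np.arange(y0, y1)[:, None] - sy
    xx = np.arange(x0, x1)[None, :] - sx
    d = np.hypot(yy, xx)
    means = []
    for r in range(r_max_px + 1):
        ring = (d >= r - 0.5) & (d < r + 0.5) if r > 0 else d < 0.5
        if not ring.any():
            break
        means.append(float(win[ring].mean()))
    for r in range(1, len(means)):
        prev = means[r - 1]
        drop = (prev - means[r]) / prev if prev > 1e-12 else 0.0
        if drop < flatten_tol:
            return means[r]
    return means[-1]


def grow_spot(frame: np.ndarray, seed: tuple[int, int], border_threshold_fu: float,
              claimed: np.ndarray | None = None,
              max_pixels: int = 10000) -> Punctum | None:
    """Grow one spot from a seed maximum by monotone-descent region growing.

    Pixels are visited in order of decreasing intensity starting from the
    seed; a pixel is accepted iff its intensity is above the border
    threshold, no greater than the accepted 4-neighbour through which it is
    reached, and (by construction) 4-adjacent to the region.  Pixels already
    ``claimed`` by previously grown spots are never taken.  Returns ``None``
    if the seed itself is not above the border or already claimed.

    Centroid coordinates are in pixels here; calibration to nm happens in
    :func:`segment_spots`.
    """
    frame = np.asarray(frame, dtype=np.float64)
    ny, nx = frame.shape
    sy, sx = seed
    if claimed is not None and claimed[sy, sx]:
        return None
    if frame[sy, sx] <= border_threshold_fu:
        return None
    accepted: list[tuple[int, int]] = []
    in_region = np.zeros((ny, nx), dtype=bool)
    dead = np.zeros((ny, nx), dtype=bool)   # rejected on intensity: permanent
    heap: list[tuple[float, int, int, float]] = [(-frame[sy, sx], sy, sx, math.inf)]
    while heap and len(accepted) < max_pixels:
        negint, y, x, parent_int = heapq.heappop(heap)
        if in_region[y, x] or dead[y, x]:
            continue
        if claimed is not None and claimed[y, x]:
            dead[y, x] = True
            continue
        i = -negint
        if i <= border_threshold_fu:
            dead[y, x] = True
            continue
        if i > parent_int:
            # not reachable through this parent; other queued entries may still
            # accept it via a brighter neighbour
            continue
        in_region[y, x] = True
        accepted.append((y, x))
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yn, xn = y + dy, x + dx
            if 0 <= yn < ny and 0 <= xn < nx and not in_region[yn, xn] and not dead[yn, xn]:
                heapq.heappush(heap, (-frame[yn, xn], yn, xn, i))
    pix = np.array(accepted, dtype=int)
    weights = frame[pix[:, 0], pix[:, 1]] - border_threshold_fu
    cy, cx = (weights[:, None] * pix).sum(axis=0) / weights.sum()
    return Punctum(
        id=-1, frame=-1,
        centroid_x_nm=float(cx), centroid_y_nm=float(cy),  # px for now
        pixel_set=pix,
        integrated_intensity_fu=float(weights.sum()),
        peak_intensity_fu=float(frame[sy, sx]),
        border_threshold_fu=float(border_threshold_fu),
    )


def refine_centroid_gaussian(raw: np.ndarray, seed: tuple[int, int],
                             background: float, radius_px: int = 4
                             ) -> tuple[float, float] | None:
    """Sub-pixel centroid from a 2-D Gaussian least-squares fit on the raw frame.

    Fits amplitude, centre, width and offset in a ``(2r+1)²`` window around
    the seed.  Returns (y, x) in pixels, or ``None`` when the fit fails or
    wanders more than 2 px from the seed (caller falls back to the region
    centroid).
    """
    from scipy.optimize import curve_fit

    ny, nx = raw.shape
    sy, sx = seed
    y0, y1 = max(sy - radius_px, 0), min(sy + radius_px + 1, ny)
    x0, x1 = max(sx - radius_px, 0), min(sx + radius_px + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    z = raw[y0:y1, x0:x1].ravel()

    def model(_, a, cy, cx, s, off):
        return (a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
                + off).ravel()

    import warnings

    from scipy.optimize import OptimizeWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                model, None, z,
                p0=[max(raw[sy, sx] - background, 1e-6), sy, sx, 1.2, background],
                maxfev=200)
    except RuntimeError:
        return None
    cy, cx = float(popt[1]), float(popt[2])
    if math.hypot(cy - sy, cx - sx) > 2.0:
        return None
    return cy, cx


def estimate_seed_threshold(frame: np.ndarray, k_sigma: float = 5.0) -> float:
    """Robust per-image seed threshold: median + k · (1.4826·MAD)."""
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med + k_sigma * 1.4826 * mad


def segment_spots(stack: ImageStack, config: SpotConfig | None = None) -> SegmentationResult:
    """Segment puncta in every frame of a background-corrected stack.

    Seeds are processed in decreasing seed-intensity order; contested pixels
    belong to the first spot that claims them.  Deterministic for identical
    input and configuration.
    """
    config = config or SpotConfig()
    puncta: list[Punctum] = []
    next_id = 0
    for t in range(stack.n_frames):
        raw = stack.frame(t).astype(np.float64)
        work = (ndimage.gaussian_filter(raw, config.smooth_sigma_px)
                if config.smooth_sigma_px > 0 else raw)
        thr = (config.seed_threshold_fu if config.seed_threshold_fu is not None
               else estimate_seed_threshold(work, config.k_sigma))
        seeds = find_local_maxima(work, thr)
        claimed = np.zeros(work.shape, dtype=bool)
        for seed in seeds:
            if claimed[seed]:
                continue
            border = radial_border_threshold(work, seed, config.r_max_px,
                                             config.flatten_tol)
            p = grow_spot(work, seed, border, claimed=claimed,
                          max_pixels=config.max_spot_pixels)
            if p is None:
                continue
            claimed[p.pixel_set[:, 0], p.pixel_set[:, 1]] = True
            if config.localizer == "gaussian_fit":
                refined = refine_centroid_gaussian(raw, seed, border,
                                                   config.localizer_radius_px)
                if refined is not None:
                    p.centroid_y_nm, p.centroid_x_nm = refined
            p.id = next_id
            p.frame = t
            p.centroid_x_nm *= stack.pixel_size_nm
            p.centroid_y_nm *= stack.pixel_size_nm
            puncta.append(p)
            next_id += 1
    params = {
        "seed_threshold_fu": config.seed_threshold_fu, "k_sigma": config.k_sigma,
        "smooth_sigma_px": config.smooth_sigma_px, "flatten_tol": config.flatten_tol,
        "r_max_px": config.r_max_px,
    }
    return SegmentationResult(puncta, stack.n_frames, stack.pixel_size_nm, params)


def puncta_fluorescence_fraction(seg: SegmentationResult, stack: ImageStack,
                                 mask: CellMask) -> np.ndarray:
    """Fraction of whole-cell fluorescence attributed to puncta, per frame.

    Numerator: sum of punctum integrated (above-border) intensities in the
    frame; denominator: total intensity within the cell mask.  A consistency
    check on segmentation thresholds.
    """
    out = np.zeros(stack.n_frames)
    for t in range(stack.n_frames):
        total = float(stack.frame(t)[mask.mask].sum())
        if total <= 0:
            raise ValueError(f"zero whole-cell fluorescence in frame {t}")
        spot_sum = sum(p.integrated_intensity_fu for p in seg.frame_puncta(t))
        out[t] = min(spot_sum / total, 1.0)
    return out


def match_to_truth(detected_xy_nm: np.ndarray, truth_xy_nm: np.ndarray,
                   tol_nm: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth points.

    Returns (n_matched, n_detected, n_truth); recall = matched/truth,
    precision = matched/detected.  Used by recovery tests and reports.
    """
    det = np.atleast_2d(detected_xy_nm)
    tru = np.atleast_2d(truth_xy_nm)
    if det.size == 0 or tru.size == 0:
        return 0, len(det), len(tru)
    d = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
    matched = 0
    used_det = np.zeros(len(det), dtype=bool)
    used_tru = np.zeros(len(tru), dtype=bool)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > tol_nm:
            break
        if used_det[i] or used_tru[j]:
            continue
        used_det[i] = used_tru[j] = True
        matched += 1
    return matched, len(det), len(tru)
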