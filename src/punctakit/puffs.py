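"""Ca2+ puff detection, site mapping and fluorescence-to-[Ca2+] calibration.

Local Ca2+-release events are detected on ΔF/F₀ movies by spatial Gaussian
smoothing, amplitude thresholding and space-time connected-component
labelling; events recurring at (nearly) the same position are grouped into
release sites by single-linkage clustering.  Whole-cell responses can be
expressed as ΔF/F_max against the Ca2+-saturated indicator, and population
fluorescence is calibrated with [Ca2+] = K_D (F − F_min)/(F_max − F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .core import ImageStack


@dataclass
class PuffEvent:
    """One detected transient local Ca2+-release event."""

    centroid_x_nm: float
    centroid_y_nm: float
    t_start_frame: int
    duration_frames: int
    peak_amplitude_dff: float
    site_id: int | None = None


@dataclass
class PuffSite:
    """A fixed location at which successive puffs recur."""

    site_id: int
    centroid_x_nm: float
    centroid_y_nm: float
    events: list[PuffEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class CalibrationParams:
    """Single-site indicator calibration (Fluo-8: K_D = 389 nM)."""

    k_d_nm: float = 389.0
    f_min_fu: float = 0.0
    f_max_fu: float = 1.0

    def __post_init__(self) -> None:
        if self.k_d_nm <= 0:
            raise ValueError("K_D must be > 0")
        if self.f_max_fu <= self.f_min_fu:
            raise ValueError("F_max must exceed F_min")


def compute_dff(stack: ImageStack, baseline_frames: int,
                f_max: float | np.ndarray | None = None
                ) -> tuple[ImageStack, np.ndarray]:
    """ΔF/F₀ (or ΔF/F_max) stack from a raw movie.

    F₀ is the per-pixel temporal mean over the first ``baseline_frames``
    (a pre-stimulus window).  Pixels with non-positive baseline are masked
    out (ΔF/F set to 0) and reported in the returned validity mask.  When
    ``f_max`` is given (scalar or per-pixel saturated-indicator signal), the
    denominator is F_max instead of F₀, giving ΔF/F_max.
    """
    if not 1 <= baseline_frames <= stack.n_frames:
        raise ValueError("baseline_frames out of range")
    data = stack.data.astype(np.float64)
    f0 = data[:baseline_frames].mean(axis=0)
    if f_max is None:
        denom = f0
    else:
        denom = np.broadcast_to(np.asarray(f_max, dtype=np.float64), f0.shape)
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    dff = (data - f0[None]) / safe[None]
    dff[:, ~valid] = 0.0
    out = ImageStack(dff, stack.pixel_size_nm, stack.frame_interval_s,
                     channel_label=stack.channel_label + " dFF")
    return out, valid


def detect_puffs(dff_stack: ImageStack, amp_threshold: float = 0.3,
                 min_duration_frames: int = 2,
                 spatial_sigma_px: float = 1.0,
                 low_threshold: float | None = None,
                 min_voxels: int = 10,
                 merge_radius_nm: float = 500.0,
                 merge_gap_frames: int = 3) -> list[PuffEvent]:
    """Detect transient local events in a ΔF/F₀ movie.

    Frames are Gaussian-smoothed spatially, thresholded at ``amp_threshold``
    (ΔF/F₀ strictly above), and supra-threshold voxels are connected over
    space-time (26-connectivity).  Components smaller than ``min_voxels``
    space-time voxels (isolated noise crossings — real events cover hundreds)
    or shorter than ``min_duration_frames`` are discarded.  A decay tail that
    flickers around the threshold would fragment one event into a train of
    echoes, so events closer than ``merge_radius_nm`` whose temporal gap is
    at most ``merge_gap_frames`` are merged (the echo's amplitude never
    exceeds the parent peak).  ``low_threshold`` optionally enables
    hysteresis: connectivity at the lower value, detection still requiring
    ``amp_threshold``.  Event amplitude is the maximum smoothed ΔF/F₀; the
    centroid is the amplitude-weighted spatial centroid in the peak frame.
    Event counts are monotone non-increasing in both thresholds.
    """
    if amp_threshold <= 0 or min_duration_frames < 1:
        raise ValueError("thresholds must be positive")
    if low_threshold is None:
        low_threshold = amp_threshold
    if not 0 < low_threshold <= amp_threshold:
        raise ValueError("low_threshold must be in (0, amp_threshold]")
    sm = np.empty_like(dff_stack.data, dtype=np.float64)
    for t in range(dff_stack.n_frames):
        sm[t] = (ndimage.gaussian_filter(dff_stack.frame(t), spatial_sigma_px)
                 if spatial_sigma_px > 0 else dff_stack.frame(t))
    above = sm > low_threshold
    lab, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    events: list[PuffEvent] = []
    px = dff_stack.pixel_size_nm
    for cid, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        where = lab[sl] == cid
        if where.sum() < min_voxels:
            continue
        vals = np.where(where, sm[sl], -np.inf)
        pk = np.unravel_index(np.argmax(vals), vals.shape)
        peak_amp = float(vals[pk])
        if peak_amp <= amp_threshold:
            continue
        # event timing from the frames that reach the detection threshold
        core = (vals > amp_threshold).any(axis=(1, 2))
        ts = np.nonzero(core)[0] + sl[0].start
        duration = int(ts[-1] - ts[0] + 1)
        if duration < min_duration_frames:
            continue
        peak_t = pk[0]
        w = np.where(where[peak_t], sm[sl][peak_t], 0.0)
        total = w.sum()
        yy, xx = np.mgrid[sl[1], sl[2]]
        cy = float((w * yy).sum() / total)
        cx = float((w * xx).sum() / total)
        events.append(PuffEvent(
            centroid_x_nm=cx * px, centroid_y_nm=cy * px,
            t_start_frame=int(ts[0]), duration_frames=duration,
            peak_amplitude_dff=peak_amp,
        ))
    events.sort(key=lambda e: (e.t_start_frame, e.centroid_x_nm))
    if merge_gap_frames >= 0 and merge_radius_nm > 0:
        events = _merge_event_echoes(events, merge_radius_nm, merge_gap_frames)
    return events


def _merge_event_echoes(events: list[PuffEvent], radius_nm: float,
                        gap_frames: int) -> list[PuffEvent]:
    """Merge threshold-flicker echoes into their parent event (time-ordered)."""
    merged: list[PuffEvent] = []
    for ev in events:
        parent = None
        for m in merged:
            gap = ev.t_start_frame - (m.t_start_frame + m.duration_frames - 1)
            d = np.hypot(ev.centroid_x_nm - m.centroid_x_nm,
                         ev.centroid_y_nm - m.centroid_y_nm)
            if 0 <= gap <= gap_frames and d <= radius_nm:
                parent = m
                break
        if parent is None:
            merged.append(ev)
            continue
        end = max(parent.t_start_frame + parent.duration_frames,
                  ev.t_start_frame + ev.duration_frames)
        parent.duration_frames = end - parent.t_start_frame
        if ev.peak_amplitude_dff > parent.peak_amplitude_dff:
            parent.peak_amplitude_dff = ev.peak_amplitude_dff
            parent.centroid_x_nm = ev.centroid_x_nm
            parent.centroid_y_nm = ev.centroid_y_nm
    return merged


def assign_sites(events: list[PuffEvent], site_radius_nm: float = 500.0) -> list[PuffSite]:
    """Group events into release sites by single-linkage spatial clustering.

    Events within ``site_radius_nm`` (inclusive: pairs exactly at the cutoff
    merge) chain into one site; the site centroid is the mean of member event
    centroids.  Each event is annotated with its ``site_id``.
    """
    if not events:
        return []
    pts = np.array([[e.centroid_x_nm, e.centroid_y_nm] for e in events])
    if len(events) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pts, method="single"),
                          t=site_radius_nm, criterion="distance")
    sites = []
    for sid in np.unique(labels):
        members = [e for e, l in zip(events, labels) if l == sid]
        for e in members:
            e.site_id = int(sid)
        c = pts[labels == sid].mean(axis=0)
        sites.append(PuffSite(int(sid), float(c[0]), float(c[1]), members))
    return sites


def event_to_puncta_distances(events: list[PuffEvent],
                              puncta_xy_nm) -> np.ndarray:
    """Nearest-neighbour distance (nm) from each event centroid to a punctum set.

    Used to relate Ca2+ puffs to immobile receptor puncta.
    """
    from .coloc import as_points_nm  # avoid import cycle at module load

    if not events:
        raise ValueError("no events")
    pts = as_points_nm(puncta_xy_nm)
    if pts.size == 0:
        raise ValueError("no puncta")
    ev = np.array([[e.centroid_x_nm, e.centroid_y_nm] for e in events])
    d, _ = cKDTree(pts).query(ev, k=1)
    return np.asarray(d, dtype=np.float64)


def calibrate_ca(f, params: CalibrationParams):
    """[Ca2+] in nM from indicator fluorescence.

    [Ca2+] = K_D (F − F_min) / (F_max − F); monotone increasing in F.
    F at the midpoint of the dynamic range returns exactly K_D.
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f >= params.f_max_fu):
        raise ValueError("indicator saturated: F >= F_max")
    if np.any(f < params.f_min_fu):
        raise ValueError("F below F_min")
    ca = params.k_d_nm * (f - params.f_min_fu) / (params.f_max_fu - f)
    return float(ca) if ca.ndim == 0 else ca


def ca_to_fluorescence(ca_nm, params: CalibrationParams):
    """Inverse calibration: F = (F_max·c + K_D·F_min)/(c + K_D)."""
    c = np.asarray(ca_nm, dtype=np.float64)
    f = (params.f_max_fu * c + params.k_d_nm * params.f_min_fu) / (c + params.k_d_nm)
    return float(f) if f.ndim == 0 else f
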