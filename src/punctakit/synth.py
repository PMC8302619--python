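"""Synthetic TIRF-like microscopy data with known ground truth.

Every analysis stage in this package can be exercised against data produced
here: two-channel fields of diffraction-limited puncta with a controllable
colocalized fraction, filament textures, movies of mixed mobile/immobile
particles, fluorescence-recovery curves and movies of transient local
Ca2+-release events on a ΔF/F background.

All generators take a :class:`numpy.random.Generator` or an integer seed and
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .core import CellMask, ImageStack

# ---------------------------------------------------------------------------
# noise


@dataclass
class NoiseModel:
    """Poisson shot noise plus Gaussian read noise (sCMOS/EMCCD approximation).

    ``baseline`` is a uniform camera background added before the Poisson draw;
    when ``subtract_baseline`` is applied the output emulates a
    background-corrected image (clamped at zero).
    """

    poisson: bool = True
    read_noise_sd: float = 0.0
    baseline: float = 0.0

    def apply(self, image: np.ndarray, rng: np.random.Generator,
              subtract_baseline: bool = True) -> np.ndarray:
        out = np.asarray(image, dtype=np.float64) + self.baseline
        if self.poisson:
            out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        if subtract_baseline and self.baseline:
            out = out - self.baseline
        if subtract_baseline:
            np.clip(out, 0.0, None, out=out)
        return out

    def background_sd(self) -> float:
        """Noise s.d. on a background pixel (shot + read, at the baseline)."""
        shot = self.baseline if self.poisson else 0.0
        return math.sqrt(shot + self.read_noise_sd**2)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class PuffEventTruth:
    t_start: int
    duration_frames: int
    centroid_nm: tuple[float, float]  # (x, y)
    peak_dff: float
    site_index: int


@dataclass
class TrajectoryTruth:
    positions_nm: np.ndarray  # (n_frames, 2) observed (x, y), noise included
    mobility_class: str       # immobile | diffusive | directed | confined


@dataclass
class GroundTruth:
    """Known truth accompanying a synthetic data set (fields used as needed)."""

    puncta_a_nm: np.ndarray | None = None      # (n_A, 2) true (x, y) centroids
    puncta_b_nm: np.ndarray | None = None
    colocalized: np.ndarray | None = None      # bool per A centroid
    trajectories: list[TrajectoryTruth] = field(default_factory=list)
    frap_params: dict | None = None
    puff_events: list[PuffEventTruth] = field(default_factory=list)
    filament_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# rendering helpers


def render_gaussian_spots(shape: tuple[int, int], centers_yx_px: np.ndarray,
                          amplitude, sigma_px: float) -> np.ndarray:
    """Render isotropic Gaussian spots (point-sampled at pixel centres).

    The integrated intensity of an isolated spot is ``amplitude * 2πσ²``
    (within 1% when at least 5σ from the image edge).
    """
    img = np.zeros(shape, dtype=np.float64)
    centers = np.atleast_2d(np.asarray(centers_yx_px, dtype=np.float64))
    if centers.size == 0:
        return img
    amps = np.broadcast_to(np.asarray(amplitude, dtype=np.float64), (len(centers),))
    h = max(3, int(math.ceil(5 * sigma_px)))
    ny, nx = shape
    for (yc, xc), a in zip(centers, amps):
        y0, y1 = int(math.floor(yc)) - h, int(math.floor(yc)) + h + 1
        x0, x1 = int(math.floor(xc)) - h, int(math.floor(xc)) + h + 1
        y0c, y1c = max(y0, 0), min(y1, ny)
        x0c, x1c = max(x0, 0), min(x1, nx)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy = np.arange(y0c, y1c, dtype=np.float64)[:, None]
        xx = np.arange(x0c, x1c, dtype=np.float64)[None, :]
        img[y0c:y1c, x0c:x1c] += a * np.exp(
            -((yy - yc) ** 2 + (xx - xc) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def sample_positions_in_mask(rng: np.random.Generator, mask: np.ndarray, n: int,
                             min_spacing_px: float = 0.0,
                             existing_yx: np.ndarray | None = None,
                             exclusion_yx: np.ndarray | None = None,
                             exclusion_radius_px: float = 0.0,
                             max_tries: int = 200) -> np.ndarray:
    """Dart-throw ``n`` continuous positions uniformly inside a binary mask.

    Positions keep ``min_spacing_px`` to each other and to ``existing_yx``,
    and stay at least ``exclusion_radius_px`` away from ``exclusion_yx``.
    Raises ``RuntimeError`` if placement is infeasible after bounded retries.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    placed: list[np.ndarray] = []
    anchor = [] if existing_yx is None or len(existing_yx) == 0 else [np.atleast_2d(existing_yx)]
    for _ in range(n):
        ok = False
        for _try in range(max_tries):
            k = rng.integers(len(ys))
            cand = np.array([ys[k], xs[k]], dtype=np.float64) + rng.uniform(-0.5, 0.5, 2)
            if min_spacing_px > 0:
                pool = placed + anchor
                if pool:
                    allp = np.vstack(pool)
                    if np.min(np.hypot(*(allp - cand).T)) < min_spacing_px:
                        continue
            if exclusion_yx is not None and len(exclusion_yx) > 0 and exclusion_radius_px > 0:
                d = np.hypot(*(np.atleast_2d(exclusion_yx) - cand).T)
                if np.min(d) <= exclusion_radius_px:
                    continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place {n} positions with spacing {min_spacing_px:.1f}px"
            )
    return np.array(placed) if placed else np.zeros((0, 2))


def _yx_px_to_xy_nm(yx_px: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    yx = np.atleast_2d(yx_px)
    return np.column_stack([yx[:, 1], yx[:, 0]]) * pixel_size_nm


# ---------------------------------------------------------------------------
# two-channel puncta fields


def make_puncta_field(
    mask: CellMask,
    n_a: int = 300,
    n_b: int = 300,
    coloc_fraction: float = 0.3,
    offset_radius_nm: float = 80.0,
    psf_sigma_nm: float = 110.0,
    amplitude_fu: float = 100.0,
    noise: NoiseModel | None = None,
    min_spacing_factor: float = 4.0,
    background_exclusion_nm: float | None = None,
    seed=None,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Two-channel field of diffraction-limited puncta with known colocalization.

    B-centroids are placed uniformly at random in the mask with a hard minimum
    spacing of ``min_spacing_factor * σ`` (keeps spots individually
    segmentable).  ``floor(coloc_fraction * n_a)`` A-centroids are placed
    uniformly within ``offset_radius_nm`` of distinct B-centroids and flagged
    colocalized; the remainder are placed uniformly in the mask but at least
    ``background_exclusion_nm`` (default ``2*offset_radius_nm``) from every
    B-centroid, so the generated colocalized fraction is exact rather than
    inflated by chance proximity.

    Returns the rendered channel-A and channel-B stacks and the ground truth.
    """
    rng = _as_rng(seed)
    noise = noise or NoiseModel(read_noise_sd=amplitude_fu / 10.0, baseline=20.0)
    px = mask.pixel_size_nm
    sigma_px = psf_sigma_nm / px
    spacing_px = min_spacing_factor * sigma_px
    offset_px = offset_radius_nm / px
    excl_px = (2.0 * offset_radius_nm if background_exclusion_nm is None
               else background_exclusion_nm) / px

    b_yx = sample_positions_in_mask(rng, mask.mask, n_b, min_spacing_px=spacing_px)

    n_flag = int(math.floor(coloc_fraction * n_a))
    if n_flag > n_b:
        raise ValueError("coloc_fraction * n_a exceeds n_b")
    a_list: list[np.ndarray] = []
    if n_flag:
        partners = rng.choice(n_b, size=n_flag, replace=False)
        for j in partners:
            best = None
            for _try in range(50):
                r = offset_px * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                cand = b_yx[j] + np.array([r * math.sin(th), r * math.cos(th)])
                iy, ix = int(round(cand[0])), int(round(cand[1]))
                if not (0 <= iy < mask.mask.shape[0] and 0 <= ix < mask.mask.shape[1]
                        and mask.mask[iy, ix]):
                    continue
                best = cand
                if not a_list or np.min(np.hypot(*(np.array(a_list) - cand).T)) >= spacing_px:
                    break
            if best is None:
                raise RuntimeError("could not place colocalized A centroid inside mask")
            a_list.append(best)
    a_flagged = np.array(a_list) if a_list else np.zeros((0, 2))
    a_rand = sample_positions_in_mask(
        rng, mask.mask, n_a - n_flag, min_spacing_px=spacing_px,
        existing_yx=a_flagged, exclusion_yx=b_yx, exclusion_radius_px=excl_px,
    )
    a_yx = np.vstack([a_flagged, a_rand]) if len(a_rand) else a_flagged
    flags = np.zeros(n_a, dtype=bool)
    flags[:n_flag] = True

    img_a = render_gaussian_spots(mask.mask.shape, a_yx, amplitude_fu, sigma_px)
    img_b = render_gaussian_spots(mask.mask.shape, b_yx, amplitude_fu, sigma_px)
    stack_a = ImageStack(noise.apply(img_a, rng), px, channel_label="A")
    stack_b = ImageStack(noise.apply(img_b, rng), px, channel_label="B")
    truth = GroundTruth(
        puncta_a_nm=_yx_px_to_xy_nm(a_yx, px),
        puncta_b_nm=_yx_px_to_xy_nm(b_yx, px),
        colocalized=flags,
    )
    return stack_a, stack_b, truth


# ---------------------------------------------------------------------------
# filament textures


def make_filament_image(
    mask: CellMask,
    n_filaments: int = 10,
    psf_sigma_nm: float = 110.0,
    amplitude_fu: float = 50.0,
    noise: NoiseModel | None = None,
    n_waypoints: int = 5,
    seed=None,
) -> tuple[ImageStack, np.ndarray]:
    """Smooth random curves with Gaussian cross-section, emulating actin texture.

    Each filament is a cubic spline through random in-mask waypoints, sampled
    uniformly in arc length and rendered by Gaussian smoothing of the
    centre-line.  The returned truth mask marks pixels within the
    full-width-half-maximum footprint of the rendered filaments.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = _as_rng(seed)
    noise = noise or NoiseModel(poisson=False)
    px = mask.pixel_size_nm
    sigma_px = max(psf_sigma_nm / px, 0.5)
    shape = mask.mask.shape
    centreline = np.zeros(shape, dtype=np.float64)
    centre_mask = np.zeros(shape, dtype=bool)
    for _ in range(n_filaments):
        wp = sample_positions_in_mask(rng, mask.mask, n_waypoints,
                                      min_spacing_px=min(shape) / (2 * n_waypoints))
        # order waypoints along their first principal axis to avoid zig-zags
        c = wp - wp.mean(axis=0)
        axis = np.linalg.svd(c, full_matrices=False)[2][0]
        wp = wp[np.argsort(c @ axis)]
        tck, _u = splprep([wp[:, 0], wp[:, 1]], s=0, k=min(3, len(wp) - 1))
        u = np.linspace(0, 1, 2000)
        yy, xx = splev(u, tck)
        # resample uniformly in arc length for even deposition
        seglen = np.hypot(np.diff(yy), np.diff(xx))
        arclen = np.concatenate([[0], np.cumsum(seglen)])
        total = arclen[-1]
        n_samp = max(int(total / 0.2), 2)
        ui = np.interp(np.linspace(0, total, n_samp), arclen, u)
        yy, xx = splev(ui, tck)
        iy = np.clip(np.round(yy).astype(int), 0, shape[0] - 1)
        ix = np.clip(np.round(xx).astype(int), 0, shape[1] - 1)
        inside = mask.mask[iy, ix]
        np.add.at(centreline, (iy[inside], ix[inside]), total / n_samp)
        centre_mask[iy[inside], ix[inside]] = True
    img = ndimage.gaussian_filter(centreline, sigma_px) * amplitude_fu * sigma_px * math.sqrt(2 * math.pi)
    # FWHM footprint: within sigma*sqrt(2 ln 2) of the centre-line
    dist = ndimage.distance_transform_edt(~centre_mask)
    truth = (dist <= sigma_px * math.sqrt(2 * math.log(2))) & mask.mask
    stack = ImageStack(noise.apply(img, rng), px, channel_label="filaments")
    return stack, truth


# ---------------------------------------------------------------------------
# motion movies


_MOTION_CLASSES = ("immobile", "diffusive", "directed", "confined")


def make_trajectories(
    n_particles: int,
    class_mix: dict[str, float],
    n_frames: int,
    frame_interval_s: float,
    d_um2_s: float = 0.01,
    v_um_s: float = 0.5,
    loc_noise_nm: float = 20.0,
    box_um: tuple[float, float] = (20.0, 20.0),
    confinement_radius_um: float = 0.25,
    seed=None,
) -> list[TrajectoryTruth]:
    """Simulate 2-D particle tracks of mixed mobility classes (positions in nm).

    immobile: fixed position plus isotropic Gaussian localization noise;
    diffusive: Brownian steps with per-axis variance ``2 D Δt``;
    directed: constant-velocity drift plus noise;
    confined: Brownian motion reflected at a circular boundary.
    Localization noise is added to every class.
    """
    mix = {k: class_mix.get(k, 0.0) for k in _MOTION_CLASSES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = _as_rng(seed)
    counts = {k: int(round(p * n_particles)) for k, p in mix.items()}
    # fix rounding drift on the largest class
    drift = n_particles - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    dt = frame_interval_s
    box_nm = (box_um[0] * 1000.0, box_um[1] * 1000.0)
    step_sd_nm = math.sqrt(2.0 * d_um2_s * dt) * 1000.0
    out: list[TrajectoryTruth] = []
    for cls in _MOTION_CLASSES:
        for _ in range(counts[cls]):
            p0 = rng.uniform([0.1 * box_nm[0], 0.1 * box_nm[1]],
                             [0.9 * box_nm[0], 0.9 * box_nm[1]])
            if cls == "immobile":
                pos = np.tile(p0, (n_frames, 1))
            elif cls == "diffusive":
                steps = rng.normal(0.0, step_sd_nm, size=(n_frames - 1, 2))
                pos = p0 + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            elif cls == "directed":
                th = rng.uniform(0, 2 * math.pi)
                vel = np.array([math.cos(th), math.sin(th)]) * v_um_s * 1000.0
                t = np.arange(n_frames)[:, None] * dt
                pos = p0 + vel * t
            else:  # confined: reflecting circular boundary
                r_nm = confinement_radius_um * 1000.0
                pos = np.empty((n_frames, 2))
                pos[0] = p0
                for i in range(1, n_frames):
                    cand = pos[i - 1] + rng.normal(0.0, step_sd_nm, 2)
                    d = np.linalg.norm(cand - p0)
                    if d > r_nm:
                        cand = p0 + (cand - p0) * (2 * r_nm - d) / d
                    pos[i] = cand
            if loc_noise_nm > 0:
                pos = pos + rng.normal(0.0, loc_noise_nm, size=pos.shape)
            # keep inside the rendering box
            pos[:, 0] = np.clip(pos[:, 0], 0, box_nm[0] - 1)
            pos[:, 1] = np.clip(pos[:, 1], 0, box_nm[1] - 1)
            out.append(TrajectoryTruth(positions_nm=pos, mobility_class=cls))
    return out


def make_motion_movie(
    mask: CellMask,
    n_particles: int = 50,
    class_mix: dict[str, float] | None = None,
    d_um2_s: float = 0.01,
    v_um_s: float = 0.5,
    loc_noise_nm: float = 20.0,
    n_frames: int = 300,
    frame_interval_s: float = 0.1,
    psf_sigma_nm: float = 110.0,
    amplitude_fu: float = 100.0,
    noise: NoiseModel | None = None,
    seed=None,
) -> tuple[ImageStack, GroundTruth]:
    """Render mixed-mobility particle tracks as a movie of Gaussian spots."""
    if n_frames < 45:
        raise ValueError("n_frames must be >= 45 (minimum classifiable length)")
    class_mix = class_mix or {"immobile": 0.3, "diffusive": 0.6, "directed": 0.1}
    rng = _as_rng(seed)
    noise = noise or NoiseModel(read_noise_sd=amplitude_fu / 10.0, baseline=20.0)
    px = mask.pixel_size_nm
    ny, nx = mask.mask.shape
    box_um = (nx * px / 1000.0, ny * px / 1000.0)
    trajs = make_trajectories(
        n_particles, class_mix, n_frames, frame_interval_s,
        d_um2_s=d_um2_s, v_um_s=v_um_s, loc_noise_nm=loc_noise_nm,
        box_um=box_um, seed=rng,
    )
    sigma_px = psf_sigma_nm / px
    frames = np.empty((n_frames, ny, nx))
    for t in range(n_frames):
        yx = np.array([[tr.positions_nm[t, 1] / px, tr.positions_nm[t, 0] / px]
                       for tr in trajs])
        frames[t] = noise.apply(
            render_gaussian_spots((ny, nx), yx, amplitude_fu, sigma_px), rng)
    stack = ImageStack(frames, px, frame_interval_s, channel_label="motion")
    return stack, GroundTruth(trajectories=trajs)


# ---------------------------------------------------------------------------
# FRAP curves


def make_frap_curve(
    f_pre: float = 1.0,
    f_post: float = 0.2,
    mobile_fraction: float = 0.6,
    tau_s: float = 10.0,
    n_points: int = 100,
    noise_sd: float = 0.02,
    frame_interval_s: float = 1.0,
    n_prebleach: int = 5,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, int, GroundTruth]:
    """Single-exponential FRAP recovery with pre-bleach frames and noise.

    Post-bleach: ``F(t) = F_post + Mf (F_pre − F_post)(1 − exp(−t/τ))``.
    Returns (times_s, intensities, bleach_frame, truth).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if f_post >= f_pre:
        raise ValueError("F_post must be < F_pre")
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    rng = _as_rng(seed)
    t = np.arange(n_prebleach + n_points) * frame_interval_s
    f = np.empty_like(t)
    f[:n_prebleach] = f_pre
    trec = t[n_prebleach:] - t[n_prebleach]
    f[n_prebleach:] = f_post + mobile_fraction * (f_pre - f_post) * (1.0 - np.exp(-trec / tau_s))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    truth = GroundTruth(frap_params={
        "f_pre": f_pre, "f_post": f_post, "mobile_fraction": mobile_fraction,
        "tau_s": tau_s,
    })
    return t, f, n_prebleach, truth


# ---------------------------------------------------------------------------
# Ca2+ puff movies


def puff_baseline_for_snr(peak_dff: float, snr: float, read_noise_sd: float = 2.0) -> float:
    """Baseline (FU) at which an event of ``peak_dff`` has the requested SNR.

    SNR is defined as peak signal (baseline·ΔF/F₀) over the background noise
    s.d. sqrt(baseline + read²) of a Poisson+read camera model.
    """
    # solve (b*dff)^2 = snr^2 (b + read^2)
    a = peak_dff**2
    b = -(snr**2)
    c = -(snr**2) * read_noise_sd**2
    return (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)


def make_puff_movie(
    mask: CellMask,
    site_positions_nm: np.ndarray,
    events_per_site: int = 5,
    peak_dff: float = 1.0,
    rise_frames: int = 2,
    decay_frames: float = 8.0,
    spatial_sigma_nm: float = 600.0,
    baseline_fu: float = 100.0,
    noise: NoiseModel | None = None,
    n_frames: int = 400,
    n_baseline_frames: int = 50,
    frame_interval_s: float = 0.05,
    site_jitter_nm: float = 100.0,
    seed=None,
) -> tuple[ImageStack, GroundTruth]:
    """Movie of transient local Ca2+-release events on a uniform baseline.

    Each event multiplies the baseline locally by ``1 + ΔF/F₀(t)`` with a
    Gaussian spatial profile, a linear rise over ``rise_frames`` and an
    exponential decay with time constant ``decay_frames``.  Event centroids
    jitter by ``site_jitter_nm`` around their site (puff centroids wander
    within a site).  Sites must lie inside the mask; no event starts before
    ``n_baseline_frames``.
    """
    rng = _as_rng(seed)
    noise = noise or NoiseModel(read_noise_sd=2.0)
    px = mask.pixel_size_nm
    ny, nx = mask.mask.shape
    sites = np.atleast_2d(np.asarray(site_positions_nm, dtype=np.float64))
    for sx, sy in sites:
        iy, ix = int(round(sy / px)), int(round(sx / px))
        if not (0 <= iy < ny and 0 <= ix < nx and mask.mask[iy, ix]):
            raise ValueError("site outside mask")
    sigma_px = spatial_sigma_nm / px
    # event end = when amplitude decays to 10% of peak
    tail = int(math.ceil(decay_frames * math.log(10.0)))
    events: list[PuffEventTruth] = []
    for si in range(len(sites)):
        n_ev = events_per_site
        if n_ev == 0:
            continue
        # stratified starts: one event per equal time slot, separated enough
        # that successive events at a site are individually countable
        usable = n_frames - n_baseline_frames - rise_frames - tail - 1
        min_sep = rise_frames + tail + 2
        slot = usable // n_ev
        if slot < min_sep:
            raise ValueError("too many events per site for n_frames")
        starts = np.array([
            k * slot + rng.integers(slot - min_sep + 1) for k in range(n_ev)
        ]) + n_baseline_frames
        for t0 in starts:
            jitter = rng.normal(0.0, site_jitter_nm, 2) if site_jitter_nm > 0 else np.zeros(2)
            cx, cy = sites[si] + jitter
            events.append(PuffEventTruth(
                t_start=int(t0), duration_frames=rise_frames + tail,
                centroid_nm=(float(cx), float(cy)),
                peak_dff=peak_dff, site_index=si,
            ))
    dff = np.zeros((n_frames, ny, nx))
    yy = np.arange(ny, dtype=np.float64)[:, None]
    xx = np.arange(nx, dtype=np.float64)[None, :]
    for ev in events:
        cx_px, cy_px = ev.centroid_nm[0] / px, ev.centroid_nm[1] / px
        profile = np.exp(-((yy - cy_px) ** 2 + (xx - cx_px) ** 2) / (2 * sigma_px**2))
        for k in range(ev.duration_frames):
            t = ev.t_start + k
            if t >= n_frames:
                break
            if k < rise_frames:
                a = ev.peak_dff * (k + 1) / rise_frames
            else:
                a = ev.peak_dff * math.exp(-(k - rise_frames + 1) / decay_frames)
            dff[t] += a * profile
    movie = baseline_fu * (1.0 + dff) * mask.mask[None, :, :]
    noisy = np.empty_like(movie)
    for t in range(n_frames):
        noisy[t] = noise.apply(movie[t], rng, subtract_baseline=False)
    stack = ImageStack(noisy, px, frame_interval_s, channel_label="Ca")
    return stack, GroundTruth(puff_events=events)
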