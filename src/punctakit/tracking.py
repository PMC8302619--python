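"""Particle linking, MSD analysis and mobility classification.

Per-frame puncta are linked into trajectories by minimum-total-distance
bipartite matching between consecutive frames, gated by a maximum speed
(1.5 µm/s by default — the displacement threshold above which no genuine
punctum moves), followed by gap closing across short detection dropouts.
Each sufficiently long trajectory (≥ 45 frames by default) gets a
time-averaged MSD, a power-law fit γ² = 4 D t^α on the first lags, and a
mobility class from the anomalous exponent α: immobile below 0.1,
sub-diffusive below 0.8, diffusive below 1.2, directed above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ImageStack
from .spots import SegmentationResult

ALPHA_IMMOBILE = 0.1
ALPHA_DIFFUSIVE_LOW = 0.8
ALPHA_DIRECTED = 1.2
MIN_TRAJECTORY_FRAMES = 45
MAX_SPEED_UM_S = 1.5


@dataclass
class Trajectory:
    id: int
    frames: np.ndarray       # strictly increasing frame indices (gaps allowed)
    positions_nm: np.ndarray  # (n, 2) of (x, y)

    @property
    def length_frames(self) -> int:
        return len(self.frames)


@dataclass
class MSDFit:
    trajectory_id: int
    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    d_um2_s: float
    alpha: float
    n_fit_lags: int
    mobility_class: str | None = None


def match_frame_pairs(pos1_nm: np.ndarray, pos2_nm: np.ndarray,
                      max_dist_nm: float) -> list[tuple[int, int]]:
    """Optimal gated assignment between detections of two frames.

    Minimizes total cost where a matched pair costs its distance (only pairs
    within ``max_dist_nm`` are allowed) and every unmatched detection costs
    ``max_dist_nm``; equivalently, match as many gated pairs as possible with
    minimum total distance.  Solved with the augmented linear-sum-assignment
    construction; deterministic and order-independent.
    """
    n1, n2 = len(pos1_nm), len(pos2_nm)
    if n1 == 0 or n2 == 0:
        return []
    d = np.hypot(pos1_nm[:, None, 0] - pos2_nm[None, :, 0],
                 pos1_nm[:, None, 1] - pos2_nm[None, :, 1])
    big = 1e9
    top_left = np.where(d <= max_dist_nm, d, big)
    top_right = np.full((n1, n1), big)
    np.fill_diagonal(top_right, max_dist_nm)
    bottom_left = np.full((n2, n2), big)
    np.fill_diagonal(bottom_left, max_dist_nm)
    bottom_right = np.zeros((n2, n1))
    cost = np.block([[top_left, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n1 and c < n2 and d[r, c] <= max_dist_nm]


def link_puncta(seg: SegmentationResult, max_speed_um_s: float = MAX_SPEED_UM_S,
                max_gap_frames: int = 2,
                frame_interval_s: float | None = None) -> list[Trajectory]:
    """Link per-frame puncta into trajectories with gap closing.

    Consecutive frames are linked by gated min-cost matching; track segments
    are then joined across up to ``max_gap_frames`` missed frames when the
    implied speed over the gap stays within ``max_speed_um_s``.
    """
    if frame_interval_s is None:
        raise ValueError("frame_interval_s is required")
    dt = frame_interval_s
    gate_nm = max_speed_um_s * dt * 1000.0
    frames = sorted({p.frame for p in seg.puncta})
    by_frame = {t: seg.frame_puncta(t) for t in frames}
    pos = {t: np.array([[p.centroid_x_nm, p.centroid_y_nm] for p in by_frame[t]])
           if by_frame[t] else np.zeros((0, 2)) for t in frames}

    # build segments by frame-to-frame linking
    segments: list[tuple[list[int], list[np.ndarray]]] = []
    open_by_idx: dict[int, int] = {}  # detection idx in current frame -> segment idx
    for k, t in enumerate(frames):
        new_open: dict[int, int] = {}
        if k == 0 or frames[k - 1] != t - 1:
            links = []
        else:
            links = match_frame_pairs(pos[frames[k - 1]], pos[t], gate_nm)
        linked_j = set()
        for i, j in links:
            si = open_by_idx.get(i)
            if si is None:
                continue
            segments[si][0].append(t)
            segments[si][1].append(pos[t][j])
            new_open[j] = si
            linked_j.add(j)
        for j in range(len(pos[t])):
            if j not in linked_j:
                segments.append(([t], [pos[t][j]]))
                new_open[j] = len(segments) - 1
        open_by_idx = new_open

    # gap closing: join segment ends to later segment starts
    ends = np.array([s[0][-1] for s in segments])
    starts = np.array([s[0][0] for s in segments])
    end_pos = np.array([s[1][-1] for s in segments])
    start_pos = np.array([s[1][0] for s in segments])
    n = len(segments)
    if n and max_gap_frames > 0:
        big = 1e9
        cost = np.full((n, n), big)
        any_cand = False
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gap = starts[j] - ends[i]
                if gap < 2 or gap - 1 > max_gap_frames:
                    continue
                dist = math.hypot(*(start_pos[j] - end_pos[i]))
                if dist <= max_speed_um_s * gap * dt * 1000.0:
                    cost[i, j] = dist
                    any_cand = True
        if any_cand:
            nolink = max_speed_um_s * (max_gap_frames + 1) * dt * 1000.0
            aug = np.block([
                [cost, np.where(np.eye(n), nolink, big)],
                [np.where(np.eye(n), nolink, big), np.zeros((n, n))],
            ])
            rows, cols = linear_sum_assignment(aug)
            succ = {}
            for r, c in zip(rows, cols):
                if r < n and c < n and cost[r, c] < big:
                    succ[r] = c
            merged_into = {}
            for i in sorted(succ):
                root = i
                while root in merged_into:
                    root = merged_into[root]
                j = succ[i]
                segments[root][0].extend(segments[j][0])
                segments[root][1].extend(segments[j][1])
                merged_into[j] = root
            segments = [s for i, s in enumerate(segments) if i not in merged_into]

    return [Trajectory(i, np.array(f), np.array(p))
            for i, (f, p) in enumerate(segments)]


def compute_msd(traj: Trajectory, frame_interval_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over all in-trajectory frame pairs at each lag.

    Returns (lag_times_s, msd_um2); lags supported by fewer than 2
    displacement pairs are dropped.
    """
    if traj.length_frames < 2:
        raise ValueError("trajectory too short for MSD")
    f0 = traj.frames - traj.frames[0]
    span = int(f0[-1]) + 1
    grid = np.full((span, 2), np.nan)
    grid[f0] = traj.positions_nm / 1000.0  # µm
    lags, msds = [], []
    for lag in range(1, span):
        disp = grid[lag:] - grid[:-lag]
        sq = disp[:, 0] ** 2 + disp[:, 1] ** 2
        valid = ~np.isnan(sq)
        if valid.sum() >= 2:
            lags.append(lag * frame_interval_s)
            msds.append(float(sq[valid].mean()))
    if not lags:
        raise ValueError("no lag supported by >= 2 pairs")
    return np.array(lags), np.array(msds)


def fit_anomalous_exponent(lag_times_s: np.ndarray, msd_um2: np.ndarray,
                           n_fit_lags: int = 10) -> tuple[float, float]:
    """Fit γ² = 4 D t^α by least squares on log t vs log MSD.

    Uses the first ``n_fit_lags`` lags (the noisy long-lag tail is excluded).
    Returns (D in µm²/s, α).  An all-zero MSD — a perfectly stationary
    trajectory — is assigned D = 0, α = 0 rather than a fit failure.
    """
    t = np.asarray(lag_times_s)[:n_fit_lags]
    m = np.asarray(msd_um2)[:n_fit_lags]
    if np.all(m <= 0):
        return 0.0, 0.0
    pos = m > 0
    if pos.sum() < 3:
        raise ValueError("need >= 3 positive MSD values among the fit lags")
    slope, intercept = np.polyfit(np.log(t[pos]), np.log(m[pos]), 1)
    return float(np.exp(intercept) / 4.0), float(slope)


def classify_alpha(alpha: float, alpha_immobile: float = ALPHA_IMMOBILE,
                   alpha_diffusive_low: float = ALPHA_DIFFUSIVE_LOW,
                   alpha_directed: float = ALPHA_DIRECTED) -> str:
    """Mobility class from the anomalous exponent (band edges configurable)."""
    if alpha < alpha_immobile:
        return "immobile"
    if alpha < alpha_diffusive_low:
        return "subdiffusive"
    if alpha < alpha_directed:
        return "diffusive"
    return "directed"


def analyze_trajectories(trajs: list[Trajectory], frame_interval_s: float,
                         n_fit_lags: int = 10,
                         min_length_frames: int = MIN_TRAJECTORY_FRAMES,
                         alpha_immobile: float = ALPHA_IMMOBILE,
                         alpha_diffusive_low: float = ALPHA_DIFFUSIVE_LOW,
                         alpha_directed: float = ALPHA_DIRECTED) -> list[MSDFit]:
    """MSD-fit and classify every trajectory of at least the minimum length.

    Shorter trajectories are excluded from classification entirely.
    """
    fits = []
    for tr in trajs:
        if tr.length_frames < min_length_frames:
            continue
        lags, msd = compute_msd(tr, frame_interval_s)
        d, alpha = fit_anomalous_exponent(lags, msd, n_fit_lags)
        cls = classify_alpha(alpha, alpha_immobile, alpha_diffusive_low, alpha_directed)
        fits.append(MSDFit(tr.id, lags, msd, d, alpha, n_fit_lags, cls))
    return fits


def count_immobile(fits: list[MSDFit]) -> int:
    """Number of trajectories classified immobile (per-cell immobile count)."""
    return sum(1 for f in fits if f.mobility_class == "immobile")


def temporal_overlay(stack: ImageStack, interval_s: float = 30.0,
                     t_start: int = 0) -> np.ndarray:
    """Two-colour overlay of frames separated by ``interval_s``.

    The earlier frame maps to green, the later to magenta (red+blue) of an
    RGB float image scaled to [0, 1]; immobile structures coincide and appear
    white/grey, mobile ones separate into green and magenta.
    """
    if stack.frame_interval_s is None:
        raise ValueError("stack has no frame interval")
    shift = int(round(interval_s / stack.frame_interval_s))
    if t_start + shift >= stack.n_frames:
        raise ValueError("interval exceeds movie duration")
    g = stack.frame(t_start).astype(np.float64)
    m = stack.frame(t_start + shift).astype(np.float64)
    scale = max(g.max(), m.max()) or 1.0
    rgb = np.zeros(g.shape + (3,))
    rgb[..., 1] = g / scale
    rgb[..., 0] = rgb[..., 2] = m / scale
    return rgb
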