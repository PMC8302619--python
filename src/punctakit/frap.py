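"""Fluorescence recovery after photobleaching: normalization and mobile fraction.

A background-corrected bleach-ROI trace is normalized to its pre-bleach mean
and the mobile fraction is the recovered share of the bleach depth,

    Mf = (F_plateau − F_post) / (F_pre − F_post),

with the plateau taken from a single-exponential recovery fit
``F(t) = F_post + (F_plateau − F_post)(1 − exp(−t/τ))`` (mean of the final
frames as fallback when the fit fails).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FRAPRecord:
    """One bleach-ROI recovery trace (background-corrected intensities)."""

    times_s: np.ndarray
    intensities_fu: np.ndarray
    bleach_frame: int
    roi_diameter_um: float = 2.3
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.intensities_fu = np.asarray(self.intensities_fu, dtype=np.float64)
        if self.times_s.shape != self.intensities_fu.shape:
            raise ValueError("times and intensities differ in length")
        if not 0 < self.bleach_frame < len(self.times_s):
            raise ValueError("bleach_frame out of range")


@dataclass
class FRAPFit:
    f_pre: float
    f_post: float
    f_plateau: float
    tau_s: float | None
    mobile_fraction: float


def normalize_frap(record: FRAPRecord) -> FRAPRecord:
    """Divide the trace by the mean of the pre-bleach frames (≥ 3 required)."""
    if record.bleach_frame < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    f_pre = record.intensities_fu[: record.bleach_frame].mean()
    if f_pre <= 0:
        raise ValueError("non-positive pre-bleach intensity")
    return replace(record, intensities_fu=record.intensities_fu / f_pre,
                   normalized=True)


def mobile_fraction(record: FRAPRecord, plateau_window: int | None = None,
                    min_bleach_depth: float = 0.05) -> FRAPFit:
    """Mobile fraction from an exponential-recovery fit of a normalized trace.

    ``plateau_window`` is the number of final frames used by the fallback
    plateau estimate (default: last 20% of post-bleach frames).  Raises if
    the bleach depth F_pre − F_post is below ``min_bleach_depth`` (no bleach
    to recover from).  The result is clamped to [0, 1].
    """
    rec = record if record.normalized else normalize_frap(record)
    f_pre = float(rec.intensities_fu[: rec.bleach_frame].mean())
    post_t = rec.times_s[rec.bleach_frame:] - rec.times_s[rec.bleach_frame]
    post_f = rec.intensities_fu[rec.bleach_frame:]
    if plateau_window is None:
        plateau_window = max(int(0.2 * len(post_f)), 1)
    if len(post_f) < plateau_window:
        raise ValueError("fewer post-bleach frames than the plateau window")
    f_post0 = float(post_f[0])
    if f_pre - f_post0 < min_bleach_depth:
        raise ValueError("no bleach depth: F_pre ~= F_post")

    def model(t, f_post, f_plateau, tau):
        return f_post + (f_plateau - f_post) * (1.0 - np.exp(-t / tau))

    tau = None
    try:
        span = post_t[-1] or 1.0
        popt, _ = curve_fit(
            model, post_t, post_f,
            p0=[f_post0, float(post_f[-plateau_window:].mean()), span / 5.0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        f_post, f_plateau, tau = float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError:
        f_post = f_post0
        f_plateau = float(post_f[-plateau_window:].mean())
    mf = (f_plateau - f_post) / (f_pre - f_post)
    return FRAPFit(f_pre, f_post, f_plateau, tau,
                   float(np.clip(mf, 0.0, 1.0)))
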