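"""Saturation-time statistics: ROI filling curves, exponential tau, tests.

Acquisition time in localization microscopy is governed by how quickly the
vessel fills with localization events.  Within a 25 x 25 pixel region of
interest the saturation curve is the fraction of vessel pixels that have
received at least one localization by time ``t``; normalized by its maximum
and fitted with ``S(t) = 1 - exp(-t / tau)``, its time constant ``tau`` is
the time to 63% (1 - 1/e) of the final value.  Replicate taus are compared
with unpaired two-sample t-tests at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "SaturationCurve",
    "TauEstimate",
    "TauComparison",
    "saturation_curve",
    "fit_exponential",
    "percent_increase",
    "compare_taus",
]

R2_FLAG_THRESHOLD = 0.98


@dataclass
class SaturationCurve:
    """Vessel-pixel saturation within an ROI over acquisition time.

    ``fraction`` is normalized by its maximum (1.0 at the end of the
    analyzed window); ``fraction_raw`` is the unnormalized fill fraction of
    the vessel mask.  ``empty`` flags a curve with no localization at all,
    for which normalization is skipped.
    """

    times_s: np.ndarray
    fraction: np.ndarray
    fraction_raw: np.ndarray
    n_vessel_px: int
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "fraction": self.fraction,
                "fraction_raw": self.fraction_raw,
            }
        )


@dataclass
class TauEstimate:
    """Fitted exponential time constant and goodness of fit."""

    tau_s: float
    r_squared: float
    flagged: bool

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(t, float) / self.tau_s)


@dataclass
class TauComparison:
    """Two-sample t-test between replicate tau groups (mean +- SD each)."""

    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    significant: bool


def saturation_curve(
    localizations: pd.DataFrame,
    roi: tuple[int, int, int],
    vessel_mask: np.ndarray,
    frame_rate_hz: float,
    n_frames: int | None = None,
) -> SaturationCurve:
    """Build the ROI saturation curve from a localization table.

    ``roi`` is ``(row0, col0, size)`` on the upsampled grid and
    ``vessel_mask`` the full-grid boolean vessel footprint; saturation
    counts only vessel pixels inside the ROI.  Each localization marks its
    (rounded) pixel as visited; the curve is the cumulative fraction of
    vessel pixels visited by each frame time, normalized by its maximum.
    """
    r0, c0, size = roi
    mask_roi = vessel_mask[r0 : r0 + size, c0 : c0 + size]
    n_vessel = int(mask_roi.sum())
    if n_vessel == 0:
        raise ValueError("vessel mask is empty within the ROI")
    if n_frames is None:
        n_frames = int(localizations["frame"].max()) + 1 if len(localizations) else 1
    first_hit = np.full((size, size), -1, np.int64)
    if len(localizations):
        rr = np.rint(localizations["row"].to_numpy(float)).astype(int) - r0
        cc = np.rint(localizations["col"].to_numpy(float)).astype(int) - c0
        ff = localizations["frame"].to_numpy(int)
        inside = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        inside &= ff < n_frames
        rr, cc, ff = rr[inside], cc[inside], ff[inside]
        in_vessel = mask_roi[rr, cc]
        rr, cc, ff = rr[in_vessel], cc[in_vessel], ff[in_vessel]
        order = np.argsort(ff)[::-1]  # later frames first; last write wins -> earliest
        first_hit[rr[order], cc[order]] = ff[order]
    hits = first_hit[(first_hit >= 0) & mask_roi]
    counts = np.bincount(hits, minlength=n_frames) if hits.size else np.zeros(n_frames)
    raw = np.cumsum(counts[:n_frames]) / n_vessel
    times = (np.arange(n_frames) + 1) / frame_rate_hz
    peak = raw.max()
    if peak <= 0:
        return SaturationCurve(times, raw.copy(), raw, n_vessel, empty=True)
    return SaturationCurve(times, raw / peak, raw, n_vessel)


def fit_exponential(curve: SaturationCurve, min_points: int = 10) -> TauEstimate:
    """Least-squares fit of ``S(t) = 1 - exp(-t/tau)`` to a normalized curve.

    Returns the time constant (the time to 63% of the asymptote) and the
    coefficient of determination; fits with R^2 below 0.98 are flagged.
    """
    t = np.asarray(curve.times_s, float)
    y = np.asarray(curve.fraction, float)
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} time points, got {t.size}")
    if curve.empty or y.max() <= 0:
        raise ValueError("degenerate saturation curve: no localization events")
    # initial guess: first crossing of 1 - 1/e
    target = 1.0 - np.exp(-1.0)
    above = np.nonzero(y >= target)[0]
    tau0 = t[above[0]] if above.size else t[-1] / 2.0
    tau0 = max(tau0, t[1] - t[0])
    try:
        popt, _ = curve_fit(
            lambda tt, tau: 1.0 - np.exp(-tt / tau),
            t,
            y,
            p0=[tau0],
            bounds=(1e-9, np.inf),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ValueError(f"exponential fit failed: {exc}") from exc
    tau = float(popt[0])
    resid = y - (1.0 - np.exp(-t / tau))
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return TauEstimate(tau_s=tau, r_squared=r2, flagged=not (r2 >= R2_FLAG_THRESHOLD))


def percent_increase(tau_branch_s: float, tau_main_s: float) -> float:
    """Relative increase of the branch time constant over the main, in %."""
    if tau_main_s <= 0:
        raise ValueError(f"reference tau must be positive, got {tau_main_s}")
    return (tau_branch_s - tau_main_s) / tau_main_s * 100.0


def compare_taus(group_a, group_b, alpha: float = 0.05) -> TauComparison:
    """Unpaired two-tailed two-sample t-test between replicate tau groups."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return TauComparison(
        t_statistic=float(t_stat),
        p_value=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        significant=bool(p < alpha),
    )
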