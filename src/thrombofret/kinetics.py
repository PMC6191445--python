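"""Thrombus growth metrics, peak areas, and cGMP/Ca2+ lead-lag estimation.

Growth profiles (thrombus area versus time) are summarized by the standard
descriptors: time to maximal size, maximal size, half-dissolution time
(first crossing of 50% of the maximum after the peak, linearly
interpolated; censored if never reached), area under the curve, and the
stabilized size at the end of the experiment.  Peak areas of dR/R traces
are trapezoidal integrals above a linear chord between manually chosen
borders (linear-baseline drift correction).

The lead-lag estimator quantifies the chronological order of cGMP and Ca2+
changes: it cross-correlates the first differences of the two traces
(optionally sign-inverting the second for anticorrelated signals), finds
the integer lag of maximal normalized correlation within +-max_lag, and
refines it by parabolic interpolation.  A negative lag means the first
trace precedes the second.  Raw-trace correlation would be dominated by
slow drifts; differencing suppresses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticsReport",
    "LeadLagResult",
    "growth_metrics",
    "peak_area",
    "lead_lag",
    "recovery_time",
]


@dataclass(frozen=True)
class KineticsReport:
    """Summary of one thrombus growth profile.

    ``t_half_dissolution`` is the time from the maximum to 50% of the
    maximum; NaN with ``censored=True`` when the area never falls that far
    within the observed span.  ``auc`` integrates area minus the pre-injury
    baseline; ``auc_raw`` integrates the area itself.
    """

    t_max: float
    a_max: float
    t_half_dissolution: float
    censored: bool
    auc: float
    auc_raw: float
    a_end: float
    t_end: float
    baseline: float

    def to_dict(self) -> dict:
        return {
            "t_max_s": self.t_max,
            "a_max_um2": self.a_max,
            "t_half_dissolution_s": self.t_half_dissolution,
            "half_dissolution_censored": self.censored,
            "auc_um2_s": self.auc,
            "auc_raw_um2_s": self.auc_raw,
            "a_end_um2": self.a_end,
            "t_end_s": self.t_end,
            "baseline_um2": self.baseline,
        }


@dataclass(frozen=True)
class LeadLagResult:
    """Lag (s) of trace y relative to trace x; negative = x precedes y."""

    lag_s: float
    peak_corr: float
    low_confidence: bool


def growth_metrics(t, area, t_end: float | None = None, baseline: float = 0.0) -> KineticsReport:
    """Growth descriptors of an area-versus-time profile.

    Ties at the maximum resolve to the earliest frame.  The half-dissolution
    crossing is linearly interpolated between the bracketing frames.  The
    AUC is the trapezoidal integral over [t[0], t_end] of (area - baseline),
    with ``baseline`` the pre-injury area (0 for a laser-injury field).
    """
    t = np.asarray(t, dtype=float)
    area = np.asarray(area, dtype=float)
    if len(t) != len(area) or len(t) < 3:
        raise ValueError("need matching t/area arrays with >= 3 points")
    if (np.diff(t) <= 0).any():
        raise ValueError("time grid must be strictly increasing")
    if t_end is None:
        t_end = float(t[-1])
    if not (t[0] <= t_end <= t[-1]):
        raise ValueError("t_end outside the trace support")

    # restrict to [t0, t_end], interpolating the endpoint
    a_end = float(np.interp(t_end, t, area))
    keep = t <= t_end
    tt = np.append(t[keep], t_end) if t[keep][-1] < t_end else t[keep]
    aa = np.append(area[keep], a_end) if t[keep][-1] < t_end else area[keep]

    i_max = int(np.argmax(aa))  # argmax takes the first of tied maxima
    t_max = float(tt[i_max])
    a_max = float(aa[i_max])

    t_half = np.nan
    censored = True
    if a_max > 0:
        half = 0.5 * a_max
        below = np.nonzero(aa[i_max:] <= half)[0]
        if below.size:
            j = below[0] + i_max
            if aa[j] == half or j == i_max:
                t_cross = tt[j]
            else:
                t_cross = tt[j - 1] + (tt[j] - tt[j - 1]) * (
                    (aa[j - 1] - half) / (aa[j - 1] - aa[j])
                )
            t_half = float(t_cross - t_max)
            censored = False

    auc_raw = float(np.trapezoid(aa, tt))
    auc = float(np.trapezoid(aa - baseline, tt))
    return KineticsReport(
        t_max=t_max, a_max=a_max, t_half_dissolution=t_half, censored=censored,
        auc=auc, auc_raw=auc_raw, a_end=a_end, t_end=float(t_end),
        baseline=float(baseline),
    )


def peak_area(t, x, borders: tuple[float, float]) -> float:
    """Peak area above a linear baseline between manual borders.

    The baseline is the chord connecting the trace values at the two border
    times; the result is the trapezoidal integral of (trace - chord) over
    [start, end].  A purely linear trace therefore has zero peak area.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    start, end = borders
    if start >= end:
        raise ValueError("peak borders must satisfy start < end")
    if start < t[0] or end > t[-1]:
        raise ValueError("peak borders outside the trace support")
    x0 = np.interp(start, t, x)
    x1 = np.interp(end, t, x)
    inner = (t > start) & (t < end)
    tt = np.concatenate([[start], t[inner], [end]])
    xx = np.concatenate([[x0], x[inner], [x1]])
    chord = x0 + (x1 - x0) * (tt - start) / (end - start)
    return float(np.trapezoid(xx - chord, tt))


def lead_lag(
    t, x, y, max_lag: float, invert_y: bool = False, min_corr: float = 0.5,
    smooth_sigma: float = 0.0,
) -> LeadLagResult:
    """Lag between two traces by derivative cross-correlation.

    Computes the normalized correlation of the first differences of ``x``
    and ``y`` (``y`` sign-inverted for anticorrelated pairs) at every
    integer lag within +-``max_lag`` seconds, takes the argmax and refines
    it by parabolic interpolation of the correlation peak.  Negative lag
    means ``x`` precedes ``y``.  A peak correlation below ``min_corr``
    raises the low-confidence flag.  ``smooth_sigma`` (frames) applies a
    Gaussian temporal filter to both traces before differencing; with shot
    noise a sigma of ~1 frame suppresses the uncorrelated noise floor of
    the derivative correlation without shifting the peak.
    """
    from scipy import ndimage

    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if smooth_sigma > 0:
        x = ndimage.gaussian_filter1d(x, smooth_sigma)
        y = ndimage.gaussian_filter1d(y, smooth_sigma)
    if len(t) < 2:
        raise ValueError("traces too short")
    dt = float(t[1] - t[0])
    if max_lag < dt:
        raise ValueError("max_lag must be at least one frame interval")
    max_shift = int(round(max_lag / dt))
    dx = np.diff(x)
    dy = np.diff(y) * (-1.0 if invert_y else 1.0)
    if len(dx) <= 2 * max_shift:
        raise ValueError("traces shorter than twice the lag search window")

    def corr_at(shift: int) -> float:
        # correlate dx(t + shift) with dy(t)
        if shift >= 0:
            a, b = dx[shift:], dy[: len(dy) - shift]
        else:
            a, b = dx[: len(dx) + shift], dy[-shift:]
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    shifts = np.arange(-max_shift, max_shift + 1)
    corr = np.array([corr_at(s) for s in shifts])
    i = int(np.argmax(corr))
    best = shifts[i]
    refined = float(best)
    if 0 < i < len(shifts) - 1:
        c_m, c_0, c_p = corr[i - 1], corr[i], corr[i + 1]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            refined = best + 0.5 * (c_m - c_p) / denom
    peak = float(corr[i])
    return LeadLagResult(
        lag_s=refined * dt, peak_corr=peak, low_confidence=peak < min_corr
    )


def recovery_time(t, trace, t_event: float, band: float = 0.05) -> float:
    """Time after ``t_event`` for a baseline-normalized trace to re-enter
    and stay within +-``band`` of zero.

    ``trace`` is typically a dR/R trace whose pre-stimulus baseline is 0.
    Returns 0.0 if the trace is already (and stays) inside the band at
    ``t_event`` and ``inf`` if it is still outside at the last frame.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    after = t >= t_event
    if not after.any():
        raise ValueError("t_event beyond the trace support")
    tt = t[after]
    out = np.abs(trace[after]) > band
    if not out.any():
        return 0.0
    last_out = np.nonzero(out)[0][-1]
    if last_out == len(tt) - 1:
        return float("inf")
    return float(tt[last_out + 1] - t_event)
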