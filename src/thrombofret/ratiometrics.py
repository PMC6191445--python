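"""Background-corrected trace extraction, FRET ratios and sensor calibration.

The cGMP readout is the emission ratio R = F480/F535 of a CFP/YFP FRET
sensor: cGMP binding lowers FRET, so CFP emission rises, YFP emission falls
and R increases with cGMP.  Region traces are background-corrected mean
intensities inside the dynamic masks; ratios are normalized to a
pre-stimulus baseline (dR/R) and screened by a signal-to-noise criterion
(traces with SNR < 2.5 are excluded).

Calibration uses a Hill-type model

    R(c) = r_min + (r_max - r_min) * c^n / (ec50^n + c^n)

with an exact algebraic inverse.  Above ``c_sat`` (default 3 uM) the sensor
is considered saturated: the inverse then reports ``c_sat`` as a lower bound
together with a saturation flag.  The Ca2+ readout is the classic Fura-2
excitation ratio F340/F380, processed the same way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CFP, FURA_340, FURA_380, YFP, TimeLapseStack
from .segment import MaskSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SensorModel",
    "RegionTraces",
    "RatioTrace",
    "estimate_background",
    "extract_traces",
    "compute_ratio",
    "normalize",
    "normalize_trace",
    "snr_filter",
    "sensor_forward",
    "sensor_inverse",
    "fura_signal",
]

_CHANNEL_COLUMNS = {CFP: "F480", YFP: "F535", FURA_340: "F340", FURA_380: "F380"}


@dataclass(frozen=True)
class SensorModel:
    """Hill-type cGMP -> emission-ratio calibration.

    ec50 (uM) and hill_n set the midpoint and steepness; r_min/r_max bound
    the ratio; c_sat (uM) is the upper quantification limit above which the
    readout is treated as saturated.  Defaults describe a cGi500-class
    sensor: ec50 0.5 uM, n 1, saturation above 3 uM.
    """

    ec50: float = 0.5
    hill_n: float = 1.0
    r_min: float = 1.0
    r_max: float = 2.0
    c_sat: float = 3.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require r_max > r_min > 0")
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ValueError("ec50 and hill_n must be > 0")
        if self.c_sat <= self.ec50:
            raise ValueError("c_sat must exceed ec50")

    def occupancy(self, c):
        """Fractional sensor occupancy theta(c) in [0, 1)."""
        c = np.asarray(c, dtype=float)
        cn = np.power(np.clip(c, 0, None), self.hill_n)
        return cn / (self.ec50**self.hill_n + cn)

    def forward(self, c):
        return sensor_forward(c, self)

    def inverse(self, r):
        return sensor_inverse(r, self)

    def to_dict(self) -> dict:
        return {
            "ec50": self.ec50, "hill_n": self.hill_n,
            "r_min": self.r_min, "r_max": self.r_max, "c_sat": self.c_sat,
        }


def sensor_forward(c, model: SensorModel):
    """Emission ratio R for cGMP concentration ``c`` (uM); increasing in c."""
    c_arr = np.asarray(c, dtype=float)
    if (c_arr < 0).any():
        raise ValueError("cGMP concentration must be >= 0")
    r = model.r_min + (model.r_max - model.r_min) * model.occupancy(c_arr)
    return float(r) if np.isscalar(c) else r


def sensor_inverse(r, model: SensorModel, tol: float = 1e-9):
    """Invert the calibration: ratio -> (concentration, saturated flag).

    The algebraic inverse of :func:`sensor_forward` is applied where the
    inferred concentration is below ``model.c_sat``.  At or above ``c_sat``
    (including ratios at or beyond ``r_max``) the sensor cannot be
    quantified: the returned concentration is the lower bound ``c_sat`` and
    the saturated flag is set.  Ratios outside [r_min, r_max] beyond ``tol``
    are clipped with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    out_of_range = (r_arr < model.r_min - tol) | (r_arr > model.r_max + tol)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} ratio value(s) outside "
            f"[{model.r_min}, {model.r_max}]: clipped",
            stacklevel=2,
        )
    theta = (r_arr - model.r_min) / (model.r_max - model.r_min)
    theta = np.clip(theta, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = model.ec50 * np.power(theta / (1.0 - theta), 1.0 / model.hill_n)
    c = np.where(theta >= 1.0, np.inf, c)
    saturated = c >= model.c_sat
    c = np.where(saturated, model.c_sat, c)
    if np.isscalar(r):
        return float(c), bool(saturated)
    return c, saturated


@dataclass
class RegionTraces:
    """Background-corrected per-region, per-channel mean intensity traces.

    ``df`` is long form with columns ``t_s, region, <channels...>, empty``;
    empty-mask frames carry NaN intensities and ``empty=True``.
    """

    df: pd.DataFrame
    channels: list[str]
    dt: float

    def region(self, label: str) -> pd.DataFrame:
        sub = self.df[self.df["region"] == label]
        if sub.empty:
            raise KeyError(f"no traces for region {label!r}")
        return sub.reset_index(drop=True)

    @property
    def regions(self) -> list[str]:
        return list(self.df["region"].unique())


@dataclass
class RatioTrace:
    """A ratio trace for one region, with normalization and QC state."""

    region: str
    t: np.ndarray
    r: np.ndarray            # NaN on invalid frames
    valid: np.ndarray        # bool per frame
    kind: str = "F480/F535"
    baseline_window: tuple[float, float] | None = None
    r_baseline: float | None = None
    dr_over_r: np.ndarray | None = None
    snr: float | None = None
    excluded: bool = False
    notes: list[str] = field(default_factory=list)


def estimate_background(
    stack: TimeLapseStack,
    whole_masks: MaskSeries | None = None,
    bg_roi: tuple[int, int, int, int] | None = None,
    dilate_px: int = 5,
) -> pd.DataFrame:
    """Per-channel, per-frame background estimate.

    With ``bg_roi`` (row0, row1, col0, col1): the mean intensity of that
    rectangle, which must be disjoint from every whole mask.  Without a ROI:
    the median of pixels outside the whole mask dilated by ``dilate_px``.
    Returns a frame-indexed DataFrame with one column per channel name.
    """
    T = stack.n_frames
    out = {}
    if bg_roi is not None:
        r0, r1, c0, c1 = bg_roi
        if r1 <= r0 or c1 <= c0:
            raise ValueError("bg_roi must be a non-empty (row0, row1, col0, col1)")
        if whole_masks is not None and whole_masks.whole[:, r0:r1, c0:c1].any():
            raise ValueError("bg_roi intersects the thrombus mask")
        for ch in stack.channel_names:
            out[_CHANNEL_COLUMNS.get(ch, ch)] = stack.channel(ch)[
                :, r0:r1, c0:c1
            ].mean(axis=(1, 2))
    else:
        if whole_masks is None:
            raise ValueError("either whole_masks or bg_roi is required")
        structure = np.ones((2 * dilate_px + 1, 2 * dilate_px + 1), dtype=bool)
        bg_region = np.empty_like(whole_masks.whole)
        for i in range(T):
            bg_region[i] = ~ndimage.binary_dilation(
                whole_masks.whole[i], structure=structure
            )
        if not bg_region.any(axis=(1, 2)).all():
            raise ValueError("no background pixels left after dilation")
        for ch in stack.channel_names:
            movie = stack.channel(ch)
            vals = np.empty(T)
            for i in range(T):
                vals[i] = np.median(movie[i][bg_region[i]])
            out[_CHANNEL_COLUMNS.get(ch, ch)] = vals
    return pd.DataFrame(out)


def extract_traces(
    stack: TimeLapseStack, masks: MaskSeries, background: pd.DataFrame
) -> RegionTraces:
    """Mean background-corrected intensity per region and frame.

    The dynamic masks select the thrombus pixels of each raw channel image;
    the per-frame background is subtracted before averaging.  Empty-mask
    frames yield NaN and are flagged.
    """
    if masks.whole.shape[1:] != stack.shape_yx:
        raise ValueError("masks and stack have different image shapes")
    if masks.n_frames != stack.n_frames:
        raise ValueError("masks and stack have different frame counts")
    rows = []
    channels = [_CHANNEL_COLUMNS.get(ch, ch) for ch in stack.channel_names]
    movies = {col: stack.channel(ch).astype(np.float64)
              for ch, col in zip(stack.channel_names, channels)}
    for label in masks.labels:
        region_masks = masks.region(label)
        n_px = region_masks.sum(axis=(1, 2))
        if not n_px.any():
            raise ValueError(f"region {label!r} is empty in every frame")
        for i in range(masks.n_frames):
            row = {"t_s": i * stack.dt, "region": label, "empty": n_px[i] == 0}
            for col in channels:
                if n_px[i] == 0:
                    row[col] = np.nan
                else:
                    row[col] = (
                        movies[col][i][region_masks[i]].mean()
                        - background[col].iloc[i]
                    )
            rows.append(row)
    df = pd.DataFrame(rows)
    return RegionTraces(df=df, channels=channels, dt=stack.dt)


def compute_ratio(traces: RegionTraces) -> dict[str, RatioTrace]:
    """FRET ratio R = F480/F535 per region.

    Frames with non-positive F535 (or empty masks) are flagged invalid; a
    region whose trace is more than half invalid raises.
    """
    if not {"F480", "F535"} <= set(traces.channels):
        raise ValueError("traces lack F480/F535 emission channels")
    out = {}
    for label in traces.regions:
        sub = traces.region(label)
        t = sub["t_s"].to_numpy(dtype=float)
        f480 = sub["F480"].to_numpy(dtype=float)
        f535 = sub["F535"].to_numpy(dtype=float)
        valid = np.isfinite(f480) & np.isfinite(f535) & (f535 > 0)
        if valid.sum() < 0.5 * len(valid):
            raise ValueError(
                f"region {label!r}: more than 50% of frames are invalid"
            )
        r = np.full_like(f480, np.nan)
        r[valid] = f480[valid] / f535[valid]
        out[label] = RatioTrace(region=label, t=t, r=r, valid=valid)
    return out


def normalize_trace(t, x, baseline_window, valid=None):
    """Generic baseline normalization dX/X = (X - X_base)/X_base.

    ``baseline_window`` is a half-open time interval (start_s, end_s) that
    must contain at least 3 valid frames.  Returns (dx_over_x, x_baseline).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    valid = np.isfinite(x) if valid is None else np.asarray(valid, bool) & np.isfinite(x)
    lo, hi = baseline_window
    in_win = (t >= lo) & (t < hi) & valid
    if in_win.sum() < 3:
        raise ValueError("baseline window contains fewer than 3 valid frames")
    x_base = float(x[in_win].mean())
    if x_base == 0:
        raise ValueError("baseline mean is zero; cannot normalize")
    return (x - x_base) / x_base, x_base


def normalize(trace: RatioTrace, baseline_window: tuple[float, float]) -> RatioTrace:
    """Fill ``dr_over_r`` of a ratio trace relative to its baseline window."""
    dr, r_base = normalize_trace(trace.t, trace.r, baseline_window, trace.valid)
    trace.baseline_window = tuple(baseline_window)
    trace.r_baseline = r_base
    trace.dr_over_r = dr
    return trace


def snr_filter(
    ratio_traces: list[RatioTrace] | dict[str, RatioTrace],
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    threshold: float = 2.5,
) -> tuple[list[RatioTrace], list[RatioTrace], pd.DataFrame]:
    """Exclude traces with signal-to-noise ratio below ``threshold``.

    SNR is the peak absolute deviation of R from its baseline mean inside
    the response window, divided by the SD of R over the baseline window.
    A zero-variance baseline yields SNR = inf: the trace is retained with a
    warning.  Decisions are deterministic and logged.
    """
    if isinstance(ratio_traces, dict):
        ratio_traces = list(ratio_traces.values())
    retained, excluded, log_rows = [], [], []
    for tr in ratio_traces:
        lo, hi = baseline_window
        base = (tr.t >= lo) & (tr.t < hi) & tr.valid
        rlo, rhi = response_window
        resp = (tr.t >= rlo) & (tr.t < rhi) & tr.valid
        if base.sum() < 2 or resp.sum() == 0:
            raise ValueError(
                f"region {tr.region!r}: baseline/response windows too sparse"
            )
        r_base = tr.r[base].mean()
        sd = tr.r[base].std(ddof=1)
        peak = np.abs(tr.r[resp] - r_base).max()
        if sd == 0:
            warnings.warn(
                f"region {tr.region!r}: zero baseline variance, SNR undefined "
                "(trace retained)",
                stacklevel=2,
            )
            snr = np.inf
        else:
            snr = peak / sd
        tr.snr = float(snr)
        tr.excluded = bool(snr < threshold)
        if tr.excluded:
            tr.notes.append(f"excluded: SNR {snr:.3g} < {threshold}")
            logger.info("region %s excluded (SNR %.3g < %g)", tr.region, snr, threshold)
            excluded.append(tr)
        else:
            retained.append(tr)
        log_rows.append(
            {"region": tr.region, "snr": tr.snr, "excluded": tr.excluded,
             "threshold": threshold}
        )
    return retained, excluded, pd.DataFrame(log_rows)


def fura_signal(traces: RegionTraces) -> dict[str, RatioTrace]:
    """Fura-2 Ca2+ ratio F340/F380 per region (background-corrected).

    The ratio rises with intracellular Ca2+.  For lead-lag display against
    cGMP, the trace can be normalized and sign-inverted downstream.
    """
    if not {"F340", "F380"} <= set(traces.channels):
        raise ValueError("traces lack the F340/F380 excitation channels")
    out = {}
    for label in traces.regions:
        sub = traces.region(label)
        t = sub["t_s"].to_numpy(dtype=float)
        f340 = sub["F340"].to_numpy(dtype=float)
        f380 = sub["F380"].to_numpy(dtype=float)
        valid = np.isfinite(f340) & np.isfinite(f380) & (f380 > 0)
        ratio = np.full_like(f340, np.nan)
        ratio[valid] = f340[valid] / f380[valid]
        out[label] = RatioTrace(
            region=label, t=t, r=ratio, valid=valid, kind="F340/F380"
        )
    return out
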