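"""Synthetic dual-emission thrombus movies with exported ground truth.

The generator encodes the signal model of shear-dependent platelet cGMP
imaging so that every downstream stage (segmentation, ratiometrics,
kinetics, statistics) can be tested end to end without real data:

* a flow on/off schedule drives region-wise cGMP with first-order on/off
  kinetics (sustained elevation while flow is on, exponential return to the
  basal level within tens of seconds after flow cessation);
* the thrombus periphery carries a higher cGMP concentration than its core
  (shear-exposed shell versus densely packed interior), by default above the
  sensor saturation bound so that saturation handling is exercised;
* cGMP maps to anticorrelated CFP/YFP emission through the Hill-type sensor
  model: photons are redistributed between donor and acceptor at fixed total
  brightness, so the pixelwise CFP/YFP ratio equals the calibration curve
  exactly in noise-free rendering;
* optional Fura-2 channels render a Ca2+ signal coupled to cGMP with a sign
  (default anticorrelated) and a time lag (default 2 s, Ca2+ follows cGMP);
* noise is Poisson shot noise on expected counts plus additive Gaussian read
  noise, fully seeded: the same seed reproduces the stack bit for bit.

Geometry is a centered disc whose area follows a configurable growth/
dissolution profile; an outer annulus (default 20% of the radius) is the
periphery.  Brightness across the thrombus is the projected thickness of a
hemispherical cap, ``sqrt(1 - (d/r)^2)``, so the summed-emission image has
the shallow dome profile typical of epifluorescence of a mounded aggregate;
:func:`consistent_threshold` returns the manual segmentation threshold whose
1.2 x intensity-erosion contour coincides with the geometric core boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .io import CFP, FURA_340, FURA_380, YFP, TimeLapseStack
from .ratiometrics import SensorModel
from .segment import MaskSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FlowSchedule",
    "CgmpKinetics",
    "AreaProfile",
    "CaModel",
    "NoiseModel",
    "Geometry",
    "Brightness",
    "GroundTruth",
    "make_flow_schedule",
    "simulate_region_cgmp",
    "simulate_region_ca",
    "make_area_profile",
    "constant_area_profile",
    "render_movie",
    "consistent_threshold",
    "default_flow_movie",
    "default_growth_movie",
    "write_ground_truth",
]


@dataclass(frozen=True)
class FlowSchedule:
    """Flow on/off protocol on a regular frame grid.

    ``on_windows`` are half-open (start_s, end_s) intervals with flow on,
    sorted, non-overlapping and contained in [0, duration).
    """

    duration: float
    dt: float = 1.0
    on_windows: tuple[tuple[float, float], ...] = ()
    shear_rate_on: float = 500.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        prev_end = -np.inf
        for start, end in self.on_windows:
            if not (0 <= start < end <= self.duration):
                raise ValueError(
                    f"window ({start}, {end}) outside [0, {self.duration})"
                )
            if start < prev_end:
                raise ValueError("flow windows overlap or are unsorted")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def flow_on(self) -> np.ndarray:
        """Boolean per-frame flow indicator (half-open window convention)."""
        t = self.times
        on = np.zeros(self.n_frames, dtype=bool)
        for start, end in self.on_windows:
            on |= (t >= start) & (t < end)
        return on

    def shear_rate(self) -> np.ndarray:
        return np.where(self.flow_on(), self.shear_rate_on, 0.0)


def make_flow_schedule(
    on_windows, duration: float, dt: float = 1.0, shear_rate_on: float = 500.0
) -> FlowSchedule:
    """Validated flow schedule from a list of (start, end) on-intervals."""
    windows = tuple(tuple(map(float, w)) for w in sorted(on_windows))
    return FlowSchedule(
        duration=duration, dt=dt, on_windows=windows, shear_rate_on=shear_rate_on
    )


@dataclass(frozen=True)
class CgmpKinetics:
    """First-order cGMP on/off kinetics per thrombus region (uM, s).

    While flow is on, cGMP relaxes toward the region's on-level with time
    constant ``tau_on``; after flow cessation it relaxes back to ``c_base``
    with ``tau_off``.  The periphery on-level exceeds the core on-level
    (shear-exposed shell), and the default periphery level lies above the
    sensor saturation bound.  Defaults let the trace re-enter a few percent
    of baseline well within ~20 s of flow-off.
    """

    c_base: float = 0.1
    c_on_core: float = 0.8
    c_on_periphery: float = 4.0
    tau_on: float = 4.0
    tau_off: float = 5.0

    def __post_init__(self) -> None:
        if not (self.c_on_periphery >= self.c_on_core >= self.c_base >= 0):
            raise ValueError("require c_on_periphery >= c_on_core >= c_base >= 0")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("time constants must be > 0")


def simulate_region_cgmp(schedule: FlowSchedule, kin: CgmpKinetics) -> pd.DataFrame:
    """Region cGMP traces (uM) on the schedule's frame grid.

    Exact per-frame integration of dc/dt = (c_target - c)/tau with the
    target and time constant switching with the flow state (c_on while on,
    c_base while off).  Columns: ``t, core, periphery``.
    """
    if schedule.dt >= min(kin.tau_on, kin.tau_off) / 2:
        warnings.warn(
            "frame interval is coarse relative to the kinetics "
            "(dt >= tau/2); transients are under-resolved",
            stacklevel=2,
        )
    on = schedule.flow_on()
    n = schedule.n_frames
    out = {"t": schedule.times}
    for region, c_on in (("core", kin.c_on_core), ("periphery", kin.c_on_periphery)):
        c = np.empty(n)
        c[0] = kin.c_base if not on[0] else kin.c_base  # starts at rest
        for k in range(1, n):
            target = c_on if on[k - 1] else kin.c_base
            tau = kin.tau_on if on[k - 1] else kin.tau_off
            decay = np.exp(-schedule.dt / tau)
            c[k] = target + (c[k - 1] - target) * decay
        out[region] = c
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CaModel:
    """Coupling of the Ca2+ signal to cGMP (arbitrary concentration units).

    ``coupling = -1`` (default) makes Ca2+ anticorrelated with cGMP: the
    pre-activated thrombus rests at ``ca_high`` and Ca2+ falls when cGMP
    rises, after a delay ``lag`` (cGMP changes precede Ca2+ changes).
    """

    ca_base: float = 0.1
    ca_high: float = 1.0
    lag: float = 2.0
    coupling: int = -1

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.coupling not in (-1, 1):
            raise ValueError("coupling must be -1 or +1")
        if self.ca_high <= self.ca_base:
            raise ValueError("ca_high must exceed ca_base")


def simulate_region_ca(
    cgmp: pd.DataFrame, ca: CaModel, kin: CgmpKinetics
) -> pd.DataFrame:
    """Ca2+ traces driven by the (lagged) normalized cGMP drive.

    The drive is the cGMP excursion above base, normalized to the largest
    configured on-level, shifted by ``ca.lag`` seconds (edge-held).  With
    anticorrelated coupling Ca2+ = ca_high - (ca_high - ca_base) * drive.
    """
    t = cgmp["t"].to_numpy()
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    shift = int(round(ca.lag / dt))
    span = max(kin.c_on_periphery - kin.c_base, 1e-12)
    out = {"t": t}
    for region in ("core", "periphery"):
        drive = np.clip((cgmp[region].to_numpy() - kin.c_base) / span, 0.0, 1.0)
        if shift > 0:
            drive = np.concatenate([np.full(shift, drive[0]), drive[:-shift]])
        if ca.coupling == -1:
            out[region] = ca.ca_high - (ca.ca_high - ca.ca_base) * drive
        else:
            out[region] = ca.ca_base + (ca.ca_high - ca.ca_base) * drive
    return pd.DataFrame(out)


@dataclass(frozen=True)
class AreaProfile:
    """Thrombus area (um^2) over time; non-negative, shared time grid."""

    t: np.ndarray
    area: np.ndarray
    a_base: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.area, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "area", a)
        if len(t) != len(a):
            raise ValueError("t and area must have equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("time grid must be strictly increasing")
        if (a < 0).any():
            raise ValueError("area must be >= 0 everywhere")


def make_area_profile(
    a_base: float,
    a_max: float,
    t_injury: float,
    t_max: float,
    a_end: float,
    t_end: float,
    shape: str = "linear",
    dt: float = 1.0,
) -> AreaProfile:
    """Unimodal growth/dissolution area profile on a regular grid.

    Rises from ``a_base`` at ``t_injury`` to ``a_max`` at ``t_max`` and
    decays to ``a_end`` at ``t_end``; ``shape`` selects linear ramps or
    logistic transitions (knot values matched to <1% of ``a_max``).
    """
    if not (t_injury < t_max < t_end):
        raise ValueError("require t_injury < t_max < t_end")
    if not (a_base <= a_end <= a_max):
        raise ValueError("require a_base <= a_end <= a_max")
    if shape not in ("linear", "logistic"):
        raise ValueError("shape must be 'linear' or 'logistic'")
    t = np.arange(0.0, t_end + dt / 2, dt)
    a = np.full_like(t, float(a_base))
    rise = (t >= t_injury) & (t <= t_max)
    fall = t > t_max
    if shape == "linear":
        a[rise] = a_base + (a_max - a_base) * (t[rise] - t_injury) / (t_max - t_injury)
        a[fall] = a_max + (a_end - a_max) * (t[fall] - t_max) / (t_end - t_max)
    else:
        # logistic transitions: value within 0.5% of each knot at the knot
        k_knot = 2 * np.log(199.0)
        mid_up = 0.5 * (t_injury + t_max)
        k_up = k_knot / (t_max - t_injury)
        seg = t >= t_injury
        a[seg] = a_base + (a_max - a_base) / (1 + np.exp(-k_up * (t[seg] - mid_up)))
        if a_end < a_max:
            mid_dn = 0.5 * (t_max + t_end)
            k_dn = k_knot / (t_end - t_max)
            a[fall] = a_end + (a_max - a_end) / (1 + np.exp(k_dn * (t[fall] - mid_dn)))
    return AreaProfile(t=t, area=a, a_base=a_base)


def constant_area_profile(area_um2: float, duration: float, dt: float = 1.0) -> AreaProfile:
    """Preformed thrombus of fixed area (the flow-chamber scenario)."""
    t = np.arange(0.0, duration, dt)
    return AreaProfile(t=t, area=np.full_like(t, float(area_um2)), a_base=area_um2)


@dataclass(frozen=True)
class NoiseModel:
    """Camera/photon noise: Poisson shot noise plus Gaussian read noise.

    ``background_level`` is the mean background in counts added to every
    channel (tissue autofluorescence plus camera offset).  With
    ``shot_noise`` on, pixel values are Poisson draws of the expected
    counts; read noise is additive Gaussian with SD ``read_noise_sd``.
    Everything is driven by ``seed``.
    """

    background_level: float = 150.0
    shot_noise: bool = True
    read_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")

    @property
    def active(self) -> bool:
        return self.shot_noise or self.read_noise_sd > 0


@dataclass(frozen=True)
class Geometry:
    """Image geometry: frame shape, pixel size, thrombus center, annulus."""

    shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 1.0
    center: tuple[float, float] | None = None
    annulus_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not (0 < self.annulus_frac < 1):
            raise ValueError("annulus_frac must be in (0, 1)")

    @property
    def center_yx(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass(frozen=True)
class Brightness:
    """Peak emission amplitudes (counts above background at the apex)."""

    fret_total: float = 140.0  # CFP + YFP summed counts
    fura_total: float = 140.0  # F340 + F380 summed counts
    fura_r_min: float = 0.5    # Fura-2 ratio bounds over the Ca range
    fura_r_max: float = 2.0

    def __post_init__(self) -> None:
        if self.fret_total <= 0 or self.fura_total <= 0:
            raise ValueError("brightness amplitudes must be > 0")
        if not (self.fura_r_max > self.fura_r_min > 0):
            raise ValueError("require fura_r_max > fura_r_min > 0")


@dataclass
class GroundTruth:
    """Everything the generator knows: masks, region traces, parameters."""

    masks: MaskSeries
    cgmp: pd.DataFrame          # columns t, core, periphery (uM)
    ca: pd.DataFrame | None     # columns t, core, periphery (arb. units)
    params: dict = field(default_factory=dict)


def consistent_threshold(
    noise: NoiseModel | None = None,
    brightness: Brightness | None = None,
    geometry: Geometry | None = None,
    core_factor: float = 1.2,
) -> float:
    """Manual whole-thrombus threshold matched to the rendered dome.

    Returns the summed-emission threshold T such that the intensity-erosion
    core criterion (pixels >= core_factor * T) cuts the hemispherical-cap
    brightness profile exactly at the geometric core/periphery boundary
    (radius (1 - annulus_frac) * r).  Solving
    ``core_factor * T = bg + A * sqrt(1 - (1 - w)^2)`` for T.
    """
    noise = noise or NoiseModel()
    brightness = brightness or Brightness()
    geometry = geometry or Geometry()
    bg_sum = 2.0 * noise.background_level
    f_core = np.sqrt(1.0 - (1.0 - geometry.annulus_frac) ** 2)
    return float((bg_sum + brightness.fret_total * f_core) / core_factor)


def _dome(dist_px: np.ndarray, r_px: float) -> np.ndarray:
    """Projected thickness of a hemispherical cap of radius r (0 outside)."""
    u2 = (dist_px / r_px) ** 2
    return np.sqrt(np.clip(1.0 - u2, 0.0, None))


def render_movie(
    area_profile: AreaProfile,
    cgmp: pd.DataFrame,
    geometry: Geometry | None = None,
    sensor: SensorModel | None = None,
    noise: NoiseModel | None = None,
    brightness: Brightness | None = None,
    ca_model: CaModel | None = None,
    kinetics: CgmpKinetics | None = None,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render the forward model into a movie plus exact ground truth.

    The thrombus is a centered disc of area A(t); the outer annulus
    (fraction ``annulus_frac`` of the radius) carries the periphery cGMP,
    the interior the core cGMP.  Per pixel the expected emission above
    background is split between CFP and YFP so that their ratio equals
    ``sensor.forward(c)`` exactly:

        CFP = S(d) * R/(1+R),   YFP = S(d) / (1+R),   R = sensor_forward(c)

    with ``S(d)`` the dome brightness.  cGMP binding therefore raises CFP
    and lowers YFP (anticorrelated channels).  With ``ca_model`` set, Fura-2
    channels are rendered analogously from the lagged Ca2+ traces.  With
    noise active the stack is Poisson + read-noise corrupted uint16; with
    ``noise=None`` (or all noise off and zero background) expectations are
    returned as float64.
    """
    geometry = geometry or Geometry()
    sensor = sensor or SensorModel()
    brightness = brightness or Brightness()
    if kinetics is None and ca_model is not None:
        raise ValueError("ca_model requires the CgmpKinetics used for the cGMP traces")

    t = cgmp["t"].to_numpy()
    if len(t) != len(area_profile.t) or not np.allclose(t, area_profile.t):
        raise ValueError("cGMP traces and area profile must share the time grid")
    dt = t[1] - t[0] if len(t) > 1 else 1.0

    H, W = geometry.shape
    cy, cx = geometry.center_yx
    px_area = geometry.pixel_size_um**2
    r_max_px = np.sqrt(area_profile.area.max() / np.pi) / geometry.pixel_size_um
    if (cy - r_max_px < 0 or cy + r_max_px > H - 1
            or cx - r_max_px < 0 or cx + r_max_px > W - 1):
        raise ValueError("thrombus at maximal area does not fit in the frame")

    yy, xx = np.mgrid[0:H, 0:W]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    channels = [CFP, YFP]
    ca_traces = None
    if ca_model is not None:
        channels += [FURA_340, FURA_380]
        ca_traces = simulate_region_ca(cgmp, ca_model, kinetics)

    T = len(t)
    bg = noise.background_level if noise is not None else 0.0
    expected = np.full((T, len(channels), H, W), float(bg))
    whole = np.zeros((T, H, W), dtype=bool)
    core = np.zeros_like(whole)

    r_ratio = {
        "core": sensor.forward(cgmp["core"].to_numpy()),
        "periphery": sensor.forward(cgmp["periphery"].to_numpy()),
    }
    if ca_traces is not None:
        ca_lo, ca_hi = ca_model.ca_base, ca_model.ca_high
        fura_ratio = {}
        for region in ("core", "periphery"):
            norm = (ca_traces[region].to_numpy() - ca_lo) / (ca_hi - ca_lo)
            fura_ratio[region] = (
                brightness.fura_r_min
                + (brightness.fura_r_max - brightness.fura_r_min) * np.clip(norm, 0, 1)
            )

    for k in range(T):
        a = area_profile.area[k]
        if a <= 0:
            continue
        r_px = np.sqrt(a / np.pi) / geometry.pixel_size_um
        inside = dist <= r_px
        if not inside.any():
            continue
        whole[k] = inside
        core[k] = dist <= (1.0 - geometry.annulus_frac) * r_px
        dome = _dome(dist, r_px)
        for region, region_mask in (("core", core[k]), ("periphery", inside & ~core[k])):
            if not region_mask.any():
                continue
            s = brightness.fret_total * dome[region_mask]
            r = r_ratio[region][k]
            expected[k, 0][region_mask] = bg + s * r / (1.0 + r)
            expected[k, 1][region_mask] = bg + s / (1.0 + r)
            if ca_traces is not None:
                s_ca = brightness.fura_total * dome[region_mask]
                rho = fura_ratio[region][k]
                expected[k, 2][region_mask] = bg + s_ca * rho / (1.0 + rho)
                expected[k, 3][region_mask] = bg + s_ca / (1.0 + rho)

    if noise is not None and noise.active:
        rng = np.random.default_rng(noise.seed)
        data = expected
        if noise.shot_noise:
            data = rng.poisson(data).astype(np.float64)
        if noise.read_noise_sd > 0:
            data = data + rng.normal(0.0, noise.read_noise_sd, size=data.shape)
        data = np.rint(data)
        n_clipped = int((data < 0).sum() + (data > 65535).sum())
        if n_clipped:
            logger.info("clipped %d pixels to the uint16 range", n_clipped)
        data = np.clip(data, 0, 65535).astype(np.uint16)
    else:
        data = expected

    stack = TimeLapseStack(
        data=data,
        channel_names=channels,
        dt=dt,
        pixel_size_um=geometry.pixel_size_um,
    )

    masks = MaskSeries(
        whole=whole,
        core=core,
        periphery=whole & ~core,
        params={"source": "synthetic ground truth",
                "annulus_frac": geometry.annulus_frac},
    )
    params = {
        "geometry": asdict(geometry),
        "sensor": sensor.to_dict(),
        "brightness": asdict(brightness),
        "noise": asdict(noise) if noise is not None else None,
        "ca_model": asdict(ca_model) if ca_model is not None else None,
        "kinetics": asdict(kinetics) if kinetics is not None else None,
        "dt": dt,
        "pixel_area_um2": px_area,
    }
    gt = GroundTruth(masks=masks, cgmp=cgmp, ca=ca_traces, params=params)
    return stack, gt


def default_flow_movie(
    seed: int = 0,
    duration: float = 240.0,
    dt: float = 1.0,
    on_windows=((60.0, 120.0),),
    include_ca: bool = False,
    noise: NoiseModel | None = None,
    geometry: Geometry | None = None,
    kinetics: CgmpKinetics | None = None,
    sensor: SensorModel | None = None,
    area_um2: float = 5000.0,
) -> tuple[TimeLapseStack, GroundTruth, FlowSchedule]:
    """Default flow-chamber scenario: preformed thrombus, flow on 60-120 s.

    1 Hz acquisition, constant thrombus area, default kinetics (periphery
    saturating at 4 uM, core 0.8 uM) and default Poisson + read noise with
    the given seed.
    """
    geometry = geometry or Geometry()
    kinetics = kinetics or CgmpKinetics()
    sensor = sensor or SensorModel()
    if noise is None:
        noise = NoiseModel(seed=seed)
    schedule = make_flow_schedule(on_windows, duration=duration, dt=dt)
    cgmp = simulate_region_cgmp(schedule, kinetics)
    area = constant_area_profile(area_um2, duration=duration, dt=dt)
    ca_model = CaModel() if include_ca else None
    stack, gt = render_movie(
        area, cgmp, geometry=geometry, sensor=sensor, noise=noise,
        ca_model=ca_model, kinetics=kinetics,
    )
    gt.params["schedule"] = {
        "duration": duration, "dt": dt,
        "on_windows": [list(w) for w in schedule.on_windows],
        "shear_rate_on": schedule.shear_rate_on,
    }
    return stack, gt, schedule


def default_growth_movie(
    seed: int = 0,
    dt: float = 1.0,
    a_max: float = 2000.0,
    t_max: float = 60.0,
    a_end: float = 800.0,
    t_end: float = 300.0,
    shape: str = "linear",
    noise: NoiseModel | None = None,
    geometry: Geometry | None = None,
    sensor: SensorModel | None = None,
) -> tuple[TimeLapseStack, GroundTruth, AreaProfile]:
    """Default injury scenario: thrombus grows, peaks and partly dissolves.

    Endogenous cGMP is held at steady region levels (shear-exposed periphery
    above core) while the area follows the requested profile; used to test
    growth-metric recovery through the imaging pipeline.  The default pixel
    size (0.5 um, a 40x intravital configuration) keeps the area
    quantization of small dissolving thrombi below a few percent.
    """
    geometry = geometry or Geometry(shape=(160, 160), pixel_size_um=0.5)
    sensor = sensor or SensorModel()
    if noise is None:
        noise = NoiseModel(seed=seed)
    area = make_area_profile(
        a_base=0.0, a_max=a_max, t_injury=0.0, t_max=t_max,
        a_end=a_end, t_end=t_end, shape=shape, dt=dt,
    )
    kin = CgmpKinetics()
    n = len(area.t)
    cgmp = pd.DataFrame({
        "t": area.t,
        "core": np.full(n, kin.c_on_core),
        "periphery": np.full(n, kin.c_on_periphery),
    })
    stack, gt = render_movie(
        area, cgmp, geometry=geometry, sensor=sensor, noise=noise, kinetics=kin,
    )
    gt.params["area_profile"] = {
        "a_base": 0.0, "a_max": a_max, "t_max": t_max,
        "a_end": a_end, "t_end": t_end, "shape": shape,
    }
    return stack, gt, area


def write_ground_truth(gt: GroundTruth, outdir) -> None:
    """Persist ground truth: traces as CSV, masks as TIFF, params as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.cgmp.to_csv(outdir / "gt_cgmp.csv", index=False, float_format="%.10g")
    if gt.ca is not None:
        gt.ca.to_csv(outdir / "gt_ca.csv", index=False, float_format="%.10g")
    for label in gt.masks.labels:
        tifffile.imwrite(
            outdir / f"gt_mask_{label}.tif",
            (gt.masks.region(label).astype(np.uint8) * 255),
        )
    with open(outdir / "gt_params.json", "w") as fh:
        json.dump(gt.params, fh, indent=2, default=str)
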