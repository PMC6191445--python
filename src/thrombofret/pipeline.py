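"""End-to-end pipeline: simulate/read -> segment -> quantify -> kinetics.

``run_pipeline`` executes the full analysis in acquisition order and
returns an in-memory bundle; ``write_report`` persists it with stable file
names and a provenance manifest (config, seed, versions, per-file SHA-256
checksums).  Identical configuration and seed reproduce identical numeric
outputs and therefore an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import kinetics as tk
from . import ratiometrics as rm
from . import segment as seg
from . import synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_report"]

#: sustained-response rule: dR/R beyond this many baseline SDs ...
RESPONSE_SD_FACTOR = 3.0
#: ... for at least this many consecutive response-window frames
RESPONSE_MIN_FRAMES = 5


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Either ``stack_path`` points at a TIFF movie, or ``simulate`` holds
    keyword arguments for :func:`thrombofret.synth.default_flow_movie`
    (``{}`` simulates the default flow on/off scenario).  Windows default
    to the flow schedule: baseline = the 10 valid frames before the first
    flow-on event, response = the span of the on-windows.
    """

    simulate: dict | None = field(default_factory=dict)
    stack_path: str | None = None
    channel_names: list[str] | None = None
    dt: float | None = None
    pixel_size_um: float | None = None
    seg_params: seg.SegmentationParams = field(default_factory=seg.SegmentationParams)
    sensor: rm.SensorModel = field(default_factory=rm.SensorModel)
    baseline_window: tuple[float, float] | None = None
    response_window: tuple[float, float] | None = None
    snr_threshold: float = 2.5
    lead_lag_max_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.stack_path is None:
            raise ValueError("config needs either simulate parameters or a stack path")
        if self.simulate is not None and self.stack_path is not None:
            raise ValueError("simulate and stack_path are mutually exclusive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seg_params"] = asdict(self.seg_params)
        d["sensor"] = self.sensor.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seg_params" in d and isinstance(d["seg_params"], dict):
            d["seg_params"] = seg.SegmentationParams(**d["seg_params"])
        if "sensor" in d and isinstance(d["sensor"], dict):
            d["sensor"] = rm.SensorModel(**d["sensor"])
        for key in ("baseline_window", "response_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _default_windows(config: RunConfig, schedule, times: np.ndarray):
    """Baseline/response windows from the flow schedule (or trace halves)."""
    baseline = config.baseline_window
    response = config.response_window
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    if schedule is not None and schedule.on_windows:
        first_on = schedule.on_windows[0][0]
        last_off = schedule.on_windows[-1][1]
        if baseline is None:
            baseline = (max(0.0, first_on - 10 * dt), first_on)
        if response is None:
            response = (first_on, last_off)
    else:
        # no stimulus: baseline = first 10 frames, response = the rest
        if baseline is None:
            baseline = (times[0], times[0] + 10 * dt)
        if response is None:
            response = (times[0] + 10 * dt, times[-1] + dt)
    return baseline, response


def _sustained_response(trace: rm.RatioTrace, response_window) -> bool:
    """True if dR/R exceeds 3 x baseline SD for >= 5 consecutive frames."""
    if trace.dr_over_r is None or trace.r_baseline is None:
        return False
    lo, hi = trace.baseline_window
    base = (trace.t >= lo) & (trace.t < hi) & trace.valid
    sd = np.nanstd(trace.r[base] / trace.r_baseline - 1.0, ddof=1)
    rlo, rhi = response_window
    resp = (trace.t >= rlo) & (trace.t < rhi) & trace.valid
    above = np.abs(trace.dr_over_r[resp]) > RESPONSE_SD_FACTOR * sd
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= RESPONSE_MIN_FRAMES:
            return True
    return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/read -> segment -> ratiometrics -> kinetics.

    Returns a bundle with the stack metadata, masks, area table, traces,
    ratio traces (with dR/R, inferred cGMP and QC state), the growth
    kinetics report and a scalar summary.  Any stage failure propagates
    with the stage named in the log.
    """
    bundle: dict = {"config": config.to_dict()}
    schedule = None
    ground_truth = None

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        logger.info("stage simulate: default flow movie, args %s", sim_kwargs)
        stack, ground_truth, schedule = synth.default_flow_movie(**sim_kwargs)
        # the generator's matched manual threshold, unless the user set one
        if isinstance(config.seg_params.threshold, str):
            noise = synth.NoiseModel(**ground_truth.params["noise"])
            geometry = synth.Geometry(
                **{**ground_truth.params["geometry"],
                   "shape": tuple(ground_truth.params["geometry"]["shape"]),
                   "center": None}
            )
            thr = synth.consistent_threshold(
                noise=noise, geometry=geometry,
                brightness=synth.Brightness(**ground_truth.params["brightness"]),
                core_factor=config.seg_params.core_factor,
            )
            config = RunConfig.from_dict(
                {**config.to_dict(),
                 "seg_params": {**asdict(config.seg_params), "threshold": thr}}
            )
            logger.info("using generator-matched manual threshold %g", thr)
    else:
        logger.info("stage read: %s", config.stack_path)
        stack = tio.read_stack(
            config.stack_path, channel_names=config.channel_names,
            dt=config.dt, pixel_size_um=config.pixel_size_um,
        )

    logger.info("stage segment")
    masks = seg.segment_stack(stack, config.seg_params)
    areas = seg.area_table(masks, stack.dt, stack.pixel_size_um)

    logger.info("stage ratiometrics")
    background = rm.estimate_background(stack, whole_masks=masks)
    traces = rm.extract_traces(stack, masks, background)
    ratios = rm.compute_ratio(traces)

    baseline_window, response_window = _default_windows(config, schedule, stack.times)
    for trace in ratios.values():
        rm.normalize(trace, baseline_window)
    retained, excluded, snr_log = rm.snr_filter(
        ratios, baseline_window, response_window, threshold=config.snr_threshold
    )

    # inferred cGMP with saturation handling
    inferred = {}
    for label, trace in ratios.items():
        c, saturated = rm.sensor_inverse(
            np.where(trace.valid, trace.r, np.nan), config.sensor
        )
        inferred[label] = {"c_uM": c, "saturated": saturated}

    fura = None
    if stack.has_channels(tio.FURA_340, tio.FURA_380):
        fura = rm.fura_signal(traces)
        for trace in fura.values():
            rm.normalize(trace, baseline_window)

    logger.info("stage kinetics")
    whole_area = areas[areas["region"] == "whole"]
    report = tk.growth_metrics(
        whole_area["t_s"].to_numpy(), whole_area["area_um2"].to_numpy()
    )

    summary: dict = {
        "baseline_window": list(baseline_window),
        "response_window": list(response_window),
        "n_frames": stack.n_frames,
        "regions": {},
    }
    rlo, rhi = response_window
    for label, trace in ratios.items():
        resp = (trace.t >= rlo) & (trace.t < rhi) & trace.valid
        region_summary = {
            "mean_dr_over_r_response": float(np.nanmean(trace.dr_over_r[resp])),
            "snr": trace.snr,
            "excluded": trace.excluded,
            "responded": _sustained_response(trace, response_window),
        }
        # plateau = mean over the second half of the response window
        plateau = resp & (trace.t >= (rlo + rhi) / 2.0)
        if plateau.any():
            r_plateau = float(np.nanmean(trace.r[plateau]))
            c_pl, sat_pl = rm.sensor_inverse(r_plateau, config.sensor)
            region_summary.update(
                {"plateau_r": r_plateau, "plateau_c_uM": c_pl,
                 "plateau_saturated": sat_pl}
            )
        summary["regions"][label] = region_summary

    if schedule is not None and schedule.on_windows:
        t_off = schedule.on_windows[-1][1]
        whole_trace = ratios["whole"]
        summary["recovery_time_s"] = tk.recovery_time(
            whole_trace.t, whole_trace.dr_over_r, t_off, band=0.05
        )

    if fura is not None:
        ll = tk.lead_lag(
            ratios["whole"].t, ratios["whole"].dr_over_r,
            fura["whole"].dr_over_r, max_lag=config.lead_lag_max_s,
            invert_y=True, smooth_sigma=1.0,
        )
        summary["lead_lag"] = {
            "lag_s": ll.lag_s, "peak_corr": ll.peak_corr,
            "low_confidence": ll.low_confidence,
            "estimator": "derivative cross-correlation (quantitative addition; "
                         "source comparisons of trace order were visual)",
        }

    bundle.update(
        stack=stack, masks=masks, areas=areas, background=background,
        traces=traces, ratios=ratios, inferred=inferred, fura=fura,
        snr_log=snr_log, kinetics=report, summary=summary,
        ground_truth=ground_truth, schedule=schedule,
        windows={"baseline": baseline_window, "response": response_window},
    )
    return bundle


def _ratio_table(bundle: dict) -> pd.DataFrame:
    rows = []
    fura = bundle.get("fura")
    for label, trace in bundle["ratios"].items():
        inf = bundle["inferred"][label]
        ca = fura[label].r if fura is not None and label in fura else None
        for i, t in enumerate(trace.t):
            row = {
                "t_s": t, "region": label,
                "R": trace.r[i],
                "dR_over_R": trace.dr_over_r[i] if trace.dr_over_r is not None else np.nan,
                "snr": trace.snr, "excluded": trace.excluded,
                "c_uM": inf["c_uM"][i], "saturated": bool(inf["saturated"][i]),
            }
            if ca is not None:
                row["ca_ratio"] = ca[i]
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(bundle: dict, outdir) -> dict:
    """Write all pipeline artifacts and the provenance manifest.

    Stable file names, CSVs with documented headers, JSON manifest listing
    every file with its SHA-256 checksum.  Re-writing the same bundle is
    idempotent (identical checksums).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"

    trace_df = bundle["traces"].df
    files = {
        "areas.csv": lambda p: bundle["areas"].to_csv(p, index=False, float_format=ff),
        "traces.csv": lambda p: trace_df.to_csv(p, index=False, float_format=ff),
        "ratios.csv": lambda p: _ratio_table(bundle).to_csv(p, index=False, float_format=ff),
        "snr_log.csv": lambda p: bundle["snr_log"].to_csv(p, index=False, float_format=ff),
        "kinetics.csv": lambda p: pd.DataFrame(
            [bundle["kinetics"].to_dict()]
        ).to_csv(p, index=False, float_format=ff),
    }
    for name, writer in files.items():
        writer(outdir / name)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True, default=_json_default)
    with open(outdir / "config.json", "w") as fh:
        json.dump(bundle["config"], fh, indent=2, sort_keys=True, default=_json_default)

    checksums = {}
    for name in [*files, "summary.json", "config.json"]:
        checksums[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
    manifest = {
        "files": checksums,
        "combined_hash": hashlib.sha256(
            json.dumps(checksums, sort_keys=True).encode()
        ).hexdigest(),
        "seed": bundle["config"].get("seed"),
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__

    return {
        "thrombofret": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }
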