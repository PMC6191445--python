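"""Dynamic thrombus segmentation and core/periphery partition.

The thrombus is segmented per frame from the summed CFP + YFP emission image:
the sum is Gaussian-blurred (default sigma 2 px), thresholded (manual count
value, or Otsu on the brightest frame), and the largest 8-connected component
is kept as the whole-thrombus mask.  The mask is then partitioned by an
intensity-erosion rule: pixels at least ``core_factor`` (default 1.2) times
the whole-thrombus threshold form the core; the remainder of the mask is the
flow-exposed periphery.  A morphological-erosion alternative for the core is
available behind ``core_method="erosion"`` for comparison.

Per frame, core and periphery always partition the whole mask exactly.
Empty-mask frames are flagged, never dropped: downstream trace extraction
skips them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .io import CFP, YFP, TimeLapseStack

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "MaskSeries",
    "preprocess",
    "segment_whole",
    "split_core_periphery",
    "segment_stack",
    "area_table",
]

REGION_LABELS = ("whole", "core", "periphery")


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the dynamic-mask pipeline.

    blur_sigma
        Gaussian blur radius in pixels applied to the CFP+YFP sum (>= 0).
    threshold
        Whole-thrombus intensity threshold in summed counts, or ``"otsu"``
        to derive it from the brightest frame of the blurred sum.
    core_factor
        Core pixels are those >= ``core_factor * threshold`` (> 1).
    core_method
        ``"intensity"`` (default) or ``"erosion"`` (morphological erosion of
        the whole mask by ``erosion_px``).
    """

    blur_sigma: float = 2.0
    threshold: float | str = "otsu"
    core_factor: float = 1.2
    core_method: str = "intensity"
    erosion_px: int = 5

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.core_factor <= 1:
            raise ValueError("core_factor must be > 1")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be a count value or 'otsu'")
        if self.core_method not in ("intensity", "erosion"):
            raise ValueError("core_method must be 'intensity' or 'erosion'")


@dataclass
class MaskSeries:
    """Per-frame boolean masks for the thrombus regions.

    ``whole`` is always present; ``core``/``periphery`` appear after
    :func:`split_core_periphery`.  ``empty`` flags frames whose whole mask
    has no pixels.  ``params`` records the provenance (threshold actually
    used, blur sigma, core rule).
    """

    whole: np.ndarray  # (T, H, W) bool
    core: np.ndarray | None = None
    periphery: np.ndarray | None = None
    empty: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.whole = np.asarray(self.whole, dtype=bool)
        if self.whole.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if self.empty is None:
            self.empty = ~self.whole.any(axis=(1, 2))

    @property
    def n_frames(self) -> int:
        return self.whole.shape[0]

    def region(self, label: str) -> np.ndarray:
        if label == "whole":
            return self.whole
        m = getattr(self, label, None)
        if m is None:
            raise KeyError(f"region {label!r} not available")
        return m

    @property
    def labels(self) -> tuple[str, ...]:
        return ("whole", "core", "periphery") if self.core is not None else ("whole",)

    def partition_ok(self) -> bool:
        """Check core | periphery == whole and core & periphery == {} per frame."""
        if self.core is None or self.periphery is None:
            return False
        union_ok = ((self.core | self.periphery) == self.whole).all()
        disjoint_ok = not (self.core & self.periphery).any()
        return bool(union_ok and disjoint_ok)


def preprocess(stack: TimeLapseStack, params: SegmentationParams) -> np.ndarray:
    """Blurred CFP+YFP sum movie, (T, H, W) float64.

    Reflective boundary handling keeps the total intensity of an
    interior-supported blob unchanged.
    """
    for ch in (CFP, YFP):
        if ch not in stack.channel_names:
            raise ValueError(f"stack is missing required channel {ch!r}")
    summed = stack.channel(CFP).astype(np.float64) + stack.channel(YFP)
    if params.blur_sigma == 0:
        return summed
    out = np.empty_like(summed)
    for i in range(summed.shape[0]):
        ndimage.gaussian_filter(
            summed[i], sigma=params.blur_sigma, output=out[i], mode="reflect"
        )
    return out


def _resolve_threshold(blurred: np.ndarray, params: SegmentationParams) -> float:
    if not isinstance(params.threshold, str):
        logger.info("manual whole-thrombus threshold: %g counts", params.threshold)
        return float(params.threshold)
    brightest = int(np.argmax(blurred.sum(axis=(1, 2))))
    thr = float(threshold_otsu(blurred[brightest]))
    logger.info("Otsu threshold %g counts (from frame %d)", thr, brightest)
    return thr


def _largest_component(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    lab = measure.label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def segment_whole(blurred: np.ndarray, params: SegmentationParams) -> MaskSeries:
    """Threshold the blurred sum movie into per-frame whole-thrombus masks.

    Keeps the largest 8-connected component per frame (one injury site, one
    thrombus); flags empty frames instead of dropping them.
    """
    thr = _resolve_threshold(blurred, params)
    if thr > blurred.max():
        warnings.warn(
            "threshold exceeds the global maximum: all frames empty", stacklevel=2
        )
    whole = np.empty(blurred.shape, dtype=bool)
    for i in range(blurred.shape[0]):
        whole[i] = _largest_component(blurred[i] >= thr)
    ms = MaskSeries(
        whole=whole,
        params={
            "threshold": thr,
            "threshold_mode": params.threshold if isinstance(params.threshold, str) else "manual",
            "blur_sigma": params.blur_sigma,
        },
    )
    n_empty = int(ms.empty.sum())
    if n_empty:
        logger.info("%d/%d frames have an empty whole mask", n_empty, ms.n_frames)
    return ms


def split_core_periphery(
    blurred: np.ndarray, whole: MaskSeries, params: SegmentationParams
) -> MaskSeries:
    """Partition the whole mask into core and periphery.

    Intensity rule (default): core = whole AND blurred >= core_factor * threshold.
    Erosion rule: core = whole eroded by a disc of radius ``erosion_px``.
    The periphery is always the set difference whole \\ core.
    """
    thr = whole.params.get("threshold")
    if thr is None:
        raise ValueError("whole masks carry no threshold; run segment_whole first")
    if params.core_method == "intensity":
        core = whole.whole & (blurred >= params.core_factor * thr)
    else:
        footprint = morphology.disk(params.erosion_px)
        core = np.empty_like(whole.whole)
        for i in range(whole.n_frames):
            core[i] = ndimage.binary_erosion(whole.whole[i], structure=footprint)
        core &= whole.whole
    periphery = whole.whole & ~core
    return MaskSeries(
        whole=whole.whole,
        core=core,
        periphery=periphery,
        empty=whole.empty,
        params={**whole.params, "core_factor": params.core_factor,
                "core_method": params.core_method},
    )


def segment_stack(stack: TimeLapseStack, params: SegmentationParams | None = None) -> MaskSeries:
    """Full segmentation convenience wrapper: preprocess, threshold, split."""
    params = params or SegmentationParams()
    blurred = preprocess(stack, params)
    whole = segment_whole(blurred, params)
    return split_core_periphery(blurred, whole, params)


def area_table(masks: MaskSeries, dt: float, pixel_size_um: float) -> pd.DataFrame:
    """Per-frame region areas: columns frame, t_s, region, area_px, area_um2."""
    px_area = pixel_size_um**2
    rows = []
    for label in masks.labels:
        counts = masks.region(label).sum(axis=(1, 2))
        for i, n in enumerate(counts):
            rows.append(
                {"frame": i, "t_s": i * dt, "region": label,
                 "area_px": int(n), "area_um2": float(n * px_area)}
            )
    return pd.DataFrame(rows)
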