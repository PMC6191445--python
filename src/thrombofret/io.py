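"""TIFF stack I/O and the in-memory time-lapse container.

A movie is held as a ``TimeLapseStack``: a T x C x H x W array of non-negative
intensities plus named channels, the frame interval ``dt`` (s) and the pixel
size (um).  Stacks are written as multi-page TIFF with axes ``TCYX`` and the
acquisition metadata embedded in the file; ``read_stack`` restores them
bit-identically.  Explicit arguments always win over file metadata (and the
override is logged), mirroring how acquisition software metadata is commonly
incomplete or wrong.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "CFP",
    "YFP",
    "FURA_340",
    "FURA_380",
    "TimeLapseStack",
    "read_stack",
    "write_stack",
]

# canonical channel names: emission wavelength for the FRET pair (445 nm
# excitation), excitation wavelength for the Fura-2 pair
CFP = "EM480"
YFP = "EM535"
FURA_340 = "EX340"
FURA_380 = "EX380"


@dataclass
class TimeLapseStack:
    """Multi-channel time-lapse movie.

    Parameters
    ----------
    data : ndarray, shape (T, C, H, W)
        Non-negative intensities (counts).
    channel_names : list of str
        One label per channel, e.g. ``["EM480", "EM535"]``.
    dt : float
        Frame interval in seconds (> 0).
    pixel_size_um : float
        Pixel edge length in micrometres.
    """

    data: np.ndarray
    channel_names: list[str]
    dt: float = 1.0
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be T x C x H x W")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if np.issubdtype(self.data.dtype, np.floating) and (self.data < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds from acquisition start."""
        return np.arange(self.n_frames) * self.dt

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) movie of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.data[:, idx]

    def has_channels(self, *names: str) -> bool:
        return all(n in self.channel_names for n in names)


def write_stack(stack: TimeLapseStack, path) -> None:
    """Write a stack as multi-page TIFF (axes TCYX, metadata embedded)."""
    meta = {
        "axes": "TCYX",
        "channel_names": list(stack.channel_names),
        "dt": stack.dt,
        "pixel_size_um": stack.pixel_size_um,
    }
    tifffile.imwrite(path, stack.data, photometric="minisblack", metadata=meta)


def read_stack(
    path,
    channel_names: list[str] | None = None,
    dt: float | None = None,
    pixel_size_um: float | None = None,
) -> TimeLapseStack:
    """Read a TIFF time-lapse stack.

    4-D files are interpreted as T x C x H x W.  A plain 3-D page series is
    treated as channel-interleaved: the page count must be divisible by the
    number of channels given via ``channel_names``.  Explicit arguments
    override file metadata (logged at INFO).
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])

    file_channels = meta.get("channel_names")
    if channel_names is not None and file_channels and channel_names != file_channels:
        logger.info(
            "channel map override: file says %s, using %s", file_channels, channel_names
        )
    names = channel_names or file_channels

    if data.ndim == 3:
        if names is None:
            raise ValueError(
                "3-D TIFF with no channel metadata: pass channel_names to "
                "resolve the interleaved layout"
            )
        n_ch = len(names)
        if data.shape[0] % n_ch:
            raise ValueError(
                f"{data.shape[0]} pages are not divisible by {n_ch} channels"
            )
        data = data.reshape(data.shape[0] // n_ch, n_ch, *data.shape[1:])
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF dimensionality: {data.ndim}")

    if names is None:
        raise ValueError("channel names missing: not in metadata and not given")

    def _resolve(arg, key, default):
        file_val = meta.get(key)
        if arg is not None:
            if file_val is not None and arg != file_val:
                logger.info("%s override: file says %s, using %s", key, file_val, arg)
            return arg
        return file_val if file_val is not None else default

    return TimeLapseStack(
        data=data,
        channel_names=list(names),
        dt=_resolve(dt, "dt", 1.0),
        pixel_size_um=_resolve(pixel_size_um, "pixel_size_um", 1.0),
    )
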