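"""Data model and I/O for two-channel fluorescence Z-stacks.

A stack holds one neuron imaged in two emission channels: a cytoplasmic GFP
fill (used for segmentation) and an Alexa594 membrane label (the quantified
signal).  Arrays use the ``(slice, row, col)`` convention, 0-based, with the
physical origin at pixel centers.  Intensities are stored as float64
regardless of on-disk bit depth because all downstream quantities are means
and ratios.

On disk a stack is a multi-page TIFF whose pages are either interleaved
two-channel planes (page ``2i`` and ``2i+1`` belong to optical slice ``i``)
or two separate single-channel series stacked back to back.  Channel identity
is always declared by the caller; no wavelength auto-detection is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from receptorquant.errors import ConfigurationError, MalformedFileError

__all__ = [
    "TwoChannelStack",
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "deinterleave",
    "interleave",
    "read_sidecar",
    "load_config",
]

#: accepted channel names, in canonical order
CHANNELS = ("gfp", "a594")


@dataclass
class TwoChannelStack:
    """A registered two-channel Z-stack for one cell.

    Parameters
    ----------
    gfp, a594 : ndarray, shape (n_slices, n_rows, n_cols)
        Intensity arrays in arbitrary units.  Stored as float64.
    pixel_size_um : float
        Lateral physical pixel size in micrometres (~0.08 µm for the
        two-photon acquisitions this models).
    slice_spacing_um : float
        Axial spacing between optical slices (0.5 µm typical).
    cell_id, condition : str
        Free-text identifiers used for pairing and grouping.
    """

    gfp: np.ndarray
    a594: np.ndarray
    pixel_size_um: float
    slice_spacing_um: float = 0.5
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.gfp = np.asarray(self.gfp, dtype=np.float64)
        self.a594 = np.asarray(self.a594, dtype=np.float64)
        if self.gfp.ndim != 3 or self.a594.ndim != 3:
            raise ValueError("channel arrays must be 3-D (slice, row, col)")
        if self.gfp.shape != self.a594.shape:
            raise ValueError(
                f"channel shapes differ: gfp {self.gfp.shape} vs a594 {self.a594.shape}"
            )
        if self.gfp.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not (self.slice_spacing_um > 0):
            raise ValueError("slice_spacing_um must be positive")
        if np.nanmin(self.gfp) < 0 or np.nanmin(self.a594) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.gfp.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gfp.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the image and spike pipelines.

    Defaults reproduce the published analysis settings: sigma-1 Gaussian
    smoothing of the GFP channel, an 8-pixel (~0.6 µm at 0.08 µm/px) inward
    erosion defining the cytoplasm, ten analyzed optical slices, and 15-s
    binning of spike counts.
    """

    blur_sigma: float = 1.0
    erosion_px: int = 8
    n_slices_analyzed: int = 10
    rng_seed: int = 0
    spike_threshold_sd: float = 4.0
    bin_seconds: float = 15.0
    contour_side: str = "outer"  # which side of the mask edge carries the line
    subtract_background: bool = False
    excluded_slices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if not isinstance(self.erosion_px, (int, np.integer)) or self.erosion_px < 1:
            raise ValueError("erosion_px must be a positive integer")
        if self.n_slices_analyzed < 1:
            raise ValueError("n_slices_analyzed must be >= 1")
        if self.spike_threshold_sd <= 0:
            raise ValueError("spike_threshold_sd must be positive")
        if self.bin_seconds <= 0:
            raise ValueError("bin_seconds must be positive")
        if self.contour_side not in ("outer", "inner"):
            raise ValueError("contour_side must be 'outer' or 'inner'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def deinterleave(
    pages: Sequence[np.ndarray] | np.ndarray, first: str = "gfp"
) -> tuple[np.ndarray, np.ndarray]:
    """Split an interleaved page sequence into (gfp_planes, a594_planes).

    Plane ``i`` of the first-declared channel comes from page ``2i`` and of
    the other channel from page ``2i+1``.

    Raises
    ------
    MalformedFileError
        If the number of pages is odd.
    """
    pages = np.asarray(pages, dtype=np.float64)
    if pages.ndim != 3:
        raise ValueError("pages must be a sequence of 2-D planes")
    if pages.shape[0] % 2 != 0:
        raise MalformedFileError(
            f"interleaved layout requires an even page count, got {pages.shape[0]}"
        )
    if first not in CHANNELS:
        raise ValueError(f"first channel must be one of {CHANNELS}")
    even, odd = pages[0::2], pages[1::2]
    return (even, odd) if first == "gfp" else (odd, even)


def interleave(gfp: np.ndarray, a594: np.ndarray, first: str = "gfp") -> np.ndarray:
    """Inverse of :func:`deinterleave`: weave two channel stacks into pages."""
    gfp = np.asarray(gfp, dtype=np.float64)
    a594 = np.asarray(a594, dtype=np.float64)
    if gfp.shape != a594.shape:
        raise ValueError("channels must share a shape")
    pages = np.empty((2 * gfp.shape[0],) + gfp.shape[1:], dtype=np.float64)
    a, b = (gfp, a594) if first == "gfp" else (a594, gfp)
    pages[0::2] = a
    pages[1::2] = b
    return pages


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Best-effort physical pixel size (µm) from TIFF resolution tags.

    A size is only trusted when the unit is explicit: a CENTIMETER/INCH
    resolution unit tag, ImageJ metadata declaring microns, or a metadata
    JSON in the image description with ``unit: micron``.
    """
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value if isinstance(xres.value, tuple) else (xres.value, 1)
    if num == 0:
        return None
    size = float(Fraction(int(den), int(num)))  # unit per pixel
    unit_val = getattr(unit, "value", None) if unit is not None else None
    unit_name = getattr(unit_val, "name", str(unit_val)).upper() if unit_val else ""
    if "CENTIMETER" in unit_name:
        return size * 1e4
    if "INCH" in unit_name:
        return size * 2.54e4
    ij = tif.imagej_metadata or {}
    declared = ij.get("unit")
    if declared is None and page.description:
        try:
            declared = json.loads(page.description).get("unit")
        except (json.JSONDecodeError, AttributeError):
            declared = None
    if declared in ("micron", "um", "µm"):
        return size
    return None


def read_stack(
    path: str | Path,
    channel_order: Sequence[str] = CHANNELS,
    layout: str = "interleaved",
    pixel_size_um: float | None = None,
    slice_spacing_um: float = 0.5,
    cell_id: str = "",
    condition: str = "",
) -> TwoChannelStack:
    """Read a two-channel multi-page TIFF into a :class:`TwoChannelStack`.

    Parameters
    ----------
    channel_order : sequence of {"gfp", "a594"}
        Which channel comes first, either per interleaved page pair or as the
        first series under the ``"split"`` layout.
    layout : {"interleaved", "split"}
        ``"interleaved"``: pages alternate channels.  ``"split"``: first half
        of the pages is one channel, second half the other.
    pixel_size_um : float, optional
        Overrides (or supplies, when tags are absent) the physical pixel size.

    Raises
    ------
    MalformedFileError
        Odd page count under either layout.
    ConfigurationError
        No pixel size in the file tags and no override given.
    """
    path = Path(path)
    if tuple(channel_order) not in ((CHANNELS), tuple(reversed(CHANNELS))):
        raise ValueError(f"channel_order must be a permutation of {CHANNELS}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        if pages.ndim == 2:
            pages = pages[np.newaxis]
        tag_pixel_size = _pixel_size_from_tags(tif)
    if pixel_size_um is None:
        pixel_size_um = tag_pixel_size
    if pixel_size_um is None:
        raise ConfigurationError(
            f"{path}: no pixel size in TIFF tags and no pixel_size_um override"
        )
    first = channel_order[0]
    if layout == "interleaved":
        gfp, a594 = deinterleave(pages, first=first)
    elif layout == "split":
        if pages.shape[0] % 2 != 0:
            raise MalformedFileError(
                f"{path}: split layout requires an even page count, got {pages.shape[0]}"
            )
        half = pages.shape[0] // 2
        a, b = pages[:half], pages[half:]
        gfp, a594 = (a, b) if first == "gfp" else (b, a)
    else:
        raise ValueError("layout must be 'interleaved' or 'split'")
    return TwoChannelStack(
        gfp=gfp,
        a594=a594,
        pixel_size_um=float(pixel_size_um),
        slice_spacing_um=slice_spacing_um,
        cell_id=cell_id,
        condition=condition,
    )


def write_stack(
    path: str | Path,
    stack: TwoChannelStack,
    layout: str = "interleaved",
    channel_order: Sequence[str] = CHANNELS,
) -> None:
    """Write a stack to a multi-page TIFF.

    Pages are written as float64 so a round trip preserves intensities
    bit-for-bit.
    """
    first = channel_order[0]
    if layout == "interleaved":
        pages = interleave(stack.gfp, stack.a594, first=first)
    elif layout == "split":
        a, b = (stack.gfp, stack.a594) if first == "gfp" else (stack.a594, stack.gfp)
        pages = np.concatenate([a, b], axis=0)
    else:
        raise ValueError("layout must be 'interleaved' or 'split'")
    # resolution tags: pixels per µm, with the micron unit declared in the
    # description metadata (ImageJ convention)
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        Path(path),
        pages,
        resolution=(res, res),
        resolutionunit="NONE",
        metadata={"unit": "micron", "spacing": stack.slice_spacing_um},
    )


def read_sidecar(path: str | Path) -> dict:
    """Read a per-cell JSON metadata sidecar (cell_id, condition, pixel size)."""
    with open(path) as fh:
        meta = json.load(fh)
    if not isinstance(meta, dict):
        raise ConfigurationError(f"{path}: sidecar must be a JSON object")
    return meta


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "excluded_slices" in raw:
        raw["excluded_slices"] = tuple(raw["excluded_slices"])
    return AnalysisConfig(**raw)
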