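"""Membrane fluorescence profiling along the mask edge.

The cell mask derived from the GFP fill is converted to a one-pixel line
(the ordered outer-boundary ring, cut at a random break as in the original
macro, where the break turns a closed selection into a line), and the mean
Alexa594 intensity is collected along that line per optical slice.  Slice
means are pooled with equal weight into the cell's mean membrane
fluorescence, F-memb.  The break position and traversal direction cannot
affect a mean and tests assert as much; the break is kept, seeded, for
fidelity and reproducibility.

The line sits on the foreground side of the mask edge by default (the
membrane label surrounds the GFP fill, so the outer boundary maximizes
overlap with the rim); ``side="inner"`` shifts it one pixel inward.  Both
choices are within one pixel (~0.08 µm) of the true edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from receptorquant.errors import ContourError
from receptorquant.segmentation import CellMask, _STRUCT8
from receptorquant.stack_model import AnalysisConfig, TwoChannelStack

__all__ = [
    "MembraneContour",
    "MembraneMeasurement",
    "MembraneProfiler",
    "mask_to_contour",
    "membrane_mean",
    "pooled_f_memb",
    "percent_of_control",
]

@dataclass
class MembraneContour:
    """Ordered one-pixel boundary line of a mask slice.

    ``path`` is the closed boundary ring stored as an open sequence of
    ``(row, col)`` pixels: the ring is cut once, at ``break_index`` positions
    from the canonical (raster-order) start, and consecutive entries are
    8-neighbors.
    """

    path: np.ndarray
    break_index: int

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64)
        if self.path.ndim != 2 or self.path.shape[1] != 2:
            raise ValueError("path must be an (n, 2) coordinate array")
        if self.path.shape[0] < 1:
            raise ValueError("path must contain at least one pixel")

    @property
    def length_px(self) -> int:
        return self.path.shape[0]


@dataclass
class MembraneMeasurement:
    """Per-slice membrane means and their pooled average (F-memb)."""

    per_slice_means: np.ndarray
    f_memb: float
    n_slices: int

    def __post_init__(self) -> None:
        self.per_slice_means = np.asarray(self.per_slice_means, dtype=np.float64)
        if self.per_slice_means.shape != (self.n_slices,):
            raise ValueError("one mean per analyzed slice required")


def _validate_single_filled_component(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask slice must be 2-D")
    if not mask.any():
        raise ContourError("empty mask slice")
    _, n = ndimage.label(mask, structure=_STRUCT8)
    if n != 1:
        raise ContourError(f"mask has {n} components; expected exactly one")
    if not np.array_equal(ndimage.binary_fill_holes(mask), mask):
        raise ContourError("mask contains internal holes")
    return mask


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Order the outer boundary pixels of a mask into a clockwise ring.

    The boundary set — foreground pixels with any 8-neighbor background
    (image edges count as background) — is ordered by each pixel's
    arc-length position along the subpixel 0.5-level iso-contour of the
    mask, which is a single closed curve for a hole-free component.
    Returns the ordered (row, col) ring, each boundary pixel exactly once.
    """
    n_fg = int(mask.sum())
    if n_fg == 1:
        rows, cols = np.nonzero(mask)
        return np.array([(int(rows[0]), int(cols[0]))], dtype=np.int64)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    eroded = ndimage.binary_erosion(padded, structure=_STRUCT8)
    boundary = padded & ~eroded
    pix = np.argwhere(boundary).astype(np.float64)

    curves = measure.find_contours(padded.astype(np.float64), 0.5)
    curve = max(curves, key=len)
    # clockwise orientation in (row, col) display coordinates
    closed = np.vstack([curve, curve[:1]])
    signed_area = 0.5 * np.sum(
        closed[:-1, 1] * closed[1:, 0] - closed[1:, 1] * closed[:-1, 0]
    )
    if signed_area < 0:
        curve = curve[::-1]
        closed = np.vstack([curve, curve[:1]])
    seg_vec = np.diff(closed, axis=0)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    seg_start_s = np.concatenate([[0.0], np.cumsum(seg_len)[:-1]])

    # arc-length parameter of each boundary pixel: projection onto the
    # nearest curve segment
    diff = pix[:, None, :] - closed[None, :-1, :]
    denom = np.maximum(seg_len**2, 1e-12)
    t = np.clip(np.einsum("pks,ks->pk", diff, seg_vec) / denom, 0.0, 1.0)
    proj = closed[None, :-1, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = np.sum((pix[:, None, :] - proj) ** 2, axis=2)
    k_best = np.argmin(d2, axis=1)
    s = seg_start_s[k_best] + t[np.arange(len(pix)), k_best] * seg_len[k_best]
    order = np.argsort(s, kind="stable")
    return (pix[order].astype(np.int64)) - 1


def mask_to_contour(
    mask_slice: np.ndarray,
    rng_seed: int = 0,
    side: str = "outer",
) -> MembraneContour:
    """Order the one-pixel boundary of a mask slice into a broken ring.

    Parameters
    ----------
    mask_slice : 2-D bool array
        One hole-free 8-connected component.
    rng_seed : int
        Seeds the position of the ring break (reproducible; irrelevant to
        any mean along the line).
    side : {"outer", "inner"}
        ``"outer"``: boundary pixels of the mask itself (foreground side of
        the edge).  ``"inner"``: boundary of the mask eroded by one pixel.

    Raises
    ------
    ContourError
        If the mask is empty, multi-component or contains holes.
    """
    mask = _validate_single_filled_component(mask_slice)
    if side == "inner":
        eroded = ndimage.binary_erosion(mask, structure=_STRUCT8)
        if not eroded.any():
            raise ContourError("mask too thin for an inner contour")
        # inner erosion can split thin shapes; keep the largest piece
        labels, n = ndimage.label(eroded, structure=_STRUCT8)
        if n > 1:
            sizes = ndimage.sum_labels(eroded, labels, np.arange(1, n + 1))
            eroded = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(eroded)
    elif side != "outer":
        raise ValueError("side must be 'outer' or 'inner'")
    ring = _trace_boundary(mask)
    rng = np.random.default_rng(rng_seed)
    break_index = int(rng.integers(ring.shape[0]))
    return MembraneContour(path=np.roll(ring, -break_index, axis=0), break_index=break_index)


def membrane_mean(contour: MembraneContour, a594_slice: np.ndarray) -> float:
    """Arithmetic mean of channel intensity at the contour pixels.

    Each boundary pixel is weighted once; the break position has no effect.
    """
    plane = np.asarray(a594_slice, dtype=np.float64)
    if contour.length_px == 0:
        raise ContourError("empty contour")
    r, c = contour.path[:, 0], contour.path[:, 1]
    if r.min() < 0 or c.min() < 0 or r.max() >= plane.shape[0] or c.max() >= plane.shape[1]:
        raise ValueError("contour coordinates fall outside the slice")
    return float(plane[r, c].mean())


class MembraneProfiler(BaseEstimator):
    """Membrane-line profiler pooling per-slice means into F-memb.

    Parameters
    ----------
    side : {"outer", "inner"}
        Which side of the mask edge carries the one-pixel line.
    n_slices_analyzed : int
        Number of consecutive slices pooled (ten in the published
        acquisitions).
    rng_seed : int
        Seeds the (inconsequential) ring break per slice.
    """

    def __init__(self, side: str = "outer", n_slices_analyzed: int = 10, rng_seed: int = 0):
        self.side = side
        self.n_slices_analyzed = n_slices_analyzed
        self.rng_seed = rng_seed

    def fit(self, X=None, y=None) -> "MembraneProfiler":
        return self

    def analyzed_slices(self, n_available: int, excluded: tuple[int, ...] = ()) -> list[int]:
        n = min(self.n_slices_analyzed, n_available)
        keep = [i for i in range(n) if i not in set(excluded)]
        if not keep:
            raise ValueError("slice exclusion removed every analyzed slice")
        return keep

    def measure(
        self,
        stack: TwoChannelStack,
        cell_mask: CellMask,
        excluded_slices: tuple[int, ...] = (),
    ) -> MembraneMeasurement:
        """Profile the Alexa594 channel along each slice's membrane line."""
        if cell_mask.masks.shape != stack.shape:
            raise ValueError("mask and stack shapes differ")
        keep = self.analyzed_slices(stack.n_slices, excluded_slices)
        means = []
        for i in keep:
            contour = mask_to_contour(
                cell_mask.masks[i], rng_seed=self.rng_seed + i, side=self.side
            )
            means.append(membrane_mean(contour, stack.a594[i]))
        means = np.asarray(means)
        return MembraneMeasurement(
            per_slice_means=means, f_memb=float(means.mean()), n_slices=len(keep)
        )


def pooled_f_memb(
    stack: TwoChannelStack, cell_mask: CellMask, config: AnalysisConfig
) -> MembraneMeasurement:
    """F-memb of a stack under ``config`` (thin wrapper over the profiler)."""
    profiler = MembraneProfiler(
        side=config.contour_side,
        n_slices_analyzed=config.n_slices_analyzed,
        rng_seed=config.rng_seed,
    )
    return profiler.measure(stack, cell_mask, excluded_slices=config.excluded_slices)


def percent_of_control(group_mean: float, control_mean: float) -> int:
    """Group mean as a percentage of the control mean, to the nearest integer.

    Raises
    ------
    ValueError
        If the control mean is not strictly positive.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    return int(np.floor(100.0 * group_mean / control_mean + 0.5))
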