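"""Erosion-defined cytoplasm measurement and F/F0 internalization ratios.

The cytoplasm of a cell is defined by eroding the GFP-derived cell mask
inward by a fixed band (8 px ≈ 0.6 µm at 0.08 µm/px) with a Euclidean disk
structuring element, excluding the membrane-plus-optical-blur annulus.
Per-slice mean Alexa594 intensity over the eroded region, pooled across
slices, gives F-cyt.  Together with F-memb the compartment fractions
F-memb/(F-memb+F-cyt) and F-cyt/(F-memb+F-cyt) are formed; an agonist's
effect is reported as F/F0, the ratio of each fraction after treatment to
the same fraction before.  Working in fractions (not raw intensities) makes
the readout invariant to uniform acquisition-gain drift between the two
time points, and a cytoplasmic F/F0 above 1 indicates internalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from sklearn.base import BaseEstimator

from receptorquant.errors import DegenerateGeometryError
from receptorquant.membrane_quant import MembraneProfiler
from receptorquant.segmentation import CellMask, CellSegmenter
from receptorquant.stack_model import AnalysisConfig, TwoChannelStack

__all__ = [
    "CompartmentMeasurement",
    "InternalizationResult",
    "CompartmentAnalyzer",
    "cytoplasm_region",
    "f_cyt",
    "compartment_fractions",
    "internalization_ratios",
]


@dataclass
class CompartmentMeasurement:
    """Membrane and cytoplasm means with their normalized fractions."""

    f_memb: float
    f_cyt: float
    memb_fraction: float
    cyt_fraction: float

    def __post_init__(self) -> None:
        if not np.isclose(self.memb_fraction + self.cyt_fraction, 1.0, rtol=0, atol=1e-12):
            raise ValueError("fractions must sum to 1")


@dataclass
class InternalizationResult:
    """Before/after compartment fractions and their F/F0 ratios."""

    f_over_f0_cyt: float
    f_over_f0_memb: float
    before: CompartmentMeasurement
    after: CompartmentMeasurement


def cytoplasm_region(mask_slice: np.ndarray, erosion_px: int) -> np.ndarray:
    """Erode a mask slice inward by ``erosion_px`` (Euclidean disk element).

    The returned region is the eroded interior: a subset of the mask with
    the band adjacent to the membrane excluded in every direction.

    Raises
    ------
    DegenerateGeometryError
        If erosion empties the mask (cell thinner than twice the band).
    """
    mask = np.asarray(mask_slice, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask slice must be 2-D")
    if not isinstance(erosion_px, (int, np.integer)) or erosion_px < 1:
        raise ValueError("erosion_px must be a positive integer")
    region = ndimage.binary_erosion(mask, structure=disk(erosion_px).astype(bool))
    if not region.any():
        raise DegenerateGeometryError(
            f"erosion by {erosion_px} px emptied the mask "
            f"(cell thinner than {2 * erosion_px} px)"
        )
    return region


def f_cyt(region_masks: np.ndarray, a594_stack: np.ndarray) -> float:
    """Pooled mean cytoplasmic intensity: per-slice region means, averaged.

    Raises
    ------
    DegenerateGeometryError
        If any analyzed slice has an empty region.
    """
    regions = np.asarray(region_masks, dtype=bool)
    planes = np.asarray(a594_stack, dtype=np.float64)
    if regions.shape != planes.shape:
        raise ValueError("region masks and intensity stack shapes differ")
    means = []
    for i in range(regions.shape[0]):
        if not regions[i].any():
            raise DegenerateGeometryError(f"slice {i}: empty cytoplasm region")
        means.append(float(planes[i][regions[i]].mean()))
    return float(np.mean(means))


def compartment_fractions(f_memb: float, f_cyt: float) -> CompartmentMeasurement:
    """Normalize the two compartment means into fractions summing to one."""
    total = f_memb + f_cyt
    if not total > 0:
        raise ValueError("f_memb + f_cyt must be positive")
    memb = f_memb / total
    # derive the complement so the two fractions sum to 1 exactly
    return CompartmentMeasurement(
        f_memb=float(f_memb),
        f_cyt=float(f_cyt),
        memb_fraction=float(memb),
        cyt_fraction=float(1.0 - memb),
    )


def internalization_ratios(
    before: CompartmentMeasurement, after: CompartmentMeasurement
) -> InternalizationResult:
    """F/F0 for both compartments of one cell.

    ``before`` and ``after`` must come from the same cell imaged at the two
    time points.  Values near 1 mean no redistribution; a cytoplasmic ratio
    above 1 indicates internalization.
    """
    if before.cyt_fraction <= 0 or before.memb_fraction <= 0:
        raise ValueError("before-fractions must be positive for F/F0")
    return InternalizationResult(
        f_over_f0_cyt=after.cyt_fraction / before.cyt_fraction,
        f_over_f0_memb=after.memb_fraction / before.memb_fraction,
        before=before,
        after=after,
    )


class CompartmentAnalyzer(BaseEstimator):
    """End-to-end membrane/cytoplasm quantification for one stack or pair.

    Segments the GFP channel, profiles F-memb along the membrane line,
    measures F-cyt over the erosion-defined interior, and forms the
    compartment fractions.

    Parameters
    ----------
    blur_sigma : float
        GFP smoothing width for segmentation (pixels).
    erosion_px : int
        Inward band width defining the cytoplasm (8 px ≈ 0.6 µm).
    side : {"outer", "inner"}
        Side of the mask edge carrying the membrane line.
    n_slices_analyzed : int
        Consecutive slices pooled per stack.
    rng_seed : int
        Seeds the (inconsequential) membrane-line break.
    """

    def __init__(
        self,
        blur_sigma: float = 1.0,
        erosion_px: int = 8,
        side: str = "outer",
        n_slices_analyzed: int = 10,
        rng_seed: int = 0,
    ):
        self.blur_sigma = blur_sigma
        self.erosion_px = erosion_px
        self.side = side
        self.n_slices_analyzed = n_slices_analyzed
        self.rng_seed = rng_seed

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "CompartmentAnalyzer":
        return cls(
            blur_sigma=config.blur_sigma,
            erosion_px=config.erosion_px,
            side=config.contour_side,
            n_slices_analyzed=config.n_slices_analyzed,
            rng_seed=config.rng_seed,
        )

    def fit(self, X=None, y=None) -> "CompartmentAnalyzer":
        return self

    def analyze(
        self,
        stack: TwoChannelStack,
        cell_mask: CellMask | None = None,
        excluded_slices: tuple[int, ...] = (),
    ) -> CompartmentMeasurement:
        """Measure F-memb, F-cyt and their fractions for one stack."""
        if cell_mask is None:
            cell_mask = CellSegmenter(blur_sigma=self.blur_sigma).transform(stack)
        profiler = MembraneProfiler(
            side=self.side,
            n_slices_analyzed=self.n_slices_analyzed,
            rng_seed=self.rng_seed,
        )
        memb = profiler.measure(stack, cell_mask, excluded_slices=excluded_slices)
        keep = profiler.analyzed_slices(stack.n_slices, excluded_slices)
        regions = np.stack(
            [cytoplasm_region(cell_mask.masks[i], self.erosion_px) for i in keep]
        )
        cyt = f_cyt(regions, stack.a594[keep])
        return compartment_fractions(memb.f_memb, cyt)

    def analyze_pair(
        self, before: TwoChannelStack, after: TwoChannelStack
    ) -> InternalizationResult:
        """F/F0 internalization readout for a before/after stack pair.

        Pairing is by ``cell_id`` metadata; no image registration is
        attempted (region means are robust to small drift).
        """
        if before.cell_id != after.cell_id:
            raise ValueError(
                f"before/after cell_id mismatch: {before.cell_id!r} vs {after.cell_id!r}"
            )
        return internalization_ratios(self.analyze(before), self.analyze(after))
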