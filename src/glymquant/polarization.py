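"""Donut-method AQP4 polarization scoring.

AQP4 is polarized when it concentrates at perivascular astrocyte endfeet
rather than over the cell body.  The donut method scores this as

    rate = (I_PAS - I_ASS) / I_global * 100

where I_PAS is the AQP4 fluorescence in a periastrocyte annulus obtained by
expanding the GFAP-positive range 5 pixels outward (minus the GFAP range
itself, so the two ROIs are disjoint), I_ASS is the AQP4 fluorescence over
the astrocyte soma, and I_global is the AQP4 fluorescence of the entire
image.  Printed group values run ~39-72, i.e. the raw ratio is on a 0-100
scale.  The per-section score is the mean over that section's three images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .images import MultiChannelImage
from .segmentation import AstrocyteSegmentation

__all__ = ["PolarizationResult", "donut_rois", "polarization_rate", "section_rate"]


@dataclass(frozen=True)
class PolarizationResult:
    """Donut-method score with its three ROI intensities (a.u.)."""

    i_pas: float
    i_ass: float
    i_global: float
    rate: float
    statistic: str = "sum"

    def __post_init__(self):
        # with summed intensities over disjoint subregions the score is
        # bounded; the mean statistic carries no such bound
        if self.statistic == "sum" and not -100.0 - 1e-9 <= self.rate <= 100.0 + 1e-9:
            raise ValueError(f"rate {self.rate} outside [-100, 100]")


def donut_rois(
    seg: AstrocyteSegmentation, dilation_px: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Build the two donut ROIs from a segmentation.

    ROI_PAS is the annulus of pixels reached by dilating the GFAP mask
    ``dilation_px`` pixels (8-connectivity square element) minus the GFAP
    mask itself; ROI_ASS is the union of soma masks.  The masks are
    disjoint by construction; dilation clips at the image border.
    """
    if dilation_px < 1:
        raise ValueError(f"dilation_px must be >= 1, got {dilation_px}")
    selem = morphology.footprint_rectangle((2 * dilation_px + 1,) * 2)
    dilated = morphology.dilation(seg.gfap_mask, selem)
    roi_pas = dilated & ~seg.gfap_mask
    roi_ass = seg.soma_union()
    return roi_pas, roi_ass


def polarization_rate(
    image: MultiChannelImage,
    rois: tuple[np.ndarray, np.ndarray],
    statistic: str = "sum",
    aqp4_channel: str = "AQP4",
) -> PolarizationResult:
    """Score one image with the donut formula.

    ``statistic`` selects summed ("sum", default: the generator's intensity
    conservation is stated in sums) or mean ("mean") ROI intensity.
    """
    image.require(aqp4_channel)
    aqp4 = image[aqp4_channel]
    roi_pas, roi_ass = rois
    if statistic == "sum":
        i_pas = float(aqp4[roi_pas].sum())
        i_ass = float(aqp4[roi_ass].sum())
        i_global = float(aqp4.sum())
    elif statistic == "mean":
        if not roi_pas.any() or not roi_ass.any():
            raise ValueError("empty ROI: mean intensity undefined")
        i_pas = float(aqp4[roi_pas].mean())
        i_ass = float(aqp4[roi_ass].mean())
        i_global = float(aqp4.mean())
    else:
        raise ValueError(f"statistic must be 'sum' or 'mean', got {statistic!r}")
    if i_global == 0:
        raise ZeroDivisionError(
            "global AQP4 intensity is zero: polarization rate undefined"
        )
    rate = (i_pas - i_ass) / i_global * 100.0
    return PolarizationResult(i_pas=i_pas, i_ass=i_ass, i_global=i_global,
                              rate=rate, statistic=statistic)


def section_rate(results: list[PolarizationResult]) -> float:
    """Per-section polarization: mean of the section's (three) image rates."""
    if not results:
        raise ValueError("no image results to average")
    return float(np.mean([r.rate for r in results]))
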