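"""Astrocyte segmentation from GFAP/DAPI channels.

The study's source images were quantified manually in ImageJ; this module is
a reproducible, parameter-documented stand-in.  A global automatic threshold
(Otsu by default) binarises the GFAP channel; connected components above an
area cutoff become candidate cells; the soma of each cell is the core that
survives a morphological opening at soma scale; the skeleton is the
topological skeleton of the whole component; the nucleus centroid comes from
the DAPI component overlapping the soma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .images import MultiChannelImage

__all__ = ["AstrocyteSegmentation", "SegmentationParams", "segment_astrocytes"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the GFAP/DAPI segmentation.

    soma_opening_radius_px : radius (px) of the disk structuring element
        whose opening defines the soma core.  Must be below the soma radius
        in pixels and above the process half-width.
    min_cell_area_um2 : components smaller than this are discarded.
    threshold_method : "otsu" or a fixed numeric threshold.
    """

    soma_opening_radius_px: int = 8
    min_cell_area_um2: float = 20.0
    threshold_method: str | float = "otsu"
    dapi_threshold_method: str | float = "otsu"


@dataclass
class AstrocyteSegmentation:
    """Per-image segmentation: global GFAP mask plus per-cell structures."""

    gfap_mask: np.ndarray                    # binary, whole image
    labels: np.ndarray                       # int label image, 0 = background
    soma_masks: dict[int, np.ndarray]        # per retained cell
    skeletons: dict[int, np.ndarray]
    nucleus_centroids: dict[int, tuple[float, float]]   # (row, col)
    pixel_size_um: float
    excluded_cells: list[int] = field(default_factory=list)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.soma_masks)

    @property
    def n_cells(self) -> int:
        return len(self.soma_masks)

    def soma_union(self) -> np.ndarray:
        out = np.zeros_like(self.gfap_mask, dtype=bool)
        for m in self.soma_masks.values():
            out |= m
        return out


def _threshold(arr: np.ndarray, method: str | float) -> np.ndarray:
    if isinstance(method, (int, float)):
        return arr > float(method)
    if method == "otsu":
        if arr.min() == arr.max():          # blank image: nothing above threshold
            return np.zeros(arr.shape, dtype=bool)
        return arr > filters.threshold_otsu(arr)
    raise ValueError(f"unknown threshold method {method!r}")


def segment_astrocytes(
    image: MultiChannelImage,
    params: SegmentationParams = SegmentationParams(),
    gfap_channel: str = "GFAP",
    dapi_channel: str = "DAPI",
) -> AstrocyteSegmentation:
    """Segment astrocytes from the GFAP channel with DAPI nuclei.

    Cells whose soma overlaps no DAPI nucleus are excluded (and logged);
    touching cells are reported as one merged label, never split.
    A blank image yields an empty segmentation without error.
    """
    image.require(gfap_channel, dapi_channel)
    gfap = image[gfap_channel]
    dapi = image[dapi_channel]
    px = image.pixel_size_um

    mask = _threshold(gfap, params.threshold_method)
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))

    min_area_px = params.min_cell_area_um2 / px**2
    selem = morphology.disk(params.soma_opening_radius_px)

    dapi_mask = _threshold(dapi, params.dapi_threshold_method)
    dapi_labels, _ = ndi.label(dapi_mask, structure=np.ones((3, 3), dtype=int))

    soma_masks: dict[int, np.ndarray] = {}
    skeletons: dict[int, np.ndarray] = {}
    centroids: dict[int, tuple[float, float]] = {}
    excluded: list[int] = []

    for lab in range(1, labels.max() + 1):
        cell = labels == lab
        if cell.sum() < min_area_px:
            labels[cell] = 0
            continue
        soma = morphology.opening(cell, selem)
        if not soma.any():
            # component too thin to hold a soma at this scale
            excluded.append(lab)
            log.info("cell %d excluded: no soma core at opening radius %d px",
                     lab, params.soma_opening_radius_px)
            continue
        nuc_ids = np.unique(dapi_labels[soma])
        nuc_ids = nuc_ids[nuc_ids > 0]
        if nuc_ids.size == 0:
            excluded.append(lab)
            log.info("cell %d excluded: no DAPI nucleus overlapping its soma", lab)
            continue
        # largest-overlap nucleus wins when several touch the soma
        best = max(nuc_ids, key=lambda i: np.count_nonzero((dapi_labels == i) & soma))
        centroids[lab] = tuple(ndi.center_of_mass(dapi_labels == best))
        soma_masks[lab] = soma
        skeletons[lab] = morphology.skeletonize(cell)

    return AstrocyteSegmentation(
        gfap_mask=mask,
        labels=labels,
        soma_masks=soma_masks,
        skeletons=skeletons,
        nucleus_centroids=centroids,
        pixel_size_um=px,
        excluded_cells=excluded,
    )
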