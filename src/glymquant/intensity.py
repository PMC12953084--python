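"""Nuclear-translocation and channel-intensity quantification.

NF-κB p65 activation is read out as the fraction of a cell's p65
fluorescence that lies within its DAPI-defined nuclear mask; ROS burden is
read out as mean DHE channel intensity.  Group results are reported as fold
change relative to the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import MultiChannelImage
from .segmentation import _threshold

__all__ = [
    "NuclearTranslocationResult",
    "ROSResult",
    "nuclear_translocation",
    "mean_intensity",
    "normalize_to_control",
]

_EIGHT = np.ones((3, 3), dtype=int)


def _marker_foreground(marker: np.ndarray, method: str | float) -> np.ndarray:
    """Foreground of a marker channel.

    The marker image typically has three intensity classes (background,
    cytoplasm, bright nuclei); a binary Otsu can cut between cytoplasm and
    nucleus and truncate the cell.  "auto" takes the lowest threshold of a
    three-class multi-Otsu, falling back to binary Otsu on degenerate
    histograms.
    """
    if method != "auto":
        return _threshold(marker, method)
    from skimage import filters

    try:
        lo = filters.threshold_multiotsu(marker, classes=3)[0]
        return marker > lo
    except ValueError:
        return _threshold(marker, "otsu")


@dataclass(frozen=True)
class NuclearTranslocationResult:
    """Per-image p65 nuclear-translocation quantification."""

    nuclear_intensity: float          # p65 within DAPI masks, a.u.
    total_intensity: float            # p65 over all cells, a.u.
    nuclear_fraction: float           # per-image mean over cells
    per_cell_fractions: np.ndarray = field(repr=False, default=None)
    relative_to_control: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.nuclear_fraction <= 1.0 + 1e-12:
            raise ValueError(f"nuclear_fraction {self.nuclear_fraction} outside [0, 1]")


@dataclass(frozen=True)
class ROSResult:
    """Mean channel intensity over an ROI (DHE/ROS readout)."""

    mean_intensity: float
    background: float = 0.0
    relative_to_control: float | None = None

    def __post_init__(self):
        if self.mean_intensity < 0:
            raise ValueError("mean intensity must be >= 0")


def nuclear_translocation(
    image: MultiChannelImage,
    marker_channel: str = "p65",
    dapi_channel: str = "DAPI",
    nuclei_mask: np.ndarray | None = None,
    cell_masks: np.ndarray | None = None,
    threshold_method: str | float = "auto",
) -> NuclearTranslocationResult:
    """Fraction of marker fluorescence inside the nuclear mask, per cell.

    Each DAPI nucleus seeds one cell; the cell mask is the marker-positive
    component containing that nucleus (union with the nucleus itself).
    ``nuclei_mask``/``cell_masks`` may be supplied to bypass thresholding.
    The per-image value is the mean of per-cell fractions.
    """
    image.require(marker_channel, dapi_channel)
    marker = image[marker_channel]
    if nuclei_mask is None:
        nuclei_mask = _threshold(
            image[dapi_channel],
            "otsu" if threshold_method == "auto" else threshold_method,
        )
    nuc_labels, n_nuclei = ndi.label(nuclei_mask, structure=_EIGHT)
    if n_nuclei == 0:
        raise ValueError("no nuclei found in DAPI channel")
    if cell_masks is None:
        cell_masks = _marker_foreground(marker, threshold_method) | nuclei_mask
    cell_labels, _ = ndi.label(cell_masks, structure=_EIGHT)

    fractions = []
    nuclear_sum = 0.0
    total_sum = 0.0
    for nuc in range(1, n_nuclei + 1):
        nmask = nuc_labels == nuc
        owners = np.unique(cell_labels[nmask])
        owners = owners[owners > 0]
        if owners.size == 0:
            continue
        cmask = np.isin(cell_labels, owners)
        nuc_i = float(marker[nmask].sum())
        tot_i = float(marker[cmask].sum())
        if tot_i <= 0:
            continue
        fractions.append(min(nuc_i / tot_i, 1.0))
        nuclear_sum += nuc_i
        total_sum += tot_i
    if not fractions:
        raise ValueError("no cell had measurable marker intensity")
    return NuclearTranslocationResult(
        nuclear_intensity=nuclear_sum,
        total_intensity=total_sum,
        nuclear_fraction=float(np.mean(fractions)),
        per_cell_fractions=np.asarray(fractions),
    )


def mean_intensity(
    image: MultiChannelImage,
    channel: str,
    roi_mask: np.ndarray | None = None,
    background: float = 0.0,
) -> ROSResult:
    """Mean intensity of a channel over an ROI (whole image by default),
    with optional recorded background subtraction (floored at zero)."""
    image.require(channel)
    arr = image[channel]
    if roi_mask is None:
        roi_mask = np.ones(arr.shape, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    value = float(arr[roi_mask].mean()) - background
    return ROSResult(mean_intensity=max(value, 0.0), background=background)


def normalize_to_control(
    values: pd.Series | pd.DataFrame,
    groups: pd.Series | None = None,
    control_group: str = "C",
    value_col: str = "value",
    group_col: str = "group",
) -> pd.Series:
    """Divide each value by the control-group mean (fold change vs control).

    Accepts a long-format DataFrame (``value_col``/``group_col``) or a value
    Series plus a parallel group Series.  The control group's own mean maps
    to exactly 1.
    """
    if isinstance(values, pd.DataFrame):
        groups = values[group_col]
        values = values[value_col]
    if groups is None:
        raise ValueError("group labels required")
    groups = pd.Series(np.asarray(groups), index=values.index)
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} absent")
    ctrl_mean = values[groups == control_group].mean()
    if ctrl_mean == 0 or not np.isfinite(ctrl_mean):
        raise ZeroDivisionError("control-group mean is zero or undefined")
    return values / ctrl_mean
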