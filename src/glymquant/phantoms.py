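"""Synthetic fluorescence-microscopy phantoms with exact ground truth.

The phantoms emulate confocal fields of spinal-cord astrocytes around a
central vessel: disk somata with random-walk branched processes (GFAP
channel), nuclei (DAPI), and an AQP4 channel whose intensity is partitioned
between the perivascular annulus, the somata and the rest of the image so
that the donut-method score of the noise-free image equals a requested
ground-truth polarization exactly.

Exactness is achieved by construction: the geometry is rendered first, the
quantifier's own segmentation and ROI construction are run on the noise-free
channels to obtain the very masks scoring will use, and intensity is then
solved for per region.  Naive texture synthesis could not guarantee the
ground truth.

A second phantom family renders p65/MMP-9/DAPI fields with a known nuclear
fraction of p65 for the translocation quantifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

from .images import MultiChannelImage
from .polarization import donut_rois
from .segmentation import SegmentationParams, segment_astrocytes

__all__ = [
    "ImagePhantomConfig",
    "TranslocationPhantomConfig",
    "AstrocyteGroundTruth",
    "TranslocationGroundTruth",
    "generate_astrocyte_image",
    "generate_translocation_image",
]


@dataclass(frozen=True)
class ImagePhantomConfig:
    """Parameters of one astrocyte/AQP4 phantom field.

    ``true_polarization`` is on the donut method's 0-100 scale (negative
    values mean soma-dominant AQP4).  ``aqp4_total_intensity`` is the total
    AQP4 budget before noise, conserved exactly; ``background`` is a uniform
    AQP4 floor included in that budget (a nonzero floor keeps additive noise
    clipping negligible, but caps the achievable |polarization| below 100).
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_astrocytes: int = 5
    vessel_radius_um: float = 6.0
    soma_radius_um: float = 6.0
    n_processes: int = 5
    process_length_um: float = 20.0
    true_polarization: float = 72.41
    aqp4_total_intensity: float = 1e7
    gfap_intensity: float = 200.0
    dapi_intensity: float = 180.0
    noise_sd: float = 5.0
    background: float = 20.0
    seed: int = 0
    dilation_px: int = 5
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    pas_ass_spare_fraction: float = 0.2   # share of slack painted into both ROIs

    def validate(self) -> None:
        if not -100.0 <= self.true_polarization <= 100.0:
            raise ValueError("true_polarization must lie in [-100, 100]")
        for name in ("pixel_size_um", "vessel_radius_um", "soma_radius_um",
                     "process_length_um", "aqp4_total_intensity",
                     "gfap_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.background < 0:
            raise ValueError("noise_sd and background must be >= 0")
        if self.n_astrocytes < 1 or self.n_processes < 0:
            raise ValueError("need >= 1 astrocyte and >= 0 processes")
        h, w = self.image_size
        soma_px = self.soma_radius_um / self.pixel_size_um
        if 2 * soma_px >= min(h, w):
            raise ValueError("soma does not fit inside the image")


@dataclass
class AstrocyteGroundTruth:
    """Exact generative truth for one phantom field."""

    true_polarization: float
    soma_masks: dict[int, np.ndarray]
    process_polylines: dict[int, list[np.ndarray]]   # per cell, (k,2) vertex arrays
    nucleus_centroids: dict[int, tuple[float, float]]
    roi_pas: np.ndarray
    roi_ass: np.ndarray
    i_pas: float
    i_ass: float
    i_global: float


def _disk_mask(shape, center, radius_px) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius_px, shape=shape)
    m[rr, cc] = True
    return m


def _random_walk_polyline(rng, start, heading, length_px, n_seg=6, jitter=0.30):
    pts = [np.asarray(start, dtype=float)]
    step = length_px / n_seg
    for _ in range(n_seg):
        heading += rng.normal(0.0, jitter)
        pts.append(pts[-1] + step * np.array([np.sin(heading), np.cos(heading)]))
    return np.array(pts)


def _rasterize_polyline(mask, pts) -> None:
    h, w = mask.shape
    p = np.clip(np.round(pts).astype(int), [0, 0], [h - 1, w - 1])
    for a, b in zip(p[:-1], p[1:]):
        rr, cc = draw.line(a[0], a[1], b[0], b[1])
        mask[rr, cc] = True


def _place_somata(cfg: ImagePhantomConfig, rng) -> list[tuple[float, float]]:
    """Place soma centres around the central vessel by rejection sampling."""
    h, w = cfg.image_size
    px = cfg.pixel_size_um
    center = np.array([h / 2, w / 2])
    vessel_r = cfg.vessel_radius_um / px
    soma_r = cfg.soma_radius_um / px
    min_sep = 2 * soma_r + 6.0 / px          # >= 6 um clearance between somata
    lo = vessel_r + soma_r + 2.0 / px        # just outside the vessel wall
    hi = min(h, w) / 2 - soma_r - cfg.dilation_px - 2
    if hi <= lo:
        raise ValueError("image too small for vessel + somata + annulus")
    centers: list[np.ndarray] = []
    for i in range(cfg.n_astrocytes):
        base_angle = 2 * np.pi * i / cfg.n_astrocytes
        for _ in range(200):
            ang = base_angle + rng.normal(0.0, 0.25)
            rad = rng.uniform(lo, hi)
            c = center + rad * np.array([np.sin(ang), np.cos(ang)])
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"could not place {cfg.n_astrocytes} non-overlapping somata; "
                "reduce n_astrocytes or soma_radius_um"
            )
    return [tuple(c) for c in centers]


def generate_astrocyte_image(
    config: ImagePhantomConfig,
) -> tuple[MultiChannelImage, AstrocyteGroundTruth]:
    """Render one GFAP/AQP4/DAPI phantom with exact donut-score ground truth.

    Raises ``ValueError`` for geometrically impossible configurations and
    when the AQP4 budget cannot realise the requested polarization over the
    background floor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    px = config.pixel_size_um
    soma_r = config.soma_radius_um / px

    # ---- geometry --------------------------------------------------------
    centers = _place_somata(config, rng)
    gfap_mask = np.zeros((h, w), dtype=bool)
    dapi = np.zeros((h, w))
    polylines: dict[int, list[np.ndarray]] = {}
    for i, c in enumerate(centers):
        gfap_mask |= _disk_mask((h, w), c, soma_r)
        dapi[_disk_mask((h, w), c, 0.5 * soma_r)] = config.dapi_intensity
        cell_lines = []
        for j in range(config.n_processes):
            heading = 2 * np.pi * j / max(config.n_processes, 1) + rng.normal(0, 0.3)
            start = np.asarray(c) + (soma_r - 1) * np.array(
                [np.sin(heading), np.cos(heading)]
            )
            length = max(rng.normal(config.process_length_um,
                                    0.2 * config.process_length_um), 2.0) / px
            line = _random_walk_polyline(rng, start, heading, length)
            _rasterize_polyline(gfap_mask, line)
            cell_lines.append(line)
        polylines[i] = cell_lines
    gfap = np.where(gfap_mask, config.gfap_intensity, 0.0)

    # ---- ROI masks exactly as the quantifier will build them -------------
    clean = MultiChannelImage(
        channels={"GFAP": gfap.copy(), "AQP4": np.zeros((h, w)), "DAPI": dapi.copy()},
        pixel_size_um=px,
    )
    seg = segment_astrocytes(clean, config.seg_params)
    roi_pas, roi_ass = donut_rois(seg, config.dilation_px)
    n_p, n_a = int(roi_pas.sum()), int(roi_ass.sum())
    n_pix = h * w
    if n_p == 0 or n_a == 0:
        raise ValueError("degenerate phantom: empty donut ROI")

    # ---- solve the intensity allocation ----------------------------------
    # totals: I_PAS = b*n_p + P, I_ASS = b*n_a + A, I_global = T;
    # require I_PAS - I_ASS = q*T with P, A >= 0 and P + A <= T - b*N.
    T = config.aqp4_total_intensity
    b = config.background
    q = config.true_polarization / 100.0
    extra = T - b * n_pix
    D = q * T - b * (n_p - n_a)
    if extra < 0 or abs(D) > extra:
        raise ValueError(
            f"AQP4 budget {T} cannot realise polarization "
            f"{config.true_polarization} over background {b}; raise "
            "aqp4_total_intensity or lower background"
        )
    s = 0.5 * config.pas_ass_spare_fraction * (extra - abs(D))
    P = max(D, 0.0) + s
    A = max(-D, 0.0) + s
    R = extra - P - A
    rest = ~(roi_pas | roi_ass)
    n_r = int(rest.sum())

    aqp4 = np.full((h, w), b, dtype=float)
    aqp4[roi_pas] += P / n_p
    aqp4[roi_ass] += A / n_a
    if n_r:
        aqp4[rest] += R / n_r

    truth = AstrocyteGroundTruth(
        true_polarization=config.true_polarization,
        soma_masks=seg.soma_masks,
        process_polylines=polylines,
        nucleus_centroids=seg.nucleus_centroids,
        roi_pas=roi_pas,
        roi_ass=roi_ass,
        i_pas=b * n_p + P,
        i_ass=b * n_a + A,
        i_global=T,
    )

    channels = {"GFAP": gfap, "AQP4": aqp4, "DAPI": dapi}
    if config.noise_sd > 0:
        channels = {
            name: np.clip(arr + rng.normal(0.0, config.noise_sd, arr.shape), 0, None)
            for name, arr in channels.items()
        }
    image = MultiChannelImage(channels=channels, pixel_size_um=px,
                              metadata={"phantom_seed": config.seed})
    return image, truth


# ---------------------------------------------------------------------------
# p65 translocation phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranslocationPhantomConfig:
    """Parameters of one p65/MMP-9/DAPI phantom field.

    ``nuclear_fraction`` of each cell's p65 budget is painted inside its
    nucleus, the remainder over the cytoplasmic ring.
    """

    n_cells: int = 12
    nuclear_fraction: float = 0.5
    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    cell_radius_um: float = 10.0
    nucleus_radius_um: float = 4.0
    p65_total_per_cell: float = 1e5
    mmp9_intensity_scale: float = 50.0
    dapi_intensity: float = 180.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError("nuclear_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need >= 1 cell")
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus must be smaller than the cell")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TranslocationGroundTruth:
    nuclear_fraction: float
    cell_centers: list[tuple[float, float]]
    nuclei_mask: np.ndarray
    cell_masks: np.ndarray


def generate_translocation_image(
    config: TranslocationPhantomConfig,
) -> tuple[MultiChannelImage, TranslocationGroundTruth]:
    """Render one p65/MMP-9/DAPI phantom with a known nuclear p65 fraction."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    px = config.pixel_size_um
    cell_r = config.cell_radius_um / px
    nuc_r = config.nucleus_radius_um / px

    centers: list[np.ndarray] = []
    for _ in range(config.n_cells):
        for _ in range(500):
            c = rng.uniform([cell_r + 1, cell_r + 1], [h - cell_r - 1, w - cell_r - 1])
            if all(np.hypot(*(c - o)) >= 2 * cell_r + 4 for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError(f"could not place {config.n_cells} non-overlapping cells")

    p65 = np.zeros((h, w))
    mmp9 = np.zeros((h, w))
    dapi = np.zeros((h, w))
    nuclei = np.zeros((h, w), dtype=bool)
    cells = np.zeros((h, w), dtype=bool)
    f = config.nuclear_fraction
    B = config.p65_total_per_cell
    for c in centers:
        cell = _disk_mask((h, w), c, cell_r)
        nuc = _disk_mask((h, w), c, nuc_r)
        ring = cell & ~nuc
        p65[nuc] += f * B / nuc.sum()
        if ring.any():
            p65[ring] += (1 - f) * B / ring.sum()
        mmp9[ring] += config.mmp9_intensity_scale
        dapi[nuc] = config.dapi_intensity
        nuclei |= nuc
        cells |= cell

    truth = TranslocationGroundTruth(
        nuclear_fraction=f,
        cell_centers=[tuple(c) for c in centers],
        nuclei_mask=nuclei,
        cell_masks=cells,
    )
    channels = {"p65": p65, "MMP-9": mmp9, "DAPI": dapi}
    if config.noise_sd > 0:
        channels = {
            name: np.clip(arr + rng.normal(0.0, config.noise_sd, arr.shape), 0, None)
            for name, arr in channels.items()
        }
    image = MultiChannelImage(channels=channels, pixel_size_um=px,
                              metadata={"phantom_seed": config.seed})
    return image, truth
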