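"""Quantitative digital image analysis for chromogenic H-DAB IHC.

Beer–Lambert optical-density transform, two-stain linear unmixing with
explicit unit stain vectors, watershed nucleus detection on the hematoxylin
channel, DAB-positivity classification, and per-slide quantification
(analyzed area in mm², counts, % positive, cells/mm²).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .config import DetectionParams


class FormatError(ValueError):
    """Raised for rasters that are not 8-bit RGB."""


class NumericalError(ValueError):
    """Raised when a stain system is singular."""


class DegenerateGeometryError(ValueError):
    """Raised when an analysis mask is empty."""


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density vectors for a stain set (rows: stains)."""

    vectors: np.ndarray  # (3, 3), rows = stains, cols = (R, G, B) OD
    names: tuple[str, ...] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.shape != (3, 3):
            raise ValueError("StainVectors needs a 3x3 matrix")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit Euclidean norm")
        if not np.isfinite(np.linalg.cond(v)):
            raise NumericalError(f"singular stain matrix for {self.names}")

    @classmethod
    def hdab(cls) -> "StainVectors":
        """Standard H-DAB optical-density vectors (Ruifrok–Johnston values);
        the residual is the normalized cross product of the two."""
        h = np.array([0.65, 0.70, 0.29])
        d = np.array([0.27, 0.57, 0.78])
        res = np.cross(h, d)
        m = np.stack([h / np.linalg.norm(h), d / np.linalg.norm(d), res / np.linalg.norm(res)])
        return cls(m)


class Deconvolution(NamedTuple):
    concentrations: np.ndarray  # (..., 3), per-stain, clipped at 0
    residual: np.ndarray  # (...), RMS reconstruction residual in OD units


@dataclass(frozen=True)
class CellDetection:
    centroid: tuple[float, float]  # (row, col) px
    nucleus_area: float  # px²
    mean_dab_od: float = 0.0
    positive: bool = False


@dataclass(frozen=True)
class MarkerQuantification:
    patient_id: str
    marker: str
    analyzed_area: float  # mm²
    n_cells: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.analyzed_area <= 0:
            raise DegenerateGeometryError("analyzed area must be > 0")
        if not 0 <= self.n_positive <= self.n_cells:
            raise ValueError("0 <= n_positive <= n_cells violated")

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_cells if self.n_cells else 0.0

    @property
    def density_positive(self) -> float:
        return self.n_positive / self.analyzed_area


def rgb_to_od(
    image: np.ndarray,
    background_intensity: Sequence[float] | float = 255.0,
    eps: float = 0.5,
) -> np.ndarray:
    """Per-channel optical density, OD = −log10((I + eps) / I0), clipped ≥ 0."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError("expected an RGB raster with 3 channels")
    i0 = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ValueError("background_intensity must be > 0")
    od = -np.log10((img.astype(float) + eps) / i0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, background_intensity: Sequence[float] | float = 255.0) -> np.ndarray:
    """Inverse Beer–Lambert transform, I = I0 · 10^(−OD) (float, unclipped)."""
    i0 = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,))
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def deconvolve(od: np.ndarray, vectors: StainVectors) -> Deconvolution:
    """Unmix an OD raster into per-stain concentrations.

    Solves OD = cᵀ·M per pixel (M rows are the unit stain vectors), clips
    negative concentrations to zero and reports the RMS reconstruction
    residual after clipping.
    """
    od_arr = np.asarray(od, dtype=float)
    if od_arr.shape[-1] != 3:
        raise FormatError("OD raster must have 3 channels")
    m = vectors.vectors
    if np.linalg.cond(m) > 1e8:
        raise NumericalError(f"singular stain matrix for {vectors.names}")
    conc = od_arr @ np.linalg.inv(m)
    conc = np.clip(conc, 0.0, None)
    recon = conc @ m
    residual = np.sqrt(np.mean((recon - od_arr) ** 2, axis=-1))
    return Deconvolution(conc, residual)


def detect_cells(
    hematoxylin: np.ndarray,
    tissue_mask: np.ndarray,
    params: DetectionParams,
) -> list[CellDetection]:
    """Detect nuclei in a hematoxylin concentration raster.

    Gaussian smoothing (sigma = sigma_factor × min radius), local maxima
    above ``h_threshold`` as seeds, watershed on the smoothed signal to split
    touching nuclei, area filtering, centroids restricted to the tissue mask.
    """
    hema = np.asarray(hematoxylin, dtype=float)
    mask = np.asarray(tissue_mask, dtype=bool)
    if hema.shape != mask.shape:
        raise ValueError("raster and mask must share a shape")
    if not mask.any():
        raise DegenerateGeometryError("tissue mask is empty")
    px = params.pixel_size_um
    sigma_px = params.sigma_factor * params.min_radius_um / px
    smooth = gaussian(hema, sigma=sigma_px, preserve_range=True)
    fg = (smooth > params.h_threshold) & mask
    if not fg.any():
        return []
    # seeds from the Euclidean distance transform: robust to touching,
    # roughly round nuclei of varying staining intensity
    dist = ndi.distance_transform_edt(fg)
    min_dist = max(int(round(params.peak_min_distance_um / px)), 1)
    peaks = peak_local_max(dist, min_distance=min_dist, labels=fg)
    if len(peaks) == 0:
        return []
    seeds = np.zeros(hema.shape, dtype=np.int32)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, seeds, mask=fg)
    min_area_px = params.min_nucleus_area_um2 / px**2
    max_area_px = params.max_nucleus_area_um2 / px**2
    detections = []
    for region in regionprops(labels):
        if not min_area_px <= region.area <= max_area_px:
            continue
        r, c = region.centroid
        ri, ci = int(round(r)), int(round(c))
        if not mask[min(ri, mask.shape[0] - 1), min(ci, mask.shape[1] - 1)]:
            continue
        detections.append(CellDetection(centroid=(r, c), nucleus_area=float(region.area)))
    return detections


def classify_dab(
    detections: Sequence[CellDetection],
    dab: np.ndarray,
    od_threshold: float,
    params: DetectionParams | None = None,
) -> list[CellDetection]:
    """Flag each detection positive iff its mean DAB signal over a disc around
    the centroid exceeds ``od_threshold`` (deterministic)."""
    if od_threshold <= 0:
        raise ValueError("od_threshold must be > 0")
    params = params or DetectionParams()
    dab_arr = np.asarray(dab, dtype=float)
    r_px = max(params.classify_radius_um / params.pixel_size_um, 1.0)
    span = int(np.ceil(r_px))
    dy, dx = np.mgrid[-span : span + 1, -span : span + 1]
    disc = dy**2 + dx**2 <= r_px**2
    offs_y, offs_x = dy[disc], dx[disc]
    h, w = dab_arr.shape
    out = []
    for det in detections:
        r0, c0 = int(round(det.centroid[0])), int(round(det.centroid[1]))
        ys = np.clip(r0 + offs_y, 0, h - 1)
        xs = np.clip(c0 + offs_x, 0, w - 1)
        mean_od = float(dab_arr[ys, xs].mean())
        out.append(replace(det, mean_dab_od=mean_od, positive=mean_od > od_threshold))
    return out


def quantify(
    slide,
    detections: Sequence[CellDetection],
    exclude_epithelium: bool = False,
) -> MarkerQuantification:
    """Per-slide quantification over the analysis mask.

    The analysis mask is the tissue mask, minus the epithelium when
    ``exclude_epithelium`` (the rule applied to CD138, whose antibody stains
    epithelial cells).  Detections outside the mask are dropped before
    counting; area is mask pixels × pixel_size² converted to mm².
    """
    mask = np.asarray(slide.tissue_mask, dtype=bool)
    if exclude_epithelium:
        mask = mask & ~np.asarray(slide.epithelium_mask, dtype=bool)
    area_mm2 = float(mask.sum()) * slide.pixel_size**2 / 1e6
    if area_mm2 <= 0:
        raise DegenerateGeometryError("analyzed area is zero")
    kept = [
        d
        for d in detections
        if mask[
            min(int(round(d.centroid[0])), mask.shape[0] - 1),
            min(int(round(d.centroid[1])), mask.shape[1] - 1),
        ]
    ]
    n_pos = sum(1 for d in kept if d.positive)
    return MarkerQuantification(
        patient_id=slide.patient_id,
        marker=slide.marker,
        analyzed_area=area_mm2,
        n_cells=len(kept),
        n_positive=n_pos,
    )


def quantify_slide(
    slide,
    params: DetectionParams | None = None,
    vectors: StainVectors | None = None,
    exclude_epithelium: bool | None = None,
) -> MarkerQuantification:
    """Full per-slide pipeline: OD → deconvolution → nucleus detection →
    DAB classification → quantification.

    ``exclude_epithelium`` defaults to the marker rule (True for CD138).
    """
    from .config import EPITHELIUM_EXCLUDED_MARKERS

    params = params or DetectionParams()
    if params.pixel_size_um != slide.pixel_size:
        params = replace(params, pixel_size_um=slide.pixel_size)
    vectors = vectors or StainVectors.hdab()
    if exclude_epithelium is None:
        exclude_epithelium = slide.marker in EPITHELIUM_EXCLUDED_MARKERS
    od = rgb_to_od(slide.image)
    conc = deconvolve(od, vectors).concentrations
    detections = detect_cells(conc[..., 0], slide.tissue_mask, params)
    detections = classify_dab(detections, conc[..., 1], params.dab_od_threshold, params)
    return quantify(slide, detections, exclude_epithelium)
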