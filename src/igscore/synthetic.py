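"""Synthetic cohorts and rendered IHC tiles with planted ground truth.

The generator emulates the study conditions of a two-group gingival-biopsy
cohort: 11 healthy controls vs 11 stage III/IV periodontitis patients, a
five-marker immune panel (CD3 T cells, CD20 B cells, CD138 plasma cells,
CD68 macrophages, CD66b neutrophils), per-marker infiltration grades 0–3
with matched ground-truth cell densities, Table-1-style covariates, and
brightfield H-DAB tiles in which every cell is planted at a known position
with a known positivity flag.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEEP_MARKERS,
    GROUPS,
    HEALTHY,
    JUNCTION_MARKERS,
    MARKERS,
    PERIODONTITIS,
    CohortConfig,
    ConfigurationError,
    EPITHELIUM_EXCLUDED_MARKERS,
)
from .stain import StainVectors, od_to_rgb


class DegenerateGeometryError(ValueError):
    """Raised when a slide has no usable tissue."""


@dataclass
class PatientTruth:
    """Ground truth for one simulated subject."""

    patient_id: str
    group: str
    age: float
    gender: str  # "F" / "M"
    smoker: bool
    stage: int | None  # None for healthy controls
    ppd: float  # probing pocket depth, mm
    cal: float  # clinical attachment loss, mm
    bop: float  # bleeding on probing, %
    total_bacteria: float  # ng
    pg_amount: float  # ng
    true_grade: dict[str, int] = field(default_factory=dict)
    true_density: dict[str, float] = field(default_factory=dict)
    true_positive_fraction: dict[str, float] = field(default_factory=dict)
    pauci: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.total_bacteria > 0 and self.pg_amount > self.total_bacteria:
            raise ValueError("pg_amount cannot exceed total_bacteria")

    @property
    def ig_total(self) -> int:
        return int(sum(self.true_grade.values()))


@dataclass
class PlantedCell:
    x_px: float  # column
    y_px: float  # row
    radius_px: float
    positive: bool


@dataclass
class SyntheticSlide:
    """One rendered marker tile with masks and the planted-cell sidecar."""

    patient_id: str
    marker: str
    image: np.ndarray  # (H, W, 3) uint8
    pixel_size: float  # µm/px
    tissue_mask: np.ndarray  # (H, W) bool
    epithelium_mask: np.ndarray  # (H, W) bool
    planted_cells: list[PlantedCell]

    @property
    def tissue_area_mm2(self) -> float:
        return float(self.tissue_mask.sum()) * self.pixel_size**2 / 1e6

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_px": [c.x_px for c in self.planted_cells],
                "y_px": [c.y_px for c in self.planted_cells],
                "radius_px": [c.radius_px for c in self.planted_cells],
                "positive": [int(c.positive) for c in self.planted_cells],
            }
        )


def _draw_discrete(rng: np.random.Generator, table: dict) -> float:
    keys = sorted(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return float(rng.choice(np.asarray(keys, dtype=float), p=probs))


def _exact_count_flags(rng: np.random.Generator, n: int, prob: float) -> np.ndarray:
    """Boolean vector with exactly round(prob*n) True entries, randomly placed.

    Used for binary cohort composition (gender, smoking, pg presence, stage)
    so the default cohort reproduces the reported counts exactly.
    """
    k = int(round(prob * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def generate_cohort(config: CohortConfig | None = None) -> list[PatientTruth]:
    """Draw a deterministic synthetic cohort from ``config`` (seeded).

    Covariates follow the configured per-group distributions; per-marker
    grades follow ``grade_distributions`` and densities are uniform within
    the grade's density band.  *P. gingivalis* is present in exactly
    round(prevalence × n) patients per group, as a per-patient ratio of the
    total-bacteria amount.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_params
    patients: list[PatientTruth] = []
    for group, n in ((HEALTHY, config.n_healthy), (PERIODONTITIS, config.n_periodontitis)):
        female = _exact_count_flags(rng, n, cov["female_prob"][group])
        smoker = _exact_count_flags(rng, n, cov["smoker_prob"][group])
        pg_present = _exact_count_flags(rng, n, cov["pg_prevalence"][group])
        if group == PERIODONTITIS:
            stage4 = _exact_count_flags(rng, n, cov["stage4_prob"])
            pauci = _exact_count_flags(rng, n, config.pauci_fraction)
        else:
            stage4 = np.zeros(n, dtype=bool)
            pauci = np.zeros(n, dtype=bool)
        prefix = "H" if group == HEALTHY else "P"
        for i in range(n):
            age_lo, age_hi = cov["age_uniform"][group]
            mu, sigma = cov["total_bacteria_lognorm"][group]
            total_ng = float(rng.lognormal(mu, sigma))
            if pg_present[i]:
                lmu, lsig = cov["pg_ratio_logitnorm"]
                ratio = 1.0 / (1.0 + np.exp(-rng.normal(lmu, lsig)))
                pg_ng = float(ratio * total_ng)
            else:
                pg_ng = 0.0
            patient = PatientTruth(
                patient_id=f"{prefix}{i + 1:02d}",
                group=group,
                age=float(np.round(rng.uniform(age_lo, age_hi), 1)),
                gender="F" if female[i] else "M",
                smoker=bool(smoker[i]),
                stage=(4 if stage4[i] else 3) if group == PERIODONTITIS else None,
                ppd=_draw_discrete(rng, cov["ppd_mm"][group]),
                cal=_draw_discrete(rng, cov["cal_mm"][group]),
                bop=float(cov["bop_pct"][group]),
                total_bacteria=round(total_ng, 3),
                pg_amount=round(pg_ng, 3),
                pauci=bool(pauci[i]),
            )
            grade_group = HEALTHY if patient.pauci else group
            for marker in config.markers:
                probs = np.asarray(config.grade_probs(grade_group, marker), dtype=float)
                grade = int(rng.choice(4, p=probs / probs.sum()))
                lo, hi = config.density_band(marker, grade)
                density = float(rng.uniform(lo, hi))
                patient.true_grade[marker] = grade
                patient.true_density[marker] = round(density, 3)
                patient.true_positive_fraction[marker] = round(
                    min(1.0, density / config.image_params.total_cell_density), 6
                )
            patients.append(patient)
    return patients


def cohort_to_frame(cohort: Sequence[PatientTruth], markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    """Tabulate a cohort with the documented CSV column layout."""
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "group": p.group,
            "age": p.age,
            "gender": p.gender,
            "smoker": int(p.smoker),
            "stage": "NA" if p.stage is None else p.stage,
            "ppd_mm": p.ppd,
            "cal_mm": p.cal,
            "bop_pct": p.bop,
            "total_bacteria_ng": p.total_bacteria,
            "pg_ng": p.pg_amount,
        }
        for m in markers:
            row[f"true_grade_{m}"] = p.true_grade[m]
            row[f"true_density_{m}"] = p.true_density[m]
        rows.append(row)
    columns = [
        "patient_id", "group", "age", "gender", "smoker", "stage",
        "ppd_mm", "cal_mm", "bop_pct", "total_bacteria_ng", "pg_ng",
    ] + [f"true_{kind}_{m}" for m in markers for kind in ("grade", "density")]
    return pd.DataFrame(rows, columns=columns)


def simulate_observers(
    true_grade: int, n_observers: int, noise: float, rng: np.random.Generator
) -> list[int]:
    """Independent observer grades: each equals the truth with probability
    1 − noise, otherwise truth ± 1 (direction 50/50, clamped to [0, 3])."""
    if not 0 <= true_grade <= 3:
        raise ValueError("true_grade must lie in 0..3")
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    grades = []
    for _ in range(n_observers):
        g = true_grade
        if rng.random() < noise:
            g = int(np.clip(g + rng.choice((-1, 1)), 0, 3))
        grades.append(int(g))
    return grades


def draw_ig_totals(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Scores-only fast path: draw per-patient IG totals for one cohort.

    Uses the same grade distributions and pauci-immune mixture as
    :func:`generate_cohort` but skips covariates and rendering; returns
    (totals, labels) with label 1 = periodontitis.
    """
    totals, labels = [], []
    for group, n in ((HEALTHY, config.n_healthy), (PERIODONTITIS, config.n_periodontitis)):
        if group == PERIODONTITIS:
            pauci = _exact_count_flags(rng, n, config.pauci_fraction)
        else:
            pauci = np.zeros(n, dtype=bool)
        for i in range(n):
            grade_group = HEALTHY if pauci[i] else group
            total = 0
            for marker in config.markers:
                probs = np.asarray(config.grade_probs(grade_group, marker), dtype=float)
                total += int(rng.choice(4, p=probs / probs.sum()))
            totals.append(total)
            labels.append(int(group == PERIODONTITIS))
    return np.asarray(totals), np.asarray(labels)


# ---------------------------------------------------------------------------
# slide rendering
# ---------------------------------------------------------------------------

def _epithelium_depths(width: int, depth_px: float, rng: np.random.Generator) -> np.ndarray:
    """Per-column epithelial depth: a gently undulating boundary (rete-ridge
    like), always at least one pixel deep."""
    x = np.arange(width)
    phase = rng.uniform(0, 2 * np.pi)
    wave = 0.75 + 0.25 * np.sin(2 * np.pi * 2.0 * x / max(width, 1) + phase)
    return np.maximum(depth_px * wave, 1.0)


def _sample_in_mask(rng: np.random.Generator, mask_idx: np.ndarray, n: int, width: int):
    flat = rng.choice(mask_idx, size=n, replace=True)
    rows, cols = np.divmod(flat, width)
    jitter = rng.uniform(-0.5, 0.5, size=(2, n))
    return rows + jitter[0], cols + jitter[1]


def render_slide(
    patient: PatientTruth,
    marker: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SyntheticSlide:
    """Render one H-DAB tile for ``patient`` × ``marker``.

    The planted positive count is round(true_density × tissue area); positives
    are placed by the marker's spatial kernel (CD3/CD20/CD66b in the junction
    band, CD68 uniform in connective tissue, CD138 away from the band), the
    remaining nuclei are counterstain-only, and colors follow a two-stain
    Beer–Lambert absorbance model so stain deconvolution can recover them.
    For CD138 a diffuse DAB wash over the epithelium emulates the antibody's
    epithelial cross-reactivity.
    """
    if marker not in config.markers:
        raise ValueError(f"marker {marker!r} not in configured panel")
    ip = config.image_params
    h = w = ip.tile_px
    px = ip.pixel_size_um

    tissue = np.ones((h, w), dtype=bool)
    if not tissue.any():
        raise DegenerateGeometryError("tissue area is zero")
    depths = _epithelium_depths(w, ip.epithelium_depth_um / px, rng)
    rows = np.arange(h)[:, None]
    epithelium = rows < depths[None, :]
    band = (~epithelium) & (rows < (depths + ip.band_width_um / px)[None, :])
    connective = tissue & ~epithelium
    far = connective & ~band

    tissue_mm2 = tissue.sum() * px**2 / 1e6
    conn_idx = np.flatnonzero(connective)
    band_idx = np.flatnonzero(band)
    far_idx = np.flatnonzero(far)
    tissue_idx = np.flatnonzero(tissue)

    density = patient.true_density[marker]
    n_pos = int(round(density * tissue_mm2))
    n_total = int(round(ip.total_cell_density * tissue_mm2))
    n_neg = max(n_total - n_pos, 0)

    # positive placement per the marker's spatial kernel
    pos_rows = np.empty(0)
    pos_cols = np.empty(0)
    if n_pos:
        if marker in JUNCTION_MARKERS and len(band_idx):
            in_pref = rng.random(n_pos) < ip.band_affinity
            pref_idx, alt_idx = band_idx, conn_idx
        elif marker in DEEP_MARKERS and len(far_idx):
            in_pref = rng.random(n_pos) < ip.band_affinity
            pref_idx, alt_idx = far_idx, conn_idx
        else:
            in_pref = np.zeros(n_pos, dtype=bool)
            pref_idx, alt_idx = conn_idx, conn_idx
        n_pref = int(in_pref.sum())
        r1, c1 = _sample_in_mask(rng, pref_idx, n_pref, w)
        r2, c2 = _sample_in_mask(rng, alt_idx, n_pos - n_pref, w)
        pos_rows = np.concatenate([r1, r2])
        pos_cols = np.concatenate([c1, c2])
    neg_rows, neg_cols = _sample_in_mask(rng, tissue_idx, n_neg, w)

    radii_um = rng.uniform(*ip.cell_radius_um, size=n_pos + n_neg)
    radii_px = radii_um / px
    all_rows = np.concatenate([pos_rows, neg_rows])
    all_cols = np.concatenate([pos_cols, neg_cols])
    positive = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])

    hema = np.zeros((h, w), dtype=np.float32)
    dab = np.zeros((h, w), dtype=np.float32)
    hema_amp = rng.uniform(*ip.hema_amplitude, size=n_pos + n_neg)
    dab_amp = rng.uniform(*ip.dab_amplitude, size=n_pos + n_neg)
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n_pos + n_neg):
        r = radii_px[i]
        r0, c0 = all_rows[i], all_cols[i]
        rlo, rhi = max(int(r0 - r) - 1, 0), min(int(r0 + r) + 2, h)
        clo, chi = max(int(c0 - r) - 1, 0), min(int(c0 + r) + 2, w)
        sub_y = yy[rlo:rhi, clo:chi]
        sub_x = xx[rlo:rhi, clo:chi]
        inside = (sub_y - r0) ** 2 + (sub_x - c0) ** 2 <= r * r
        hema[rlo:rhi, clo:chi][inside] += hema_amp[i]
        if positive[i]:
            dab[rlo:rhi, clo:chi][inside] += dab_amp[i]

    if marker in EPITHELIUM_EXCLUDED_MARKERS:
        dab[epithelium] += ip.epithelial_dab

    vectors = StainVectors.hdab()
    od = hema[..., None] * vectors.vectors[0] + dab[..., None] * vectors.vectors[1]
    image = od_to_rgb(od).astype(np.float32)
    if ip.background_noise > 0:
        image = image + rng.normal(0.0, ip.background_noise * 255.0, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    cells = [
        PlantedCell(float(all_cols[i]), float(all_rows[i]), float(radii_px[i]), bool(positive[i]))
        for i in range(n_pos + n_neg)
    ]
    return SyntheticSlide(
        patient_id=patient.patient_id,
        marker=marker,
        image=image,
        pixel_size=px,
        tissue_mask=tissue,
        epithelium_mask=epithelium,
        planted_cells=cells,
    )


def render_cohort_slides(
    cohort: Sequence[PatientTruth], config: CohortConfig
) -> Iterable[SyntheticSlide]:
    """Render every patient × marker tile, deterministically seeded per slide."""
    base = np.random.SeedSequence(config.seed)
    children = base.spawn(len(cohort) * len(config.markers))
    k = 0
    for patient in cohort:
        for marker in config.markers:
            yield render_slide(patient, marker, config, np.random.default_rng(children[k]))
            k += 1


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    cohort: Sequence[PatientTruth],
    slides: Iterable[SyntheticSlide],
    out_dir,
    config: CohortConfig | None = None,
) -> dict:
    """Write the cohort CSV, per-slide rasters + sidecars, and a manifest.

    The manifest records the seed, a config hash, and a content hash per file
    (computed from the underlying array/table bytes, so it is deterministic
    across re-runs with the same seed).
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "slides").mkdir(exist_ok=True)

    df = cohort_to_frame(cohort, config.markers if config else MARKERS)
    cohort_path = out / "cohort.csv"
    df.to_csv(cohort_path, index=False)
    entries = [
        {
            "path": "cohort.csv",
            "kind": "cohort",
            "sha256": hashlib.sha256(cohort_path.read_bytes()).hexdigest(),
        }
    ]

    slide_entries = []
    for slide in slides:
        stem = f"{slide.patient_id}_{slide.marker}"
        img_path = out / "slides" / f"{stem}.tiff"
        tifffile.imwrite(img_path, slide.image, photometric="rgb")
        tissue_path = out / "slides" / f"{stem}_tissue.png"
        epi_path = out / "slides" / f"{stem}_epithelium.png"
        iio.imwrite(tissue_path, (slide.tissue_mask * 255).astype(np.uint8))
        iio.imwrite(epi_path, (slide.epithelium_mask * 255).astype(np.uint8))
        cells_path = out / "slides" / f"{stem}_cells.csv"
        slide.cells_frame().to_csv(cells_path, index=False)
        content = hashlib.sha256()
        content.update(slide.image.tobytes())
        content.update(slide.tissue_mask.tobytes())
        content.update(slide.epithelium_mask.tobytes())
        content.update(cells_path.read_bytes())
        slide_entries.append(
            {
                "patient_id": slide.patient_id,
                "marker": slide.marker,
                "image": f"slides/{stem}.tiff",
                "tissue_mask": f"slides/{stem}_tissue.png",
                "epithelium_mask": f"slides/{stem}_epithelium.png",
                "cells": f"slides/{stem}_cells.csv",
                "pixel_size_um": slide.pixel_size,
                "sha256": content.hexdigest(),
            }
        )

    manifest = {
        "seed": config.seed if config else None,
        "config_sha256": config.config_hash() if config else None,
        "n_patients": len(cohort),
        "n_slides": len(slide_entries),
        "files": entries,
        "slides": slide_entries,
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
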