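"""Configuration objects for the IG-score pipeline.

Everything that calibrates the synthetic cohort generator, the image
renderer, the stain-quantification stage and the grading stage lives here,
so that a single :class:`CohortConfig` (plus a seed) fully determines a run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Marker panel of the immunologic gingival score, in reporting order.
MARKERS: tuple[str, ...] = ("CD3", "CD20", "CD138", "CD68", "CD66b")

HEALTHY = "healthy"
PERIODONTITIS = "periodontitis"
GROUPS = (HEALTHY, PERIODONTITIS)

#: Markers whose positive cells concentrate in the band of connective tissue
#: adjacent to the epithelium (the epithelio-connective junction).
JUNCTION_MARKERS = frozenset({"CD3", "CD20", "CD66b"})
#: Marker whose positive cells sit deeper in the connective tissue.
DEEP_MARKERS = frozenset({"CD138"})
#: Marker requiring epithelium exclusion during quantification (the CD138
#: antibody also stains epithelial cells).
EPITHELIUM_EXCLUDED_MARKERS = frozenset({"CD138"})


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class ImageParams:
    """Rendering and geometry parameters for synthetic IHC tiles.

    The tile is a flat piece of gingiva seen from above: a wavy band of
    epithelium along the top edge, connective tissue below it.  All
    distances are physical (µm) and converted to pixels with
    ``pixel_size_um``.
    """

    tile_px: int = 2000
    pixel_size_um: float = 0.5
    #: mean depth of the epithelial layer from the top edge, µm
    epithelium_depth_um: float = 80.0
    #: width of the junction band of connective tissue below the epithelium, µm
    band_width_um: float = 150.0
    #: fraction of junction/deep markers' positives planted inside their
    #: preferred compartment
    band_affinity: float = 0.75
    cell_radius_um: tuple[float, float] = (3.0, 5.0)
    #: overall nucleated-cell density in tissue, cells/mm²
    total_cell_density: float = 2500.0
    #: per-cell hematoxylin amplitude range (optical-density units)
    hema_amplitude: tuple[float, float] = (0.5, 0.9)
    #: per-cell DAB amplitude range for positive cells (optical-density units)
    dab_amplitude: tuple[float, float] = (0.6, 1.0)
    #: diffuse epithelial DAB (optical density) for markers with epithelial
    #: cross-reactivity (CD138)
    epithelial_dab: float = 0.4
    #: additive intensity noise, as a fraction of full scale (255)
    background_noise: float = 0.01

    def __post_init__(self) -> None:
        if self.tile_px < 8:
            raise ConfigurationError("image_params.tile_px must be >= 8")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("image_params.pixel_size_um must be > 0")
        lo, hi = self.cell_radius_um
        if not 0 < lo <= hi:
            raise ConfigurationError("image_params.cell_radius_um must be increasing and > 0")

    @property
    def tile_area_mm2(self) -> float:
        return (self.tile_px * self.pixel_size_um) ** 2 / 1e6


def default_grade_distributions() -> dict[str, dict[str, tuple[float, ...]]]:
    """Per group × marker probabilities over grades 0–3.

    Calibrated so that simulated per-marker grade medians/IQRs and the IG
    totals reproduce the reported cohort summaries: healthy ~ 1 point total
    (CD68 typically grade 1, the rest 0), periodontitis ~ 9 points total
    (every marker typically grade 2).
    """
    healthy_other = (0.85, 0.13, 0.02, 0.0)
    perio_other = (0.10, 0.25, 0.35, 0.30)
    return {
        HEALTHY: {
            m: ((0.35, 0.50, 0.14, 0.01) if m == "CD68" else healthy_other)
            for m in MARKERS
        },
        PERIODONTITIS: {
            m: ((0.05, 0.20, 0.50, 0.25) if m == "CD138" else perio_other)
            for m in MARKERS
        },
    }


#: Ground-truth positive-cell density band per grade, cells/mm².  The
#: semi-quantitative atlas is visual; these numeric anchors are an artifact
#: calibration, surfaced in config.
DEFAULT_DENSITY_PER_GRADE: tuple[tuple[float, float], ...] = (
    (0.0, 25.0),
    (25.0, 200.0),
    (200.0, 800.0),
    (800.0, 2000.0),
)


def default_density_per_grade() -> dict[str, tuple[tuple[float, float], ...]]:
    return {m: DEFAULT_DENSITY_PER_GRADE for m in MARKERS}


def default_covariate_params() -> dict:
    """Distribution parameters for the demographic / clinical / bacteriologic
    covariates, calibrated to the reported Table-1 style summaries
    (median (Q1–Q3)–mean per group).

    ``age``: uniform within the printed IQR per group.  ``ppd``/``cal``:
    discrete mm distributions matching the printed median/quartiles/mean.
    ``total_bacteria``: log-normal (median, IQR-matched sigma).  P. gingivalis
    is modelled as a per-patient ratio (logit-normal, median 33%, IQR 14–54%)
    of the patient's total-bacteria amount, applied to the patients assigned
    pg-positive by prevalence.
    """
    return {
        "age_uniform": {HEALTHY: (17.0, 20.5), PERIODONTITIS: (52.0, 58.0)},
        "female_prob": {HEALTHY: 9 / 11, PERIODONTITIS: 4 / 11},
        "smoker_prob": {HEALTHY: 1 / 11, PERIODONTITIS: 6 / 11},
        "stage4_prob": 7 / 11,
        "ppd_mm": {
            HEALTHY: {1: 0.4, 2: 0.6},
            PERIODONTITIS: {5: 0.05, 6: 0.30, 7: 0.35, 8: 0.20, 9: 0.10},
        },
        "cal_mm": {
            HEALTHY: {0: 1.0},
            PERIODONTITIS: {3: 0.55, 5: 0.10, 6: 0.05, 7: 0.30},
        },
        "bop_pct": {HEALTHY: 0.0, PERIODONTITIS: 100.0},
        "total_bacteria_lognorm": {
            HEALTHY: (math.log(6.93), 0.635),
            PERIODONTITIS: (math.log(11.98), 1.158),
        },
        "pg_prevalence": {HEALTHY: 1 / 11, PERIODONTITIS: 10 / 11},
        "pg_ratio_logitnorm": (_logit(0.33), 1.47),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full calibration of a synthetic cohort.

    Defaults reproduce the study conditions: 11 healthy controls vs 11
    stage III/IV periodontitis patients, five-marker panel, grade
    distributions matched to the reported per-marker medians/IQRs, and a
    1-in-11 "pauci-immune" periodontitis patient whose infiltrate looks
    healthy-like.
    """

    n_healthy: int = 11
    n_periodontitis: int = 11
    seed: int = 0
    markers: tuple[str, ...] = MARKERS
    grade_distributions: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=default_grade_distributions
    )
    density_per_grade: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=default_density_per_grade
    )
    covariate_params: Mapping = field(default_factory=default_covariate_params)
    #: probability an observer's grade deviates ±1 from truth
    observer_noise: float = 0.18
    #: fraction of periodontitis patients with a pauci-immune (healthy-like)
    #: infiltrate
    pauci_fraction: float = 1 / 11
    #: calibration target for the median IG total per group
    ig_median_target: Mapping[str, float] = field(
        default_factory=lambda: {HEALTHY: 1.0, PERIODONTITIS: 9.0}
    )
    image_params: ImageParams = field(default_factory=ImageParams)

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_periodontitis < 1:
            raise ConfigurationError("n_healthy and n_periodontitis must be >= 1")
        if not 0.0 <= self.observer_noise <= 1.0:
            raise ConfigurationError("observer_noise must lie in [0, 1]")
        if not 0.0 <= self.pauci_fraction <= 1.0:
            raise ConfigurationError("pauci_fraction must lie in [0, 1]")
        for group, per_marker in self.grade_distributions.items():
            for marker, probs in per_marker.items():
                if len(probs) != 4 or any(p < 0 for p in probs):
                    raise ConfigurationError(
                        f"grade_distributions[{group}][{marker}] must be 4 nonnegative probabilities"
                    )
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"grade_distributions[{group}][{marker}] must sum to 1"
                    )
        for marker in self.markers:
            bands = self.density_per_grade[marker]
            if len(bands) != 4:
                raise ConfigurationError(f"density_per_grade[{marker}] needs 4 bands")
            for g in range(3):
                if not bands[g][0] <= bands[g][1] <= bands[g + 1][0] <= bands[g + 1][1]:
                    raise ConfigurationError(
                        f"density_per_grade[{marker}] bands must be disjoint and increasing"
                    )

    def grade_probs(self, group: str, marker: str):
        return self.grade_distributions[group][marker]

    def density_band(self, marker: str, grade: int) -> tuple[float, float]:
        return self.density_per_grade[marker][grade]

    def thresholds(self) -> "GradeThresholds":
        """Grade cut-points implied by the density bands (band lower edges)."""
        return GradeThresholds(
            {m: tuple(self.density_per_grade[m][g][0] for g in (1, 2, 3)) for m in self.markers}
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class GradeThresholds:
    """Per-marker density cut-points (c1, c2, c3) in cells/mm².

    Density < c1 is grade 0, [c1, c2) grade 1, [c2, c3) grade 2, >= c3
    grade 3 (left-closed intervals).
    """

    cutpoints: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for marker, (c1, c2, c3) in self.cutpoints.items():
            if not 0 < c1 < c2 < c3:
                raise ConfigurationError(
                    f"thresholds[{marker}] must satisfy 0 < c1 < c2 < c3"
                )

    def __getitem__(self, marker: str) -> tuple[float, float, float]:
        return tuple(self.cutpoints[marker])


@dataclass(frozen=True)
class DetectionParams:
    """Nucleus detection / DAB classification parameters.

    Detection smooths the hematoxylin channel with a Gaussian of
    ``sigma_factor`` × the minimum expected nucleus radius, finds local
    maxima above ``h_threshold`` (optical-density concentration units),
    splits touching nuclei by watershed, and filters components by area.
    """

    pixel_size_um: float = 0.5
    min_radius_um: float = 3.0
    sigma_factor: float = 0.5
    #: minimum separation between watershed seeds, µm
    peak_min_distance_um: float = 2.0
    h_threshold: float = 0.15
    min_nucleus_area_um2: float = 16.0
    max_nucleus_area_um2: float = 400.0
    dab_od_threshold: float = 0.3
    #: radius of the disc over which the mean DAB signal is taken, µm
    classify_radius_um: float = 2.0


def small_image_params(tile_px: int = 384, pixel_size_um: float = 1.0) -> ImageParams:
    """Desk-scale rendering geometry used by the test fixture and examples
    (0.147 mm² per tile at the defaults); the pipeline is identical at any
    tile size."""
    return ImageParams(tile_px=tile_px, pixel_size_um=pixel_size_um)


def config_to_yaml(config: CohortConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(config.to_dict()), fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping) -> CohortConfig:
    kwargs = dict(raw)
    if "image_params" in kwargs and isinstance(kwargs["image_params"], Mapping):
        ip = dict(kwargs["image_params"])
        for key in ("cell_radius_um", "hema_amplitude", "dab_amplitude"):
            if key in ip:
                ip[key] = tuple(ip[key])
        kwargs["image_params"] = ImageParams(**ip)
    if "markers" in kwargs:
        kwargs["markers"] = tuple(kwargs["markers"])
    if "grade_distributions" in kwargs:
        kwargs["grade_distributions"] = {
            g: {m: tuple(p) for m, p in per.items()}
            for g, per in kwargs["grade_distributions"].items()
        }
    if "density_per_grade" in kwargs:
        kwargs["density_per_grade"] = {
            m: tuple(tuple(b) for b in bands)
            for m, bands in kwargs["density_per_grade"].items()
        }
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:  # unknown field name
        raise ConfigurationError(str(exc)) from exc


def _plain(obj):
    """Recursively convert tuples to lists for YAML round-tripping."""
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
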