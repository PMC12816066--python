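import dataclasses

import numpy as np
import pytest

from igscore.config import CohortConfig, DetectionParams, small_image_params
from igscore.stain import quantify_slide
from igscore.synthetic import generate_cohort, render_cohort_slides


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Default study conditions with desk-scale tiles (384 px @ 1 µm/px)."""
    return dataclasses.replace(CohortConfig(seed=11), image_params=small_image_params())


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def rendered_slides(small_config, cohort):
    """All 22 patients × 5 markers rendered once per session."""
    return list(render_cohort_slides(cohort, small_config))


def planted_truth_in_mask(slide, exclude_epithelium: bool):
    """Planted counts/fraction/density restricted to the analysis mask."""
    mask = slide.tissue_mask.copy()
    if exclude_epithelium:
        mask &= ~slide.epithelium_mask
    h, w = mask.shape
    kept = [
        c
        for c in slide.planted_cells
        if mask[min(int(round(c.y_px)), h - 1), min(int(round(c.x_px)), w - 1)]
    ]
    n_pos = sum(c.positive for c in kept)
    area_mm2 = mask.sum() * slide.pixel_size**2 / 1e6
    return {
        "n_cells": len(kept),
        "n_positive": n_pos,
        "fraction": n_pos / max(len(kept), 1),
        "density": n_pos / area_mm2,
    }


@pytest.fixture(scope="session")
def fixture_recovery(rendered_slides):
    """Per-slide planted truth vs pipeline estimate over the whole fixture."""
    rows = []
    for slide in rendered_slides:
        exclude = slide.marker == "CD138"
        q = quantify_slide(slide, DetectionParams(pixel_size_um=slide.pixel_size))
        truth = planted_truth_in_mask(slide, exclude)
        rows.append(
            {
                "patient_id": slide.patient_id,
                "marker": slide.marker,
                "true_fraction": truth["fraction"],
                "est_fraction": q.n_positive / max(q.n_cells, 1),
                "true_density": truth["density"],
                "est_density": q.density_positive,
            }
        )
    return rows
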