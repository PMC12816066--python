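"""Readers/writers and the plain-text report for the IG-score pipeline.

CSV dialect: comma-separated, '.' decimal, UTF-8, header mandatory.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import MARKERS

logger = logging.getLogger("igscore")

COHORT_MANDATORY = ("patient_id", "group")
QUANT_COLUMNS = (
    "patient_id",
    "marker",
    "analyzed_area_mm2",
    "n_cells",
    "n_positive",
    "pct_positive",
    "density_per_mm2",
)


class SchemaError(ValueError):
    """Raised when a mandatory column is missing; names the column."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; typed columns, missing values as NaN/None,
    unknown columns preserved."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in COHORT_MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV is missing mandatory column {col!r}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def quantifications_to_frame(quants: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [q.patient_id for q in quants],
            "marker": [q.marker for q in quants],
            "analyzed_area_mm2": [q.analyzed_area for q in quants],
            "n_cells": [q.n_cells for q in quants],
            "n_positive": [q.n_positive for q in quants],
            "pct_positive": [q.pct_positive for q in quants],
            "density_per_mm2": [q.density_positive for q in quants],
        }
    )


def read_quant_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("patient_id", "marker", "density_per_mm2"):
        if col not in df.columns:
            raise SchemaError(f"quantification CSV is missing mandatory column {col!r}")
    return df


def scores_to_json(scores: Sequence, path) -> None:
    payload = [
        {
            "patient_id": s.patient_id,
            "grades": {m: int(g) for m, g in s.grades.items()},
            "reexamined": sorted(s.reexamined),
            "total": s.total,
            "classification": s.classification,
        }
        for s in scores
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def write_manifest(path, seed: int, config_hash: str, outputs: Mapping[str, str]) -> dict:
    """Record seed, config hash and package version next to every CLI run."""
    from . import __version__

    manifest = {
        "seed": seed,
        "config_sha256": config_hash,
        "igscore_version": __version__,
        "outputs": dict(outputs),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_report(
    path,
    comparisons: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    roc_summary: Mapping | None = None,
    markers: Sequence[str] = MARKERS,
) -> str:
    """Render a deterministic plain-text summary of a full run: Table-1-style
    comparisons, the per-marker + total score table, re-examined sections,
    and the ROC summary."""
    lines: list[str] = ["IG score pipeline report", "=" * 24, ""]
    if comparisons is not None and len(comparisons):
        lines += ["Group comparisons (healthy vs periodontitis)", "-" * 44]
        for _, row in comparisons.iterrows():
            lines.append(
                f"{row['variable']:<22} {row['healthy']:<22} {row['periodontitis']:<22} "
                f"[{row['test']}] p={row['p']:.4g} {row['stars']}"
            )
        lines.append("")
    if scores is not None and len(scores):
        lines += ["Score summary (median per group)", "-" * 32]
        score_rows = [f"grade_{m}" for m in markers] + ["ig_total"]
        for col in score_rows:
            per_group = scores.groupby("group")[col].median()
            rendered = "  ".join(f"{g}={per_group[g]:g}" for g in sorted(per_group.index))
            lines.append(f"{col:<14} {rendered}")
        lines.append("")
        flagged = scores[scores["reexamined"].astype(str).str.len() > 0]
        lines += ["Re-examined marker-sections", "-" * 27]
        if len(flagged):
            for _, row in flagged.iterrows():
                lines.append(f"{row['patient_id']}: {row['reexamined']}")
        else:
            lines.append("none")
        lines.append("")
    if roc_summary is not None:
        lines += [
            "Diagnostic performance",
            "-" * 22,
            f"AUC = {roc_summary['auc']:.4f}",
            f"selected cut-off = {roc_summary['selected_cutoff']}",
            f"sensitivity at cut-off = {100 * roc_summary['sensitivity']:.1f}%",
            f"specificity at cut-off = {100 * roc_summary['specificity']:.1f}%",
            "",
        ]
    text = "\n".join(lines)
    Path(path).write_text(text, encoding="utf-8")
    return text
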