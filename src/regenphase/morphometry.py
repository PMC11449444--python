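"""Defect-morphometry arithmetic for mandible resection experiments.

Inputs are measurement tables produced by manual tracing (lengths in mm,
landmark/vertex coordinates in mm); this module reproduces the downstream
quantities: relative defect size, traced defect area (shoelace), distal-stump
displacement angle, and perimeter change versus intact controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from regenphase.exceptions import FormatError, GeometryError


@dataclass
class MorphoRecord:
    animal_id: str
    time_dpi: int
    defect_length: float | None = None  # mm
    hemi_perimeter: float | None = None  # mm
    full_perimeter: float | None = None  # mm
    defect_polygon: list[tuple[float, float]] | None = None  # mm vertices
    angle_landmarks: tuple | None = None  # (p1, vertex, p2)


def relative_defect_size(r: MorphoRecord) -> tuple[float, float]:
    """Defect length as a percentage of the hemimandible and full perimeters."""
    for name in ("defect_length", "hemi_perimeter", "full_perimeter"):
        if getattr(r, name) is None:
            raise FormatError(f"record {r.animal_id}: missing {name}")
    return (
        100.0 * r.defect_length / r.hemi_perimeter,
        100.0 * r.defect_length / r.full_perimeter,
    )


def cohort_relative_defect_size(records) -> tuple[float, float]:
    """Mean relative defect size over animals (percent of hemi, of full)."""
    pairs = [relative_defect_size(r) for r in records]
    arr = np.asarray(pairs, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def polygon_area(vertices) -> float:
    """Area of a traced polygon by the shoelace formula (absolute value)."""
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def displacement_angle(p1, vertex, p2) -> float:
    """Interior angle (degrees, in [0, 180]) at ``vertex`` between p1 and p2."""
    p1, vertex, p2 = (np.asarray(p, dtype=float) for p in (p1, vertex, p2))
    a, b = p1 - vertex, p2 - vertex
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise GeometryError("angle landmarks coincide with the vertex")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def perimeter_change(resected: float, intact: float) -> float:
    """Percent by which the resected perimeter is smaller than the intact one."""
    if intact <= 0:
        raise GeometryError("intact perimeter must be positive")
    return 100.0 * (intact - resected) / intact


def average_triplicates(values) -> float:
    """Mean of repeated measurements of the same quantity on one animal."""
    return float(np.mean(np.asarray(values, dtype=float)))


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point means and n for the numeric columns of a measurement table."""
    numeric = records.select_dtypes("number").columns.difference(["time_dpi"])
    grouped = records.groupby("time_dpi")[list(numeric)]
    summary = grouped.mean()
    summary["n"] = grouped.size()
    return summary.reset_index()
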