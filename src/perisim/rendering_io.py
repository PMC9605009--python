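"""Grayscale rendering and file I/O (result JSON, CSV tables, PGM/PNG images).

The grayscale rule maps 14 dB to black (0) and 40 dB to white (255), with
intermediate sensitivities linear between gray levels 1 and 254.  Rendering
uses an integer-only tiles mode (bit-exact PGM output) and a smoothed
bilinear mode; the canvas is field-angle linear (degree ↔ pixel), 61°×61°
centred on fixation.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .exam_engine import ExamConfig, ExamResult, PointResult, PresentationRecord
from .field_geometry import grid_coords
from .observer_sim import CohortRecord

__all__ = [
    "ResultFormatError",
    "FieldTableError",
    "db_to_gray",
    "render_map",
    "write_pgm",
    "write_png",
    "write_result",
    "read_result",
    "write_field_csv",
    "read_field_csv",
    "read_sector_map",
    "write_cohort",
    "read_cohort",
]

GRAY_DB_LO = 14.0
GRAY_DB_HI = 40.0
RESULT_FORMAT = "perisim-exam-result"
RESULT_VERSION = 1
BACKGROUND_GRAY = 200


class ResultFormatError(ValueError):
    """Malformed or incomplete exam-result document."""


class FieldTableError(ValueError):
    """Malformed 30-2 field table or sector-map file."""


def db_to_gray(db: float) -> int:
    """Map a threshold in dB to an 8-bit gray level.

    14 dB → 0 (black) and 40 dB → 255 (white) exactly; interior values are
    ``round-half-up(1 + 253·(db - 14)/26)``, confined to [1, 254].  Out of
    range inputs are clamped to the endpoint with a warning.
    """
    if db < GRAY_DB_LO or db > GRAY_DB_HI:
        warnings.warn(f"threshold {db} dB outside [14, 40]; clamping", stacklevel=2)
        db = min(max(db, GRAY_DB_LO), GRAY_DB_HI)
    if db == GRAY_DB_LO:
        return 0
    if db == GRAY_DB_HI:
        return 255
    level = math.floor(1.0 + 253.0 * (db - GRAY_DB_LO) / 26.0 + 0.5)
    return int(min(max(level, 1), 254))


def _as_threshold_dict(result) -> dict[tuple[float, float], float]:
    if isinstance(result, ExamResult):
        return result.thresholds()
    return dict(result)


def render_map(
    result,
    style: str = "tiles",
    px_per_deg: int = 4,
    background: int = BACKGROUND_GRAY,
) -> np.ndarray:
    """Render a grayscale visual-field map as a uint8 array.

    ``result`` may be an :class:`ExamResult` or a mapping from (x, y) to dB.
    ``tiles`` paints each point's 6°×6° cell with its gray level (integer
    pipeline, byte-reproducible); ``interpolated`` bilinearly interpolates
    dB between grid points inside the tested cells.  Pixels outside the
    tested region take the background gray.
    """
    if style not in ("tiles", "interpolated"):
        raise ValueError("style must be 'tiles' or 'interpolated'")
    thresholds = _as_threshold_dict(result)
    half = 30.5  # 61x61-degree canvas
    size = int(round(2 * half * px_per_deg))
    img = np.full((size, size), np.uint8(background), dtype=np.uint8)

    # pixel centre coordinates in degrees
    xs = (np.arange(size) + 0.5) / px_per_deg - half
    ys = half - (np.arange(size) + 0.5) / px_per_deg

    if style == "interpolated":
        from scipy.interpolate import RegularGridInterpolator

        axis = np.array([-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0, 27.0])
        grid = np.empty((len(axis), len(axis)))
        tested = list(thresholds)
        for i, gx in enumerate(axis):
            for j, gy in enumerate(axis):
                if (gx, gy) in thresholds:
                    grid[i, j] = thresholds[(gx, gy)]
                else:
                    nearest = min(
                        tested, key=lambda c: (math.hypot(c[0] - gx, c[1] - gy), c)
                    )
                    grid[i, j] = thresholds[nearest]
        interp = RegularGridInterpolator((axis, axis), grid, method="linear")

    for (px, py), db in thresholds.items():
        col = (xs >= px - 3.0) & (xs < px + 3.0)
        row = (ys > py - 3.0) & (ys <= py + 3.0)
        if style == "tiles":
            img[np.ix_(row, col)] = db_to_gray(db)
        else:
            cx = np.clip(xs[col], -27.0, 27.0)
            cy = np.clip(ys[row], -27.0, 27.0)
            gx, gy = np.meshgrid(cx, cy)
            # round to 1e-9 dB so float noise cannot pull an exact endpoint
            # (14 -> 0, 40 -> 255) onto the interior 1-254 ramp
            vals = np.clip(
                np.round(interp(np.column_stack([gx.ravel(), gy.ravel()])), 9),
                GRAY_DB_LO,
                GRAY_DB_HI,
            )
            cell = np.array([db_to_gray(v) for v in vals], dtype=np.uint8)
            img[np.ix_(row, col)] = cell.reshape(len(cy), len(cx))
    return img


def write_pgm(path, image: np.ndarray) -> None:
    """Write a uint8 image as ASCII PGM (P2) — bit-exact across platforms."""
    arr = np.asarray(image, dtype=np.uint8)
    with open(path, "w") as fh:
        fh.write(f"P2\n{arr.shape[1]} {arr.shape[0]}\n255\n")
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_png(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# Exam result JSON
# ---------------------------------------------------------------------------

def write_result(path, result: ExamResult) -> None:
    doc = {
        "format": RESULT_FORMAT,
        "version": RESULT_VERSION,
        "eye": result.eye,
        "config": result.config,
        "fixation": result.fixation._asdict(),
        "points": [p._asdict() for p in result.points],
        "log": [list(r) for r in result.log],
        "total_presentations": result.total_presentations,
        "simulated_duration_s": result.simulated_duration_s,
        "observer_hash": result.observer_hash,
        "test_order": result.test_order,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_result(path) -> ExamResult:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("format", "eye", "config", "fixation", "points", "log",
                "total_presentations", "observer_hash"):
        if key not in doc:
            raise ResultFormatError(f"result document missing key {key!r}")
    if doc["format"] != RESULT_FORMAT:
        raise ResultFormatError(f"unexpected format {doc['format']!r}")
    expected = set(grid_coords(doc["eye"]))
    seen_coords = [(p["x"], p["y"]) for p in doc["points"]]
    dupes = {c for c in seen_coords if seen_coords.count(c) > 1}
    if dupes:
        raise ResultFormatError(f"duplicate point coordinates: {sorted(dupes)}")
    missing = expected - set(seen_coords)
    if missing:
        raise ResultFormatError(f"missing grid points: {sorted(missing)}")
    if len(doc["log"]) != doc["total_presentations"]:
        raise ResultFormatError("log length disagrees with total_presentations")
    ExamConfig.from_dict(doc["config"])  # validates the echo
    return ExamResult(
        eye=doc["eye"],
        fixation=PointResult(**doc["fixation"]),
        points=[PointResult(**p) for p in doc["points"]],
        log=[PresentationRecord(*row) for row in doc["log"]],
        total_presentations=doc["total_presentations"],
        simulated_duration_s=doc["simulated_duration_s"],
        config=doc["config"],
        observer_hash=doc["observer_hash"],
        test_order=doc.get("test_order", []),
    )


# ---------------------------------------------------------------------------
# Field tables and sector maps (CSV)
# ---------------------------------------------------------------------------

def write_field_csv(path, field: dict[tuple[float, float], float]) -> None:
    """Write a 30-2 field table with columns x_deg, y_deg, sens_db."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_deg", "y_deg", "sens_db"])
        for (x, y), v in sorted(field.items(), key=lambda kv: (-kv[0][1], kv[0][0])):
            writer.writerow([f"{x:g}", f"{y:g}", repr(float(v))])


def _parse_rows(path, n_value_cols: int):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FieldTableError(f"{path}: empty file") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 + n_value_cols:
                raise FieldTableError(f"{path}: line {lineno}: expected "
                                      f"{2 + n_value_cols} columns, got {len(row)}")
            try:
                x, y = float(row[0]), float(row[1])
                vals = [row[2 + k] for k in range(n_value_cols)]
            except ValueError as exc:
                raise FieldTableError(f"{path}: line {lineno}: {exc}") from None
            rows.append((lineno, x, y, vals))
    return header, rows


def _check_grid_coverage(path, coords: Sequence[tuple[float, float]]) -> None:
    expected = set(grid_coords("OD"))  # coordinate set is eye-independent
    seen: set[tuple[float, float]] = set()
    for c in coords:
        if c in seen:
            raise FieldTableError(f"{path}: duplicate coordinate {c}")
        seen.add(c)
    unknown = seen - expected
    if unknown:
        raise FieldTableError(f"{path}: coordinates not on the 30-2 grid: {sorted(unknown)}")
    missing = expected - seen
    if missing:
        raise FieldTableError(f"{path}: missing grid points: {sorted(missing)}")


def read_field_csv(path, require_complete: bool = True) -> dict[tuple[float, float], float]:
    """Read a field table (x_deg, y_deg, sens_db); validates 30-2 completeness."""
    _header, rows = _parse_rows(path, 1)
    field = {}
    for lineno, x, y, vals in rows:
        try:
            field[(x, y)] = float(vals[0])
        except ValueError as exc:
            raise FieldTableError(f"{path}: line {lineno}: {exc}") from None
    if require_complete:
        _check_grid_coverage(path, list(field))
    return field


def read_sector_map(path) -> dict[tuple[float, float], str]:
    """Read a sector-map CSV (x_deg, y_deg, sector_id); coords must be on-grid."""
    _header, rows = _parse_rows(path, 1)
    expected = set(grid_coords("OD"))
    mapping = {}
    for lineno, x, y, vals in rows:
        if (x, y) not in expected:
            raise FieldTableError(f"{path}: line {lineno}: ({x:g}, {y:g}) is not a 30-2 location")
        if (x, y) in mapping:
            raise FieldTableError(f"{path}: line {lineno}: duplicate coordinate ({x:g}, {y:g})")
        mapping[(x, y)] = vals[0].strip()
    return mapping


# ---------------------------------------------------------------------------
# Paired cohorts
# ---------------------------------------------------------------------------

def write_cohort(directory, records: Sequence[CohortRecord]) -> None:
    """Write a cohort: manifest.csv plus one per-eye field table."""
    import os

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "laterality", "fl", "fp", "fn", "md", "psd", "vfi"])
        for r in records:
            writer.writerow(
                [r.eye_id, r.laterality, repr(r.fl), repr(r.fp), repr(r.fn),
                 repr(r.md), repr(r.psd), repr(r.vfi)]
            )
    for r in records:
        with open(os.path.join(directory, f"{r.eye_id}.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_deg", "y_deg", "sens_a_db", "sens_b_db"])
            for (x, y) in sorted(r.sens_a, key=lambda c: (-c[1], c[0])):
                writer.writerow(
                    [f"{x:g}", f"{y:g}", repr(r.sens_a[(x, y)]), repr(r.sens_b[(x, y)])]
                )


def read_cohort(directory) -> list[CohortRecord]:
    import os

    manifest = os.path.join(directory, "manifest.csv")
    if not os.path.exists(manifest):
        raise FieldTableError(f"{directory}: no manifest.csv")
    records = []
    with open(manifest, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                eye_id = row["eye_id"]
                meta = {k: float(row[k]) for k in ("fl", "fp", "fn", "md", "psd", "vfi")}
                laterality = row["laterality"]
            except (KeyError, TypeError, ValueError) as exc:
                raise FieldTableError(f"{manifest}: line {lineno}: {exc}") from None
            eye_path = os.path.join(directory, f"{eye_id}.csv")
            _header, rows = _parse_rows(eye_path, 2)
            sens_a, sens_b = {}, {}
            for ln, x, y, vals in rows:
                try:
                    sens_a[(x, y)] = float(vals[0])
                    sens_b[(x, y)] = float(vals[1])
                except ValueError as exc:
                    raise FieldTableError(f"{eye_path}: line {ln}: {exc}") from None
            _check_grid_coverage(eye_path, list(sens_a))
            records.append(
                CohortRecord(eye_id=eye_id, laterality=laterality,
                             sens_a=sens_a, sens_b=sens_b, **meta)
            )
    return records
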