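"""Comparison statistics for paired visual-field cohorts.

Implements the analysis used to compare two perimeters tested on the same
eyes: mean sensitivities per region (global, hemifields, quadrants, GHT
sectors), Pearson correlations between devices per region and per test
location with the conventional strength cut-offs (strong r ≥ 0.7, moderate
0.4 ≤ r < 0.7, weak r < 0.4), a reliability screen (exclude eyes with
FL > 20%, FP > 15% or FN > 30%), and paired t-tests.

The default glaucoma-hemifield-test (GHT) sector map is a mirror-symmetric
five-pair clustering of the central points (paracentral, nasal, temporal,
and two arcuate sectors per hemifield); the peripheral 30-2 edge ring and
the blind-spot points are unassigned.  Published GHT cluster boundaries
vary in reproduction, so the map can be overridden from a sector-map CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .field_geometry import (
    blind_spot_coords,
    grid_coords,
    hemifield_of,
    quadrant_of,
    temporal_x,
)
from .observer_sim import CohortRecord

__all__ = [
    "SectorMap",
    "RegionCorrelation",
    "CorrelationReport",
    "PairedTResult",
    "build_default_sector_map",
    "region_points",
    "region_mean",
    "classify_r",
    "cohort_correlations",
    "reliability_filter",
    "paired_t",
    "comparison_report",
    "classification_grid",
    "GHT_SECTOR_NAMES",
    "QUADRANTS",
    "HEMIFIELDS",
]

HEMIFIELDS = ("superior", "inferior")
QUADRANTS = ("SN", "ST", "IN", "IT")
GHT_SECTOR_NAMES = ("paracentral", "nasal", "temporal", "arcuate_nasal", "arcuate_temporal")

# Default reliability-exclusion thresholds (strict inequalities).
FL_MAX = 0.20
FP_MAX = 0.15
FN_MAX = 0.30


@dataclass(frozen=True)
class SectorMap:
    """Region labels for every 30-2 location of one eye.

    ``ght`` maps a subset of coordinates to sector ids of the form
    ``sup-<name>`` / ``inf-<name>``; unassigned points carry no entry.
    """

    eye: str
    hemifield: dict[tuple[float, float], str]
    quadrant: dict[tuple[float, float], str]
    ght: dict[tuple[float, float], str]

    def regions(self) -> list[str]:
        ght_labels = sorted(set(self.ght.values()))
        return ["global", *HEMIFIELDS, *QUADRANTS, *ght_labels]


def _ght_sector(x: float, y: float, eye: str) -> Optional[str]:
    tx = temporal_x(x, eye)
    if abs(x) == 27 or abs(y) == 27:
        return None  # peripheral edge ring is outside the GHT clusters
    if (x, y) in blind_spot_coords(eye):
        return None
    prefix = "sup" if y > 0 else "inf"
    if abs(y) <= 9:
        if abs(x) <= 9:
            name = "paracentral"
        elif tx < 0:
            name = "nasal"
        else:
            name = "temporal"
    else:
        name = "arcuate_nasal" if tx < 0 else "arcuate_temporal"
    return f"{prefix}-{name}"


def build_default_sector_map(eye: str = "OD") -> SectorMap:
    """Hemifield/quadrant/GHT labelling of the 30-2 grid for one eye."""
    hemi, quad, ght = {}, {}, {}
    for (x, y) in grid_coords(eye):
        hemi[(x, y)] = hemifield_of(y)
        quad[(x, y)] = quadrant_of(x, y, eye)
        sector = _ght_sector(x, y, eye)
        if sector is not None:
            ght[(x, y)] = sector
    return SectorMap(eye=eye, hemifield=hemi, quadrant=quad, ght=ght)


def region_points(
    sector_map: SectorMap, region: str, exclude_blind_spot: bool = True
) -> list[tuple[float, float]]:
    """Coordinates belonging to a region label.

    Region labels: ``global``, hemifields, quadrants, or a GHT sector id.
    The two blind-spot points are excluded by default.
    """
    if region == "global":
        coords = list(sector_map.hemifield)
    elif region in HEMIFIELDS:
        coords = [c for c, h in sector_map.hemifield.items() if h == region]
    elif region in QUADRANTS:
        coords = [c for c, q in sector_map.quadrant.items() if q == region]
    elif region in set(sector_map.ght.values()):
        coords = [c for c, s in sector_map.ght.items() if s == region]
    else:
        raise ValueError(f"unknown region {region!r}")
    if exclude_blind_spot:
        bs = set(blind_spot_coords(sector_map.eye))
        coords = [c for c in coords if c not in bs]
    if not coords:
        raise ValueError(f"region {region!r} has no points")
    return sorted(coords, key=lambda c: (-c[1], c[0]))


def region_mean(
    field: dict[tuple[float, float], float],
    region: str,
    sector_map: SectorMap,
    exclude_blind_spot: bool = True,
) -> float:
    """Arithmetic mean sensitivity (dB) over a region's points."""
    coords = region_points(sector_map, region, exclude_blind_spot)
    try:
        return float(np.mean([field[c] for c in coords]))
    except KeyError as exc:
        raise ValueError(f"field is missing grid point {exc.args[0]}") from None


def classify_r(r: float) -> str:
    """Strength class of a Pearson correlation: strong / moderate / weak.

    Strong if r ≥ 0.7, moderate if 0.4 ≤ r < 0.7, weak if r < 0.4 (the
    boundaries are inclusive downward, matching the published cut-offs).
    """
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r >= 0.7:
        return "strong"
    if r >= 0.4:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class RegionCorrelation:
    r: Optional[float]
    n: int
    p: Optional[float]
    strength: str  # strong | moderate | weak | undefined
    undefined: bool = False


@dataclass
class CorrelationReport:
    regions: dict[str, RegionCorrelation]
    points: dict[tuple[float, float], RegionCorrelation]
    n_eyes: int


def _oriented(rec: CohortRecord, eye: str) -> CohortRecord:
    """Mirror a record into the sector map's laterality convention.

    Left- and right-eye fields are pooled in one analysis by reflecting the
    opposite laterality about the vertical meridian (x → -x), the standard
    right-eye-format convention; the 30-2 lattice maps onto itself.
    """
    if rec.laterality == eye:
        return rec
    flip = lambda f: {(-x, y): v for (x, y), v in f.items()}
    return CohortRecord(
        eye_id=rec.eye_id, laterality=eye,
        sens_a=flip(rec.sens_a), sens_b=flip(rec.sens_b),
        fl=rec.fl, fp=rec.fp, fn=rec.fn, md=rec.md, psd=rec.psd, vfi=rec.vfi,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> RegionCorrelation:
    n = len(a)
    if np.std(a) == 0 or np.std(b) == 0:
        return RegionCorrelation(r=None, n=n, p=None, strength="undefined", undefined=True)
    r, p = sps.pearsonr(a, b)
    return RegionCorrelation(r=float(r), n=n, p=float(p), strength=classify_r(float(r)))


def cohort_correlations(
    records: Sequence[CohortRecord],
    sector_map: SectorMap,
    exclude_blind_spot: bool = True,
) -> CorrelationReport:
    """Device-A vs device-B Pearson correlations per region and per location.

    Regional correlations pair the two devices' regional mean sensitivities
    across eyes; point-wise correlations pair raw sensitivities at each of
    the 76 locations.  Zero-variance series are flagged undefined rather
    than assigned a number.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 eyes to correlate")
    records = [_oriented(r, sector_map.eye) for r in records]
    regions = {}
    for region in sector_map.regions():
        a = np.array([
            region_mean(r.sens_a, region, sector_map, exclude_blind_spot) for r in records
        ])
        b = np.array([
            region_mean(r.sens_b, region, sector_map, exclude_blind_spot) for r in records
        ])
        regions[region] = _pearson(a, b)
    points = {}
    for coord in grid_coords(sector_map.eye):
        a = np.array([r.sens_a[coord] for r in records])
        b = np.array([r.sens_b[coord] for r in records])
        points[coord] = _pearson(a, b)
    return CorrelationReport(regions=regions, points=points, n_eyes=len(records))


def reliability_filter(
    records: Sequence[CohortRecord],
    fl_max: float = FL_MAX,
    fp_max: float = FP_MAX,
    fn_max: float = FN_MAX,
) -> tuple[list[CohortRecord], list[tuple[CohortRecord, list[str]]]]:
    """Screen out unreliable eyes.

    An eye is excluded iff FL > fl_max or FP > fp_max or FN > fn_max
    (strict inequalities: a record exactly at a threshold is kept).
    Returns (kept, excluded-with-violated-criteria).  A missing index is a
    record-level error, never a silent inclusion.
    """
    kept, excluded = [], []
    for rec in records:
        for name in ("fl", "fp", "fn"):
            v = getattr(rec, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"record {rec.eye_id}: missing reliability index {name}")
        reasons = []
        if rec.fl > fl_max:
            reasons.append("FL")
        if rec.fp > fp_max:
            reasons.append("FP")
        if rec.fn > fn_max:
            reasons.append("FN")
        if reasons:
            excluded.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, excluded


@dataclass(frozen=True)
class PairedTResult:
    t: Optional[float]
    p: Optional[float]
    df: int
    undefined: bool = False


def paired_t(xs: Sequence[float], ys: Sequence[float]) -> PairedTResult:
    """Two-sided paired-sample t-test on matched measurements.

    Flags the statistic as undefined when the differences have zero
    variance (including identical vectors) instead of returning a number.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D and the same length")
    n = len(xs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = xs - ys
    if np.std(d, ddof=1) == 0:
        return PairedTResult(t=None, p=None, df=n - 1, undefined=True)
    t, p = sps.ttest_rel(xs, ys)
    return PairedTResult(t=float(t), p=float(p), df=n - 1)


def comparison_report(
    records: Sequence[CohortRecord],
    sector_map: SectorMap,
    exclude_blind_spot: bool = True,
) -> dict:
    """Machine-readable two-device comparison of an (already filtered) cohort.

    Contains regional and point-wise correlations with strength classes, the
    count of strong/moderate/weak locations, and a paired t-test of the two
    devices' global mean sensitivities.
    """
    report = cohort_correlations(records, sector_map, exclude_blind_spot)
    oriented = [_oriented(r, sector_map.eye) for r in records]
    gm_a = [region_mean(r.sens_a, "global", sector_map, exclude_blind_spot) for r in oriented]
    gm_b = [region_mean(r.sens_b, "global", sector_map, exclude_blind_spot) for r in oriented]
    tt = paired_t(gm_a, gm_b)
    counts = {"strong": 0, "moderate": 0, "weak": 0, "undefined": 0}
    for rc in report.points.values():
        counts[rc.strength] += 1
    return {
        "n_eyes": report.n_eyes,
        "regions": {
            name: {"r": rc.r, "n": rc.n, "p": rc.p, "strength": rc.strength}
            for name, rc in report.regions.items()
        },
        "points": [
            {"x": x, "y": y, "r": rc.r, "n": rc.n, "p": rc.p, "strength": rc.strength}
            for (x, y), rc in sorted(report.points.items(), key=lambda kv: (-kv[0][1], kv[0][0]))
        ],
        "point_strength_counts": counts,
        "global_paired_t": {"t": tt.t, "p": tt.p, "df": tt.df, "undefined": tt.undefined},
    }


_STRENGTH_GRAY = {"strong": 255, "moderate": 170, "weak": 85, "undefined": 30}


def classification_grid(report: dict, px_per_cell: int = 8) -> np.ndarray:
    """Render the per-point strength classification as a grayscale grid image.

    Strong/moderate/weak map to three gray levels (255/170/85); background 0.
    """
    axis = [-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0, 27.0]
    size = len(axis) * px_per_cell
    img = np.zeros((size, size), dtype=np.uint8)
    for entry in report["points"]:
        i = axis.index(-entry["y"])  # top row (y = +27) first
        j = axis.index(entry["x"])
        level = _STRENGTH_GRAY[entry["strength"]]
        img[i * px_per_cell:(i + 1) * px_per_cell, j * px_per_cell:(j + 1) * px_per_cell] = level
    return img
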