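"""Test-grid and angular geometry for simulated perimetry.

The test pattern is the Humphrey 30-2 layout: a 6°-spaced lattice offset 3°
from both meridians, covering the central 30° of visual field with 76 points
per eye.  Field angles follow the clinical chart convention: positive x is
toward the patient's right, positive y is up, so for a right eye (OD) the
temporal field is +x and the blind spot sits near (+15°, -3°/+3°).

Stimuli are placed on a virtual bowl — a sphere of radius 330 mm centred at
the eye — by converting field angles to a 3-D direction and scaling to the
bowl radius.  Gaze-contingent presentation rotates the whole bowl frame with
the measured gaze direction so that the intended retinal eccentricity is
preserved exactly regardless of eye movement.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridPoint",
    "BowlPoint",
    "GazeSample",
    "OutOfDisplayError",
    "build_grid_30_2",
    "field_to_bowl",
    "bowl_to_field",
    "gaze_contingent_position",
    "goldmann_iii_angle",
    "stimulus_extent_on_bowl",
    "blind_spot_coords",
    "hemifield_of",
    "quadrant_of",
    "temporal_x",
    "grid_coords",
    "write_grid_csv",
    "ECCENTRICITY_LIMIT_DEG",
    "BOWL_RADIUS_MM",
]

#: Inclusion radius for the 30-2 lattice.  The closest retained lattice point
#: sits at eccentricity sqrt(9^2 + 27^2) ≈ 28.46°; the closest excluded one at
#: sqrt(21^2 + 21^2) ≈ 29.70°, so any cut-off in between yields the canonical
#: 76-point pattern.
ECCENTRICITY_LIMIT_DEG = 28.5

#: Default virtual-bowl radius in millimetres.
BOWL_RADIUS_MM = 330.0

#: Half-spacing-offset lattice values on each axis, in degrees.
LATTICE_DEG = (3, 9, 15, 21, 27)

_VALID_EYES = ("OD", "OS")


class OutOfDisplayError(ValueError):
    """Combined gaze + target direction points outside the displayable hemisphere."""


@dataclass(frozen=True)
class GridPoint:
    """One 30-2 test location.

    Parameters
    ----------
    x, y : float
        Field azimuth / elevation in degrees (x positive toward the
        patient's right, y positive up).
    eye : str
        Laterality, ``"OD"`` (right) or ``"OS"`` (left).
    """

    x: float
    y: float
    eye: str = "OD"

    def __post_init__(self) -> None:
        if self.eye not in _VALID_EYES:
            raise ValueError(f"eye must be one of {_VALID_EYES}, got {self.eye!r}")

    @property
    def eccentricity(self) -> float:
        """Chart eccentricity: Euclidean distance from fixation in chart degrees."""
        return math.hypot(self.x, self.y)

    @property
    def angular_eccentricity(self) -> float:
        """True angular distance (degrees) of the target direction from the
        straight-ahead axis under the tangent-plane composition.

        Slightly smaller than the chart eccentricity off the meridians
        (e.g. 21.18° vs 21.21° at (3, 21)); this is the quantity preserved
        exactly by gaze-contingent repositioning.
        """
        tx = math.tan(math.radians(self.x))
        ty = math.tan(math.radians(self.y))
        return math.degrees(math.atan(math.hypot(tx, ty)))


@dataclass(frozen=True)
class BowlPoint:
    """A stimulus position on the virtual bowl, millimetres, eye-centred.

    The coordinate frame is right-handed with z toward the bowl apex
    (straight ahead), x to the patient's right and y up.
    """

    px: float
    py: float
    pz: float
    radius: float = BOWL_RADIUS_MM

    @property
    def norm(self) -> float:
        return math.sqrt(self.px**2 + self.py**2 + self.pz**2)

    def as_array(self) -> np.ndarray:
        return np.array([self.px, self.py, self.pz])


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample: time in seconds, gaze direction in degrees."""

    t: float
    gx: float
    gy: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("gaze sample time must be non-negative")


def build_grid_30_2(eye: str = "OD") -> tuple[GridPoint, ...]:
    """Construct the 76-point 30-2 test grid for one eye.

    Points lie on the lattice ``|x|, |y| ∈ {3, 9, 15, 21, 27}`` and are kept
    when their eccentricity does not exceed :data:`ECCENTRICITY_LIMIT_DEG`.
    The order is deterministic: row-major, top row (y = +27) first, x
    ascending within a row.

    Returns
    -------
    tuple of GridPoint
        Exactly 76 points: 38 per hemifield, 19 per quadrant.
    """
    if eye not in _VALID_EYES:
        raise ValueError(f"eye must be one of {_VALID_EYES}, got {eye!r}")
    axis = sorted({v for a in LATTICE_DEG for v in (a, -a)})
    points = []
    for y in sorted(axis, reverse=True):
        for x in axis:
            if math.hypot(x, y) <= ECCENTRICITY_LIMIT_DEG:
                points.append(GridPoint(float(x), float(y), eye))
    return tuple(points)


def grid_coords(eye: str = "OD") -> tuple[tuple[float, float], ...]:
    """Coordinate pairs of the 30-2 grid in canonical order."""
    return tuple((p.x, p.y) for p in build_grid_30_2(eye))


def _direction(x_deg: float, y_deg: float) -> np.ndarray:
    """Unit direction vector for tangent-plane field angles (x, y)."""
    if abs(x_deg) >= 90 or abs(y_deg) >= 90:
        raise ValueError("field angles must lie strictly within ±90°")
    d = np.array([math.tan(math.radians(x_deg)), math.tan(math.radians(y_deg)), 1.0])
    return d / np.linalg.norm(d)


def field_to_bowl(x_deg: float, y_deg: float, radius: float = BOWL_RADIUS_MM) -> BowlPoint:
    """Project field angles onto the virtual bowl.

    The direction is ``normalize(tan x, tan y, 1)`` scaled to the bowl
    radius, so a stimulus subtends a constant visual angle at every
    eccentricity.

    Raises
    ------
    ValueError
        If either angle is at or beyond ±90°, or radius is not positive.
    """
    if radius <= 0:
        raise ValueError("bowl radius must be positive")
    d = _direction(x_deg, y_deg) * radius
    return BowlPoint(float(d[0]), float(d[1]), float(d[2]), radius)


def bowl_to_field(point: BowlPoint) -> tuple[float, float]:
    """Recover field angles (degrees) from a bowl point; inverse of field_to_bowl."""
    if point.pz <= 0:
        raise ValueError("bowl point must lie in the forward hemisphere")
    x = math.degrees(math.atan(point.px / point.pz))
    y = math.degrees(math.atan(point.py / point.pz))
    return x, y


def _rotation_from_z_to(g: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying the +z axis onto unit vector ``g``.

    Uses the minimal (geodesic) rotation about the axis z × g.  Identity when
    g is already +z.
    """
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, g)
    s = np.linalg.norm(axis)
    c = float(np.dot(z, g))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        raise OutOfDisplayError("gaze direction is opposite the display axis")
    axis = axis / s
    angle = math.atan2(s, c)
    # Rodrigues' formula
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def gaze_contingent_position(
    target: GridPoint, gaze: GazeSample, radius: float = BOWL_RADIUS_MM
) -> BowlPoint:
    """Reposition a target with the current gaze so eccentricity is preserved.

    The target direction is rotated by the rotation that carries the
    straight-ahead axis onto the gaze direction, then projected to the bowl.
    The angle between the gaze direction and the returned stimulus direction
    equals the target's eccentricity exactly (to numerical precision).

    Raises
    ------
    OutOfDisplayError
        If the combined direction leaves the forward (displayable)
        hemisphere; callers should log the skip and retry with a fresh gaze
        sample.
    """
    g = _direction(gaze.gx, gaze.gy)
    rot = _rotation_from_z_to(g)
    v = rot @ _direction(target.x, target.y)
    if v[2] <= 0:
        raise OutOfDisplayError(
            f"target ({target.x}, {target.y}) with gaze ({gaze.gx}, {gaze.gy}) "
            "falls outside the displayable hemisphere"
        )
    v = v * radius
    return BowlPoint(float(v[0]), float(v[1]), float(v[2]), radius)


def goldmann_iii_angle(area_mm2: float = 4.0, bowl_mm: float = 300.0) -> float:
    """Angular diameter in degrees of a circular target of given area.

    Defaults reproduce the Goldmann size III stimulus: a 4 mm² disc viewed
    at the historical 300 mm Goldmann bowl distance subtends
    ``2·atan(sqrt(4/π)/300) ≈ 0.43°``.  The angular size is taken as
    normative even on bowls of other radii; the physical extent follows from
    :func:`stimulus_extent_on_bowl`.
    """
    if area_mm2 <= 0 or bowl_mm <= 0:
        raise ValueError("area and bowl distance must be positive")
    return math.degrees(2.0 * math.atan(math.sqrt(area_mm2 / math.pi) / bowl_mm))


def stimulus_extent_on_bowl(angular_diameter_deg: float, radius: float = BOWL_RADIUS_MM) -> float:
    """Physical chord-plane extent (mm) of a stimulus of given angular size.

    ``2·radius·tan(diameter/2)``; monotone increasing in both arguments.
    """
    if angular_diameter_deg < 0 or angular_diameter_deg >= 90:
        raise ValueError("angular diameter must be in [0, 90)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * radius * math.tan(math.radians(angular_diameter_deg) / 2.0)


def temporal_x(x: float, eye: str) -> float:
    """Signed temporal coordinate: positive toward the temporal field."""
    return x if eye == "OD" else -x


def blind_spot_coords(eye: str = "OD") -> tuple[tuple[float, float], tuple[float, float]]:
    """The two grid points flanking the physiologic blind spot (temporal 15°, ±3°)."""
    t = 15.0 if eye == "OD" else -15.0
    return ((t, 3.0), (t, -3.0))


def hemifield_of(y: float) -> str:
    """Superior/inferior hemifield label for a grid y coordinate."""
    if y == 0:
        raise ValueError("30-2 points never lie on the horizontal meridian")
    return "superior" if y > 0 else "inferior"


def quadrant_of(x: float, y: float, eye: str) -> str:
    """Quadrant label (SN, ST, IN, IT) under the nasal/temporal convention."""
    if x == 0 or y == 0:
        raise ValueError("30-2 points never lie on a meridian")
    vertical = "S" if y > 0 else "I"
    horizontal = "T" if temporal_x(x, eye) > 0 else "N"
    return vertical + horizontal


def write_grid_csv(path, points: Sequence[GridPoint] | Iterable[GridPoint]) -> None:
    """Export a grid as CSV with columns x_deg, y_deg, eye (row-major order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_deg", "y_deg", "eye"])
        for p in points:
            writer.writerow([p.x, p.y, p.eye])
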