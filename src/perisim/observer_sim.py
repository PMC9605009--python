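"""Simulated patients for desk-scale perimetry experiments.

A :class:`TrueField` is the ground-truth sensitivity surface: a hill of
vision (apex at fixation, declining with eccentricity) with optional
injected scotomas — blind spot, nasal step, arcuate defect, quadrantanopia,
or the spectacle-rim artifact seen when a headset pushes eyeglass frames
into the peripheral field.

An :class:`ObserverModel` answers seen/not-seen queries through a
frequency-of-seeing (psychometric) function with false-positive and
false-negative rates folded in as floor and ceiling:

    p_seen = fp + (1 - fp - fn) · Φ((t_eff - presented) / fos_slope)

where ``t_eff`` is the true sensitivity at the effective retinal location.
With gaze tracking on, the stimulus follows the eye and the effective
location is the intended one; with tracking off, the stimulus lands at the
intended location displaced by the current gaze error and the truth is
evaluated there by bilinear interpolation on the 6° lattice.

Gaze wander is a first-order autoregressive process with a configurable
stationary standard deviation, emulating fixation instability at the eye
tracker's 120 Hz sampling rate.

The module also generates synthetic paired cohorts — two measured fields per
eye, as if the same eye had been tested on two devices — with an analytically
known expected correlation between the devices' global mean sensitivities,
for exercising the comparison statistics end-to-end.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import norm

from .field_geometry import (
    GazeSample,
    blind_spot_coords,
    build_grid_30_2,
    hemifield_of,
    quadrant_of,
    temporal_x,
)

__all__ = [
    "TrueField",
    "ObserverModel",
    "CohortRecord",
    "GazeWanderer",
    "LESION_KINDS",
    "make_normal_field",
    "inject_lesion",
    "respond",
    "gaze_trace",
    "make_paired_cohort",
    "nominal_global_r",
    "indep_sd_for_target_r",
]

LESION_KINDS = ("blind_spot", "nasal_step", "arcuate", "quadrantanopia", "rim_artifact")

#: Lattice axis shared by x and y: uniform 6° spacing including the central gap.
_LATTICE_AXIS = np.array([-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0, 27.0])

#: Default AR(1) correlation time of gaze wander, seconds.
_GAZE_TAU_S = 0.2

FIXATION = (0.0, 0.0)


@dataclass
class TrueField:
    """Ground-truth sensitivity map of one eye, in dB, on the 30-2 grid.

    ``values`` maps (x, y) in degrees to true sensitivity; the fixation
    point (0, 0) is included in addition to the 76 grid points because the
    exam thresholds it first.  Truth is kept in [0, 50] dB — it may lie
    outside the device's testable range.
    """

    eye: str
    values: dict[tuple[float, float], float]
    lesions: tuple[dict, ...] = ()

    def grid_values(self) -> dict[tuple[float, float], float]:
        """Values on the 76 test locations only (fixation excluded)."""
        return {k: v for k, v in self.values.items() if k != FIXATION}

    def __getitem__(self, coord: tuple[float, float]) -> float:
        return self.values[coord]


def make_normal_field(
    s0: float = 33.0,
    slope: float = 0.3,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
    eye: str = "OD",
) -> TrueField:
    """Generate a normal hill-of-vision field.

    Sensitivity at eccentricity e is ``s0 - slope·e`` plus Gaussian
    point-to-point variation with SD ``noise_sd``, clipped to [0, 50] dB.
    Defaults (33 dB apex, 0.3 dB/° decline, 1 dB noise) are conventional
    normative values for a middle-aged adult.
    """
    if not 20 <= s0 <= 45:
        raise ValueError("apex sensitivity s0 must be in [20, 45] dB")
    if slope < 0:
        raise ValueError("hill slope must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[tuple[float, float], float] = {}
    for coord in (FIXATION, *((p.x, p.y) for p in build_grid_30_2(eye))):
        ecc = math.hypot(*coord)
        v = s0 - slope * ecc
        if noise_sd > 0:
            v += rng.normal(0.0, noise_sd)
        values[coord] = float(np.clip(v, 0.0, 50.0))
    return TrueField(eye=eye, values=values)


def _lesion_coords(field: TrueField, kind: str, params: dict) -> list[tuple[float, float]]:
    eye = field.eye
    hemi = params.get("hemifield", "superior")
    coords = []
    for (x, y) in field.grid_values():
        tx = temporal_x(x, eye)
        ecc = math.hypot(x, y)
        if kind == "blind_spot":
            hit = (x, y) in blind_spot_coords(eye)
        elif kind == "nasal_step":
            hit = tx < 0 and abs(y) <= 9 and hemifield_of(y) == hemi
        elif kind == "arcuate":
            # Arcuate sweep within the 9°-21° annulus of one hemifield, from
            # the nasal side around to the blind-spot column (temporal x
            # beyond 15° is spared).
            hit = 9 <= ecc <= 21 and hemifield_of(y) == hemi and tx <= 15
        elif kind == "quadrantanopia":
            hit = quadrant_of(x, y, eye) == params.get("quadrant", "ST")
        elif kind == "rim_artifact":
            side = params.get("side", "inferior")
            if side in ("superior", "inferior"):
                on_side = hemifield_of(y) == side
            elif side in ("temporal", "nasal"):
                on_side = (tx > 0) == (side == "temporal")
            else:
                raise ValueError(f"unknown rim side {side!r}")
            hit = ecc >= 21 and on_side
        else:
            raise ValueError(f"unknown lesion kind {kind!r}; choose from {LESION_KINDS}")
        if hit:
            coords.append((x, y))
    return coords


def inject_lesion(field: TrueField, kind: str, depth: float, **params) -> TrueField:
    """Return a copy of ``field`` with a scotoma of the given kind and depth.

    ``depth`` (dB) is subtracted over the lesion's point set, floored at
    0 dB.  Supported kinds: blind_spot, nasal_step, arcuate, quadrantanopia,
    rim_artifact; ``params`` select the hemifield/quadrant/side as relevant.
    """
    if depth < 0:
        raise ValueError("lesion depth must be non-negative")
    coords = _lesion_coords(field, kind, params)
    values = dict(field.values)
    for c in coords:
        values[c] = max(0.0, values[c] - depth)
    record = {"kind": kind, "depth": depth, **params}
    return TrueField(eye=field.eye, values=values, lesions=field.lesions + (record,))


def _build_interpolator(field: TrueField) -> RegularGridInterpolator:
    """Bilinear interpolator of the truth over the 10×10 6°-spaced lattice.

    The 24 lattice corners outside the 30-2 pattern are filled with the value
    of the nearest tested point so queries near the rim stay finite.
    """
    vals = field.grid_values()
    grid = np.empty((len(_LATTICE_AXIS), len(_LATTICE_AXIS)))
    tested = list(vals.keys())
    for i, x in enumerate(_LATTICE_AXIS):
        for j, y in enumerate(_LATTICE_AXIS):
            if (x, y) in vals:
                grid[i, j] = vals[(x, y)]
            else:
                nearest = min(tested, key=lambda c: (math.hypot(c[0] - x, c[1] - y), c))
                grid[i, j] = vals[nearest]
    return RegularGridInterpolator(
        (_LATTICE_AXIS, _LATTICE_AXIS), grid, method="linear", bounds_error=False, fill_value=None
    )


class GazeWanderer:
    """AR(1) gaze-wander process with stationary per-axis SD ``gaze_sd``.

    ``step(dt)`` advances the process by ``dt`` seconds using the
    discretised Ornstein–Uhlenbeck update ``g ← ρ·g + N(0, sd²(1-ρ²))`` with
    ``ρ = exp(-dt/τ)``, so the stationary SD is independent of the stepping
    rate.
    """

    def __init__(self, gaze_sd: float, rng: np.random.Generator, tau: float = _GAZE_TAU_S):
        if gaze_sd < 0:
            raise ValueError("gaze_sd must be non-negative")
        self.gaze_sd = gaze_sd
        self.tau = tau
        self._rng = rng
        self._state = (
            rng.normal(0.0, gaze_sd, size=2) if gaze_sd > 0 else np.zeros(2)
        )

    def step(self, dt: float) -> tuple[float, float]:
        if self.gaze_sd == 0:
            return (0.0, 0.0)
        rho = math.exp(-dt / self.tau)
        innov_sd = self.gaze_sd * math.sqrt(max(0.0, 1.0 - rho * rho))
        self._state = rho * self._state + self._rng.normal(0.0, innov_sd, size=2)
        return (float(self._state[0]), float(self._state[1]))


def gaze_trace(
    duration: float,
    gaze_sd: float,
    rate: float = 120.0,
    seed: Optional[int] = None,
    tau: float = _GAZE_TAU_S,
) -> list[GazeSample]:
    """Simulate an eye-tracker trace of fixational gaze wander.

    Returns ``ceil(duration·rate)`` samples at the given sampling rate with
    per-axis stationary SD ``gaze_sd`` degrees.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = math.ceil(duration * rate)
    wanderer = GazeWanderer(gaze_sd, np.random.default_rng(seed), tau=tau)
    dt = 1.0 / rate
    samples = []
    for k in range(n):
        if k == 0:
            gx, gy = (
                (float(wanderer._state[0]), float(wanderer._state[1]))
                if gaze_sd > 0
                else (0.0, 0.0)
            )
        else:
            gx, gy = wanderer.step(dt)
        samples.append(GazeSample(t=k * dt, gx=gx, gy=gy))
    return samples


@dataclass
class ObserverModel:
    """A simulated patient: truth field plus response and gaze parameters.

    Attributes
    ----------
    true_field : TrueField
        Ground-truth sensitivities.
    fos_slope : float
        Spread (dB) of the frequency-of-seeing curve; 0 gives a step
        observer.
    fp_rate, fn_rate : float
        False-positive floor and false-negative ceiling of the response
        probability, each in [0, 0.5).
    gaze_sd : float
        Stationary SD of fixational gaze wander, degrees (the eye tracker's
        stated accuracy is 0.5°-1.1°).
    rng_seed : int
        Seeds independent response and gaze streams; two observers built
        with the same seed behave identically.
    """

    true_field: TrueField
    fos_slope: float = 1.0
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    gaze_sd: float = 1.0
    rng_seed: int = 0
    _resp_rng: np.random.Generator = dataclass_field(init=False, repr=False)
    _gaze_rng: np.random.Generator = dataclass_field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.fp_rate < 0.5 and 0 <= self.fn_rate < 0.5):
            raise ValueError("fp and fn rates must lie in [0, 0.5)")
        if self.fos_slope < 0:
            raise ValueError("fos_slope must be non-negative")
        if self.gaze_sd < 0:
            raise ValueError("gaze_sd must be non-negative")
        resp_ss, gaze_ss = np.random.SeedSequence(self.rng_seed).spawn(2)
        self._resp_rng = np.random.default_rng(resp_ss)
        self._gaze_rng = np.random.default_rng(gaze_ss)
        self._interp = None

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = _build_interpolator(self.true_field)
        return self._interp

    def effective_sensitivity(
        self, location: tuple[float, float], gaze_offset: Optional[tuple[float, float]]
    ) -> float:
        """Truth at the retinal location actually stimulated.

        With tracking on (``gaze_offset is None``) this is the stored truth
        at the intended location.  With tracking off, a stimulus at field
        position ``location`` lands at retinal position ``location - gaze``;
        the displacement effect is evaluated as an interpolated *difference*
        so that a zero gaze error reproduces the stored truth exactly.
        """
        base = self.true_field[location]
        if gaze_offset is None or gaze_offset == (0.0, 0.0):
            return base
        interp = self.interpolator()
        lo, hi = _LATTICE_AXIS[0], _LATTICE_AXIS[-1]
        shifted = np.clip(
            [location[0] - gaze_offset[0], location[1] - gaze_offset[1]], lo, hi
        )
        here = np.clip(location, lo, hi)
        delta = float(interp(shifted)[0]) - float(interp(here)[0])
        return float(np.clip(base + delta, 0.0, 50.0))

    def descriptor(self) -> dict:
        """JSON-serializable description of the observer (for reproducibility)."""
        return {
            "eye": self.true_field.eye,
            "fos_slope": self.fos_slope,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "gaze_sd": self.gaze_sd,
            "rng_seed": self.rng_seed,
            "lesions": list(self.true_field.lesions),
            "true_field": {f"{x:g},{y:g}": v for (x, y), v in sorted(self.true_field.values.items())},
        }

    def descriptor_hash(self) -> str:
        blob = json.dumps(self.descriptor(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def respond(
    observer: ObserverModel,
    location: tuple[float, float],
    presented_db: float,
    gaze_offset: Optional[tuple[float, float]] = None,
) -> bool:
    """Draw one seen/not-seen response from the observer's stream.

    ``gaze_offset`` is the current gaze error in degrees when tracking is
    off; pass ``None`` when the display is gaze-contingent.
    """
    t_eff = observer.effective_sensitivity(location, gaze_offset)
    if observer.fos_slope == 0:
        phi = 1.0 if t_eff > presented_db else (0.5 if t_eff == presented_db else 0.0)
    else:
        phi = norm.cdf((t_eff - presented_db) / observer.fos_slope)
    p_seen = observer.fp_rate + (1.0 - observer.fp_rate - observer.fn_rate) * phi
    return bool(observer._resp_rng.random() < p_seen)


# ---------------------------------------------------------------------------
# Synthetic paired cohorts for the comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    """One eye measured on two devices, with reliability indices and metadata.

    ``sens_a`` / ``sens_b`` map 30-2 coordinates to measured sensitivity on
    device A and device B.  ``fl``, ``fp``, ``fn`` are fixation-loss /
    false-positive / false-negative proportions in [0, 1].  ``md``, ``psd``,
    ``vfi`` are passthrough summary indices (not computed here).
    """

    eye_id: str
    laterality: str
    sens_a: dict[tuple[float, float], float]
    sens_b: dict[tuple[float, float], float]
    fl: float
    fp: float
    fn: float
    md: float
    psd: float
    vfi: float


def _indep_mean_variance(indep_sd: float, n_points: int) -> float:
    # The per-device error is a per-eye session offset (SD = indep_sd/2)
    # plus per-point noise (SD = indep_sd); contribution to the variance of
    # the eye's mean sensitivity:
    return indep_sd**2 * (0.25 + 1.0 / n_points)


def nominal_global_r(
    shared_sd: float = 1.0,
    indep_sd_a: float = 1.95,
    indep_sd_b: float = 1.95,
    apex_sd: float = 2.0,
    truth_noise_sd: float = 1.0,
    n_points: int = 74,
) -> float:
    """Expected Pearson correlation of paired global mean sensitivities.

    Between-eye variance of the shared signal (hill apex plus per-point
    truth and shared distortion averaged over ``n_points`` locations)
    divided by the geometric mean of the two devices' total variances.
    """
    c = apex_sd**2 + (truth_noise_sd**2 + shared_sd**2) / n_points
    va = _indep_mean_variance(indep_sd_a, n_points)
    vb = _indep_mean_variance(indep_sd_b, n_points)
    return c / math.sqrt((c + va) * (c + vb))


def indep_sd_for_target_r(
    target_r: float,
    shared_sd: float = 1.0,
    apex_sd: float = 2.0,
    truth_noise_sd: float = 1.0,
    n_points: int = 74,
) -> float:
    """Symmetric per-device noise SD that yields a given nominal global r."""
    if not 0 < target_r <= 1:
        raise ValueError("target correlation must be in (0, 1]")
    c = apex_sd**2 + (truth_noise_sd**2 + shared_sd**2) / n_points
    v = c * (1.0 - target_r) / target_r
    return math.sqrt(v / (0.25 + 1.0 / n_points))


def make_paired_cohort(
    n_eyes: int,
    shared_sd: float = 1.0,
    indep_sd_a: float = 1.95,
    indep_sd_b: float = 1.95,
    seed: int = 0,
    apex_mean: float = 33.0,
    apex_sd: float = 2.0,
    hill_slope: float = 0.3,
    truth_noise_sd: float = 1.0,
    fl_range: tuple[float, float] = (0.0, 0.22),
    fp_range: tuple[float, float] = (0.0, 0.16),
    fn_range: tuple[float, float] = (0.0, 0.32),
) -> list[CohortRecord]:
    """Generate a synthetic paired cohort for two-device comparison.

    Per eye: a hill-of-vision truth with apex drawn from N(apex_mean,
    apex_sd²); both devices measure truth plus a *shared* per-point
    distortion (SD ``shared_sd``); each device then adds an independent
    per-eye session offset (SD = indep_sd/2) and independent per-point noise
    (SD = indep_sd).  With both independent SDs zero the two devices agree
    exactly and the global-mean correlation is 1.  The expected correlation
    is :func:`nominal_global_r`; the defaults give ≈ 0.80.

    Reliability indices are uniform over the given ranges (defaults yield
    roughly a fifth of eyes failing the FL > 20% / FP > 15% / FN > 30%
    screen); MD/PSD/VFI are drawn as plausible passthrough metadata.
    """
    if n_eyes < 3:
        raise ValueError("need at least 3 eyes")
    for sd in (shared_sd, indep_sd_a, indep_sd_b):
        if sd < 0:
            raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_eyes):
        laterality = "OD" if i % 2 == 0 else "OS"
        eye_coords = [(p.x, p.y) for p in build_grid_30_2(laterality)]
        apex = float(np.clip(rng.normal(apex_mean, apex_sd), 20.0, 45.0))
        ecc = np.array([math.hypot(x, y) for x, y in eye_coords])
        truth = apex - hill_slope * ecc + rng.normal(0.0, truth_noise_sd, len(eye_coords))
        shared = rng.normal(0.0, shared_sd, len(eye_coords))
        offset_a = rng.normal(0.0, indep_sd_a / 2.0) if indep_sd_a > 0 else 0.0
        offset_b = rng.normal(0.0, indep_sd_b / 2.0) if indep_sd_b > 0 else 0.0
        noise_a = rng.normal(0.0, indep_sd_a, len(eye_coords)) if indep_sd_a > 0 else 0.0
        noise_b = rng.normal(0.0, indep_sd_b, len(eye_coords)) if indep_sd_b > 0 else 0.0
        a = truth + shared + offset_a + noise_a
        b = truth + shared + offset_b + noise_b
        records.append(
            CohortRecord(
                eye_id=f"eye{i:03d}",
                laterality=laterality,
                sens_a={c: float(v) for c, v in zip(eye_coords, a)},
                sens_b={c: float(v) for c, v in zip(eye_coords, b)},
                fl=float(rng.uniform(*fl_range)),
                fp=float(rng.uniform(*fp_range)),
                fn=float(rng.uniform(*fn_range)),
                md=float(rng.normal(-3.43, 4.2)),
                psd=float(abs(rng.normal(5.65, 4.5))),
                vfi=float(np.clip(rng.normal(90.4, 13.0), 0.0, 100.0)),
            )
        )
    return records
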