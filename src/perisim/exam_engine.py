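"""Orchestration of a complete simulated visual-field exam.

The exam thresholds the fixation point first (unseeded, so the first
stimulus is the 27 dB midpoint of the 14-40 dB range), then visits the 76
grid points in a seeded random order, each with its own bisection staircase
seeded by the central threshold.  Every presentation draws a gaze sample,
computes the stimulus position on the virtual bowl — gaze-contingent when
tracking is on, uncorrected when off — queries the observer and updates the
staircase.  Locations are completed one staircase at a time.

Simulated time accrues a fixed budget per presentation: stimulus duration
plus response window plus inter-stimulus interval (response-time truncation
on early responses is not modelled).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dataclass_field
from typing import NamedTuple, Optional

import numpy as np

from . import staircase as sc
from .field_geometry import (
    BOWL_RADIUS_MM,
    GazeSample,
    GridPoint,
    OutOfDisplayError,
    build_grid_30_2,
    field_to_bowl,
    gaze_contingent_position,
)
from .observer_sim import FIXATION, GazeWanderer, ObserverModel, respond
from .photometry import DEFAULT_SPEC, LuminanceSpec, clamp_to_device

__all__ = [
    "ExamConfig",
    "ExamResult",
    "PointResult",
    "PresentationRecord",
    "GridMismatchError",
    "run_exam",
    "simulated_duration",
]


class GridMismatchError(ValueError):
    """Observer's truth field does not cover the configured test grid."""


@dataclass(frozen=True)
class ExamConfig:
    """Exam parameters.

    ``seeding="central"`` starts every staircase at the central threshold
    (the literal strategy); ``"neighbour"`` is an extension that seeds each
    point with the mean threshold of already-completed 6° lattice
    neighbours, falling back to the central threshold.
    """

    eye: str = "OD"
    luminance: LuminanceSpec = DEFAULT_SPEC
    stimulus_ms: float = 200.0
    response_window_ms: float = 1000.0
    inter_stimulus_ms: float = 500.0
    tracking: bool = True
    seeding: str = "central"
    order_seed: int = 0
    bowl_radius_mm: float = BOWL_RADIUS_MM

    def __post_init__(self) -> None:
        if min(self.stimulus_ms, self.response_window_ms, self.inter_stimulus_ms) <= 0:
            raise ValueError("all durations must be positive")
        if self.stimulus_ms > self.response_window_ms:
            raise ValueError("stimulus duration cannot exceed the response window")
        if self.seeding not in ("central", "neighbour"):
            raise ValueError("seeding must be 'central' or 'neighbour'")

    @property
    def per_presentation_s(self) -> float:
        return (self.stimulus_ms + self.response_window_ms + self.inter_stimulus_ms) / 1000.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["luminance"] = asdict(self.luminance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExamConfig":
        d = dict(d)
        lum = d.pop("luminance", None)
        if isinstance(lum, dict):
            d["luminance"] = LuminanceSpec(**lum)
        return cls(**d)


class PresentationRecord(NamedTuple):
    """One presentation: location index (-1 = fixation), field coords, intensity, response."""

    location_index: int
    x: float
    y: float
    presented_db: float
    seen: bool
    elapsed_ms: float


class PointResult(NamedTuple):
    x: float
    y: float
    threshold_db: float
    floored: bool
    ceilinged: bool


@dataclass
class ExamResult:
    """Full output of one simulated exam."""

    eye: str
    fixation: PointResult
    points: list[PointResult]
    log: list[PresentationRecord]
    total_presentations: int
    simulated_duration_s: float
    config: dict
    observer_hash: str
    test_order: list[int] = dataclass_field(default_factory=list)

    def thresholds(self) -> dict[tuple[float, float], float]:
        """Per-point final thresholds keyed by (x, y)."""
        return {(p.x, p.y): p.threshold_db for p in self.points}


def _neighbour_seed(
    coord: tuple[float, float], done: dict[tuple[float, float], float]
) -> Optional[float]:
    x, y = coord
    vals = [done[c] for c in ((x - 6, y), (x + 6, y), (x, y - 6), (x, y + 6)) if c in done]
    return sum(vals) / len(vals) if vals else None


def run_exam(observer: ObserverModel, config: ExamConfig) -> ExamResult:
    """Run a full simulated exam of one eye.

    Deterministic given the observer's ``rng_seed`` and the config's
    ``order_seed``: identical pairs reproduce byte-identical results.
    """
    grid = build_grid_30_2(config.eye)
    truth_coords = set(observer.true_field.grid_values())
    wanted = {(p.x, p.y) for p in grid}
    if observer.true_field.eye != config.eye or truth_coords != wanted:
        raise GridMismatchError(
            "observer truth field does not match the configured grid "
            f"(eye {observer.true_field.eye!r} vs {config.eye!r})"
        )

    wanderer = GazeWanderer(observer.gaze_sd, observer._gaze_rng)
    dt = config.per_presentation_s
    log: list[PresentationRecord] = []
    elapsed_ms = 0.0

    def run_staircase(coord: tuple[float, float], index: int, seed_db: Optional[float]):
        nonlocal elapsed_ms
        try:
            state = sc.init_state(seed=seed_db)
        except ValueError:
            state = sc.init_state()
        target = GridPoint(coord[0], coord[1], config.eye) if coord != FIXATION else None
        while not state.terminated:
            intensity, _ = clamp_to_device(sc.next_intensity(state), config.luminance)
            gx, gy = wanderer.step(dt)
            gaze = GazeSample(t=elapsed_ms / 1000.0, gx=gx, gy=gy)
            if target is not None:
                if config.tracking:
                    for _attempt in range(10):
                        try:
                            gaze_contingent_position(target, gaze, config.bowl_radius_mm)
                            break
                        except OutOfDisplayError:
                            gx, gy = wanderer.step(dt)
                            gaze = GazeSample(t=elapsed_ms / 1000.0, gx=gx, gy=gy)
                else:
                    field_to_bowl(coord[0], coord[1], config.bowl_radius_mm)
            seen = respond(
                observer,
                coord,
                intensity,
                gaze_offset=None if config.tracking else (gx, gy),
            )
            state = sc.update(state, intensity, seen)
            elapsed_ms += dt * 1000.0
            log.append(
                PresentationRecord(index, coord[0], coord[1], intensity, seen, elapsed_ms)
            )
        return PointResult(
            coord[0], coord[1], sc.final_threshold(state), state.floored, state.ceilinged
        )

    fixation = run_staircase(FIXATION, -1, None)
    central = fixation.threshold_db

    order = [int(i) for i in np.random.default_rng(config.order_seed).permutation(len(grid))]
    done: dict[tuple[float, float], float] = {}
    results: dict[int, PointResult] = {}
    for idx in order:
        coord = (grid[idx].x, grid[idx].y)
        if config.seeding == "neighbour":
            seed_db = _neighbour_seed(coord, done)
            if seed_db is None:
                seed_db = central
        else:
            seed_db = central
        res = run_staircase(coord, idx, seed_db)
        results[idx] = res
        done[coord] = res.threshold_db

    points = [results[i] for i in range(len(grid))]
    return ExamResult(
        eye=config.eye,
        fixation=fixation,
        points=points,
        log=log,
        total_presentations=len(log),
        simulated_duration_s=len(log) * dt,
        config=config.to_dict(),
        observer_hash=observer.descriptor_hash(),
        test_order=order,
    )


def simulated_duration(result: ExamResult) -> float:
    """Simulated exam duration in seconds, recomputed from the config echo."""
    cfg = ExamConfig.from_dict(result.config)
    return result.total_presentations * cfg.per_presentation_s
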