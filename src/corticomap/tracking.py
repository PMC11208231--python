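"""Spiral tracking test: target generation and the three motor outcomes.

Seated participants steer a cursor with trunk inclination to follow a point
moving anticlockwise along an Archimedean spiral spanning 13.5 x 13.5
degrees (each axis -6.25 to +6.25 deg).  The per-sample tracking error is
the Euclidean distance between target and cursor,

    e_i = sqrt((target_x_i - actual_x_i)^2 + (target_y_i - actual_y_i)^2),

and a ~2-minute trial is scored by three outcomes:

* ``angular_near`` — the mean of the closest q % errors (default q = 90),
* ``time_near``    — the percentage of time with error < r (default 0.9 deg),
* ``path``         — the sum of all per-sample errors (sampling-rate
  dependent by construction; record the rate alongside).

The first of the two recorded trials is a practice trial and is excluded
from analysis by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrackingTrial",
    "TrackingOutcomes",
    "SPIRAL_RMAX_DEG",
    "spiral_target",
    "tracking_error",
    "angular_near",
    "time_near",
    "path",
    "travelled_distance",
    "score_trial",
]

SPIRAL_RMAX_DEG = 6.25
DEFAULT_TURNS = 4
DEFAULT_Q_PCT = 90.0
DEFAULT_R_DEG = 0.9


@dataclass(frozen=True)
class TrackingTrial:
    """Synchronized target/actual trunk-angle series, degrees."""

    t: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    actual_x: np.ndarray
    actual_y: np.ndarray
    sampling_rate: float
    practice: bool = False

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("target_x", "target_y", "actual_x", "actual_y"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length differs from t")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "target_x": self.target_x,
                "target_y": self.target_y,
                "actual_x": self.actual_x,
                "actual_y": self.actual_y,
            }
        )


@dataclass(frozen=True)
class TrackingOutcomes:
    angular_near: float  # degrees
    time_near: float  # percent of samples
    path: float  # degrees (sum of errors)
    sampling_rate: float


def spiral_target(
    t: float | np.ndarray,
    duration: float,
    n_turns: int = DEFAULT_TURNS,
    r_max: float = SPIRAL_RMAX_DEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Archimedean spiral position at time ``t`` of a ``duration``-second trial.

    theta grows anticlockwise at constant rate from 0 to 2*pi*n_turns and the
    radius grows linearly, r(theta) = r_max * theta / theta_max, so the path
    starts at the center and ends on the 6.25-degree rim.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > duration):
        raise ValueError("t outside [0, duration]")
    theta_max = 2.0 * math.pi * n_turns
    theta = theta_max * t_arr / duration
    r = r_max * theta / theta_max
    return r * np.cos(theta), r * np.sin(theta)


def tracking_error(trial: TrackingTrial) -> np.ndarray:
    """Per-sample Euclidean distance between target and cursor, degrees."""
    dx = trial.target_x - trial.actual_x
    dy = trial.target_y - trial.actual_y
    return np.hypot(dx, dy)


def _check_errors(errors: np.ndarray) -> np.ndarray:
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error series")
    return e


def angular_near(errors: np.ndarray, q: float = DEFAULT_Q_PCT) -> float:
    """Mean of the closest q % tracking errors (smallest ceil(q/100*n) values)."""
    e = _check_errors(errors)
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    k = math.ceil(q / 100.0 * e.size)
    return float(np.mean(np.sort(e, kind="stable")[:k]))


def time_near(errors: np.ndarray, r: float = DEFAULT_R_DEG) -> float:
    """Percentage of samples with error strictly below r degrees."""
    e = _check_errors(errors)
    if r <= 0:
        raise ValueError("r must be positive")
    return float(100.0 * np.count_nonzero(e < r) / e.size)


def path(errors: np.ndarray) -> float:
    """Sum of all per-sample target-to-cursor differences, degrees."""
    return float(np.sum(_check_errors(errors)))


def travelled_distance(trial: TrackingTrial) -> float:
    """Total distance travelled by the cursor over the trial, degrees.

    Secondary path variant (arc length of the actual trajectory); not the
    default outcome.
    """
    dx = np.diff(trial.actual_x)
    dy = np.diff(trial.actual_y)
    return float(np.sum(np.hypot(dx, dy)))


def score_trial(
    trial: TrackingTrial,
    q: float = DEFAULT_Q_PCT,
    r: float = DEFAULT_R_DEG,
) -> TrackingOutcomes:
    """All three outcomes of one trial."""
    e = tracking_error(trial)
    return TrackingOutcomes(
        angular_near=angular_near(e, q=q),
        time_near=time_near(e, r=r),
        path=path(e),
        sampling_rate=trial.sampling_rate,
    )
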