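"""Scoring of the quantitative sensory testing (QST) battery and the
sensory-accuracy tests into one outcome row per subject.

Tests and conventions:

* vibration sense — Rydel-Seiffer tuning fork over L4, 0-8 scale; score is
  the mean of three trials (higher = better).
* pressure pain threshold (PPT) — algometer over paraspinal L5, Newtons;
  mean of three repetitions.
* conditioned pain modulation (CPM) — PPT repeated during a cold-pressor
  conditioning stimulus; absolute effect = mean(during) - mean(before) in N,
  relative effect = 100 * absolute / mean(before) in %.  Positive values
  mean the threshold rose under conditioning (efficient inhibition); set
  ``sign=-1`` to flip the convention.
* temporal summation (TS) — mean 0-10 pain rating after a train of ten
  pinprick stimuli minus the mean rating after single stimuli (five
  repetitions each).
* graphaesthesia — 20 numbers drawn on the back; error rate = incorrect/20.
* two-point discrimination (TPD) — ascending caliper staircase from 20 mm in
  5 mm steps at six paraspinal locations; threshold per location is the
  first distance perceived as two points, and the subject's score is the
  mean over the six locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "vibration_threshold",
    "pressure_pain_threshold",
    "temporal_summation",
    "cpm_effects",
    "graphaesthesia_error_rate",
    "two_point_threshold",
    "tpd_staircase",
    "TPD_START_MM",
    "TPD_STEP_MM",
]

TPD_START_MM = 20.0
TPD_STEP_MM = 5.0


def _as_floats(values: Sequence[float], n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} requires exactly {n} values, got shape {arr.shape}")
    return arr


def vibration_threshold(trials: Sequence[float]) -> float:
    """Mean of three tuning-fork readings on the 0-8 scale."""
    arr = _as_floats(trials, 3, "vibration_threshold")
    if np.any(arr < 0) or np.any(arr > 8):
        raise ValueError("vibration readings must lie on the 0-8 scale")
    return float(arr.mean())


def pressure_pain_threshold(trials: Sequence[float]) -> float:
    """Mean of three algometer forces in Newtons."""
    arr = _as_floats(trials, 3, "pressure_pain_threshold")
    if np.any(arr <= 0):
        raise ValueError("PPT forces must be positive")
    return float(arr.mean())


def temporal_summation(single: Sequence[float], train: Sequence[float]) -> float:
    """mean(train-of-10 ratings) - mean(single-stimulus ratings), 0-10 scale."""
    s = _as_floats(single, 5, "temporal_summation single")
    t = _as_floats(train, 5, "temporal_summation train")
    for arr, label in ((s, "single"), (t, "train")):
        if np.any(arr < 0) or np.any(arr > 10):
            raise ValueError(f"{label} ratings must lie on the 0-10 scale")
    return float(t.mean() - s.mean())


def cpm_effects(
    ppt_before: Sequence[float], ppt_during: Sequence[float], sign: int = 1
) -> tuple[float, float]:
    """Absolute (N) and relative (%) conditioned pain modulation effects."""
    before = pressure_pain_threshold(ppt_before)
    during = pressure_pain_threshold(ppt_during)
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    cpm_abs = sign * (during - before)
    cpm_rel = 100.0 * cpm_abs / before
    return float(cpm_abs), float(cpm_rel)


def graphaesthesia_error_rate(incorrect: int, total: int = 20) -> float:
    """Fraction of drawn figures identified incorrectly."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= incorrect <= total:
        raise ValueError(f"incorrect must be within [0, {total}]")
    return incorrect / total


def two_point_threshold(location_means: Sequence[float]) -> float:
    """Mean of the six per-location two-point thresholds, mm."""
    arr = _as_floats(location_means, 6, "two_point_threshold")
    if np.any(arr < TPD_START_MM):
        raise ValueError(f"TPD thresholds start at {TPD_START_MM:.0f} mm")
    return float(arr.mean())


def tpd_staircase(
    responses: Sequence[str],
    start_mm: float = TPD_START_MM,
    step_mm: float = TPD_STEP_MM,
    ceiling_mm: float | None = None,
) -> float | None:
    """Threshold from one ascending one/two staircase at a single location.

    The caliper starts at ``start_mm`` and widens by ``step_mm`` after every
    "one" response; the threshold is the first distance at which "two" is
    reported, i.e. ``start + step * (#ones before the first "two")``.  If the
    participant never reports "two" the threshold is missing (``None``)
    unless a ``ceiling_mm`` substitute is configured.
    """
    n_ones = 0
    for resp in responses:
        if resp == "two":
            return start_mm + step_mm * n_ones
        if resp != "one":
            raise ValueError(f"responses must be 'one' or 'two', got {resp!r}")
        n_ones += 1
    return ceiling_mm  # never perceived two points
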