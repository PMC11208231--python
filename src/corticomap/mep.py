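"""Motor evoked potential (MEP) extraction from stimulus-locked EMG.

A TMS pulse delivered over the motor cortex evokes, in a responsive muscle,
a short biphasic EMG deflection (the MEP).  The processing chain here is the
conventional one for trunk-muscle mapping studies:

1. high-pass filter the EMG at 30 Hz (removes movement artifact and DC),
2. cut a 500 ms epoch starting at each stimulus,
3. quantify each epoch by its peak-to-peak amplitude,
4. accept an epoch as an MEP when peak-to-peak exceeds 50 uV (strict), and
5. within a muscle, discard accepted MEPs smaller than 25 % of the largest
   accepted response (strict ``<``; ties with the threshold are retained).

Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "EmgEpoch",
    "MepRecord",
    "RejectionReason",
    "EPOCH_DURATION_S",
    "MEP_THRESHOLD_UV",
    "PEAK_FRACTION",
    "highpass",
    "extract_epoch",
    "peak_to_peak",
    "detect_meps",
    "filter_low_amplitude",
    "records_to_frame",
]

EPOCH_DURATION_S = 0.5
MEP_THRESHOLD_UV = 50.0
PEAK_FRACTION = 0.25


class RejectionReason(str, Enum):
    NONE = "none"
    BELOW_50UV = "below_50uV"
    BELOW_25PCT_PEAK = "below_25pct_peak"


@dataclass(frozen=True)
class EmgEpoch:
    """A stimulus-locked EMG segment.

    Parameters
    ----------
    samples
        EMG samples in microvolts, starting at the stimulus.
    sampling_rate
        Sampling frequency in Hz.
    t0
        Stimulus time within the parent recording, seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("EmgEpoch.samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("EmgEpoch.sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class MepRecord:
    """Per-stimulation MEP decision for one muscle."""

    stim_id: int
    muscle: str
    peak_to_peak: float
    accepted: bool
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.peak_to_peak < 0:
            raise ValueError("peak_to_peak must be non-negative")
        if self.accepted and self.rejection_reason is not RejectionReason.NONE:
            raise ValueError("accepted records cannot carry a rejection reason")


def highpass(
    samples: np.ndarray, sampling_rate: float, cutoff: float = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass filter.

    Applied forward-backward (``sosfiltfilt``) so MEP latencies are not
    shifted; the effective attenuation is the squared magnitude response of
    the ``order``-th order Butterworth design.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("EMG contains non-finite samples")
    nyquist = sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = _signal.butter(order, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    return _signal.sosfiltfilt(sos, x, axis=-1)


def extract_epoch(
    recording: np.ndarray,
    sampling_rate: float,
    stim_time: float,
    stim_id: int | None = None,
    duration: float = EPOCH_DURATION_S,
) -> EmgEpoch:
    """Cut the half-open window ``[stim_time, stim_time + duration)``.

    Raises ``ValueError`` (naming ``stim_id`` when given) if the window runs
    past the end of the recording.
    """
    x = np.asarray(recording, dtype=float)
    start = int(round(stim_time * sampling_rate))
    n = int(round(duration * sampling_rate))
    if start < 0 or start + n > x.size:
        label = f"stim {stim_id}: " if stim_id is not None else ""
        raise ValueError(
            f"{label}epoch [{stim_time:.3f}, {stim_time + duration:.3f}) s "
            f"exceeds the recording ({x.size / sampling_rate:.3f} s)"
        )
    return EmgEpoch(x[start : start + n], sampling_rate, t0=stim_time)


def peak_to_peak(epoch: EmgEpoch | np.ndarray) -> float:
    """Peak-to-peak amplitude, max(samples) - min(samples), in uV."""
    samples = epoch.samples if isinstance(epoch, EmgEpoch) else np.asarray(epoch, float)
    if samples.size == 0:
        raise ValueError("cannot take peak-to-peak of an empty epoch")
    return float(np.max(samples) - np.min(samples))


def detect_meps(
    epochs: Mapping[int, EmgEpoch],
    muscle: str,
    threshold: float = MEP_THRESHOLD_UV,
) -> list[MepRecord]:
    """Classify each epoch as MEP / no MEP by the strict ``> threshold`` rule."""
    records = []
    for stim_id, epoch in epochs.items():
        ptp = peak_to_peak(epoch)
        ok = ptp > threshold
        records.append(
            MepRecord(
                stim_id=stim_id,
                muscle=muscle,
                peak_to_peak=ptp,
                accepted=ok,
                rejection_reason=RejectionReason.NONE if ok else RejectionReason.BELOW_50UV,
            )
        )
    return records


def filter_low_amplitude(
    records: Sequence[MepRecord], fraction: float = PEAK_FRACTION
) -> list[MepRecord]:
    """Discard accepted MEPs below ``fraction`` of the muscle's peak response.

    The peak response is the largest accepted peak-to-peak amplitude within
    the muscle's session.  Records strictly below ``fraction * peak`` are
    flagged ``below_25pct_peak``; the peak itself always survives, so the
    retained set is never empty.  Idempotent: a second pass removes nothing,
    because the peak of the retained set equals the original peak.
    """
    accepted = [r for r in records if r.accepted]
    if not accepted:
        raise ValueError("filter_low_amplitude requires at least one accepted MEP")
    peak = max(r.peak_to_peak for r in accepted)
    out: list[MepRecord] = []
    for r in records:
        if r.accepted and r.peak_to_peak < fraction * peak:
            out.append(
                MepRecord(r.stim_id, r.muscle, r.peak_to_peak, False, RejectionReason.BELOW_25PCT_PEAK)
            )
        else:
            out.append(MepRecord(r.stim_id, r.muscle, r.peak_to_peak, r.accepted, r.rejection_reason))
    return out


def records_to_frame(records: Sequence[MepRecord]) -> pd.DataFrame:
    """MepRecord list as a tidy table (one row per stimulation x muscle)."""
    return pd.DataFrame(
        {
            "stim_id": [r.stim_id for r in records],
            "muscle": [r.muscle for r in records],
            "peak_to_peak_uv": [r.peak_to_peak for r in records],
            "accepted": [r.accepted for r in records],
            "rejection_reason": [r.rejection_reason.value for r in records],
        }
    )
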