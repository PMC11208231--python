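"""Synthetic cohorts with known ground truth.

Everything the pipeline consumes can be generated here in the same shape as
a real study export: a 25 + 25 age/sex-matched cohort, per-subject TMS
mapping sessions over four trunk muscles (100 stimulations at pseudorandom
scalp positions with synthetic stimulus-locked EMG epochs), ~2-minute
spiral-tracking trials, and raw QST records.  The generative models are
deliberately simple but fully parameterised, so every downstream estimate
can be checked against the planted truth:

* MEP amplitude surface — an isotropic Gaussian bump over the scalp patch,
  ``amplitude(site) = peak * exp(-d^2 / (2 * spatial_sd^2))`` with ``d`` the
  distance from the muscle's true CoG; each epoch embeds one biphasic MEP
  waveform of exactly that peak-to-peak amplitude plus white EMG noise.
* Subject-level test outcomes — ``value = test mean + group_effect * 1[LBP]
  + subject intercept + residual``, with the subject intercept shared across
  the tests of a subject (N(0, subject_sd^2) per test family scale).
* Tracking — the spiral target passed through a first-order lag filter plus
  isotropic Gaussian angular noise.
* Missing motor-map outcomes — whole subject x muscle slots deleted
  completely at random at ``missing_rate``.

Randomness is fully reproducible: every entity derives its own substream
from the root seed by stable hashing of (seed, subject, role), so adding
subjects never reshuffles existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import MUSCLES
from .mep import EmgEpoch
from .tracking import SPIRAL_RMAX_DEG, TrackingTrial, spiral_target

__all__ = [
    "SimulationConfig",
    "TrackingParams",
    "TestParams",
    "StimulationEvent",
    "QstRaw",
    "SyntheticCohort",
    "CLINICAL_TESTS",
    "map_test_labels",
    "substream",
    "amplitude_surface",
    "gen_subjects",
    "gen_tms_session",
    "gen_tracking_trial",
    "gen_qst_raw",
    "gen_outcome_table",
    "gen_cohort",
]

CLINICAL_TESTS = (
    "temporal_summation",
    "ppt",
    "cpm_rel",
    "cpm_abs",
    "vibration",
    "graphaesthesia",
    "two_point",
    "path",
    "angular_near",
    "time_near",
)

#: canonical-frame (left hemisphere, X < 0) true CoGs, mm.  Z values sit on
#: the default scalp dome (apex 72 mm, radius 100 mm) at each muscle's
#: (x, y) center, so the surface-constrained sites can recover all axes.
_DEFAULT_TRUE_COG = {
    "longissimus_L3": (-12.0, -28.0, 71.99),
    "longissimus_L5": (-10.0, -30.0, 71.91),
    "obliquus_externus": (-16.0, -24.0, 71.91),
    "obliquus_internus": (-14.0, -26.0, 71.99),
}

#: planted LBP - control differences, in each test's own units.  The
#: non-zero defaults are the study-scale effects the pipeline should be able
#: to detect: a more lateral longissimus-L5 CoG (canonical frame: more
#: negative X), a lower obliquus-internus CoG, and stronger temporal
#: summation of pain.
_DEFAULT_GROUP_EFFECTS = {
    "cog_x:longissimus_L5": -5.916,
    "cog_z:obliquus_internus": -2.709,
    "temporal_summation": 0.992,
}


@dataclass(frozen=True)
class TestParams:
    """Control-group mean and variance components for one test outcome."""

    mean: float
    subject_sd: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("TestParams SDs must be non-negative")


def _default_test_params() -> dict[str, TestParams]:
    params: dict[str, TestParams] = {
        "temporal_summation": TestParams(1.0, 0.85, 0.85),
        "ppt": TestParams(60.0, 15.0, 15.0),
        "cpm_rel": TestParams(10.0, 15.0, 15.0),
        "cpm_abs": TestParams(5.0, 15.0, 15.0),
        "vibration": TestParams(6.5, 0.55, 0.55),
        "graphaesthesia": TestParams(0.15, 0.11, 0.11),
        "two_point": TestParams(55.0, 11.0, 11.0),
        "path": TestParams(250.0, 21.0, 21.0),
        "angular_near": TestParams(0.6, 0.21, 0.21),
        "time_near": TestParams(65.0, 10.5, 10.5),
    }
    for muscle, cog in _DEFAULT_TRUE_COG.items():
        params[f"area:{muscle}"] = TestParams(1500.0, 800.0, 1200.0)
        params[f"cog_x:{muscle}"] = TestParams(cog[0], 5.0, 6.0)
        params[f"cog_y:{muscle}"] = TestParams(cog[1], 5.0, 7.0)
        params[f"cog_z:{muscle}"] = TestParams(cog[2], 3.0, 4.0)
    return params


def map_test_labels(muscles: Sequence[str] = MUSCLES) -> list[str]:
    """Outcome labels of the motor-map features (area + three CoG axes)."""
    labels = [f"area:{m}" for m in muscles]
    for axis in ("x", "y", "z"):
        labels += [f"cog_{axis}:{m}" for m in muscles]
    return labels


@dataclass(frozen=True)
class TrackingParams:
    duration_s: float = 120.0
    sampling_rate: float = 50.0
    n_turns: int = 4
    lag_tau_s: float = 0.15
    noise_sd_deg: float = 0.3

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("tracking.duration_s must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("tracking.sampling_rate must be positive")
        if self.lag_tau_s < 0:
            raise ValueError("tracking.lag_tau_s must be non-negative")
        if self.noise_sd_deg < 0:
            raise ValueError("tracking.noise_sd_deg must be non-negative")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the case-control design: 25 subjects per group, four
    trunk muscles mapped with 100 pseudorandom stimulations on a 60 x 60 mm
    scalp patch, 6.5 % of motor-map outcomes missing completely at random,
    and study-scale planted group effects (see module docstring).
    """

    n_per_group: int = 25
    n_stims: int = 100
    seed: int = 0
    muscles: tuple[str, ...] = MUSCLES
    true_cog: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRUE_COG)
    )
    amplitude_peak_uv: float = 400.0
    amplitude_spatial_sd_mm: float = 10.0
    noise_sd_uv: float = 5.0
    patch_extent_mm: float = 60.0
    patch_center: tuple[float, float] | None = None  # default: mean of true CoGs
    scalp_apex_z: float = 72.0
    scalp_radius_mm: float = 100.0  # dome curvature of the stimulated surface
    emg_sampling_rate: float = 2000.0
    missing_rate: float = 0.065
    left_hemisphere_fraction: float = 9.0 / 25.0
    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_EFFECTS)
    )
    test_params: dict[str, TestParams] = field(default_factory=_default_test_params)
    tracking: TrackingParams = field(default_factory=TrackingParams)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_stims < 1:
            raise ValueError("n_stims must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.amplitude_peak_uv <= 0:
            raise ValueError("amplitude_peak_uv must be positive")
        if self.amplitude_spatial_sd_mm <= 0:
            raise ValueError("amplitude_spatial_sd_mm must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if self.patch_extent_mm <= 0:
            raise ValueError("patch_extent_mm must be positive")
        if self.scalp_radius_mm <= 0:
            raise ValueError("scalp_radius_mm must be positive")
        if not 0 <= self.left_hemisphere_fraction <= 1:
            raise ValueError("left_hemisphere_fraction must lie in [0, 1]")
        for muscle in self.muscles:
            if muscle not in self.true_cog:
                raise ValueError(f"true_cog missing entry for muscle {muscle!r}")
        for label, tp in self.test_params.items():
            if tp.subject_sd < 0 or tp.residual_sd < 0:
                raise ValueError(f"test_params[{label!r}] SDs must be non-negative")
        self.tracking.validate()

    # -- helpers ---------------------------------------------------------
    def patch_center_xy(self) -> tuple[float, float]:
        if self.patch_center is not None:
            return self.patch_center
        cogs = np.array([self.true_cog[m] for m in self.muscles], dtype=float)
        return float(cogs[:, 0].mean()), float(cogs[:, 1].mean())

    def dome_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Height of the stimulated surface: a paraboloidal scalp dome with
        apex ``scalp_apex_z`` above the patch center."""
        cx, cy = self.patch_center_xy()
        return self.scalp_apex_z - ((np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2) / (
            2.0 * self.scalp_radius_mm
        )

    def true_cog_for(self, muscle: str, group: str) -> np.ndarray:
        """Canonical-frame true CoG including the planted group shift."""
        cog = np.array(self.true_cog[muscle], dtype=float)
        if group == "LBP":
            for i, axis in enumerate(("x", "y", "z")):
                cog[i] += self.group_effects.get(f"cog_{axis}:{muscle}", 0.0)
        return cog

    def all_test_labels(self) -> list[str]:
        return map_test_labels(self.muscles) + list(CLINICAL_TESTS)


@dataclass(frozen=True)
class StimulationEvent:
    """One TMS pulse: template-space coordinates plus the evoked EMG epoch."""

    stim_id: int
    coords: tuple[float, float, float]
    epoch: EmgEpoch


@dataclass(frozen=True)
class QstRaw:
    """Raw QST records for one subject, as collected at the bench."""

    vibration_trials: tuple[float, float, float]
    ppt_trials: tuple[float, float, float]
    cpm_ppt_during: tuple[float, float, float]
    cpm_nprs_hand: tuple[float, float, float]  # recorded, not scored
    ts_single: tuple[float, ...]
    ts_train: tuple[float, ...]
    graph_incorrect: int
    tpd_thresholds: tuple[float, ...]


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    outcomes: pd.DataFrame  # wide, one row per subject, NaN = missing
    qst_raw: dict[str, QstRaw]
    tracking_trials: dict[str, list[TrackingTrial]]
    tms_sessions: dict[str, dict[str, list[StimulationEvent]]]
    ground_truth: dict


def substream(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-entity RNG from the root seed and a tag tuple.

    Tags are hashed with CRC-32 (stable across platforms and sessions) so a
    given (seed, subject, role) always yields the same stream regardless of
    how many other entities were generated.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def gen_subjects(cfg: SimulationConfig) -> pd.DataFrame:
    """Matched cohort table: id, group, age, sex, hemisphere."""
    cfg.validate()
    rng = substream(cfg.seed, "subjects")
    rows = []
    n = cfg.n_per_group
    for i in range(n):
        age = float(np.clip(np.round(rng.normal(40.0, 14.0)), 18, 65))
        sex = "M" if i < round(n * 12 / 25) else "F"
        hemi = "left" if rng.random() < cfg.left_hemisphere_fraction else "right"
        for group in ("LBP", "control"):
            prefix = "P" if group == "LBP" else "C"
            rows.append(
                {
                    "subject": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "age": age,  # matched pairs share age and sex
                    "sex": sex,
                    "hemisphere": hemi,
                }
            )
    return pd.DataFrame(rows)


# -- TMS sessions --------------------------------------------------------

_MEP_FREQ_HZ = 100.0  # biphasic MEP carrier; one full cycle per epoch
_MEP_ONSET_S = 0.020


def _mep_epoch(
    amplitude_uv: float,
    sampling_rate: float,
    noise_sd_uv: float,
    rng: np.random.Generator,
) -> EmgEpoch:
    """A 500 ms epoch embedding one biphasic deflection of programmed
    peak-to-peak amplitude (exact when noise_sd is 0 and the sampling grid
    hits the waveform extrema, which holds for rates divisible by 100 Hz)."""
    n = int(round(0.5 * sampling_rate))
    samples = rng.normal(0.0, noise_sd_uv, n) if noise_sd_uv > 0 else np.zeros(n)
    period = sampling_rate / _MEP_FREQ_HZ
    start = int(round(_MEP_ONSET_S * sampling_rate))
    idx = np.arange(int(round(period)))
    if start + idx.size <= n and amplitude_uv > 0:
        samples[start : start + idx.size] += (amplitude_uv / 2.0) * np.sin(
            2.0 * np.pi * idx / period
        )
    return EmgEpoch(samples, sampling_rate)


def _session_sites(cfg: SimulationConfig, subject: str) -> np.ndarray:
    """Pseudorandom stimulation sites, shared by all muscles of a session.

    (x, y) uniform over the scalp patch; z on the curved scalp dome."""
    rng = substream(cfg.seed, subject, "sites")
    cx, cy = cfg.patch_center_xy()
    half = cfg.patch_extent_mm / 2.0
    xy = rng.uniform([cx - half, cy - half], [cx + half, cy + half], size=(cfg.n_stims, 2))
    z = cfg.dome_z(xy[:, 0], xy[:, 1])
    return np.column_stack([xy, z])


def amplitude_surface(
    cfg: SimulationConfig, muscle: str, sites: np.ndarray, group: str = "control"
) -> np.ndarray:
    """Noiseless MEP amplitude at 3-D ``sites`` for one muscle's map:
    ``peak * exp(-d^2 / (2 * spatial_sd^2))`` with d the distance to the
    muscle's (group-shifted) true CoG."""
    true_cog = cfg.true_cog_for(muscle, group)
    d = np.linalg.norm(np.atleast_2d(sites) - true_cog, axis=1)
    return cfg.amplitude_peak_uv * np.exp(-(d**2) / (2.0 * cfg.amplitude_spatial_sd_mm**2))


def gen_tms_session(
    cfg: SimulationConfig, subject: str, muscle: str, group: str = "control",
    hemisphere: str = "left", responsive: bool = True,
) -> list[StimulationEvent]:
    """One muscle's mapping session: n_stims events with synthetic epochs.

    Site coordinates are identical across the muscles of a subject (one
    physical pulse drives all EMG channels); the amplitude surface is the
    muscle's own Gaussian bump around its (group-shifted) true CoG.  For
    right-hemisphere subjects the whole session is generated mirrored
    (X > 0), as a real navigated export would be.  ``responsive=False``
    emulates a muscle in which no MEP could be elicited (noise-only
    epochs), the mechanism behind missing motor-map outcomes.
    """
    cfg.validate()
    if muscle not in cfg.muscles:
        raise ValueError(f"unknown muscle {muscle!r}")
    sites = _session_sites(cfg, subject)
    amplitudes = amplitude_surface(cfg, muscle, sites, group)
    if not responsive:
        amplitudes = np.zeros_like(amplitudes)
    rng = substream(cfg.seed, subject, muscle, "emg")
    events = []
    for i in range(cfg.n_stims):
        epoch = _mep_epoch(amplitudes[i], cfg.emg_sampling_rate, cfg.noise_sd_uv, rng)
        coords = sites[i].copy()
        if hemisphere == "right":
            coords[0] *= -1.0
        events.append(StimulationEvent(i, tuple(coords), epoch))
    return events


# -- tracking ------------------------------------------------------------

def gen_tracking_trial(
    cfg: SimulationConfig, subject: str, practice: bool = False
) -> TrackingTrial:
    """Spiral target followed through a first-order lag plus angular noise."""
    cfg.validate()
    p = cfg.tracking
    n = int(round(p.duration_s * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate
    tx, ty = spiral_target(t, p.duration_s, n_turns=p.n_turns)
    rng = substream(cfg.seed, subject, "tracking", "practice" if practice else "main")
    ax, ay = tx.copy(), ty.copy()
    if p.lag_tau_s > 0:
        alpha = float(np.exp(-1.0 / (p.sampling_rate * p.lag_tau_s)))
        # y[i] = alpha*y[i-1] + (1-alpha)*x[i]  (exponential first-order lag)
        from scipy.signal import lfilter

        ax = lfilter([1.0 - alpha], [1.0, -alpha], tx)
        ay = lfilter([1.0 - alpha], [1.0, -alpha], ty)
    if p.noise_sd_deg > 0:
        ax = ax + rng.normal(0.0, p.noise_sd_deg, n)
        ay = ay + rng.normal(0.0, p.noise_sd_deg, n)
    return TrackingTrial(t, tx, ty, ax, ay, p.sampling_rate, practice=practice)


# -- QST raw records -----------------------------------------------------

def gen_qst_raw(values: Mapping[str, float], rng: np.random.Generator) -> QstRaw:
    """Raw bench records consistent with the subject's target test values.

    Replicate trials are set equal to the target so the scorers reproduce
    the planted outcome exactly, except where the instrument quantises:
    graphaesthesia rounds to a count of 20 and TPD to the 5 mm caliper grid.
    The relative CPM effect is implied by PPT and the absolute effect.
    """
    vib = float(np.clip(values["vibration"], 0.0, 8.0))
    ppt = max(float(values["ppt"]), 1.0)
    cpm_abs = float(values["cpm_abs"])
    during = max(ppt + cpm_abs, 1.0)
    ts = float(np.clip(values["temporal_summation"], -2.0, 8.0))
    single = 2.0
    graph_n = int(np.clip(round(values["graphaesthesia"] * 20), 0, 20))
    tpd = float(values["two_point"])
    tpd_grid = max(20.0, 20.0 + 5.0 * round((tpd - 20.0) / 5.0))
    return QstRaw(
        vibration_trials=(vib,) * 3,
        ppt_trials=(ppt,) * 3,
        cpm_ppt_during=(during,) * 3,
        cpm_nprs_hand=tuple(np.round(rng.uniform(3, 7, 3), 0)),
        ts_single=(single,) * 5,
        ts_train=(single + ts,) * 5,
        graph_incorrect=graph_n,
        tpd_thresholds=(tpd_grid,) * 6,
    )


# -- outcome table and full cohort --------------------------------------

def gen_outcome_table(cfg: SimulationConfig, subjects: pd.DataFrame) -> pd.DataFrame:
    """Planted subject-level outcomes for every test label.

    value = mean + group_effect * 1[LBP] + subject_intercept * (subject_sd /
    its own scale) + residual.  The subject intercept is a single standard-
    normal draw per subject, scaled by each test's subject_sd, which makes
    the tests of a subject positively correlated — the reason the analysis
    models need a random intercept.
    """
    labels = cfg.all_test_labels()
    rows = []
    for _, subj in subjects.iterrows():
        rng = substream(cfg.seed, subj["subject"], "outcomes")
        u = rng.standard_normal()
        row: dict[str, float | str] = {"subject": subj["subject"], "group": subj["group"]}
        for label in labels:
            tp = cfg.test_params[label]
            effect = cfg.group_effects.get(label, 0.0) if subj["group"] == "LBP" else 0.0
            row[label] = tp.mean + effect + tp.subject_sd * u + rng.normal(0.0, tp.residual_sd)
        rows.append(row)
    return pd.DataFrame(rows)


def _apply_map_missingness(
    cfg: SimulationConfig, outcomes: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Delete whole subject x muscle motor-map slots completely at random."""
    rng = substream(cfg.seed, "missingness")
    out = outcomes.copy()
    missing_per_muscle = {m: 0 for m in cfg.muscles}
    for idx in out.index:
        for muscle in cfg.muscles:
            if rng.random() < cfg.missing_rate:
                cols = [f"area:{muscle}"] + [f"cog_{a}:{muscle}" for a in "xyz"]
                out.loc[idx, cols] = np.nan
                missing_per_muscle[muscle] += 1
    return out, missing_per_muscle


def gen_cohort(cfg: SimulationConfig, raw: bool = True) -> SyntheticCohort:
    """Full synthetic cohort; ``raw=False`` skips the (heavier) EMG,
    tracking and QST record synthesis and returns outcome tables only."""
    cfg.validate()
    subjects = gen_subjects(cfg)
    outcomes = gen_outcome_table(cfg, subjects)
    outcomes, missing_per_muscle = _apply_map_missingness(cfg, outcomes)

    qst_raw: dict[str, QstRaw] = {}
    tracking_trials: dict[str, list[TrackingTrial]] = {}
    tms_sessions: dict[str, dict[str, list[StimulationEvent]]] = {}
    if raw:
        for _, subj in subjects.iterrows():
            sid = subj["subject"]
            values = outcomes.set_index("subject").loc[sid]
            qst_raw[sid] = gen_qst_raw(values, substream(cfg.seed, sid, "qst"))
            tracking_trials[sid] = [
                gen_tracking_trial(cfg, sid, practice=True),
                gen_tracking_trial(cfg, sid, practice=False),
            ]
            slot_values = outcomes.set_index("subject").loc[sid]
            tms_sessions[sid] = {
                m: gen_tms_session(
                    cfg,
                    sid,
                    m,
                    group=subj["group"],
                    hemisphere=subj["hemisphere"],
                    # a slot deleted by the missingness mechanism corresponds
                    # to a muscle in which no MEP could be elicited
                    responsive=not np.isnan(slot_values[f"area:{m}"]),
                )
                for m in cfg.muscles
            }

    ground_truth = {
        "group_effects": dict(cfg.group_effects),
        "true_cog": {m: tuple(v) for m, v in cfg.true_cog.items()},
        "test_params": {k: asdict(v) for k, v in cfg.test_params.items()},
        "missing_per_muscle": missing_per_muscle,
        "seed": cfg.seed,
    }
    return SyntheticCohort(
        subjects=subjects,
        outcomes=outcomes,
        qst_raw=qst_raw,
        tracking_trials=tracking_trials,
        tms_sessions=tms_sessions,
        ground_truth=ground_truth,
    )
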