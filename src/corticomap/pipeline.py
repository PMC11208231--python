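"""End-to-end orchestration: generate or ingest raw data, process it into
subject-level outcomes, fit the group-difference and association models, and
write a reproducible report bundle.

Stages (synthetic mode; file mode joins at stage 2):

1. generate — synthetic cohort with known ground truth (:mod:`.synth`);
2. MEP processing — 30 Hz high-pass, 500 ms epochs, > 50 uV acceptance,
   25 %-of-peak retention (:mod:`.mep`);
3. motor maps — hemisphere mirroring, CoG and area per muscle
   (:mod:`.mapping`);
4. tracking and clinical scoring (:mod:`.tracking`, :mod:`.clinical`);
5. mixed models per outcome family, association models with the
   significance-gated within-group stratification (:mod:`.models`);
6. report bundle — CSV tables stamped with the config hash, cohort/missing
   accounting, and a plain-text report.

Identical config + seed produces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import signal as _signal

from . import clinical, io, mep, models, tracking
from .mapping import MUSCLES, MotorMap, maps_to_frame, mirror_hemisphere, summarize_map
from .models import default_families, estimates_to_frame
from .synth import (
    CLINICAL_TESTS,
    QstRaw,
    SimulationConfig,
    SyntheticCohort,
    gen_cohort,
)

__all__ = [
    "RunConfig",
    "CohortAccounting",
    "account_missing",
    "process_session",
    "score_qst",
    "run",
]

log = logging.getLogger("corticomap")


@dataclass
class RunConfig:
    """Validated, fully serialisable description of one pipeline run."""

    mode: Literal["synthetic", "files"] = "synthetic"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    data_dir: str | None = None  # files mode input directory
    outdir: str = "corticomap_out"
    q_pct: float = tracking.DEFAULT_Q_PCT
    r_deg: float = tracking.DEFAULT_R_DEG
    area_method: Literal["alpha_shape", "convex_hull"] = "alpha_shape"
    alpha_mm: float = 15.0
    gate_alpha: float = 0.05
    associations: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files" and not self.data_dir:
            raise ValueError("data_dir is required in files mode")
        if not 0 < self.q_pct <= 100:
            raise ValueError("q_pct must be in (0, 100]")
        if self.r_deg <= 0:
            raise ValueError("r_deg must be positive")
        if not 0 < self.gate_alpha < 1:
            raise ValueError("gate_alpha must be in (0, 1)")
        if self.area_method not in ("alpha_shape", "convex_hull"):
            raise ValueError(f"unknown area_method {self.area_method!r}")
        if self.mode == "synthetic":
            self.sim.validate()

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        from .synth import TestParams, TrackingParams

        if "tracking" in sim_d:
            sim_d["tracking"] = TrackingParams(**sim_d["tracking"])
        if "test_params" in sim_d:
            sim_d["test_params"] = {
                k: TestParams(**v) if isinstance(v, Mapping) else v
                for k, v in sim_d["test_params"].items()
            }
        for key in ("true_cog",):
            if key in sim_d:
                sim_d[key] = {k: tuple(v) for k, v in sim_d[key].items()}
        if "muscles" in sim_d:
            sim_d["muscles"] = tuple(sim_d["muscles"])
        cfg = cls(**{**d, "sim": SimulationConfig(**sim_d)})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class CohortAccounting:
    """Outcome-slot bookkeeping for the motor-map dataset."""

    n_subjects: int
    n_muscles: int
    missing_per_muscle: dict[str, int]
    total_slots: int
    n_missing: int
    missing_pct: float  # one decimal

    @classmethod
    def from_counts(cls, missing_per_muscle: Mapping[str, int], n_subjects: int) -> "CohortAccounting":
        n_muscles = len(missing_per_muscle)
        total = n_subjects * n_muscles
        n_missing = int(sum(missing_per_muscle.values()))
        if n_missing > total:
            raise ValueError("more missing slots than slots")
        return cls(
            n_subjects=n_subjects,
            n_muscles=n_muscles,
            missing_per_muscle=dict(missing_per_muscle),
            total_slots=total,
            n_missing=n_missing,
            missing_pct=round(100.0 * n_missing / total, 1),
        )


def account_missing(map_table: pd.DataFrame) -> CohortAccounting:
    """Per-muscle missing counts and overall missing percentage.

    Expects one row per subject x muscle; a slot is missing when its CoG is
    absent (no MEPs could be elicited).  Duplicate subject x muscle rows are
    an error.
    """
    if map_table.duplicated(subset=["subject", "muscle"]).any():
        dupes = map_table[map_table.duplicated(subset=["subject", "muscle"], keep=False)]
        raise ValueError(f"duplicate subject x muscle rows: {sorted(set(dupes['subject']))}")
    n_subjects = map_table["subject"].nunique()
    missing = (
        map_table.assign(_miss=map_table["cog_x"].isna())
        .groupby("muscle", sort=False)["_miss"]
        .sum()
        .astype(int)
        .to_dict()
    )
    return CohortAccounting.from_counts(missing, n_subjects)


# -- raw-data processing -------------------------------------------------

def _filter_epochs(epochs: Mapping[int, mep.EmgEpoch], cutoff: float = 30.0) -> dict[int, mep.EmgEpoch]:
    """High-pass all epochs of a session in one vectorised filtfilt pass."""
    ids = list(epochs)
    if not ids:
        return {}
    rate = epochs[ids[0]].sampling_rate
    stack = np.vstack([epochs[i].samples for i in ids])
    sos = _signal.butter(4, cutoff, btype="highpass", fs=rate, output="sos")
    filtered = _signal.sosfiltfilt(sos, stack, axis=-1)
    return {i: mep.EmgEpoch(filtered[k], rate) for k, i in enumerate(ids)}


def process_session(
    epochs: Mapping[int, mep.EmgEpoch],
    coords: pd.DataFrame,
    muscle: str,
    hemisphere: str,
    area_method: str = "alpha_shape",
    alpha_mm: float = 15.0,
) -> MotorMap:
    """Raw epochs + stimulation coordinates -> one muscle's MotorMap.

    Applies the full MEP chain, mirrors the coordinates onto the canonical
    (left) hemisphere, and summarises CoG and area.  A session without any
    accepted MEP yields a map flagged ``no_meps`` (a missing outcome)."""
    filtered = _filter_epochs(epochs)
    records = mep.detect_meps(filtered, muscle)
    if any(r.accepted for r in records):
        records = mep.filter_low_amplitude(records)
    pooled = coords.copy()
    pooled[["x", "y", "z"]] = mirror_hemisphere(
        pooled[["x", "y", "z"]].to_numpy(), hemisphere, onto="left"
    )
    return summarize_map(muscle, records, pooled, method=area_method, alpha=alpha_mm)


def score_qst(raw: QstRaw) -> dict[str, float]:
    """One subject's raw QST records -> scored clinical outcomes."""
    cpm_abs, cpm_rel = clinical.cpm_effects(raw.ppt_trials, raw.cpm_ppt_during)
    return {
        "vibration": clinical.vibration_threshold(raw.vibration_trials),
        "ppt": clinical.pressure_pain_threshold(raw.ppt_trials),
        "cpm_abs": cpm_abs,
        "cpm_rel": cpm_rel,
        "temporal_summation": clinical.temporal_summation(raw.ts_single, raw.ts_train),
        "graphaesthesia": clinical.graphaesthesia_error_rate(raw.graph_incorrect),
        "two_point": clinical.two_point_threshold(raw.tpd_thresholds),
    }


def _analysis_table(
    subjects: pd.DataFrame,
    maps: dict[str, dict[str, MotorMap]],
    clinical_rows: dict[str, dict[str, float]],
    tracking_rows: dict[str, tracking.TrackingOutcomes],
) -> pd.DataFrame:
    rows = []
    for _, subj in subjects.iterrows():
        sid = subj["subject"]
        row: dict = {"subject": sid, "group": subj["group"]}
        for muscle, m in maps.get(sid, {}).items():
            row[f"area:{muscle}"] = np.nan if m.missing else m.area_mm2
            for i, axis in enumerate("xyz"):
                row[f"cog_{axis}:{muscle}"] = np.nan if m.missing else m.cog[i]
        row.update(clinical_rows.get(sid, {}))
        if sid in tracking_rows:
            t = tracking_rows[sid]
            row["angular_near"] = t.angular_near
            row["time_near"] = t.time_near
            row["path"] = t.path
        rows.append(row)
    return pd.DataFrame(rows)


# -- the run -------------------------------------------------------------

def _load_files_cohort(cfg: RunConfig) -> tuple[pd.DataFrame, dict, dict, dict]:
    root = Path(cfg.data_dir)
    subjects = io.read_csv(root / "subjects.csv")
    required = {"subject", "group", "hemisphere"}
    if not required <= set(subjects.columns):
        missing = sorted(required - set(subjects.columns))
        raise ValueError(f"subjects.csv is missing columns: {missing}")
    qst = io.read_csv(root / "qst.csv").set_index("subject")
    muscles = [m for m in MUSCLES if any((root / "emg").glob(f"*_{m}.csv"))]
    epochs, coords, trials, raws = {}, {}, {}, {}
    for sid in subjects["subject"]:
        coords[sid] = io.read_session_coords(root, sid)
        epochs[sid] = {m: io.read_session_epochs(root, sid, m) for m in muscles}
        trials[sid] = io.read_tracking_trial(root, sid, "main")
        raws[sid] = io.qst_row_to_raw(qst.loc[sid])
    return subjects, epochs, coords, {"trials": trials, "qst": raws}


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to cfg.outdir.

    Returns a dict with the in-memory tables (subjects, maps, outcomes,
    accounting, group estimates, association estimates, report text).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash()}

    # stage 1: obtain raw data
    if cfg.mode == "synthetic":
        cohort = gen_cohort(cfg.sim, raw=True)
        subjects = cohort.subjects
        epoch_source = {
            sid: {m: {e.stim_id: e.epoch for e in events} for m, events in by_muscle.items()}
            for sid, by_muscle in cohort.tms_sessions.items()
        }
        coords_source = {
            sid: pd.DataFrame(
                [(e.stim_id, *e.coords) for e in next(iter(by_muscle.values()))],
                columns=["stim_id", "x", "y", "z"],
            )
            for sid, by_muscle in cohort.tms_sessions.items()
        }
        trials = {sid: ts[1] for sid, ts in cohort.tracking_trials.items()}
        qst_raws = cohort.qst_raw
    else:
        subjects, epoch_source, coords_source, extra = _load_files_cohort(cfg)
        trials, qst_raws = extra["trials"], extra["qst"]
    log.info("stage generate/ingest: %d subjects", len(subjects))

    # stages 2-3: MEP processing and motor maps
    hemi = subjects.set_index("subject")["hemisphere"]
    maps: dict[str, dict[str, MotorMap]] = {}
    for sid, by_muscle in epoch_source.items():
        maps[sid] = {
            m: process_session(
                eps, coords_source[sid], m, hemi[sid],
                area_method=cfg.area_method, alpha_mm=cfg.alpha_mm,
            )
            for m, eps in by_muscle.items()
        }
    map_table = maps_to_frame(maps)
    accounting = account_missing(map_table) if not map_table.empty else None
    if accounting:
        log.info(
            "stage maps: %d slots, %d missing (%.1f%%)",
            accounting.total_slots, accounting.n_missing, accounting.missing_pct,
        )

    # stage 4: clinical + tracking scoring
    clinical_rows = {sid: score_qst(raw) for sid, raw in qst_raws.items()}
    tracking_rows = {
        sid: tracking.score_trial(tr, q=cfg.q_pct, r=cfg.r_deg) for sid, tr in trials.items()
    }
    outcomes = _analysis_table(subjects, maps, clinical_rows, tracking_rows)
    log.info("stage scoring: %d outcome rows", len(outcomes))

    # stage 5: models
    families = default_families(
        tuple(next(iter(maps.values())).keys()) if maps else MUSCLES
    )
    group_estimates: dict[str, list] = {}
    for name, family in families.items():
        if not all(t in outcomes.columns for t in family.tests):
            continue
        long = models.stack_long(outcomes, family)
        log.info("family %s: %d long rows", name, len(long))
        group_estimates[name] = models.fit_group_model(long)

    association_rows = []
    if cfg.associations:
        map_families = {k: v for k, v in families.items() if k in ("area", "cog_ml", "cog_ap", "cog_vert")}
        predictors = [c for c in CLINICAL_TESTS if c in outcomes.columns]
        for fam_name, family in map_families.items():
            for pred in predictors:
                long = models.stack_long(outcomes, family)
                pvals = outcomes.set_index("subject")[pred]
                long[pred] = long["subject"].map(pvals)
                try:
                    pooled = models.fit_association_model(long, predictor=pred)
                except ValueError:
                    continue
                for e in pooled:
                    association_rows.append((fam_name, pred, "all", e))
                if any(e.p < cfg.gate_alpha for e in pooled):
                    for grp in ("LBP", "control"):
                        for e in models.stratified_association(long, grp, predictor=pred):
                            association_rows.append((fam_name, pred, grp, e))

    # stage 6: report bundle
    io.write_csv(subjects, outdir / "subjects.csv", stamp)
    io.write_csv(map_table, outdir / "maps.csv", stamp)
    io.write_csv(outcomes, outdir / "analysis_outcomes.csv", stamp)
    est_frame = estimates_to_frame(group_estimates)
    io.write_csv(est_frame, outdir / "group_estimates.csv", stamp)
    assoc_frame = pd.DataFrame(
        [
            {
                "family": fam, "predictor": pred, "scope": scope, "test": e.test,
                "beta": e.beta, "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "p": e.p, "flags": ";".join(e.flags),
            }
            for fam, pred, scope, e in association_rows
        ],
        columns=["family", "predictor", "scope", "test", "beta", "se",
                 "ci_low", "ci_high", "p", "flags"],
    )
    io.write_csv(assoc_frame, outdir / "association_estimates.csv", stamp)
    if accounting:
        (outdir / "accounting.json").write_text(
            json.dumps({**stamp, **dataclasses.asdict(accounting)}, indent=2)
        )
    (outdir / "config.json").write_text(
        json.dumps({**stamp, "config": cfg.to_dict()}, indent=2, default=str)
    )
    report = models.render_tables(group_estimates)
    if accounting:
        report += (
            f"\nMotor-map outcome slots: {accounting.total_slots} "
            f"({accounting.n_missing} missing, {accounting.missing_pct}%)\n"
        )
    (outdir / "report.txt").write_text(report)

    return {
        "subjects": subjects,
        "maps": map_table,
        "outcomes": outcomes,
        "accounting": accounting,
        "group_estimates": group_estimates,
        "association_estimates": assoc_frame,
        "report": report,
    }
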