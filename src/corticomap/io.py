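"""CSV/JSON schemas shared by synthetic exports and the file-based pipeline.

All files are UTF-8, comma-separated, header row, "." decimal separator.
Optional ``# key: value`` comment lines at the top carry provenance (e.g.
the run-config hash); readers skip them.

Layout of a study directory (as written by ``corticomap simulate``)::

    subjects.csv                      subject, group, age, sex, hemisphere
    qst.csv                           wide per-subject raw QST records
    coords/<subject>.csv              stim_id, x, y, z        (mm, template space)
    emg/<subject>_<muscle>.csv        stim_id, sample_index, uv   (long format)
    emg/<subject>_<muscle>.json       {"sampling_rate": ..., "epoch_duration_s": ...}
    tracking/<subject>_<trial>.csv    t, target_x, target_y, actual_x, actual_y
    tracking/<subject>_<trial>.json   {"sampling_rate": ..., "practice": ...}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .mep import EmgEpoch
from .synth import QstRaw, StimulationEvent
from .tracking import TrackingTrial

__all__ = [
    "write_csv",
    "read_csv",
    "write_session",
    "read_session_epochs",
    "read_session_coords",
    "write_tracking_trial",
    "read_tracking_trial",
    "qst_raw_to_row",
    "qst_row_to_raw",
]


def write_csv(df: pd.DataFrame, path: Path | str, header_comments: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (header_comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- TMS sessions --------------------------------------------------------

def write_session(
    events: list[StimulationEvent],
    subject: str,
    muscle: str,
    outdir: Path | str,
    header_comments: Mapping[str, str] | None = None,
) -> None:
    """EMG epochs as one long CSV per subject x muscle plus a JSON sidecar,
    and the (muscle-independent) stimulation coordinates per subject."""
    outdir = Path(outdir)
    n = len(events)
    if n == 0:
        raise ValueError("cannot write an empty session")
    epoch_len = events[0].epoch.samples.size
    emg = pd.DataFrame(
        {
            "stim_id": np.repeat([e.stim_id for e in events], epoch_len),
            "sample_index": np.tile(np.arange(epoch_len), n),
            "uv": np.concatenate([e.epoch.samples for e in events]),
        }
    )
    write_csv(emg, outdir / "emg" / f"{subject}_{muscle}.csv", header_comments)
    sidecar = {
        "sampling_rate": events[0].epoch.sampling_rate,
        "epoch_duration_s": epoch_len / events[0].epoch.sampling_rate,
    }
    (outdir / "emg" / f"{subject}_{muscle}.json").write_text(json.dumps(sidecar))
    coords = pd.DataFrame(
        [(e.stim_id, *e.coords) for e in events], columns=["stim_id", "x", "y", "z"]
    )
    write_csv(coords, outdir / "coords" / f"{subject}.csv", header_comments)


def read_session_epochs(outdir: Path | str, subject: str, muscle: str) -> dict[int, EmgEpoch]:
    outdir = Path(outdir)
    emg = read_csv(outdir / "emg" / f"{subject}_{muscle}.csv")
    sidecar = json.loads((outdir / "emg" / f"{subject}_{muscle}.json").read_text())
    rate = float(sidecar["sampling_rate"])
    epochs: dict[int, EmgEpoch] = {}
    for stim_id, g in emg.groupby("stim_id", sort=True):
        samples = g.sort_values("sample_index")["uv"].to_numpy()
        epochs[int(stim_id)] = EmgEpoch(samples, rate)
    return epochs


def read_session_coords(outdir: Path | str, subject: str) -> pd.DataFrame:
    return read_csv(Path(outdir) / "coords" / f"{subject}.csv")


# -- tracking ------------------------------------------------------------

def write_tracking_trial(
    trial: TrackingTrial, subject: str, label: str, outdir: Path | str,
    header_comments: Mapping[str, str] | None = None,
) -> None:
    outdir = Path(outdir)
    write_csv(trial.to_frame(), outdir / "tracking" / f"{subject}_{label}.csv", header_comments)
    meta = {"sampling_rate": trial.sampling_rate, "practice": trial.practice}
    (outdir / "tracking" / f"{subject}_{label}.json").write_text(json.dumps(meta))


def read_tracking_trial(outdir: Path | str, subject: str, label: str) -> TrackingTrial:
    outdir = Path(outdir)
    df = read_csv(outdir / "tracking" / f"{subject}_{label}.csv")
    meta = json.loads((outdir / "tracking" / f"{subject}_{label}.json").read_text())
    return TrackingTrial(
        df["t"].to_numpy(),
        df["target_x"].to_numpy(),
        df["target_y"].to_numpy(),
        df["actual_x"].to_numpy(),
        df["actual_y"].to_numpy(),
        float(meta["sampling_rate"]),
        practice=bool(meta["practice"]),
    )


# -- QST -----------------------------------------------------------------

def qst_raw_to_row(subject: str, raw: QstRaw) -> dict:
    row: dict = {"subject": subject}
    for i, v in enumerate(raw.vibration_trials, 1):
        row[f"vibration_{i}"] = v
    for i, v in enumerate(raw.ppt_trials, 1):
        row[f"ppt_before_{i}"] = v
    for i, v in enumerate(raw.cpm_ppt_during, 1):
        row[f"ppt_during_{i}"] = v
    for i, v in enumerate(raw.cpm_nprs_hand, 1):
        row[f"cpm_nprs_hand_{i}"] = v
    for i, v in enumerate(raw.ts_single, 1):
        row[f"ts_single_{i}"] = v
    for i, v in enumerate(raw.ts_train, 1):
        row[f"ts_train_{i}"] = v
    row["graph_incorrect"] = raw.graph_incorrect
    for i, v in enumerate(raw.tpd_thresholds, 1):
        row[f"tpd_loc{i}"] = v
    return row


def qst_row_to_raw(row: Mapping) -> QstRaw:
    return QstRaw(
        vibration_trials=tuple(float(row[f"vibration_{i}"]) for i in (1, 2, 3)),
        ppt_trials=tuple(float(row[f"ppt_before_{i}"]) for i in (1, 2, 3)),
        cpm_ppt_during=tuple(float(row[f"ppt_during_{i}"]) for i in (1, 2, 3)),
        cpm_nprs_hand=tuple(float(row[f"cpm_nprs_hand_{i}"]) for i in (1, 2, 3)),
        ts_single=tuple(float(row[f"ts_single_{i}"]) for i in range(1, 6)),
        ts_train=tuple(float(row[f"ts_train_{i}"]) for i in range(1, 6)),
        graph_incorrect=int(row["graph_incorrect"]),
        tpd_thresholds=tuple(float(row[f"tpd_loc{i}"]) for i in range(1, 7)),
    )
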