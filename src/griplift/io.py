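"""File formats: per-trial CSV + JSON sidecar, session manifest, tables.

Records are tiny (a few hundred samples), so everything is plain text:

* one CSV per trial with a unit comment line and header
  ``t,gf,lf_stand,az`` (seconds, N, N, m/s^2);
* a JSON sidecar ``<stem>.meta.json`` with the trial context
  (participant, g_level, trial_index, phase, phase_index, mass, fs,
  seed);
* an optional ``<stem>.truth.json`` with the generator's ground truth;
* a session ``manifest.tsv`` listing every trial file with its context;
* metrics/switch/summary tables as TSV with unit-bearing headers.

Floats are written with 17 significant digits, so a write/read
round-trip is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .errors import FormatError
from .records import GroundTruth, TrialContext, TrialRecording
from .synthetic import SimulatedTrial

__all__ = [
    "write_trial",
    "read_trial",
    "write_session",
    "read_manifest",
    "read_manifest_trials",
    "write_metrics",
    "read_metrics",
]

logger = logging.getLogger(__name__)

_UNITS_COMMENT = "# units: t=s, gf=N, lf_stand=N, az=m/s^2"
_COLUMNS = ["t", "gf", "lf_stand", "az"]
_SIDECAR_REQUIRED = ["participant", "g_level", "trial_index", "phase", "mass", "fs"]
_FLOAT_FMT = "%.17g"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_name(csv_path.stem + ".meta.json")


def _truth_path(csv_path: Path) -> Path:
    return csv_path.with_name(csv_path.stem + ".truth.json")


def write_trial(
    path: Path | str,
    recording: TrialRecording,
    context: TrialContext,
    truth: Optional[GroundTruth] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write one trial CSV plus its JSON sidecar (and ground truth if given)."""
    path = Path(path)
    recording.validate()
    frame = pd.DataFrame(
        {
            "t": recording.t,
            "gf": recording.gf,
            "lf_stand": recording.lf_stand,
            "az": recording.az,
        }
    )
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    meta = {
        "participant": context.participant,
        "g_level": context.g_level,
        "trial_index": context.trial_index,
        "phase": context.phase,
        "phase_index": context.phase_index,
        "mass": context.mass,
        "fs": recording.fs,
        "seed": seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    if truth is not None:
        _truth_path(path).write_text(
            json.dumps(dataclasses.asdict(truth), indent=1)
        )
    return path


def read_trial(path: Path | str) -> Tuple[TrialRecording, TrialContext]:
    """Read a trial CSV and its sidecar; validates format and grid.

    Raises :class:`FormatError` naming the offending file/column on
    missing columns, a non-uniform time grid, non-finite values, or a
    sidecar lacking required fields.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trial file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    meta = json.loads(sidecar.read_text())
    missing_meta = [k for k in _SIDECAR_REQUIRED if k not in meta or meta[k] is None]
    if missing_meta:
        raise FormatError(f"{sidecar}: missing required field(s) {missing_meta}")
    recording = TrialRecording(
        t=frame["t"].to_numpy(),
        gf=frame["gf"].to_numpy(),
        lf_stand=frame["lf_stand"].to_numpy(),
        az=frame["az"].to_numpy(),
        fs=float(meta["fs"]),
    )
    recording.validate()  # raises FormatError with row/column detail
    context = TrialContext(
        participant=str(meta["participant"]),
        g_level=float(meta["g_level"]),
        trial_index=int(meta["trial_index"]),
        phase=str(meta["phase"]),
        mass=float(meta["mass"]),
        phase_index=int(meta.get("phase_index", 0)),
    )
    return recording, context


def read_truth(path: Path | str) -> GroundTruth:
    """Read the ground-truth JSON written next to a generated trial."""
    p = _truth_path(Path(path))
    if not p.exists():
        raise FormatError(f"ground-truth file not found: {p}")
    return GroundTruth(**json.loads(p.read_text()))


def _trial_filename(context: TrialContext) -> str:
    return (
        f"{context.participant}_phase{context.phase_index}"
        f"_T{context.trial_index}.csv"
    )


def write_session(
    out_dir: Path | str,
    trials: Sequence[SimulatedTrial],
    seed: Optional[int] = None,
) -> Path:
    """Write every trial of a simulated session plus ``manifest.tsv``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        name = _trial_filename(trial.context)
        write_trial(out_dir / name, trial.recording, trial.context, trial.truth, seed)
        rows.append(
            {
                "path": name,
                "participant": trial.context.participant,
                "g_level": trial.context.g_level,
                "trial_index": trial.context.trial_index,
                "phase": trial.context.phase,
                "phase_index": trial.context.phase_index,
                "mass": trial.context.mass,
                "fs": trial.recording.fs,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False, float_format=_FLOAT_FMT)
    return manifest


def read_manifest(path: Path | str) -> pd.DataFrame:
    """Read a session manifest; checks that every listed trial file exists."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["path", "participant", "g_level", "trial_index", "phase", "mass", "fs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: manifest lists no trials")
    key = df[["participant", "phase_index", "trial_index"]] if "phase_index" in df else None
    if key is not None and key.duplicated().any():
        raise FormatError(f"{path}: duplicate (participant, phase, trial) rows")
    return df


def read_manifest_trials(
    path: Path | str,
) -> List[Tuple[TrialRecording, TrialContext]]:
    """Load every trial a manifest lists (paths resolved next to it)."""
    path = Path(path)
    df = read_manifest(path)
    out = []
    for rel in df["path"]:
        out.append(read_trial(path.parent / rel))
    return out


def write_metrics(path: Path | str, metrics_frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics_frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_metrics(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metrics table not found: {path}")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
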