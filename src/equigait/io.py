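"""On-disk dialect for trial recordings and ground-truth sidecars.

A trial is stored as two plain CSV files sharing a stem: ``<stem>.kin.csv``
(kinematic channels, mm) and ``<stem>.emg.csv`` (sEMG channels, arbitrary
units). Each file starts with a ``# key: value`` header block declaring
horse, condition, induced side, sampling rate and time origin, optionally
followed by externally detected impact times. Values are written at full
float precision so a write/read round-trip is exact.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DataFormatError, LANDMARKS, TrialRecording, emg_channels

__all__ = ["read_trial", "write_trial", "write_ground_truth", "load_cohort"]

_FLOAT_FMT = "%.17g"


def _part(stem: str | Path, kind: str) -> Path:
    return Path(f"{stem}.{kind}.csv")


def _write_stream(
    path: Path,
    df: pd.DataFrame,
    header: dict[str, str],
    overwrite: bool,
) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    buf = _io.StringIO()
    for key, value in header.items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text(buf.getvalue())


def write_trial(rec: TrialRecording, stem: str | Path, overwrite: bool = False) -> Path:
    """Write ``<stem>.kin.csv`` and ``<stem>.emg.csv``; returns the stem."""
    rec.validate()
    stem = Path(stem)
    common = {
        "horse_id": rec.horse_id,
        "condition": rec.condition,
        "induced_side": rec.induced_side,
        "t0": repr(float(rec.t0)),
    }
    kin_header = dict(common, sampling_hz=repr(float(rec.kin_hz)), units="mm")
    if rec.events is not None:
        for limb in ("left", "right"):
            kin_header[f"events_{limb}"] = ",".join(
                _FLOAT_FMT % v for v in np.asarray(rec.events[limb], float)
            )
    emg_header = dict(common, sampling_hz=repr(float(rec.emg_hz)), units="au")
    _write_stream(_part(stem, "kin"), rec.kin, kin_header, overwrite)
    _write_stream(_part(stem, "emg"), rec.emg, emg_header, overwrite)
    return stem


def _read_stream(path: Path) -> tuple[pd.DataFrame, dict[str, str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        header[key.strip()] = value.strip()
        n_header += 1
    try:
        df = pd.read_csv(
            _io.StringIO("".join(lines[n_header:])), float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise DataFormatError(f"{path}: inconsistent column lengths or missing values")
    for key in ("horse_id", "condition", "induced_side", "sampling_hz"):
        if key not in header:
            raise DataFormatError(f"{path}: header missing {key!r}")
    return df, header


def read_trial(stem: str | Path) -> TrialRecording:
    """Read a trial written by :func:`write_trial`; validates channels."""
    stem = Path(stem)
    kin, kin_hdr = _read_stream(_part(stem, "kin"))
    emg, emg_hdr = _read_stream(_part(stem, "emg"))
    missing = [lm for lm in LANDMARKS if lm not in kin.columns]
    if missing:
        raise DataFormatError(
            "missing required kinematic channel(s): " + ", ".join(repr(m) for m in missing)
        )
    unknown = [c for c in emg.columns if c not in emg_channels()]
    if unknown:
        raise DataFormatError(f"unknown sEMG channel(s): {unknown}")
    events = None
    if "events_left" in kin_hdr and "events_right" in kin_hdr:
        events = {
            limb: np.array(
                [float(v) for v in kin_hdr[f"events_{limb}"].split(",") if v], float
            )
            for limb in ("left", "right")
        }
    rec = TrialRecording(
        horse_id=kin_hdr["horse_id"],
        condition=kin_hdr["condition"],
        induced_side=kin_hdr["induced_side"],
        kin=kin,
        emg=emg,
        kin_hz=float(kin_hdr["sampling_hz"]),
        emg_hz=float(emg_hdr["sampling_hz"]),
        t0=float(kin_hdr.get("t0", 0.0)),
        events=events,
    )
    return rec.validate()


def write_ground_truth(truth, stem: str | Path, overwrite: bool = False) -> Path:
    """JSON sidecar (``<stem>.truth.json``) with the generator's ground truth."""
    path = Path(f"{stem}.truth.json")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    payload = {
        "horse_id": truth.horse_id,
        "condition": truth.condition,
        "induced_side": truth.induced_side,
        "stride_frequency_hz": truth.stride_frequency_hz,
        "impacts_left": list(map(float, truth.impacts_left)),
        "impacts_right": list(map(float, truth.impacts_right)),
        "injected_asymmetry_mm": truth.injected_asymmetry_mm,
        "realized_min_diff_mm": truth.realized_min_diff_mm,
        "muscle_factors": truth.muscle_factors,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_cohort(directory: str | Path) -> list[TrialRecording]:
    """Read every ``*.kin.csv``/``*.emg.csv`` trial pair in a directory."""
    directory = Path(directory)
    stems = sorted(p.with_suffix("") for p in directory.glob("*.kin.csv"))
    stems = [Path(str(s)[: -len(".kin")]) for s in stems]
    if not stems:
        raise DataFormatError(f"no trial files found in {directory}")
    return [read_trial(s) for s in stems]


def load_yaml_config(path: str | Path) -> dict:
    """Read a run-configuration mapping from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: expected a mapping at top level")
    return data
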