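"""Core containers and vocabulary for synchronized gait + sEMG trials.

A trial is one pass of one horse under one experimental condition:
vertical displacement of upper-body and hind-hoof markers sampled at a
kinematic rate (default 200 Hz), and bilateral surface-EMG channels for
seven superficial muscles sampled at an sEMG rate (default 2000 Hz).
Both streams share the same time origin (hardware-synchronized capture).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

#: Required kinematic channels (vertical displacement, mm, positive up).
LANDMARKS = (
    "poll",
    "withers",
    "pelvis",
    "tuber_coxae_left",
    "tuber_coxae_right",
    "hoof_hind_left",
    "hoof_hind_right",
)

#: Midline landmarks used for MinDiff/MaxDiff.
UPPER_BODY = ("poll", "withers", "pelvis")

#: Bilaterally recorded superficial muscles.
MUSCLES = (
    "latissimus",
    "triceps",
    "biceps",
    "gluteal",
    "semitendinosus",
    "longissimus_T14",
    "longissimus_L1",
)

SIDES = ("left", "right")

#: Experimental conditions: two measurement days, each a baseline trot
#: followed by an induced lameness (fore- or hindlimb).
CONDITIONS = ("baseline1", "iFL", "baseline2", "iHL")
INDUCTIONS = ("iFL", "iHL")
#: Baseline condition paired with each induction (same measurement day).
BASELINE_OF = {"iFL": "baseline1", "iHL": "baseline2"}
#: Measurement session (day) of each condition.
SESSION_OF = {"baseline1": 1, "iFL": 1, "baseline2": 2, "iHL": 2}

INDUCED_SIDES = ("left", "right", "none")


class EquigaitError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(EquigaitError):
    """Invalid configuration value (rates, thresholds, filter settings)."""


class DataFormatError(EquigaitError):
    """Malformed or inconsistent on-disk trial data."""


class InsufficientDataError(EquigaitError):
    """Not enough samples/events/strides to compute the requested quantity."""


def emg_channel(muscle: str, side: str) -> str:
    """Canonical column name of one sEMG channel."""
    return f"{muscle}_{side}"


def emg_channels() -> list[str]:
    return [emg_channel(m, s) for m in MUSCLES for s in SIDES]


@dataclass
class TrialRecording:
    """Synchronized kinematic and sEMG streams for one trial.

    ``kin`` holds one column per landmark (mm, positive up) at ``kin_hz``;
    ``emg`` one column per ``muscle_side`` channel (arbitrary units) at
    ``emg_hz``. ``events`` optionally carries externally supplied hindlimb
    impact times (seconds), bypassing detection downstream.
    """

    horse_id: str
    condition: str
    induced_side: str
    kin: pd.DataFrame
    emg: pd.DataFrame
    kin_hz: float
    emg_hz: float
    t0: float = 0.0
    events: Mapping[str, np.ndarray] | None = None

    def validate(self) -> "TrialRecording":
        if self.condition not in CONDITIONS:
            raise DataFormatError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.induced_side not in INDUCED_SIDES:
            raise DataFormatError(f"unknown induced side {self.induced_side!r}")
        if self.kin_hz <= 0 or self.emg_hz <= 0:
            raise ConfigurationError("sampling rates must be positive")
        missing = [lm for lm in LANDMARKS if lm not in self.kin.columns]
        if missing:
            raise DataFormatError(
                f"missing required kinematic channel(s): {', '.join(missing)}"
            )
        valid_emg = set(emg_channels())
        unknown = [c for c in self.emg.columns if c not in valid_emg]
        if unknown:
            raise DataFormatError(f"unknown sEMG channel(s): {', '.join(unknown)}")
        if len(self.emg.columns) == 0:
            raise DataFormatError("trial has no sEMG channels")
        return self

    # -- time axes -------------------------------------------------------
    def kin_time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.kin)) / self.kin_hz

    def emg_time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.emg)) / self.emg_hz

    @property
    def duration(self) -> float:
        return len(self.kin) / self.kin_hz


def _swap_side(name: str) -> str:
    if name.endswith("_left"):
        return name[: -len("_left")] + "_right"
    if name.endswith("_right"):
        return name[: -len("_right")] + "_left"
    return name


def mirror_recording(rec: TrialRecording) -> TrialRecording:
    """Left-right mirror of a trial.

    Swaps every left/right-labelled channel (hooves, tubera coxae, sEMG
    sides) and flips the induced side; midline channels are untouched.
    Used to express that all asymmetry indices are odd under reflection.
    """
    kin = rec.kin.rename(columns=_swap_side)[list(rec.kin.columns)]
    emg = rec.emg.rename(columns=_swap_side)[list(rec.emg.columns)]
    flipped = {"left": "right", "right": "left", "none": "none"}[rec.induced_side]
    events = None
    if rec.events is not None:
        events = {
            "left": np.asarray(rec.events["right"], float),
            "right": np.asarray(rec.events["left"], float),
        }
    return replace(rec, kin=kin, emg=emg, induced_side=flipped, events=events)
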