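"""Hindlimb impact detection and stride segmentation.

Impacts are detected from hind-hoof vertical position: a downward crossing
of a height threshold (10% of the channel's range above its per-trial
minimum) with negative velocity, refined to the first sample entering the
stance plateau, debounced at 60% of the running stride period. A crossing
not followed by an actual stance dwell (e.g. a recording truncated at
touch-down) is not emitted.

Strides are half-open windows between successive impacts of one reference
limb: ipsilateral segmentation for side-specific sEMG parameters, left-
hindlimb segmentation for asymmetry parameters (so left and right share
one temporal domain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, TrialRecording

__all__ = [
    "GaitEvents",
    "Stride",
    "detect_hind_impacts",
    "segment_strides",
    "stride_frequency",
]


@dataclass
class GaitEvents:
    """Strictly increasing hindlimb impact times per limb (seconds)."""

    impacts_left: np.ndarray
    impacts_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("impacts_left", "impacts_right"):
            arr = np.asarray(getattr(self, name), float)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, arr)

    def impacts(self, limb: str) -> np.ndarray:
        if limb not in ("left", "right"):
            raise ValueError(f"unknown limb {limb!r}")
        return self.impacts_left if limb == "left" else self.impacts_right


@dataclass(frozen=True)
class Stride:
    """Half-open stride window [start, end) referenced to one hindlimb."""

    start: float
    end: float
    reference_limb: str
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("stride end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _detect_one(z: np.ndarray, fs: float, t0: float, limb: str) -> np.ndarray:
    z = np.asarray(z, float)
    lo, hi = z.min(), z.max()
    span = hi - lo
    if span < 5.0:  # mm; essentially flat channel = no locomotion
        raise InsufficientDataError(
            f"hoof_hind_{limb}: no locomotion detected (range {span:.2f} mm)"
        )
    thr = lo + 0.10 * span
    plateau = lo + 0.02 * span

    below = z < thr
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    if crossings.size == 0:
        raise InsufficientDataError(f"hoof_hind_{limb}: no threshold crossings")

    gaps = np.diff(crossings)
    median_gap = float(np.median(gaps)) if gaps.size else len(z)
    dwell = max(int(0.10 * median_gap), 2)

    impacts_idx = []
    last = -np.inf
    for c in crossings:
        if c - last < 0.6 * median_gap:
            continue
        # negative velocity at the crossing
        if z[c] >= z[c - 1]:
            continue
        # refine: first sample entering the stance plateau
        window_end = min(c + max(int(0.5 * median_gap), dwell), len(z))
        seg = z[c:window_end]
        hit = np.flatnonzero(seg <= plateau)
        if hit.size == 0:
            continue  # never reached stance (e.g. truncated contact)
        i = c + int(hit[0])
        # require an actual stance dwell below the threshold
        if i + dwell > len(z) or np.any(z[i : i + dwell] >= thr):
            continue
        impacts_idx.append(i)
        last = c
    if len(impacts_idx) < 3:
        raise InsufficientDataError(
            f"hoof_hind_{limb}: only {len(impacts_idx)} impacts detected (need >= 3)"
        )
    return t0 + np.asarray(impacts_idx, float) / fs


def detect_hind_impacts(rec: TrialRecording) -> GaitEvents:
    """Detect hindlimb impacts, or pass through externally supplied events."""
    if rec.events is not None:
        return GaitEvents(
            impacts_left=np.asarray(rec.events["left"], float),
            impacts_right=np.asarray(rec.events["right"], float),
        )
    left = _detect_one(rec.kin["hoof_hind_left"].to_numpy(), rec.kin_hz, rec.t0, "left")
    right = _detect_one(
        rec.kin["hoof_hind_right"].to_numpy(), rec.kin_hz, rec.t0, "right"
    )
    return GaitEvents(impacts_left=left, impacts_right=right)


def segment_strides(events: GaitEvents, reference_limb: str) -> list[Stride]:
    """Contiguous half-open strides between successive reference-limb impacts."""
    imp = events.impacts(reference_limb)
    if imp.size < 2:
        raise InsufficientDataError(
            f"need >= 2 {reference_limb} impacts to segment strides, got {imp.size}"
        )
    return [
        Stride(start=float(imp[k]), end=float(imp[k + 1]),
               reference_limb=reference_limb, index=k)
        for k in range(imp.size - 1)
    ]


def stride_frequency(strides: list[Stride]) -> float:
    """Reciprocal of the median stride duration (strides/s)."""
    if not strides:
        raise InsufficientDataError("no strides")
    durations = np.array([s.duration for s in strides])
    return float(1.0 / np.median(durations))
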