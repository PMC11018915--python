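"""Upper-body movement asymmetry: MinDiff, MaxDiff and Hip Hike.

At trot the vertical displacement of midline landmarks (poll, withers,
pelvis) oscillates twice per stride; a unilateral lameness makes the two
per-stride minima (MinDiff) and maxima (MaxDiff) unequal. Hip Hike is the
left-right difference in tuber coxae vertical range within each limb's
stance and swing windows. All indices follow the convention that a
positive value means the left-associated quantity is larger, so they are
odd under left-right mirroring of the trial.

Displacement is high-pass filtered (zero-phase 4th-order Butterworth)
with a cut-off adapted to the measured stride frequency, removing body-
height drift while preserving both the double-oscillation (2f) and the
asymmetry component (f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    ConfigurationError,
    InsufficientDataError,
    TrialRecording,
)
from .events import GaitEvents, Stride

__all__ = [
    "adaptive_highpass",
    "min_max_diff",
    "hip_hike",
    "stride_asymmetry_table",
    "InductionCheck",
    "induction_sufficient",
    "InvalidStrideError",
]

#: Default cut-off as a fraction of stride frequency.
CUTOFF_FACTOR = 0.5
#: Asymmetry columns of a stride table.
ASYM_COLUMNS = (
    "min_diff_poll",
    "min_diff_withers",
    "min_diff_pelvis",
    "max_diff_poll",
    "max_diff_withers",
    "max_diff_pelvis",
    "hip_hike_stance",
    "hip_hike_swing",
)


class InvalidStrideError(InsufficientDataError):
    """Stride lacks the extrema/events needed for an asymmetry index."""


def adaptive_highpass(
    series: np.ndarray,
    sampling_hz: float,
    stride_freq: float,
    cutoff_factor: float = CUTOFF_FACTOR,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass at ``cutoff_factor * stride_freq``."""
    if stride_freq <= 0:
        raise ConfigurationError("stride frequency must be positive")
    cutoff = cutoff_factor * stride_freq
    if cutoff >= sampling_hz / 2:
        raise ConfigurationError(
            f"cut-off {cutoff:.3g} Hz is at/above Nyquist ({sampling_hz / 2:.3g} Hz)"
        )
    x = np.asarray(series, float)
    sos = sps.butter(order, cutoff, btype="highpass", fs=sampling_hz, output="sos")
    try:
        return sps.sosfiltfilt(sos, x)
    except ValueError as exc:  # series shorter than the filter warm-up
        raise InsufficientDataError(f"series too short to filter: {exc}") from exc


def _has_interior_extrema(x: np.ndarray) -> bool:
    d = np.sign(np.diff(x))
    d = d[d != 0]
    if d.size < 2:
        return False
    turns = np.diff(d)
    return bool(np.any(turns > 0) and np.any(turns < 0))


def min_max_diff(stride_series: np.ndarray) -> tuple[float, float]:
    """Per-stride (MinDiff, MaxDiff): first-half extremum minus second-half.

    Halves are split at the stride's time midpoint. A stride whose halves
    do not each contain an interior local minimum and maximum (flat or
    aperiodic displacement) raises :class:`InvalidStrideError` and should
    be dropped downstream.
    """
    x = np.asarray(stride_series, float)
    if x.size < 8:
        raise InvalidStrideError("stride too short for extrema analysis")
    mid = x.size // 2
    first, second = x[:mid], x[mid:]
    if not (_has_interior_extrema(first) and _has_interior_extrema(second)):
        raise InvalidStrideError("stride lacks two local minima/maxima")
    min_diff = float(first.min() - second.min())
    max_diff = float(first.max() - second.max())
    return min_diff, max_diff


def _window_slice(t0: float, fs: float, n: int, start: float, end: float) -> slice:
    i0 = int(np.ceil((start - t0) * fs - 1e-9))
    i1 = int(np.ceil((end - t0) * fs - 1e-9))
    i0, i1 = max(i0, 0), min(i1, n)
    if i1 <= i0:
        raise InvalidStrideError("empty sample window")
    return slice(i0, i1)


def hip_hike(
    left_tc: np.ndarray,
    right_tc: np.ndarray,
    stride: Stride,
    events: GaitEvents,
    sampling_hz: float,
    t0: float = 0.0,
) -> tuple[float, float]:
    """(HipHike_stance, HipHike_swing) for one left-referenced stride.

    Each limb's stance/swing windows are split at the contralateral
    impact: left stance = [left impact, right impact), left swing =
    [right impact, next left impact), and symmetrically for the right
    limb (its swing extends to the following right impact). The index is
    the left minus right tuber coxae (max - min) amplitude per window.
    """
    lt = np.asarray(left_tc, float)
    rt = np.asarray(right_tc, float)
    n = lt.size
    right_imp = events.impacts("right")
    inside = right_imp[(right_imp > stride.start) & (right_imp < stride.end)]
    if inside.size == 0:
        raise InvalidStrideError("no contralateral impact inside stride")
    r = float(inside[0])
    nxt = right_imp[right_imp >= stride.end]
    if nxt.size == 0:
        raise InvalidStrideError("no contralateral impact after stride end")
    r_next = float(nxt[0])

    def amp(x: np.ndarray, a: float, b: float) -> float:
        seg = x[_window_slice(t0, sampling_hz, n, a, b)]
        return float(seg.max() - seg.min())

    stance = amp(lt, stride.start, r) - amp(rt, r, stride.end)
    swing = amp(lt, r, stride.end) - amp(rt, stride.end, r_next)
    return stance, swing


def stride_asymmetry_table(
    rec: TrialRecording,
    events: GaitEvents,
    strides: list[Stride],
    stride_freq: float,
    cutoff_factor: float = CUTOFF_FACTOR,
) -> tuple[pd.DataFrame, int]:
    """Per-stride asymmetry indices for a left-referenced stride list.

    Returns the table of valid strides and the count of strides dropped
    for missing extrema or events.
    """
    fs = rec.kin_hz
    filt = {
        lm: adaptive_highpass(rec.kin[lm].to_numpy(), fs, stride_freq, cutoff_factor)
        for lm in ("poll", "withers", "pelvis", "tuber_coxae_left", "tuber_coxae_right")
    }
    n = len(rec.kin)
    rows = []
    n_invalid = 0
    for stride in strides:
        try:
            sl = _window_slice(rec.t0, fs, n, stride.start, stride.end)
            row: dict[str, float] = {"stride": stride.index}
            for lm in ("poll", "withers", "pelvis"):
                mn, mx = min_max_diff(filt[lm][sl])
                row[f"min_diff_{lm}"] = mn
                row[f"max_diff_{lm}"] = mx
            hh_stance, hh_swing = hip_hike(
                filt["tuber_coxae_left"],
                filt["tuber_coxae_right"],
                stride,
                events,
                fs,
                rec.t0,
            )
            row["hip_hike_stance"] = hh_stance
            row["hip_hike_swing"] = hh_swing
        except InvalidStrideError:
            n_invalid += 1
            continue
        rows.append(row)
    cols = ["stride", *ASYM_COLUMNS]
    df = pd.DataFrame(rows, columns=cols)
    return df, n_invalid


@dataclass(frozen=True)
class InductionCheck:
    """Outcome of the lameness-induction sufficiency rule."""

    limb: str  # "fore" or "hind"
    delta_head_mm: float
    delta_pelvis_mm: float
    sd_ok: bool
    sufficient: bool


_RULE = {
    "fore": (("min_diff_poll", "max_diff_poll"), 13.0),
    "hind": (("min_diff_pelvis", "max_diff_pelvis"), 5.0),
}


def induction_sufficient(
    baseline: pd.DataFrame,
    induced: pd.DataFrame,
    limb: str,
    head_threshold_mm: float = 13.0,
    pelvis_threshold_mm: float = 5.0,
) -> InductionCheck:
    """Was the induced asymmetry change large and consistent enough?

    The change (|mean induced - mean baseline|) of the relevant head or
    pelvis parameter must reach its reference value (13 mm head for a
    forelimb induction, 5 mm pelvis for a hindlimb one) with the induced
    condition's SD smaller than its mean magnitude for the triggering
    parameter.
    """
    if limb not in _RULE:
        raise ConfigurationError(f"limb must be 'fore' or 'hind', got {limb!r}")
    params, _ = _RULE[limb]
    threshold = head_threshold_mm if limb == "fore" else pelvis_threshold_mm
    if len(baseline) < 2 or len(induced) < 2:
        raise InsufficientDataError("need >= 2 strides per condition")

    deltas = {}
    sufficient = False
    sd_ok_any = False
    for p in params:
        delta = abs(float(induced[p].mean()) - float(baseline[p].mean()))
        deltas[p] = delta
        sd_ok = float(induced[p].std(ddof=1)) < abs(float(induced[p].mean()))
        if delta >= threshold and sd_ok:
            sufficient = True
        if delta >= threshold:
            sd_ok_any = sd_ok_any or sd_ok
    best = max(deltas.values())
    head = best if limb == "fore" else _pair_delta(baseline, induced, "fore")
    pelvis = best if limb == "hind" else _pair_delta(baseline, induced, "hind")
    return InductionCheck(
        limb=limb,
        delta_head_mm=head,
        delta_pelvis_mm=pelvis,
        sd_ok=sd_ok_any if best >= threshold else False,
        sufficient=sufficient,
    )


def _pair_delta(baseline: pd.DataFrame, induced: pd.DataFrame, limb: str) -> float:
    params, _ = _RULE[limb]
    return max(
        abs(float(induced[p].mean()) - float(baseline[p].mean())) for p in params
    )
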