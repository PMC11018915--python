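"""Synthetic trotting-horse trials with known, injected lameness effects.

The generator emulates the study design this package analyses: a cohort of
horses measured on two days, each day a non-lame baseline trot followed by
an induced fore- (iFL) or hindlimb (iHL) lameness trial, with the induced
side balanced across the cohort.

Signal model per trial (all components seeded and deterministic):

* Upper-body vertical displacement of midline landmarks (poll, withers,
  pelvis) is the classic double oscillation of trot at twice the stride
  frequency ``f``, plus a controlled component at ``f`` that offsets the
  two per-stride minima by the injected asymmetry (and the maxima by 0.6
  of it), plus slow body-height drift and white measurement noise.
* Left/right tubera coxae oscillate at ``2f`` with an amplitude split
  proportional to the injected hip-hike asymmetry.
* Hind hooves alternate half-sine swing arcs with zero-height stance
  plateaus; the swing-to-stance transition defines ground-truth impacts.
* Each sEMG channel is ``dc_offset + scale * envelope(stride phase) *
  carrier`` where the carrier is band-limited (20-450 Hz) Gaussian noise
  and the envelope is a muscle-specific Gaussian burst per stride. The
  burst amplitude carries lognormal stride-to-stride variability; the
  per-condition ``muscle_scale`` factor is the injected lameness effect.

Stride-to-stride sEMG amplitude multipliers are drawn per (horse, muscle,
side, stride index), independent of condition, so condition contrasts of
mean ARV equal the injected scale factor exactly while per-class marginal
distributions (all that ROC analysis sees) are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    CONDITIONS,
    ConfigurationError,
    INDUCTIONS,
    LANDMARKS,
    MUSCLES,
    SIDES,
    TrialRecording,
    emg_channel,
)

__all__ = ["SimConfig", "SimGroundTruth", "generate_trial", "generate_cohort"]

#: Fraction of the stride after ipsilateral impact at which the first
#: displacement minimum occurs (minima are interior to each half-stride).
_MIN_PHASE = 0.12
#: Hind-hoof swing arc height (mm) and stance duty factor at trot.
_SWING_HEIGHT_MM = 80.0
_STANCE_DUTY = 0.45
#: Stride phase of each muscle's activation burst (ipsilateral hind cycle).
_MUSCLE_PHASE = {
    "latissimus": 0.20,
    "triceps": 0.10,
    "biceps": 0.55,
    "gluteal": 0.05,
    "semitendinosus": 0.62,
    "longissimus_T14": 0.30,
    "longissimus_L1": 0.35,
}
_BURST_WIDTH = 0.08  # gaussian sigma in stride-phase units
_TONIC_LEVEL = 0.25  # envelope floor relative to burst peak

_DEF_AMPLITUDE = {"poll": 45.0, "withers": 25.0, "pelvis": 35.0, "tuber_coxae": 30.0}

# Injected min-to-min asymmetry magnitudes (mm) per condition. Baselines
# are symmetric; iFL is dominated by head nod, iHL by pelvis drop and hip
# hike, with smaller compensatory components elsewhere.
_DEF_ASYMMETRY = {
    "baseline1": {},
    "baseline2": {},
    "iFL": {"poll": 25.0, "withers": 8.0, "pelvis": 2.0, "tuber_coxae": 2.0},
    "iHL": {"poll": 5.0, "withers": 6.0, "pelvis": 10.0, "tuber_coxae": 14.0},
}

# Per-(muscle, role, condition) sEMG amplitude factors, role being the
# lame (LS, ipsilateral to induction) or non-lame (NLS) side. Hindlimb
# induction drives a strong non-lame-side biceps increase and lame-side
# gluteal/semitendinosus increases; other muscles rise mildly and mostly
# bilaterally. Forelimb induction produces smaller, triceps-led changes.
_DEF_MUSCLE_SCALE = {
    "iFL": {
        ("triceps", "NLS"): 1.25,
        ("triceps", "LS"): 1.20,
        ("biceps", "NLS"): 1.20,
        ("biceps", "LS"): 1.05,
        ("semitendinosus", "NLS"): 1.20,
        ("semitendinosus", "LS"): 1.05,
        ("gluteal", "NLS"): 1.05,
        ("gluteal", "LS"): 1.05,
        ("latissimus", "NLS"): 1.10,
        ("latissimus", "LS"): 1.10,
        ("longissimus_T14", "NLS"): 1.05,
        ("longissimus_T14", "LS"): 1.05,
        ("longissimus_L1", "NLS"): 1.05,
        ("longissimus_L1", "LS"): 1.05,
    },
    "iHL": {
        ("biceps", "NLS"): 1.50,
        ("biceps", "LS"): 1.15,
        ("gluteal", "LS"): 1.40,
        ("gluteal", "NLS"): 1.10,
        ("semitendinosus", "LS"): 1.40,
        ("semitendinosus", "NLS"): 1.10,
        ("longissimus_T14", "LS"): 1.15,
        ("longissimus_T14", "NLS"): 1.10,
        ("longissimus_L1", "LS"): 1.10,
        ("longissimus_L1", "NLS"): 1.05,
        ("triceps", "LS"): 1.15,
        ("triceps", "NLS"): 1.15,
        ("latissimus", "LS"): 1.10,
        ("latissimus", "NLS"): 1.10,
    },
}

_COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``asymmetry_mm`` maps condition -> landmark-group -> injected
    min-to-min offset magnitude (mm); ``muscle_scale`` maps condition ->
    (muscle, LS/NLS role) -> amplitude factor (unlisted entries are 1).
    The same seed always yields a bit-identical cohort.
    """

    n_horses: int = 8
    strides_per_trial: int = 25
    stride_frequency_hz: float | None = None  # fixed rate; None -> per-horse draw
    stride_frequency_range: tuple[float, float] = (1.3, 1.6)
    kin_sampling_hz: float = 200.0
    emg_sampling_hz: float = 2000.0
    displacement_amplitude_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_AMPLITUDE)
    )
    asymmetry_mm: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEF_ASYMMETRY.items()}
    )
    muscle_scale: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEF_MUSCLE_SCALE.items()}
    )
    emg_noise_sd: float = 1.0
    emg_stride_cv: float = 0.15  # lognormal sigma of per-stride burst amplitude
    dc_offset: float = 0.2
    kin_noise_sd_mm: float = 0.5
    kin_stride_jitter_mm: float = 1.5  # per-stride SD of the asymmetry component
    drift_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kin_sampling_hz <= 0 or self.emg_sampling_hz <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.strides_per_trial < 2:
            raise ConfigurationError("strides_per_trial must be >= 2")
        if self.n_horses < 1:
            raise ConfigurationError("n_horses must be >= 1")
        lo, hi = self.stride_frequency_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("invalid stride_frequency_range")
        if self.stride_frequency_hz is not None and self.stride_frequency_hz <= 0:
            raise ConfigurationError("stride_frequency_hz must be positive")
        for lm, amp in self.displacement_amplitude_mm.items():
            if amp <= 0:
                raise ConfigurationError(f"non-positive amplitude for {lm!r}")
        if self.emg_noise_sd <= 0:
            raise ConfigurationError("emg_noise_sd must be positive")
        for cond, scales in self.muscle_scale.items():
            for key, s in scales.items():
                if s <= 0:
                    raise ConfigurationError(f"non-positive muscle scale {key} ({cond})")


@dataclass
class SimGroundTruth:
    """Known quantities behind one generated trial (test oracle plumbing)."""

    horse_id: str
    condition: str
    induced_side: str
    stride_frequency_hz: float
    impacts_left: np.ndarray  # seconds, strictly increasing
    impacts_right: np.ndarray
    injected_asymmetry_mm: dict[str, float]  # signed, per landmark group
    realized_min_diff_mm: dict[str, float]  # numeric oracle on noise-free midline
    muscle_factors: dict[str, float]  # channel name -> amplitude factor


def induced_sides(config: SimConfig) -> list[str]:
    """Deterministic, balanced left/right induction assignment per horse."""
    n = config.n_horses
    if n % 2:
        warnings.warn(
            "odd n_horses: left/right induction assignment cannot be balanced",
            stacklevel=2,
        )
    sides = ["left"] * ((n + 1) // 2) + ["right"] * (n // 2)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51DE]))
    return [sides[i] for i in rng.permutation(n)]


def _horse_frequency(config: SimConfig, horse_index: int) -> float:
    if config.stride_frequency_hz is not None:
        return float(config.stride_frequency_hz)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, horse_index, 0xF0]))
    lo, hi = config.stride_frequency_range
    return float(rng.uniform(lo, hi))


def _stride_multipliers(
    config: SimConfig, horse_index: int, muscle: str, side: str, n: int
) -> np.ndarray:
    """Lognormal per-stride burst amplitude multipliers, condition-independent."""
    key = [config.seed, horse_index, 0xE9, MUSCLES.index(muscle), SIDES.index(side)]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    return np.exp(config.emg_stride_cv * rng.standard_normal(n))


def _kin_stride_values(
    rng: np.random.Generator, base: float, jitter: float, n: int
) -> np.ndarray:
    # stride-to-stride variation around the trial's injected asymmetry;
    # centred within the trial so the null stays calibrated at AUC 0.5
    dev = jitter * rng.standard_normal(n)
    if n > 1:
        dev -= dev.mean()
    return base + dev


def _interp_nodes(t: np.ndarray, node_t: np.ndarray, node_v: np.ndarray) -> np.ndarray:
    return np.interp(t, node_t, node_v)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return sd * x / x.std()


def _role_of(side: str, induced_side: str) -> str:
    return "LS" if side == induced_side else "NLS"


def _signed_asym(magnitude: float, induced_side: str) -> float:
    # Left inductions read negative under the "positive = left larger"
    # convention; right inductions positive (they are negated at the
    # mirroring stage downstream).
    if induced_side == "right":
        return magnitude
    return -magnitude


def _midline_clean(
    t: np.ndarray, f: float, t_start: float, amp: float, a_t: np.ndarray
) -> np.ndarray:
    """Noise-free midline displacement given a time-varying asymmetry a(t)."""
    tau = t - t_start - _MIN_PHASE / f
    base = -amp * np.cos(4 * np.pi * f * tau)
    asym = 0.5 * a_t * np.cos(2 * np.pi * f * tau) + 0.3 * a_t * np.sin(
        2 * np.pi * f * tau
    )
    return base + asym


def _oracle_min_diff(
    f: float, kin_hz: float, t_start: float, amp: float, a: float
) -> float:
    """Numeric first-half-min minus second-half-min on one clean stride."""
    n = max(int(round(kin_hz / f)), 8)
    t = t_start + np.arange(n) / kin_hz
    z = _midline_clean(t, f, t_start, amp, np.full(n, a))
    mid = n // 2
    return float(z[:mid].min() - z[mid:].min())


def _hoof_height(t: np.ndarray, impacts: np.ndarray, f: float) -> np.ndarray:
    """Half-sine swing arcs with zero-height stance plateaus."""
    period = 1.0 / f
    stance = _STANCE_DUTY * period
    z = np.zeros_like(t)
    # swing between liftoff (impact + stance) and the next impact
    lifts = impacts + stance
    for k in range(len(impacts)):
        start = lifts[k]
        end = impacts[k + 1] if k + 1 < len(impacts) else None
        if end is None:
            break
        m = (t >= start) & (t < end)
        z[m] = _SWING_HEIGHT_MM * np.sin(np.pi * (t[m] - start) / (end - start))
    # before the first impact: the tail of a swing arc landing into it
    dur = period - stance
    m = (t >= impacts[0] - dur) & (t < impacts[0])
    if m.any():
        z[m] = _SWING_HEIGHT_MM * np.clip(
            np.sin(np.pi * (t[m] - (impacts[0] - dur)) / dur), 0.0, None
        )
    return z


def generate_trial(
    config: SimConfig,
    horse_index: int,
    condition: str,
    induced_side: str | None = None,
) -> tuple[TrialRecording, SimGroundTruth]:
    """Generate one synchronized trial plus its ground truth.

    ``induced_side`` defaults to the cohort's deterministic balanced
    assignment for this horse; it only affects induced conditions.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if not 0 <= horse_index < config.n_horses:
        raise ConfigurationError("horse_index out of range")
    if induced_side is None:
        induced_side = induced_sides(config)[horse_index]
    horse_id = f"H{horse_index + 1:02d}"
    is_induced = condition in INDUCTIONS
    trial_side = induced_side if is_induced else "none"

    f = _horse_frequency(config, horse_index)
    period = 1.0 / f
    n_strides = config.strides_per_trial
    t_start = period  # lead-in margin
    impacts_left = t_start + np.arange(n_strides + 2) / f
    impacts_right = impacts_left + 0.5 * period
    duration = t_start + (n_strides + 3) * period

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, horse_index, _COND_INDEX[condition], 0xA1])
    )

    # ---------------- kinematics ----------------
    n_kin = int(round(duration * config.kin_sampling_hz))
    t = np.arange(n_kin) / config.kin_sampling_hz
    kin = {}
    asym_cfg = config.asymmetry_mm.get(condition, {})
    injected: dict[str, float] = {}
    realized: dict[str, float] = {}

    node_t = t_start + (np.arange(n_strides + 2) + 0.5) / f
    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = config.drift_mm * np.sin(2 * np.pi * 0.07 * t + drift_phase)

    for lm in ("poll", "withers", "pelvis"):
        amp = config.displacement_amplitude_mm[lm]
        a = _signed_asym(float(asym_cfg.get(lm, 0.0)), induced_side) if is_induced else 0.0
        injected[lm] = a
        nodes = _kin_stride_values(rng, a, config.kin_stride_jitter_mm, len(node_t))
        a_t = _interp_nodes(t, node_t, nodes)
        z = _midline_clean(t, f, t_start, amp, a_t)
        z += drift + config.kin_noise_sd_mm * rng.standard_normal(n_kin)
        kin[lm] = z
        realized[lm] = _oracle_min_diff(f, config.kin_sampling_hz, t_start, amp, a)

    amp_tc = config.displacement_amplitude_mm.get("tuber_coxae", 30.0)
    a_tc = (
        _signed_asym(float(asym_cfg.get("tuber_coxae", 0.0)), induced_side)
        if is_induced
        else 0.0
    )
    injected["tuber_coxae"] = a_tc
    nodes_tc = _kin_stride_values(rng, a_tc, config.kin_stride_jitter_mm, len(node_t))
    a_tc_t = _interp_nodes(t, node_t, nodes_tc)
    tau = t - t_start - _MIN_PHASE / f
    for side, sgn in (("left", +1.0), ("right", -1.0)):
        amp_side = amp_tc + sgn * a_tc_t / 4.0
        z = -amp_side * np.cos(4 * np.pi * f * tau)
        z += drift + config.kin_noise_sd_mm * rng.standard_normal(n_kin)
        kin[f"tuber_coxae_{side}"] = z

    for side, impacts in (("left", impacts_left), ("right", impacts_right)):
        z = _hoof_height(t, impacts, f)
        z += config.kin_noise_sd_mm * 0.6 * rng.standard_normal(n_kin)
        kin[f"hoof_hind_{side}"] = z

    kin_df = pd.DataFrame({lm: kin[lm] for lm in LANDMARKS})

    # ---------------- sEMG ----------------
    # identical stream durations: derive the sEMG length from the kinematic one
    n_emg = int(round(n_kin * config.emg_sampling_hz / config.kin_sampling_hz))
    te = np.arange(n_emg) / config.emg_sampling_hz
    scale_cfg = config.muscle_scale.get(condition, {})
    emg = {}
    factors: dict[str, float] = {}
    for muscle in MUSCLES:
        for side in SIDES:
            role = _role_of(side, induced_side)
            s = float(scale_cfg.get((muscle, role), 1.0)) if is_induced else 1.0
            factors[emg_channel(muscle, side)] = s
            offset = 0.0 if side == "left" else 0.5 * period
            phase = np.mod((te - t_start - offset) * f, 1.0)
            d = np.minimum(np.abs(phase - _MUSCLE_PHASE[muscle]),
                           1.0 - np.abs(phase - _MUSCLE_PHASE[muscle]))
            env = _TONIC_LEVEL + np.exp(-0.5 * (d / _BURST_WIDTH) ** 2)
            # per-stride amplitude multiplier, segmented on ipsilateral impacts
            imp = impacts_left if side == "left" else impacts_right
            mult = _stride_multipliers(config, horse_index, muscle, side, len(imp) + 1)
            idx = np.searchsorted(imp, te, side="right")
            carrier = _bandlimited_noise(rng, n_emg, config.emg_sampling_hz,
                                         config.emg_noise_sd)
            emg[emg_channel(muscle, side)] = (
                config.dc_offset + s * mult[idx] * env * carrier
            )
    emg_df = pd.DataFrame(emg)

    rec = TrialRecording(
        horse_id=horse_id,
        condition=condition,
        induced_side=trial_side,
        kin=kin_df,
        emg=emg_df,
        kin_hz=config.kin_sampling_hz,
        emg_hz=config.emg_sampling_hz,
    ).validate()
    truth = SimGroundTruth(
        horse_id=horse_id,
        condition=condition,
        induced_side=induced_side,
        stride_frequency_hz=f,
        impacts_left=impacts_left,
        impacts_right=impacts_right,
        injected_asymmetry_mm=injected,
        realized_min_diff_mm=realized,
        muscle_factors=factors,
    )
    return rec, truth


def generate_cohort(config: SimConfig) -> list[tuple[TrialRecording, SimGroundTruth]]:
    """All horses x 4 conditions, induced side balanced across horses."""
    sides = induced_sides(config)
    out = []
    for h in range(config.n_horses):
        for condition in CONDITIONS:
            out.append(generate_trial(config, h, condition, induced_side=sides[h]))
    return out
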