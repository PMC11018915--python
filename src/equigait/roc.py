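"""ROC/AUC/Youden classification of non-lame vs lame strides.

Each stride-level parameter (sEMGabs, sEMGasym, kinematic asymmetry
indices) is treated as a univariate classifier of baseline vs induced-
lameness strides, pooled across horses. Right-limb inductions are first
mirrored (signed indices negated, sEMGabs sides relabelled) so all data
read as left-limb inductions, and sEMGabs sides are renamed LS (lame
side, ipsilateral to induction) / NLS (non-lame side).

The ROC curve evaluates every midpoint between consecutive distinct
pooled values (plus infinite sentinels). The classification direction is
fixed a priori per parameter family — sEMGabs: lame above the cut-off;
signed asymmetry parameters (sEMGasym and kinematic): lame below, per the
left-induction sign convention — so AUC below 0.5 is possible and
reported as-is. The cut-off maximizes Youden's J = sensitivity +
specificity - 1; trapezoidal AUC equals the Mann-Whitney probability that
a random lame stride scores beyond a random baseline stride (ties count
half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BASELINE_OF,
    DataFormatError,
    InsufficientDataError,
    INDUCTIONS,
    MUSCLES,
)

__all__ = [
    "roc_curve",
    "auc",
    "youden_optimal",
    "interpret_auc",
    "mirror_parameters",
    "assign_roles",
    "parameter_names",
    "build_results_table",
    "ROCResult",
]

#: Fixed classification direction per parameter family.
DIRECTION = {"semg_abs": "greater", "semg_asym": "less", "kinematic": "less"}

#: Display names for the kinematic indices, in table order.
KINEMATIC_PARAMS = (
    ("min_diff_poll", "MinDiff Poll"),
    ("min_diff_withers", "MinDiff Withers"),
    ("min_diff_pelvis", "MinDiff Pelvis"),
    ("max_diff_poll", "MaxDiff Poll"),
    ("max_diff_withers", "MaxDiff Withers"),
    ("max_diff_pelvis", "MaxDiff Pelvis"),
    ("hip_hike_stance", "Hip Hike Stance"),
    ("hip_hike_swing", "Hip Hike Swing"),
)


def _as_arrays(baseline_values, lame_values) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(baseline_values, float)
    l = np.asarray(lame_values, float)
    if b.size == 0 or l.size == 0:
        raise InsufficientDataError("both classes need at least one value")
    return b, l


def roc_curve(baseline_values, lame_values, direction: str = "greater") -> pd.DataFrame:
    """(threshold, sensitivity, specificity) at every candidate cut-off.

    Thresholds are midpoints between consecutive distinct pooled values
    plus -inf/+inf sentinels. For ``direction='greater'`` a stride is
    called lame when its value exceeds the threshold; for ``'less'`` when
    it falls below.
    """
    if direction not in ("greater", "less"):
        raise DataFormatError(f"unknown direction {direction!r}")
    b, l = _as_arrays(baseline_values, lame_values)
    pooled = np.unique(np.concatenate([b, l]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    if direction == "greater":
        sens = np.array([(l > t).mean() for t in thresholds])
        spec = np.array([(b <= t).mean() for t in thresholds])
    else:
        sens = np.array([(l < t).mean() for t in thresholds])
        spec = np.array([(b >= t).mean() for t in thresholds])
    return pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )


def auc(baseline_values, lame_values, direction: str = "greater") -> float:
    """Trapezoidal area under the ROC curve in (1-specificity, sensitivity)."""
    curve = roc_curve(baseline_values, lame_values, direction)
    fpr = 1.0 - curve["specificity"].to_numpy()
    tpr = curve["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def youden_optimal(curve: pd.DataFrame) -> tuple[float, float, float]:
    """(cut-off, sensitivity, specificity) maximizing J = sens + spec - 1.

    Ties are broken by higher specificity, then by smaller |cut-off| (so
    finite midpoints beat the infinite sentinels).
    """
    if curve.empty:
        raise InsufficientDataError("empty ROC curve")
    j = curve["sensitivity"] + curve["specificity"] - 1.0
    best = curve.assign(j=j).sort_values(
        by=["j", "specificity", "threshold"],
        key=lambda col: np.abs(col) if col.name == "threshold" else col,
        ascending=[False, False, True],
    ).iloc[0]
    return float(best["threshold"]), float(best["sensitivity"]), float(best["specificity"])


def interpret_auc(value: float) -> str:
    """Discrimination band of an AUC value."""
    if not 0.0 <= value <= 1.0:
        raise DataFormatError(f"AUC {value} outside [0, 1]")
    if value >= 0.90:
        return "excellent"
    if value >= 0.80:
        return "good"
    if value >= 0.70:
        return "fair"
    if value >= 0.60:
        return "poor"
    return "chance"


# ---------------------------------------------------------------------------
# mirroring and table assembly
# ---------------------------------------------------------------------------

_SIDE_SWAP = {"left": "right", "right": "left"}


def mirror_parameters(samples: pd.DataFrame) -> pd.DataFrame:
    """Re-express right-limb inductions as left-limb ones.

    For rows whose horse had a right-side induction: signed parameters
    (kinematic, sEMGasym) are negated and sEMGabs side labels are swapped
    left<->right. Left-induction rows pass through. Applying the mirror
    twice restores the input.
    """
    required = {"family", "value", "induced_side", "class_label"}
    missing = required - set(samples.columns)
    if missing:
        raise DataFormatError(f"samples missing columns: {sorted(missing)}")
    bad = (samples["class_label"] == "lame") & (samples["induced_side"] == "none")
    if bad.any():
        raise DataFormatError("lame samples with induced_side='none'")
    out = samples.copy()
    right = out["induced_side"] == "right"
    signed = out["family"].isin(("semg_asym", "kinematic"))
    out.loc[right & signed, "value"] *= -1.0
    if "side" in out.columns:
        flip = right & (out["family"] == "semg_abs")
        out.loc[flip, "side"] = out.loc[flip, "side"].map(_SIDE_SWAP)
    return out


def assign_roles(samples: pd.DataFrame) -> pd.DataFrame:
    """Name parameters on mirrored (all-left-induction) samples.

    sEMGabs sides map to roles — left = LS (lame side), right = NLS — and
    every row gets its display parameter name.
    """
    out = samples.copy()
    names = np.empty(len(out), dtype=object)
    is_abs = out["family"] == "semg_abs"
    role = out.loc[is_abs, "side"].map({"left": "LS", "right": "NLS"})
    if role.isna().any():
        raise DataFormatError("sEMGabs rows need side labels 'left'/'right'")
    names[np.flatnonzero(is_abs)] = (
        "sEMGabs " + role + " " + out.loc[is_abs, "muscle"]
    ).to_numpy()
    is_asym = out["family"] == "semg_asym"
    names[np.flatnonzero(is_asym)] = ("sEMGasym " + out.loc[is_asym, "muscle"]).to_numpy()
    is_kin = out["family"] == "kinematic"
    if "parameter" in out.columns:
        names[np.flatnonzero(is_kin)] = out.loc[is_kin, "parameter"]
    out["parameter"] = names
    return out


def parameter_names() -> list[tuple[str, str]]:
    """(parameter, family) rows in canonical table order (29 per induction)."""
    rows = []
    for m in MUSCLES:
        rows.append((f"sEMGabs NLS {m}", "semg_abs"))
        rows.append((f"sEMGabs LS {m}", "semg_abs"))
    rows.extend((f"sEMGasym {m}", "semg_asym") for m in MUSCLES)
    rows.extend((name, "kinematic") for _, name in KINEMATIC_PARAMS)
    return rows


@dataclass(frozen=True)
class ROCResult:
    parameter: str
    induction: str
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    interpretation: str
    direction: str
    n_baseline: int
    n_lame: int


def build_results_table(samples: pd.DataFrame) -> pd.DataFrame:
    """One ROC row per parameter x induction (baseline1-iFL, baseline2-iHL).

    ``samples`` must already be mirrored and role-labelled, with columns
    parameter / family / condition / class_label / value.
    """
    rows = []
    for induction in INDUCTIONS:
        baseline_cond = BASELINE_OF[induction]
        subset = samples[samples["condition"].isin((baseline_cond, induction))]
        if subset.empty or induction not in set(subset["condition"]):
            raise DataFormatError(f"no samples for pairing {baseline_cond}/{induction}")
        for parameter, family in parameter_names():
            part = subset[subset["parameter"] == parameter]
            if part.empty:
                continue
            b = part.loc[part["class_label"] == "baseline", "value"].to_numpy()
            l = part.loc[part["class_label"] == "lame", "value"].to_numpy()
            direction = DIRECTION[family]
            curve = roc_curve(b, l, direction)
            area = auc(b, l, direction)
            cutoff, sens, spec = youden_optimal(curve)
            rows.append(
                ROCResult(
                    parameter=parameter,
                    induction=induction,
                    auc=area,
                    sensitivity=sens,
                    specificity=spec,
                    cutoff=cutoff,
                    interpretation=interpret_auc(area),
                    direction=direction,
                    n_baseline=int(b.size),
                    n_lame=int(l.size),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
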