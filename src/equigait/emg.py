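"""sEMG conditioning and stride-level amplitude parameters.

Raw sEMG is DC-offset removed, high-pass filtered (zero-phase 4th-order
Butterworth, 40 Hz cut-off) and full-wave rectified. The average rectified
value (ARV) over each stride quantifies amplitude; per horse, muscle, side
and condition, ARVs outside mean +/- 2 SD are discarded, and survivors are
normalized to the maximum ARV of the corresponding same-day baseline
condition (so baseline values peak at 100% and induced values may exceed
it).

Two stride-level parameters follow:

* ``sEMGabs`` — the normalized ARV of one muscle on one side, computed on
  strides segmented by that side's own (ipsilateral) hindlimb impacts.
* ``sEMGasym`` — left minus right normalized ARV within one muscle, on
  strides segmented by left-hindlimb impacts so both sides share one
  temporal domain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BASELINE_OF,
    ConfigurationError,
    DataFormatError,
    InsufficientDataError,
    SESSION_OF,
)
from .events import Stride

__all__ = [
    "preprocess_emg",
    "stride_arv",
    "remove_arv_outliers",
    "normalize_to_baseline_max",
    "semg_abs",
    "semg_asym",
]

logger = logging.getLogger(__name__)

#: Columns of an ARV record table.
ARV_COLUMNS = (
    "horse_id",
    "muscle",
    "side",
    "condition",
    "stride",
    "reference",
    "arv_raw",
)

DEFAULT_EMG_CUTOFF_HZ = 40.0


def preprocess_emg(
    raw: np.ndarray, sampling_hz: float, cutoff_hz: float = DEFAULT_EMG_CUTOFF_HZ
) -> np.ndarray:
    """DC removal, zero-phase 4th-order Butterworth high-pass, rectification."""
    if sampling_hz <= 2 * cutoff_hz:
        raise ConfigurationError(
            f"sampling rate {sampling_hz} Hz too low for a {cutoff_hz} Hz high-pass"
        )
    x = np.asarray(raw, float)
    x = x - x.mean()
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=sampling_hz, output="sos")
    try:
        y = sps.sosfiltfilt(sos, x)
    except ValueError as exc:
        raise InsufficientDataError(f"series too short to filter: {exc}") from exc
    return np.abs(y)


def stride_arv(
    rectified: np.ndarray, stride: Stride, sampling_hz: float, t0: float = 0.0
) -> float:
    """Arithmetic mean of the rectified signal over [start, end)."""
    x = np.asarray(rectified, float)
    i0 = int(np.ceil((stride.start - t0) * sampling_hz - 1e-9))
    i1 = int(np.ceil((stride.end - t0) * sampling_hz - 1e-9))
    i0, i1 = max(i0, 0), min(i1, x.size)
    if i1 <= i0:
        raise InsufficientDataError("stride window contains no samples")
    return float(x[i0:i1].mean())


def remove_arv_outliers(
    records: pd.DataFrame, sd_multiplier: float = 2.0, ddof: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass outlier removal within horse x muscle x side x condition.

    Limits are mean +/- ``sd_multiplier`` * SD of ``arv_raw``, computed on
    the whole group before any removal (sample SD by default). Groups
    smaller than 3 are kept untouched with a warning.
    """
    if records.empty:
        return records.copy(), records.iloc[0:0].copy()
    keys = ["horse_id", "muscle", "side", "condition"]
    if "reference" in records.columns:
        keys.append("reference")
    keep_mask = np.ones(len(records), dtype=bool)
    for name, grp in records.groupby(keys, sort=False):
        if len(grp) < 3:
            logger.warning("ARV group %s has <3 strides; outlier removal skipped", name)
            continue
        mean = grp["arv_raw"].mean()
        sd = grp["arv_raw"].std(ddof=ddof)
        lo, hi = mean - sd_multiplier * sd, mean + sd_multiplier * sd
        bad = (grp["arv_raw"] < lo) | (grp["arv_raw"] > hi)
        keep_mask[records.index.get_indexer(grp.index[bad])] = False
    kept = records.iloc[keep_mask].reset_index(drop=True)
    removed = records.iloc[~keep_mask].reset_index(drop=True)
    if len(removed):
        logger.info("removed %d ARV outliers of %d records", len(removed), len(records))
    return kept, removed


def normalize_to_baseline_max(records: pd.DataFrame) -> pd.DataFrame:
    """Set ``arv_norm`` = 100 * arv_raw / same-day baseline maximum.

    The reference is, per horse x muscle x side (and segmentation
    reference), the maximum surviving baseline ARV of the session the
    condition belongs to (baseline1 for day 1, baseline2 for day 2).
    """
    out = records.copy()
    out["arv_norm"] = np.nan
    keys = ["horse_id", "muscle", "side"]
    if "reference" in out.columns:
        keys.append("reference")
    for name, grp in out.groupby(keys, sort=False):
        for session in (1, 2):
            in_session = grp["condition"].map(SESSION_OF) == session
            if not in_session.any():
                continue
            baseline_cond = f"baseline{session}"
            base = grp.loc[in_session & (grp["condition"] == baseline_cond), "arv_raw"]
            if base.empty:
                raise DataFormatError(
                    f"no surviving {baseline_cond} strides for group {name}"
                )
            ref = float(base.max())
            if ref <= 0:
                raise DataFormatError(
                    f"non-positive baseline maximum for group {name}"
                )
            idx = grp.index[in_session]
            out.loc[idx, "arv_norm"] = 100.0 * out.loc[idx, "arv_raw"] / ref
    return out


def _require_reference(records: pd.DataFrame, expected: str) -> None:
    refs = set(records["reference"].unique())
    if refs != {expected}:
        raise DataFormatError(
            f"records must all be {expected!r}-referenced, got {sorted(refs)}"
        )


def semg_abs(records: pd.DataFrame) -> pd.DataFrame:
    """One sample per stride per muscle x side: value = normalized ARV.

    Input must be ipsilaterally segmented (each side on its own hindlimb's
    impacts) and already normalized.
    """
    _require_reference(records, "ipsilateral")
    if records["arv_norm"].isna().any():
        raise DataFormatError("records must be normalized before sampling")
    out = records.loc[
        :, ["horse_id", "muscle", "side", "condition", "stride", "arv_norm"]
    ].copy()
    out = out.rename(columns={"arv_norm": "value"})
    out["family"] = "semg_abs"
    out["class_label"] = np.where(
        out["condition"].isin(BASELINE_OF.values()), "baseline", "lame"
    )
    return out.reset_index(drop=True)


def semg_asym(records: pd.DataFrame) -> pd.DataFrame:
    """Left minus right normalized ARV per left-referenced stride and muscle.

    Strides where either side's ARV was removed as an outlier are skipped
    (and counted in the log).
    """
    _require_reference(records, "left")
    if records["arv_norm"].isna().any():
        raise DataFormatError("records must be normalized before sampling")
    wide = records.pivot_table(
        index=["horse_id", "muscle", "condition", "stride"],
        columns="side",
        values="arv_norm",
        aggfunc="first",
    )
    for side in ("left", "right"):
        if side not in wide.columns:
            wide[side] = np.nan
    incomplete = wide["left"].isna() | wide["right"].isna()
    if incomplete.any():
        logger.info(
            "sEMGasym: skipped %d strides lacking one side's ARV", int(incomplete.sum())
        )
    wide = wide.loc[~incomplete]
    out = wide.reset_index()
    out["value"] = out["left"] - out["right"]
    out["family"] = "semg_asym"
    out["side"] = None
    out["class_label"] = np.where(
        out["condition"].isin(BASELINE_OF.values()), "baseline", "lame"
    )
    return out.loc[
        :, ["horse_id", "muscle", "side", "condition", "stride", "value",
            "family", "class_label"]
    ].reset_index(drop=True)
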