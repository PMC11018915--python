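"""ROC/AUC/Youden correctness against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equigait import (
    DataFormatError,
    assign_roles,
    auc,
    build_results_table,
    interpret_auc,
    mirror_parameters,
    roc_curve,
    youden_optimal,
)
from equigait.roc import parameter_names


def mann_whitney_auc(baseline, lame):
    """All-pairs probability that a lame value exceeds a baseline value."""
    b = np.asarray(baseline, float)[:, None]
    l = np.asarray(lame, float)[None, :]
    wins = (l > b).sum() + 0.5 * (l == b).sum()
    return wins / (b.size * l.size)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)

    def test_interleaved(self):
        """3 of 4 (lame, baseline) pairs have lame > baseline."""
        assert auc([1, 3], [2, 4]) == pytest.approx(0.75)

    def test_with_tie(self):
        """3 wins plus half a tie over 4 pairs."""
        assert auc([1, 2], [2, 3]) == pytest.approx(0.875)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            nb, nl = rng.integers(2, 31, size=2)
            # integer support to force ties
            b = rng.integers(0, 10, nb).astype(float)
            l = rng.integers(0, 10, nl).astype(float) + rng.choice([0.0, 0.5])
            assert abs(auc(b, l) - mann_whitney_auc(b, l)) < 1e-12

    def test_complement_identity(self):
        rng = np.random.default_rng(7)
        b, l = rng.integers(0, 6, 12).astype(float), rng.integers(0, 6, 9).astype(float)
        assert auc(b, l) + auc(l, b) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        b, l = rng.normal(0, 1, 25), rng.normal(0.7, 1, 25)
        direct = auc(b, l)
        warped = auc(np.exp(b), np.exp(l))
        assert warped == pytest.approx(direct, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        b, l = rng.normal(0, 1, 40), rng.normal(0.5, 1.3, 30)
        y = np.r_[np.zeros(40), np.ones(30)]
        assert auc(b, l) == pytest.approx(
            roc_auc_score(y, np.r_[b, l]), abs=1e-12
        )

    def test_direction_less(self):
        assert auc([4, 5, 6], [1, 2, 3], direction="less") == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=15),
        st.lists(st.integers(0, 8), min_size=2, max_size=15),
    )
    def test_complement_property(self, b, l):
        """AUC(baseline, lame) + AUC(lame, baseline) = 1 with half-ties."""
        assert auc(b, l) + auc(l, b) == pytest.approx(1.0, abs=1e-12)
        assert abs(auc(b, l) - mann_whitney_auc(b, l)) < 1e-12


class TestROCCurve:
    def test_separable_has_perfect_point(self):
        curve = roc_curve([1, 2], [5, 6])
        row = curve[(curve.sensitivity == 1.0) & (curve.specificity == 1.0)]
        assert len(row) == 1
        assert row["threshold"].iloc[0] == pytest.approx(3.5)

    def test_enumerated_operating_points(self):
        curve = roc_curve([1, 3], [2, 4])
        pairs = set(zip(curve["sensitivity"], curve["specificity"]))
        assert (1.0, 0.5) in pairs and (0.5, 1.0) in pairs

    def test_identical_values_uninformative(self):
        curve = roc_curve([2, 2, 2], [2, 2, 2])
        assert np.allclose(curve["sensitivity"] + curve["specificity"], 1.0)

    def test_empty_class_rejected(self):
        from equigait.core import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            roc_curve([], [1.0])


def brute_force_youden(baseline, lame, direction="greater"):
    b, l = np.asarray(baseline, float), np.asarray(lame, float)
    pooled = np.unique(np.r_[b, l])
    mids = np.r_[-np.inf, (pooled[:-1] + pooled[1:]) / 2, np.inf]
    best = None
    for t in mids:
        sens = (l > t).mean() if direction == "greater" else (l < t).mean()
        spec = (b <= t).mean() if direction == "greater" else (b >= t).mean()
        j = sens + spec - 1
        key = (j, spec, -abs(t))
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1:], best[0][0]


class TestYouden:
    def test_separable(self):
        cutoff, sens, spec = youden_optimal(roc_curve([1, 2], [5, 6]))
        assert (cutoff, sens, spec) == (3.5, 1.0, 1.0)

    def test_tie_break_prefers_specificity(self):
        cutoff, sens, spec = youden_optimal(roc_curve([1, 3], [2, 4]))
        assert cutoff == pytest.approx(3.5)
        assert (sens, spec) == (0.5, 1.0)

    def test_uninformative_j_zero(self):
        curve = roc_curve([2, 2], [2, 2])
        _, sens, spec = youden_optimal(curve)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            b = rng.integers(0, 8, rng.integers(3, 20)).astype(float)
            l = rng.integers(0, 8, rng.integers(3, 20)).astype(float)
            curve = roc_curve(b, l)
            cutoff, sens, spec = youden_optimal(curve)
            (bt_cut, bt_sens, bt_spec), bt_j = brute_force_youden(b, l)
            assert sens + spec - 1 == pytest.approx(bt_j, abs=1e-12)
            assert cutoff == pytest.approx(bt_cut, abs=1e-12)


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.95, "excellent"),
            (0.90, "excellent"),
            (0.85, "good"),
            (0.75, "fair"),
            (0.65, "poor"),
            (0.55, "chance"),
            (0.40, "chance"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_auc(value) == band

    def test_out_of_range(self):
        with pytest.raises(DataFormatError):
            interpret_auc(1.2)


def _sample_frame(rng, n=30):
    rows = []
    for horse, side_ind in (("H01", "left"), ("H02", "right")):
        for family in ("semg_abs", "semg_asym", "kinematic"):
            for k in range(n):
                rows.append(
                    {
                        "horse_id": horse,
                        "family": family,
                        "parameter": "MinDiff Poll" if family == "kinematic" else None,
                        "muscle": None if family == "kinematic" else "biceps",
                        "side": "left" if (family == "semg_abs" and k % 2) else (
                            "right" if family == "semg_abs" else None),
                        "condition": "iFL" if k % 2 else "baseline1",
                        "class_label": "lame" if k % 2 else "baseline",
                        "stride": k,
                        "value": float(rng.normal()),
                        "induced_side": side_ind,
                    }
                )
    return pd.DataFrame(rows)


class TestMirroring:
    def test_right_induction_negates_signed_values(self):
        df = _sample_frame(np.random.default_rng(3))
        out = mirror_parameters(df)
        right = df["induced_side"] == "right"
        signed = df["family"].isin(("semg_asym", "kinematic"))
        np.testing.assert_allclose(
            out.loc[right & signed, "value"], -df.loc[right & signed, "value"]
        )
        np.testing.assert_allclose(
            out.loc[~right, "value"], df.loc[~right, "value"]
        )

    def test_right_induction_swaps_abs_sides(self):
        df = _sample_frame(np.random.default_rng(4))
        out = mirror_parameters(df)
        right_abs = (df["induced_side"] == "right") & (df["family"] == "semg_abs")
        assert (
            out.loc[right_abs, "side"]
            == df.loc[right_abs, "side"].map({"left": "right", "right": "left"})
        ).all()

    def test_involution(self):
        df = _sample_frame(np.random.default_rng(5))
        twice = mirror_parameters(mirror_parameters(df))
        pd.testing.assert_frame_equal(twice, df)

    def test_lame_without_side_rejected(self):
        df = _sample_frame(np.random.default_rng(6))
        df.loc[df.index[:5], "induced_side"] = "none"
        with pytest.raises(DataFormatError):
            mirror_parameters(df)

    def test_roles_after_mirror(self):
        df = _sample_frame(np.random.default_rng(8))
        out = assign_roles(mirror_parameters(df))
        is_abs = out["family"] == "semg_abs"
        assert set(out.loc[is_abs, "parameter"]) <= {
            "sEMGabs LS biceps", "sEMGabs NLS biceps"
        }
        assert (out.loc[out["family"] == "semg_asym", "parameter"]
                == "sEMGasym biceps").all()


class TestResultsTable:
    def test_expected_row_structure(self):
        assert len(parameter_names()) == 29
        assert sum(1 for _, f in parameter_names() if f == "semg_abs") == 14
        assert sum(1 for _, f in parameter_names() if f == "semg_asym") == 7
        assert sum(1 for _, f in parameter_names() if f == "kinematic") == 8

    def test_missing_pairing_rejected(self):
        df = _sample_frame(np.random.default_rng(10))
        df = assign_roles(mirror_parameters(df))
        with pytest.raises(DataFormatError):
            build_results_table(df[df["condition"] == "baseline1"])
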