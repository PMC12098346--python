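"""Thermodynamic closed forms and ΔΔG classification contracts."""

import math

import pandas as pd
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from structscope import (
    DdgThresholds,
    ThermoConstants,
    batch_report,
    classify,
    kd_fold_change,
    make_ddg_table,
    read_ddg_table,
    rt,
)


class TestClosedForms:
    def test_rt_at_25C_rounds_to_0_6(self):
        value = rt(ThermoConstants())
        assert 0.59 <= value <= 0.60
        assert round(value, 1) == 0.6

    def test_rt_linearity_and_zero(self):
        assert rt(ThermoConstants(temperature=0.0)) == 0.0
        assert rt(ThermoConstants(temperature=596.3)) == pytest.approx(
            2 * rt(ThermoConstants(temperature=298.15)), rel=1e-9
        )

    def test_one_kcal_gives_about_5_fold(self):
        fold = kd_fold_change(1.0)
        assert round(fold) == 5
        assert fold == pytest.approx(5.41, abs=0.01)

    def test_fold_change_against_arbitrary_precision_oracle(self):
        # independent high-precision evaluation via sympy
        r = sympy.Rational("1.9872042586e-3") * sympy.Rational("298.15")
        expected = float(sympy.exp(sympy.Rational("0.6") / r).evalf(30))
        assert kd_fold_change(0.6) == pytest.approx(expected, rel=1e-12)

    def test_zero_ddg_is_exactly_one_fold(self):
        assert kd_fold_change(0.0) == 1.0

    @given(a=st.floats(-3, 3), b=st.floats(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_fold_change_multiplicative_in_magnitude(self, a, b):
        a, b = abs(a), abs(b)
        assert kd_fold_change(a + b) == pytest.approx(
            kd_fold_change(a) * kd_fold_change(b), rel=1e-9
        )

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            kd_fold_change(float("nan"))
        with pytest.raises(ValueError):
            classify(float("inf"))


class TestClassify:
    @pytest.mark.parametrize(
        "ddg,expected",
        [
            (1.2, "significant"),
            (1.0, "above_noise"),  # strictly-larger-than boundary
            (0.8, "above_noise"),
            (0.6, "within_noise"),  # noise boundary inclusive
            (-0.3, "within_noise"),  # magnitude-based
            (-2.0, "significant"),
            (0.0, "within_noise"),
        ],
    )
    def test_boundary_behaviour(self, ddg, expected):
        assert classify(ddg) == expected

    @given(st.floats(0, 5), st.floats(0, 5))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_magnitude(self, x, y):
        order = {"within_noise": 0, "above_noise": 1, "significant": 2}
        if abs(x) <= abs(y):
            assert order[classify(x)] <= order[classify(y)]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DdgThresholds(significant=0.5, noise=0.6)


class TestBatchReport:
    def test_empty_table(self):
        table, summary = batch_report(pd.DataFrame(columns=["complex_id", "mutation",
                                                            "ddg_stability", "ddg_affinity"]))
        assert table.empty
        assert "rows: 0" in summary

    def test_destabilizing_stability_with_noise_level_affinity_pattern(self):
        df = pd.DataFrame(
            {
                "complex_id": ["4kfm", "model_lc", "model_bs"],
                "mutation": ["L95P"] * 3,
                "ddg_stability": [1.8, 2.1, 1.5],
                "ddg_affinity": [0.58, 0.55, 0.60],
            }
        )
        table, summary = batch_report(df)
        assert (table["class_stability"] == "significant").all()
        assert (table["class_affinity"] == "within_noise").all()
        assert "stability change significant" in summary

    def test_row_error_does_not_stop_run(self):
        df = pd.DataFrame(
            {
                "complex_id": ["ok", "bad"],
                "mutation": ["L95P", "L95P"],
                "ddg_stability": [1.5, "oops"],
                "ddg_affinity": [0.3, 0.3],
            }
        )
        table, summary = batch_report(df)
        by_id = table.set_index("complex_id")
        assert by_id.loc["ok", "class_stability"] == "significant"
        assert by_id.loc["bad", "class_stability"] == "error"
        assert "1 row(s)" in summary

    def test_rows_sorted_by_complex_id(self):
        df = pd.DataFrame(
            {
                "complex_id": ["z", "a", "m"],
                "mutation": ["L95P"] * 3,
                "ddg_stability": [0.1, 0.2, 0.3],
                "ddg_affinity": [0.1, 0.2, 0.3],
            }
        )
        table, _ = batch_report(df)
        assert list(table["complex_id"]) == ["a", "m", "z"]

    def test_planted_classes_recovered_from_generated_table(self, tmp_path):
        m = make_ddg_table(seed=31, n_rows=15, out_dir=tmp_path / "ddg")
        table, _ = batch_report(read_ddg_table(m.paths["table"]))
        truth = {r["complex_id"]: r for r in m.truth["rows"]}
        for row in table.itertuples():
            assert row.class_stability == truth[row.complex_id]["class_stability"]
            assert row.class_affinity == truth[row.complex_id]["class_affinity"]

    def test_classification_equals_rowwise_reference(self):
        # independent per-row oracle against the vectorised report
        import numpy as np

        rng = np.random.default_rng(8)
        vals = np.round(rng.uniform(-3, 3, size=(30, 2)), 3)
        df = pd.DataFrame(
            {
                "complex_id": [f"c{i:02d}" for i in range(30)],
                "mutation": ["L95P"] * 30,
                "ddg_stability": vals[:, 0],
                "ddg_affinity": vals[:, 1],
            }
        )
        table, _ = batch_report(df)

        def oracle(x):
            m = abs(x)
            return "significant" if m > 1.0 else ("above_noise" if m > 0.6 else "within_noise")

        by_id = table.set_index("complex_id")
        for i in range(30):
            cid = f"c{i:02d}"
            assert by_id.loc[cid, "class_stability"] == oracle(vals[i, 0])
            assert by_id.loc[cid, "class_affinity"] == oracle(vals[i, 1])
            assert by_id.loc[cid, "kd_fold_change"] == pytest.approx(
                math.exp(abs(vals[i, 1]) / rt()), rel=1e-9
            )
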