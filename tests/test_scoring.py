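import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from predictc.errors import ConfigurationError, ValidationError
from predictc.normalization import ExpressionMatrix
from predictc.panel import MarkerPanel
from predictc.scoring import (
    HIGH,
    HIGH_CTC,
    LOW,
    LOW_CTC,
    MISSING,
    UNEVALUABLE,
    CutoffSet,
    call_marker,
    call_panel,
    compute_cutoff,
    score_cohort,
)

MARKERS = MarkerPanel().markers


def interp_percentile(values, p):
    """Independent oracle: linear interpolation at position 1 + (n-1)p/100."""
    x = sorted(values)
    h = (len(x) - 1) * p / 100.0
    lo = math.floor(h)
    if lo + 1 >= len(x):
        return x[-1]
    return x[lo] + (h - lo) * (x[lo + 1] - x[lo])


class TestComputeCutoff:
    def test_quartile_on_all_permutations(self):
        # order must not matter, and the value must match the declared
        # order-statistic interpolation
        for perm in itertools.permutations([0.0, 1.0, 2.0, 3.0]):
            assert compute_cutoff(perm, 75) == pytest.approx(2.25)
        assert interp_percentile([0, 1, 2, 3], 75) == pytest.approx(2.25)

    @given(
        values=st.lists(st.floats(-30, 30, allow_nan=False), min_size=1, max_size=40),
        p=st.floats(0.5, 99.5),
    )
    def test_matches_interpolation_oracle(self, values, p):
        assert compute_cutoff(values, p) == pytest.approx(
            interp_percentile(values, p), abs=1e-9
        )

    def test_constant_sample(self):
        assert compute_cutoff([5.5, 5.5, 5.5], 40) == 5.5

    def test_single_value(self):
        assert compute_cutoff([5.0], 75) == 5.0

    def test_limits_are_min_and_max(self):
        values = [3.0, -7.0, 1.0, 12.0]
        assert compute_cutoff(values, 99.999999) == pytest.approx(12.0, abs=1e-4)
        assert compute_cutoff(values, 0.000001) == pytest.approx(-7.0, abs=1e-4)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            compute_cutoff([], 75)


class TestCallMarker:
    @pytest.mark.parametrize(
        "value, cutoff, expected",
        [(2.5, 2.25, HIGH), (2.25, 2.25, LOW), (-15.0, 0.0, LOW)],
    )
    def test_strict_greater_rule(self, value, cutoff, expected):
        assert call_marker(value, cutoff) == expected


def _calls(n_high, n_low, n_missing=0):
    states = [HIGH] * n_high + [LOW] * n_low + [MISSING] * n_missing
    return dict(zip(MARKERS, states))


class TestCallPanel:
    @pytest.mark.parametrize(
        "n_high, n_low, n_missing, expected",
        [
            (4, 3, 0, HIGH_CTC),
            (3, 4, 0, LOW_CTC),
            (3, 3, 1, UNEVALUABLE),
            (7, 0, 0, HIGH_CTC),
            (0, 0, 7, UNEVALUABLE),
        ],
    )
    def test_majority_rule(self, n_high, n_low, n_missing, expected):
        assert call_panel(_calls(n_high, n_low, n_missing), 4) == expected

    def test_degenerate_threshold_one(self):
        assert call_panel(_calls(1, 6), 1) == HIGH_CTC

    def test_exhaustive_vote_counts(self):
        """Over all 3^7 marker-call vectors the vote reduces to tallies."""
        for states in itertools.product([LOW, HIGH, MISSING], repeat=7):
            calls = dict(zip(MARKERS, states))
            n_high = states.count(HIGH)
            n_low = states.count(LOW)
            expected = (
                HIGH_CTC if n_high >= 4 else LOW_CTC if n_low >= 4 else UNEVALUABLE
            )
            assert call_panel(calls, 4) == expected

    def test_monotone_in_single_marker_flip(self):
        """Flipping one marker low->high never demotes high-CTC to low-CTC."""
        for states in itertools.product([LOW, HIGH], repeat=7):
            before = call_panel(dict(zip(MARKERS, states)), 4)
            for i, s in enumerate(states):
                if s == LOW:
                    flipped = list(states)
                    flipped[i] = HIGH
                    after = call_panel(dict(zip(MARKERS, flipped)), 4)
                    assert not (before == HIGH_CTC and after == LOW_CTC)


def _expression_from_wide(wide_rows):
    rows = []
    for pid, tp, values in wide_rows:
        for marker, v in zip(MARKERS, values):
            if v is not None:
                rows.append(
                    {"patient_id": pid, "timepoint": tp, "marker": marker,
                     "delta_cq": v}
                )
    return ExpressionMatrix(
        long=pd.DataFrame(rows, columns=["patient_id", "timepoint", "marker", "delta_cq"])
    )


class TestScoreCohort:
    def test_identical_values_everyone_low(self):
        expr = _expression_from_wide(
            [(f"P{i}", "baseline", [-8.0] * 7) for i in range(10)]
        )
        panel = MarkerPanel()
        cutoffs = CutoffSet.from_expression(expr, panel)
        calls = score_cohort(expr, cutoffs, panel)
        assert (calls["group"] == LOW_CTC).all()

    def test_missing_cutoff_is_configuration_error(self):
        expr = _expression_from_wide([("P1", "baseline", [-8.0] * 7)])
        cutoffs = CutoffSet(
            table=pd.DataFrame(
                [{"marker": "GAPDH", "timepoint": "baseline", "cutoff": 0.0}]
            ),
            percentile=75,
            provenance="supplied",
        )
        with pytest.raises(ConfigurationError, match="VIL1"):
            score_cohort(expr, cutoffs)

    def test_scale_equivariance_of_cutoffs_and_calls(self):
        rng = np.random.default_rng(5)
        base = [
            (f"P{i}", "baseline", list(rng.normal(-10, 3, size=7))) for i in range(40)
        ]
        shifted = [
            (pid, tp, [v + (3.0 if m == 0 else 0.0) for m, v in enumerate(vals)])
            for pid, tp, vals in base
        ]
        panel = MarkerPanel()
        e1, e2 = _expression_from_wide(base), _expression_from_wide(shifted)
        c1 = CutoffSet.from_expression(e1, panel)
        c2 = CutoffSet.from_expression(e2, panel)
        first = panel.markers[0]
        assert c2.get(first, "baseline") == pytest.approx(
            c1.get(first, "baseline") + 3.0
        )
        pd.testing.assert_frame_equal(
            score_cohort(e1, c1, panel), score_cohort(e2, c2, panel)
        )

    def test_percentile_cutoff_caps_high_fraction(self):
        """With correlated markers and a 75th-percentile cutoff, roughly a
        quarter of patients land in the high-CTC group."""
        from predictc import PrediCTCModel
        from predictc.simulate import GeneratorConfig, generate_cohort

        fracs = []
        for seed in range(5):
            cohort = generate_cohort(
                GeneratorConfig(nr_shift=0.0, missing_sample_rate=0.0), seed=seed
            )
            model = PrediCTCModel.from_dataframes(cohort.cq, cohort.clinical)
            res = model.fit()
            base = res.panel_calls[res.panel_calls["timepoint"] == "baseline"]
            fracs.append((base["group"] == HIGH_CTC).mean())
        mean_frac = np.mean(fracs)
        assert 0.10 <= mean_frac <= 0.30

    def test_cutoffset_round_trips_yaml_and_csv(self, tmp_path):
        expr = _expression_from_wide(
            [(f"P{i}", "baseline", [float(i + m) for m in range(7)]) for i in range(9)]
        )
        cutoffs = CutoffSet.from_expression(expr, MarkerPanel())
        cutoffs.to_yaml(tmp_path / "c.yaml")
        cutoffs.to_csv(tmp_path / "c.csv")
        from_yaml = CutoffSet.from_yaml(tmp_path / "c.yaml")
        from_csv = CutoffSet.from_csv(tmp_path / "c.csv")
        for marker in MARKERS:
            assert from_yaml.get(marker, "baseline") == pytest.approx(
                cutoffs.get(marker, "baseline")
            )
            assert from_csv.get(marker, "baseline") == pytest.approx(
                cutoffs.get(marker, "baseline")
            )
        assert from_yaml.provenance == "supplied"
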