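"""Plug-in estimation: tabulation, positivity, point estimates, bootstrap."""

import io

import numpy as np
import pandas as pd
import pytest

from prevfrac import (
    ImpactFractionModel,
    SimConfig,
    case_weights,
    check_positivity,
    estimate,
    proportional_sample,
    random_spec,
    read_records,
    sample_population,
    table1,
    tabulate,
    total_measures,
    write_records,
)
from prevfrac.exceptions import (
    NotIdentifiableError,
    PositivityError,
    RecordError,
)

from conftest import TRIAL_PF_TOTAL, TRIAL_WEIGHTS


def _records(m, a, y, **extra):
    return pd.DataFrame({"m": m, "a": a, "y": y, **extra})


class TestTabulate:
    def test_balanced_single_stratum(self):
        df = _records(["s"] * 100, [0] * 50 + [1] * 50, [0, 1] * 50)
        t = tabulate(df).set_index(["m", "a"])
        assert t.loc[("s", 0), "mass"] == 0.5
        assert t.loc[("s", 1), "mass"] == 0.5

    def test_proportional_sample_reproduces_fixture_exactly(self, trial_spec):
        t = tabulate(proportional_sample(trial_spec, 10_000)).set_index(["m", "a"])
        for c in trial_spec.cells:
            row = t.loc[(c.stratum, c.arm)]
            assert row["mass"] == pytest.approx(c.mass, abs=1e-15)
            assert row["risk"] == pytest.approx(c.observed_risk, abs=1e-15)

    def test_empty_table_errors(self):
        with pytest.raises(RecordError, match="empty"):
            tabulate(pd.DataFrame(columns=["m", "a", "y"]))

    def test_invalid_codes_rejected(self):
        with pytest.raises(RecordError, match="binary"):
            tabulate(_records(["s", "s"], [0, 2], [0, 1]))

    def test_consistency_violation_detected(self):
        df = _records(["s"], [1], [0], y0=[0], y1=[1])
        with pytest.raises(RecordError, match="consistency"):
            tabulate(df)


class TestPositivity:
    def test_balanced_sample_has_no_empty_cells(self):
        df = _records(list("xyz") * 4, [0, 1] * 6, [0, 1] * 6)
        assert check_positivity(df).ok

    def test_missing_arm_is_flagged(self):
        df = _records(["x", "x", "y"], [0, 1, 0], [1, 0, 1])
        rep = check_positivity(df)
        assert rep.empty_cells == (("y", 1),)

    def test_trial_proportional_sample_six_cells(self, trial_spec):
        rep = check_positivity(proportional_sample(trial_spec, 10_000))
        assert len(rep.counts) == 6 and rep.ok

    def test_estimation_raises_on_violation(self):
        df = _records(["x", "x", "y"], [0, 1, 0], [1, 0, 1])
        with pytest.raises(PositivityError, match="'y'"):
            estimate(df, "pf", b_reps=0)


class TestPointEstimates:
    def test_proportional_trial_sample_recovers_printed_total(self, trial_spec):
        df = proportional_sample(trial_spec, 100_000, emit_potential_outcomes=False)
        res = estimate(df, "pf", b_reps=0)
        assert round(res.total.point, 2) == 0.23
        assert res.total.point == pytest.approx(TRIAL_PF_TOTAL, abs=1e-12)
        for m, w in TRIAL_WEIGHTS.items():
            assert res.weights[m].point == pytest.approx(w, abs=1e-12)

    def test_no_effect_data_estimates_zero_with_degenerate_ci(self):
        # y identical in both arms within every stratum (constant per
        # stratum): every resample reproduces the same zero contrast
        df = _records(
            ["p"] * 40 + ["q"] * 40,
            ([0] * 20 + [1] * 20) * 2,
            [1] * 40 + [0] * 40,
        )
        res = estimate(df, "pf", b_reps=200, seed=3)
        assert res.total.point == 0.0
        assert res.total.ci_low == res.total.ci_high == 0.0

    def test_plug_in_matches_empirical_spec_measures(self, trial_spec):
        """Dual route: the counts engine and the population formulas applied
        to the implied empirical spec give identical numbers."""
        df = sample_population(SimConfig(trial_spec, n=5000, seed=2))
        for measure in ("pf", "af"):
            res = estimate(df, measure, b_reps=0)
            ms = total_measures(res.empirical_spec)
            assert res.total.point == pytest.approx(ms[measure], abs=1e-12)
            w = case_weights(res.empirical_spec)
            for m, est in res.weights.items():
                assert est.point == pytest.approx(w[m], abs=1e-12)

    def test_parameter_recovery_at_large_n(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=200_000, seed=11))
        truth = total_measures(trial_spec)
        for measure, t in (("pf", truth.pf_total), ("af", truth.af_total)):
            res = estimate(df, measure, b_reps=0)
            assert abs(res.total.point - t) < 0.01
        res = estimate(df, "pf", b_reps=0)
        for m, w in TRIAL_WEIGHTS.items():
            assert abs(res.weights[m].point - w) < 0.01

    def test_marginal_assumption_ignores_stratum(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=50_000, seed=4))
        res = estimate(df, "pf", assumption="marginal_exchangeability", b_reps=0)
        treated_risk = df.loc[df.a == 1, "y"].mean()
        p_y1 = df["y"].mean()
        assert res.total.point == pytest.approx(
            (p_y1 - treated_risk) / p_y1, abs=1e-12
        )

    def test_estimated_weights_sum_to_one_exactly(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=3000, seed=8))
        res = estimate(df, "pf", b_reps=0)
        assert sum(e.point for e in res.weights.values()) == pytest.approx(
            1.0, abs=1e-12
        )


class TestIdentification:
    def test_pp_requires_oracle_or_monotonicity(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=1000, seed=0))
        with pytest.raises(NotIdentifiableError, match="monotone"):
            estimate(df, "pp", b_reps=0)

    def test_pp_under_monotonicity_equals_pf(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=5000, seed=0))
        pp = estimate(df, "pp", monotone=True, b_reps=0)
        pf = estimate(df, "pf", b_reps=0)
        assert pp.total.point == pf.total.point
        assert pp.reported_as == "pf"

    def test_oracle_assumption_uses_potential_outcomes(self, trial_spec):
        df = proportional_sample(trial_spec, 100_000, emit_potential_outcomes=True)
        truth = total_measures(trial_spec)
        for measure, t in (
            ("pf", truth.pf_total), ("af", truth.af_total),
            ("pp", truth.pp_total), ("ap", truth.ap_total),
        ):
            res = estimate(
                df, measure, assumption="oracle_potential_outcomes", b_reps=0
            )
            assert res.total.point == pytest.approx(t, abs=1e-12)

    def test_oracle_without_columns_errors(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=100, seed=0))
        with pytest.raises(NotIdentifiableError, match="y0 and y1"):
            estimate(df, "pf", assumption="oracle_potential_outcomes", b_reps=0)


class TestBootstrap:
    def test_seed_is_mandatory(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=500, seed=0))
        with pytest.raises(ValueError, match="seed"):
            estimate(df, "pf", b_reps=100)

    def test_interval_brackets_point_and_is_reproducible(self, trial_spec):
        df = sample_population(SimConfig(trial_spec, n=4000, seed=21))
        r1 = estimate(df, "pf", b_reps=400, seed=5)
        r2 = estimate(df, "pf", b_reps=400, seed=5)
        assert r1.total.ci_low <= r1.total.point <= r1.total.ci_high
        assert (r1.total.ci_low, r1.total.ci_high) == (
            r2.total.ci_low, r2.total.ci_high
        )
        assert r1.total.ci_low < r1.total.ci_high

    def test_error_shrinks_at_root_n_rate(self, trial_spec):
        """RMSE of the pf plug-in across seeds scales like n^(-1/2): two
        decades of n should shrink it roughly tenfold."""
        truth = total_measures(trial_spec).pf_total
        rmse = {}
        for n in (1000, 10_000, 100_000):
            errs = []
            for seed in range(24):
                df = sample_population(SimConfig(trial_spec, n=n, seed=1000 + seed))
                errs.append(estimate(df, "pf", b_reps=0).total.point - truth)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        ratio = rmse[1000] / rmse[100_000]
        assert 4.0 < ratio < 25.0  # 10 expected; wide band for 24 seeds
        assert rmse[1000] > rmse[10_000] > rmse[100_000]


class TestRecordsIO:
    def test_round_trip(self, tmp_path, trial_spec):
        df = sample_population(
            SimConfig(trial_spec, n=200, seed=6, emit_potential_outcomes=True)
        )
        path = tmp_path / "r.csv"
        write_records(df, path)
        back = read_records(path)
        pd.testing.assert_frame_equal(
            back.astype({"a": np.int8, "y": np.int8}), df, check_dtype=False
        )

    @pytest.mark.parametrize("bad", ["TRUE", "1.0", "yes", ""])
    def test_loose_binary_encodings_rejected(self, bad):
        csv = f"m,a,y\ns,0,1\ns,1,{bad}\n"
        with pytest.raises(RecordError):
            read_records(io.StringIO(csv))

    def test_arbitrary_stratum_strings_allowed(self):
        csv = "m,a,y\nage<65;male,0,1\nage<65;male,1,0\n"
        df = read_records(io.StringIO(csv))
        assert list(df["m"].unique()) == ["age<65;male"]
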