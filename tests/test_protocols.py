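import numpy as np
import pytest

from exminmod.model_core import ModelParameters
from exminmod.protocols import (
    InsulinKinetics,
    MealKinetics,
    ProtocolSpec,
    STUDY1_PROTOCOLS,
    STUDY2_STRATEGIES,
    _bout_session,
    basal_rate_for,
    glycemic_outcomes,
    insulin_submodel,
    meal_submodel,
    run_study1,
    run_study2,
)
from exminmod.simulate import Trajectory
from exminmod.synthetic_cohort import CohortSpec, sample_cohort


@pytest.fixture(scope="module")
def small_cohort():
    return sample_cohort(CohortSpec(n_subjects=4, seed=5))


class TestInsulinSubmodel:
    def test_zero_inputs_zero_insulin(self):
        f = insulin_submodel([(0.0, 0.0)], [], t_span=(0.0, 200.0))
        assert np.all(f.values == 0.0)

    def test_constant_basal_reaches_analytic_plateau(self):
        kin = InsulinKinetics()
        rate = 1.0  # U/h
        f = insulin_submodel([(0.0, rate)], [], kinetics=kin, t_span=(0.0, 600.0))
        expected = kin.steady_plasma(rate * 1000.0 / 60.0)
        assert f(600.0) == pytest.approx(expected, rel=0.01)
        # starts at steady state too
        assert f(0.0) == pytest.approx(expected, rel=0.01)

    def test_bolus_response_is_linear(self):
        kin = InsulinKinetics()
        base = insulin_submodel([(0.0, 0.0)], [(60.0, 8.0)], kin, (0.0, 400.0))
        quarter = insulin_submodel([(0.0, 0.0)], [(60.0, 2.0)], kin, (0.0, 400.0))
        assert quarter.values.max() == pytest.approx(0.25 * base.values.max(), rel=1e-6)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            insulin_submodel([(0.0, 1.0)], [(30.0, -2.0)])
        with pytest.raises(ValueError, match="negative"):
            insulin_submodel([(0.0, -1.0)])

    def test_basal_rate_for_round_trips(self):
        kin = InsulinKinetics()
        u = basal_rate_for(10.0, kin)
        assert kin.steady_plasma(u) == pytest.approx(10.0)


class TestMealSubmodel:
    def test_zero_carbs_zero_appearance(self):
        f = meal_submodel(0.0, 60.0)
        assert np.all(f.values == 0.0)

    def test_mass_balance(self):
        kin = MealKinetics()
        f = meal_submodel(75.0, 30.0, kinetics=kin, t_span=(0.0, 800.0), dt=0.25)
        integral = np.trapezoid(f.values, f.times)
        expected = 75.0 * (1000.0 / 180.16) * kin.bioavailability / kin.vg
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_appearance_still_positive_at_exercise_onset(self):
        # 75 g breakfast, exercise 90 min later
        f = meal_submodel(75.0, 120.0, t_span=(0.0, 400.0))
        assert f(210.0) > 0.05 * f.values.max()

    def test_negative_carbs_rejected(self):
        with pytest.raises(ValueError):
            meal_submodel(-1.0, 0.0)


class TestGlycemicOutcomes:
    def _traj(self, times, g):
        z = np.zeros_like(np.asarray(times, float))
        return Trajectory(times=np.asarray(times, float), G=np.asarray(g, float),
                          X=z, inc1=z, inc2=z)

    def test_constant_in_band(self):
        t = np.linspace(0, 100, 51)
        rep = glycemic_outcomes({"a": self._traj(t, np.full(51, 5.0))}, (0, 100))
        row = rep.per_subject.loc["a"]
        assert row["pct_4_8"] == 100.0
        assert row["pct_4_10"] == 100.0
        assert row["pct_below_4"] == 0.0

    def test_band_nesting_for_high_glucose(self):
        t = np.linspace(0, 100, 51)
        rep = glycemic_outcomes({"a": self._traj(t, np.full(51, 9.0))}, (0, 100))
        row = rep.per_subject.loc["a"]
        assert row["pct_4_8"] == 0.0 and row["pct_4_10"] == 100.0

    def test_linear_ramp_geometry(self):
        rep = glycemic_outcomes(
            {"a": self._traj([0.0, 100.0], [3.0, 5.0])}, (0, 100)
        )
        assert rep.per_subject.loc["a", "pct_below_4"] == pytest.approx(50.0)

    def test_empty_window_rejected(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(ValueError, match="empty"):
            glycemic_outcomes({"a": self._traj(t, np.full(11, 5.0))}, (50, 50))

    def test_window_outside_span_rejected(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(ValueError, match="outside"):
            glycemic_outcomes({"a": self._traj(t, np.full(11, 5.0))}, (50, 150))


class TestProtocolSpec:
    def test_single_strategy_enforced(self):
        with pytest.raises(ValueError, match="one insulin-reduction"):
            ProtocolSpec(
                intensity=0.5, duration=60.0, exercise_start=100.0,
                bolus_reduction=0.5, pump_suspend=True,
            )

    def test_bout_structure_must_sum(self):
        with pytest.raises(ValueError, match="bout"):
            ProtocolSpec(
                intensity=0.5, duration=60.0, exercise_start=100.0,
                bouts=((15.0, 5.0), (15.0, 0.0)),
            )

    def test_study_tables_are_valid(self):
        assert len(STUDY1_PROTOCOLS) == 8
        assert set(STUDY2_STRATEGIES) == {
            "pump-stop", "basal-80-90min", "basal-50-90min"
        }
        p4 = STUDY1_PROTOCOLS[4]
        assert (p4.intensity, p4.duration, p4.bolus_reduction) == (0.5, 60.0, 0.75)


class TestStudy1:
    def test_larger_bolus_reduction_is_safer(self, small_cohort):
        _, rep50 = run_study1(small_cohort, protocol_id=3)
        _, rep75 = run_study1(small_cohort, protocol_id=4)
        assert rep75.cohort_mean("end_glucose") > rep50.cohort_mean("end_glucose")
        assert rep75.cohort_mean("pct_below_4") <= rep50.cohort_mean("pct_below_4")

    def test_no_reduction_gives_lowest_mid_exercise_glucose(self, small_cohort):
        trajs = {}
        for pid in (5, 6):  # same intensity/duration, 0% vs 50% reduction
            t, _ = run_study1(small_cohort, protocol_id=pid)
            spec = STUDY1_PROTOCOLS[pid]
            mid = spec.exercise_start + spec.duration / 2.0
            trajs[pid] = np.mean(
                [np.interp(mid, tr.times, tr.G) for tr in t.values()]
            )
        assert trajs[5] < trajs[6]

    def test_insulin_dose_monotone_pointwise(self, small_cohort):
        # a larger bolus reduction (less insulin) never lowers glucose
        t3, _ = run_study1(small_cohort, protocol_id=3)  # 50% reduction
        t4, _ = run_study1(small_cohort, protocol_id=4)  # 75% reduction
        for sid in t3:
            assert np.all(t4[sid].G >= t3[sid].G - 1e-9)

    def test_deterministic_given_cohort(self, small_cohort):
        _, a = run_study1(small_cohort, protocol_id=1)
        _, b = run_study1(small_cohort, protocol_id=1)
        assert a.per_subject.equals(b.per_subject)

    def test_unknown_protocol_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="protocol_id"):
            run_study1(small_cohort, protocol_id=9)


class TestStudy2:
    def test_80_percent_reduction_smallest_drop(self, small_cohort):
        drops = {
            s: run_study2(small_cohort, s)[1].cohort_mean("drop")
            for s in STUDY2_STRATEGIES
        }
        assert drops["basal-80-90min"] == min(drops.values())

    def test_rest_periods_have_zero_intensity_increment(self, small_cohort):
        trajs, _ = run_study2(small_cohort, "pump-stop")
        traj = next(iter(trajs.values()))
        # mid-rest instants: 180+15+2.5 etc.
        for rest_mid in (197.5, 217.5, 237.5):
            i = np.argmin(np.abs(traj.times - rest_mid))
            assert traj.inc1[i] == pytest.approx(0.0, abs=1e-12)

    def test_without_exercise_gains_drops_driven_by_insulin_only(self):
        cohort = [
            ModelParameters(Gp0=32.0, p1=0.002, p2=0.03, p3=1.6e-5, Insb=10.0,
                            e1=0.0, e2=0.0, variant=6)
        ]
        drops = {
            s: run_study2(cohort, s)[1].cohort_mean("drop")
            for s in STUDY2_STRATEGIES
        }
        # more residual insulin -> larger drop
        assert drops["basal-50-90min"] > drops["basal-80-90min"]

    def test_unknown_strategy_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="strategy"):
            run_study2(small_cohort, "no-such-arm")


class TestBoutTrace:
    def test_bout_session_spans_duration(self):
        s = _bout_session(STUDY2_STRATEGIES["pump-stop"])
        assert s.t_start == 180.0 and s.duration == 75.0
        # work plateau at 50% of span, rest at 0
        assert float(s.pvo2(188.0)) == pytest.approx(0.5)
        assert float(s.pvo2(197.0)) == 0.0


class TestOutcomeInvariants:
    def test_band_nesting_on_simulated_reports(self, small_cohort):
        for pid in (1, 4, 7):
            _, rep = run_study1(small_cohort, protocol_id=pid)
            df = rep.per_subject
            assert (df["pct_4_8"] <= df["pct_4_10"] + 1e-9).all()
            assert (df["pct_below_3_3"] <= df["pct_below_4"] + 1e-9).all()

    def test_summary_text_mentions_bands(self, small_cohort):
        _, rep = run_study2(small_cohort, "basal-80-90min")
        text = rep.summary_text()
        assert "Time spent between 4-8 mmol/L" in text
        assert "Time spent below 3.3 mmol/L" in text
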