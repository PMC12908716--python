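import numpy as np
import pytest

from fieldgaze import pointing_tasks as pt
from fieldgaze.errors import CoverageError, DegenerateInputError, UndefinedBearingError
from fieldgaze.records import PointingTrial
from fieldgaze.synthetic_data import LinearConfidence, simulate_pointing_session

LOC = (34.675, 33.040)


class TestTrueBearing:
    def test_meridian_north(self):
        assert pt.true_bearing(0.0, 0.0, 1.0, 0.0) == pytest.approx(0.0)

    def test_equator_east(self):
        assert pt.true_bearing(0.0, 0.0, 0.0, 1.0) == pytest.approx(90.0)

    def test_mid_latitude_frozen_value(self):
        assert pt.true_bearing(50.0, 0.0, 50.0, 1.0) == pytest.approx(89.6169737611, abs=1e-9)

    def test_reciprocal_differs_by_180_on_great_circle_axes(self):
        assert (pt.true_bearing(0, 0, 1, 0) - pt.true_bearing(1, 0, 0, 0)) % 360 == pytest.approx(180.0)
        assert (pt.true_bearing(0, 0, 0, 1) - pt.true_bearing(0, 1, 0, 0)) % 360 == pytest.approx(180.0)

    def test_coincident_points(self):
        with pytest.raises(UndefinedBearingError):
            pt.true_bearing(1.0, 2.0, 1.0, 2.0)


class TestDeclination:
    def test_identity_arithmetic_wrap(self):
        assert pt.apply_declination(100.0, 0.0) == pytest.approx(100.0)
        assert pt.apply_declination(100.0, 4.5) == pytest.approx(104.5)
        assert pt.apply_declination(358.0, 5.0) == pytest.approx(3.0)


def _trial(reading, task="building", lat2=34.7, lon2=33.1, declination=0.0, confidence=None):
    return PointingTrial(
        trial_id="t1", task=task, lat1=LOC[0], lon1=LOC[1], lat2=lat2, lon2=lon2,
        target_id="b1" if task == "building" else None,
        compass_reading_deg=reading, declination_deg=declination, confidence=confidence,
    )


class TestPointingError:
    def test_exact_pointing_zero_error(self):
        bearing = pt.true_bearing(LOC[0], LOC[1], 34.7, 33.1)
        score = pt.pointing_error(_trial(bearing))
        assert score.signed_error_deg == pytest.approx(0.0)

    def test_signed_wrap_cases(self):
        s = pt.pointing_error(_trial(70.0, task="north", lat2=None, lon2=None))
        assert s.true_bearing_deg == 0.0
        assert s.signed_error_deg == pytest.approx(70.0)
        s2 = pt.pointing_error(_trial(350.0, task="north", lat2=None, lon2=None))
        assert s2.signed_error_deg == pytest.approx(-10.0)
        assert s2.abs_error_deg == pytest.approx(10.0)

    def test_declination_moves_pointed_direction(self):
        s = pt.pointing_error(_trial(10.0, task="north", lat2=None, lon2=None, declination=-10.0))
        assert s.pointed_true_deg == pytest.approx(0.0)
        assert s.signed_error_deg == pytest.approx(0.0)

    def test_invariant_to_full_turn_of_compass_reading(self):
        s1 = pt.pointing_error(_trial(359.9, task="north", lat2=None, lon2=None))
        s2 = pt.pointing_error(_trial((359.9 + 360.0) % 360.0, task="north", lat2=None, lon2=None))
        assert s1.signed_error_deg == pytest.approx(s2.signed_error_deg)


class TestAggregate:
    @staticmethod
    def _scores(errors, task="building"):
        return [
            pt.PointingScore(
                trial_id=str(i), task=task, target_id=f"b{i}",
                true_bearing_deg=0.0, pointed_true_deg=e % 360.0, signed_error_deg=e,
            )
            for i, e in enumerate(errors)
        ]

    def test_three_point_closed_form(self):
        df = pt.aggregate_scores(self._scores([10.0, -20.0, 30.0]), group_by="task")
        assert df.loc[0, "mean_abs_error_deg"] == pytest.approx(20.0)
        assert df.loc[0, "sd_abs_error_deg"] == pytest.approx(10.0)

    def test_single_score_sd_absent(self):
        df = pt.aggregate_scores(self._scores([10.0]), group_by="task")
        assert np.isnan(df.loc[0, "sd_abs_error_deg"])

    def test_empty_raises(self):
        with pytest.raises(CoverageError):
            pt.aggregate_scores([], group_by="task")


class TestSyntheticRecovery:
    def test_zero_noise_scores_exactly_zero(self):
        targets = {"b1": (34.7, 33.1), "b2": (34.6, 33.0)}
        trials, _ = simulate_pointing_session(LOC, targets, angular_noise_sd_deg=0.0,
                                              declination_deg=3.9, seed=1)
        for s in pt.score_trials(trials):
            assert s.abs_error_deg == pytest.approx(0.0, abs=1e-9)

    def test_folded_normal_mean_and_sd_recovery(self):
        sd = 10.0
        targets = {f"b{i}": (34.7 + 0.01 * i, 33.1) for i in range(8)}
        trials, truth = simulate_pointing_session(
            LOC, targets, angular_noise_sd_deg=sd, seed=2, n_repeats=400
        )
        scores = pt.score_trials(trials)
        abs_err = np.array([s.abs_error_deg for s in scores])
        n = abs_err.size
        expected = sd * np.sqrt(2.0 / np.pi)
        se = sd * np.sqrt(1.0 - 2.0 / np.pi) / np.sqrt(n)
        assert abs(abs_err.mean() - expected) < 3.0 * se
        # signed errors match the generator's recorded truth exactly
        signed = np.array([s.signed_error_deg for s in scores])
        np.testing.assert_allclose(signed, truth.trials["true_signed_error_deg"], atol=1e-9)

    def test_fixed_seed_reproducible_trial_order(self):
        targets = {f"b{i}": (34.7, 33.1 + 0.01 * i) for i in range(5)}
        t1, _ = simulate_pointing_session(LOC, targets, seed=9)
        t2, _ = simulate_pointing_session(LOC, targets, seed=9)
        assert [t.trial_id for t in t1] == [t.trial_id for t in t2]
        assert [t.compass_reading_deg for t in t1] == [t.compass_reading_deg for t in t2]


class TestConfidenceCorrelation:
    def test_monotone_link_gives_negative_rho(self):
        targets = {f"b{i}": (34.7 + 0.005 * i, 33.1 - 0.004 * i) for i in range(8)}
        trials, _ = simulate_pointing_session(
            LOC, targets, angular_noise_sd_deg=25.0, seed=3, n_repeats=5,
            confidence_model=LinearConfidence(scale_deg=60.0),
        )
        by_target = pt.aggregate_scores(pt.score_trials(trials), group_by="target")
        by_target = by_target[by_target["target"] != "north"]
        r = pt.confidence_correlation(by_target)
        assert r.statistic < 0
        assert r.method == "exact"

    def test_constant_confidence_undefined(self):
        scores = [
            pt.PointingScore(str(i), "building", f"b{i}", 0.0, 10.0, 10.0 + i, confidence=5)
            for i in range(4)
        ]
        by_target = pt.aggregate_scores(scores, group_by="target")
        with pytest.raises(DegenerateInputError):
            pt.confidence_correlation(by_target)
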