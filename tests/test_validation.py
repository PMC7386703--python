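"""Quality cross-tabulation, error rates, agreement and growth statistics."""
from datetime import date

import numpy as np
import pytest
from scipy import stats

from ovilog import synth, validation
from ovilog.types import AnimalRecord
from ovilog.utils import round_half_up
from ovilog.validation import GrowthRecord, QualityCrossTab


def published_crosstab() -> QualityCrossTab:
    """The evaluation cross-tabulation reconstructed from its margins.

    1720 strips in total; 1493 accepted (algorithm quality < 2) splitting
    631/575/251/36 over visual classes I–IV; 130 class-IV strips overall;
    133 good strips (class I/II) rejected at quality 3. The implied rejected
    counts (94 + 133 = 227) complete the table exactly; the I-vs-II split of
    the 133 is immaterial to every rate.
    """
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 0], counts[1, 0], counts[2, 0], counts[3, 0] = 631, 575, 251, 36
    counts[1, 3] = 133        # rejected despite good visual quality
    counts[3, 2] = 94         # class IV correctly rejected
    return QualityCrossTab(counts)


class TestCrossTab:
    def test_tally_and_order_invariance(self):
        pairs = [("I", 0), ("IV", 1), ("II", 3), ("I", 0)]
        a = validation.crosstab(pairs)
        b = validation.crosstab(list(reversed(pairs)))
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.n_total == 4 and a.counts[0, 0] == 2

    def test_empty_input_zero_matrix(self):
        ct = validation.crosstab([])
        assert ct.n_total == 0 and not ct.counts.any()

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            validation.crosstab([("V", 0)])
        with pytest.raises(ValueError):
            validation.crosstab([("I", 5)])


class TestPublishedRates:
    """The printed evaluation percentages fall out of the rate operations."""

    def test_false_real(self):
        assert round_half_up(validation.false_real_rate(published_crosstab())) == 2.1

    def test_real_false(self):
        assert round_half_up(validation.real_false_rate(published_crosstab())) == 7.7

    def test_acceptance_success(self):
        assert round_half_up(validation.acceptance_success_rate(published_crosstab())) == 97.6

    def test_accepted_class_shares(self):
        shares = validation.accepted_class_percentages(published_crosstab())
        assert shares == {"I": 42.3, "II": 38.5, "III": 16.8, "IV": 2.4}
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.2)

    def test_class_iv_share_and_accept_share(self):
        ct = published_crosstab()
        assert round_half_up(validation.manual_class_share(ct, "IV")) == 7.6
        assert round_half_up(validation.below_threshold_share(ct)) == 86.8

    def test_retrieval_percentages(self):
        assert validation.retrieval_rate(30, 22) == 73.0
        assert validation.retrieval_rate(40, 32) == 80.0


class TestRateEdgeCases:
    def test_zero_and_full_false_real(self):
        clean = validation.crosstab([("I", 0)] * 5)
        assert validation.false_real_rate(clean) == 0.0
        all_bad = validation.crosstab([("IV", 0)] * 5)
        assert validation.false_real_rate(all_bad) == 100.0
        assert validation.acceptance_success_rate(all_bad) == 0.0

    def test_no_rejected_good_strips(self):
        ct = validation.crosstab([("I", 0), ("II", 1)])
        assert validation.real_false_rate(ct) == 0.0

    def test_wide_reading_includes_quality_2(self):
        ct = validation.crosstab([("I", 2), ("I", 3), ("II", 0), ("III", 0)])
        assert validation.real_false_rate(ct, algo_reading="eq3") == 25.0
        assert validation.real_false_rate(ct, algo_reading="ge2") == 50.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            validation.false_real_rate(validation.crosstab([]))

    def test_single_class_share_is_100(self):
        ct = validation.crosstab([("II", 0)] * 7)
        assert validation.accepted_class_percentages(ct)["II"] == 100.0


class TestAgreement:
    def test_identical_pairs(self):
        s = validation.agreement_stats([(100.0, 100.0), (120.0, 120.0)])
        assert s.mean_diff_bpm == 0.0 and s.sd_diff == 0.0
        assert s.slope_through_origin == pytest.approx(1.0)

    def test_constant_offset(self):
        s = validation.agreement_stats([(101.0, 100.0), (121.0, 120.0), (81.0, 80.0)])
        assert s.mean_diff_bpm == pytest.approx(1.0)
        assert s.min_diff == pytest.approx(1.0) and s.max_diff == pytest.approx(1.0)

    def test_forced_origin_slope_recovers_calibration(self):
        # manual reads ~1% above the sensor: the inverse forced-origin slope
        # of sensor on manual recovers the 1.01 factor
        rng = np.random.default_rng(5)
        sensor = rng.uniform(60, 200, size=600)
        manual = 1.01 * sensor + rng.normal(0, 5, size=600)
        s = validation.agreement_stats(list(zip(sensor, manual)))
        assert 1.0 / s.slope_through_origin == pytest.approx(1.01, abs=0.01)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            validation.agreement_stats([(100.0, 100.0)])


class TestActivityMeans:
    def test_constant_active_cell(self):
        ms, labels = synth.gen_activity_observation(noise_sd=0.0, passive_offset=0.0, seed=1)
        table = validation.activity_means(ms, labels, {})
        for (_, _), row in table.iterrows():
            assert row["mean"] == pytest.approx(112.0) and row["sd"] == pytest.approx(0.0)

    def test_passive_offset_recovered_within_se(self):
        ms, labels = synth.gen_activity_observation(
            n_hours=24.0, base_hr=106.0, passive_offset=-16.0, noise_sd=5.0, seed=3
        )
        table = validation.activity_means(ms, labels, {"obs": "adult_female"})
        act = table.loc[("adult_female", "active")]
        pas = table.loc[("adult_female", "passive")]
        diff = act["mean"] - pas["mean"]
        se = np.sqrt(act["sd"] ** 2 / act["n"] + pas["sd"] ** 2 / pas["n"])
        assert diff == pytest.approx(16.0, abs=3 * se)

    def test_unlabelled_measurements_rejected(self):
        ms, _ = synth.gen_activity_observation(seed=1)
        with pytest.raises(ValueError):
            validation.activity_means(ms, [], {})


class TestGrowth:
    def _record(self, birth_w, fall_w, days=140):
        from datetime import timedelta

        birth = date(2016, 4, 15)
        return AnimalRecord(
            "x", "coastal", "juvenile_female", birth, birth + timedelta(days=49),
            birth + timedelta(days=days), birth_weight_g=birth_w, fall_weight_g=fall_w,
        )

    def test_growth_rate_formula(self):
        assert validation.growth_rate(self._record(5000, 45000)) == pytest.approx(285.71, abs=0.01)

    def test_no_gain_and_negative_gain(self):
        assert validation.growth_rate(self._record(5000, 5000)) == 0.0
        assert validation.growth_rate(self._record(5000, 4300)) < 0.0

    def test_missing_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            validation.growth_rate(self._record(None, 45000))

    def test_identical_groups_no_difference(self):
        recs = [GrowthRecord(f"s{i}", 250.0 + i, "sensor") for i in range(5)]
        recs += [GrowthRecord(f"c{i}", 250.0 + i, "control") for i in range(5)]
        out = validation.growth_comparison(recs)
        assert out["mean_difference"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_power_at_moderate_effect(self):
        # 30 g/day true difference, SD 40, n = 35 per group: Welch should
        # reject at alpha 0.05 in >= 80% of replicates
        rng = np.random.default_rng(17)
        hits = 0
        reps = 300
        for _ in range(reps):
            recs = [GrowthRecord(f"s{i}", float(rng.normal(250, 40)), "sensor") for i in range(35)]
            recs += [GrowthRecord(f"c{i}", float(rng.normal(220, 40)), "control") for i in range(35)]
            if validation.growth_comparison(recs)["p_value"] < 0.05:
                hits += 1
        assert hits / reps >= 0.80

    def test_birth_day_adjustment_removes_seasonal_confound(self):
        # growth declines with birth day; sensor lambs born later on average.
        # Unadjusted comparison is confounded, adjusted is not.
        rng = np.random.default_rng(23)
        recs = []
        for i in range(60):
            d = int(rng.integers(95, 115))
            recs.append(GrowthRecord(f"s{i}", 400 - 1.5 * d + float(rng.normal(0, 8)),
                                     "sensor", birth_day_of_year=d))
        for i in range(60):
            d = int(rng.integers(85, 105))
            recs.append(GrowthRecord(f"c{i}", 400 - 1.5 * d + float(rng.normal(0, 8)),
                                     "control", birth_day_of_year=d))
        raw = validation.growth_comparison(recs)
        adj = validation.growth_comparison(recs, adjust_birth_day=True)
        assert raw["p_value"] < 0.01       # spurious difference
        assert adj["p_value"] > 0.05       # removed by the adjustment

    def test_small_group_rejected(self):
        recs = [GrowthRecord("s", 250.0, "sensor"), GrowthRecord("c1", 250.0, "control"),
                GrowthRecord("c2", 255.0, "control")]
        with pytest.raises(ValueError):
            validation.growth_comparison(recs)


class TestRoundHalfUp:
    @pytest.mark.parametrize("x,nd,expected", [(2.15, 1, 2.2), (2.25, 1, 2.3),
                                               (97.55, 1, 97.6), (73.33, 0, 73.0)])
    def test_ties_away_from_zero(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
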