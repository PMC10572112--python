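import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdkeys.fluctuation import (
    build_feature_record,
    log_ratio_sd,
    restricted_key_filter,
)
from pdkeys.io import SubjectMetadata
from pdkeys.latency import extract_latencies
from pdkeys.outliers import OutlierPolicy
from pdkeys.simulate import TypistProfile, generate_session
from conftest import make_series, make_session


def two_pass_log_ratio_sd(values):
    """Independent oracle: explicit two-pass mean/variance over log-ratios."""
    ratios = [
        math.log(values[i + 1] / values[i])
        for i in range(len(values) - 1)
        if values[i] > 0 and values[i + 1] > 0
    ]
    if len(ratios) < 2:
        return math.nan
    m = sum(ratios) / len(ratios)
    var = sum((r - m) ** 2 for r in ratios) / (len(ratios) - 1)
    return math.sqrt(var)


class TestLogRatioSd:
    def test_constant_series_is_zero(self):
        assert log_ratio_sd([0.2] * 5) == 0.0

    def test_geometric_series_is_zero(self):
        assert log_ratio_sd([1.0, 2.0, 4.0, 8.0]) == 0.0

    def test_hand_computed_alternating(self):
        # ratios {ln 2, -ln 2, ln 2}, sample SD = 0.80041...
        assert log_ratio_sd([0.1, 0.2, 0.1, 0.2]) == pytest.approx(0.8004, abs=1e-4)

    def test_scale_invariance(self, rng):
        v = rng.lognormal(0, 0.5, 40)
        assert log_ratio_sd(v * 3.7) == pytest.approx(log_ratio_sd(v), abs=1e-12)

    def test_two_pass_oracle_equivalence(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 21))
            v = rng.lognormal(0, 1, n)
            assert log_ratio_sd(v) == pytest.approx(two_pass_log_ratio_sd(v), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance_property(self, seed):
        r = np.random.default_rng(seed)
        v = r.lognormal(0, 1, int(r.integers(3, 50)))
        c = float(r.uniform(0.01, 100))
        assert log_ratio_sd(c * v) == pytest.approx(log_ratio_sd(v), abs=1e-10)

    def test_order_sensitivity_counterexample(self):
        # a sequential dispersion measure: permuting the series changes it
        v = [1.0, 2.0, 4.0, 8.0]          # geometric: statistic 0
        assert log_ratio_sd(v) == 0.0
        assert log_ratio_sd([1.0, 4.0, 2.0, 8.0]) > 0.0

    def test_short_series_missing_not_zero(self):
        assert math.isnan(log_ratio_sd([0.1, 0.2]))

    def test_nonpositive_survivors_drop_adjacent_ratios(self):
        # zero at position 2 excludes ratios (1,2) and (2,3)
        v = [0.1, 0.2, 0.0, 0.4, 0.2, 0.1]
        expected = np.std(
            [math.log(0.2 / 0.1), math.log(0.2 / 0.4), math.log(0.1 / 0.2)], ddof=1
        )
        assert log_ratio_sd(v) == pytest.approx(expected, abs=1e-12)

    def test_strict_pair_policy_drops_bridging_ratios(self):
        values = np.array([0.1, 0.2, 0.4])
        original_index = np.array([0, 1, 5])  # a gap: values 2..4 were removed
        strict = log_ratio_sd(values, original_index, pair_policy="strict")
        # only the (0,1) ratio remains -> fewer than 2 ratios -> missing
        assert math.isnan(strict)
        compact = log_ratio_sd(values, original_index, pair_policy="compact")
        assert not math.isnan(compact)

    def test_closed_form_sqrt2_sigma(self, rng):
        # iid log-normal intervals: log-ratios are Normal(0, 2 sigma^2)
        sigma = 0.5
        stats = [log_ratio_sd(rng.lognormal(0, sigma, 1500)) for _ in range(50)]
        assert np.mean(stats) == pytest.approx(math.sqrt(2) * sigma, rel=0.02)


class TestRestrictedKeyFilter:
    def test_backspace_hold_dropped(self):
        sess = make_session(
            [0.0, 0.5, 1.0, 1.5], [0.1, 0.6, 1.1, 1.6], ["a", "space", "backspace", "b"]
        )
        hl = extract_latencies(sess)["HL"]
        kept = restricted_key_filter(hl, sess)
        assert len(kept) == 3
        assert 2 not in kept.pair_index[:, 0]  # the backspace event

    def test_pairwise_series_needs_both_events_allowed(self):
        sess = make_session(
            [0.0, 0.5, 1.0], [0.1, 0.6, 1.1], ["a", "shift", "b"]
        )
        il = extract_latencies(sess)["IL"]
        kept = restricted_key_filter(il, sess)
        assert len(kept) == 0  # both IL values touch the shift event

    def test_no_special_keys_identity(self, rng):
        sess = make_session([0, 0.5, 1.0], [0.1, 0.6, 1.1], ["a", "1", "."])
        hl = extract_latencies(sess)["HL"]
        np.testing.assert_array_equal(restricted_key_filter(hl, sess).values, hl.values)

    def test_all_special_keys_gives_missing_statistic(self):
        sess = make_session(
            [0, 0.5, 1.0, 1.5], [0.1, 0.6, 1.1, 1.6], ["shift"] * 4
        )
        hl = extract_latencies(sess)["HL"]
        kept = restricted_key_filter(hl, sess)
        assert len(kept) == 0
        assert math.isnan(log_ratio_sd(kept.values))


class TestBuildFeatureRecord:
    def test_composition_on_toy_session(self):
        sess = make_session(
            [0.0, 0.5, 1.0, 1.6, 2.4],
            [0.1, 0.7, 1.15, 1.8, 2.5],
            ["a", "b", "space", "c", "d"],
        )
        meta = SubjectMetadata("s1", "de_novo_pd", updrs3=19.0, aftap=95.0)
        rec, reports = build_feature_record(sess, meta)
        lat = extract_latencies(sess)
        assert rec.il_sd == pytest.approx(log_ratio_sd(lat["IL"].values), abs=1e-12)
        assert rec.hl_sd == pytest.approx(log_ratio_sd(lat["HL"].values), abs=1e-12)
        # no special keys -> restricted statistic equals the all-key HL one
        assert rec.sd_restricted == pytest.approx(rec.hl_sd, abs=1e-12)
        assert rec.group == "de_novo_pd" and rec.updrs3 == 19.0
        assert rec.word_count == 2.0
        assert len(reports) == 4

    def test_two_event_session_fluctuation_missing_speed_present(self):
        sess = make_session([0.0, 1.0], [0.1, 1.1], ["a", "b"])
        rec, _ = build_feature_record(sess, SubjectMetadata("s", "control"))
        assert math.isnan(rec.il_sd) and math.isnan(rec.hl_sd)
        assert rec.typing_speed > 0

    def test_recovers_generator_sigma(self):
        profile = TypistProfile(
            sigma_logIL=0.81, n_keystrokes=1500,
            outlier_rate=0.0, rollover_prob=0.0,
        )
        stats = []
        for seed in range(20):
            sess = generate_session(profile, seed)
            rec, _ = build_feature_record(sess, SubjectMetadata("s", "control"))
            stats.append(rec.il_sd)
        assert np.mean(stats) == pytest.approx(math.sqrt(2) * 0.81, rel=0.02)

    def test_never_fabricates_zero(self):
        sess = make_session([0.0, 0.2, 0.4], [0.1, 0.3, 0.5], ["shift", "shift", "shift"])
        rec, _ = build_feature_record(sess, SubjectMetadata("s", "control"))
        assert math.isnan(rec.sd_restricted)
        assert rec.sd_restricted != 0.0
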