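from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dilic.corpus_io import Label
from dilic.pattern_mining import Pattern
from dilic.pattern_scoring import (
    FDA_COLUMN,
    SIDER_COLUMN,
    TOTAL_WEIGHT_COLUMN,
    WeightConfig,
    build_feature_matrix,
    compute_total_weight,
    score_pattern,
    score_patterns,
)
from dilic.text_processing import Transaction


def _p(items, sp, sn):
    return Pattern(items=frozenset(items), support_pos=sp, support_neg=sn)


class TestScorePattern:
    def test_unsmoothed_class_ratio(self):
        assert score_pattern(_p(["a"], 3, 1), smoothing=0).class_score_pos == 0.75

    @pytest.mark.parametrize("smoothing", [0.0, 0.5, 1.0, 5.0])
    def test_balanced_supports_score_half(self, smoothing):
        sp = score_pattern(_p(["a"], 7, 7), smoothing)
        assert sp.class_score_pos == pytest.approx(0.5)

    def test_pseudo_count(self):
        sp = score_pattern(_p(["a"], 5, 0), smoothing=1)
        assert sp.class_score_pos == pytest.approx(6 / 7)

    def test_zero_total_support_rejected(self):
        with pytest.raises(ValueError, match="zero total support"):
            score_pattern(_p(["a"], 0, 0))

    @settings(derandomize=True, max_examples=100)
    @given(
        sp=st.integers(0, 10_000),
        sn=st.integers(0, 10_000),
        smoothing=st.floats(0, 10),
    )
    def test_scores_sum_to_one(self, sp, sn, smoothing):
        if sp + sn == 0:
            return
        s = score_pattern(_p(["a"], sp, sn), smoothing)
        assert abs(s.class_score_pos + s.class_score_neg - 1) < 1e-12
        if smoothing > 0:
            assert 0 < s.class_score_pos < 1


def _straight_line_total_weight(row, w_f, w_l, w_fda, w_sider, fda, sider):
    """Independent re-statement of the four-term weight sum."""
    t1 = sum(w_f * c["freq"] * c["key"] for c in row)
    t2 = sum(w_l * c["len"] * c["key"] for c in row)
    return t1 + t2 + w_fda * fda + w_sider * sider


class TestTotalWeight:
    def test_single_present_keyword_set(self):
        cfg = WeightConfig(w_freq=1, w_len=1, w_fda=1, w_sider=1)
        row = [{"freq": 2, "len": 1, "key": 1}]
        assert compute_total_weight(row, cfg) == 3

    def test_absence_annihilates(self):
        cfg = WeightConfig()
        row = [{"freq": 5, "len": 3, "key": 0}, {"freq": 2, "len": 2, "key": 0}]
        assert compute_total_weight(row, cfg, fda_hits=0, sider_hits=0) == 0

    def test_hand_summed_two_sets_with_fda_hit(self):
        cfg = WeightConfig(w_freq=1, w_len=1, w_fda=2, w_sider=0)
        row = [{"freq": 1, "len": 1, "key": 1}, {"freq": 1, "len": 2, "key": 1}]
        # (1+1) + (1+2) + one FDA hit boosted by 2 = 7
        assert compute_total_weight(row, cfg, fda_hits=1) == 7

    def test_invalid_components(self):
        cfg = WeightConfig()
        with pytest.raises(ValueError):
            compute_total_weight([{"freq": 1, "len": 1, "key": 2}], cfg)
        with pytest.raises(ValueError):
            compute_total_weight([{"freq": -1, "len": 1, "key": 1}], cfg)

    def test_matches_independent_formula_on_random_rows(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            row = [
                {
                    "freq": int(rng.integers(0, 10)),
                    "len": int(rng.integers(1, 4)),
                    "key": int(rng.integers(0, 2)),
                }
                for _ in range(int(rng.integers(1, 8)))
            ]
            w = [float(rng.uniform(0, 3)) for _ in range(4)]
            fda, sider = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            cfg = WeightConfig(w_freq=w[0], w_len=w[1], w_fda=w[2], w_sider=w[3])
            assert compute_total_weight(row, cfg, fda, sider) == pytest.approx(
                _straight_line_total_weight(row, *w, fda, sider)
            )


def _t(doc_id, freqs, label=Label.POSITIVE):
    return Transaction(doc_id, label, Counter(freqs))


class TestFeatureMatrix:
    def setup_method(self):
        # patterns: {liver} 3+/1-, {liver,injury} 2+/0-
        self.scored = score_patterns(
            [_p(["liver"], 3, 1), _p(["injury", "liver"], 2, 0)], smoothing=0
        )

    def test_hand_computed_toy_matrix(self):
        trans = [
            _t("d1", {"liver": 2, "injury": 1}),
            _t("d2", {"liver": 1}),
            _t("d3", {"alt": 1}, Label.NEGATIVE),
        ]
        cfg = WeightConfig(w_freq=1, w_len=1, w_fda=2, w_sider=2)
        m = build_feature_matrix(trans, self.scored, {"d1": (1, 0)}, cfg)
        # pattern {liver}: score 0.75; {injury,liver}: score 1.0, freq=min=1, len 2
        assert m.values.loc["d1", "liver"] == pytest.approx(0.75 * (2 + 1))
        assert m.values.loc["d1", "injury&liver"] == pytest.approx(1.0 * (1 + 2))
        assert m.values.loc["d1", FDA_COLUMN] == 2.0
        assert m.values.loc["d1", TOTAL_WEIGHT_COLUMN] == pytest.approx(3 + 3 + 2)
        assert m.values.loc["d2", "liver"] == pytest.approx(0.75 * (1 + 1))
        assert m.values.loc["d2", TOTAL_WEIGHT_COLUMN] == pytest.approx(2)
        assert (m.values.loc["d3"] == 0).all()

    def test_vocabulary_mismatch_is_hard_error(self):
        trans = [_t("d1", {"kidney": 1})]
        with pytest.raises(ValueError, match="vocabular"):
            build_feature_matrix(trans, self.scored, None)

    def test_drug_boost_monotone(self):
        base = _t("d1", {"liver": 1})
        with_drug = _t("d1", {"liver": 1, "acetaminophen": 1})
        m0 = build_feature_matrix([base], self.scored, {"d1": (0, 0)})
        m1 = build_feature_matrix([with_drug], self.scored, {"d1": (1, 1)})
        for col in (FDA_COLUMN, SIDER_COLUMN, TOTAL_WEIGHT_COLUMN):
            assert m1.values.loc["d1", col] >= m0.values.loc["d1", col]

    def test_reproducible_bit_for_bit(self):
        trans = [_t("d1", {"liver": 2}), _t("d2", {"liver": 1, "injury": 1})]
        a = build_feature_matrix(trans, self.scored, None)
        b = build_feature_matrix(trans, self.scored, None)
        assert a.values.equals(b.values)
        assert list(a.values.columns) == list(b.values.columns)

    def test_empty_pattern_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_matrix([_t("d1", {"liver": 1})], [], None)
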