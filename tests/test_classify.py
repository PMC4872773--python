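import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from lncbreadth.classify import (
    classify_gene,
    classify_transcript,
    coefficient_of_variation,
    js_specificity,
)


def js_oracle(profile):
    """Independent oracle: scipy's Jensen-Shannon distance (= sqrt of the
    base-2 divergence) against every single-tissue point distribution."""
    p = np.asarray(profile, float)
    p = p / p.sum()
    best, arg = -np.inf, None
    for t in range(p.size):
        e = np.zeros_like(p)
        e[t] = 1.0
        score = 1.0 - jensenshannon(p, e, base=2)
        if score > best:
            best, arg = score, t
    return best, arg


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([2, 2, 2, 2]) == 0.0

    def test_two_point_value(self):
        # sd = sqrt(2), mean = 2
        assert coefficient_of_variation([1, 3]) == pytest.approx(0.70710678, abs=1e-8)

    def test_zero_mean_is_infinite(self):
        assert coefficient_of_variation([0, 0, 0]) == math.inf


class TestJsSpecificity:
    def test_point_mass_scores_one(self):
        s = js_specificity([1, 0, 0], ["a", "b", "c"])
        assert s.score == pytest.approx(1.0, abs=1e-12)
        assert s.argmax_tissue == "a"

    def test_two_tissue_even_split(self):
        # H(3/4, 1/4) = 0.811278, JSD = 0.311278, score = 1 - sqrt(JSD)
        assert js_specificity([0.5, 0.5]).score == pytest.approx(0.442077, abs=1e-6)

    def test_uniform_twenty_tissues_matches_oracle(self):
        score, _ = js_oracle(np.ones(20))
        assert js_specificity(np.ones(20)).score == pytest.approx(score, abs=1e-10)

    @given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=30).filter(lambda v: sum(v) > 1e-6))
    @settings(derandomize=True, max_examples=150)
    def test_matches_entropy_oracle(self, profile):
        score, arg = js_oracle(profile)
        s = js_specificity(profile)
        assert s.score == pytest.approx(score, abs=1e-10)

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=10),
           st.floats(0.1, 1000.0))
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariant(self, profile, factor):
        a = js_specificity(profile).score
        b = js_specificity([v * factor for v in profile]).score
        assert a == pytest.approx(b, abs=1e-9)

    def test_spreading_mass_strictly_decreases_score(self):
        # move mass from one tissue to a second in steps: score must fall
        scores = [js_specificity([1.0 - eps, eps, 0.0]).score for eps in np.linspace(0, 0.5, 11)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            js_specificity([0.0, 0.0])


class TestClassifyTranscript:
    tissues = [f"t{i}" for i in range(20)]

    def test_ue_when_everywhere_and_stable(self):
        rng = np.random.default_rng(0)
        row = 5.0 * np.exp(rng.normal(0, 0.2, 20))
        r = classify_transcript(row, 0.14, self.tissues, feature_id="x")
        assert r.label == "UE" and r.cv < 1

    def test_ts_single_tissue_high_score(self):
        row = np.full(20, 0.01)
        row[7] = 9.0
        r = classify_transcript(row, 0.14, self.tissues)
        assert r.label == "TS"
        assert r.ts_tissue == "t7"
        assert r.specificity.score > 0.4

    def test_intermediate_width_is_other(self):
        row = np.zeros(20)
        row[:3] = 5.0
        r = classify_transcript(row, 0.14, self.tissues)
        assert r.label == "other" and r.expression_width == 3

    def test_everywhere_but_unstable_is_other(self):
        row = np.full(20, 0.2)
        row[0] = 100.0  # CV >> 1
        r = classify_transcript(row, 0.14, self.tissues)
        assert r.label == "other" and r.cv >= 1

    def test_ue_ts_mutually_exclusive_by_width(self):
        # UE needs width == n (> 1); TS needs width == 1
        row = np.full(20, 5.0)
        assert classify_transcript(row, 0.14, self.tissues).label == "UE"


class TestClassifyGene:
    def mk(self, label, cv=0.5, score=0.9, width=20, tissue=None):
        from lncbreadth.classify import ClassificationResult, SpecificityScore

        return ClassificationResult(
            "tx", "transcript", label, cv, SpecificityScore(score, tissue or "t0"), width, tissue
        )

    def test_one_ue_transcript_suffices(self):
        r = classify_gene([self.mk("UE"), self.mk("other", width=3)], "g")
        assert r.label == "UE" and not r.conflict

    def test_all_other(self):
        r = classify_gene([self.mk("other", width=3), self.mk("other", width=2)], "g")
        assert r.label == "other"

    def test_ue_ts_conflict_resolves_to_ue_with_flag(self):
        r = classify_gene([self.mk("UE"), self.mk("TS", width=1, tissue="t3")], "g")
        assert r.label == "UE" and r.conflict

    def test_ts_gene_carries_tissue(self):
        r = classify_gene([self.mk("TS", width=1, tissue="t5"), self.mk("other", width=4)], "g")
        assert r.label == "TS" and r.ts_tissue == "t5"

    def test_empty_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_gene([], "g")


class TestMicroFixture:
    """The hand-checked worked example ties the pieces together."""

    def test_frozen_values(self, micro):
        from lncbreadth.classify import classify_transcript

        exp = micro.expected
        for gid, row in micro.matrix.iterrows():
            r = classify_transcript(
                row.to_numpy(), micro.threshold, list(micro.matrix.columns), feature_id=gid
            )
            assert r.label == exp["labels"][gid], gid
            assert r.expression_width == exp["widths"][gid], gid
            if gid in exp["cv"]:
                assert r.cv == pytest.approx(exp["cv"][gid], abs=1e-9)
            if gid in exp["js"]:
                assert r.specificity.score == pytest.approx(exp["js"][gid], abs=1e-9)
            if gid in exp["ts_tissue"]:
                assert r.ts_tissue == exp["ts_tissue"][gid]
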