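"""Question-answer trust, trust densities, trust spectrum and NetTrustScore."""

import numpy as np
import pytest

from skillseq.classifier import PredictionRecord
from skillseq.sequences import ValidationError
from skillseq.trust import (
    TrustConfig,
    question_answer_trust,
    trust_density,
    trust_spectrum_and_nts,
)


def record(true, pred, conf, trial_id="t"):
    probs = np.array([conf, 1 - conf]) if pred == "pass" else np.array([1 - conf, conf])
    return PredictionRecord(trial_id=trial_id, true_class=true, predicted_class=pred,
                            confidence=conf, class_probabilities=probs,
                            class_names=["pass", "fail"])


def random_records(rng, n):
    recs = []
    for i in range(n):
        true = rng.choice(["pass", "fail"])
        pred = rng.choice(["pass", "fail"])
        conf = float(rng.uniform(0.5, 1.0))
        recs.append(record(true, pred, conf, trial_id=f"t{i}"))
    return recs


class TestQuestionAnswerTrust:
    @pytest.mark.parametrize("correct,conf,alpha,beta,expected", [
        (True, 0.9, 1, 1, 0.9),
        (False, 0.9, 1, 1, 0.1),
        (True, 0.8, 2, 1, 0.64),
    ])
    def test_hand_examples(self, correct, conf, alpha, beta, expected):
        r = record("pass", "pass" if correct else "fail", conf)
        q = question_answer_trust(r, TrustConfig(alpha=alpha, beta=beta))
        assert q == pytest.approx(expected)

    def test_full_grid_matches_formula(self):
        """C in {0,...,1} x alpha,beta in {1,2} x correct/incorrect."""
        for conf in np.linspace(0, 1, 11):
            for a in (1.0, 2.0):
                for b in (1.0, 2.0):
                    cfg = TrustConfig(alpha=a, beta=b)
                    q_t = question_answer_trust(record("pass", "pass", conf), cfg)
                    q_f = question_answer_trust(record("pass", "fail", conf), cfg)
                    assert q_t == pytest.approx(conf ** a)
                    assert q_f == pytest.approx(1 - conf ** b)
                    assert 0.0 <= q_t <= 1.0 and 0.0 <= q_f <= 1.0


class TestTrustDensity:
    def test_point_mass_peaks_at_value(self):
        curve = trust_density(np.full(20, 1.0))
        assert abs(curve.grid[np.argmax(curve.density)] - 1.0) < 0.05

    def test_integrates_to_one(self, rng):
        for _ in range(5):
            q = rng.uniform(0.2, 0.9, size=60)
            assert trust_density(q).integral == pytest.approx(1.0, abs=0.01)

    def test_bimodal_has_two_local_maxima(self):
        q = np.array([0.1] * 50 + [0.9] * 50)
        curve = trust_density(q)
        d = curve.density
        is_peak = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        peaks = curve.grid[1:-1][is_peak]
        assert any(abs(p - 0.1) < 0.1 for p in peaks)
        assert any(abs(p - 0.9) < 0.1 for p in peaks)

    def test_needs_two_values(self):
        with pytest.raises(ValidationError):
            trust_density(np.array([0.5]))


class TestSpectrumAndNTS:
    def test_class_mean(self):
        recs = [record("pass", "pass", 1.0, "a"), record("pass", "fail", 0.5, "b")]
        rep = trust_spectrum_and_nts(recs)
        assert rep.classes["pass"].trust_spectrum == pytest.approx((1.0 + 0.5) / 2)

    def test_prevalence_weighted_nts(self):
        # engineer T_M(pass)=0.8 with P=0.75 and T_M(fail)=0.6 with P=0.25
        recs = [record("pass", "pass", 0.8, f"p{i}") for i in range(3)]
        recs += [record("fail", "fail", 0.6, "f0")]
        rep = trust_spectrum_and_nts(recs)
        assert rep.nts == pytest.approx(0.75 * 0.8 + 0.25 * 0.6)

    def test_oracle_classifier_nts_one(self):
        recs = [record("pass", "pass", 1.0, f"t{i}") for i in range(5)]
        rep = trust_spectrum_and_nts(recs)
        assert rep.nts == pytest.approx(1.0)

    def test_confident_adversary_nts_zero(self):
        recs = [record("pass", "fail", 1.0, f"t{i}") for i in range(5)]
        assert trust_spectrum_and_nts(recs).nts == pytest.approx(0.0)

    def test_matches_brute_force_on_random_record_sets(self, rng):
        cfg = TrustConfig()
        for _ in range(50):
            recs = random_records(rng, int(rng.integers(4, 40)))
            rep = trust_spectrum_and_nts(recs, cfg, densities=False)
            # independent brute force
            nts = 0.0
            for z in {r.true_class for r in recs}:
                qs = [r.confidence if r.predicted_class == z else 1 - r.confidence
                      for r in recs if r.true_class == z]
                t_m = sum(qs) / len(qs)
                assert rep.classes[z].trust_spectrum == pytest.approx(t_m)
                nts += len(qs) / len(recs) * t_m
            assert rep.nts == pytest.approx(nts)

    def test_permutation_invariance(self, rng):
        recs = random_records(rng, 30)
        rep1 = trust_spectrum_and_nts(recs, densities=False)
        shuffled = [recs[i] for i in rng.permutation(30)]
        rep2 = trust_spectrum_and_nts(shuffled, densities=False)
        assert rep1.nts == pytest.approx(rep2.nts)
        for z in rep1.classes:
            assert rep1.classes[z].trust_spectrum == pytest.approx(
                rep2.classes[z].trust_spectrum)

    def test_nts_monotonic_in_confidence(self):
        """Raising a correct prediction's C raises NTS; a wrong one's lowers it."""
        base = [record("pass", "pass", 0.7, "a"), record("pass", "fail", 0.7, "b"),
                record("fail", "fail", 0.9, "c")]
        nts0 = trust_spectrum_and_nts(base, densities=False).nts
        up_correct = [record("pass", "pass", 0.9, "a")] + base[1:]
        assert trust_spectrum_and_nts(up_correct, densities=False).nts >= nts0
        up_wrong = [base[0], record("pass", "fail", 0.9, "b"), base[2]]
        assert trust_spectrum_and_nts(up_wrong, densities=False).nts <= nts0

    def test_empty_class_flagged_undefined(self):
        recs = [record("pass", "pass", 0.9, "a"), record("pass", "pass", 0.8, "b")]
        rep = trust_spectrum_and_nts(recs, class_names=["pass", "fail"])
        assert rep.undefined_classes == ["fail"]
        assert rep.classes["fail"].trust_spectrum is None

    def test_conditional_nts_subset_means(self):
        recs = [record("pass", "pass", 0.9, "a"), record("pass", "pass", 0.7, "b"),
                record("pass", "fail", 0.6, "c")]
        rep = trust_spectrum_and_nts(recs)
        assert rep.classes["pass"].conditional_nts_matched == pytest.approx(0.8)
        assert rep.classes["pass"].conditional_nts_mismatched == pytest.approx(0.4)
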