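"""Evaluation statistics: AUC, Youden cutoff, utility panel, McNemar, RF baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lnmil.cohort import cohort_to_frame, generate_cohort
from lnmil.splits import make_version_split
from lnmil.stats import (
    ConfusionCounts,
    _utility_raw,
    clinical_utility,
    confusion_at,
    encode_covariates,
    jsccr_baseline,
    mcnemar,
    reconstruct_counts,
    reduction_vs_guideline,
    rf_baseline,
    roc_auc,
    youden_cutoff,
)


def pairwise_auc_oracle(scores, labels):
    """Exhaustive concordance: ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Scan every candidate threshold, exhaustively."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best = None
    for t in cands:
        pred = scores > t
        sens = (pred & (labels == 1)).sum() / labels.sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        key = (sens + spec - 1, sens, -t)
        if best is None or key > best[0]:
            best = (key, (t, sens, spec))
    return best[1]


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pairwise_example(self):
        # positives {0.9, 0.3}, negatives {0.6, 0.1}: 3 of 4 pairs concordant
        assert roc_auc([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 25), st.integers(1, 25), st.integers(0, 10_000))
    def test_matches_concordance_oracle(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        # coarse grid makes ties frequent, exercising midrank handling
        scores = rng.integers(0, 5, size=n_pos + n_neg) / 4.0
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        assert roc_auc(scores, labels) == pytest.approx(pairwise_auc_oracle(scores, labels))


class TestYouden:
    def test_perfect_separation(self):
        t, sens, spec = youden_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 1.0

    def test_tie_resolved_toward_sensitivity(self):
        # max J = 0.5 at two thresholds; the lower one gives sensitivity 1
        t, sens, spec = youden_cutoff([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0])
        assert t < 0.3
        assert sens == 1.0 and spec == 0.5

    def test_shift_invariance(self):
        scores = [0.9, 0.3, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        t0, s0, p0 = youden_cutoff(scores, labels)
        t1, s1, p1 = youden_cutoff([s + 2.0 for s in scores], labels)
        assert t1 == pytest.approx(t0 + 2.0)
        assert (s1, p1) == (s0, p0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n_pos + n_neg), 2)
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        assert youden_cutoff(scores, labels) == pytest.approx(youden_oracle(scores, labels))


class TestClinicalUtility:
    def test_surgical_test_set_panel(self):
        # 16 tp / 22 fp / 134 tn / 5 fn, a surgical-only held-out set
        rep = clinical_utility(ConfusionCounts(tp=16, fp=22, tn=134, fn=5))
        assert rep.ppv == 42.1
        assert rep.unnecessary_surgery == 57.9

    def test_endoscopic_test_set_panel(self):
        rep = clinical_utility(ConfusionCounts(tp=13, fp=28, tn=38, fn=1))
        assert rep.ppv == 31.7
        assert rep.accuracy == 63.8
        assert rep.unnecessary_surgery == 68.3
        assert rep.missed_lnm == 7.1

    def test_perfect_classifier(self):
        rep = clinical_utility(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.accuracy) == (100, 100, 100, 100)
        assert rep.unnecessary_surgery == 0.0 and rep.missed_lnm == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_complement_identities_before_rounding(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        raw = _utility_raw(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert raw["missed_lnm"] == pytest.approx(100 - raw["sensitivity"], abs=1e-9)
        if raw["ppv"] is not None:
            assert raw["unnecessary_surgery"] == pytest.approx(100 - raw["ppv"], abs=1e-9)


class TestJsccrBaseline:
    def test_endoscopic_test_composition(self):
        _, rep = jsccr_baseline([1] * 14 + [0] * 66)
        assert rep.ppv == 17.5 and rep.unnecessary_surgery == 82.5

    def test_surgical_test_composition(self):
        _, rep = jsccr_baseline([1] * 21 + [0] * 156)
        assert rep.unnecessary_surgery == 88.1

    def test_all_positive_labels(self):
        counts, rep = jsccr_baseline([1, 1, 1])
        assert rep.ppv == 100.0 and rep.unnecessary_surgery == 0.0
        assert rep.specificity == 0.0  # no negatives: 0/0 convention not hit
        assert counts.fp == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.integers(1, 40))
    def test_always_perfect_sensitivity_zero_specificity(self, n_pos, n_neg):
        _, rep = jsccr_baseline([1] * n_pos + [0] * n_neg)
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0
        assert rep.missed_lnm == 0.0


class TestReduction:
    def test_reduction_examples(self):
        m = clinical_utility(ConfusionCounts(tp=13, fp=28, tn=38, fn=1))
        _, g = jsccr_baseline([1] * 14 + [0] * 66)
        assert reduction_vs_guideline(m, g) == 14.2
        m1 = clinical_utility(ConfusionCounts(tp=15, fp=11, tn=145, fn=6))
        _, g1 = jsccr_baseline([1] * 21 + [0] * 156)
        assert reduction_vs_guideline(m1, g1) == 45.8

    def test_identical_reports_give_zero(self):
        _, g = jsccr_baseline([1, 0])
        assert reduction_vs_guideline(g, g) == 0.0


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = np.r_[np.ones(5), np.zeros(5), np.ones(10)].astype(bool)
        b = np.r_[np.zeros(5), np.ones(5), np.ones(10)].astype(bool)
        stat, p = mcnemar(a, b)
        assert stat is None  # exact regime
        assert p == pytest.approx(1.0)

    def test_one_sided_discordance_exact_binomial(self):
        a = np.r_[np.ones(10), np.ones(5)].astype(bool)
        b = np.r_[np.zeros(10), np.ones(5)].astype(bool)
        _, p = mcnemar(a, b)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_chi_square_with_continuity_correction(self):
        a = np.r_[np.ones(30), np.zeros(10), np.ones(5)].astype(bool)
        b = np.r_[np.zeros(30), np.ones(10), np.ones(5)].astype(bool)
        stat, p = mcnemar(a, b)
        assert stat == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)  # 9.025
        assert p == pytest.approx(float(sps.chi2.sf(9.025, 1)))

    def test_no_discordance(self):
        v = np.array([True, False, True])
        stat, p = mcnemar(v, v)
        assert stat is None and p == 1.0

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            mcnemar([True], [True, False])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12))
    def test_exact_p_matches_binomial_oracle(self, b, c):
        if b + c == 0:
            return
        a_vec = np.r_[np.ones(b), np.zeros(c)].astype(bool)
        b_vec = np.r_[np.zeros(b), np.ones(c)].astype(bool)
        _, p = mcnemar(a_vec, b_vec)
        k = min(b, c)
        expect = min(1.0, 2 * sps.binom.cdf(k, b + c, 0.5))
        assert p == pytest.approx(expect, rel=1e-6)


class TestReconstructCounts:
    def test_round_trips_published_rates(self):
        c = reconstruct_counts(92.9, 57.6, 14, 66)
        assert (c.tp, c.fn, c.tn, c.fp) == (13, 1, 38, 28)
        c = reconstruct_counts(71.4, 92.9, 21, 156)
        assert (c.tp, c.fn, c.tn, c.fp) == (15, 6, 145, 11)


class TestRfBaseline:
    @pytest.fixture(scope="class")
    def tabular(self):
        cohort = generate_cohort(300, 300, 0.15, 0.15, seed=21)
        feats = encode_covariates(cohort_to_frame(cohort))
        labels = {r.patient_id: r.lnm_label for r in cohort}
        plan = make_version_split(cohort, 2, seed=21)
        return cohort, feats, labels, plan

    def test_500_trees(self, tabular):
        _, feats, labels, plan = tabular
        y = [labels[p] for p in feats.index]
        _, _, models = rf_baseline(feats, y, plan, seed=0)
        assert all(m.n_estimators == 500 for m in models)

    def test_separable_feature(self, tabular):
        _, feats, labels, plan = tabular
        y = [labels[p] for p in feats.index]
        cheat = feats.copy()
        cheat["oracle"] = [labels[p] + 0.01 * (i % 3) for i, p in enumerate(feats.index)]
        _, auc, _ = rf_baseline(cheat, y, plan, seed=0)
        assert auc >= 0.99

    def test_label_permutation_null(self, tabular):
        _, feats, labels, plan = tabular
        rng = np.random.default_rng(17)
        y = rng.permutation([labels[p] for p in feats.index])
        _, auc, _ = rf_baseline(feats, list(y), plan, seed=0)
        assert 0.35 <= auc <= 0.65

    def test_informative_covariates_beat_chance(self, tabular):
        # lvi/budding are enriched in positives, so the RF should edge past 0.5
        _, feats, labels, plan = tabular
        y = [labels[p] for p in feats.index]
        fold_aucs, auc, _ = rf_baseline(feats, y, plan, seed=0)
        assert len(fold_aucs) == 5
        assert auc > 0.5

    def test_non_numeric_rejected(self, tabular):
        cohort, feats, labels, plan = tabular
        bad = cohort_to_frame(cohort).set_index("patient_id")[["sex"]]
        with pytest.raises(ValueError, match="non-numeric"):
            rf_baseline(bad, [labels[p] for p in bad.index], plan)


def test_confusion_at_threshold():
    counts = confusion_at([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0], 0.5)
    assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)
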