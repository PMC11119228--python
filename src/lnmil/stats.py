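"""ROC/AUC, Youden cutoff, clinical-utility panel, all-positive guideline
baseline, McNemar comparison and the clinicopathologic random-forest baseline.

The clinical-utility panel expresses a binary LNM classifier in surgical-triage
terms: *unnecessary additional surgery* is the fraction of strategy-positive
patients who are truly LNM-negative (= 100 - PPV) and *missed LNM* the fraction
of truly positive patients called negative (= 100 - sensitivity).  The JSCCR
guideline baseline sends every high-risk patient to surgery — an all-positive
classifier with 100% sensitivity and 0% specificity — and the panel quantifies
how much unnecessary surgery a probabilistic model avoids relative to it.

All percentages are rounded half-up to one decimal, matching printed clinical
tables; reductions are differences of the rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .util import nearest_int, round_half_up


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class UtilityReport:
    """Table-style metric panel, percentages rounded half-up to one decimal."""

    sensitivity: float
    specificity: float
    ppv: float | None
    accuracy: float
    unnecessary_surgery: float | None
    missed_lnm: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "unnecessary_surgery": self.unnecessary_surgery,
            "missed_lnm": self.missed_lnm,
        }


def roc_auc(scores, labels) -> float:
    """Rank-based (concordance) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus +/-inf;
    a patient is called positive when score > threshold.  Ties are broken
    toward higher sensitivity, then toward the lower threshold.  Returns
    ``(threshold, sensitivity, specificity)`` as fractions.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("Youden cutoff needs both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    best = None
    for t in candidates:
        pred = scores > t
        sens = float((pred & (labels == 1)).sum()) / n_pos
        spec = float((~pred & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)  # maximize J, then sensitivity, then prefer lower t
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec))
    return best[1]


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int((pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )


def _utility_raw(c: ConfusionCounts) -> dict:
    """Unrounded panel; identities unnecessary = 100 - ppv and
    missed = 100 - sensitivity hold exactly here.

    Degenerate one-class inputs use the 0/0 -> "all correct" convention
    (e.g. specificity is 0 when there are no negatives and none were called
    negative), so the all-positive guideline strategy is well defined on any
    label vector.
    """
    if c.n_pos == 0 and c.n_neg == 0:
        raise ValueError("empty confusion matrix")
    n_called_pos = c.tp + c.fp
    sens = 100.0 * c.tp / c.n_pos if c.n_pos else (100.0 if c.fn == 0 else 0.0)
    spec = 100.0 * c.tn / c.n_neg if c.n_neg else (100.0 if c.fp else 0.0)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": 100.0 * (c.tp + c.tn) / (c.n_pos + c.n_neg),
        "missed_lnm": 100.0 - sens,
    }
    if n_called_pos > 0:
        out["ppv"] = 100.0 * c.tp / n_called_pos
        out["unnecessary_surgery"] = 100.0 * c.fp / n_called_pos
    else:
        out["ppv"] = None
        out["unnecessary_surgery"] = None
    return out


def clinical_utility(counts: ConfusionCounts) -> UtilityReport:
    """The clinical-utility panel for one strategy (rounded percentages)."""
    raw = _utility_raw(counts)
    rnd = {k: (round_half_up(v, 1) if v is not None else None) for k, v in raw.items()}
    return UtilityReport(**rnd)


def jsccr_baseline(labels) -> tuple[ConfusionCounts, UtilityReport]:
    """All-positive guideline strategy: everyone is sent to surgery."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty labels")
    counts = ConfusionCounts(tp=int(labels.sum()), fp=int((labels == 0).sum()), tn=0, fn=0)
    return counts, clinical_utility(counts)


def reduction_vs_guideline(model: UtilityReport, guideline: UtilityReport) -> float:
    """Unnecessary-surgery percentage points avoided vs the guideline.

    Computed as the difference of the already-rounded panel values, which is
    how printed tables do the arithmetic.
    """
    if model.unnecessary_surgery is None or guideline.unnecessary_surgery is None:
        raise ValueError("unnecessary-surgery rate undefined (no called positives)")
    return round_half_up(guideline.unnecessary_surgery - model.unnecessary_surgery, 1)


def reconstruct_counts(sens_pct: float, spec_pct: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Bridge from a published sensitivity/specificity to integer counts
    (nearest-integer rounding of rate x n)."""
    tp = nearest_int(sens_pct / 100.0 * n_pos)
    tn = nearest_int(spec_pct / 100.0 * n_neg)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def mcnemar(correct_a, correct_b, exact_limit: int = 25) -> tuple[float | None, float]:
    """Paired comparison of two strategies' per-patient correctness vectors.

    Discordant counts: b = (a correct, b wrong), c = (a wrong, b correct).
    Exact two-sided binomial p when b + c < ``exact_limit``, else the
    continuity-corrected chi-square (|b-c|-1)^2/(b+c).  Returns
    ``(statistic or None, p)``; with no discordant pairs p = 1.0.
    """
    a = np.asarray(correct_a, dtype=bool)
    bv = np.asarray(correct_b, dtype=bool)
    if a.shape != bv.shape:
        raise ValueError("correctness vectors must be paired (equal length)")
    b = int((a & ~bv).sum())
    c = int((~a & bv).sum())
    if b + c == 0:
        return None, 1.0
    table = [[int((a & bv).sum()), b], [c, int((~a & ~bv).sum())]]
    exact = (b + c) < exact_limit
    res = _sm_mcnemar(table, exact=exact, correction=True)
    stat = None if exact else float(res.statistic)
    return stat, float(res.pvalue)


def rf_baseline(features, labels, plan, n_trees: int = 500, seed: int = 0):
    """Random-forest clinicopathologic baseline under the same CV/ensemble
    protocol as the MIL model.

    ``features`` is a numeric patient-level DataFrame indexed by patient_id;
    non-numeric columns are rejected (encode categoricals first).  Returns
    ``(fold_aucs, test_auc, models)``.
    """
    import pandas as pd

    feats = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    bad = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric feature columns must be encoded: {bad}")
    y = pd.Series(np.asarray(labels, dtype=int), index=feats.index)

    fold_aucs, models = [], []
    folds = sorted(set(plan.fold_assignment.values()))
    for k in folds:
        tr = [p for p in plan.train_patient_ids if plan.fold_assignment[p] != k]
        va = [p for p in plan.train_patient_ids if plan.fold_assignment[p] == k]
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=(seed + k) % (2**32))
        rf.fit(feats.loc[tr], y.loc[tr])
        fold_aucs.append(roc_auc(rf.predict_proba(feats.loc[va])[:, 1], y.loc[va]))
        models.append(rf)
    test_ids = plan.test_patient_ids
    probs = np.mean([m.predict_proba(feats.loc[test_ids])[:, 1] for m in models], axis=0)
    test_auc = roc_auc(probs, y.loc[test_ids])
    return fold_aucs, test_auc, models


def encode_covariates(cohort_frame) -> "pd.DataFrame":  # noqa: F821
    """Numeric encoding of the cohort covariate table for the RF baseline.

    Covariates follow the clinicopathologic feature list: age, sex, BMI,
    comorbidity, family history, smoking, alcohol, location, cancer size,
    SM depth, differentiation, LVI, budding, MSI.
    """
    import pandas as pd

    df = cohort_frame.set_index("patient_id")
    lvl3 = {"never": 0, "ex": 1, "current": 2}
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"]
    out["sex"] = (df["sex"] == "M").astype(int)
    out["bmi"] = df["bmi"]
    out["comorbidity"] = df["comorbidity"]
    out["family_history"] = df["family_history"]
    out["smoking"] = df["smoking"].map(lvl3)
    out["alcohol"] = df["alcohol"].map(lvl3)
    out["tumor_location"] = (df["tumor_location"] == "right").astype(int)
    out["cancer_size_mm"] = df["cancer_size_mm"]
    out["sm_depth_um"] = df["sm_depth_um"]
    out["differentiation"] = df["differentiation"].map({"well": 0, "moderate": 1, "poor": 2})
    out["lvi"] = df["lvi"]
    out["budding"] = df["budding"]
    out["msi"] = df["msi"].map({"stable": 0, "unstable": 1, "unknown": 2})
    return out
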