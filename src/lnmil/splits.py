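"""Patient-level train/test versions, stratified 5-fold CV, and ensembling.

The evaluation protocol defines four "versions" built from one global
class-by-specimen-stratified 80/20 patient split:

* Version 1 — train and test restricted to surgical patients;
* Version 2 — the global split as-is (both specimen types on both sides);
* Version 3 — full training set, test restricted to surgical patients;
* Version 4 — full training set, test restricted to endoscopic patients.

Versions 2–4 share the one randomization, so the version-3 and version-4 test
sets partition the version-2 test set exactly.  Per-stratum training counts
are floor(0.8 n) with largest-remainder reallocation so the per-class totals
equal floor(0.8 n_class); remainder ties go to the endoscopic stratum.

Folds are assigned at patient level with class stratification; every slide of
a patient stays on one side of every split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import ENDOSCOPIC, SURGICAL, PatientRecord
from .model import ModelParams, predict_bag, pretrain_fe, train_end_to_end
from .stats import roc_auc
from .tiling import Bag

VERSIONS = (1, 2, 3, 4)


@dataclass
class SplitPlan:
    version: int
    train_patient_ids: list[str]
    test_patient_ids: list[str]
    fold_assignment: dict[str, int]  # patient_id -> fold in 1..5
    seed: int

    def check_no_leak(self) -> None:
        if set(self.train_patient_ids) & set(self.test_patient_ids):
            raise AssertionError("patient appears in both train and test")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "train_patient_ids": self.train_patient_ids,
                    "test_patient_ids": self.test_patient_ids,
                    "fold_assignment": self.fold_assignment,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["version"], d["train_patient_ids"], d["test_patient_ids"],
                   {k: int(v) for k, v in d["fold_assignment"].items()}, d["seed"])


@dataclass
class PatientPrediction:
    patient_id: str
    probability: float
    true_label: int


def _apportion_train_counts(counts: dict[tuple[str, int], int], ratio: float = 0.8):
    """Largest-remainder apportionment of per-stratum training counts.

    For each class, stratum quotas floor(ratio*n) are topped up in order of
    fractional remainder until the class total floor(ratio*N_class) is met;
    ties favour the endoscopic stratum.
    """
    train: dict[tuple[str, int], int] = {}
    for label in (0, 1):
        strata = [s for s in (ENDOSCOPIC, SURGICAL) if (s, label) in counts]
        total = sum(counts[(s, label)] for s in strata)
        target = int(np.floor(ratio * total))
        quotas = {s: ratio * counts[(s, label)] for s in strata}
        base = {s: int(np.floor(quotas[s])) for s in strata}
        short = target - sum(base.values())
        # remainder desc, endoscopic first on ties (rounded so float noise in
        # ratio*n cannot decide a genuine tie)
        order = sorted(strata, key=lambda s: (-round(quotas[s] - base[s], 9), s != ENDOSCOPIC))
        for s in order[:short]:
            base[s] += 1
        for s in strata:
            train[(s, label)] = base[s]
    return train


def make_version_split(cohort: list[PatientRecord], version: int, seed: int = 0,
                       n_folds: int = 5) -> SplitPlan:
    """Build the patient-level split for one version (deterministic given seed)."""
    if version not in VERSIONS:
        raise ValueError(f"version must be one of {VERSIONS}")
    strata_ids: dict[tuple[str, int], list[str]] = {}
    for r in cohort:
        strata_ids.setdefault((r.specimen_type, r.lnm_label), []).append(r.patient_id)
    present = {r.specimen_type for r in cohort}
    if version >= 2 and present != {ENDOSCOPIC, SURGICAL}:
        raise ValueError("versions 2-4 need both specimen types in the cohort")

    rng = np.random.default_rng(seed)
    counts = {k: len(v) for k, v in strata_ids.items()}
    train_counts = _apportion_train_counts(counts)
    train_ids, test_ids = [], []
    for key in sorted(strata_ids):
        ids = sorted(strata_ids[key])
        rng.shuffle(ids)
        k = train_counts[key]
        train_ids += ids[:k]
        test_ids += ids[k:]

    stratum_of = {r.patient_id: r.specimen_type for r in cohort}
    label_of = {r.patient_id: r.lnm_label for r in cohort}
    if version == 1:
        train_ids = [p for p in train_ids if stratum_of[p] == SURGICAL]
        test_ids = [p for p in test_ids if stratum_of[p] == SURGICAL]
    elif version == 3:
        test_ids = [p for p in test_ids if stratum_of[p] == SURGICAL]
    elif version == 4:
        test_ids = [p for p in test_ids if stratum_of[p] == ENDOSCOPIC]

    train_ids = sorted(train_ids)
    y = np.array([label_of[p] for p in train_ids])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    fold_assignment: dict[str, int] = {}
    for fold, (_tr, val) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        for i in val:
            fold_assignment[train_ids[i]] = fold
    plan = SplitPlan(version, train_ids, sorted(test_ids), fold_assignment, seed)
    plan.check_no_leak()
    return plan


def split_counts(plan: SplitPlan, cohort: list[PatientRecord]) -> dict:
    """Patient counts by side and class (for checking against published tables)."""
    label_of = {r.patient_id: r.lnm_label for r in cohort}
    out = {}
    for side, ids in (("train", plan.train_patient_ids), ("test", plan.test_patient_ids)):
        pos = sum(label_of[p] for p in ids)
        out[side] = {"pos": pos, "neg": len(ids) - pos}
    return out


def run_cv(plan: SplitPlan, bags: list[Bag], trainer: dict | None = None,
           seed: int | None = None) -> tuple[list[ModelParams], list[float]]:
    """Train one model per fold (pretraining the FE fold-wise) and log val AUCs.

    Fold k trains on folds != k and validates on fold k at patient level.  The
    FE of each fold is pre-trained only on that fold's training patients, so no
    validation patch is seen before validation.
    """
    seed = plan.seed if seed is None else seed
    by_pid: dict[str, list[Bag]] = {}
    for b in bags:
        by_pid.setdefault(b.patient_id, []).append(b)
    missing = [p for p in plan.train_patient_ids if p not in by_pid]
    if missing:
        raise ValueError(f"bags missing for training patients: {missing[:5]}")
    label_of = {p: next(b.inherited_label for b in bs) for p, bs in by_pid.items()}

    folds = sorted(set(plan.fold_assignment.values()))
    models, fold_aucs = [], []
    for k in folds:
        tr_pids = [p for p in plan.train_patient_ids if plan.fold_assignment[p] != k]
        va_pids = [p for p in plan.train_patient_ids if plan.fold_assignment[p] == k]
        for name, pids in (("training", tr_pids), ("validation", va_pids)):
            labs = {label_of[p] for p in pids}
            if labs != {0, 1}:
                raise ValueError(f"fold {k}: {name} side has a single class; enlarge the cohort")
        tr_bags = [b for p in tr_pids for b in by_pid[p]]
        fe = pretrain_fe(tr_bags, hyper=trainer, seed=seed + 100 * k)
        mdl = train_end_to_end(tr_bags, init=fe, hyper=trainer, seed=seed + 100 * k + 1)
        preds = ensemble_predict([mdl], [b for p in va_pids for b in by_pid[p]],
                                 patient_ids=va_pids)
        auc = roc_auc([pp.probability for pp in preds], [pp.true_label for pp in preds])
        models.append(mdl)
        fold_aucs.append(auc)
    return models, fold_aucs


def ensemble_predict(models: list[ModelParams], bags: list[Bag],
                     patient_ids: list[str] | None = None) -> list[PatientPrediction]:
    """Average fold-model probabilities per slide, then slides per patient."""
    by_pid: dict[str, list[Bag]] = {}
    for b in bags:
        by_pid.setdefault(b.patient_id, []).append(b)
    pids = sorted(by_pid) if patient_ids is None else list(patient_ids)
    missing = [p for p in pids if p not in by_pid]
    if missing:
        raise ValueError(f"no slides for test patients: {missing[:5]}")
    out = []
    for pid in pids:
        slide_probs = []
        for bag in by_pid[pid]:
            probs = [predict_bag(m, bag).probability for m in models]
            slide_probs.append(float(np.mean(probs)))
        out.append(
            PatientPrediction(
                patient_id=pid,
                probability=float(np.mean(slide_probs)),
                true_label=by_pid[pid][0].inherited_label,
            )
        )
    return out
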