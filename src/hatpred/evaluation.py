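"""Performance evaluation: Sn/Sp/Pr, ROC/AUC, LOO and k-fold validation.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP) and precision
Pr = TP/(TP+FP); a prediction is positive when score >= cutoff.  Undefined
ratios (0/0) are reported as ``None`` rather than 0.

The score-cutoff convention used throughout (training objective, threshold
calibration): the cutoff at a target specificity is the smallest observed
score value such that the fraction of negatives strictly below it reaches
the target; tied negative scores push the cutoff above the whole tied block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SiteAnnotation, Substrate, build_dataset
from .scoring import HatModel, ScoringError, score_dataset


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


@dataclass
class EvalReport:
    """Per-example scores with the derived ROC curve and summary metrics."""

    hat: str
    scheme: str
    scores: pd.DataFrame  # columns protein_id, position, label, score
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    metrics_at: dict[float, tuple] = field(default_factory=dict)

    @property
    def positive_scores(self) -> np.ndarray:
        return self.scores.loc[self.scores["label"] == "positive", "score"].to_numpy()

    @property
    def negative_scores(self) -> np.ndarray:
        return self.scores.loc[self.scores["label"] == "negative", "score"].to_numpy()

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "hat": self.hat,
            "scheme": self.scheme,
            "n_positive": int((self.scores["label"] == "positive").sum()),
            "n_negative": int((self.scores["label"] == "negative").sum()),
            "auc": self.auc,
            "metrics_at": {
                str(c): {"Sn": sn, "Sp": sp, "Pr": pr}
                for c, (sn, sp, pr) in self.metrics_at.items()
            },
        }


def confusion_at(
    scores: Sequence[float], labels: Sequence[str], cutoff: float
) -> ConfusionCounts:
    """Confusion counts with the inclusive rule: positive iff score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise EvaluationError("no examples")
    pos = labels == "positive"
    called = scores >= cutoff
    return ConfusionCounts(
        TP=int((pos & called).sum()),
        FP=int((~pos & called).sum()),
        TN=int((~pos & ~called).sum()),
        FN=int((pos & ~called).sum()),
    )


def sn_sp_pr(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """Sensitivity, specificity and precision; 0/0 ratios return None."""
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    pr = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else None
    return sn, sp, pr


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC over all distinct cutoffs and the trapezoidal AUC.

    Tied scores are grouped (one ROC vertex per distinct score), which makes
    the trapezoidal area equal to the Mann-Whitney statistic with half credit
    for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "positive"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    # group boundaries: indices where the next score differs
    boundary = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tp_cum = np.cumsum(sorted_pos)[boundary]
    fp_cum = np.cumsum(~sorted_pos)[boundary]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def cutoff_at_specificity(neg_scores: Sequence[float], target: float) -> float:
    """Smallest score value whose specificity (fraction of negatives strictly
    below) reaches ``target``; above the maximum negative if none qualifies."""
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    n = neg.size
    if n == 0:
        raise EvaluationError("no negative scores")
    need = math.ceil(target * n)  # negatives that must fall strictly below
    if need == 0:
        return float(neg[0])
    distinct = np.unique(neg)
    below = np.searchsorted(neg, distinct, side="left")
    ok = np.nonzero(below >= need)[0]
    if ok.size:
        return float(distinct[ok[0]])
    return float(np.nextafter(neg[-1], np.inf))


def sn_at_sp(
    pos_scores: Sequence[float], neg_scores: Sequence[float], sp_anchor: float
) -> float:
    """Sensitivity at the cutoff anchored at a target specificity."""
    cutoff = cutoff_at_specificity(neg_scores, sp_anchor)
    pos = np.asarray(pos_scores, dtype=float)
    if pos.size == 0:
        raise EvaluationError("no positive scores")
    return float((pos >= cutoff).mean())


#: Tier name -> specificity target used when calibrating score thresholds.
TIER_SPECIFICITY = {"high": 0.95, "medium": 0.90, "low": 0.85}


def calibrate_thresholds(report: EvalReport) -> dict[str, float]:
    """High/medium/low cutoffs at LOO specificities of ~0.95/0.90/0.85."""
    neg = report.negative_scores
    cuts = {
        tier: cutoff_at_specificity(neg, sp) for tier, sp in TIER_SPECIFICITY.items()
    }
    assert cuts["high"] >= cuts["medium"] >= cuts["low"]
    return cuts


def _assemble_report(hat: str, scheme: str, scores: pd.DataFrame) -> EvalReport:
    points, auc = roc_auc(scores["score"], scores["label"])
    report = EvalReport(hat=hat, scheme=scheme, scores=scores, roc_points=points, auc=auc)
    for tier, sp in TIER_SPECIFICITY.items():
        cut = cutoff_at_specificity(report.negative_scores, sp)
        report.metrics_at[cut] = sn_sp_pr(
            confusion_at(scores["score"], scores["label"], cut)
        )
    return report


def loo_validate(
    substrates: Sequence[Substrate],
    annotations: Sequence[SiteAnnotation],
    hat: str,
    model: HatModel,
) -> EvalReport:
    """Leave-one-out validation: positives scored with self-exclusion."""
    dataset = build_dataset(substrates, annotations, hat, model.m, model.n)
    scores = score_dataset(dataset, model, loo=True)
    return _assemble_report(hat, "loo", scores)


def kfold_validate(
    substrates: Sequence[Substrate],
    annotations: Sequence[SiteAnnotation],
    hat: str,
    k: int,
    seed: int,
    model: HatModel,
    retrain: bool = False,
    config=None,
) -> EvalReport:
    """Stratified k-fold cross-validation.

    Positives and negatives are split into k folds independently with a
    seeded RNG.  Each fold is scored against a model whose reference
    peptides come only from the other folds' positives; with
    ``retrain=True`` the position weights and matrix are additionally
    re-trained on the training folds (see the training module).
    """
    dataset = build_dataset(substrates, annotations, hat, model.m, model.n)
    n_pos = len(dataset.positives)
    if k > n_pos:
        raise EvaluationError(
            f"k={k} exceeds the {n_pos} positive sites available for {hat}"
        )
    if k < 2:
        raise EvaluationError("k must be at least 2")
    rng = np.random.default_rng(seed)
    pos_fold = np.arange(n_pos) % k
    rng.shuffle(pos_fold)
    neg_fold = np.arange(len(dataset.negatives)) % k
    rng.shuffle(neg_fold)

    frames = []
    for fold in range(k):
        train_pos = [w for w, f in zip(dataset.positives, pos_fold) if f != fold]
        test_pos = [w for w, f in zip(dataset.positives, pos_fold) if f == fold]
        test_neg = [w for w, f in zip(dataset.negatives, neg_fold) if f == fold]
        fold_model = HatModel(
            hat=hat,
            m=model.m,
            n=model.n,
            matrix=model.matrix.copy(),
            weights=model.weights.copy(),
            positives=train_pos,
        )
        if retrain:
            from .training import mutate_matrix, train_weights

            train_neg = [w for w, f in zip(dataset.negatives, neg_fold) if f != fold]
            sub = type(dataset)(
                hat=hat, m=model.m, n=model.n, positives=train_pos, negatives=train_neg
            )
            fold_model.weights, _ = train_weights(sub, fold_model, config)
            fold_model.matrix, _ = mutate_matrix(sub, fold_model, config)
        fold_ds = type(dataset)(
            hat=hat, m=model.m, n=model.n, positives=test_pos, negatives=test_neg
        )
        if not test_pos and not test_neg:
            continue
        try:
            frames.append(score_dataset(fold_ds, fold_model, loo=False))
        except ScoringError:
            raise EvaluationError(f"fold {fold} has no reference peptides")
    scores = pd.concat(frames, ignore_index=True)
    return _assemble_report(hat, f"kfold({k})", scores)
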