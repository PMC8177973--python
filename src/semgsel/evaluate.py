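"""Gesture-classification evaluation with an RBF-kernel SVM.

Windows restricted to the selected channels/features are classified under
stratified k-fold cross-validation (default 5 folds); precision and recall
are computed per class from one-vs-rest confusion counts and
macro-averaged, accuracy both per fold and overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per class."""

    classes: tuple
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])).tolist())
        n = len(y_true)
        tp, fp, tn, fn = (np.zeros(len(classes), dtype=int) for _ in range(4))
        for k, c in enumerate(classes):
            t = y_true == c
            p = y_pred == c
            tp[k] = np.sum(t & p)
            fp[k] = np.sum(~t & p)
            fn[k] = np.sum(t & ~p)
            tn[k] = n - tp[k] - fp[k] - fn[k]
        return cls(classes=classes, tp=tp, fp=fp, tn=tn, fn=fn)

    @property
    def n_total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0]) \
            if len(self.classes) else 0


def _safe_div(num, den):
    """num/den with 0 (and a flag) where the denominator is zero."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    undef = den == 0
    out = np.where(undef, 0.0, num / np.where(undef, 1.0, den))
    return out, undef


def compute_metrics(cc: ConfusionCounts) -> dict:
    """Per-class and macro precision/recall/accuracy from one-vs-rest
    counts.  Undefined ratios (zero denominator) are reported as 0 and
    flagged."""
    prec, prec_undef = _safe_div(cc.tp, cc.tp + cc.fp)
    rec, rec_undef = _safe_div(cc.tp, cc.tp + cc.fn)
    acc = (cc.tp + cc.tn) / np.maximum(cc.tp + cc.fp + cc.tn + cc.fn, 1)
    overall = float(cc.tp.sum()) / cc.n_total if cc.n_total else 0.0
    per_class = {
        str(c): {
            "precision": float(prec[k]),
            "recall": float(rec[k]),
            "accuracy": float(acc[k]),
            "precision_undefined": bool(prec_undef[k]),
            "recall_undefined": bool(rec_undef[k]),
            "tp": int(cc.tp[k]), "fp": int(cc.fp[k]),
            "tn": int(cc.tn[k]), "fn": int(cc.fn[k]),
        }
        for k, c in enumerate(cc.classes)
    }
    return {
        "per_class": per_class,
        "macro_precision": float(prec.mean()) if len(prec) else 0.0,
        "macro_recall": float(rec.mean()) if len(rec) else 0.0,
        "overall_accuracy": overall,
    }


@dataclass
class EvalReport:
    """Cross-validation report; serializes losslessly to/from JSON."""

    accuracy_mean: float
    fold_accuracies: list
    overall_accuracy: float
    macro_precision: float
    macro_recall: float
    per_class: dict
    channels: list
    features: list
    folds: int
    seed: int
    classifier: dict

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kw)

    @classmethod
    def from_json(cls, s: str) -> "EvalReport":
        return cls(**json.loads(s))

    def summary(self) -> str:
        lines = [
            "SVM-RBF cross-validated gesture classification",
            "=" * 46,
            f"channels          {self.channels}",
            f"features          {self.features}",
            f"folds / seed      {self.folds} / {self.seed}",
            f"mean accuracy     {100 * self.accuracy_mean:.2f}%",
            f"macro precision   {100 * self.macro_precision:.2f}%",
            f"macro recall      {100 * self.macro_recall:.2f}%",
        ]
        return "\n".join(lines)


DEFAULT_CLF = {"C": 1.0, "gamma": "scale", "kernel": "rbf"}


def crossval_evaluate(feat, subset_channels=None, subset_features=None,
                      folds: int = 5, clf_config: dict | None = None,
                      seed: int = 0) -> EvalReport:
    """Stratified k-fold CV of an SVM-RBF on the selected rows.

    The scaler is fit on training folds only.  Raises when some class has
    fewer members than folds (reduce ``folds``).
    """
    fm = feat
    if subset_channels is not None or subset_features is not None:
        fm = fm.subset(channels=subset_channels, features=subset_features)
    X = fm.values.T            # windows x variables
    y = np.asarray(fm.col_labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {int(counts.min())} windows; "
            f"use folds <= {int(counts.min())}")
    cfg = dict(DEFAULT_CLF)
    if clf_config:
        cfg.update(clf_config)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_acc = []
    for tr, te in skf.split(X, y):
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svm", SVC(**cfg))])
        pipe.fit(X[tr], y[tr])
        pred = pipe.predict(X[te])
        y_pred[te] = pred
        fold_acc.append(float(np.mean(pred == y[te])))
    metrics = compute_metrics(ConfusionCounts.from_predictions(y, y_pred))
    channels = sorted({str(ch) for ch, _ in fm.row_index})
    feats_used = []
    for _, ft in fm.row_index:
        if ft not in feats_used:
            feats_used.append(ft)
    return EvalReport(
        accuracy_mean=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc,
        overall_accuracy=metrics["overall_accuracy"],
        macro_precision=metrics["macro_precision"],
        macro_recall=metrics["macro_recall"],
        per_class=metrics["per_class"],
        channels=channels,
        features=feats_used,
        folds=folds,
        seed=seed,
        classifier=cfg,
    )
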