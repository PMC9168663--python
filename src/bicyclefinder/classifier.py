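"""Binomial logistic classifier over structural features.

The model is a GLM with logit link fitted by iteratively reweighted least
squares on transcripts labeled ``family`` (coded 1) or ``non_family``
(coded 0); unlabeled transcripts never enter training.  The classification
threshold is not 0.5 but the grid cutoff (0 to 0.98 in steps of 0.02) at
which the precision/recall ratio is closest to 1, so that false positives
and false negatives are expected in roughly equal numbers.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from bicyclefinder.structure_features import FEATURE_NAMES

#: probability grid scanned for the cutoff: 0, 0.02, ..., 0.98
DEFAULT_GRID = tuple(round(0.02 * i, 2) for i in range(50))

#: deterministic tie-break when several cutoffs are equally close to P/R = 1
TIE_BREAK_RULE = "min |P/R - 1|, then max (P + R), then lowest threshold"


@dataclass
class ClassifierModel:
    """Fitted coefficients, intercept, selected probability cutoff and metadata."""

    coefficients: dict[str, float]
    intercept: float
    cutoff: float | None = None
    training_meta: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "cutoff": self.cutoff,
                "training_meta": self.training_meta,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | os.PathLike) -> "ClassifierModel":
        if os.path.exists(str(text_or_path)):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        else:
            obj = json.loads(text_or_path)
        return cls(
            coefficients=dict(obj["coefficients"]),
            intercept=float(obj["intercept"]),
            cutoff=None if obj.get("cutoff") is None else float(obj["cutoff"]),
            training_meta=dict(obj.get("training_meta", {})),
        )


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray  # NaN where no positive predictions
    recall: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


@dataclass
class CrossValResult:
    cutoffs: np.ndarray
    mean: float
    sd: float
    n_replicates: int
    n_skipped: int
    error: str | None = None


def _design_matrix(
    features: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in predictors if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks predictor column(s): {missing}")
    X = features.loc[:, list(predictors)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in design matrix")
    return np.column_stack([np.ones(len(X)), X]), X


def _labeled_rows(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    mask = features["label"].isin(["family", "non_family"])
    sub = features.loc[mask]
    y = (sub["label"] == "family").to_numpy(dtype=float)
    return sub, y


def fit_logistic(
    features: pd.DataFrame,
    predictors: Sequence[str] = FEATURE_NAMES,
    ridge_alpha: float | None = None,
    maxiter: int = 200,
) -> ClassifierModel:
    """Maximum-likelihood logistic fit (IRLS) of family membership on predictors.

    Only rows labeled ``family``/``non_family`` are used.  Quasi-separation
    -- near-inevitable here, since the family is structurally extreme --
    is detected and flagged in ``training_meta['separation']``; the
    iteration-capped estimate is returned, or a ridge-penalized refit when
    ``ridge_alpha`` is given (the penalty is recorded).  The cutoff is not
    set; see :func:`select_cutoff` / :func:`train_classifier`.
    """
    sub, y = _labeled_rows(features)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"training requires both classes; got {n_pos} family / {n_neg} non_family rows"
        )
    Xc, _ = _design_matrix(sub, predictors)
    glm = sm.GLM(y, Xc, family=sm.families.Binomial())
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        res = glm.fit(maxiter=maxiter, tol=1e-10)
        separation = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.converged)
    if not np.all(np.isfinite(params)):
        separation = True
    if separation and ridge_alpha is not None:
        params = np.asarray(
            glm.fit_regularized(alpha=ridge_alpha, L1_wt=0.0).params, dtype=float
        )
        converged = True
    meta = {
        "n_positive": n_pos,
        "n_negative": n_neg,
        "converged": converged,
        "separation": separation,
        "ridge_alpha": ridge_alpha if separation else None,
        "predictors": list(predictors),
    }
    return ClassifierModel(
        coefficients=dict(zip(predictors, (float(b) for b in params[1:]))),
        intercept=float(params[0]),
        training_meta=meta,
    )


def predict_prob(model: ClassifierModel, features: pd.DataFrame) -> np.ndarray:
    """Per-row probability 1/(1+exp(-(intercept + x.beta))) of family membership."""
    predictors = list(model.coefficients)
    _, X = _design_matrix(features, predictors)
    eta = model.intercept + X @ np.array([model.coefficients[p] for p in predictors])
    return expit(eta)


def _counts_at(probs: np.ndarray, labels: np.ndarray, t: float) -> tuple[int, int, int, int]:
    pred = probs >= t  # closed at the threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def precision_recall_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_GRID,
) -> PRCurve:
    """Precision and recall over the threshold grid.

    Predicted-positive means ``p >= t``.  Precision is NaN at thresholds
    with no positive predictions (TP + FP = 0) rather than imputed.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have the same length")
    if labels.sum() == 0:
        raise ValueError("precision-recall curve requires at least one positive label")
    rows = [_counts_at(probs, labels, t) for t in thresholds]
    tp, fp, fn, tn = (np.array(col) for col in zip(*rows))
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    recall = tp / (tp + fn)
    return PRCurve(np.asarray(thresholds, dtype=float), precision, recall, tp, fp, fn, tn)


def select_cutoff(curve: PRCurve) -> float:
    """Grid threshold at which precision/recall is closest to 1.

    Considers only thresholds where the ratio is defined (precision
    defined, recall > 0).  Ties break by larger precision + recall, then by
    the lower threshold (:data:`TIE_BREAK_RULE`).
    """
    best: tuple[float, float, float] | None = None
    best_t: float | None = None
    for t, p, r in zip(curve.thresholds, curve.precision, curve.recall):
        if math.isnan(p) or r == 0:
            continue
        key = (abs(p / r - 1.0), -(p + r), t)
        if best is None or key < best:
            best, best_t = key, float(t)
    if best_t is None:
        raise ValueError("no threshold with a defined precision/recall ratio")
    return best_t


def evaluate_at(probs: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[float, float]:
    """(precision, recall) at a fixed probability cutoff; precision NaN if no calls."""
    tp, fp, fn, _ = _counts_at(np.asarray(probs, float), np.asarray(labels, int), cutoff)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall


def train_classifier(
    features: pd.DataFrame,
    predictors: Sequence[str] = FEATURE_NAMES,
    thresholds: Sequence[float] = DEFAULT_GRID,
    ridge_alpha: float | None = None,
) -> ClassifierModel:
    """Fit on all labeled rows and select the P/R-equalized cutoff on the training set."""
    model = fit_logistic(features, predictors=predictors, ridge_alpha=ridge_alpha)
    sub, y = _labeled_rows(features)
    curve = precision_recall_curve(predict_prob(model, sub), y, thresholds)
    model.cutoff = select_cutoff(curve)
    p, r = evaluate_at(predict_prob(model, sub), y, model.cutoff)
    model.training_meta.update(
        {
            "cutoff_tie_break": TIE_BREAK_RULE,
            "training_precision": p,
            "training_recall": r,
        }
    )
    return model


def cross_validate(
    features: pd.DataFrame,
    train_frac: float = 0.7,
    reps: int = 100,
    seed: int | None = None,
    predictors: Sequence[str] = FEATURE_NAMES,
    thresholds: Sequence[float] = DEFAULT_GRID,
    ridge_alpha: float | None = None,
) -> CrossValResult:
    """Distribution of the selected cutoff over random train/test splits.

    Each replicate draws an unstratified uniform ``train_frac`` split, fits
    on the training part and selects the cutoff on held-out predictions.
    Replicates whose train or test part is single-class are skipped and
    counted.  Fully reproducible under a fixed seed.
    """
    if reps <= 0:
        return CrossValResult(np.array([]), float("nan"), float("nan"), 0, 0, "reps must be >= 1")
    sub, y = _labeled_rows(features)
    sub = sub.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(sub)
    n_train = int(round(train_frac * n))
    cutoffs = []
    skipped = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(te) == 0 or len(set(y[tr])) < 2 or len(set(y[te])) < 2:
            skipped += 1
            continue
        try:
            model = fit_logistic(sub.iloc[tr], predictors=predictors, ridge_alpha=ridge_alpha)
            curve = precision_recall_curve(
                predict_prob(model, sub.iloc[te]), y[te], thresholds
            )
            cutoffs.append(select_cutoff(curve))
        except ValueError:
            skipped += 1
    arr = np.array(cutoffs)
    mean = float(arr.mean()) if arr.size else float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return CrossValResult(arr, mean, sd, reps, skipped)


def ablate_predictors(
    features: pd.DataFrame,
    full_model: ClassifierModel,
    ridge_alpha: float | None = None,
) -> pd.DataFrame:
    """Drop-one and single-predictor refits, all scored at the full model's cutoff.

    Returns one row per configuration (``full``, ``drop:<name>``,
    ``single:<name>``) with precision and recall on the labeled rows at
    ``full_model.cutoff``; configurations whose refit fails are marked
    ``failed`` and do not abort the rest.
    """
    if full_model.cutoff is None:
        raise ValueError("full model has no cutoff; train it first")
    predictors = list(full_model.coefficients)
    sub, y = _labeled_rows(features)
    configs: list[tuple[str, str, list[str]]] = [("full", "full", predictors)]
    for p in predictors:
        configs.append((f"drop:{p}", "drop_one", [q for q in predictors if q != p]))
    for p in predictors:
        configs.append((f"single:{p}", "single", [p]))
    rows = []
    for name, kind, preds in configs:
        try:
            if name == "full":
                model = full_model
            else:
                model = fit_logistic(sub, predictors=preds, ridge_alpha=ridge_alpha)
            prec, rec = evaluate_at(predict_prob(model, sub), y, full_model.cutoff)
            rows.append(
                {"config": name, "kind": kind, "precision": prec, "recall": rec, "failed": False}
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                {
                    "config": name,
                    "kind": kind,
                    "precision": float("nan"),
                    "recall": float("nan"),
                    "failed": True,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


def classify_candidates(model: ClassifierModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score a feature table and flag rows with probability >= cutoff as candidates."""
    if model.cutoff is None:
        raise ValueError("model has no cutoff; train or set one before classifying")
    out = features.copy()
    if len(out) == 0:
        out["probability"] = pd.Series(dtype=float)
        out["candidate"] = pd.Series(dtype=bool)
        return out
    probs = predict_prob(model, features)
    out["probability"] = probs
    out["candidate"] = probs >= model.cutoff
    return out
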