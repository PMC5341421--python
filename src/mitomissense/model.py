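"""Classifier pipeline: min-max normalization, SMOTE, RBF-SVM, evaluation.

The training recipe: features are rescaled to [0, 1] using the training
partition's min/max (validation values are transformed with the same spec and
deliberately not clipped); the rare damaging class is oversampled with SMOTE
(synthetic points interpolated attribute-wise between a minority sample and
one of its k=5 nearest minority neighbors) until the classes balance; an
RBF-kernel SVM is fit, with C and gamma chosen by stratified 10-fold
cross-validated grid search maximizing mean balanced accuracy.  SMOTE runs
inside each CV fold on the training folds only, so synthetic points never
leak into a fold's evaluation half.

SMOTE is implemented here directly: the interval contract (every synthetic
attribute lies between its seed's and its neighbor's value) and per-seed
determinism are part of this module's tested surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .curation import DAMAGING, NEUTRAL

MODEL_FORMAT_VERSION = 1

#: powers-of-four RBF grid bracketing the published operating point (C=200, gamma=0.01)
DEFAULT_C_GRID = tuple(float(2**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2**e) for e in range(-15, 4, 2))


class UndefinedMetricError(ZeroDivisionError):
    """A confusion metric's denominator is zero."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-feature (min, max) learned from the training partition."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """(x - min) / (max - min); constant features map to 0; no clipping.

        Validation data transformed with a training-fit spec may legitimately
        fall outside [0, 1].
        """
        X = np.asarray(X, dtype=float)
        mins = np.asarray(self.mins)
        span = np.asarray(self.maxs) - mins
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - mins[nz]) / span[nz]
        return out

    def invert(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        mins = np.asarray(self.mins)
        span = np.asarray(self.maxs) - mins
        return Z * span + mins


def fit_normalization(X: np.ndarray) -> NormalizationSpec:
    """Learn per-feature min/max from training data; warns on constant features."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit normalization on an empty table")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    if (maxs == mins).any():
        import warnings

        warnings.warn("constant feature(s); normalized to 0", stacklevel=2)
    return NormalizationSpec(tuple(mins.tolist()), tuple(maxs.tolist()))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoteParams:
    k_neighbors: int = 5
    seed: int = 1
    #: minority:majority size ratio to reach after oversampling
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def smote(
    minority: np.ndarray, params: SmoteParams, n_synthetic: int
) -> np.ndarray:
    """Generate synthetic minority samples by neighbor interpolation.

    Each synthetic point takes a random minority seed sample and one of its
    ``k_neighbors`` nearest minority neighbors (Euclidean), and for every
    attribute independently moves a uniform random fraction of the way from
    the seed's value toward the neighbor's, so each attribute stays inside
    the closed interval between the two.  Reproducible per ``params.seed``.
    """
    minority = np.asarray(minority, dtype=float)
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be non-negative")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1] if minority.ndim == 2 else 0))
    n = minority.shape[0]
    if n <= params.k_neighbors:
        raise ValueError(
            f"SMOTE needs more than k={params.k_neighbors} minority samples, "
            f"got {n}; reduce k explicitly"
        )
    rng = np.random.default_rng(params.seed)
    dist = pairwise_distances(minority)
    np.fill_diagonal(dist, np.inf)
    # k nearest minority neighbors of each sample, nearest first
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, : params.k_neighbors]
    seeds = rng.integers(0, n, size=n_synthetic)
    picks = rng.integers(0, params.k_neighbors, size=n_synthetic)
    gaps = rng.random((n_synthetic, minority.shape[1]))
    base = minority[seeds]
    other = minority[neighbors[seeds, picks]]
    return base + gaps * (other - base)


def oversample_to_balance(
    X: np.ndarray, y: np.ndarray, params: SmoteParams
) -> tuple[np.ndarray, np.ndarray]:
    """Append SMOTE samples so minority/majority reaches ``params.target_ratio``."""
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError("oversampling requires exactly two classes")
    minority_label = labels[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_target = int(round(params.target_ratio * n_maj))
    n_synthetic = max(0, n_target - n_min)
    if n_synthetic == 0:
        return np.asarray(X, dtype=float), y.copy()
    synth = smote(np.asarray(X, dtype=float)[y == minority_label], params, n_synthetic)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_synthetic, minority_label, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    """A trained RBF-SVM plus everything needed to reapply it."""

    C: float
    gamma: float
    normalization: NormalizationSpec
    smote_params: SmoteParams
    classes: tuple[str, str] = (DAMAGING, NEUTRAL)
    svc: SVC = field(default=None, repr=False)
    cv_report: Optional[list[dict]] = field(default=None, repr=False)
    training_digest: Optional[str] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic damaging/neutral labels; every input gets a label.

        ``X`` is on the raw feature scale; the stored normalization is applied
        first.  Non-finite features are an error, never an 'unknown' output.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        return self.svc.predict(self.normalization.apply(X))

    def save(self, path) -> None:
        """Serialize the operating point and preprocessing provenance as JSON.

        The SVC itself is re-fit on load from the stored support data; only
        plain-text, versioned content is written.
        """
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "C": self.C,
            "gamma": self.gamma,
            "classes": list(self.classes),
            "normalization": {"mins": self.normalization.mins,
                              "maxs": self.normalization.maxs},
            "smote": {"k_neighbors": self.smote_params.k_neighbors,
                      "seed": self.smote_params.seed,
                      "target_ratio": self.smote_params.target_ratio},
            "training_digest": self.training_digest,
            "training_X": self._train_X.tolist(),
            "training_y": self._train_y.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SvmModel":
        payload = json.loads(Path(path).read_text())
        if payload["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format {payload['format_version']} unsupported"
            )
        spec = NormalizationSpec(
            tuple(payload["normalization"]["mins"]),
            tuple(payload["normalization"]["maxs"]),
        )
        sp = SmoteParams(**payload["smote"])
        model = cls(payload["C"], payload["gamma"], spec, sp,
                    tuple(payload["classes"]),
                    training_digest=payload.get("training_digest"))
        model._fit(np.asarray(payload["training_X"], dtype=float),
                   np.asarray(payload["training_y"]))
        return model

    def _fit(self, X_norm: np.ndarray, y: np.ndarray) -> None:
        self._train_X = X_norm
        self._train_y = np.asarray(y)
        self.svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self.svc.fit(X_norm, self._train_y)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for lab in np.unique(y_true):
        mask = y_true == lab
        accs.append(np.mean(y_pred[mask] == lab))
    return float(np.mean(accs))


def grid_search_train(
    X: np.ndarray,
    y: Sequence[str],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = 1,
    smote_params: SmoteParams = SmoteParams(),
) -> SvmModel:
    """Grid-search an RBF-SVM with stratified k-fold CV and fold-internal SMOTE.

    ``X`` is on the raw feature scale.  For every (C, gamma): each CV split
    fits normalization and SMOTE on the training folds only, scores the held
    fold, and the grid point with the best mean balanced accuracy wins (ties
    broken toward smaller C, then smaller gamma).  The returned model is
    refit on the full, SMOTE-balanced training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"{folds}-fold"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    report = []
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            scores = []
            for tr, te in splits:
                spec = fit_normalization(X[tr])
                X_tr, y_tr = oversample_to_balance(
                    spec.apply(X[tr]), y[tr], smote_params
                )
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit(X_tr, y_tr)
                scores.append(
                    _balanced_accuracy(y[te], svc.predict(spec.apply(X[te])))
                )
            mean_score = float(np.mean(scores))
            report.append({"C": C, "gamma": gamma, "mean_balanced_accuracy": mean_score})
            key = (mean_score, -C, -gamma)
            if best is None or key > best[0]:
                best = (key, C, gamma)
    _, C, gamma = best
    spec = fit_normalization(X)
    X_bal, y_bal = oversample_to_balance(spec.apply(X), y, smote_params)
    model = SvmModel(C, gamma, spec, smote_params, cv_report=report)
    model._fit(X_bal, y_bal)
    return model


def train_at(
    X: np.ndarray,
    y: Sequence[str],
    C: float,
    gamma: float,
    smote_params: SmoteParams = SmoteParams(),
) -> SvmModel:
    """Fit directly at a chosen (C, gamma) operating point, no grid search."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    spec = fit_normalization(X)
    X_bal, y_bal = oversample_to_balance(spec.apply(X), y, smote_params)
    model = SvmModel(C, gamma, spec, smote_params)
    model._fit(X_bal, y_bal)
    return model


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    predicted: Sequence[str],
    truth: Sequence[str],
    unknown_policy: str = NEUTRAL,
) -> ConfusionCounts:
    """Tally a prediction run against truth labels.

    Some external predictors abstain on hard variants; an ``"unknown"``
    prediction is mapped to ``unknown_policy`` (default neutral) before
    counting, so the four counts always partition the inputs.  Damaging is
    the positive class.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if p == "unknown":
            p = unknown_policy
        if t == DAMAGING:
            tp, fn = (tp + 1, fn) if p == DAMAGING else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == NEUTRAL else (tn, fp + 1)
    return ConfusionCounts(tp, tn, fp, fn)


def sensitivity(c: ConfusionCounts) -> float:
    """100 x TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive truth items")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """100 x TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative truth items")
    return 100.0 * c.tn / (c.tn + c.fp)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of group_a, p).

    Ties get midranks.  Small samples (both n <= 20) without ties use the
    exact null distribution; otherwise the tie-corrected normal
    approximation (with continuity correction) applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= 20 and b.size <= 20
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
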