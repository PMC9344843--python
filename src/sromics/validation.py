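"""Leak-free evaluation: splits, k-fold CV, metrics, one-vs-rest.

The central discipline is that nothing about the test rows -- mutual
information priors, sampling state, fitted parameters, quantiles -- is ever
computed from them.  Each CV fold therefore starts a completely fresh search
(:func:`sromics.search.run_search` re-estimates its priors from the fold's
training rows only), which is what prevents feature-selection leakage on
wide tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataio import Dataset
from .errors import ValidationError
from .expr_core import FittedModel
from .search import SearchConfig, run_search

__all__ = [
    "auc",
    "confusion",
    "stratified_split",
    "kfold_cv",
    "one_vs_rest",
    "FoldResult",
    "CVSummary",
    "OneVsRestResult",
]


def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equivalent to the fraction of (positive, negative) pairs ranked
    correctly, with ties counted as one half.
    """
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.size != scores.size:
        raise ValidationError("labels and scores must have equal length")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC is undefined with a single class")
    ranks = rankdata(scores)
    return float((np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion(labels, scores, threshold: float = 0.5) -> dict[str, int]:
    """2x2 counts at a probability threshold (predict 1 when score > threshold)."""
    labels = np.asarray(labels, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pred = scores > threshold
    pos = labels == 1
    return {
        "tp": int(np.sum(pred & pos)),
        "fn": int(np.sum(~pred & pos)),
        "fp": int(np.sum(pred & ~pos)),
        "tn": int(np.sum(~pred & ~pos)),
    }


def stratified_split(
    data: Dataset,
    test_fraction: float,
    strata: str | None = None,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Seeded train/test split, stratified on a label column when given.

    Each stratum contributes ``round(test_fraction * n_stratum)`` test rows,
    so the per-stratum test proportion is within one sample of the requested
    fraction.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    if strata is None:
        groups = {None: np.arange(n)}
    else:
        col = data.column(strata)
        groups = {v: np.nonzero(col == v)[0] for v in np.unique(col)}
    test_idx: list[int] = []
    for label, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(
                f"stratum {label!r} has fewer than 2 members and cannot be split"
            )
        k = int(round(test_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:k].tolist())
    test_idx = sorted(test_idx)
    train_idx = sorted(set(range(n)) - set(test_idx))
    return data.subset(train_idx), data.subset(test_idx)


@dataclass
class FoldResult:
    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    models: list[FittedModel]
    train_auc: list[float]
    test_auc: list[float]
    train_confusion: list[dict]
    test_confusion: list[dict]

    @property
    def best_test_auc(self) -> float:
        """Test AUC of the rank-1 (criterion-best) model of this fold."""
        return self.test_auc[0]


@dataclass
class CVSummary:
    k: int
    mean_test_auc: float
    sd_test_auc: float
    per_fold_test_auc: list[float]
    skipped_folds: list[int]


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(fold,)).generate_state(1)[0] % 2**31)


def kfold_cv(
    data: Dataset, config: SearchConfig | None = None, k: int = 5
) -> tuple[list[FoldResult], CVSummary]:
    """Stratified k-fold CV with a fresh search (fresh priors) per fold.

    The summary reports mean and standard deviation of the per-fold best
    models' test AUC -- the statistic conventionally quoted for this kind of
    harness.  Folds whose training rows contain a single class are skipped
    with a warning.
    """
    config = config or SearchConfig()
    if k < 2:
        raise ValidationError("k must be >= 2")
    y = data.y
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("kfold_cv requires a binary 0/1 target")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(data.n_samples)
    splitter = StratifiedKFold(n_splits=k, shuffle=False)
    results: list[FoldResult] = []
    skipped: list[int] = []
    for fold, (tr, te) in enumerate(splitter.split(perm.reshape(-1, 1), y[perm])):
        train_idx = perm[tr]
        test_idx = perm[te]
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            warnings.warn(f"fold {fold}: single-class training set, skipped")
            skipped.append(fold)
            continue
        fold_cfg = replace(config, seed=_fold_seed(config.seed, fold))
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        models = run_search(train, fold_cfg)
        tr_auc, te_auc, tr_cm, te_cm = [], [], [], []
        for m in models:
            p_tr = m.predict(train)
            p_te = m.predict(test)
            tr_auc.append(auc(train.y, p_tr))
            te_auc.append(auc(test.y, p_te))
            tr_cm.append(confusion(train.y, p_tr))
            te_cm.append(confusion(test.y, p_te))
        results.append(
            FoldResult(
                fold=fold,
                train_index=train_idx,
                test_index=test_idx,
                models=models,
                train_auc=tr_auc,
                test_auc=te_auc,
                train_confusion=tr_cm,
                test_confusion=te_cm,
            )
        )
    if not results:
        raise ValidationError("every fold was skipped; check the target column")
    best = [r.best_test_auc for r in results]
    summary = CVSummary(
        k=k,
        mean_test_auc=float(np.mean(best)),
        sd_test_auc=float(np.std(best, ddof=1)) if len(best) > 1 else 0.0,
        per_fold_test_auc=best,
        skipped_folds=skipped,
    )
    return results, summary


@dataclass
class OneVsRestResult:
    classes: list[float]
    model_lists: dict[float, list[FittedModel]]
    train_accuracy: float

    def predict(self, samples) -> np.ndarray:
        """Class of maximal per-class probability; ties -> lowest class."""
        if (
            len(self.classes) == 2
            and self.model_lists[self.classes[0]] is self.model_lists[self.classes[1]]
        ):
            p = self.model_lists[self.classes[1]][0].predict(samples)
            return np.where(p > 0.5, self.classes[1], self.classes[0])
        probs = np.column_stack(
            [self.model_lists[c][0].predict(samples) for c in self.classes]
        )
        winners = np.argmax(probs, axis=1)  # argmax takes the first maximum
        return np.array([self.classes[i] for i in winners])


def one_vs_rest(data: Dataset, config: SearchConfig | None = None):
    """Multiclass reduction: one binary search per class.

    With two classes this delegates to a single binary :func:`run_search`.
    Returns an :class:`OneVsRestResult` whose combined predictor picks the
    class with maximal probability (lowest class index on ties).
    """
    config = config or SearchConfig()
    y = data.y
    classes = sorted(float(v) for v in np.unique(y))
    counts = {c: int(np.sum(y == c)) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValidationError(f"classes with fewer than 2 members: {small}")
    if len(classes) < 2:
        raise ValidationError("one_vs_rest needs at least 2 classes")
    if len(classes) == 2:
        binary = Dataset(
            frame=data.frame.assign(**{data.target: (y == classes[1]).astype(float)}),
            target=data.target,
            provenance=data.provenance,
        )
        models = run_search(binary, config)
        result = OneVsRestResult(
            classes=classes,
            model_lists={classes[0]: models, classes[1]: models},
            train_accuracy=float("nan"),
        )
        pred = np.where(models[0].predict(data) > 0.5, classes[1], classes[0])
        result.train_accuracy = float(np.mean(pred == y))
        return result
    model_lists: dict[float, list[FittedModel]] = {}
    for i, c in enumerate(classes):
        binary = Dataset(
            frame=data.frame.assign(**{data.target: (y == c).astype(float)}),
            target=data.target,
            provenance=data.provenance,
        )
        model_lists[c] = run_search(binary, replace(config, seed=_fold_seed(config.seed, i)))
    result = OneVsRestResult(classes=classes, model_lists=model_lists, train_accuracy=0.0)
    result.train_accuracy = float(np.mean(result.predict(data) == y))
    return result
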