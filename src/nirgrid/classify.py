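"""Repeated, stratified, nested cross-validation of the PCA-LDA classifier.

The model is a pipeline of NIPALS PCA (dimension reduction) and LDA; the only
tuned hyperparameter is the number of principal components, optimized in an
inner cross-validation loop, while the outer loop estimates performance. The
whole design is repeated with fresh stratified splits and accuracies are
aggregated as mean +/- std over repetitions, with the confusion matrix summed
over repetitions (so each true-class column totals n_k * repetitions).

Accuracy is also reported against the chance rate r = 100%/c as the
accuracy-to-random ratio a/r, which makes models with different class counts
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block import SpectraBlock
from .exceptions import ParameterError
from .lda import LinearDiscriminantClassifier
from .pca import NipalsPCA
from .pipeline import PipelineSpec, apply_pipeline, msc_references_from_samples

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CVConfig:
    """Nested-CV design.

    outer_folds=5 / inner_folds=10 with stratified random sampling; the
    design is repeated ``repetitions`` times (5 for screening, 20 for final
    evaluation) with per-repetition seeds ``seed + rep``. ``pc_search`` is
    the inclusive range of candidate PC counts; it is truncated per fold to
    what the training size allows and (with ``cap_pcs_by_class``, the
    default) to the smallest per-class training count, so every class mean
    is estimated from at least as many samples as retained dimensions --
    without that guard, imbalanced designs drift toward high PC counts where
    small-class means are noise-dominated and the chance floor rises well
    above 100/c. ``fold_safe_msc`` moves the MSC reference
    computation inside the outer folds (leakage-free variant); the default
    False reproduces the original workflow, which computes the reference on
    all samples before splitting.
    """

    outer_folds: int = 5
    inner_folds: int = 10
    repetitions: int = 20
    pc_search: tuple[int, int] = (1, 40)
    seed: int = 0
    fold_safe_msc: bool = False
    cap_pcs_by_class: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ParameterError("outer and inner folds must both be >= 2")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        lo, hi = self.pc_search
        if lo < 1 or hi < lo:
            raise ParameterError("pc_search must be a non-empty range of >= 1")


@dataclass
class ClassificationResult:
    """Aggregated output of one repeated nested-CV run.

    ``confusion`` is indexed [predicted, true] with classes in
    ``class_names`` order; counts are summed over repetitions.
    ``per_rep_accuracy`` holds fractions; the mean/std fields are percent.
    """

    class_names: np.ndarray
    per_rep_accuracy: np.ndarray
    confusion: np.ndarray
    chosen_pcs: list[int]
    repetitions: int
    class_counts: np.ndarray = field(default=None)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.per_rep_accuracy) * 100.0)

    @property
    def accuracy_std(self) -> float:
        if self.per_rep_accuracy.size < 2:
            return 0.0
        return float(np.std(self.per_rep_accuracy, ddof=1) * 100.0)

    @property
    def n_classes(self) -> int:
        return int(self.class_names.size)

    def metrics(self) -> "Metrics":
        return accuracy_to_random(self.accuracy_mean, self.n_classes)

    def confusion_frame(self, percentages: bool = False) -> pd.DataFrame:
        """Confusion matrix with true classes as columns, predicted as rows;
        percentages normalize each true-class column."""
        M = self.confusion.astype(float)
        if percentages:
            totals = M.sum(axis=0)
            M = 100.0 * M / np.where(totals > 0, totals, 1.0)
        return pd.DataFrame(M, index=self.class_names, columns=self.class_names)

    def summary(self) -> dict:
        m = self.metrics()
        return {
            "accuracy_mean_pct": round(self.accuracy_mean, 2),
            "accuracy_std_pct": round(self.accuracy_std, 2),
            "n_classes": self.n_classes,
            "random_rate_pct": round(m.random_rate, 2),
            "accuracy_to_random": round(m.ratio, 2),
            "repetitions": self.repetitions,
        }


@dataclass(frozen=True)
class Metrics:
    """Chance rate r = 100/c (%) and accuracy-to-random ratio a/r."""

    random_rate: float
    ratio: float


def accuracy_to_random(a: float, c: int) -> Metrics:
    """Chance rate and accuracy-to-random ratio for accuracy ``a`` (percent)
    over ``c`` classes: r = 100/c, ratio = a/r = a*c/100."""
    if c < 2:
        raise ParameterError("accuracy-to-random needs at least 2 classes")
    if not 0.0 <= a <= 100.0:
        raise ParameterError("accuracy must be in [0, 100] percent")
    r = 100.0 / c
    return Metrics(random_rate=r, ratio=a / r)


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------
def stratified_folds(labels, k: int, seed) -> np.ndarray:
    """Stratified k-fold assignment, deterministic given the seed.

    Per class (in sorted name order) the members are shuffled and dealt
    round-robin over the folds ordered by their current total size (ties ->
    lowest fold index). This keeps every fold's class proportions within one
    member of n_k/k and the fold totals within one of n/k.

    Returns an integer array of fold indices (0..k-1), one per sample.
    """
    if k < 2:
        raise ParameterError("need at least 2 folds")
    labels = np.asarray(labels).astype(str)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignment = np.full(labels.shape[0], -1, dtype=int)
    totals = np.zeros(k, dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        order = np.lexsort((np.arange(k), totals))  # by load, ties -> low index
        for j, m in enumerate(members):
            f = order[j % k]
            assignment[m] = f
            totals[f] += 1
    return assignment


# ---------------------------------------------------------------------------
# PCA-LDA model
# ---------------------------------------------------------------------------
class PCALDA:
    """NIPALS-PCA + LDA classifier (scikit-learn-style estimator)."""

    def __init__(self, n_components: int, ridge: float = 1e-8, priors: str = "equal"):
        self.n_components = n_components
        self.ridge = ridge
        self.priors = priors

    def get_params(self, deep: bool = True):  # noqa: ARG002
        return {"n_components": self.n_components, "ridge": self.ridge, "priors": self.priors}

    def set_params(self, **params):
        for key, v in params.items():
            setattr(self, key, v)
        return self

    def __sklearn_tags__(self):
        from ._sklearn_compat import classifier_tags

        return classifier_tags()

    def fit(self, X, y):
        self.pca_ = NipalsPCA(self.n_components).fit(X)
        self.lda_ = LinearDiscriminantClassifier(self.ridge, self.priors).fit(
            self.pca_.scores_, y
        )
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X):
        return self.lda_.predict(self.pca_.transform(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y).astype(str)))


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------
def _select_pc_count(
    X: np.ndarray,
    y: np.ndarray,
    pc_candidates: np.ndarray,
    inner_folds: int,
    rng: np.random.Generator,
    ridge: float,
    priors: str,
) -> int:
    """Inner CV: mean validation accuracy per candidate PC count; the best
    count wins, ties -> fewest PCs. One PCA fit per inner fold at the largest
    candidate; LDA is refit per truncation of the score matrix."""
    classes, y_idx = np.unique(y, return_inverse=True)
    smallest = int(np.bincount(y_idx).min())
    k_in = max(2, min(inner_folds, smallest))
    folds = stratified_folds(y, k_in, rng)
    pc_max = int(pc_candidates.max())
    acc = np.zeros((k_in, pc_candidates.size))
    for f in range(k_in):
        tr = folds != f
        va = ~tr
        n_tr = int(tr.sum())
        cap = min(pc_max, n_tr - 1, X.shape[1])
        pca = NipalsPCA(cap).fit(X[tr])
        scores_tr = pca.scores_
        scores_va = pca.transform(X[va])
        y_tr, y_va = y[tr], y[va]
        for i, kpc in enumerate(pc_candidates):
            kk = min(int(kpc), cap)
            lda = LinearDiscriminantClassifier(ridge, priors).fit(scores_tr[:, :kk], y_tr)
            acc[f, i] = np.mean(lda.predict(scores_va[:, :kk]) == y_va)
    mean_acc = acc.mean(axis=0)
    return int(pc_candidates[int(np.argmax(mean_acc))])


def nested_cv(
    block: SpectraBlock,
    cv: CVConfig,
    pipeline_spec: PipelineSpec | None = None,
    ridge: float = 1e-8,
    priors: str = "equal",
) -> ClassificationResult:
    """Repeated stratified nested CV of PCA-LDA on a per-sample block.

    ``block`` is normally the output of :func:`nirgrid.pipeline.apply_pipeline`
    (one spectrum per sample). With ``cv.fold_safe_msc`` set, pass the raw
    scan-level block together with ``pipeline_spec``: the pre-processing is
    then re-run per outer fold with the MSC reference computed from the
    training samples only.

    Per repetition ``rep`` the seed is ``cv.seed + rep``; the outer split is
    a stratified ``cv.outer_folds``-fold, and per outer fold an inner
    stratified CV (folds capped at the smallest training-class size) selects
    the PC count from ``cv.pc_search`` maximizing mean inner accuracy (ties
    -> fewest PCs). The model is refit on the full outer-training set and
    outer-test predictions accumulate into the confusion matrix.
    """
    fold_safe = cv.fold_safe_msc and pipeline_spec is not None and pipeline_spec.msc
    if cv.fold_safe_msc and pipeline_spec is None:
        raise ParameterError("fold_safe_msc requires the pipeline_spec")

    if fold_safe:
        raw = block
        sample_ids = raw.unique_samples()
        cls_map = raw.sample_class_map()
        y = np.array([str(cls_map[s]) for s in sample_ids])
        n = sample_ids.size
    else:
        if np.unique(block.sample_id.astype(str)).size != block.n_scans:
            raise ParameterError(
                "nested_cv expects one spectrum per sample; run apply_pipeline first"
            )
        X_all = block.intensities
        y = block.class_label.astype(str)
        n = block.n_scans

    classes = np.unique(y)
    c = classes.size
    if c < 2:
        raise ParameterError("need at least 2 classes")
    class_to_idx = {cl: i for i, cl in enumerate(classes)}

    pc_lo, pc_hi = cv.pc_search
    confusion = np.zeros((c, c), dtype=int)
    per_rep = np.zeros(cv.repetitions)
    chosen_pcs: list[int] = []

    for rep in range(cv.repetitions):
        rep_seed = cv.seed + rep
        outer = stratified_folds(y, cv.outer_folds, rep_seed)
        correct = 0
        for f in range(cv.outer_folds):
            test = outer == f
            train = ~test
            if fold_safe:
                refs = msc_references_from_samples(raw, pipeline_spec, sample_ids[train])
                processed = apply_pipeline(raw, pipeline_spec, refs)
                # apply_pipeline preserves sample order of first appearance
                X_all = processed.intensities
            X_tr, y_tr = X_all[train], y[train]
            X_te, y_te = X_all[test], y[test]

            n_tr = int(train.sum())
            cap = min(pc_hi, X_tr.shape[1], n_tr - c - 1)
            if cv.cap_pcs_by_class:
                smallest_train = min(int(np.sum(y_tr == cl)) for cl in classes)
                cap = min(cap, smallest_train)
            if cap < pc_hi:
                logger.debug(
                    "rep %d fold %d: pc_search upper bound truncated to %d", rep, f, cap
                )
            cap = max(cap, pc_lo)
            candidates = np.arange(pc_lo, cap + 1)

            inner_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cv.seed, spawn_key=(rep, f))
            )
            best_k = _select_pc_count(
                X_tr, y_tr, candidates, cv.inner_folds, inner_rng, ridge, priors
            )
            chosen_pcs.append(best_k)

            model = PCALDA(best_k, ridge, priors).fit(X_tr, y_tr)
            pred = model.predict(X_te)
            correct += int(np.sum(pred == y_te))
            for p_lbl, t_lbl in zip(pred, y_te):
                confusion[class_to_idx[p_lbl], class_to_idx[t_lbl]] += 1
        per_rep[rep] = correct / n

    counts = np.array([int(np.sum(y == cl)) for cl in classes])
    return ClassificationResult(
        class_names=classes,
        per_rep_accuracy=per_rep,
        confusion=confusion,
        chosen_pcs=chosen_pcs,
        repetitions=cv.repetitions,
        class_counts=counts,
    )
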