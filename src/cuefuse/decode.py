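"""Near-vs-far pattern decoding: leave-one-run-out linear SVM, within and
across cue conditions, with recursive feature elimination for the transfer
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .patterns import PatternMatrix

logger = logging.getLogger("cuefuse")


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear maximum-margin classifier settings.  C is the soft-margin
    regularization constant (libsvm default 1.0)."""

    C: float = 1.0


@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-run-out folds: each run is the test run exactly once."""

    folds: tuple[tuple[tuple[int, ...], int], ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def run_ids(self) -> tuple[int, ...]:
        return tuple(test for _, test in self.folds)


@dataclass
class DecodingResult:
    """Cross-validated accuracy for one condition (or transfer direction).

    ``accuracy`` is the pooled proportion correct: the mean of per-fold
    accuracies weighted by each fold's test-pattern count.
    """

    condition: str
    direction: str  # within | cross_D_to_M | cross_M_to_D | cross_mean
    per_fold_accuracies: np.ndarray
    per_fold_counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_test_patterns(self) -> int:
        return int(self.per_fold_counts.sum())

    @property
    def accuracy(self) -> float:
        return float(
            np.average(self.per_fold_accuracies, weights=self.per_fold_counts)
        )


def plan_folds(run_ids) -> FoldPlan:
    """Build leave-one-run-out folds, ordered by run id."""
    runs = sorted(set(int(r) for r in np.asarray(run_ids).ravel()))
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")
    folds = tuple(
        (tuple(r for r in runs if r != test), test) for test in runs
    )
    return FoldPlan(folds=folds)


def _fit_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: ClassifierConfig,
) -> tuple[float, int]:
    """Train the linear SVM and score the held-out patterns.

    Decision values of exactly 0 are scored as errors (conservative,
    deterministic tie policy).
    """
    clf = SVC(kernel="linear", C=config.C)
    clf.fit(X_train, y_train)
    df = clf.decision_function(X_test)
    # decision_function is positive for the class sorted last (+1 here)
    correct = (df * y_test) > 0
    return float(correct.mean()), int(correct.size)


def _check_fold(y: np.ndarray, fold_desc: str) -> None:
    if y.size == 0 or np.unique(y).size < 2:
        raise ValueError(f"missing class in training data for fold {fold_desc}")


def cv_decode(
    pm: PatternMatrix,
    condition: str,
    plan: FoldPlan,
    config: ClassifierConfig = ClassifierConfig(),
    signs: np.ndarray | None = None,
    voxel_subsets: list[np.ndarray] | None = None,
) -> DecodingResult:
    """Leave-one-run-out near-vs-far decoding within one condition.

    ``signs`` optionally overrides the label vector (used by permutation
    tests); ``voxel_subsets`` optionally restricts each fold to a per-fold
    voxel subset (used after RFE).
    """
    sub = pm.select(condition)
    y_all = sub.signs if signs is None else np.asarray(signs)
    if signs is not None and y_all.shape[0] != len(sub):
        raise ValueError("signs override must match the condition's patterns")
    accs, counts = [], []
    for f, (train_runs, test_run) in enumerate(plan.folds):
        tr = np.isin(sub.run_ids, train_runs)
        te = sub.run_ids == test_run
        assert not np.any(tr & te), "fold leaks a training run into the test set"
        if te.sum() == 0:
            raise ValueError(f"no test patterns for run {test_run}")
        _check_fold(y_all[tr], f"test_run={test_run}")
        X_tr, X_te = sub.patterns[tr], sub.patterns[te]
        if voxel_subsets is not None:
            X_tr = X_tr[:, voxel_subsets[f]]
            X_te = X_te[:, voxel_subsets[f]]
        acc, n = _fit_score(X_tr, y_all[tr], X_te, y_all[te], config)
        accs.append(acc)
        counts.append(n)
    return DecodingResult(
        condition=condition,
        direction="within",
        per_fold_accuracies=np.asarray(accs),
        per_fold_counts=np.asarray(counts),
        metadata={"C": config.C},
    )


@dataclass
class CrossDecodeResult:
    """Both cross-cue directions plus their mean."""

    d_to_m: DecodingResult
    m_to_d: DecodingResult
    mean: DecodingResult


def cross_decode_one_direction(
    pm: PatternMatrix,
    train_condition: str,
    test_condition: str,
    plan: FoldPlan,
    config: ClassifierConfig = ClassifierConfig(),
    voxel_subsets: list[np.ndarray] | None = None,
    train_signs: np.ndarray | None = None,
    direction: str = "cross_D_to_M",
) -> DecodingResult:
    """One transfer direction: per fold, train on ``train_condition`` patterns
    from the training runs, test on ``test_condition`` patterns from the
    held-out run.  ``train_signs`` optionally overrides the training labels
    (used by the permutation baseline)."""
    tr_sub = pm.select(train_condition)
    te_sub = pm.select(test_condition)
    y_tr_all = tr_sub.signs if train_signs is None else np.asarray(train_signs)
    if y_tr_all.shape[0] != len(tr_sub):
        raise ValueError("train_signs must match the training condition's patterns")
    accs, counts = [], []
    for f, (train_runs, test_run) in enumerate(plan.folds):
        tr = np.isin(tr_sub.run_ids, train_runs)
        te = te_sub.run_ids == test_run
        if te.sum() == 0:
            raise ValueError(f"no test patterns for run {test_run}")
        _check_fold(y_tr_all[tr], f"test_run={test_run}")
        X_tr, X_te = tr_sub.patterns[tr], te_sub.patterns[te]
        if voxel_subsets is not None:
            X_tr = X_tr[:, voxel_subsets[f]]
            X_te = X_te[:, voxel_subsets[f]]
        acc, n = _fit_score(X_tr, y_tr_all[tr], X_te, te_sub.signs[te], config)
        accs.append(acc)
        counts.append(n)
    return DecodingResult(
        condition=f"{train_condition}->{test_condition}",
        direction=direction,
        per_fold_accuracies=np.asarray(accs),
        per_fold_counts=np.asarray(counts),
        metadata={"C": config.C},
    )


def cross_cue_decode(
    pm: PatternMatrix,
    train_condition: str,
    test_condition: str,
    plan: FoldPlan,
    config: ClassifierConfig = ClassifierConfig(),
    voxel_subsets: list[np.ndarray] | None = None,
) -> CrossDecodeResult:
    """Transfer decoding in both directions plus their mean."""
    fwd = cross_decode_one_direction(
        pm, train_condition, test_condition, plan, config=config,
        voxel_subsets=voxel_subsets, direction="cross_D_to_M",
    )
    bwd = cross_decode_one_direction(
        pm, test_condition, train_condition, plan, config=config,
        voxel_subsets=voxel_subsets, direction="cross_M_to_D",
    )
    mean = DecodingResult(
        condition=f"{train_condition}<->{test_condition}",
        direction="cross_mean",
        per_fold_accuracies=(fwd.per_fold_accuracies + bwd.per_fold_accuracies) / 2,
        per_fold_counts=fwd.per_fold_counts + bwd.per_fold_counts,
        metadata={"C": config.C},
    )
    return CrossDecodeResult(d_to_m=fwd, m_to_d=bwd, mean=mean)


def merge_decoding_results(results: list[DecodingResult]) -> DecodingResult:
    """Pool decoding results from independent sessions into one result whose
    folds are the concatenated session folds.

    Fold-level bootstrap inference on the merged result then resamples
    session-folds as exchangeable units — the group-level analogue of
    resampling runs within one session.
    """
    if len(results) < 1:
        raise ValueError("need at least one result to merge")
    cond = results[0].condition
    direction = results[0].direction
    for r in results[1:]:
        if r.condition != cond or r.direction != direction:
            raise ValueError("can only merge results of the same condition/direction")
    return DecodingResult(
        condition=cond,
        direction=direction,
        per_fold_accuracies=np.concatenate(
            [r.per_fold_accuracies for r in results]
        ),
        per_fold_counts=np.concatenate([r.per_fold_counts for r in results]),
        metadata={"n_sessions": len(results)},
    )


def rfe_select(
    pm: PatternMatrix,
    condition: str,
    plan: FoldPlan,
    step_fraction: float = 0.1,
    floor_count: int = 50,
    config: ClassifierConfig = ClassifierConfig(),
) -> list[np.ndarray]:
    """Recursive feature elimination, computed inside each outer fold's
    training data only (no test leakage).

    Per iteration the ``step_fraction`` of remaining voxels with the smallest
    absolute classifier weight is removed, stopping at ``floor_count``.
    Returns one voxel-position subset per fold, aligned with ``plan.folds``.
    """
    if not (0 < step_fraction < 1):
        raise ValueError("step_fraction must lie in (0, 1)")
    sub = pm.select(condition)
    n_vox = sub.n_voxels
    if floor_count >= n_vox:
        logger.warning(
            "RFE floor %d >= voxel count %d: identity selection", floor_count, n_vox
        )
        return [np.arange(n_vox) for _ in plan.folds]
    subsets = []
    for train_runs, _test_run in plan.folds:
        tr = np.isin(sub.run_ids, train_runs)
        X, y = sub.patterns[tr], sub.signs[tr]
        keep = np.arange(n_vox)
        while keep.size > floor_count:
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(X[:, keep], y)
            w = np.abs(np.asarray(clf.coef_).ravel())
            n_drop = min(
                max(1, int(np.floor(step_fraction * keep.size))),
                keep.size - floor_count,
            )
            order = np.argsort(w, kind="stable")
            keep = np.delete(keep, order[:n_drop])
        subsets.append(np.sort(keep))
    return subsets
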