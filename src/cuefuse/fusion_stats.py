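"""Fusion-vs-independence inference: d' conversion, quadratic-summation bound,
integration and transfer indices, bootstrap and permutation tests, Bonferroni
control.

Sensitivity is measured in d' units, d' = sqrt(2) * erfinv(2p - 1) for a
proportion correct p (equivalently the standard-normal quantile of p).  An
independent two-cue code predicts congruent-condition sensitivity equal to the
Pythagorean quadratic sum of the single-cue sensitivities; a fusion mechanism
exceeds it and suffers when the cues conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import special

from .decode import (
    ClassifierConfig,
    DecodingResult,
    FoldPlan,
    cross_decode_one_direction,
)
from .patterns import PatternMatrix

logger = logging.getLogger("cuefuse")


# ---------------------------------------------------------------------------
# Point estimates
# ---------------------------------------------------------------------------

def clamp_proportion(p: float | np.ndarray, clamp_n: int) -> float | np.ndarray:
    """Clamp p into [1/(2n), 1 - 1/(2n)] so d' stays finite at p in {0, 1}."""
    if clamp_n <= 0:
        raise ValueError("clamp_n must be positive")
    lo = 1.0 / (2 * clamp_n)
    return np.clip(p, lo, 1.0 - lo)


def dprime(p: float | np.ndarray, clamp_n: int = 10_000) -> float | np.ndarray:
    """Convert proportion correct to d' = sqrt(2) * erfinv(2p - 1)."""
    p = clamp_proportion(np.asarray(p, dtype=float), clamp_n)
    out = np.sqrt(2.0) * special.erfinv(2.0 * p - 1.0)
    return float(out) if out.ndim == 0 else out


def quadratic_sum(d_d: float, d_m: float) -> float:
    """Pythagorean combination of two single-cue sensitivities: the
    independence prediction for the two-cue condition."""
    return float(np.sqrt(d_d**2 + d_m**2))


def integration_index(d_dm: float, d_d: float, d_m: float) -> float:
    """phi = d'_{D+M} / sqrt(d'_D^2 + d'_M^2) - 1.

    phi = 0 is the independence (quadratic-summation) bound; phi > 0 exceeds
    it, as expected under fusion.  Undefined when both single-cue d' are 0.
    """
    qs = quadratic_sum(d_d, d_m)
    if qs == 0:
        raise ZeroDivisionError(
            "integration index undefined: both single-cue d' are zero"
        )
    return d_dm / qs - 1.0


def transfer_index(d_t: float, d_d: float, d_m: float) -> float:
    """T = 2 d'_T / (d'_D + d'_M); T = 1 means depth information transfers
    fully across cues."""
    denom = d_d + d_m
    if denom == 0:
        raise ZeroDivisionError(
            "transfer index undefined: single-cue d' sum to zero"
        )
    return 2.0 * d_t / denom


@dataclass
class SensitivityEstimate:
    """Proportion correct and its d' transform for one decoding result."""

    p: float
    n: int
    label: str

    @property
    def dprime(self) -> float:
        return float(dprime(self.p, clamp_n=max(self.n, 1)))

    @classmethod
    def from_result(cls, res: DecodingResult, label: str) -> "SensitivityEstimate":
        return cls(p=res.accuracy, n=res.n_test_patterns, label=label)


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------

@dataclass
class IndexEstimate:
    """An integration/transfer index (or accuracy contrast) with its
    fold-resampling bootstrap distribution and one-sided p-value."""

    kind: str
    point: float
    bootstrap_samples: np.ndarray
    p_value: float
    ci68: tuple[float, float]
    ci95: tuple[float, float]
    unreliable: bool = False
    metadata: dict = field(default_factory=dict)


def _pooled_acc(
    res: DecodingResult,
    fold_idx: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pooled accuracy over resampled folds; fold_idx has shape (B, n_folds).

    When ``rng`` is given, a second resampling level draws each resampled
    fold's correct count from a binomial at that fold's accuracy, so the
    bootstrap reflects both run-level and test-pattern-level sampling noise.
    """
    acc = res.per_fold_accuracies[fold_idx]
    cnt = res.per_fold_counts[fold_idx]
    if rng is not None:
        acc = rng.binomial(cnt.astype(int), acc) / cnt
    return (acc * cnt).sum(axis=1) / cnt.sum(axis=1)


def bootstrap_index(
    results: Mapping[str, DecodingResult],
    index_fn: Callable[..., float],
    arg_order: Sequence[str],
    B: int = 10_000,
    seed: int = 0,
    null_value: float = 0.0,
    kind: str = "integration",
    two_level: bool = True,
) -> IndexEstimate:
    """Bootstrap an index by resampling cross-validation folds (runs) with
    replacement, jointly across conditions.

    Per resample the pooled accuracy of each condition is recomputed, turned
    into d' and passed to ``index_fn`` in ``arg_order``.  With ``two_level``
    (default) each resampled fold's accuracy is additionally binomially
    resampled over its test patterns, so the interval reflects run-level and
    pattern-level sampling noise; set False to resample folds only.  The
    one-sided p-value is (1 + #{samples <= null_value}) / (B + 1); percentile
    68% and 95% intervals are attached.  If the index is undefined in more
    than half of the resamples the estimate is flagged unreliable.
    """
    first = results[arg_order[0]]
    n_folds = first.per_fold_accuracies.size
    if n_folds < 3:
        raise ValueError("bootstrap over folds needs >= 3 folds")
    for key in arg_order:
        if results[key].per_fold_accuracies.size != n_folds:
            raise ValueError("all conditions must share the fold plan")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n_folds, size=(B, n_folds))

    dprimes = {}
    for key in arg_order:
        res = results[key]
        p = _pooled_acc(res, idx, rng=rng if two_level else None)
        dprimes[key] = dprime(p, clamp_n=max(res.n_test_patterns, 1))

    samples = np.full(B, np.nan)
    cols = np.stack([dprimes[k] for k in arg_order], axis=1)
    for b in range(B):
        try:
            samples[b] = index_fn(*cols[b])
        except ZeroDivisionError:
            pass
    valid = samples[~np.isnan(samples)]
    unreliable = valid.size < B / 2
    if unreliable:
        logger.warning(
            "bootstrap index %s: undefined in %d/%d resamples", kind,
            B - valid.size, B,
        )

    point_args = []
    for key in arg_order:
        res = results[key]
        point_args.append(dprime(res.accuracy, clamp_n=max(res.n_test_patterns, 1)))
    try:
        point = index_fn(*point_args)
    except ZeroDivisionError:
        point = float("nan")

    if valid.size == 0:
        return IndexEstimate(
            kind=kind, point=point, bootstrap_samples=samples,
            p_value=1.0, ci68=(np.nan, np.nan), ci95=(np.nan, np.nan),
            unreliable=True,
        )
    p_value = (1 + int((valid <= null_value).sum())) / (valid.size + 1)
    ci68 = tuple(np.percentile(valid, [16, 84]))
    ci95 = tuple(np.percentile(valid, [2.5, 97.5]))
    return IndexEstimate(
        kind=kind, point=point, bootstrap_samples=samples, p_value=p_value,
        ci68=(float(ci68[0]), float(ci68[1])),
        ci95=(float(ci95[0]), float(ci95[1])),
        unreliable=unreliable,
        metadata={"B": B, "seed": seed, "null_value": null_value},
    )


def bootstrap_integration_index(
    congruent: DecodingResult,
    disparity: DecodingResult,
    motion: DecodingResult,
    B: int = 10_000,
    seed: int = 0,
) -> IndexEstimate:
    """Integration index phi with fold-bootstrap inference against phi <= 0."""
    return bootstrap_index(
        {"dm": congruent, "d": disparity, "m": motion},
        integration_index,
        arg_order=("dm", "d", "m"),
        B=B,
        seed=seed,
        kind="integration",
    )


def bootstrap_transfer_index(
    transfer: DecodingResult,
    disparity: DecodingResult,
    motion: DecodingResult,
    B: int = 10_000,
    seed: int = 0,
) -> IndexEstimate:
    """Transfer index T with fold-bootstrap inference against T <= 0.
    ``transfer`` is the direction-averaged cross-cue result."""
    return bootstrap_index(
        {"t": transfer, "d": disparity, "m": motion},
        transfer_index,
        arg_order=("t", "d", "m"),
        B=B,
        seed=seed,
        kind="transfer",
    )


def congruency_contrast(
    congruent: DecodingResult,
    incongruent: DecodingResult,
    B: int = 10_000,
    seed: int = 0,
    two_level: bool = True,
) -> IndexEstimate:
    """Bootstrap the accuracy difference (congruent - incongruent) over folds
    (two-level: folds, then test patterns within fold); one-sided p for a
    difference <= 0 (fusion predicts a positive drop)."""
    n_folds = congruent.per_fold_accuracies.size
    if incongruent.per_fold_accuracies.size != n_folds:
        raise ValueError("congruent/incongruent results must share the fold plan")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n_folds, size=(B, n_folds))
    inner = rng if two_level else None
    diff = _pooled_acc(congruent, idx, rng=inner) - _pooled_acc(
        incongruent, idx, rng=inner
    )
    point = congruent.accuracy - incongruent.accuracy
    p_value = (1 + int((diff <= 0.0).sum())) / (B + 1)
    return IndexEstimate(
        kind="congruency",
        point=float(point),
        bootstrap_samples=diff,
        p_value=p_value,
        ci68=tuple(float(x) for x in np.percentile(diff, [16, 84])),
        ci95=tuple(float(x) for x in np.percentile(diff, [2.5, 97.5])),
        metadata={"B": B, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Permutation baseline for the transfer test
# ---------------------------------------------------------------------------

@dataclass
class PermutationBaseline:
    """Null distribution of transfer indices under within-run label
    permutation; the significance threshold is its 95th percentile."""

    distribution: np.ndarray
    n_permutations: int

    @property
    def threshold(self) -> float:
        return float(np.percentile(self.distribution, 95))

    def significant(self, observed: float) -> bool:
        return observed > self.threshold


def permutation_baseline(
    pm: PatternMatrix,
    train_condition: str,
    test_condition: str,
    plan: FoldPlan,
    d_single: tuple[float, float],
    n_perm: int = 1_000,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    voxel_subsets: list[np.ndarray] | None = None,
) -> PermutationBaseline:
    """Chance baseline for the transfer index.

    Per permutation the near/far labels of the training condition are shuffled
    within each run, the direction-averaged cross-cue accuracy is recomputed,
    and the transfer index is formed against the observed single-cue
    sensitivities ``d_single`` = (d'_D, d'_M).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d_d, d_m = d_single
    dist = np.empty(n_perm)

    def shuffled_signs(condition: str) -> np.ndarray:
        sub = pm.select(condition)
        y = sub.signs.copy()
        for run in np.unique(sub.run_ids):
            m = sub.run_ids == run
            y[m] = rng.permutation(y[m])
        return y

    for i in range(n_perm):
        res_fwd = cross_decode_one_direction(
            pm, train_condition, test_condition, plan, config=config,
            voxel_subsets=voxel_subsets,
            train_signs=shuffled_signs(train_condition),
        )
        res_bwd = cross_decode_one_direction(
            pm, test_condition, train_condition, plan, config=config,
            voxel_subsets=voxel_subsets,
            train_signs=shuffled_signs(test_condition),
        )
        acc = (res_fwd.accuracy + res_bwd.accuracy) / 2
        n = res_fwd.n_test_patterns + res_bwd.n_test_patterns
        d_t = dprime(acc, clamp_n=max(n, 1))
        dist[i] = transfer_index(float(d_t), d_d, d_m)
    return PermutationBaseline(distribution=dist, n_permutations=n_perm)


def permutation_baseline_group(
    sessions: Sequence[tuple[PatternMatrix, FoldPlan]],
    train_condition: str,
    test_condition: str,
    d_single: tuple[float, float],
    n_perm: int = 1_000,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
) -> PermutationBaseline:
    """Chance baseline for a transfer index pooled over independent sessions.

    Per permutation the training-condition labels are shuffled within run in
    every session, cross-cue decoding is recomputed for both directions in all
    sessions, and the count-weighted pooled accuracy is converted to d' and to
    a transfer index against the observed single-cue sensitivities.
    """
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d_d, d_m = d_single
    dist = np.empty(n_perm)

    def shuffled_signs(pm: PatternMatrix, condition: str) -> np.ndarray:
        sub = pm.select(condition)
        y = sub.signs.copy()
        for run in np.unique(sub.run_ids):
            m = sub.run_ids == run
            y[m] = rng.permutation(y[m])
        return y

    for i in range(n_perm):
        hits = 0.0
        total = 0
        for pm, plan in sessions:
            res_fwd = cross_decode_one_direction(
                pm, train_condition, test_condition, plan, config=config,
                train_signs=shuffled_signs(pm, train_condition),
            )
            res_bwd = cross_decode_one_direction(
                pm, test_condition, train_condition, plan, config=config,
                train_signs=shuffled_signs(pm, test_condition),
            )
            for res in (res_fwd, res_bwd):
                hits += res.accuracy * res.n_test_patterns
                total += res.n_test_patterns
        d_t = dprime(hits / total, clamp_n=max(total, 1))
        dist[i] = transfer_index(float(d_t), d_d, d_m)
    return PermutationBaseline(distribution=dist, n_permutations=n_perm)


def bonferroni(p_values: Sequence[float], alpha: float = 0.01) -> np.ndarray:
    """Reject H0 where p < alpha / m, m = number of tests in the family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return p < alpha / p.size
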