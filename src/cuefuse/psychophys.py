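"""Two-interval depth-discrimination behavior: per-level d', psychometric
fits, j.n.d.-based sensitivity, and the behavioral quadratic-summation test.

Trials carry a signed target-vs-reference depth offset (arcmin); the subject
reports "farther" or "nearer".  Per-level sensitivity uses the bias-corrected
d' = (z(H) - z(F)) / 2 from the "farther"-response rates to farther (H) and
nearer (F) targets, which equals the quantile transform of proportion correct
for an unbiased observer.  Sensitivity across levels is summarized as 1/jnd
from a maximum-likelihood cumulative-Gaussian fit, where the j.n.d. is the
50%-to-84% offset (one fitted sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fusion_stats import clamp_proportion, quadratic_sum

logger = logging.getLogger("cuefuse")

MAX_LAPSE = 0.1  # bound on the fitted lapse rate; stabilizes small-sample fits


# ---------------------------------------------------------------------------
# Per-level sensitivity
# ---------------------------------------------------------------------------

def _z(p: float, n: int) -> float:
    return float(stats.norm.ppf(clamp_proportion(p, max(n, 1))))


def dprime_by_level(
    trials: pd.DataFrame, n_boot: int = 2_000, seed: int = 0
) -> pd.DataFrame:
    """d' per (condition, |offset|) with bootstrap 95% CIs over trials.

    Levels observed with only one offset sign are skipped with a log message.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    t = trials.copy()
    t["abs_offset"] = t["offset_arcmin"].abs()
    t["farther_resp"] = t["response"] == "farther"
    for (cond, level), grp in t.groupby(["condition", "abs_offset"], sort=True):
        far = grp[grp["offset_arcmin"] > 0]["farther_resp"].to_numpy()
        near = grp[grp["offset_arcmin"] < 0]["farther_resp"].to_numpy()
        if far.size == 0 or near.size == 0:
            logger.warning(
                "level %.3g (%s): only one offset sign present, skipped", level, cond
            )
            continue
        d = _dprime_hf(far, near)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = _dprime_hf(
                rng.choice(far, size=far.size, replace=True),
                rng.choice(near, size=near.size, replace=True),
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "condition": cond,
                "abs_offset": float(level),
                "dprime": d,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_trials": int(grp.shape[0]),
            }
        )
    return pd.DataFrame(rows)


def _dprime_hf(farther_resp_far: np.ndarray, farther_resp_near: np.ndarray) -> float:
    h = _z(float(farther_resp_far.mean()), farther_resp_far.size)
    f = _z(float(farther_resp_near.mean()), farther_resp_near.size)
    return (h - f) / 2.0


def pooled_accuracy(trials: pd.DataFrame) -> float:
    """Overall proportion correct across all levels (trial-weighted)."""
    return float(trials["correct"].mean())


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit of P("farther") vs signed offset with lapse.

    jnd is the offset change from the 50% to the 84% point of the fitted
    curve, i.e. one sigma; sensitivity is its reciprocal (arcmin^-1).
    """

    condition: str
    mu: float
    sigma: float
    lapse: float
    converged: bool
    n_trials: int

    @property
    def jnd(self) -> float:
        if not self.converged:
            raise ValueError("no j.n.d. for a non-converged fit")
        return self.sigma

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.jnd


def _neg_log_likelihood(
    params: np.ndarray, offsets: np.ndarray, farther: np.ndarray
) -> float:
    mu, log_sigma, lapse = params
    sigma = np.exp(log_sigma)
    p = lapse / 2.0 + (1.0 - lapse) * stats.norm.cdf((offsets - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(np.where(farther, np.log(p), np.log1p(-p))))


_SIGMA_BOUNDS = (1e-3, 1e3)


def fit_psychometric(
    trials: pd.DataFrame, condition: str
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit for one condition.

    Fits bias mu, spread sigma, and a lapse rate bounded at 0.1.  The fit is
    flagged non-converged when the optimizer fails or sigma hits its bounds
    (step-function or pure-guessing data are unidentifiable).
    """
    grp = trials[trials["condition"] == condition]
    offsets = grp["offset_arcmin"].to_numpy(dtype=float)
    farther = (grp["response"] == "farther").to_numpy()
    if np.unique(offsets).size < 6:
        raise ValueError("psychometric fit needs >= 6 distinct signed levels")
    span = float(offsets.max() - offsets.min())
    x0 = np.array([0.0, np.log(span / 4.0), 0.02])
    res = optimize.minimize(
        _neg_log_likelihood,
        x0,
        args=(offsets, farther),
        method="L-BFGS-B",
        bounds=[
            (-span, span),
            (np.log(_SIGMA_BOUNDS[0]), np.log(_SIGMA_BOUNDS[1])),
            (0.0, MAX_LAPSE),
        ],
    )
    mu, log_sigma, lapse = res.x
    sigma = float(np.exp(log_sigma))
    at_bound = (
        sigma <= _SIGMA_BOUNDS[0] * (1 + 1e-6)
        or sigma >= _SIGMA_BOUNDS[1] * (1 - 1e-6)
    )
    converged = bool(res.success) and not at_bound
    if not converged:
        logger.warning("psychometric fit for %s flagged non-converged", condition)
    return PsychometricFit(
        condition=condition,
        mu=float(mu),
        sigma=sigma,
        lapse=float(lapse),
        converged=converged,
        n_trials=int(offsets.size),
    )


# ---------------------------------------------------------------------------
# Behavioral quadratic-summation test
# ---------------------------------------------------------------------------

@dataclass
class BehavioralQuadraticTest:
    """Comparison of congruent-cue sensitivity against the quadratic sum of
    the single-cue sensitivities (and against the incongruent condition)."""

    sensitivities: dict  # condition -> 1/jnd, for converged fits
    quadratic_sum_sensitivity: float
    congruent_exceeds_quadratic_sum: bool | None
    congruent_exceeds_incongruent: bool | None
    p_vs_quadratic_sum: float | None
    p_vs_incongruent: float | None
    partial: bool  # True when some condition's fit is missing/non-converged


def behavioral_quadratic_test(
    trials: pd.DataFrame, n_boot: int = 200, seed: int = 0
) -> BehavioralQuadraticTest:
    """Fit each condition, form the quadratic sum of single-cue sensitivities,
    and bootstrap (trial resampling + refit) one-sided p-values for the
    congruent condition exceeding (i) the quadratic sum and (ii) the
    incongruent sensitivity.  Missing or non-converged fits yield a partial
    record instead of an error.
    """
    fits: dict[str, PsychometricFit] = {}
    for cond in ("disparity", "motion", "congruent", "incongruent"):
        if (trials["condition"] == cond).any():
            try:
                fit = fit_psychometric(trials, cond)
            except ValueError:
                continue
            if fit.converged:
                fits[cond] = fit
    required = {"disparity", "motion", "congruent"}
    if not required <= set(fits):
        missing = required - set(fits)
        logger.warning("behavioral quadratic test: missing fits for %s", missing)
        return BehavioralQuadraticTest(
            sensitivities={c: f.sensitivity for c, f in fits.items()},
            quadratic_sum_sensitivity=float("nan"),
            congruent_exceeds_quadratic_sum=None,
            congruent_exceeds_incongruent=None,
            p_vs_quadratic_sum=None,
            p_vs_incongruent=None,
            partial=True,
        )

    sens = {c: f.sensitivity for c, f in fits.items()}
    qs = quadratic_sum(sens["disparity"], sens["motion"])
    has_incon = "incongruent" in sens

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    diffs_qs = np.full(n_boot, np.nan)
    diffs_incon = np.full(n_boot, np.nan)
    by_cond = {c: trials[trials["condition"] == c] for c in fits}
    for b in range(n_boot):
        s_b = {}
        ok = True
        for cond, grp in by_cond.items():
            resampled = grp.sample(n=len(grp), replace=True, random_state=rng)
            try:
                fit = fit_psychometric(resampled, cond)
            except ValueError:
                ok = False
                break
            if not fit.converged:
                ok = False
                break
            s_b[cond] = fit.sensitivity
        if not ok:
            continue
        diffs_qs[b] = s_b["congruent"] - quadratic_sum(
            s_b["disparity"], s_b["motion"]
        )
        if has_incon:
            diffs_incon[b] = s_b["congruent"] - s_b["incongruent"]

    def one_sided_p(diffs: np.ndarray) -> float | None:
        valid = diffs[~np.isnan(diffs)]
        if valid.size == 0:
            return None
        return (1 + int((valid <= 0).sum())) / (valid.size + 1)

    return BehavioralQuadraticTest(
        sensitivities=sens,
        quadratic_sum_sensitivity=qs,
        congruent_exceeds_quadratic_sum=sens["congruent"] > qs,
        congruent_exceeds_incongruent=(
            sens["congruent"] > sens["incongruent"] if has_incon else None
        ),
        p_vs_quadratic_sum=one_sided_p(diffs_qs),
        p_vs_incongruent=one_sided_p(diffs_incon) if has_incon else None,
        partial=False,
    )
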