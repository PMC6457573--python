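"""Population-mixture simulation and chi-square fitting.

Simulates condition-wise decoding profiles for populations whose fusion-unit
fraction varies over a grid, then estimates the fusion fraction behind an
empirical profile by minimizing a chi-square distance over the grid.  This is
how a fused-cue fraction (e.g. "about a third of the units") is read off a
measured decoding profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decode import ClassifierConfig, cv_decode, plan_folds
from .fusion_stats import dprime, quadratic_sum
from .patterns import dataset_to_patterns
from .synthdata import CONDITIONS, ExperimentDesign, PopulationSpec, generate_dataset

logger = logging.getLogger("cuefuse")

PROFILE_CONDITIONS = CONDITIONS  # disparity, motion, congruent, incongruent


@dataclass
class DecodingProfile:
    """Mean accuracy and SEM per condition, plus the quadratic-summation
    prediction derived from the single-cue entries."""

    accuracies: dict  # condition -> mean accuracy
    sems: dict  # condition -> SEM (NaN when n_replicates == 1)
    n_replicates: int
    f_fusion: float | None = None

    @property
    def quadratic_sum_prediction(self) -> float:
        """Accuracy implied by the quadratic sum of single-cue d' values."""
        from scipy.stats import norm

        d_d = float(dprime(self.accuracies["disparity"]))
        d_m = float(dprime(self.accuracies["motion"]))
        return float(norm.cdf(quadratic_sum(d_d, d_m)))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        acc = np.array([self.accuracies[c] for c in PROFILE_CONDITIONS])
        sem = np.array([self.sems[c] for c in PROFILE_CONDITIONS])
        return acc, sem


@dataclass
class MixtureGrid:
    """Simulated decoding profiles along a grid of fusion fractions."""

    fractions: np.ndarray
    profiles: list[DecodingProfile]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size == 0:
            raise ValueError("empty mixture grid")
        if np.any(np.diff(f) <= 0) or f.min() < 0 or f.max() > 1:
            raise ValueError("fractions must be strictly increasing in [0, 1]")


def simulate_profile(
    f_fusion: float,
    base_spec: PopulationSpec,
    design: ExperimentDesign,
    n_replicates: int = 5,
    seed: int = 0,
    cap: int | None = 150,
    config: ClassifierConfig = ClassifierConfig(),
) -> DecodingProfile:
    """Decoding profile of a population with the given fusion fraction.

    Per replicate: generate a dataset (non-fusion mass split equally between
    the two single-cue unit types), extract patterns, and decode all four
    conditions with leave-one-run-out cross-validation.  Returns the mean and
    SEM over replicates; SEM is NaN (and flagged) with a single replicate.
    """
    spec = base_spec.with_fusion_fraction(f_fusion)
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_replicates)]
    accs = {c: [] for c in PROFILE_CONDITIONS}
    for rep_seed in child_seeds:
        ds = generate_dataset(spec, design, seed=rep_seed)
        pm = dataset_to_patterns(ds, cap=cap)
        plan = plan_folds(pm.run_ids)
        for cond in PROFILE_CONDITIONS:
            accs[cond].append(cv_decode(pm, cond, plan, config=config).accuracy)
    means = {c: float(np.mean(v)) for c, v in accs.items()}
    if n_replicates > 1:
        sems = {
            c: float(np.std(v, ddof=1) / np.sqrt(n_replicates))
            for c, v in accs.items()
        }
    else:
        logger.warning("simulate_profile: SEM undefined with n_replicates=1")
        sems = {c: float("nan") for c in PROFILE_CONDITIONS}
    return DecodingProfile(
        accuracies=means, sems=sems, n_replicates=n_replicates, f_fusion=f_fusion
    )


def build_mixture_grid(
    base_spec: PopulationSpec,
    design: ExperimentDesign,
    fractions=None,
    n_replicates: int = 5,
    seed: int = 0,
    cap: int | None = 150,
) -> MixtureGrid:
    """Simulate the full grid of fusion fractions (default 0, 0.1, ..., 1)."""
    if fractions is None:
        fractions = np.round(np.linspace(0.0, 1.0, 11), 10)
    fractions = np.asarray(fractions, dtype=float)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(fractions))
    profiles = [
        simulate_profile(
            float(f), base_spec, design, n_replicates=n_replicates,
            seed=int(s.generate_state(1)[0] % 2**31), cap=cap,
        )
        for f, s in zip(fractions, children)
    ]
    return MixtureGrid(fractions=fractions, profiles=profiles)


def chi2_fit(
    empirical: DecodingProfile, grid: MixtureGrid
) -> tuple[float, np.ndarray]:
    """Estimate the fusion fraction by chi-square distance over the grid.

    chi2(f) = sum over the four conditions of (emp - sim(f))^2 / SE^2 with
    SE^2 = emp SEM^2 + sim SEM^2 (both noise sources treated symmetrically).
    Ties are broken toward the smaller fraction and logged.
    """
    emp_acc, emp_sem = empirical.as_arrays()
    if np.any(~(emp_sem > 0)):
        raise ValueError("empirical SEMs must be positive for the chi-square fit")
    curve = np.empty(grid.fractions.size)
    for i, prof in enumerate(grid.profiles):
        sim_acc, sim_sem = prof.as_arrays()
        var = emp_sem**2 + np.nan_to_num(sim_sem, nan=0.0) ** 2
        curve[i] = float(np.sum((emp_acc - sim_acc) ** 2 / var))
    best_idx = int(np.argmin(curve))  # argmin returns the first (smallest f) on ties
    if np.sum(curve == curve[best_idx]) > 1:
        logger.warning("chi2_fit: tie in chi-square curve, smallest fraction kept")
    return float(grid.fractions[best_idx]), curve
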