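"""Synthetic fMRI block-design data and behavioral trials for cue-integration decoding.

The generator emulates a two-cue depth experiment: on every stimulus block a
planar target is rendered nearer or farther than a reference using binocular
disparity, relative motion, or both (congruent or incongruent).  Voxel time
series are noisy sparse mixtures of three unit types — disparity-only,
motion-only, and fusion units that average the two cue signals with reduced
variance — so downstream decoding can be validated against a known population
composition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cuefuse")

CONDITIONS = ("disparity", "motion", "congruent", "incongruent")
SIGNS = ("near", "far")
UNIT_KINDS = ("fusion", "disparity_only", "motion_only")


# ---------------------------------------------------------------------------
# Stimulus labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class StimulusLabel:
    """One of the 8 stimuli: condition x near/far depth sign.

    ``cue_signs`` gives the signed depth each cue carries (+1 near, -1 far,
    0 flat).  For the incongruent condition the class label is anchored to
    the disparity sign: "incongruent near" means disparity-near/motion-far.
    """

    condition: str
    sign: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")

    @property
    def sign_value(self) -> int:
        return +1 if self.sign == "near" else -1

    @property
    def cue_signs(self) -> tuple[int, int]:
        s = self.sign_value
        if self.condition == "disparity":
            return (s, 0)
        if self.condition == "motion":
            return (0, s)
        if self.condition == "congruent":
            return (s, s)
        return (s, -s)  # incongruent, anchored on disparity


ALL_LABELS: tuple[StimulusLabel, ...] = tuple(
    StimulusLabel(c, s) for c in CONDITIONS for s in SIGNS
)


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Block-design timing: 24 16-s stimulus blocks per run flanked by 16-s
    fixation, TR 2 s (416-s runs, 208 volumes), 2-volume hemodynamic shift."""

    n_runs: int = 10
    blocks_per_run: int = 24
    block_duration_s: float = 16.0
    tr_s: float = 2.0
    fixation_s: float = 16.0
    hemodynamic_shift_volumes: int = 2

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.blocks_per_run % len(ALL_LABELS) != 0:
            raise ValueError(
                f"blocks_per_run={self.blocks_per_run} must be divisible by "
                f"{len(ALL_LABELS)} for balanced stimulus counts"
            )
        for name in ("block_duration_s", "fixation_s"):
            if getattr(self, name) % self.tr_s != 0:
                raise ValueError(f"{name} must be an integer number of TRs")

    @property
    def run_duration_s(self) -> float:
        return 2 * self.fixation_s + self.blocks_per_run * self.block_duration_s

    @property
    def volumes_per_run(self) -> int:
        return int(round(self.run_duration_s / self.tr_s))

    @property
    def block_volumes(self) -> int:
        return int(round(self.block_duration_s / self.tr_s))

    @property
    def fixation_volumes(self) -> int:
        return int(round(self.fixation_s / self.tr_s))

    @property
    def blocks_per_label(self) -> int:
        return self.blocks_per_run // len(ALL_LABELS)

    def block_onset_volume(self, block_index: int) -> int:
        return self.fixation_volumes + block_index * self.block_volumes


# ---------------------------------------------------------------------------
# Population specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Generative description of the simulated neuronal population and its
    voxel sampling.

    Fractions of the three unit types must sum to one.  Fusion units average
    the two cue signals and have their trial-to-trial noise scaled by
    ``fusion_noise_gain`` < 1, implementing the variance-reduction premise of
    optimal cue combination.  Defaults put single-cue decoding in the 70-85%
    accuracy range at 10 runs, comparable to a well-driven visual ROI.
    """

    n_units: int = 200
    f_fusion: float = 0.35
    f_disparity: float = 0.325
    f_motion: float = 0.325
    tuning_amplitude: float = 1.0
    fusion_noise_gain: float = 0.7071067811865476  # 1/sqrt(2), optimal fusion
    unit_noise_sd: float = 6.0
    n_voxels: int = 300
    mixing_sparsity: float = 0.25
    voxel_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        fr = (self.f_fusion, self.f_disparity, self.f_motion)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("unit fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"unit fractions must sum to 1, got {sum(fr)}")
        if not (0 < self.fusion_noise_gain <= 1):
            raise ValueError("fusion_noise_gain must lie in (0, 1]")
        if not (0 < self.mixing_sparsity <= 1):
            raise ValueError("mixing_sparsity must lie in (0, 1]")
        if self.n_units < 1 or self.n_voxels < 1:
            raise ValueError("n_units and n_voxels must be positive")

    def with_fusion_fraction(self, f_fusion: float) -> "PopulationSpec":
        """Same spec with a new fusion fraction; the remaining mass is split
        equally between disparity-only and motion-only units."""
        rest = (1.0 - f_fusion) / 2.0
        return PopulationSpec(
            n_units=self.n_units,
            f_fusion=f_fusion,
            f_disparity=rest,
            f_motion=rest,
            tuning_amplitude=self.tuning_amplitude,
            fusion_noise_gain=self.fusion_noise_gain,
            unit_noise_sd=self.unit_noise_sd,
            n_voxels=self.n_voxels,
            mixing_sparsity=self.mixing_sparsity,
            voxel_noise_sd=self.voxel_noise_sd,
        )


def unit_mean_response(
    unit_kind: str, label: StimulusLabel, spec: PopulationSpec, preferred_sign: int = +1
) -> float:
    """Noise-free mean response of a single unit to a stimulus.

    Disparity-only units respond to the disparity sign, motion-only units to
    the motion sign, and fusion units to the average of the two; every unit's
    response is multiplied by its preferred sign so near- and far-preferring
    units coexist in the population.
    """
    if unit_kind not in UNIT_KINDS:
        raise ValueError(f"unknown unit kind {unit_kind!r}")
    if preferred_sign not in (-1, 1):
        raise ValueError("preferred_sign must be +1 or -1")
    d, m = label.cue_signs
    if unit_kind == "disparity_only":
        drive = float(d)
    elif unit_kind == "motion_only":
        drive = float(m)
    else:
        drive = (d + m) / 2.0
    return spec.tuning_amplitude * preferred_sign * drive


def unit_response(
    unit_kind: str,
    label: StimulusLabel,
    spec: PopulationSpec,
    rng: np.random.Generator,
    preferred_sign: int = +1,
) -> float:
    """Single stochastic unit response: tuned mean plus Gaussian noise.

    Fusion units carry noise scaled by ``fusion_noise_gain`` (< 1), the
    variance reduction of a fused estimate relative to its components.
    """
    mean = unit_mean_response(unit_kind, label, spec, preferred_sign)
    sd = spec.unit_noise_sd
    if unit_kind == "fusion":
        sd = sd * spec.fusion_noise_gain
    return mean + sd * float(rng.standard_normal())


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Simulated runs (voxel x volume per run), the block events table, and
    the generative ground truth needed for recovery tests."""

    runs: list[np.ndarray]  # each (n_voxels, volumes_per_run)
    events: pd.DataFrame  # run, block, condition, sign, onset_volume
    design: ExperimentDesign
    spec: PopulationSpec
    mixing_weights: np.ndarray  # (n_voxels, n_units), sparse nonnegative
    unit_kinds: np.ndarray  # (n_units,) strings
    preferred_signs: np.ndarray  # (n_units,) +-1
    seed: int

    @property
    def truth(self) -> dict:
        counts = {k: int((self.unit_kinds == k).sum()) for k in UNIT_KINDS}
        return {
            "f_fusion": self.spec.f_fusion,
            "f_disparity": self.spec.f_disparity,
            "f_motion": self.spec.f_motion,
            "unit_counts": counts,
            "seed": self.seed,
        }

    def to_4d(self, shape: tuple[int, int, int] | None = None) -> list[np.ndarray]:
        """Reshape each run's (voxel, t) matrix into a 4-D (x, y, z, t)
        volume.  Voxels fill the grid in C order; extra grid cells are zero."""
        n_vox = self.runs[0].shape[0]
        if shape is None:
            side = int(np.ceil(n_vox ** (1 / 3)))
            shape = (side, side, side)
        if np.prod(shape) < n_vox:
            raise ValueError(f"grid {shape} too small for {n_vox} voxels")
        out = []
        for run in self.runs:
            vol = np.zeros((int(np.prod(shape)), run.shape[1]))
            vol[:n_vox] = run
            out.append(vol.reshape(*shape, run.shape[1]))
        return out

    def write(self, out_dir: str | Path, voxel_size_mm: float = 1.0) -> dict[str, Path]:
        """Write volumes as NIfTI-1 (one 4-D file per run), events as TSV,
        and ground truth as a JSON sidecar."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        paths: dict[str, Path] = {}
        for i, vol in enumerate(self.to_4d()):
            p = out / f"run-{i:02d}_bold.nii"
            nib.Nifti1Image(vol.astype(np.float32), affine).to_filename(p)
            paths[f"run-{i:02d}"] = p
        events_path = out / "events.tsv"
        self.events.to_csv(events_path, sep="\t", index=False)
        paths["events"] = events_path
        truth_path = out / "truth.json"
        truth = dict(self.truth)
        truth["mixing_weights_shape"] = list(self.mixing_weights.shape)
        truth_path.write_text(json.dumps(truth, indent=2))
        paths["truth"] = truth_path
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _make_events(design: ExperimentDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for run in range(design.n_runs):
        labels = list(ALL_LABELS) * design.blocks_per_label
        order = rng.permutation(len(labels))
        for block, idx in enumerate(order):
            lab = labels[idx]
            rows.append(
                {
                    "run": run,
                    "block": block,
                    "condition": lab.condition,
                    "sign": lab.sign,
                    "onset_volume": design.block_onset_volume(block),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    spec: PopulationSpec, design: ExperimentDesign, seed: int
) -> SyntheticDataset:
    """Simulate a full block-design experiment from a population mixture.

    Per block, every unit emits its tuned mean response plus Gaussian noise;
    each voxel is a fixed sparse nonnegative mixture of units plus voxel
    noise.  Block responses are embedded into a boxcar time course delayed by
    the hemodynamic shift, on a zero fixation baseline, so that pattern
    extraction can be exercised end to end.  One seed drives unit
    construction, mixing, block order, and all noise through deterministic
    sub-streams.
    """
    root = np.random.SeedSequence(seed)
    ss_units, ss_mix, ss_events, ss_noise = root.spawn(4)

    rng_units = np.random.default_rng(ss_units)
    n = spec.n_units
    # Unit type assignment: deterministic counts (largest remainder), random order
    counts = np.floor(
        np.array([spec.f_fusion, spec.f_disparity, spec.f_motion]) * n
    ).astype(int)
    frac = np.array([spec.f_fusion, spec.f_disparity, spec.f_motion]) * n - counts
    while counts.sum() < n:
        i = int(np.argmax(frac))
        counts[i] += 1
        frac[i] = -1
    unit_kinds = np.repeat(np.array(UNIT_KINDS, dtype=object), counts)
    rng_units.shuffle(unit_kinds)
    preferred_signs = rng_units.choice([-1, 1], size=n)

    # Sparse nonnegative mixing weights, fixed for the dataset
    rng_mix = np.random.default_rng(ss_mix)
    k = max(1, int(round(spec.mixing_sparsity * n)))
    weights = np.zeros((spec.n_voxels, n))
    for v in range(spec.n_voxels):
        idx = rng_mix.choice(n, size=k, replace=False)
        weights[v, idx] = rng_mix.uniform(0.0, 1.0, size=k)

    events = _make_events(design, np.random.default_rng(ss_events))

    # Mean response of each unit to each of the 8 labels
    label_index = {lab: i for i, lab in enumerate(ALL_LABELS)}
    mean_resp = np.zeros((n, len(ALL_LABELS)))
    noise_sd = np.full(n, spec.unit_noise_sd)
    for u in range(n):
        for lab, j in label_index.items():
            mean_resp[u, j] = unit_mean_response(
                str(unit_kinds[u]), lab, spec, int(preferred_signs[u])
            )
        if unit_kinds[u] == "fusion":
            noise_sd[u] *= spec.fusion_noise_gain

    rng_noise = np.random.default_rng(ss_noise)
    runs = []
    for run in range(design.n_runs):
        ev = events[events["run"] == run]
        ts = np.zeros((spec.n_voxels, design.volumes_per_run))
        for _, row in ev.iterrows():
            lab = StimulusLabel(row["condition"], row["sign"])
            j = label_index[lab]
            unit_r = mean_resp[:, j] + noise_sd * rng_noise.standard_normal(n)
            voxel_r = weights @ unit_r
            voxel_r += spec.voxel_noise_sd * rng_noise.standard_normal(spec.n_voxels)
            start = int(row["onset_volume"]) + design.hemodynamic_shift_volumes
            stop = min(start + design.block_volumes, design.volumes_per_run)
            ts[:, start:stop] = voxel_r[:, None]
        runs.append(ts)

    return SyntheticDataset(
        runs=runs,
        events=events,
        design=design,
        spec=spec,
        mixing_weights=weights,
        unit_kinds=unit_kinds,
        preferred_signs=preferred_signs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Behavioral observer and trials
# ---------------------------------------------------------------------------

#: 12 target-vs-reference depth offsets (arcmin), up to 6.3, as used per sign.
DEFAULT_DEPTH_LEVELS: tuple[float, ...] = tuple(
    round(x, 3) for x in np.linspace(0.3, 6.3, 12)
)


@dataclass(frozen=True)
class BehavioralObserver:
    """Cumulative-Gaussian two-interval observer.

    ``noise_sd`` maps condition -> internal noise (arcmin); responses are
    "farther" when the internal estimate of the signed offset exceeds zero,
    with a lapse rate of random responses and an additive bias.
    """

    noise_sd: dict = field(
        default_factory=lambda: {
            "disparity": 1.5,
            "motion": 2.5,
            "congruent": 1.2862,  # optimal fusion of the two single-cue noises
            "incongruent": 2.5,
        }
    )
    lapse_rate: float = 0.02
    bias: float = 0.0

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be positive")
        if not (0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must lie in [0, 0.5)")

    @classmethod
    def fusing(
        cls, sigma_disparity: float, sigma_motion: float,
        lapse_rate: float = 0.0, bias: float = 0.0,
    ) -> "BehavioralObserver":
        """Observer whose congruent-cue noise follows optimal fusion
        (1/sigma_C^2 = 1/sigma_D^2 + 1/sigma_M^2) and whose incongruent noise
        reverts to the worse single cue."""
        sigma_c = 1.0 / np.sqrt(sigma_disparity**-2 + sigma_motion**-2)
        return cls(
            noise_sd={
                "disparity": sigma_disparity,
                "motion": sigma_motion,
                "congruent": float(sigma_c),
                "incongruent": max(sigma_disparity, sigma_motion),
            },
            lapse_rate=lapse_rate,
            bias=bias,
        )


def generate_behavioral_runs(
    observer: BehavioralObserver,
    depth_levels: Sequence[float] = DEFAULT_DEPTH_LEVELS,
    trials_per_level: int = 15,
    n_runs: int = 1,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-interval depth-discrimination runs.

    Each run presents every |offset| level ``trials_per_level`` times per
    depth sign per condition (the default 12 levels x 15 trials x 2 signs =
    360 trials per condition per run).  Positive offsets mean the target is
    farther than the reference; a correct response matches the offset sign.
    """
    levels = [float(abs(x)) for x in depth_levels]
    if len(levels) == 0:
        raise ValueError("depth_levels must be nonempty")
    if trials_per_level < 1:
        raise ValueError("trials_per_level must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for run in range(n_runs):
        for cond in conditions:
            sd = observer.noise_sd[cond]
            for level in levels:
                for sign in (+1, -1):
                    offset = sign * level
                    est = offset + observer.bias + sd * rng.standard_normal(
                        trials_per_level
                    )
                    resp_farther = est > 0
                    lapse = rng.random(trials_per_level) < observer.lapse_rate
                    coin = rng.random(trials_per_level) < 0.5
                    resp_farther = np.where(lapse, coin, resp_farther)
                    for t in range(trials_per_level):
                        farther = bool(resp_farther[t])
                        rows.append(
                            {
                                "run": run,
                                "condition": cond,
                                "offset_arcmin": offset,
                                "response": "farther" if farther else "nearer",
                                "correct": farther == (offset > 0),
                            }
                        )
    return pd.DataFrame(rows)
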