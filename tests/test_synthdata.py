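"""Stimulus labels, design arithmetic, and the synthetic generator."""

import numpy as np
import pytest

from cuefuse import (
    ALL_LABELS,
    BehavioralObserver,
    ExperimentDesign,
    PopulationSpec,
    StimulusLabel,
    generate_behavioral_runs,
    generate_dataset,
    unit_response,
)
from cuefuse.synthdata import unit_mean_response


class TestStimulusLabels:
    def test_eight_distinct_labels(self):
        assert len(ALL_LABELS) == 8
        assert len(set(ALL_LABELS)) == 8

    def test_single_cue_labels_carry_one_cue(self):
        near_disp = StimulusLabel("disparity", "near")
        far_motion = StimulusLabel("motion", "far")
        assert near_disp.cue_signs == (1, 0)
        assert far_motion.cue_signs == (0, -1)

    def test_congruent_cues_agree_incongruent_oppose(self):
        assert StimulusLabel("congruent", "near").cue_signs == (1, 1)
        assert StimulusLabel("congruent", "far").cue_signs == (-1, -1)
        # incongruent class label is anchored on the disparity sign
        assert StimulusLabel("incongruent", "near").cue_signs == (1, -1)
        assert StimulusLabel("incongruent", "far").cue_signs == (-1, 1)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            StimulusLabel("texture", "near")


class TestUnitResponses:
    def test_fusion_unit_silent_for_incongruent(self):
        spec = PopulationSpec()
        for sign in ("near", "far"):
            lab = StimulusLabel("incongruent", sign)
            assert unit_mean_response("fusion", lab, spec) == 0.0

    def test_fusion_unit_averages_congruent_cues(self):
        spec = PopulationSpec(tuning_amplitude=2.0)
        lab = StimulusLabel("congruent", "near")
        assert unit_mean_response("fusion", lab, spec) == 2.0
        half = unit_mean_response("fusion", StimulusLabel("disparity", "near"), spec)
        assert half == 1.0

    def test_single_cue_unit_ignores_other_cue(self):
        spec = PopulationSpec()
        lab = StimulusLabel("motion", "near")
        assert unit_mean_response("disparity_only", lab, spec) == 0.0
        assert unit_mean_response("motion_only", lab, spec) == 1.0

    def test_preferred_sign_flips_response(self):
        spec = PopulationSpec()
        lab = StimulusLabel("disparity", "near")
        up = unit_mean_response("disparity_only", lab, spec, preferred_sign=+1)
        dn = unit_mean_response("disparity_only", lab, spec, preferred_sign=-1)
        assert up == -dn != 0

    def test_fusion_noise_reduced_relative_to_single_units(self):
        spec = PopulationSpec(unit_noise_sd=1.0)
        lab = StimulusLabel("incongruent", "near")
        rng = np.random.default_rng(0)
        fusion = np.array([unit_response("fusion", lab, spec, rng) for _ in range(4000)])
        rng = np.random.default_rng(0)
        single = np.array(
            [unit_response("motion_only", StimulusLabel("disparity", "near"), spec, rng)
             for _ in range(4000)]
        )
        assert fusion.std() == pytest.approx(single.std() / np.sqrt(2), rel=0.05)


class TestDesignArithmetic:
    def test_default_block_design_timing(self):
        d = ExperimentDesign()
        assert d.run_duration_s == 416.0
        assert d.volumes_per_run == 208
        assert d.blocks_per_run == 24
        assert d.block_volumes == 8
        assert d.fixation_volumes == 8
        assert d.blocks_per_label == 3

    def test_block_onsets_tile_the_run(self):
        d = ExperimentDesign()
        onsets = [d.block_onset_volume(i) for i in range(d.blocks_per_run)]
        assert onsets[0] == d.fixation_volumes
        assert np.all(np.diff(onsets) == d.block_volumes)
        assert onsets[-1] + d.block_volumes + d.fixation_volumes == d.volumes_per_run

    def test_unbalanced_block_count_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(blocks_per_run=20)

    def test_non_integer_tr_multiple_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(block_duration_s=15.0)


class TestPopulationSpec:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PopulationSpec(f_fusion=0.5, f_disparity=0.5, f_motion=0.5)

    def test_with_fusion_fraction_splits_remainder_equally(self):
        spec = PopulationSpec().with_fusion_fraction(0.4)
        assert spec.f_fusion == 0.4
        assert spec.f_disparity == spec.f_motion == pytest.approx(0.3)


class TestGenerateDataset:
    def test_shapes_and_balanced_events(self, tiny_dataset, tiny_design, tiny_spec):
        assert len(tiny_dataset.runs) == tiny_design.n_runs
        for run in tiny_dataset.runs:
            assert run.shape == (tiny_spec.n_voxels, tiny_design.volumes_per_run)
        ev = tiny_dataset.events
        assert len(ev) == tiny_design.n_runs * tiny_design.blocks_per_run
        per_label = ev.groupby(["run", "condition", "sign"]).size()
        assert (per_label == tiny_design.blocks_per_label).all()

    def test_same_seed_reproduces_different_seed_differs(self, tiny_spec, tiny_design):
        a = generate_dataset(tiny_spec, tiny_design, seed=3)
        b = generate_dataset(tiny_spec, tiny_design, seed=3)
        c = generate_dataset(tiny_spec, tiny_design, seed=4)
        for ra, rb in zip(a.runs, b.runs):
            np.testing.assert_array_equal(ra, rb)
        assert not np.allclose(a.runs[0], c.runs[0])

    def test_unit_counts_follow_fractions(self):
        spec = PopulationSpec(n_units=200)
        ds = generate_dataset(spec, ExperimentDesign(n_runs=2), seed=0)
        counts = ds.truth["unit_counts"]
        assert counts["fusion"] == 70
        assert counts["disparity_only"] == counts["motion_only"] == 65
        assert sum(counts.values()) == 200

    def test_fixation_volumes_stay_at_baseline(self, tiny_dataset, tiny_design):
        # with a 2-volume shift, the first 2 volumes precede any block response
        for run in tiny_dataset.runs:
            assert np.all(run[:, : tiny_design.hemodynamic_shift_volumes] == 0)

    def test_mixing_weights_sparse_and_nonnegative(self, tiny_dataset, tiny_spec):
        w = tiny_dataset.mixing_weights
        assert w.shape == (tiny_spec.n_voxels, tiny_spec.n_units)
        assert np.all(w >= 0)
        k = max(1, int(round(tiny_spec.mixing_sparsity * tiny_spec.n_units)))
        assert np.all((w > 0).sum(axis=1) <= k)


class TestBehavioralRuns:
    def test_trial_count_per_condition(self):
        df = generate_behavioral_runs(BehavioralObserver(), seed=1)
        per_cond = df.groupby("condition").size()
        assert (per_cond == 360).all()  # 12 levels x 15 trials x 2 signs

    def test_correctness_matches_response_and_offset(self):
        df = generate_behavioral_runs(BehavioralObserver(), seed=2)
        expected = (df["response"] == "farther") == (df["offset_arcmin"] > 0)
        assert (df["correct"] == expected).all()

    def test_lapse_free_observer_is_perfect_at_huge_offsets(self):
        obs = BehavioralObserver(
            noise_sd={"disparity": 0.01, "motion": 0.01, "congruent": 0.01,
                      "incongruent": 0.01},
            lapse_rate=0.0,
        )
        df = generate_behavioral_runs(obs, depth_levels=(50.0,), seed=3)
        assert df["correct"].all()

    def test_fusing_observer_noise_is_optimal_combination(self):
        obs = BehavioralObserver.fusing(1.5, 2.5)
        expected = 1.0 / np.sqrt(1.5**-2 + 2.5**-2)
        assert obs.noise_sd["congruent"] == pytest.approx(expected)
        assert obs.noise_sd["incongruent"] == 2.5
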