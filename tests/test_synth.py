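"""Synthetic generator: determinism, construction fidelity, survey coupling."""

import dataclasses

import numpy as np
import pytest

from padrom import reference
from padrom.kinematics import euler_yxz, joint_quaternion
from padrom.rom import (
    CONDITIONS,
    STATIC_TASK_PLANES,
    STATIC_TASKS,
    ExtractionConfig,
    extract_study_records,
    extract_trial_records,
    middle_axis_continuous,
    phase_rom,
    static_rom,
)
from padrom.synth import (
    GeneratorConfig,
    generate_shot_trial,
    generate_static_trial,
    generate_study,
    generate_survey,
    protector_restriction,
    write_study,
)
from padrom.rom import ShotEvents


def _clean_channel(trial, joint, side, channel):
    """Joint-angle channel straight from raw (unfiltered) quaternions."""
    from padrom.rom import JOINT_SEGMENTS, _CHANNEL_INDEX

    prox_stem, dist_stem = JOINT_SEGMENTS[joint]
    prox = trial.segments[prox_stem if prox_stem == "upper_spine" else f"{prox_stem}_{side}"]
    dist = trial.segments[f"{dist_stem}_{side}"]
    qj = joint_quaternion(prox.frames, dist.frames)
    y, x, z = euler_yxz(qj)
    angles = np.stack([y, x, z], axis=-1)
    if channel == "x":
        return middle_axis_continuous(angles)
    return angles[:, _CHANNEL_INDEX[channel]]


class TestDeterminism:
    def test_same_seed_identical_trials(self, tiny_config):
        t1, g1 = generate_static_trial(tiny_config, 0, "ibx", "sho_flex", 2)
        t2, g2 = generate_static_trial(tiny_config, 0, "ibx", "sho_flex", 2)
        for name in t1.segments:
            np.testing.assert_array_equal(t1.segments[name].frames, t2.segments[name].frames)
        assert g1 == g2

    def test_trials_independent_of_iteration_order(self, tiny_config):
        direct, _ = generate_shot_trial(tiny_config, 1, "heilong", "slap_shot", 2)
        for trial, _ in generate_study(tiny_config, tasks=("slap_shot",), conditions=("heilong",)):
            if trial.participant_id == "p02" and trial.repetition == 2:
                for name in direct.segments:
                    np.testing.assert_array_equal(
                        trial.segments[name].frames, direct.segments[name].frames
                    )
                break


class TestStreamInvariants:
    def test_unit_norm_and_sign_continuity(self, tiny_config):
        trial, _ = generate_shot_trial(tiny_config, 0, "vik_max", "slap_shot", 1)
        for series in trial.segments.values():
            np.testing.assert_allclose(np.linalg.norm(series.frames, axis=1), 1.0, atol=1e-9)
            dots = np.sum(series.frames[:-1] * series.frames[1:], axis=1)
            assert np.all(dots > 0)


class TestStaticConstruction:
    def test_noiseless_round_trip_exact(self, noiseless_config):
        trial, truth = generate_static_trial(noiseless_config, 0, "no_pads", "sho_flex", 1)
        chan = _clean_channel(trial, "shoulder", "l", "y")
        got = static_rom(chan, trial.sample_rate, +1)
        assert got == pytest.approx(truth.rom_deg["sho_flex_l"], abs=1e-6)
        control = float(reference.static_table().loc["sho_flex", "no_pads_mean"])
        assert truth.rom_deg["sho_flex"] == pytest.approx(control, abs=1e-9)

    def test_abduction_beyond_ninety_degrees_recovered(self, noiseless_config):
        trial, truth = generate_static_trial(noiseless_config, 0, "no_pads", "sho_abd", 1)
        chan = _clean_channel(trial, "shoulder", "l", "x")
        got = static_rom(chan, trial.sample_rate, -1)
        assert truth.rom_deg["sho_abd_l"] > 120.0
        assert got == pytest.approx(truth.rom_deg["sho_abd_l"], abs=1e-6)

    def test_restriction_factor_scales_peak(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config)
        cfg.static_factors = dict(cfg.static_factors)
        cfg.static_factors[("ibx", "elb_flex")] = 0.85
        _, t_pad = generate_static_trial(cfg, 0, "ibx", "elb_flex", 1)
        _, t_ctl = generate_static_trial(cfg, 0, "no_pads", "elb_flex", 1)
        assert t_pad.rom_deg["elb_flex"] / t_ctl.rom_deg["elb_flex"] == pytest.approx(0.85)

    def test_full_extraction_close_at_default_noise(self, tiny_config):
        trial, truth = generate_static_trial(tiny_config, 0, "no_pads", "sho_flex", 1)
        rec = extract_trial_records(trial)[0]
        assert rec.rom_deg == pytest.approx(truth.rom_deg["sho_flex"], abs=1.5)


class TestShotConstruction:
    def test_wrist_shot_has_no_swing_top(self, tiny_config):
        _, truth = generate_shot_trial(tiny_config, 0, "no_pads", "wrist_shot", 1)
        assert truth.st_frame is None
        assert truth.si_frame < truth.sr_frame

    def test_slap_event_ordering(self, tiny_config):
        _, truth = generate_shot_trial(tiny_config, 0, "no_pads", "slap_shot", 1)
        assert truth.si_frame < truth.st_frame < truth.sr_frame

    def test_noiseless_phase_rom_matches_design(self, noiseless_config):
        trial, truth = generate_shot_trial(noiseless_config, 0, "no_pads", "slap_shot", 1)
        events = ShotEvents(
            truth.design_si_frame, truth.design_sr_frame, truth.design_st_frame
        )
        chan = _clean_channel(trial, "elbow", "l", "y")
        for phase in ("si_st", "st_sr"):
            assert phase_rom(chan, events, phase) == pytest.approx(
                truth.rom_deg[f"{phase}:elb_flex_l"], abs=1e-6
            )

    def test_wrist_noiseless_phase_rom_matches_design(self, noiseless_config):
        trial, truth = generate_shot_trial(noiseless_config, 0, "heilong", "wrist_shot", 1)
        events = ShotEvents(truth.design_si_frame, truth.design_sr_frame)
        for plane, (joint, channel) in [
            ("sho_flex_ext_l", ("shoulder", "y")),
            ("forearm_pro_sup_r", ("forearm", "z")),
        ]:
            side = plane[-1]
            chan = _clean_channel(trial, joint, side, channel)
            assert phase_rom(chan, events, "si_sr") == pytest.approx(
                truth.rom_deg[f"si_sr:{plane}"], abs=1e-6
            )


class TestSurvey:
    def test_scores_in_scale(self, tiny_config):
        sv = generate_survey(tiny_config)
        assert sv["score"].between(1, 5).all()
        assert sv["score"].dtype.kind == "i"

    def test_full_coupling_no_noise_ranking_inverse(self):
        cfg = GeneratorConfig(seed=0, comfort_coupling=1.0)
        # well-separated restriction levels so discretisation preserves order
        cfg.static_factors = {
            (c, t): (1.0 if c == "no_pads" else f)
            for c, f in zip(CONDITIONS, [1.0, 0.95, 0.85, 0.75, 0.65, 0.55])
            for t in STATIC_TASKS
        }
        cfg.dynamic_factors = {
            k: (1.0 if k[0] == "no_pads" else cfg.static_factors[(k[0], "sho_flex")])
            for k in cfg.dynamic_factors
        }
        sv = generate_survey(cfg)
        from padrom.comfort import aggregate_likert, comfort_score

        comfort = comfort_score(aggregate_likert(sv))
        restriction = protector_restriction(cfg).mean(axis=1)
        assert list(comfort.sort_values(ascending=False).index) == list(
            restriction.sort_values().index
        )

    def test_zero_coupling_centred_over_seeds(self):
        from padrom.comfort import aggregate_likert, comfort_score
        from padrom.stats import spearman_corr

        restr = None
        rhos = []
        for seed in range(100):
            cfg = GeneratorConfig(seed=seed, comfort_coupling=0.0)
            if restr is None:
                restr = protector_restriction(cfg).mean(axis=1)
            comfort = comfort_score(aggregate_likert(generate_survey(cfg)))
            try:
                rho, _ = spearman_corr(comfort.to_numpy(), restr.to_numpy())
            except ValueError:  # all-tied comfort vector carries no ranking
                rho = 0.0
            rhos.append(rho)
        # n=5 Spearman has SD ~0.5 per seed; 0.16 is a >3 sigma bound on the mean
        assert abs(float(np.mean(rhos))) < 0.16


class TestStudyLayout:
    def test_design_cell_count(self, tiny_config):
        table = extract_study_records(t for t, _ in generate_study(tiny_config))
        cells = table[["participant", "task", "condition"]].drop_duplicates()
        assert len(cells) == tiny_config.n_participants * 11 * 6

    def test_write_study_layout_and_rerun_identical(self, noiseless_config, tmp_path):
        cfg = dataclasses.replace(noiseless_config)
        out1 = write_study(cfg, tmp_path / "a")
        out2 = write_study(cfg, tmp_path / "b")
        m1 = (out1 / "manifest.csv").read_bytes()
        assert m1 == (out2 / "manifest.csv").read_bytes()
        import pandas as pd

        manifest = pd.read_csv(out1 / "manifest.csv")
        assert len(manifest) == cfg.n_participants * 11 * 6 * cfg.repetitions
        assert all((out1 / f).exists() for f in manifest["file"])
        assert (out1 / "survey.csv").exists() and (out1 / "ground_truth.csv").exists()

    def test_write_study_refuses_nonempty_dir(self, noiseless_config, tmp_path):
        (tmp_path / "x").mkdir()
        (tmp_path / "x" / "stray.txt").write_text("hi")
        with pytest.raises(FileExistsError):
            write_study(noiseless_config, tmp_path / "x")


class TestConfigValidation:
    def test_control_factor_must_be_one(self, tiny_config):
        bad = dict(tiny_config.static_factors)
        bad[("no_pads", "sho_flex")] = 0.9
        with pytest.raises(ValueError):
            GeneratorConfig(static_factors=bad)

    def test_factor_range_enforced(self, tiny_config):
        bad = dict(tiny_config.static_factors)
        bad[("ibx", "sho_flex")] = 1.4
        with pytest.raises(ValueError):
            GeneratorConfig(static_factors=bad)

    def test_coupling_range(self):
        with pytest.raises(ValueError):
            GeneratorConfig(comfort_coupling=1.5)
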