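"""Generator contracts: design structure, determinism, ground-truth effects."""

import numpy as np
import pandas as pd
import pytest

from affectmed import (
    CONDITIONS,
    SCALES,
    StudyConfig,
    apply_exclusions,
    generate_study,
    inject_careless,
    write_study,
)
from affectmed.screening import _pooled_sds, rating_sd
from affectmed.synthetic import read_study

from conftest import null_paths


class TestStructure:
    def test_trial_design_is_90_trials_30_per_condition(self, small_study):
        counts = small_study.trials.groupby(["participant_id", "image_type"]).size()
        assert (counts == 30).all()
        per_part = small_study.trials.groupby("participant_id").size()
        assert (per_part == 90).all()

    def test_ratings_bounded_and_items_likert(self, small_study):
        ratings = small_study.trials[list(SCALES)].to_numpy()
        assert ratings.min() >= 0.0 and ratings.max() <= 100.0
        items = small_study.participants[[f"item_{j}" for j in range(1, 11)]].to_numpy()
        assert set(np.unique(items)) <= {1, 2, 3, 4, 5}

    def test_diagnosed_count_near_binomial_mean(self):
        # n=734, p=0.1866 -> expected 137 diagnosed; observed within 3 SD
        study = generate_study(StudyConfig(n_participants=734, p_diagnosed=0.1866, seed=5))
        n_diag = int(study.participants["diagnosed"].sum())
        sd = np.sqrt(734 * 0.1866 * (1 - 0.1866))
        assert abs(n_diag - 137) < 3 * sd

    def test_same_seed_bit_identical(self):
        cfg = StudyConfig(n_participants=50, seed=42)
        s1, s2 = generate_study(cfg), generate_study(cfg)
        pd.testing.assert_frame_equal(s1.participants, s2.participants)
        pd.testing.assert_frame_equal(s1.trials, s2.trials)
        s3 = generate_study(StudyConfig(n_participants=50, seed=43))
        assert not s1.trials[list(SCALES)].equals(s3.trials[list(SCALES)])

    def test_clean_study_passes_qc(self, small_study):
        _, report = apply_exclusions(
            small_study.participants, small_study.trials, small_study.attention
        )
        assert report.n_final == report.n_enrolled


class TestEffects:
    def test_null_config_gives_null_association(self):
        # all paths zero -> diagnosis uncorrelated with disruption items
        corrs = []
        for seed in range(8):
            cfg = StudyConfig(
                n_participants=800, seed=seed, a_paths=null_paths(),
                b_paths=null_paths(), covariate_effects=(0.0,) * 6,
            )
            s = generate_study(cfg)
            score = s.participants[[f"item_{j}" for j in range(1, 11)]].mean(axis=1)
            corrs.append(np.corrcoef(s.participants["diagnosed"], score)[0, 1])
        assert abs(np.mean(corrs)) < 3.0 / np.sqrt(800 * 8)

    def test_condition_shift_ordering_in_expectation(self):
        # default shifts: infection > harm > neutral for every scale's means
        s = generate_study(StudyConfig(n_participants=1500, seed=3))
        means = s.trials.groupby("image_type")["disgust"].mean()
        assert means["infection"] > means["harm"] > means["neutral"]

    def test_score_monotone_in_latent_factor(self):
        # with loadings at 1 the items are a deterministic discretisation of
        # the factor, so the score is a nondecreasing function of it
        cfg = StudyConfig(n_participants=600, seed=9, item_loadings=(1.0,) * 10)
        s = generate_study(cfg)
        f = s.truth["latent"]["factor"].to_numpy()
        score = s.participants[[f"item_{j}" for j in range(1, 11)]].mean(axis=1).to_numpy()
        order = np.argsort(f)
        assert (np.diff(score[order]) >= 0).all()

    def test_diagnosis_shifts_latent_reactivity(self):
        a = null_paths()
        a[("neutral", "disgust")] = 0.5
        cfg = StudyConfig(n_participants=4000, seed=1, a_paths=a,
                          b_paths=null_paths(), covariate_effects=(0.0,) * 6)
        s = generate_study(cfg)
        lat = s.truth["latent"]
        d = s.participants["diagnosed"].to_numpy().astype(bool)
        gap = lat["z_neutral_disgust"][d].mean() - lat["z_neutral_disgust"][~d].mean()
        assert gap == pytest.approx(0.5, abs=0.1)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_diagnosed": 1.5},
            {"n_participants": 0},
            {"n_careless": -1},
            {"item_loadings": (0.5,) * 9},
            {"item_loadings": (0.5,) * 9 + (1.2,)},
            {"mediator_correlation": 1.0},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            generate_study(StudyConfig(**kwargs))

    def test_missing_path_keys_raise(self):
        bad = null_paths()
        del bad[("harm", "fear")]
        with pytest.raises(ValueError, match="a_paths missing"):
            generate_study(StudyConfig(a_paths=bad))


class TestCareless:
    def test_zero_injection_is_identity(self, small_study):
        out = inject_careless(small_study, 0, "constant_response")
        pd.testing.assert_frame_equal(out.trials, small_study.trials)

    def test_constant_response_produces_low_sd(self, small_study):
        out = inject_careless(small_study, 10, "constant_response", seed=4)
        sds = _pooled_sds(out.trials)
        assert (sds < 10).sum() == 10
        assert set(sds.index[sds < 10]) == set(out.truth["careless_ids"])

    def test_attention_fail_roundtrip_through_qc(self, small_study):
        out = inject_careless(small_study, 5, "attention_fail", seed=4)
        _, report = apply_exclusions(out.participants, out.trials, out.attention)
        assert report.n_attention_failed == 5
        assert set(report.excluded_ids_by_step["attention"]) == set(
            out.truth["attention_fail_ids"]
        )

    def test_unknown_mode_raises(self, small_study):
        with pytest.raises(ValueError, match="unknown careless mode"):
            inject_careless(small_study, 1, "zigzag")

    def test_injection_does_not_mutate_input(self, small_study):
        before = small_study.trials[list(SCALES)].to_numpy().copy()
        inject_careless(small_study, 5, "constant_response", seed=1)
        assert np.array_equal(before, small_study.trials[list(SCALES)].to_numpy())


def test_write_read_roundtrip(tmp_path, small_study):
    write_study(small_study, tmp_path)
    back = read_study(tmp_path)
    assert len(back.participants) == len(small_study.participants)
    assert back.truth["a_paths"] == small_study.truth["a_paths"]
    np.testing.assert_allclose(
        back.trials[list(SCALES)].to_numpy(),
        small_study.trials[list(SCALES)].to_numpy(),
        rtol=0, atol=1e-9,
    )
    # rating_sd agrees between the in-memory and round-tripped tables
    pid = small_study.participants["participant_id"].iloc[0]
    a = rating_sd(small_study.trials[small_study.trials.participant_id == pid])
    b = rating_sd(back.trials[back.trials.participant_id == pid])
    assert a == pytest.approx(b, abs=1e-9)
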