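import numpy as np
import pytest
from scipy import stats as sps

from myoquant import default_config, generate_cohort, generate_slice_stack
from myoquant.config import (
    AccelProfile,
    GeneratorConfig,
    LognormalVar,
    NormalVar,
    lognormal_from_median_iqr,
)
from myoquant.morphometry import frustum_volume

# lightweight accelerometer profile for Monte-Carlo sized cohorts
_FAST_ACCEL = AccelProfile(days=1, epoch_s=600)


class TestConfig:
    def test_default_arm_sizes(self):
        cfg = default_config()
        assert cfg.n_esld == 39 and cfg.n_hc == 18

    def test_lognormal_moment_match_recovers_median_iqr(self):
        mu, sigma = lognormal_from_median_iqr(36.6, 61.3)
        q25, q50, q75 = sps.lognorm.ppf([0.25, 0.5, 0.75], s=sigma, scale=np.exp(mu))
        assert q50 == pytest.approx(36.6, rel=1e-9)
        assert q75 - q25 == pytest.approx(61.3, rel=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            NormalVar(10.0, 0.0)
        with pytest.raises(ValueError, match="strictly positive"):
            LognormalVar(10.0, 0.0)

    def test_invalid_sizes_and_seed_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_esld=0)
        with pytest.raises(TypeError):
            GeneratorConfig(seed="one")
        with pytest.raises(TypeError):
            generate_cohort(default_config(), seed=1.5)


class TestCohortStructure:
    def test_arm_sizes_and_completeness(self, small_cohort):
        _, cohort = small_cohort
        assert len(cohort.subjects) == 10
        assert len(cohort.arm_ids("ESLD")) == 6
        assert len(cohort.arm_ids("HC")) == 4
        for sid in cohort.ids:
            assert set(cohort.slice_stacks[sid]) == {"quadriceps", "VL", "L3"}

    def test_default_sizes(self, default_cohort):
        _, cohort = default_cohort
        assert len(cohort.subjects) == 57
        assert len(cohort.arm_ids("ESLD")) == 39

    def test_controls_carry_no_fluid(self, small_cohort):
        _, cohort = small_cohort
        for s in cohort.subjects:
            if s.arm == "HC":
                assert s.ascites_grade == "none" and s.oedema_grade == "none"

    def test_determinism(self, small_cohort):
        cfg, cohort = small_cohort
        again = generate_cohort(cfg, seed=11)
        assert again == cohort

    def test_different_seeds_differ(self, small_cohort):
        cfg, cohort = small_cohort
        assert generate_cohort(cfg, seed=12) != cohort


class TestSliceStacks:
    def test_quadriceps_slice_count_and_spacing(self, default_cohort):
        _, cohort = default_cohort
        counts = []
        for sid in cohort.ids:
            q = cohort.slice_stacks[sid]["quadriceps"]
            counts.append(q.n_slices)
            assert 6 <= q.n_slices <= 8
            assert np.allclose(np.diff(q.positions), 4.0)
            assert all(a > 0 for a in q.areas)
        assert np.mean(counts) == pytest.approx(7.0, abs=0.5)

    def test_l3_is_single_slice(self, default_cohort):
        _, cohort = default_cohort
        for sid in cohort.ids:
            assert cohort.slice_stacks[sid]["L3"].n_slices == 1

    def test_unknown_muscle_rejected(self, small_cohort):
        _, cohort = small_cohort
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="unknown muscle"):
            generate_slice_stack(cohort.subjects[0], "biceps", rng, {})

    def test_stack_realises_target_volume_and_mid_area(self, default_cohort):
        cfg, cohort = default_cohort
        for sid in cohort.ids[:10]:
            q = cohort.slice_stacks[sid]["quadriceps"]
            subj = cohort.subject(sid)
            truth = cohort.truth.loc[sid]
            v = frustum_volume(q) / subj.height**2
            assert v == pytest.approx(truth["quad_volume_index"], rel=1e-6)
            mid = 0.5 * cfg.femur_height_ratio * subj.height * 100.0
            nearest = int(np.argmin(np.abs(np.asarray(q.positions) - mid)))
            assert q.areas[nearest] == pytest.approx(truth["mid_acsa"], rel=1e-9)

    def test_volume_index_recovery_over_many_subjects(self):
        """Mean frustum volume / height^2 over 200 patients stays within
        3 SE of the configured arm volume-index distribution."""
        cfg = default_config(n_esld=200, n_hc=2, accel=_FAST_ACCEL)
        cohort = generate_cohort(cfg, seed=21)
        vi = [
            frustum_volume(cohort.slice_stacks[sid]["quadriceps"])
            / cohort.subject(sid).height ** 2
            for sid in cohort.arm_ids("ESLD")
        ]
        se = cfg.esld.quad_volume_index.sd / np.sqrt(len(vi))
        assert abs(np.mean(vi) - cfg.esld.quad_volume_index.mean) < 3 * se


@pytest.fixture(scope="module")
def big_truth():
    cfg = default_config(n_esld=500, n_hc=500, accel=_FAST_ACCEL)
    return cfg, generate_cohort(cfg, seed=3).truth


class TestDistributionalRecovery:
    def test_imat_mean_recovery(self, big_truth):
        _, truth = big_truth
        esld = truth[truth["arm"] == "ESLD"]
        assert abs(esld["imat_pct"].mean() - 10.5) < 0.5

    @pytest.mark.parametrize("var", ["mid_acsa", "peak_torque", "quad_volume_index", "l3_smi"])
    def test_normal_variable_recovery(self, big_truth, var):
        cfg, truth = big_truth
        for arm, params in (("ESLD", cfg.esld), ("HC", cfg.hc)):
            x = truth.loc[truth["arm"] == arm, var]
            v = getattr(params, var)
            se = v.sd / np.sqrt(len(x))
            assert abs(x.mean() - v.mean) < 3 * se
            assert abs(x.std() - v.sd) < 3 * v.sd / np.sqrt(2 * (len(x) - 1))

    def test_lognormal_variable_recovery(self, big_truth):
        cfg, truth = big_truth
        x = truth.loc[truth["arm"] == "ESLD", "grip"]
        v = cfg.esld.grip
        assert abs(np.median(x) - v.median) < 3 * 1.2533 * v.sd / np.sqrt(len(x))


class TestLatentFactor:
    @staticmethod
    def _corr(loading_scale, n=200, seed=7):
        cfg = default_config(
            n_esld=n, n_hc=2, latent_size_loading=loading_scale, accel=_FAST_ACCEL
        )
        truth = generate_cohort(cfg, seed=seed).truth
        esld = truth[truth["arm"] == "ESLD"]
        return sps.pearsonr(esld["mid_acsa"], esld["peak_torque"])

    def test_zero_loading_gives_independence(self):
        r, p = self._corr(0.0)
        assert p > 0.01

    def test_correlation_increases_with_loading(self):
        rs = [self._corr(s)[0] for s in (0.0, 0.6, 1.0)]
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] == pytest.approx(0.68, abs=0.15)

    def test_dry_weight_correction_near_five_percent(self):
        cfg = default_config(n_esld=400, n_hc=2, accel=_FAST_ACCEL)
        cohort = generate_cohort(cfg, seed=17)
        from myoquant.anthropometry import compute_dry_weight

        fracs = [
            1.0 - compute_dry_weight(1.0, s.ascites_grade, s.oedema_grade)
            for s in cohort.subjects
            if s.arm == "ESLD"
        ]
        assert np.mean(fracs) == pytest.approx(0.054, abs=0.015)
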