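import numpy as np
import pandas as pd
import pytest

from chronopanel.features import batch_center
from chronopanel.mctq import score_frame
from chronopanel.simulate import (
    GeneratorConfig,
    generate_biomarkers,
    generate_cohort,
    generate_dataset,
    generate_followup_wave,
    generate_mctq_raw,
)


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_config):
        a = generate_dataset(small_config, seed=99, followup=True)
        b = generate_dataset(small_config, seed=99, followup=True)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.followup, b.followup)

    def test_different_seed_differs(self, small_config):
        a = generate_dataset(small_config, seed=1)
        b = generate_dataset(small_config, seed=2)
        assert not a.cohort["CHL"].equals(b.cohort["CHL"])


class TestCohortStructure:
    def test_ages_clipped_to_adult_range(self, default_dataset):
        age = default_dataset.cohort["age"]
        assert age.min() >= 18.0
        assert age.max() <= 97.0

    def test_households_shared_and_sized(self, default_dataset):
        sizes = default_dataset.cohort.groupby("household_id").size()
        assert sizes.between(1, 6).all()
        assert len(default_dataset.cohort) == 1600

    def test_invalid_config_rejected(self):
        cfg = GeneratorConfig()
        cfg.sjl.p_zero_worker = 1.5
        with pytest.raises(ValueError, match="probabilities"):
            cfg.__post_init__()
        with pytest.raises(ValueError, match="aip_mode"):
            GeneratorConfig(aip_mode="banana")


class TestRoundTrip:
    def test_scoring_recovers_planted_targets_exactly(self, default_dataset):
        """The clock times are constructed so scoring inverts them."""
        ds = default_dataset
        scored = score_frame(ds.cohort, strict_alarm=False)
        merged = scored.merge(ds.truth, on="participant_id")
        for derived, truth in [
            ("SJL", "true_SJL"),
            ("MSF_sc", "true_MSF_sc"),
            ("SD_w", "true_SD_w"),
            ("SD_f", "true_SD_f"),
            ("SD_week", "true_SD_week"),
            ("MSW", "true_MSW"),
            ("MSF", "true_MSF"),
        ]:
            err = (merged[derived] - merged[truth]).abs().max()
            assert err < 1e-9, f"{derived} round-trip error {err}"

    def test_planted_sjl_age_gradient_recovered(self):
        cfg = GeneratorConfig()
        cfg.demographics.n_participants = 5000
        cohort = generate_cohort(cfg, 3)
        _, truth = generate_mctq_raw(cohort, cfg, 3)
        from scipy.stats import spearmanr

        rho, p = spearmanr(cohort["age"], truth["true_SJL"])
        assert rho < -0.2
        assert p < 1e-10

    def test_nonworkers_have_lower_sjl_than_full_time_workers(self, default_dataset):
        ds = default_dataset
        merged = ds.cohort.merge(ds.truth, on="participant_id")
        nonworker = merged.loc[~merged["employed"], "true_SJL"].mean()
        full_time = merged.loc[merged["employed"] & (merged["work_hours"] >= 40), "true_SJL"].mean()
        assert nonworker < full_time


class TestBiomarkers:
    def test_lab_offsets_removed_by_median_centering(self, default_dataset):
        ds = default_dataset
        df = ds.cohort
        centered = batch_center(df["CHL"].to_numpy(), df["lab_id"].to_numpy())
        lab_medians = pd.Series(centered).groupby(df["lab_id"].to_numpy()).median()
        assert np.ptp(lab_medians.to_numpy()) < 1e-9

    def test_zeroed_models_give_constant_plus_offsets(self):
        cfg = GeneratorConfig()
        cfg.demographics.n_participants = 300
        for m in cfg.biomarkers.values():
            m.effects = {}
            m.hh_sd = 0.0
            m.resid_sd = 0.0
        for k in cfg.labs.offset_sd:
            cfg.labs.offset_sd[k] = 0.0
        cohort = generate_cohort(cfg, 5)
        _, truth = generate_mctq_raw(cohort, cfg, 5)
        panel, _ = generate_biomarkers(cohort, truth, cfg, 5)
        assert panel["CHL"].nunique() == 1
        assert panel["CHL"].iloc[0] == pytest.approx(cfg.biomarkers["CHL"].intercept)

    def test_derived_aip_mode_consistent_with_formula(self):
        cfg = GeneratorConfig(aip_mode="derived")
        cfg.demographics.n_participants = 300
        cohort = generate_cohort(cfg, 6)
        _, truth = generate_mctq_raw(cohort, cfg, 6)
        panel, _ = generate_biomarkers(cohort, truth, cfg, 6)
        assert np.allclose(panel["AIP"], np.log10(panel["TAG"] / panel["HDL"]))


class TestFollowup:
    def test_zero_shift_zero_noise_identity(self, small_config):
        cfg = small_config
        cfg.followup.delta_msf_sc_min = 0.0
        cfg.followup.delta_sjl_min = 0.0
        cfg.followup.delta_sd_week_min = 0.0
        cfg.followup.paired_noise_sd_min = 0.0
        cfg.followup.control_sleep_delta_min = 0.0
        ds = generate_dataset(cfg, seed=21, followup=True)
        fu = ds.followup
        assert np.allclose(fu["MSF_sc_w1"], fu["MSF_sc_w2"])
        assert np.allclose(fu["SJL_w1"], fu["SJL_w2"])

    def test_control_chronotype_change_centered_at_zero(self, default_dataset):
        fu = default_dataset.followup
        ctrl = fu[~fu["home_office"]]
        d = (ctrl["MSF_sc_w2"] - ctrl["MSF_sc_w1"]) * 60.0
        assert abs(d.mean()) < 2.0  # minutes

    def test_home_office_shifts_near_planted(self, default_dataset):
        fu = default_dataset.followup
        cfg = default_dataset.config.followup
        home = fu[fu["home_office"]]
        assert len(home) == cfg.home_office_n
        d_msf = ((home["MSF_sc_w2"] - home["MSF_sc_w1"]) * 60).mean()
        d_sjl = ((home["SJL_w2"] - home["SJL_w1"]) * 60).mean()
        d_sleep = ((home["SD_week_w2"] - home["SD_week_w1"]) * 60).mean()
        assert d_msf == pytest.approx(cfg.delta_msf_sc_min, abs=2.0)
        assert d_sjl == pytest.approx(cfg.delta_sjl_min, abs=2.0)
        assert d_sleep == pytest.approx(cfg.delta_sd_week_min, abs=2.0)

    def test_oversized_home_office_request_rejected(self, small_config):
        small_config.followup.home_office_n = 10_000
        with pytest.raises(ValueError, match="eligible"):
            generate_dataset(small_config, seed=2, followup=True)


def test_config_yaml_round_trip():
    cfg = GeneratorConfig()
    cfg.sjl.coef_chronotype = 0.25
    restored = GeneratorConfig.from_yaml(cfg.to_yaml())
    assert restored.sjl.coef_chronotype == 0.25
    assert restored.chronotype.male_coef == tuple(cfg.chronotype.male_coef)
    assert restored.biomarkers["CHL"].effects["SJL"] == cfg.biomarkers["CHL"].effects["SJL"]
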