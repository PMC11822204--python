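"""Synthetic microdata generator: determinism, marginals, analytic truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hearineq.cohort import AgeBandScheme, derive_analysis_table, filter_cohort
from hearineq.inequality import ridit_scores
from hearineq.pipeline import RIIEstimator
from hearineq.standardize import StandardPopulation
from hearineq.synthetic import (
    SyntheticConfig,
    default_hl_model,
    generate_population,
    implied_true_asp,
    implied_true_rii,
)


def one_cell_config(n=2000, seed=0, b_edu=-0.9, shares=(0.3, 0.4, 0.3), **kw):
    hl = dataclasses.replace(default_hl_model(), b_edu=b_edu, b_region={"Western": 0.0})
    return SyntheticConfig(
        n_per_region_gender=n,
        region_education_shares={("Western", "man"): shares},
        hl_model=hl,
        missing_rates=kw.pop("missing_rates", (0.0, 0.0, 0.0)),
        seed=seed,
        **kw,
    )


class TestConfigValidation:
    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            one_cell_config(shares=(0.3, 0.3, 0.3))

    def test_negative_share_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            one_cell_config(shares=(-0.1, 0.6, 0.5))

    def test_degenerate_missing_rates_refused(self):
        with pytest.raises(ValueError, match="missing rate"):
            one_cell_config(missing_rates=(0.25, 0.0, 0.0))


class TestGeneratePopulation:
    def test_seeded_determinism(self):
        cfg = one_cell_config(seed=11, missing_rates=(0.02, 0.004, 0.003))
        pd.testing.assert_frame_equal(generate_population(cfg), generate_population(cfg))

    def test_different_seed_differs(self):
        a = generate_population(one_cell_config(seed=1))
        b = generate_population(one_cell_config(seed=2))
        assert not a.equals(b)

    def test_education_shares_recovered_within_3_mc_se(self):
        shares = (0.2, 0.5, 0.3)
        n = 20000
        df = generate_population(one_cell_config(n=n, shares=shares))
        counts = df["education"].value_counts()
        for level, pi in zip(("low", "medium", "high"), shares):
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(counts[level] / n - pi) < 3 * se

    def test_srhq_split_encodes_hearing_loss_dichotomy(self):
        df = generate_population(one_cell_config(n=5000))
        assert set(df["srhq"].unique()) <= {1.0, 2.0, 3.0, 4.0, 5.0}
        # aid users appear only among the less-than-good hearing class
        assert not df.loc[df["srhq"] <= 3, "ha_use"].astype(bool).any()

    def test_no_missingness_means_full_retention(self):
        df = generate_population(one_cell_config(n=3000))
        kept, log = filter_cohort(df)
        assert log.n_retained == len(df) == len(kept)

    def test_weights_positive_mean_near_one(self):
        df = generate_population(one_cell_config(n=20000))
        assert (df["weight"] > 0).all()
        assert df["weight"].mean() == pytest.approx(1.0, abs=0.02)

    def test_waves_exclude_3_and_7(self):
        df = generate_population(one_cell_config(n=2000))
        assert set(df["wave"].unique()) <= {1, 2, 4, 5, 6, 8}

    def test_default_config_covers_all_region_gender_cells(self):
        df = generate_population(SyntheticConfig(n_per_region_gender=50, seed=0))
        assert len(df) == 50 * 8
        assert set(df["region"].unique()) == {"Northern", "Western", "Southern", "Eastern"}


class TestImpliedTruth:
    def test_no_gradient_gives_exactly_one(self, esp):
        cfg = one_cell_config(b_edu=0.0)
        assert implied_true_rii(cfg, esp, "Western", "man") == pytest.approx(1.0)

    def test_negative_education_coefficient_gives_rii_above_one(self, esp):
        cfg = one_cell_config(b_edu=-0.9)
        assert implied_true_rii(cfg, esp, "Western", "man") > 1.0

    def test_age_free_model_matches_hand_computed_logistic(self, esp):
        """With b_age = 0 the ASP per education level is a plain logistic
        value; push those through an independent polyfit line and ratio."""
        hl = dataclasses.replace(
            default_hl_model(), b_age=0.0, b_edu=-1.0, b_region={"Western": 0.0}
        )
        shares = (0.2, 0.5, 0.3)
        cfg = SyntheticConfig(
            n_per_region_gender=10,
            region_education_shares={("Western", "man"): shares},
            hl_model=hl,
            missing_rates=(0, 0, 0),
            seed=0,
        )
        x = ridit_scores(np.array(shares))
        expected_asp = expit(hl.intercept - 1.0 * x)
        assert np.allclose(
            implied_true_asp(cfg, esp, "Western", "man"), expected_asp
        )
        coef = np.polyfit(x, expected_asp, 1)
        expected_rii = np.polyval(coef, 0.0) / np.polyval(coef, 1.0)
        assert implied_true_rii(cfg, esp, "Western", "man") == pytest.approx(
            expected_rii
        )

    def test_two_point_age_support(self, esp):
        """Ages restricted to {50, 51}: both land in one band, so the ASP is
        the age-mixture of two logistic values."""
        hl = dataclasses.replace(default_hl_model(), b_region={"Western": 0.0})
        cfg = one_cell_config(age_max=51)
        cfg = dataclasses.replace(cfg, age_max=51, age_decay=1.0, hl_model=hl)
        ages = np.array([50.0, 51.0])
        x = ridit_scores(np.array([0.3, 0.4, 0.3]))
        expected = [
            np.mean(expit(hl.intercept + hl.b_age * (ages - 50) + hl.b_edu * xe))
            for xe in x
        ]
        assert np.allclose(
            implied_true_asp(cfg, esp, "Western", "man"), expected
        )


class TestParameterRecovery:
    def test_estimated_rii_near_truth_at_moderate_n(self, esp, fiveyear_scheme):
        cfg = one_cell_config(n=40000, seed=5, b_edu=-0.7)
        truth = implied_true_rii(cfg, esp, "Western", "man")
        df = generate_population(cfg)
        kept, _ = filter_cohort(df)
        cohort = derive_analysis_table(kept, scheme=fiveyear_scheme)
        est = RIIEstimator(esp)
        est.prepare(cohort)
        val = est.evaluate(np.arange(len(cohort)))
        assert val == pytest.approx(truth, abs=0.12)

    def test_null_gradient_estimate_near_one(self, esp, fiveyear_scheme):
        cfg = one_cell_config(n=40000, seed=8, b_edu=0.0)
        df = generate_population(cfg)
        kept, _ = filter_cohort(df)
        cohort = derive_analysis_table(kept, scheme=fiveyear_scheme)
        est = RIIEstimator(esp)
        est.prepare(cohort)
        assert est.evaluate(np.arange(len(cohort))) == pytest.approx(1.0, abs=0.1)
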