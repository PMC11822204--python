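"""Percentile and BCa bootstrap machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hearineq.uncertainty import (
    BootstrapSpec,
    bca_interval,
    bootstrap_estimate,
    percentile_interval,
)


def bca_oracle(replicates, point, jackknife, level=0.95):
    """Direct transcription of the BCa formulas, independent of the library path."""
    reps = np.sort(np.asarray(replicates, float))
    B = reps.size
    z0 = norm.ppf(np.sum(reps < point) / B)
    jk = np.asarray(jackknife, float)
    dev = jk.mean() - jk
    a = np.sum(dev**3) / (6.0 * np.sum(dev**2) ** 1.5)
    out = []
    for alpha in ((1 - level) / 2, 1 - (1 - level) / 2):
        z = z0 + norm.ppf(alpha)
        adj = norm.cdf(z0 + z / (1 - a * z))
        out.append(np.quantile(reps, adj, method="linear"))
    return tuple(out)


class TestPercentile:
    def test_order_statistic_oracle_on_1_to_1000(self):
        reps = np.arange(1.0, 1001.0)
        lo, hi = percentile_interval(reps, 0.95)
        # linear interpolation of order statistics: position alpha*(n-1)+1
        assert (lo, hi) == pytest.approx((25.975, 975.025))

    def test_endpoints_monotone_in_replicates(self):
        rng = np.random.default_rng(3)
        reps = rng.normal(size=400)
        lo1, hi1 = percentile_interval(reps, 0.95)
        lo2, hi2 = percentile_interval(reps + 0.5, 0.95)
        assert lo2 > lo1 and hi2 > hi1


class TestBca:
    def test_reduces_to_percentile_when_z0_and_a_zero(self):
        reps = np.arange(1.0, 1001.0)
        point = 500.5  # exactly half the replicates below: z0 = 0
        jack = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])  # symmetric: a = 0
        (lo, hi), fallback = bca_interval(reps, point, jack, 0.95)
        assert not fallback
        assert (lo, hi) == percentile_interval(reps, 0.95)

    def test_symmetric_replicates_about_point_have_zero_median_bias(self):
        reps = np.concatenate([-np.arange(1, 51.0), np.arange(1, 51.0)])
        point = 0.0
        frac_below = np.sum(reps < point) / reps.size
        assert norm.ppf(frac_below) == pytest.approx(0.0)

    def test_ten_replicate_hand_case_matches_formula_oracle(self):
        reps = np.array([1.2, 0.8, 1.5, 1.1, 0.9, 1.3, 1.7, 1.0, 1.4, 1.05])
        point = 1.15
        jack = np.array([1.1, 1.2, 1.05, 1.3, 1.15, 1.18, 1.22, 1.08, 1.12, 1.25])
        (lo, hi), fallback = bca_interval(reps, point, jack, 0.95)
        exp_lo, exp_hi = bca_oracle(reps, point, jack, 0.95)
        assert not fallback
        assert (lo, hi) == pytest.approx((exp_lo, exp_hi), rel=1e-12)

    def test_degenerate_replicates_collapse_to_point(self):
        (lo, hi), _ = bca_interval(np.full(50, 2.0), 2.0, np.full(10, 2.0), 0.95)
        assert lo == hi == 2.0

    def test_zero_jackknife_variance_falls_back_flagged(self):
        reps = np.arange(1.0, 101.0)
        (_, _), fallback = bca_interval(reps, 50.0, np.full(10, 5.0), 0.95)
        assert fallback

    def test_positive_replicates_never_give_nonpositive_bounds(self):
        rng = np.random.default_rng(9)
        reps = rng.lognormal(0.3, 0.4, size=500)
        jack = rng.lognormal(0.3, 0.05, size=40)
        (lo, hi), _ = bca_interval(reps, float(np.median(reps)), jack, 0.95)
        assert lo > 0 and hi > 0


class _MeanEstimator:
    """Weighted-mean stub exercising the resample protocol."""

    def prepare(self, cohort):
        self._v = cohort["v"].to_numpy(float)

    def evaluate(self, idx):
        return float(self._v[idx].mean())


def _toy_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "region": np.repeat(["A", "B"], n // 2),
            "gender": "man",
            "v": rng.normal(10, 2, size=n),
        }
    )


class TestBootstrapEstimate:
    def test_seeded_determinism(self):
        df = _toy_cohort()
        spec = BootstrapSpec(B=50, seed=7)
        r1 = bootstrap_estimate(df, _MeanEstimator(), spec)
        r2 = bootstrap_estimate(df, _MeanEstimator(), spec)
        assert np.array_equal(r1.replicates, r2.replicates)
        assert r1.ci == r2.ci

    def test_adding_a_stratum_does_not_perturb_existing_draws(self):
        """Per-stratum RNG streams: estimates on A-only records are identical
        whether or not stratum B exists in the cohort."""
        df = _toy_cohort()
        a_only = df[df["region"] == "A"].reset_index(drop=True)

        class AMean(_MeanEstimator):
            def prepare(self, cohort):
                v = cohort["v"].to_numpy(float)
                mask = (cohort["region"] == "A").to_numpy()
                self._v = np.where(mask, v, np.nan)

            def evaluate(self, idx):
                vals = self._v[idx]
                return float(np.nanmean(vals))

        spec = BootstrapSpec(B=20, seed=3)
        with_b = bootstrap_estimate(df, AMean(), spec)
        without_b = bootstrap_estimate(a_only, AMean(), spec)
        assert np.allclose(with_b.replicates, without_b.replicates)

    def test_zero_variation_gives_zero_width(self):
        df = _toy_cohort()
        df["v"] = 4.0
        res = bootstrap_estimate(df, _MeanEstimator(), BootstrapSpec(B=30, seed=1))
        assert res.ci == (4.0, 4.0)

    def test_stratified_resampling_preserves_stratum_sizes(self):
        df = _toy_cohort(n=40)

        class CountA:
            def prepare(self, cohort):
                self._is_a = (cohort["region"] == "A").to_numpy()

            def evaluate(self, idx):
                return float(self._is_a[idx].sum())

        res = bootstrap_estimate(df, CountA(), BootstrapSpec(B=25, seed=5))
        assert np.all(res.replicates == 20.0)

    def test_undefined_replicates_counted_not_dropped_silently(self):
        class Flaky:
            def __init__(self):
                self._k = 0

            def prepare(self, cohort):
                pass

            def evaluate(self, idx):
                self._k += 1
                return float("nan") if self._k % 4 == 0 else float(self._k)

        df = _toy_cohort(n=10)
        res = bootstrap_estimate(df, Flaky(), BootstrapSpec(B=40, seed=2))
        assert res.n_undefined == 10
        assert res.too_many_undefined  # 25% > 20% threshold

    def test_estimator_undefined_on_original_data_rejected(self):
        class AlwaysNan:
            def prepare(self, cohort):
                pass

            def evaluate(self, idx):
                return float("nan")

        with pytest.raises(ValueError, match="undefined"):
            bootstrap_estimate(_toy_cohort(), AlwaysNan(), BootstrapSpec(B=10, seed=0))

    def test_plain_callable_estimator_supported(self):
        df = _toy_cohort(n=20)
        res = bootstrap_estimate(
            df, lambda d: d["v"].mean(), BootstrapSpec(B=10, seed=4)
        )
        assert np.isfinite(res.point)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BootstrapSpec(B=1)
        with pytest.raises(ValueError):
            BootstrapSpec(ci_level=1.5)
        with pytest.raises(ValueError):
            BootstrapSpec(ci_method="studentized")
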