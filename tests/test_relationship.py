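"""Binned means, LOWESS aggregate curves and AMP-ICP phenotyping."""

import numpy as np
import pandas as pd
import pytest

import icpulse as ip
from icpulse.relationship import AmpIcpFit
from tests.conftest import minute_index_series


class TestBinning:
    def test_single_and_multiple_bins(self):
        rows = ip.bin_patient_means(np.array([21.0, 24, 25, 29, 22.5]),
                                    np.full(5, 3.0), min_count=1)
        assert len(rows) == 1 and rows["mean"].iloc[0] == 3.0
        assert rows["bin_left"].iloc[0] == 20.0
        rows = ip.bin_patient_means(np.array([5.0, 15.0]), np.array([1.0, 2.0]),
                                    min_count=1)
        assert list(rows["bin_left"]) == [0.0, 10.0]
        assert list(rows["mean"]) == [1.0, 2.0]

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 10_000)
        v = rng.standard_normal(10_000)
        rows = ip.bin_patient_means(x, v, min_count=1)
        # brute-force dictionary accumulation, no pandas
        acc: dict = {}
        for xi, vi in zip(x, v):
            key = np.floor(xi / 10) * 10
            acc.setdefault(key, []).append(vi)
        for _, r in rows.iterrows():
            assert r["mean"] == pytest.approx(np.mean(acc[r["bin_left"]]),
                                              rel=1e-12)
        assert int(rows["count"].sum()) == 10_000   # binning is a partition

    def test_low_occupancy_bins_dropped_and_missing_excluded(self):
        x = np.array([5.0] * 6 + [15.0] * 3 + [np.nan] * 4)
        v = np.ones_like(x)
        rows = ip.bin_patient_means(x, v, min_count=5)
        assert list(rows["bin_left"]) == [0.0]
        assert int(rows["count"].sum()) == 6

    def test_empty_input(self):
        assert len(ip.bin_patient_means(np.array([]), np.array([]))) == 0


def _points(x, y, patient="p0"):
    return pd.DataFrame({"patient": patient, "bin_mid": x, "mean": y})


class TestLowess:
    def test_reproduces_a_line_exactly(self):
        x = np.linspace(0, 100, 20)
        curve = ip.lowess_curve(_points(x, 2 * x + 1), n_boot=10)
        assert np.allclose(curve["fit"], 2 * curve["grid"] + 1, atol=1e-6)

    def test_constant_gives_zero_width_band(self):
        x = np.linspace(0, 100, 15)
        curve = ip.lowess_curve(_points(x, np.full(15, 4.0)), n_boot=50)
        assert np.allclose(curve["fit"], 4.0, atol=1e-9)
        assert np.allclose(curve["hi"] - curve["lo"], 0.0, atol=1e-9)

    def test_tracks_noisy_quadratic(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 200)
        sd = 0.1
        y = 0.5 * (x - 5) ** 2 + rng.normal(0, sd, 200)
        curve = ip.lowess_curve(_points(x, y), frac=0.3, n_boot=10)
        interior = (curve["grid"] > 1) & (curve["grid"] < 9)
        truth = 0.5 * (curve["grid"] - 5) ** 2
        assert np.max(np.abs(curve["fit"] - truth)[interior]) <= 3 * sd

    def test_equivariant_to_constant_shift(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 50, 25)
        y = rng.standard_normal(25)
        c0 = ip.lowess_curve(_points(x, y), n_boot=5, seed=1)
        c1 = ip.lowess_curve(_points(x, y + 10), n_boot=5, seed=1)
        assert np.allclose(c1["fit"], c0["fit"] + 10, atol=1e-9)

    def test_too_few_points_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            ip.lowess_curve(_points(np.arange(5), np.arange(5)))


class TestAmpIcpFit:
    def test_linear_relation_gives_constant_positive_derivative(self):
        rng = np.random.default_rng(0)
        icp = rng.uniform(10, 60, 300)
        amp = 0.08 * icp + 1.0
        fit = ip.fit_amp_icp_curve(icp, amp)
        assert fit.ok
        inner = (fit.grid > 15) & (fit.grid < 55)
        assert np.all(fit.derivative[inner] > 0)
        assert np.allclose(fit.derivative[inner], 0.08, rtol=0.05)

    def test_recovers_exponential_elastance_curve(self):
        rng = np.random.default_rng(1)
        icp = rng.uniform(10, 70, 400)
        amp = 1.8 * np.exp(0.025 * (icp - 17.5))
        fit = ip.fit_amp_icp_curve(icp, amp)
        truth = 1.8 * np.exp(0.025 * (fit.grid - 17.5))
        inner = slice(5, -5)
        assert np.allclose(fit.fitted[inner], truth[inner], rtol=0.05)

    def test_collapse_gives_single_sign_change(self):
        rng = np.random.default_rng(2)
        icp = np.sort(rng.uniform(10, 85, 400))
        amp = np.where(icp < 65, 1.8 * np.exp(0.025 * (icp - 17.5)),
                       1.8 * np.exp(0.025 * 47.5) - 0.15 * (icp - 65))
        fit = ip.fit_amp_icp_curve(icp, amp)
        signs = np.sign(fit.derivative[np.abs(fit.derivative) > 0.005])
        changes = int((np.diff(signs) != 0).sum())
        assert changes == 1

    def test_insufficient_span_or_data_indeterminate(self):
        rng = np.random.default_rng(3)
        icp = rng.uniform(10, 20, 300)            # only 10 mm Hg of span
        label, bp, fit = ip.phenotype_patient(icp, np.ones(300))
        assert not fit.ok and label == "indeterminate" and bp is None
        label, _, fit = ip.phenotype_patient(np.arange(30.0), np.arange(30.0))
        assert not fit.ok and label == "indeterminate"


def _fit_from_curve(grid, fitted):
    return AmpIcpFit(grid=np.asarray(grid, float),
                     fitted=np.asarray(fitted, float),
                     derivative=np.gradient(np.asarray(fitted, float), grid),
                     alpha=1.0)


class TestClassification:
    def test_increasing_convex_curve(self):
        g = np.linspace(10, 70, 61)
        label, bp = ip.classify_pattern(_fit_from_curve(g, np.exp(0.03 * g)))
        assert label == "monotonic_increase" and bp is None

    def test_constructed_breakpoint_located(self):
        g = np.linspace(10, 90, 81)
        y = np.where(g < 60, 0.2 * (g - 10), 10.0 - 0.2 * (g - 60))
        label, bp = ip.classify_pattern(_fit_from_curve(g, y))
        assert label == "upper_breakpoint"
        assert bp == pytest.approx(60.0, abs=2.0)

    def test_plateau_is_rightward_deflection(self):
        g = np.linspace(10, 70, 61)
        y = np.where(g < 40, 0.1 * (g - 10), 3.0)
        label, bp = ip.classify_pattern(_fit_from_curve(g, y))
        assert label == "rightward_deflection" and bp is None

    def test_declining_curve(self):
        g = np.linspace(10, 40, 31)
        label, _ = ip.classify_pattern(_fit_from_curve(g, 5.0 - 0.1 * g))
        assert label == "monotonic_decrease"

    def test_phenotype_recovery_on_small_cohort(self, mixed_cohort):
        hits = 0
        for p in mixed_cohort:
            idx = minute_index_series(p)
            label, bp, _ = ip.phenotype_patient(idx["mean_icp"].to_numpy(),
                                                idx["amp"].to_numpy())
            hits += label == p.truth.phenotype
            if label == "upper_breakpoint" and p.truth.breakpoint_icp is not None:
                assert abs(bp - p.truth.breakpoint_icp) <= 5.0
        assert hits >= 7        # >= 87% on 8 patients; full check at n=40
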