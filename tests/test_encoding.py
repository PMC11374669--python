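"""Kernel construction, regressor convolution and the random-slope LMEM."""

import subprocess
import sys
import tempfile
import pathlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from freechoice import encoding as enc


def simulated_cohort(
    rng, n_mice=6, n_per=600, beta=(0.1, 0.25, 0.35, -0.30, 0.10), sigma_b=0.2, sigma_eps=1.0
):
    """Model-level generative cohort with iid standard-normal regressors."""
    beta = np.asarray(beta)
    frames, ys, groups = [], [], []
    for i in range(n_mice):
        X = rng.standard_normal((n_per, 4))
        b = rng.normal(0.0, sigma_b, 4)
        y = beta[0] + X @ (beta[1:] + b) + sigma_eps * rng.standard_normal(n_per)
        frames.append(pd.DataFrame(X, columns=["xy", "wheel", "licking", "iso405"]))
        ys.append(y)
        groups.append(np.repeat(i, n_per))
    return (
        pd.concat(frames, ignore_index=True),
        np.concatenate(ys),
        np.concatenate(groups),
    )


class TestKernel:
    def test_peak_and_half_life(self):
        k = enc.build_kernel()
        assert k.values[0] == 1.0
        assert k.half_time() == pytest.approx(1.796, abs=1e-6)

    def test_tail_value_closed_form(self):
        k = enc.build_kernel()
        assert k.values[-1] == pytest.approx(2.0 ** (-60.0 / 1.796), rel=1e-9)
        assert k.values[-1] == pytest.approx(9.0e-11, rel=0.05)

    def test_strictly_decreasing_and_causal(self):
        k = enc.build_kernel()
        assert np.all(np.diff(k.values) < 0)
        assert k.t[0] == 0.0

    def test_short_duration_warns(self):
        with pytest.warns(UserWarning, match="truncates"):
            enc.build_kernel(half_life=5.0, duration=1.0)

    def test_invalid_parameters(self):
        with pytest.raises(enc.EncodingError):
            enc.build_kernel(half_life=0.0)


class TestConvolveRegressor:
    def test_impulse_yields_kernel_profile(self):
        k = enc.build_kernel(rate=20.0)
        x = np.zeros(3000)
        x[100] = 1.0
        out = enc.convolve_regressor(x, k, zscore=False)
        assert np.allclose(out[100 : 100 + len(k.values)], k.values)
        assert np.allclose(out[:100], 0.0)

    def test_zero_trace_is_degenerate(self):
        k = enc.build_kernel(rate=20.0)
        with pytest.raises(enc.DegenerateRegressorError):
            enc.convolve_regressor(np.zeros(500), k)

    def test_matches_direct_convolution_oracle(self, rng):
        k = enc.build_kernel(duration=2.0, rate=20.0)
        x = rng.standard_normal(300)
        out = enc.convolve_regressor(x, k, zscore=False)
        expected = np.array(
            [sum(x[n - m] * k.values[m] for m in range(len(k.values)) if 0 <= n - m) for n in range(300)]
        )
        assert np.allclose(out, expected)


class TestFitLmem:
    def test_noiseless_identifiability(self, rng):
        """With no random slopes and vanishing noise the fit is exact."""
        regs, y, g = simulated_cohort(rng, sigma_b=0.0, sigma_eps=1e-8)
        fit = enc.fit_lmem(regs, y, g)
        assert np.allclose(
            fit.fe_params.to_numpy(), [0.1, 0.25, 0.35, -0.30, 0.10], atol=1e-4
        )

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent cross-check against the statsmodels REML implementation."""
        import statsmodels.formula.api as smf

        regs, y, g = simulated_cohort(rng, n_mice=5, n_per=400)
        fit = enc.fit_lmem(regs, y, g)
        df = regs.copy()
        df["y"] = y
        df["mouse"] = g
        sm_fit = smf.mixedlm(
            "y ~ xy + wheel + licking + iso405",
            df,
            groups=df["mouse"],
            re_formula="0",
            vc_formula={c: f"0 + {c}" for c in ["xy", "wheel", "licking", "iso405"]},
        ).fit(reml=True)
        assert np.allclose(fit.fe_params.to_numpy(), sm_fit.params.iloc[:5], atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), sm_fit.bse.iloc[:5], atol=1e-3)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_matches_lmerTest_satterthwaite(self, rng):
        """Independent cross-check of estimates and Satterthwaite df against
        R's lme4 + lmerTest."""
        regs, y, g = simulated_cohort(rng, n_mice=5, n_per=300)
        fit = enc.fit_lmem(regs, y, g)
        satt = fit.satterthwaite()
        with tempfile.TemporaryDirectory() as d:
            csv = pathlib.Path(d) / "data.csv"
            df = regs.copy()
            df["y"] = y
            df["mouse"] = g
            df.to_csv(csv, index=False)
            script = (
                "suppressMessages(library(lmerTest));"
                f"d <- read.csv('{csv}');"
                "f <- lmer(y ~ xy + wheel + licking + iso405 +"
                " (0+xy|mouse)+(0+wheel|mouse)+(0+licking|mouse)+(0+iso405|mouse),"
                " data=d, REML=TRUE);"
                "write.csv(coef(summary(f)), stdout())"
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, check=True
            )
            from io import StringIO

            r_table = pd.read_csv(StringIO(out.stdout), index_col=0)
        assert np.allclose(fit.fe_params.to_numpy(), r_table["Estimate"], atol=1e-3)
        assert np.allclose(fit.bse.to_numpy(), r_table["Std. Error"], rtol=5e-3)
        assert np.allclose(satt["df"].to_numpy(), r_table["df"], rtol=0.05)
        assert np.allclose(satt["p"].to_numpy(), r_table["Pr(>|t|)"], rtol=0.05, atol=1e-6)

    def test_model_reduction_consistency(self, rng):
        """Dropping the random slopes from a sigma_b = 0 cohort barely moves beta."""
        regs, y, g = simulated_cohort(rng, sigma_b=0.0)
        full = enc.fit_lmem(regs, y, g)
        reduced = enc.fit_lmem(regs, y, g, random_slopes=[])
        assert np.max(np.abs(full.fe_params.to_numpy() - reduced.fe_params.to_numpy())) < 1e-3

    def test_boundary_variance_warns_but_converges(self, rng):
        regs, y, g = simulated_cohort(rng, sigma_b=0.0, n_mice=4, n_per=300)
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit = enc.fit_lmem(regs, y, g)
        assert fit.converged

    def test_single_mouse_rejected(self, rng):
        regs, y, g = simulated_cohort(rng, n_mice=2)
        mask = g == 0
        with pytest.raises(enc.EncodingError, match="2 mice"):
            enc.fit_lmem(regs[mask], y[mask], g[mask])

    def test_blups_shrink_toward_zero(self, rng):
        regs, y, g = simulated_cohort(rng, n_mice=6, n_per=800, sigma_b=0.3)
        fit = enc.fit_lmem(regs, y, g)
        re = fit.random_effects
        assert re.shape == (6, 4)
        assert np.all(np.abs(re.mean(axis=0)) < 0.2)

    def test_summary_mentions_r2(self, rng):
        regs, y, g = simulated_cohort(rng, n_mice=4, n_per=300)
        text = enc.fit_lmem(regs, y, g).summary()
        assert "R2 marginal" in text and "sigma_eps" in text


class TestSatterthwaite:
    def test_degenerate_limit_matches_ols_df(self, rng):
        """Without random slopes the df collapses to the classical n − p."""
        regs, y, g = simulated_cohort(rng, n_mice=3, n_per=200, sigma_b=0.0)
        fit = enc.fit_lmem(regs, y, g, random_slopes=[])
        df = fit.satterthwaite()["df"]
        n, p = len(y), 5
        assert np.allclose(df, n - p, rtol=0.02)

    def test_huge_df_approaches_normal_p(self, rng):
        regs, y, g = simulated_cohort(rng, n_mice=3, n_per=200, sigma_b=0.0)
        fit = enc.fit_lmem(regs, y, g, random_slopes=[])
        satt = fit.satterthwaite()
        normal_p = 2 * sps.norm.sf(np.abs(satt["t"]))
        assert np.allclose(satt["p"], normal_p, atol=1e-3)

    def test_slope_df_near_group_count(self, rng):
        """With dominant random slopes, slope df is close to n_mice − 1."""
        regs, y, g = simulated_cohort(rng, n_mice=8, n_per=1000, sigma_b=0.25)
        df = enc.fit_lmem(regs, y, g).satterthwaite()["df"]
        for name in ("xy", "wheel", "licking", "iso405"):
            assert 4.0 < df[name] < 12.0

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the Satterthwaite t-test for a null fixed effect."""
        rng = np.random.default_rng(2024)
        n_reps = 500
        rejections = 0
        for _ in range(n_reps):
            regs, y, g = simulated_cohort(
                rng, n_mice=8, n_per=120, beta=(0.1, 0.0, 0.3, -0.3, 0.1), sigma_b=0.15
            )
            fit = enc.fit_lmem(regs, y, g)
            rejections += fit.satterthwaite().loc["xy", "p"] < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestNakagawaR2:
    def test_direct_formula(self):
        r2 = enc.nakagawa_from_variances(1.0, 1.0, 2.0)
        assert r2["marginal"] == pytest.approx(0.25)
        assert r2["conditional"] == pytest.approx(0.5)

    def test_no_random_variance_collapses(self):
        r2 = enc.nakagawa_from_variances(1.0, 0.0, 3.0)
        assert r2["marginal"] == r2["conditional"]

    def test_vanishing_noise_limit(self):
        r2 = enc.nakagawa_from_variances(1.0, 0.0, 1e-12)
        assert r2["marginal"] == pytest.approx(1.0)
        assert r2["conditional"] == pytest.approx(1.0)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(enc.EncodingError):
            enc.nakagawa_from_variances(0.0, 0.0, 0.0)

    def test_fit_r2_ordering_and_range(self, rng):
        regs, y, g = simulated_cohort(rng)
        r2 = enc.fit_lmem(regs, y, g).nakagawa_r2()
        assert 0.0 <= r2["marginal"] <= r2["conditional"] <= 1.0
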