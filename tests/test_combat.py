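"""ComBat: standardization closed forms, EB fixed point, identity/limits."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from alpscombat import (
    DesignInfo,
    SimulationConfig,
    apply_harmonization,
    cohens_d,
    eb_adjust,
    estimate_hyperpriors,
    fit_standardize,
    generate_cohort,
    harmonize,
)
from alpscombat.simulate import FEATURES, ScannerEffect


def _design(batches, cov=None, index=None):
    batch = pd.Series(batches, index=index)
    cov = pd.DataFrame(cov if cov is not None else {}, index=batch.index)
    return DesignInfo(batch=batch, covariates=cov)


class TestStandardization:
    def test_single_batch_no_covariates_standardizes_to_mean0_rms1(self, rng):
        data = pd.DataFrame({"f1": rng.normal(2.0, 0.5, 40), "f2": rng.normal(-1, 2, 40)})
        fit, z = fit_standardize(data, _design(["S"] * 40))
        np.testing.assert_allclose(fit.alpha_hat, data.mean(), rtol=1e-12)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose((z**2).mean(), 1.0, rtol=1e-12)

    def test_two_equal_batches_constant_shift_closed_form(self):
        # batch B = batch A + c: gamma_ls = (-c/2, +c/2), scaled by 1/sigma on z
        base = np.array([0.0, 1.0, 2.0, 3.0])
        c = 2.0
        data = pd.DataFrame({"f": np.concatenate([base, base + c])})
        fit, z = fit_standardize(data, _design(["A"] * 4 + ["B"] * 4))
        # residuals are within-batch deviations: sigma^2 = mean([1.5,.5,.5,1.5]^2)
        sigma = np.sqrt(np.mean((base - base.mean()) ** 2))
        assert fit.sigma_hat["f"] == pytest.approx(sigma, rel=1e-12)
        assert fit.alpha_hat["f"] == pytest.approx(base.mean() + c / 2, rel=1e-12)
        za, zb = z.iloc[:4, 0].mean(), z.iloc[4:, 0].mean()
        assert za == pytest.approx(-c / 2 / sigma, rel=1e-12)
        assert zb == pytest.approx(+c / 2 / sigma, rel=1e-12)

    def test_covariate_coefficients_recovered_on_large_synthetic_cohort(self):
        cfg = SimulationConfig(
            n_per_cell=2000,
            scanners=(ScannerEffect("A", -0.1, 0.9), ScannerEffect("B", 0.1, 1.1)),
            sigma=0.2,
            seed=77,
        )
        tab = generate_cohort(cfg).table
        design = DesignInfo.from_table(tab)
        fit, _ = fit_standardize(tab[list(FEATURES)], design)
        n = len(tab)
        se_age = 0.2 / (tab.age.std() * np.sqrt(n))
        se_group = 0.2 * np.sqrt(4.0 / n)
        for f in FEATURES:
            assert abs(fit.beta_hat.loc["age", f] - (-0.005)) < 3 * se_age
            assert abs(fit.beta_hat.loc["group_AD", f] - (-0.15)) < 3 * se_group

    def test_rank_deficient_design_names_the_collinear_column(self, rng):
        n = 12
        age = rng.uniform(60, 85, n)
        cov = {"age": age, "age_copy": 2 * age}
        with pytest.raises(ValueError, match="age_copy"):
            fit_standardize(
                pd.DataFrame({"f": rng.normal(size=n)}),
                _design(["A"] * 6 + ["B"] * 6, cov),
            )

    def test_batch_with_single_subject_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 2"):
            _design(["A"] * 5 + ["B"])


class TestHyperpriors:
    def test_identical_gammas_across_features_give_zero_tau2(self):
        z = pd.DataFrame(
            {"f1": [1.0, 3.0, -1.0, 1.5], "f2": [2.0, 2.0, 0.5, 0.0]}
        )
        # shift both features so their batch means coincide
        z["f2"] += z["f1"].mean() - z["f2"].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            priors = estimate_hyperpriors(z, _design(["A"] * 4))
        assert priors.tau2["A"] == pytest.approx(0.0, abs=1e-15)

    def test_inverse_gamma_moments_round_trip(self):
        # delta2_hat = {0.5, 1.5}: mean 1.0, spread 0.25 -> lambda=6, theta=5,
        # and IG(6,5) indeed has mean 1.0 and variance 0.25
        z = pd.DataFrame(
            {
                "f1": [-np.sqrt(0.5), np.sqrt(0.5)],
                "f2": [-np.sqrt(1.5), np.sqrt(1.5)],
            }
        )
        priors = estimate_hyperpriors(z, _design(["A"] * 2))
        np.testing.assert_allclose(priors.delta2_hat.loc["A"], [0.5, 1.5], rtol=1e-12)
        lam, th = priors.lambda_["A"], priors.theta["A"]
        assert lam == pytest.approx(6.0, rel=1e-12)
        assert th == pytest.approx(5.0, rel=1e-12)
        ig_mean = th / (lam - 1)
        ig_var = th**2 / ((lam - 1) ** 2 * (lam - 2))
        assert ig_mean == pytest.approx(1.0, rel=1e-12)
        assert ig_var == pytest.approx(0.25, rel=1e-12)


def _eb_oracle(zb, g_hat, d2_hat, tau2, g_bar, lam, th, tol=1e-10, max_iter=10000):
    """Independent fixed-point solver for the conditional posterior means."""
    n = zb.shape[0]
    g, d2 = g_hat.copy(), d2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * g_hat + d2 * g_bar) / (n * tau2 + d2)
        ss = ((zb - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (th + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        if max(abs(g_new - g).max(), abs(d2_new - d2).max()) < tol:
            return g_new, d2_new
        g, d2 = g_new, d2_new
    raise RuntimeError("oracle failed to converge")


class TestEBAdjust:
    @pytest.fixture
    def small_instance(self, rng):
        # 2 batches x 3 features with distinct locations and scales
        n = 30
        rows = []
        for b, (loc, scale) in zip("AB", [(0.4, 0.8), (-0.3, 1.4)]):
            block = loc + scale * rng.normal(size=(n, 3)) * [0.9, 1.0, 1.2]
            rows.append(pd.DataFrame(block, columns=["f1", "f2", "f3"]))
        z = pd.concat(rows, ignore_index=True)
        return z, _design(["A"] * n + ["B"] * n, index=z.index)

    def test_matches_independent_fixed_point_solver(self, small_instance):
        z, design = small_instance
        priors = estimate_hyperpriors(z, design)
        g_star, d_star, n_iter, converged = eb_adjust(z, design, priors, tol=1e-12)
        assert converged and (n_iter > 0).all()
        for b in "AB":
            zb = z.loc[design.batch == b].to_numpy()
            g_ref, d2_ref = _eb_oracle(
                zb,
                priors.gamma_hat.loc[b].to_numpy(),
                priors.delta2_hat.loc[b].to_numpy(),
                priors.tau2[b],
                priors.gamma_bar[b],
                priors.lambda_[b],
                priors.theta[b],
            )
            np.testing.assert_allclose(g_star.loc[b], g_ref, atol=1e-9)
            np.testing.assert_allclose(d_star.loc[b] ** 2, d2_ref, atol=1e-9)

    def test_infinite_tau2_reproduces_unshrunk_gamma(self, small_instance):
        z, design = small_instance
        priors = estimate_hyperpriors(z, design)
        priors.tau2[:] = np.inf
        g_star, _, _, _ = eb_adjust(z, design, priors)
        pd.testing.assert_frame_equal(g_star, priors.gamma_hat)

    def test_zero_tau2_pools_gamma_completely(self, small_instance):
        z, design = small_instance
        priors = estimate_hyperpriors(z, design)
        priors.tau2[:] = 0.0
        g_star, _, _, _ = eb_adjust(z, design, priors)
        for b in "AB":
            np.testing.assert_allclose(
                g_star.loc[b], priors.gamma_bar[b], rtol=1e-12
            )

    def test_shrinkage_moves_gamma_toward_the_batch_prior_mean(self, small_instance):
        z, design = small_instance
        priors = estimate_hyperpriors(z, design)
        g_star, _, _, _ = eb_adjust(z, design, priors)
        for b in "AB":
            raw = priors.gamma_hat.loc[b] - priors.gamma_bar[b]
            shrunk = g_star.loc[b] - priors.gamma_bar[b]
            assert (shrunk.abs() <= raw.abs() + 1e-12).all()


class TestHarmonization:
    def test_single_batch_identity(self, rng):
        data = pd.DataFrame(
            {"f1": rng.normal(1.5, 0.2, 60), "f2": rng.normal(1.4, 0.25, 60)}
        )
        cov = {"age": rng.uniform(60, 85, 60)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-spread fallbacks
            harmonized, _ = harmonize(data, _design(["S"] * 60, cov))
        np.testing.assert_allclose(harmonized, data, rtol=1e-8)

    def test_no_eb_equals_independent_per_batch_restandardization(self, recovery_cohort):
        design = DesignInfo.from_table(recovery_cohort)
        data = recovery_cohort[list(FEATURES)]
        harmonized, fit = harmonize(data, design, eb=False)

        # independent oracle: put each batch's standardized residuals at
        # location 0 / scale 1, then restore the covariate structure
        fit0, z = fit_standardize(data, design)
        expected = np.empty_like(data.to_numpy())
        cov_part = design.covariates.to_numpy() @ fit0.beta_hat.to_numpy()
        for b in design.batches:
            sel = (design.batch == b).to_numpy()
            zb = z.to_numpy()[sel]
            zs = (zb - zb.mean(axis=0)) / zb.std(axis=0, ddof=0)
            expected[sel] = (
                fit0.sigma_hat.to_numpy() * zs
                + fit0.alpha_hat.to_numpy()
                + cov_part[sel]
            )
        np.testing.assert_allclose(harmonized.to_numpy(), expected, atol=1e-10)

    def test_between_scanner_effects_removed_on_synthetic_cohort(self, recovery_cohort):
        design = DesignInfo.from_table(recovery_cohort)
        harmonized, _ = harmonize(recovery_cohort[list(FEATURES)], design)
        out = recovery_cohort.copy()
        out[list(FEATURES)] = harmonized
        for f in FEATURES:
            for s1, s2 in itertools.combinations(["A", "B", "C"], 2):
                d = cohens_d(
                    out.loc[out.scanner == s1, f], out.loc[out.scanner == s2, f]
                )
                assert d < 0.1

    def test_group_effect_preserved_on_synthetic_cohort(self, recovery_cohort):
        import statsmodels.formula.api as smf

        design = DesignInfo.from_table(recovery_cohort)
        harmonized, _ = harmonize(recovery_cohort[list(FEATURES)], design)
        out = recovery_cohort.copy()
        out[list(FEATURES)] = harmonized
        out["AD"] = (out.group == "AD").astype(float)
        n = len(out)
        se_group = 0.2 * np.sqrt(4.0 / n) * 1.5  # conservative: deltas up to 1.5
        for f in FEATURES:
            m = smf.ols(f"{f} ~ age + AD", data=out).fit()
            assert abs(m.params["AD"] - (-0.15)) < 3 * se_group

    def test_near_idempotence(self, recovery_cohort):
        design = DesignInfo.from_table(recovery_cohort)
        h1, _ = harmonize(recovery_cohort[list(FEATURES)], design)
        h2, _ = harmonize(h1, design)
        diff_rms = float(np.sqrt(((h2 - h1) ** 2).to_numpy().mean()))
        spread_rms = float(np.sqrt(((h1 - h1.mean()) ** 2).to_numpy().mean()))
        assert diff_rms < 0.01 * spread_rms

    def test_residual_batch_effect_shrinks_as_n_grows(self):
        # average over replicates of the worst between-scanner |mean gap| on
        # harmonized data decreases over n_per_cell in {25, 100, 400}
        gaps = []
        for n in (25, 100, 400):
            rep_gaps = []
            for seed in range(8):
                cfg = SimulationConfig(
                    n_per_cell=n,
                    scanners=(
                        ScannerEffect("A", -0.3, 0.7),
                        ScannerEffect("B", 0.0, 1.0),
                        ScannerEffect("C", 0.3, 1.5),
                    ),
                    sigma=0.2,
                    seed=1000 + seed,
                )
                tab = generate_cohort(cfg).table
                design = DesignInfo.from_table(tab)
                harmonized, _ = harmonize(tab[list(FEATURES)], design)
                out = tab.copy()
                out[list(FEATURES)] = harmonized
                worst = max(
                    abs(
                        out.loc[out.scanner == s1, f].mean()
                        - out.loc[out.scanner == s2, f].mean()
                    )
                    for f in FEATURES
                    for s1, s2 in itertools.combinations(["A", "B", "C"], 2)
                )
                rep_gaps.append(worst)
            gaps.append(np.mean(rep_gaps))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_apply_rejects_mismatched_features_and_unknown_batches(self, recovery_cohort):
        design = DesignInfo.from_table(recovery_cohort)
        data = recovery_cohort[list(FEATURES)]
        _, fit = harmonize(data, design)
        with pytest.raises(ValueError, match="feature columns"):
            apply_harmonization(data.rename(columns={"alps_left": "x"}), design, fit)
        other = recovery_cohort.copy()
        other["scanner"] = other["scanner"].replace({"A": "Z"})
        with pytest.raises(ValueError, match="not in the fit"):
            apply_harmonization(data, DesignInfo.from_table(other), fit)

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"f1": [1.0, np.nan, 2.0, 1.5]})
        with pytest.raises(ValueError, match="missing"):
            harmonize(data, _design(["A", "A", "B", "B"]))
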