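import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from respirotraits import stats
from respirotraits.stats import (
    backward_reduce,
    effect_size_pct,
    fit_family,
    fit_lmm,
    marginal_means,
    r2_nakagawa,
    sgr_group_test,
)

# module-level alias so pytest does not collect the package function
lrt_term = stats.test_term


def make_lmm_data(
    n_batch=4,
    fish_per_batch=8,
    obs_per_fish=4,
    batch_sd=0.0,
    fish_sd=0.3,
    resid_sd=0.2,
    shelter_effect=0.0,
    trial_effect=0.0,
    rng=None,
):
    """Balanced nested dataset with a within-fish shelter/trial design."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for b in range(n_batch):
        b_eff = rng.normal(0, batch_sd)
        for f in range(fish_per_batch):
            f_eff = rng.normal(0, fish_sd)
            fid = f"B{b}F{f}"
            for k in range(obs_per_fish):
                shelter = k % 2
                trial = "final" if k >= obs_per_fish // 2 else "initial"
                y = (
                    5.0
                    + b_eff
                    + f_eff
                    + shelter * shelter_effect
                    + (trial == "final") * trial_effect
                    + rng.normal(0, resid_sd)
                )
                rows.append((b + 1, fid, trial, shelter, y))
    df = pd.DataFrame(rows, columns=["batch", "fish_id", "trial", "shelter", "y"])
    df["trial"] = pd.Categorical(df["trial"], categories=["initial", "final"])
    df["shelter"] = df["shelter"].map({0: "absent", 1: "present"}).astype("category")
    return df


class TestFitLmm:
    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(3)
        df = make_lmm_data(batch_sd=0.0, fish_sd=0.0, resid_sd=0.3,
                           shelter_effect=0.2, trial_effect=0.1, rng=rng)
        fit = fit_lmm(df, "y", ("trial", "shelter"), random="nested")
        ols = smf.ols("y ~ trial + shelter", df).fit()
        assert np.allclose(
            fit.result.fe_params.to_numpy(), ols.params.to_numpy(), atol=1e-6
        )

    def test_large_fish_variance_r2c_exceeds_r2m(self):
        df = make_lmm_data(fish_sd=1.0, resid_sd=0.2, shelter_effect=0.3,
                           rng=np.random.default_rng(4))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        r2m, r2c = r2_nakagawa(fit)
        assert r2c > r2m >= 0

    def test_balanced_contrast_equals_mean_difference(self):
        df = make_lmm_data(fish_sd=0.2, resid_sd=0.2, shelter_effect=0.4,
                           rng=np.random.default_rng(5))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        diff = (
            df[df["shelter"] == "present"]["y"].mean()
            - df[df["shelter"] == "absent"]["y"].mean()
        )
        assert fit.result.fe_params["shelter[T.present]"] == pytest.approx(diff, abs=1e-6)

    def test_singular_nested_falls_back_to_fish(self):
        df = make_lmm_data(batch_sd=0.0, fish_sd=0.5, resid_sd=0.2,
                           rng=np.random.default_rng(6))
        # force zero between-batch variability so the batch component collapses
        df["y"] -= df.groupby("batch")["y"].transform("mean")
        fit = fit_lmm(df, "y", ("shelter",), random="nested")
        assert fit.requested_random == "nested"
        assert fit.singular
        assert fit.random == "fish"


class TestTermTests:
    def test_marginality_enforced(self):
        df = make_lmm_data(rng=np.random.default_rng(7))
        fit = fit_lmm(df, "y", ("trial", "shelter", "trial:shelter"), random="fish")
        with pytest.raises(ValueError, match="interaction"):
            lrt_term(fit, "shelter")
        chi2, dof, p = lrt_term(fit, "trial:shelter")
        assert dof == 1 and 0 <= p <= 1

    def test_unknown_term_rejected(self):
        df = make_lmm_data(rng=np.random.default_rng(8))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        with pytest.raises(ValueError, match="not in model"):
            lrt_term(fit, "mass")

    def test_type_i_error_calibrated(self):
        """Null rejection rate of the LRT within the binomial 95% band."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            df = make_lmm_data(
                n_batch=4, fish_per_batch=12, obs_per_fish=6,
                batch_sd=0.1, fish_sd=0.3, resid_sd=0.2,
                shelter_effect=0.0, rng=rng,
            )
            fit = fit_lmm(df, "y", ("trial", "shelter"), random="fish")
            _, _, p = lrt_term(fit, "shelter")
            rejections += p < 0.05
        # 95% binomial interval around 0.05 for n=200: [4, 16]
        assert 4 <= rejections <= 16

    def test_power_on_strong_shelter_effect(self):
        """log-scale effect ln(0.92), 80 fish: detected in >= 80% of 50 reps."""
        rng = np.random.default_rng(321)
        hits = 0
        for _ in range(50):
            df = make_lmm_data(
                n_batch=5, fish_per_batch=16, obs_per_fish=4,
                batch_sd=0.05, fish_sd=0.25, resid_sd=0.05,
                shelter_effect=np.log(0.92), rng=rng,
            )
            fit = fit_lmm(df, "y", ("trial", "shelter"), random="nested")
            _, _, p = lrt_term(fit, "shelter")
            hits += p < 0.05
        assert hits >= 40

    def test_wald_close_to_lrt_on_well_behaved_data(self):
        # moderate effect: the two chi-squares agree only to first order
        df = make_lmm_data(fish_sd=0.3, resid_sd=0.2, shelter_effect=0.08,
                           rng=np.random.default_rng(11))
        fit = fit_lmm(df, "y", ("trial", "shelter"), random="fish")
        chi2_l, _, _ = lrt_term(fit, "shelter", flavor="lrt")
        chi2_w, _, _ = lrt_term(fit, "shelter", flavor="wald")
        assert chi2_w == pytest.approx(chi2_l, rel=0.25)


class TestBackwardReduce:
    def test_all_significant_unchanged(self):
        df = make_lmm_data(shelter_effect=1.0, trial_effect=1.0, fish_sd=0.1,
                           resid_sd=0.1, rng=np.random.default_rng(12))
        fit = fit_lmm(df, "y", ("trial", "shelter"), random="fish")
        reduced, trace = backward_reduce(fit, protected_terms=())
        assert set(reduced.terms) == {"trial", "shelter"}
        assert trace.empty

    def test_protected_terms_survive(self):
        df = make_lmm_data(shelter_effect=0.0, trial_effect=0.0,
                           rng=np.random.default_rng(13))
        fit = fit_lmm(df, "y", ("trial", "shelter"), random="fish")
        reduced, _ = backward_reduce(fit, protected_terms=("trial", "shelter"))
        assert set(reduced.terms) == {"trial", "shelter"}

    def test_noise_covariate_mostly_eliminated(self):
        rng = np.random.default_rng(14)
        eliminated = 0
        for _ in range(100):
            df = make_lmm_data(n_batch=2, fish_per_batch=8, shelter_effect=0.5,
                               fish_sd=0.2, resid_sd=0.2, rng=rng)
            df["junk"] = rng.normal(0, 1, len(df))
            fit = fit_lmm(df, "y", ("shelter", "junk"), random="fish")
            reduced, _ = backward_reduce(fit, protected_terms=("shelter",))
            eliminated += "junk" not in reduced.terms
        assert eliminated >= 90

    def test_marginality_respected_with_interaction(self):
        df = make_lmm_data(shelter_effect=0.0, trial_effect=0.0,
                           rng=np.random.default_rng(15))
        fit = fit_lmm(
            df, "y", ("trial", "shelter", "trial:shelter"), random="fish"
        )
        reduced, trace = backward_reduce(fit, protected_terms=("trial", "shelter"))
        # the interaction must leave before main effects could (and they are
        # protected anyway)
        if not trace.empty:
            assert trace.iloc[0]["dropped"] == "trial:shelter"
        assert set(reduced.terms) >= {"trial", "shelter"}


class TestR2:
    def test_intercept_only_r2m_zero(self):
        df = make_lmm_data(fish_sd=0.3, rng=np.random.default_rng(16))
        fit = fit_lmm(df, "y", (), random="fish")
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c > 0

    def test_known_variance_partition(self):
        # fixed 0.2, fish 0.3, residual 0.5 of total variance
        rng = np.random.default_rng(17)
        n_fish, obs = 500, 4
        x = np.tile([-1.0, 1.0], n_fish * obs // 2)
        fish = np.repeat([f"F{i}" for i in range(n_fish)], obs)
        f_eff = np.repeat(rng.normal(0, np.sqrt(0.3), n_fish), obs)
        y = x * np.sqrt(0.2) + f_eff + rng.normal(0, np.sqrt(0.5), n_fish * obs)
        df = pd.DataFrame({"y": y, "x": x, "fish_id": fish})
        fit = fit_lmm(df, "y", ("x",), random="fish")
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.2, abs=0.04)
        assert r2c == pytest.approx(0.5, abs=0.05)

    def test_zero_random_variance_r2c_equals_r2m(self):
        df = make_lmm_data(batch_sd=0.0, fish_sd=0.0, resid_sd=0.3,
                           shelter_effect=0.5, rng=np.random.default_rng(27))
        fit = fit_lmm(df, "y", ("shelter",), random="nested")
        r2m, r2c = r2_nakagawa(fit)
        # REML variance estimates at a true zero sit slightly above the
        # boundary, so the identity holds only to sampling precision
        assert r2c == pytest.approx(r2m, abs=0.05)
        assert r2c >= r2m

    def test_rescaling_invariance(self):
        df = make_lmm_data(fish_sd=0.3, shelter_effect=0.4,
                           rng=np.random.default_rng(18))
        fit1 = fit_lmm(df, "y", ("shelter",), random="fish")
        df2 = df.assign(y=df["y"] * 37.0)
        fit2 = fit_lmm(df2, "y", ("shelter",), random="fish")
        assert r2_nakagawa(fit1) == pytest.approx(r2_nakagawa(fit2), abs=1e-5)


class TestEffectSizes:
    def test_identical_levels_zero(self):
        df = make_lmm_data(shelter_effect=0.0, resid_sd=0.0, fish_sd=0.0,
                           rng=np.random.default_rng(19))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        pct, _ = effect_size_pct(fit, "shelter", levels=("present", "absent"))
        assert pct == pytest.approx(0.0, abs=1e-6)

    def test_log_difference_maps_to_percent(self):
        df = make_lmm_data(shelter_effect=np.log(1.10), resid_sd=0.0, fish_sd=0.0,
                           rng=np.random.default_rng(20))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        pct, (a, b) = effect_size_pct(fit, "shelter", levels=("present", "absent"))
        assert pct == pytest.approx(10.0, abs=1e-4)
        assert (a, b) == ("present", "absent")

    def test_antisymmetry(self):
        df = make_lmm_data(shelter_effect=0.23, fish_sd=0.2,
                           rng=np.random.default_rng(21))
        fit = fit_lmm(df, "y", ("trial", "shelter"), random="fish")
        ab, _ = effect_size_pct(fit, "shelter", levels=("present", "absent"))
        ba, _ = effect_size_pct(fit, "shelter", levels=("absent", "present"))
        assert (1 + ab / 100.0) * (1 + ba / 100.0) == pytest.approx(1.0, rel=1e-10)

    def test_conditioned_contrast(self):
        rng = np.random.default_rng(22)
        df = make_lmm_data(shelter_effect=0.2, trial_effect=0.1, fish_sd=0.2,
                           rng=rng)
        fit = fit_lmm(
            df, "y", ("trial", "shelter", "trial:shelter"), random="fish"
        )
        pct_all, _ = effect_size_pct(fit, "shelter", levels=("present", "absent"))
        pct_init, _ = effect_size_pct(
            fit, "shelter", levels=("present", "absent"), at={"trial": "initial"}
        )
        assert pct_all != pct_init  # interaction makes them differ

    def test_missing_level_rejected(self):
        df = make_lmm_data(rng=np.random.default_rng(23))
        fit = fit_lmm(df, "y", ("shelter",), random="fish")
        with pytest.raises(ValueError, match="not found"):
            effect_size_pct(fit, "shelter", levels=("present", "covered"))


class TestSgrGroupTest:
    def test_equal_means_no_signal(self):
        rng = np.random.default_rng(24)
        df = pd.DataFrame(
            {
                "sgr": rng.normal(0.5, 0.2, 80),
                "group_size": np.repeat([4, 8], 40),
            }
        )
        out = sgr_group_test(df)
        assert out["r2_adj"] <= 0.05
        assert out["p"] > 0.05

    def test_separated_groups(self):
        rng = np.random.default_rng(25)
        df = pd.DataFrame(
            {
                "sgr": np.concatenate(
                    [rng.normal(0.5, 0.1, 40), rng.normal(1.0, 0.1, 40)]
                ),
                "group_size": np.repeat([4, 8], 40),
            }
        )
        out = sgr_group_test(df)
        assert out["p"] < 1e-3

    def test_single_group_rejected(self):
        df = pd.DataFrame({"sgr": [0.5, 0.6], "group_size": [4, 4]})
        with pytest.raises(ValueError):
            sgr_group_test(df)

    def test_printed_moments_simulation_band(self):
        """Median adjusted R^2 from the published group moments (n=32/48)."""
        rng = np.random.default_rng(26)
        r2s = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "sgr": np.concatenate(
                        [rng.normal(0.64, 0.27, 32), rng.normal(0.50, 0.19, 48)]
                    ),
                    "group_size": np.repeat([4, 8], [32, 48]),
                }
            )
            r2s.append(sgr_group_test(df)["r2_adj"])
        assert 0.03 <= np.median(r2s) <= 0.15


class TestFamilies:
    def test_family_tables_structure(self, small_experiment, small_estimates):
        from respirotraits import traits as tm

        traits, long = tm.compute_traits(
            small_estimates,
            small_experiment["schedule"],
            small_experiment["metadata"],
            raw=small_experiment["raw"],
        )
        res = fit_family("night_mo2min", traits=traits, mo2min_long=long)
        table = res["model_table"]
        assert {"response", "effect", "chi2", "p", "r2_m_pct", "r2_c_pct"} <= set(
            table.columns
        )
        r2m, r2c = res["r2"]
        assert 0 <= r2m <= r2c <= 1
        assert {"trial", "shelter"} <= set(res["model"].terms)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            fit_family("epoc")
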