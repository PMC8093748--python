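"""Agreement regression: OLS fits, residual diagnostics, bird-space models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cscolor import agreement


def normal_equation_fit(x, y):
    """Independent closed-form OLS oracle (hand-coded normal equations)."""
    n = len(x)
    sx, sy = np.sum(x), np.sum(y)
    sxx, sxy = np.sum(x * x), np.sum(x * y)
    beta = np.linalg.solve(np.array([[n, sx], [sx, sxx]]), np.array([sy, sxy]))
    resid = y - (beta[0] + beta[1] * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return beta[1], beta[0], 1.0 - ss_res / ss_tot


class TestFitChannel:
    def test_identity_relationship(self):
        x = np.arange(10, dtype=float)
        res = agreement.fit_channel(x, x, channel="R")
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_photo_values_give_zero_r2_with_warning(self):
        x = np.arange(5, dtype=float)
        with pytest.warns(UserWarning, match="zero variance"):
            res = agreement.fit_channel(x, np.full(5, 7.0))
        assert res.r_squared == 0.0

    def test_constant_spectrometry_values_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            agreement.fit_channel(np.full(5, 1.0), np.arange(5, dtype=float))

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            agreement.fit_channel([1.0, 2.0], [1.0, 2.0])

    def test_matches_normal_equation_oracle_on_fixed_table(self, rng):
        x = rng.uniform(0, 255, 10)
        y = 0.8 * x + 12 + rng.normal(0, 5, 10)
        res = agreement.fit_channel(x, y)
        slope, intercept, r2 = normal_equation_fit(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_residuals_mean_zero(self, rng):
        x = rng.uniform(0, 255, 40)
        y = x + rng.normal(0, 10, 40)
        res = agreement.fit_channel(x, y)
        assert abs(res.residuals.mean()) < 1e-9 * res.residuals.std()

    def test_r2_invariant_to_affine_rescaling(self, rng):
        x = rng.uniform(0, 255, 30)
        y = x + rng.normal(0, 20, 30)
        base = agreement.fit_channel(x, y).r_squared
        assert agreement.fit_channel(2 * x - 30, y).r_squared == pytest.approx(base, abs=1e-12)
        assert agreement.fit_channel(x, 0.1 * y + 5).r_squared == pytest.approx(base, abs=1e-12)


class TestIndividualLevelFit:
    def _tables(self, rng, n_species=30, photos_per=1, noise=0.0):
        museum = pd.DataFrame(
            {"unit_id": [f"u{i}" for i in range(n_species)],
             "R": rng.uniform(0, 255, n_species)}
        )
        rows = []
        for _, m in museum.iterrows():
            for j in range(photos_per):
                rows.append(
                    {"photo_id": f"{m.unit_id}_p{j}", "unit_id": m.unit_id,
                     "R": m.R + rng.normal(0, noise) if noise else m.R}
                )
        return pd.DataFrame(rows), museum

    def test_one_photo_per_species_equals_species_fit(self, rng):
        photos, museum = self._tables(rng, photos_per=1, noise=5.0)
        res_i = agreement.individual_level_fit(photos, museum, "R")
        units = photos.rename(columns={"photo_id": "drop"}).groupby("unit_id", as_index=False)["R"].mean()
        merged = units.merge(museum, on="unit_id", suffixes=("_p", "_m"))
        res_s = agreement.fit_channel(merged["R_m"], merged["R_p"])
        assert res_i.r_squared == pytest.approx(res_s.r_squared, abs=1e-12)

    def test_unmatched_species_error(self, rng):
        photos, museum = self._tables(rng)
        photos.loc[0, "unit_id"] = "missing_sp"
        with pytest.raises(ValueError, match="missing_sp"):
            agreement.individual_level_fit(photos, museum, "R")

    def test_species_level_r2_exceeds_individual_level(self, rng):
        """Averaging photos removes noise: species R2 > individual R2 (the
        additive-noise prediction, checked over replicates)."""
        wins = 0
        reps = 60
        for _ in range(reps):
            truth = rng.uniform(0, 255, 40)
            noise = rng.normal(0, 40, (40, 8))
            y = truth[:, None] + noise
            museum = pd.DataFrame({"unit_id": range(40), "R": truth})
            photos = pd.DataFrame(
                {"photo_id": np.arange(320), "unit_id": np.repeat(np.arange(40), 8),
                 "R": y.ravel()}
            )
            r2_i = agreement.individual_level_fit(photos, museum, "R").r_squared
            r2_s = agreement.fit_channel(truth, y.mean(axis=1)).r_squared
            wins += r2_s > r2_i
        assert wins >= 0.9 * reps

    def test_variance_components_prediction(self, rng):
        """tau2=1, sigma2=1, n=16: species R2 ~ 16/17, individual R2 ~ 1/2."""
        n_species, n_photos, reps = 150, 16, 40
        r2_s, r2_i = [], []
        for _ in range(reps):
            truth = rng.normal(0, 1.0, n_species)
            y = truth[:, None] + rng.normal(0, 1.0, (n_species, n_photos))
            r2_s.append(agreement.fit_channel(truth, y.mean(axis=1)).r_squared)
            x_rep = np.repeat(truth, n_photos)
            r2_i.append(agreement.fit_channel(x_rep, y.ravel()).r_squared)
        for vals, theory in ((r2_s, 16 / 17), (r2_i, 0.5)):
            mean, se = np.mean(vals), np.std(vals) / np.sqrt(reps)
            assert abs(mean - theory) < 4 * se + 0.01


class TestResidualsVsCovariate:
    def test_exact_linear_residual_gives_r2_one(self):
        cov = pd.Series(np.arange(20, dtype=float))
        res = agreement.residuals_vs_covariate(cov.rename("r"), cov)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_covariate_error(self):
        resid = pd.Series(np.arange(5, dtype=float))
        with pytest.raises(ValueError, match="constant covariate"):
            agreement.residuals_vs_covariate(resid, pd.Series(np.ones(5)))

    def test_null_p_values_uniform(self, rng):
        """Independent covariate: slope p-values are U(0,1) (KS at alpha=0.01)."""
        ps = []
        for _ in range(500):
            resid = pd.Series(rng.normal(0, 1, 30))
            cov = pd.Series(rng.normal(0, 1, 30))
            ps.append(agreement.residuals_vs_covariate(resid, cov).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_age_effect_detected_on_single_channel(self, rng):
        age = rng.uniform(0, 80, 120)
        resid = pd.DataFrame(
            {"R": rng.normal(0, 5, 120), "G": rng.normal(0, 5, 120),
             "B": -0.15 * age + rng.normal(0, 5, 120)}
        )
        ps = {
            ch: agreement.residuals_vs_covariate(resid[ch], pd.Series(age)).p_value
            for ch in ("R", "G", "B")
        }
        assert ps["B"] < 0.05
        assert ps["R"] > 0.05 and ps["G"] > 0.05


class TestGroupContrast:
    def _resid(self, a_vals, b_vals):
        df = pd.DataFrame(
            {ch: np.concatenate([a_vals, b_vals]) for ch in ("R", "G", "B")}
        )
        group = pd.Series([True] * len(a_vals) + [False] * len(b_vals))
        return df, group

    def test_identical_groups_adjusted_p_is_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df, group = self._resid(v, v)
        out = agreement.group_contrast(df, group)
        assert (out["p_adjusted"] == 1.0).all()
        assert (out["effect"] == 0.0).all()

    def test_planted_two_sd_shift_is_significant(self, rng):
        a = rng.normal(2.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        df, group = self._resid(a, b)
        out = agreement.group_contrast(df, group)
        assert (out["p_adjusted"] < 0.001).all()

    def test_familywise_error_controlled_under_null(self, rng):
        """Bonferroni across 3 channels keeps FWER at or below ~5%."""
        reps, hits = 600, 0
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=["R", "G", "B"])
            group = pd.Series([True] * 15 + [False] * 15)
            out = agreement.group_contrast(df, group)
            hits += (out["p_adjusted"] < 0.05).any()
        rate = hits / reps
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_small_group_error(self):
        df, group = self._resid(np.array([1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="at least 2"):
            agreement.group_contrast(df, group)

    def test_holm_adjustment_never_exceeds_bonferroni(self, rng):
        a, b = rng.normal(0.5, 1, 20), rng.normal(0, 1, 20)
        df, group = self._resid(a, b)
        bonf = agreement.group_contrast(df, group, method="bonferroni")
        holm = agreement.group_contrast(df, group, method="holm")
        assert (holm["p_adjusted"] <= bonf["p_adjusted"] + 1e-12).all()


class TestFamilySummaries:
    def test_planted_red_family_bias_recovered(self, rng):
        units = [f"u{i}" for i in range(60)]
        fams = ["red" if i < 20 else "gray" for i in range(60)]
        resid = pd.DataFrame(
            {"unit_id": units,
             "R": rng.normal(0, 1, 60) + np.where(np.array(fams) == "red", 20.0, 0.0),
             "G": rng.normal(0, 1, 60), "B": rng.normal(0, 1, 60)}
        )
        sds = pd.DataFrame({"unit_id": units, "sd_R": 1.0, "sd_G": 1.0, "sd_B": 1.0})
        families = pd.DataFrame({"unit_id": units, "color_family": fams})
        out = agreement.family_summaries(resid, sds, families)
        red_r = out[(out.color_family == "red") & (out.channel == "R")].iloc[0]
        gray_r = out[(out.color_family == "gray") & (out.channel == "R")].iloc[0]
        assert red_r["bias_median"] == pytest.approx(20.0, abs=1.0)
        assert abs(gray_r["bias_median"]) < 1.0

    def test_multi_family_species_counted_in_each(self):
        resid = pd.DataFrame(
            {"unit_id": ["u1", "u2", "u3"], "R": [1.0, 2.0, 3.0],
             "G": 0.0, "B": 0.0}
        )
        sds = pd.DataFrame({"unit_id": ["u1", "u2", "u3"]})
        families = pd.DataFrame(
            {"unit_id": ["u1", "u1", "u2", "u3"],
             "color_family": ["red", "black", "red", "black"]}
        )
        out = agreement.family_summaries(resid, sds, families)
        counts = out[out.channel == "R"].set_index("color_family")["n_units"]
        assert counts["red"] == 2 and counts["black"] == 2

    def test_empty_family_warns_and_is_omitted(self):
        resid = pd.DataFrame({"unit_id": ["u1"] * 3, "R": [1.0, 2.0, 3.0], "G": 0.0, "B": 0.0})
        sds = pd.DataFrame({"unit_id": ["u1"]})
        families = pd.DataFrame(
            {"unit_id": ["u1", "zzz"], "color_family": ["red", "ghost"]}
        )
        with pytest.warns(UserWarning, match="ghost"):
            out = agreement.family_summaries(resid, sds, families)
        assert "ghost" not in set(out["color_family"])


class TestPredictBirdSpace:
    def _avian_from_lab(self, lab, coefs):
        out = pd.DataFrame({"unit_id": lab["unit_id"]})
        for col, (ca, cb, c0) in coefs.items():
            out[col] = ca * lab["a"] + cb * lab["b"] + c0
        return out

    def test_exact_linear_functions_give_r2_one(self, rng):
        lab = pd.DataFrame(
            {"unit_id": [f"u{i}" for i in range(20)],
             "L": rng.uniform(0, 100, 20), "a": rng.normal(0, 20, 20),
             "b": rng.normal(0, 20, 20)}
        )
        coefs = {
            "x_U": (0.01, -0.02, 0.1), "y_U": (0.03, 0.01, 0.0), "z_U": (-0.01, 0.02, 0.0),
        }
        avian = self._avian_from_lab(lab, coefs)
        avian["DL"] = 0.05 * lab["L"] + 1.0
        out = agreement.predict_bird_space(lab, avian)
        assert np.allclose(out["r2"], 1.0, atol=1e-10)

    def test_r2_matches_multiple_regression_oracle(self, rng):
        lab = pd.DataFrame(
            {"unit_id": [f"u{i}" for i in range(10)],
             "L": rng.uniform(0, 100, 10), "a": rng.normal(0, 20, 10),
             "b": rng.normal(0, 20, 10)}
        )
        avian = pd.DataFrame(
            {"unit_id": lab["unit_id"], "x_U": rng.normal(0, 1, 10),
             "y_U": rng.normal(0, 1, 10), "z_U": rng.normal(0, 1, 10)}
        )
        out = agreement.predict_bird_space(lab, avian)
        X = np.column_stack([np.ones(10), lab["a"], lab["b"]])
        for resp in ("x_U", "y_U", "z_U"):
            beta, *_ = np.linalg.lstsq(X, avian[resp].to_numpy(), rcond=None)
            resid = avian[resp].to_numpy() - X @ beta
            r2 = 1 - resid @ resid / np.sum((avian[resp] - avian[resp].mean()) ** 2)
            got = out[(out.response == resp[0]) & (out.eye_type == "U")]["r2"].iloc[0]
            assert got == pytest.approx(r2, abs=1e-10)

    def test_rank_deficient_design_raises(self):
        lab = pd.DataFrame(
            {"unit_id": ["u1", "u2", "u3", "u4", "u5"], "L": np.arange(5.0),
             "a": np.ones(5), "b": np.ones(5)}
        )
        avian = pd.DataFrame({"unit_id": lab["unit_id"], "x_U": np.arange(5.0)})
        with pytest.raises(ValueError, match="rank-deficient"):
            agreement.predict_bird_space(lab, avian)
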