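"""Mixed-model inference, regrouping schemes and the cross-space regression."""

import numpy as np
import pandas as pd
import pytest

from floravision import (
    aicc,
    fit_saturation_model,
    fit_variation_model,
    regress_across_spaces,
    regroup_mixed_systems,
    simulate_variation_table,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(202)


@pytest.fixture(scope="module")
def mixed_table(rng):
    """38-species table with the full set of mixed pollination systems."""
    return simulate_variation_table(
        rng,
        n_species={"Bee": 24, "Bird": 7, "Bee/Fly": 4, "Bee/Hawkmoth": 1, "Bee/Bird": 2},
    )


class TestRegrouping:
    @pytest.mark.parametrize(
        "scheme, n_species",
        [("main", 31), ("BeeBird->Bee", 33), ("BeeBird->Bird", 33), ("mixed->Bee", 36)],
    )
    def test_species_totals_per_scheme(self, mixed_table, scheme, n_species):
        out = regroup_mixed_systems(mixed_table, scheme)
        assert out["species_code"].nunique() == n_species
        assert set(out["pollination_system"]) == {"Bee", "Bird"}

    def test_beebird_species_relabeled(self, mixed_table):
        bb = set(
            mixed_table.loc[mixed_table.pollination_system == "Bee/Bird", "species_code"]
        )
        out = regroup_mixed_systems(mixed_table, "BeeBird->Bee")
        assert set(out.loc[out.species_code.isin(bb), "pollination_system"]) == {"Bee"}

    def test_identity_on_pure_table(self, rng):
        pure = simulate_variation_table(rng, n_species={"Bee": 3, "Bird": 3})
        out = regroup_mixed_systems(pure, "mixed->Bee")
        pd.testing.assert_frame_equal(out, pure.reset_index(drop=True))

    def test_unknown_scheme_errors(self, mixed_table):
        with pytest.raises(ValueError, match="unknown scheme"):
            regroup_mixed_systems(mixed_table, "everything->Bird")


class TestVariationModel:
    def test_population_relabeling_invariance(self, rng):
        t = simulate_variation_table(rng, n_species={"Bee": 5, "Bird": 5})
        fit1 = fit_variation_model(t)
        relabeled = t.copy()
        relabeled["population_id"] = relabeled["population_id"].map(
            lambda p: f"renamed_{hash(p) % 10_000}"
        )
        fit2 = fit_variation_model(relabeled)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)
        pd.testing.assert_frame_equal(fit1.lrt, fit2.lrt, atol=1e-6)

    def test_injected_interaction_recovered_within_two_se(self, rng):
        shift = 0.3
        t = simulate_variation_table(
            rng, cell_means={("bird", "Bird"): shift}
        )
        fit = fit_variation_model(t)
        assert fit.lrt_for("visual_system:pollination_system")["p"] < 0.05
        cm = fit.cell_means.set_index(["visual_system", "pollination_system"])
        est = (
            cm.loc[("bird", "Bird"), "estimate"]
            - cm.loc[("bird", "Bee"), "estimate"]
            - cm.loc[("bee", "Bird"), "estimate"]
            + cm.loc[("bee", "Bee"), "estimate"]
        )
        se = np.sqrt((cm["se"] ** 2).sum())
        assert abs(est - shift) < 2 * se

    def test_unreplicated_cell_errors_with_cell_name(self, rng):
        t = simulate_variation_table(rng, n_species={"Bee": 4, "Bird": 4})
        broken = t[~((t.visual_system == "bird") & (t.pollination_system == "Bird"))]
        with pytest.raises(ValueError, match="bird"):
            fit_variation_model(broken)

    def test_null_table_interaction_usually_not_significant(self):
        rejections = 0
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = simulate_variation_table(rng)
            fit = fit_variation_model(t)
            rejections += fit.lrt_for("visual_system:pollination_system")["p"] < 0.05
        assert rejections <= 4  # far from systematic rejection under the null

    def test_lrt_chi2_non_negative(self, rng):
        t = simulate_variation_table(rng)
        fit = fit_variation_model(t)
        assert (fit.lrt["chi2"] >= 0).all()
        assert (fit.lrt["df"] == 1).all()


class TestSaturationModel:
    def _saturation_table(self, rng, bee_shift=0.0):
        t = simulate_variation_table(rng, n_species={"Bee": 8, "Bird": 8})
        t = t.rename(columns={"fraction_discriminable": "saturation"})
        t["saturation"] = t["saturation"].abs() + 0.2
        mask = (t.visual_system == "bee") & (t.pollination_system == "Bee")
        t.loc[mask, "saturation"] += bee_shift
        return t

    def test_bee_pollinated_more_saturated_in_bee_space_detected(self, rng):
        t = self._saturation_table(rng, bee_shift=0.4)
        fit = fit_saturation_model(t)
        contrast = fit.contrast_for("bee")
        assert contrast["estimate"] > 0  # Bee plants minus Bird plants
        assert contrast["p"] < 0.05

    def test_near_equal_saturations_nothing_significant(self, rng):
        t = self._saturation_table(rng)
        t["saturation"] = 0.5 + rng.normal(0, 1e-3, len(t))
        fit = fit_saturation_model(t, standardize=False)
        assert (fit.lrt["p"] > 0.05).all()

    def test_shared_rescaling_leaves_tests_unchanged(self, rng):
        t = self._saturation_table(rng, bee_shift=0.2)
        fit1 = fit_saturation_model(t, standardize=False)
        t2 = t.copy()
        t2["saturation"] *= 2.0
        fit2 = fit_saturation_model(t2, standardize=False)
        i1 = fit1.lrt_for("visual_system:pollination_system")
        i2 = fit2.lrt_for("visual_system:pollination_system")
        assert i2["chi2"] == pytest.approx(i1["chi2"], abs=1e-4)


class TestCrossSpaceRegression:
    def _paired_table(self, rng, n=40, slope=2.0, noise=0.0):
        rows = []
        for i in range(n):
            bee_frac = rng.uniform(0, 0.4)
            bird_frac = slope * bee_frac + rng.normal(0, noise)
            system = "Bee" if i % 2 else "Bird"
            for vs, frac in (("bee", bee_frac), ("bird", bird_frac)):
                rows.append(
                    {
                        "population_id": f"p{i}",
                        "species_code": f"sp{i // 2}",
                        "pollination_system": system,
                        "visual_system": vs,
                        "fraction_discriminable": frac,
                    }
                )
        return pd.DataFrame(rows)

    def test_collinear_data_recovers_slope_and_r2(self, rng):
        out = regress_across_spaces(self._paired_table(rng, slope=2.0, noise=1e-9))
        base = out[out.model == "slope_only"].iloc[0]
        assert base.slope == pytest.approx(2.0, abs=1e-4)
        assert base.adj_r2 == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_gives_low_r2(self):
        rng = np.random.default_rng(31)
        t = self._paired_table(rng, n=31, slope=0.0, noise=0.2)
        out = regress_across_spaces(t)
        base = out[out.model == "slope_only"].iloc[0]
        assert abs(base.adj_r2) < 0.15
        assert base.slope_p > 0.05

    def test_aicc_matches_hand_formula(self, rng):
        import statsmodels.formula.api as smf

        t = self._paired_table(rng, slope=1.5, noise=0.05)
        out = regress_across_spaces(t)
        wide = t.pivot_table(
            index=["population_id", "species_code", "pollination_system"],
            columns="visual_system",
            values="fraction_discriminable",
        ).reset_index()
        n = len(wide)
        res = smf.ols("bird ~ bee", data=wide).fit()
        k = 3  # intercept, slope, sigma
        expect = -2 * res.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        got = out[out.model == "slope_only"].iloc[0].aicc
        assert got == pytest.approx(expect, abs=1e-9)
        assert out["best"].sum() == 1

    def test_unpaired_population_errors(self, rng):
        t = self._paired_table(rng)
        t = t.drop(t[(t.population_id == "p0") & (t.visual_system == "bird")].index)
        with pytest.raises(ValueError, match="unpaired|p0"):
            regress_across_spaces(t)


def test_aicc_helper_guards_small_n():
    assert np.isinf(aicc(0.0, k=5, n=6))
    assert aicc(-10.0, k=2, n=100) == pytest.approx(20 + 4 + 12 / 97)
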