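"""Decomposition models: geometric means, filters, ANOVA and contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import virdecomp as vd


class TestGeometricMean:
    def test_all_zero_loads_give_unit_exploitation(self):
        assert vd.geometric_mean_load([0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_equal_loads_give_load_plus_one(self):
        assert vd.geometric_mean_load([41.0] * 5) == pytest.approx(42.0)

    def test_hand_computed_mixed_loads(self):
        # {9, 99}: exp((ln10 + ln100)/2) = sqrt(1000)
        assert vd.geometric_mean_load([9.0, 99.0]) == pytest.approx(
            np.sqrt(1000.0))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            vd.geometric_mean_load([])


def _summary_row(species, dose, rep, h_max=0.1, t_at_max=5.0, n_day1=4,
                 treatment="bacterial", exploitation=50.0):
    return dict(species=species, treatment=treatment, dose_cfu=dose,
                replicate=rep, h_max=h_max, t_at_max=t_at_max,
                n_survival=36, excluded_reason="", exploitation=exploitation,
                n_load=8, n_load_day1=n_day1)


class TestFilters:
    def _meta(self, rows, early_arm=None):
        recs = []
        for b in (1.0, 2.0, 3.0, 5.0):
            for r in rows:
                t = 0.5 if (early_arm
                            and (r["species"], r["dose_cfu"], r["replicate"])
                            == early_arm) else 5.0
                recs.append(dict(species=r["species"], treatment=r["treatment"],
                                 dose_cfu=r["dose_cfu"],
                                 replicate=r["replicate"], bandwidth_b=b,
                                 t_at_max=t))
        return pd.DataFrame(recs)

    def test_complete_fixture_has_empty_exclusion_report(self):
        rows = [_summary_row("E_cloacae", d, 1) for d in (92, 920)]
        summ = pd.DataFrame(rows)
        retained, report = vd.apply_decomposition_filters(
            summ, hazard_meta=self._meta(rows))
        assert report == []
        assert len(retained) == 2

    def test_early_peak_at_all_bandwidths_is_excluded_with_reason(self):
        rows = [_summary_row("E_cloacae", 92, 1),
                _summary_row("E_cloacae", 92000, 1)]
        summ = pd.DataFrame(rows)
        retained, report = vd.apply_decomposition_filters(
            summ, hazard_meta=self._meta(rows,
                                         early_arm=("E_cloacae", 92000, 1)))
        assert len(retained) == 1
        ((species, dose, rep, reason),) = report
        assert (species, dose, rep) == ("E_cloacae", 92000, 1)
        assert reason == "max-hazard-before-day-1"

    def test_missing_day1_loads_excludes_exactly_that_arm(self):
        rows = [_summary_row("L_lactis", 92, 1),
                _summary_row("L_lactis", 92, 2, n_day1=0)]
        summ = pd.DataFrame(rows)
        retained, report = vd.apply_decomposition_filters(summ)
        assert len(retained) == 1
        assert report[0][3] == "no-day1-load-data"
        assert report[0][2] == 2

    def test_species_exclusion_and_missing_hmax(self):
        rows = [_summary_row("Ps_entomophila", 92, 1),
                _summary_row("E_cloacae", 92, 1, h_max=np.nan)]
        summ = pd.DataFrame(rows)
        retained, report = vd.apply_decomposition_filters(summ)
        assert len(retained) == 0
        reasons = {r[0]: r[3] for r in report}
        assert reasons["Ps_entomophila"] == "hazard-at-sampling-time"
        assert reasons["E_cloacae"] == "no-mortality-in-window"

    def test_rules_are_order_independent(self):
        # shuffling rows changes nothing: rules look only at row content
        rows = [_summary_row("E_cloacae", 92, 1, h_max=np.nan),
                _summary_row("Ps_entomophila", 920, 2),
                _summary_row("L_lactis", 92, 1, n_day1=0),
                _summary_row("Pr_burhodogranariea", 9200, 3)]
        summ = pd.DataFrame(rows)
        ret1, rep1 = vd.apply_decomposition_filters(summ)
        shuffled = summ.sample(frac=1, random_state=0).reset_index(drop=True)
        ret2, rep2 = vd.apply_decomposition_filters(shuffled)
        assert sorted(rep1) == sorted(rep2)
        key = ["species", "dose_cfu", "replicate"]
        assert (ret1.sort_values(key)[key].to_numpy()
                == ret2.sort_values(key)[key].to_numpy()).all()


class TestLinearAnova:
    def test_equal_group_means_give_zero_f_and_zero_d(self):
        d = pd.DataFrame({
            "species": np.repeat(["a", "b", "c"], 3),
            "y": [1.0, 2.0, 3.0] * 3,
        })
        fit = vd.fit_linear_anova(d, "y", "species")
        assert fit.anova_table.loc["C(species)", "F"] == pytest.approx(0.0,
                                                                       abs=1e-12)
        assert fit.contrasts["cohens_d"].abs().max() == pytest.approx(
            0.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        d = pd.DataFrame({
            "species": np.repeat(["a", "b"], 10),
            "y": np.concatenate([rng.normal(0, 1, 10),
                                 rng.normal(0.8, 1, 10)]),
        })
        fit = vd.fit_linear_anova(d, "y", "species")
        t = sps.ttest_ind(d[d.species == "a"].y, d[d.species == "b"].y)
        assert fit.anova_table.loc["C(species)", "F"] == pytest.approx(
            t.statistic ** 2, rel=1e-10)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        d = pd.DataFrame({
            "species": rng.choice(["a", "b", "c"], 30),
            "x": rng.normal(0, 1, 30),
            "y": rng.normal(0, 1, 30),
        })
        fit = vd.fit_linear_anova(d, "y", "species", covariate="x",
                                  interaction=True)
        # independent oracle: hand-built dummy design, normal equations
        X = np.column_stack([
            np.ones(30),
            (d.species == "b").astype(float),
            (d.species == "c").astype(float),
            d.x,
            d.x * (d.species == "b"),
            d.x * (d.species == "c"),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ d.y.to_numpy())
        order = ["Intercept", "C(species)[T.b]", "C(species)[T.c]", "x",
                 "x:C(species)[T.b]", "x:C(species)[T.c]"]
        np.testing.assert_allclose(fit.params[order].to_numpy(), beta,
                                   rtol=1e-8)

    def test_single_level_factor_is_an_error(self):
        d = pd.DataFrame({"species": ["a"] * 5, "y": np.arange(5.0)})
        with pytest.raises(ValueError):
            vd.fit_linear_anova(d, "y", "species")

    def test_aliased_design_is_reported(self):
        d = pd.DataFrame({
            "species": np.repeat(["a", "b"], 4),
            "x": np.repeat([0.0, 1.0], 4),  # x aliases the factor
            "y": np.arange(8.0),
        })
        with pytest.raises(ValueError, match="aliased"):
            vd.fit_linear_anova(d, "y", "species", covariate="x")

    def test_tukey_p_never_below_raw_p_and_d_flips_with_order(self):
        rng = np.random.default_rng(13)
        d = pd.DataFrame({
            "species": np.repeat(["a", "b", "c"], 8),
            "y": rng.normal(np.repeat([0.0, 0.5, 1.0], 8), 1.0),
        })
        fit = vd.fit_linear_anova(d, "y", "species")
        assert (fit.contrasts["p_tukey"] >= fit.contrasts["p_raw"] - 1e-12).all()
        flipped = d.assign(species=d.species.map({"a": "c", "b": "b", "c": "a"}))
        fit2 = vd.fit_linear_anova(flipped, "y", "species")
        np.testing.assert_allclose(
            sorted(fit.contrasts["cohens_d"].abs()),
            sorted(fit2.contrasts["cohens_d"].abs()), rtol=1e-10)


class TestPPPModel:
    def _noiseless(self, slopes, intercepts):
        rows = []
        species = list(slopes)
        for sp in species:
            for i, x in enumerate(np.linspace(1.0, 5.0, 6)):
                rows.append(dict(
                    species=sp, treatment="bacterial", dose_cfu=92 * (i + 1),
                    replicate=1 + i % 3, h_max=float(
                        np.exp(intercepts[sp] + slopes[sp] * x)),
                    t_at_max=5.0, exploitation=float(np.exp(x)),
                    n_load=8, n_load_day1=4))
        return pd.DataFrame(rows)

    def test_noiseless_fixture_recovers_constructed_slopes_exactly(self):
        slopes = {"a": 0.1, "b": 0.5, "c": 0.3}
        inter = {"a": -4.0, "b": -5.0, "c": -4.5}
        fit = vd.fit_ppp_model(self._noiseless(slopes, inter))
        for sp, b in slopes.items():
            assert fit.species_slopes[sp] == pytest.approx(b, abs=1e-10)

    def test_shared_exact_law_has_zero_interaction_signal(self):
        slopes = {sp: 0.4 for sp in "abc"}
        inter = {sp: -4.0 for sp in "abc"}
        fit = vd.fit_ppp_model(self._noiseless(slopes, inter))
        key = [i for i in fit.anova_table.index if ":" in i][0]
        assert fit.anova_table.loc[key, "sum_sq"] == pytest.approx(0.0,
                                                                   abs=1e-16)
        assert fit.species_slopes.std() == pytest.approx(0.0, abs=1e-10)

    def test_controls_anchor_the_intercept(self, decomposition):
        # Ringer's arms enter at exploitation 1; their mean log h_max should
        # approximate each species' fitted intercept
        fit = decomposition["ppp"]
        assert fit.species_slopes is not None
        assert fit.n_used > 30


class TestRecoveryFacets:
    def test_slope_ordering_recovered_in_at_least_95_percent(self,
                                                             ppp_recovery):
        assert ppp_recovery["ordering"] >= 0.95

    def test_equal_ppp_pair_rarely_flagged(self, ppp_recovery_flat_low):
        """The two equal-PPP species differ significantly in < 10% of runs."""
        assert ppp_recovery_flat_low["equal_pair_ns"] >= 0.90

    def test_unequal_ppp_pairs_detected(self, ppp_recovery_flat_low):
        """Both contrasts against the flat species detected >= 90% of runs."""
        assert ppp_recovery_flat_low["unequal_detected"] >= 0.90
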