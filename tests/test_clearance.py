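"""Plating arithmetic, clearance indices, rank tests and the GLM reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import virdecomp as vd
from virdecomp.clearance import GlmReport, SeparationError


class TestDetectionLimit:
    def test_study_plating_setup_gives_about_seven_cfu(self):
        raw, rounded = vd.detection_limit(100.0, 3, 5.0)
        assert raw == pytest.approx(100.0 / 15.0)
        assert rounded == 7

    def test_plating_everything_gives_limit_one(self):
        raw, rounded = vd.detection_limit(15.0, 3, 5.0)
        assert (raw, rounded) == (1.0, 1)

    def test_single_large_droplet(self):
        raw, rounded = vd.detection_limit(100.0, 1, 10.0)
        assert (raw, rounded) == (10.0, 10)

    def test_overplating_is_an_error(self):
        with pytest.raises(ValueError):
            vd.detection_limit(10.0, 3, 5.0)


class TestBackcalculation:
    def test_hand_computed_example(self):
        # mean 15 at 1:100, 5 uL of 100 uL: 15 * 100 * 20 = 30,000 CFU
        res = vd.backcalculate_load([[60, 70, 80], [12, 15, 18]],
                                    [1.0, 1e-2], 100.0, 5.0)
        assert res.load_cfu == pytest.approx(30_000.0)
        assert res.chosen_dilution == 1e-2
        assert not res.cleared

    def test_all_zero_plates_mean_cleared(self):
        res = vd.backcalculate_load([[0, 0, 0], [0, 0, 0]],
                                    [1.0, 0.1], 100.0, 5.0)
        assert res.cleared and res.load_cfu == 0.0

    def test_every_dilution_overgrown_signals_max_censoring(self):
        res = vd.backcalculate_load([[900, 950, 800], [500, 600, 400]],
                                    [1.0, 1e-2], 100.0, 5.0)
        assert res.at_max_censored
        assert np.isnan(res.load_cfu)

    def test_dilutions_must_increase(self):
        with pytest.raises(ValueError):
            vd.backcalculate_load([[1, 1, 1], [2, 2, 2]], [1e-2, 1.0],
                                  100.0, 5.0)


class TestProportionsAndIndex:
    @pytest.fixture()
    def small_arm(self):
        surv_rows, load_rows = [], []
        for i in range(36):
            # 6 deaths by day 3, another 6 by day 4
            day = 3.0 if i < 6 else (4.0 if i < 12 else 60.0)
            surv_rows.append((f"s{i}", "E_cloacae", "bacterial", 92, 1, "A",
                              day, 1))
        for day, cleared in [(3, [1, 0, 0, 0]), (4, [1, 1, 0, 0])]:
            for j, c in enumerate(cleared):
                load_rows.append((f"h{day}{j}", "E_cloacae", 92, 1, day,
                                  0.0 if c else 50.0, c, 0, 0))
        surv = pd.DataFrame(surv_rows, columns=vd.io.SURVIVAL_COLUMNS)
        loads = pd.DataFrame(load_rows, columns=vd.io.LOAD_COLUMNS)
        return surv, loads

    def test_proportion_alive_from_direct_count(self, small_arm):
        surv, _ = small_arm
        assert vd.proportion_alive(surv, "E_cloacae", 92, 1, 3) == \
            pytest.approx(30 / 36)
        assert vd.proportion_alive(surv, "E_cloacae", 92, 1, 4) == \
            pytest.approx(24 / 36)

    def test_proportion_cleared_live_counts(self, small_arm):
        _, loads = small_arm
        p, k, n = vd.proportion_cleared_live(loads, "E_cloacae", 92, 1, 3)
        assert (p, k, n) == (0.25, 1, 4)
        p4, _, _ = vd.proportion_cleared_live(loads, "E_cloacae", 92, 1, 4)
        assert p4 == 0.5

    def test_no_sampled_flies_is_flagged_undefined(self, small_arm):
        _, loads = small_arm
        p, k, n = vd.proportion_cleared_live(loads, "E_cloacae", 92, 1, 7)
        assert np.isnan(p) and n == 0

    def test_index_matches_hand_computation(self, small_arm):
        # day 3: 1/4 * 30/36 = 0.2083; day 4: 2/4 * 24/36 = 0.3333
        surv, loads = small_arm
        ci = vd.clearance_index(surv, loads, "E_cloacae", 92, 1, (3, 4))
        assert ci.value == pytest.approx((0.25 * 30 / 36 + 0.5 * 24 / 36) / 2)
        assert ci.days_available == (3, 4)

    def test_index_drops_missing_days_and_flags_empty(self, small_arm):
        surv, loads = small_arm
        ci = vd.clearance_index(surv, loads, "E_cloacae", 92, 1, (3, 7))
        assert ci.days_available == (3,)
        empty = vd.clearance_index(surv, loads, "E_cloacae", 92, 1, (7, 14))
        assert not empty.defined and np.isnan(empty.value)

    def test_index_bounds_on_simulated_experiment(self, sim_tables):
        idx = vd.clearance_indices(sim_tables["survival"],
                                   sim_tables["loads"])
        vals = idx.loc[idx["defined"], "value"]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestOverallSummaries:
    def _loads_with_counts(self, counts_by_species):
        rows = []
        for species, (cleared, total) in counts_by_species.items():
            for i in range(total):
                c = i < cleared
                rows.append((f"{species}{i}", species, 92, 1, 3,
                             0.0 if c else 100.0, int(c), 0, 0))
        return pd.DataFrame(rows, columns=vd.io.LOAD_COLUMNS)

    def test_percentages_match_direct_counts(self):
        out = vd.summarise_overall_clearance(self._loads_with_counts(
            {"E_cloacae": (177, 449), "Pr_burhodogranariea": (45, 381)}))
        got = out.set_index("species")["percent"]
        assert got["E_cloacae"] == 39.4
        assert got["Pr_burhodogranariea"] == 11.8

    def test_zero_cleared(self):
        out = vd.summarise_overall_clearance(
            self._loads_with_counts({"L_lactis": (0, 50)}))
        assert out["percent"].item() == 0.0


class TestMannWhitneyAndBH:
    @staticmethod
    def _brute_force_p(x, y):
        """Independent enumeration oracle over all group assignments."""
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        n1 = len(x)
        mu = n1 * len(y) / 2.0
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        hits = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        return hits / total

    @pytest.mark.parametrize("x, y", [
        ([0.1, 0.5, 0.9], [0.2, 0.3, 0.8]),
        ([0.0, 0.0, 0.4], [0.6, 0.7, 0.9]),
        ([1, 2, 3, 4], [2, 2, 5]),            # ties across groups
        ([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6]),
    ])
    def test_exact_p_equals_enumeration_oracle(self, x, y):
        _, p = vd.mann_whitney_u(np.asarray(x, float), np.asarray(y, float))
        assert p == pytest.approx(self._brute_force_p(
            np.asarray(x, float), np.asarray(y, float)))

    def test_bh_step_up_matches_hand_computation(self):
        adj = vd.benjamini_hochberg([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_bh_is_monotone_and_caps_at_max_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=12)
        adj = vd.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert adj.max() == pytest.approx(p.max())


class TestSpeciesComparison:
    def test_identical_indices_give_h_zero_p_one(self):
        idx = pd.DataFrame({
            "species": np.repeat(["a", "b", "c"], 4),
            "value": [0.25] * 12,
        })
        rep = vd.compare_clearance_species(idx)
        assert rep["kruskal_h"] == 0.0
        assert rep["kruskal_p"] == 1.0
        assert (rep["pairwise"]["p_bh"] == 1.0).all()

    def test_separated_groups_are_detected(self):
        idx = pd.DataFrame({
            "species": np.repeat(["a", "b", "c"], 5),
            "value": np.concatenate([np.linspace(0.5, 0.9, 5),
                                     np.linspace(0.0, 0.08, 5),
                                     np.linspace(0.01, 0.09, 5)]),
        })
        rep = vd.compare_clearance_species(idx)
        assert rep["kruskal_p"] < 0.01
        pair = rep["pairwise"].set_index("pair")
        assert pair.loc["a vs b", "p_bh"] < 0.05

    def test_fewer_than_two_groups_is_an_error(self):
        idx = pd.DataFrame({"species": ["a"] * 4, "value": [0.1] * 4})
        with pytest.raises(ValueError):
            vd.compare_clearance_species(idx)


class TestDoseLoadModel:
    def _loads(self, fn, noise=0.0, seed=0, day=7):
        rng = np.random.default_rng(seed)
        rows = []
        for rep in (1, 2, 3):
            for dose in (92, 920, 1840, 9200, 92000):
                for i in range(4):
                    load = float(np.exp(fn(dose) + noise * rng.normal()))
                    rows.append((f"f{rep}{dose}{i}", "E_cloacae", dose, rep,
                                 day, load, 0, 0, 0))
        return pd.DataFrame(rows, columns=vd.io.LOAD_COLUMNS)

    def test_noiseless_log_linear_slope_is_exact(self):
        loads = self._loads(lambda d: 2.0 + 0.5 * np.log(d))
        rep = vd.fit_dose_spbl(loads, "E_cloacae")
        assert rep.params["x"] == pytest.approx(0.5, abs=1e-12)

    def test_constant_loads_have_zero_slope(self):
        loads = self._loads(lambda d: 3.0)
        rep = vd.fit_dose_spbl(loads, "E_cloacae")
        assert rep.params["x"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        loads = self._loads(lambda d: 1.0 + 0.4 * np.log(d), noise=0.5,
                            seed=3)
        rep = vd.fit_dose_spbl(loads, "E_cloacae")
        d = loads.copy()
        y = np.log(d["load_cfu"].to_numpy())
        X = np.column_stack([np.ones(len(d)),
                             np.log(d["dose_cfu"].to_numpy(float)),
                             (d["replicate"] == 2).astype(float),
                             (d["replicate"] == 3).astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert rep.params["x"] == pytest.approx(beta[1], rel=1e-8)

    def test_below_detection_flies_are_removed_first(self):
        loads = self._loads(lambda d: 2.0 + 0.5 * np.log(d))
        loads.loc[:3, ["load_cfu", "below_detection"]] = [[0.0, 1]] * 4
        rep = vd.fit_dose_spbl(loads, "E_cloacae")
        assert rep.n_used == len(loads) - 4


class TestDeadFlyModel:
    def _dead(self, fn, seed=0, n=30, days=(15, 20, 30)):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            dose = int(rng.choice([92, 920, 9200, 92000]))
            day = int(rng.choice(days))
            p = fn(dose, day)
            rows.append((f"d{i}", "Pr_burhodogranariea", dose, 1 + i % 2,
                         "A" if i % 3 else "B", day,
                         int(rng.random() < p)))
        return pd.DataFrame(rows, columns=vd.io.DEAD_COLUMNS)

    def test_two_by_two_fixture_recovers_observed_log_odds(self):
        # two dose groups, outcome frequencies 1/4 and 3/4: the fitted
        # slope on log(log(dose)) must reproduce the observed log odds ratio
        rows = []
        for dose, k in ((92, 1), (92000, 3)):
            for i in range(4):
                rows.append((f"d{dose}{i}", "E_cloacae", dose, 1, "A", 20,
                             int(i < k)))
        dead = pd.DataFrame(rows, columns=vd.io.DEAD_COLUMNS)
        rep = vd.fit_dead_clearance(dead, "E_cloacae", include_day=False)
        x1, x2 = np.log(np.log(92)), np.log(np.log(92000))
        log_or = np.log((3 / 1) / (1 / 3))
        assert rep.params["lldose"] * (x2 - x1) == pytest.approx(log_or,
                                                                 rel=1e-6)

    def test_single_outcome_class_is_an_error(self):
        dead = self._dead(lambda dose, day: 1.0, seed=1)
        with pytest.raises(ValueError, match="one outcome class"):
            vd.fit_dead_clearance(dead, "Pr_burhodogranariea")

    def test_complete_separation_is_reported(self):
        dead = self._dead(lambda dose, day: 0.5, seed=2)
        dead["infected_at_death"] = (dead["dose_cfu"] > 1000).astype(int)
        with pytest.raises(SeparationError):
            vd.fit_dead_clearance(dead, "Pr_burhodogranariea",
                                  include_day=False)

    def test_deviance_matches_brute_force_likelihood(self):
        dead = self._dead(lambda dose, day: 0.3 + 0.4 * (dose > 1000),
                          seed=3, n=60)
        rep = vd.fit_dead_clearance(dead, "Pr_burhodogranariea")
        res = rep.result
        mu = res.fittedvalues.to_numpy()
        y = dead["infected_at_death"].to_numpy()
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        assert rep.deviance == pytest.approx(-2 * ll, abs=1e-6)


class TestConcordanceModel:
    def _counts(self, slope=4.0, rho=0.0, seed=0, n_per_cell=40):
        rng = np.random.default_rng(seed)
        rows = []
        for sp in ("a", "b", "c", "d"):
            for dose in (92, 920, 1840, 9200, 92000):
                p_live = rng.uniform(0.05, 0.8)
                k_live = rng.binomial(n_per_cell, p_live)
                # condition on the observed live proportion so the dead
                # counts are exactly binomial given the model's predictor
                p_dead = 1 / (1 + np.exp(-(-1.5 + slope * k_live / n_per_cell)))
                if rho > 0:  # beta-binomial overdispersion
                    a = p_dead * (1 - rho) / rho
                    b = (1 - p_dead) * (1 - rho) / rho
                    p_dead = rng.beta(max(a, 1e-6), max(b, 1e-6))
                k_dead = rng.binomial(n_per_cell, p_dead)
                rows.append((sp, dose, k_live, n_per_cell - k_live,
                             k_dead, n_per_cell - k_dead))
        return pd.DataFrame(rows, columns=[
            "species", "dose_cfu", "live_uninfected", "live_infected",
            "dead_uninfected", "dead_infected"])

    def test_concordant_fixture_positive_slope_binomial_dispersion(self):
        rep = vd.fit_live_dead_concordance(self._counts(slope=5.0, seed=8))
        assert rep.params["live_prop"] > 0
        assert rep.pvalues["live_prop"] < 0.01
        assert rep.dispersion < 1.6  # binomial data: X2/df close to 1

    def test_overdispersed_fixture_has_dispersion_above_one(self):
        rep = vd.fit_live_dead_concordance(
            self._counts(slope=0.0, rho=0.2, seed=9))
        assert rep.dispersion > 1.5

    def test_unrelated_proportions_rarely_significant(self):
        hits = 0
        for s in range(100):
            rep = vd.fit_live_dead_concordance(
                self._counts(slope=0.0, seed=100 + s))
            hits += rep.pvalues["live_prop"] < 0.05
        assert hits <= 10  # near-nominal type-I behaviour

    def test_constant_predictor_is_an_error(self):
        counts = self._counts(seed=10)
        counts["live_uninfected"] = 10
        counts["live_infected"] = 30
        with pytest.raises(ValueError, match="degenerate"):
            vd.fit_live_dead_concordance(counts)

    def test_pooled_counts_from_simulated_tables(self, sim_tables):
        counts = vd.live_dead_counts(sim_tables["loads"], sim_tables["dead"])
        assert {"live_uninfected", "dead_infected"} <= set(counts.columns)
        assert (counts[["live_uninfected", "live_infected",
                        "dead_uninfected", "dead_infected"]] >= 0).all().all()


def test_population_clearance_never_exceeds_survival(sim_tables):
    surv, loads = sim_tables["survival"], sim_tables["loads"]
    arms = loads[loads["dose_cfu"] > 0][
        ["species", "dose_cfu", "replicate"]].drop_duplicates()
    for species, dose, rep in arms.sample(10, random_state=1).itertuples(
            index=False):
        for day in (3, 4):
            p_cl, _, n = vd.proportion_cleared_live(loads, species, dose,
                                                    rep, day)
            if n == 0:
                continue
            p_alive = vd.proportion_alive(surv, species, dose, rep, day)
            assert p_cl * p_alive <= p_alive + 1e-12
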