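import numpy as np
import pandas as pd
import pytest

from shelfshift import envelope as env
from shelfshift import geometry as geo
from shelfshift import synthetic as syn


@pytest.fixture(scope="module")
def fitted_tracker(tracking_sim):
    hauls, catches, *_ = tracking_sim
    model = env.DeltaLognormalEnvelope.from_survey(
        "bt-1", hauls, catches, "south", "fall")
    return model, model.fit(), hauls, catches


class TestDeltaWeight:
    @pytest.mark.parametrize("p,mu,s2,expected", [
        (1.0, 0.0, 0.0, 1.0),
        (0.5, 0.0, 0.0, 0.5),
        (0.5, 1.0, 0.5, 0.5 * np.exp(1.25)),
    ])
    def test_closed_form(self, p, mu, s2, expected):
        assert env.delta_weight(p, mu, s2) == pytest.approx(expected)


class TestFit:
    def test_insufficient_positives_rejected(self, tracking_sim):
        hauls, catches, *_ = tracking_sim
        with pytest.raises(ValueError, match="positive hauls"):
            env.DeltaLognormalEnvelope.from_survey(
                "bt-1", hauls, catches, "south", "fall", min_positive=10 ** 6)

    def test_recovers_thermal_optimum(self, fitted_tracker, tracking_sim):
        # fitted presence curve vs BT is unimodal with mode within
        # 1 degree C of the simulated optimum
        model, res, hauls, _ = fitted_tracker
        *_, species = tracking_sim
        sp = next(s for s in species if s.name == "bt-1")
        grid = hauls[hauls["region"] == "south"].iloc[:200].copy()
        bts = np.linspace(model.clamp_lo["bt"], model.clamp_hi["bt"], 41)
        means = []
        for b in bts:
            g = grid.copy()
            g["bt"] = b
            means.append(res.predict(g).mean())
        mode = bts[int(np.argmax(means))]
        assert abs(mode - sp.bt_opt) < 1.0

    def test_weights_nonnegative(self, fitted_tracker):
        _, res, hauls, _ = fitted_tracker
        w = res.predict(hauls[hauls["region"] == "south"].head(500))
        assert np.all(w >= 0)

    def test_ubiquitous_species_constant_presence(self, scheme):
        # species present in every haul: presence submodel is the
        # constant 1 and the delta weight equals the positive-part mean
        dom = syn.south_domain()
        temps = syn.default_temp_field("south")
        sp = syn.SpeciesSpec("ubiq", 60, np.inf, 0, np.inf, 0, np.inf,
                             p_max=1.0, log_mean=0.5, log_sd=0.6)
        hauls, catches, _ = syn.simulate_survey(
            dom, temps, [sp], range(1980, 1990), 60, seed=9, seasons=("fall",))
        assert len(catches) == len(hauls)
        res = env.DeltaLognormalEnvelope.from_survey(
            "ubiq", hauls, catches, "south", "fall").fit()
        assert res.constant_presence
        w = res.predict(hauls.head(50))
        mu = res.positive.predict(
            env._design(res._clamped(
                res.model.frame.head(50), "positive"), res.model.strata),
            exog_smooth=res._clamped(res.model.frame.head(50), "positive")
            [["sst", "bt"]].to_numpy())
        assert np.allclose(w, np.exp(mu + res.sigma2 / 2), rtol=1e-6)

    def test_permuted_biomass_loses_thermal_signal(self, tracking_sim):
        # negative control: shuffling biomass across hauls should leave
        # an essentially flat fitted thermal response
        hauls, catches, *_ = tracking_sim
        rng = np.random.default_rng(0)
        h = hauls[hauls["region"] == "south"]
        shuffled = catches.copy()
        shuffled["haul_id"] = rng.permutation(
            h["haul_id"].sample(n=len(catches), replace=True,
                                random_state=1).to_numpy())
        model = env.DeltaLognormalEnvelope.from_survey(
            "bt-1", hauls, shuffled, "south", "fall")
        res = model.fit()
        grid = h.iloc[:200]
        bts = np.linspace(model.clamp_lo["bt"], model.clamp_hi["bt"], 21)
        means = np.array([res.predict(grid.assign(bt=b)).mean() for b in bts])
        rel_range = (means.max() - means.min()) / means.mean()
        # fit the same curve on the real catches for contrast
        real = env.DeltaLognormalEnvelope.from_survey(
            "bt-1", hauls, catches, "south", "fall").fit()
        means_real = np.array([real.predict(grid.assign(bt=b)).mean()
                               for b in bts])
        rel_range_real = (means_real.max() - means_real.min()) / means_real.mean()
        assert rel_range < rel_range_real / 3


class TestCentroidsAndVelocity:
    def test_uniform_weights_give_arithmetic_means(self, scheme):
        hauls = pd.DataFrame({
            "haul_id": ["a", "b"], "year": [1970, 1970], "season": "fall",
            "region": "south", "latitude": [40.0, 44.0], "depth": [50.0, 150.0],
            "sst": 15.0, "bt": 10.0, "stratum": "s"})

        class Uniform:
            def predict(self, df):
                return np.ones(len(df))

        cents = env.envelope_centroids(Uniform(), hauls, scheme, "south", "fall")
        assert cents["latitude"].iloc[0] == pytest.approx(42.0)

    def test_weight_ratio_hand_value(self, scheme):
        hauls = pd.DataFrame({
            "haul_id": ["a", "b"], "year": [1970, 1970], "season": "fall",
            "region": "south", "latitude": [40.0, 44.0], "depth": [50.0, 150.0],
            "sst": 15.0, "bt": 10.0, "stratum": "s"})

        class OneThree:
            def predict(self, df):
                return np.array([1.0, 3.0])

        cents = env.envelope_centroids(OneThree(), hauls, scheme, "south", "fall")
        assert cents["latitude"].iloc[0] == pytest.approx(43.0)

    def test_linear_series_exact_slope(self):
        cents = pd.DataFrame({"year_mid": np.arange(9) * 5 + 1970.0})
        cents["latitude"] = 38 + 0.05 * (cents["year_mid"] - 1970)
        cents["depth"] = 100 - 0.5 * (cents["year_mid"] - 1970)
        ve = env.climate_velocity(cents, "x")
        assert ve.lat.slope == pytest.approx(0.05)
        assert ve.depth.slope == pytest.approx(-0.5)

    def test_velocity_recovery_single_species(self, fitted_tracker,
                                              tracking_sim, scheme):
        _, res, hauls, catches = fitted_tracker
        _, _, truth, *_ = tracking_sim
        cents = env.envelope_centroids(res, hauls, scheme, "south", "fall")
        ve = env.climate_velocity(cents, "bt-1")
        true_v = truth["species"]["bt-1"]["lat_velocity"]
        assert ve.lat.slope == pytest.approx(true_v, rel=0.4)


class TestComparison:
    def test_perfect_agreement(self):
        pairs = pd.DataFrame({"predicted": [0.01, 0.03, 0.05, 0.02],
                              "observed": [0.01, 0.03, 0.05, 0.02]})
        fit = env.compare_observed_vs_velocity(pairs)
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r2"] == pytest.approx(1.0)
        assert fit["deviation_from_1to1"] == pytest.approx(0.0, abs=1e-12)

    def test_faster_than_climate(self):
        pred = np.array([0.01, 0.02, 0.03, 0.05])
        pairs = pd.DataFrame({"predicted": pred, "observed": 1.2 * pred})
        fit = env.compare_observed_vs_velocity(pairs)
        assert fit["slope"] == pytest.approx(1.2)
        assert fit["deviation_from_1to1"] > 0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            env.compare_observed_vs_velocity(
                pd.DataFrame({"predicted": [1, 2], "observed": [1, 2]}))


class TestKruskalWallis:
    def test_hand_ranked_two_groups(self):
        # values {1,2} vs {3,4}: ranks 1..4, H by the rank-sum formula
        values = pd.Series([1.0, 2.0, 3.0, 4.0])
        groups = pd.Series(["a", "a", "b", "b"])
        got = env.kruskal_wallis(values, groups)
        n, r_a, r_b = 4, 1 + 2, 3 + 4
        h_oracle = 12 / (n * (n + 1)) * (r_a ** 2 / 2 + r_b ** 2 / 2) - 3 * (n + 1)
        assert got.h == pytest.approx(h_oracle)
        assert got.df == 1

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        values = pd.Series(np.concatenate([
            rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10),
            rng.normal(10, 0.1, 10)]))
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert env.kruskal_wallis(values, groups).p < 0.001

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 400
        for _ in range(reps):
            values = pd.Series(rng.normal(0, 1, 24))
            groups = pd.Series(np.repeat(list("abcd"), 6))
            if env.kruskal_wallis(values, groups).p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_small_group_dropped(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0])
        groups = pd.Series(["a", "a", "b", "b", "c"])
        got = env.kruskal_wallis(values, groups)
        assert got.groups == ("a", "b")
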