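import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aquarisk import synthetic_data as sd
from aquarisk.geodetector import (
    discretize,
    factor_screen,
    interact,
    interaction_screen,
    q_statistic,
)
from conftest import brute_force_q


class TestDiscretize:
    def test_quantile_median_split(self):
        s = discretize(np.arange(1.0, 11.0), method="quantile", n_classes=2)
        labels = s.labels
        assert set(labels[:5]) == {0}
        assert set(labels[5:]) == {1}

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.full(10, 3.0), n_classes=2)

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0, 2.0, 1.0, 2.0]), n_classes=3)

    def test_natural_breaks_finds_the_gap(self):
        vals = np.array([1.0, 2.0, 3.0, 100.0, 101.0, 102.0])
        s = discretize(vals, method="natural_breaks", n_classes=2)
        assert list(s.labels) == [0, 0, 0, 1, 1, 1]

    def test_natural_breaks_matches_exhaustive_split_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = np.sort(rng.uniform(0, 10, 12))
            best_cost, best_split = np.inf, None
            for cut in range(1, 12):
                a, b = vals[:cut], vals[cut:]
                cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                if cost < best_cost:
                    best_cost, best_split = cost, cut
            s = discretize(vals, method="natural_breaks", n_classes=2)
            assert (s.labels == 0).sum() == best_split

    @pytest.mark.parametrize("method", ["quantile", "equal_interval", "natural_breaks", "geometric"])
    def test_every_site_assigned(self, method):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1.0, 10.0, 50)
        s = discretize(vals, method=method, n_classes=4)
        assert s.n == 50
        assert s.L <= 4
        assert s.source == "discretized"

    def test_geometric_requires_positive(self):
        with pytest.raises(ValueError):
            discretize(np.array([-1.0, 1.0, 2.0, 4.0]), method="geometric", n_classes=2)


class TestQStatistic:
    def test_single_stratum_explains_nothing(self):
        assert q_statistic([1.0, 2.0, 3.0], ["A", "A", "A"]).q == pytest.approx(0.0)

    def test_internally_constant_strata_explain_everything(self):
        assert q_statistic([1, 1, 2, 2], ["A", "A", "B", "B"]).q == pytest.approx(1.0)

    def test_hand_sum_of_squares(self):
        r = q_statistic([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert r.q == pytest.approx(0.8, abs=1e-15)
        assert r.sst == pytest.approx(5.0)
        assert r.ssw == pytest.approx(1.0)

    def test_matches_anova_eta_squared(self):
        # independent oracle: eta^2 from the one-way ANOVA F statistic
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 30)
        labels = rng.choice(["a", "b", "c"], 30)
        groups = [y[labels == g] for g in np.unique(labels)]
        f = stats.f_oneway(*groups).statistic
        dfb, dfw = len(groups) - 1, 30 - len(groups)
        eta2 = dfb * f / (dfb * f + dfw)
        assert q_statistic(y, labels).q == pytest.approx(eta2, abs=1e-12)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            q_statistic([2.0, 2.0, 2.0], ["A", "B", "C"])

    def test_singleton_strata_counted(self):
        r = q_statistic([1.0, 2.0, 3.0], ["A", "B", "B"])
        assert r.n_singletons == 1

    @settings(max_examples=150, deadline=None)
    @given(data=st.data())
    def test_equals_brute_force_ssb_over_sst(self, data):
        n = data.draw(st.integers(4, 30))
        y = data.draw(
            st.lists(st.floats(-50, 50), min_size=n, max_size=n).filter(
                lambda v: np.var(np.asarray(v)) > 0
            )
        )
        n_strata = data.draw(st.integers(2, 6))
        labels = data.draw(
            st.lists(st.integers(0, n_strata - 1), min_size=n, max_size=n)
        )
        r = q_statistic(y, labels)
        assert r.q == pytest.approx(brute_force_q(y, labels), abs=1e-12)
        assert -1e-12 <= r.q <= 1 + 1e-12


class TestInteract:
    def test_identical_stratifications_univariable_weaken(self):
        y = [1.0, 2.0, 5.0, 6.0]
        labels = ["A", "A", "B", "B"]
        res = interact(y, labels, labels)
        assert res.q12 == pytest.approx(res.q1)
        assert res.category == "univariable_weaken"

    def test_hand_example_exact_independence(self):
        y = [1.0, 2.0, 3.0, 4.0]
        res = interact(y, ["A", "A", "B", "B"], ["A", "B", "A", "B"])
        assert res.q1 == pytest.approx(0.8)
        assert res.q2 == pytest.approx(0.2)
        assert res.q12 == pytest.approx(1.0)
        assert res.category == "independent"

    def test_refinement_never_below_parents(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(6, 30)
            y = rng.normal(0, 1, n)
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            res = interact(y, a, b)
            assert res.q12 >= max(res.q1, res.q2) - 1e-12

    def test_categories_cover_enhancement_cases(self):
        # two factors explaining disjoint variance halves: q12 = q1 + q2
        y = np.array([0.0, 1.0, 10.0, 11.0])
        res = interact(y, ["lo", "lo", "hi", "hi"], ["e", "o", "e", "o"])
        assert res.category in ("independent", "nonlinear_enhance", "bivariable_enhance")


@pytest.fixture(scope="module")
def planted():
    sites = sd.generate_sites(120, seed=21)
    cov = sd.generate_covariates(sites, seed=22)
    eff = sd.EffectSpec(
        "Cr6", "Soil_Type",
        {"yellow_brown": 1.0, "paddy": 3.0, "fluvo_aquic": 6.0, "cinnamon": 10.0},
        noise_sd=0.3,
    )
    meas = sd.generate_measurements(sites, cov, effects=[eff], seed=23)
    responses = meas.groupby("site_id", sort=True)[["Cr6", "TN"]].mean()
    cov_aligned = cov.set_index("site_id").loc[responses.index]
    factors = cov_aligned[list(sd.FACTOR_NAMES)].reset_index(drop=True)
    return responses.reset_index(drop=True), factors


class TestScreens:

    def test_planted_factor_attains_top_q(self, planted):
        responses, factors = planted
        qmat = factor_screen(responses, factors)
        assert qmat.loc["Cr6"].idxmax() == "Soil_Type"
        assert qmat.loc["Cr6", "Soil_Type"] > 0.5

    def test_pure_noise_response_near_zero_q(self):
        rng = np.random.default_rng(30)
        sites = sd.generate_sites(200, seed=31)
        cov = sd.generate_covariates(sites, seed=32)
        hits = 0
        for s in range(10):
            y = pd.DataFrame({"noise": np.random.default_rng(100 + s).normal(0, 1, 200)})
            qmat = factor_screen(y, cov[list(sd.FACTOR_NAMES)])
            if (qmat.loc["noise"] <= 0.1).all():
                hits += 1
        assert hits >= 9

    def test_factor_order_irrelevant(self, planted):
        responses, factors = planted
        a = factor_screen(responses, factors)
        shuffled = factors[list(factors.columns[::-1])]
        b = factor_screen(responses, shuffled)
        for f in factors.columns:
            assert a.loc["Cr6", f] == b.loc["Cr6", f]

    def test_interaction_screen_shape_and_symmetry(self, planted):
        responses, factors = planted
        sub = factors[["DEM", "Soil_Type", "GDP"]]
        out = interaction_screen(responses, sub)
        assert len(out) == 2 * 3  # C(3,2) pairs x 2 responses
        assert not (out["factor_a"] == out["factor_b"]).any()
        swapped = interaction_screen(responses, sub[["GDP", "Soil_Type", "DEM"]])
        key = ["response"]
        merged = out.merge(
            swapped,
            left_on=key + ["factor_a", "factor_b"],
            right_on=key + ["factor_b", "factor_a"],
            suffixes=("", "_sw"),
        )
        assert np.allclose(merged["q12"], merged["q12_sw"])

    def test_disjoint_planted_effects_never_weaken(self):
        # two categorical factors driving independent variance components
        rng = np.random.default_rng(40)
        n = 300
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        y = 2.0 * a + 3.0 * b + rng.normal(0, 0.8, n)
        responses = pd.DataFrame({"y": y})
        factors = pd.DataFrame({"A": a.astype(str), "B": b.astype(str)})
        out = interaction_screen(responses, factors)
        assert out["category"].iloc[0] in ("nonlinear_enhance", "independent", "bivariable_enhance")
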