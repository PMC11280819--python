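import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aquarisk.exposure_risk import (
    DistributionSpec,
    ExposureModel,
    ToxicityRef,
    add_dose,
    carcinogenic_risk,
    classify_cr,
    classify_hq,
    fit_concentration,
    lognormal_cr_tail,
    monte_carlo_risk,
    noncarcinogenic_hq,
    risk_ranking,
)


def _point(v: float) -> DistributionSpec:
    return DistributionSpec("point", {"value": v})


def _point_exposure(ir=2.0, ef=365.0, ed=30.0, bw=70.0, populations=("adult",)) -> ExposureModel:
    specs = {"IR": _point(ir), "EF": _point(ef), "ED": _point(ed), "BW": _point(bw)}
    return ExposureModel(populations={p: dict(specs) for p in populations})


class TestDoseAlgebra:
    def test_unit_identity(self):
        assert add_dose(1, 1, 1, 1, 1, 1) == pytest.approx(1.0)

    def test_zero_concentration_zero_dose(self):
        assert add_dose(0, 2, 365, 30, 70, 10950) == 0.0

    def test_hand_arithmetic(self):
        # 0.01*2*365*30 / (70*10950) = 219/766500 = 1/3500
        got = add_dose(0.01, 2, 365, 30, 70, 10950)
        assert got == pytest.approx(1.0 / 3500.0, rel=1e-12)

    @pytest.mark.parametrize("bw,at", [(0, 1), (1, 0), (-1, 1)])
    def test_rejects_non_positive_denominator(self, bw, at):
        with pytest.raises(ValueError):
            add_dose(1, 1, 1, 1, bw, at)

    def test_cr_hq_formulas(self):
        assert carcinogenic_risk(2e-4, 1.5) == pytest.approx(3e-4)
        assert noncarcinogenic_hq(3e-4, 3e-4) == pytest.approx(1.0)
        assert carcinogenic_risk(0.0, 1.5) == 0.0
        with pytest.raises(ValueError):
            noncarcinogenic_hq(1.0, 0.0)


class TestRiskBands:
    @pytest.mark.parametrize(
        "cr,band", [(5e-7, "low"), (1e-5, "potential"), (1e-6, "potential"),
                    (1e-4, "potential"), (2e-4, "high")]
    )
    def test_cr_bands(self, cr, band):
        assert classify_cr(cr) == band

    def test_hq_threshold_inclusive(self):
        assert classify_hq(1.0) == "acceptable"
        assert classify_hq(1.0001) == "high"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cr(-1e-9)
        with pytest.raises(ValueError):
            classify_hq(-0.1)


class TestFitConcentration:
    def test_constant_series_collapses_to_point_mass(self):
        spec = fit_concentration([0.3, 0.3, 0.3])
        assert spec.family == "point"
        assert spec.params["value"] == pytest.approx(0.3)

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(42)
        mu, sigma, n = -6.0, 0.5, 2000
        sample = np.exp(rng.normal(mu, sigma, n))
        spec = fit_concentration(sample)
        se_mu = sigma / np.sqrt(n)
        assert abs(spec.params["mu"] - mu) < 3 * se_mu

    def test_fitted_spec_samples_positive(self):
        spec = fit_concentration([0.1, 0.2, 0.4, 0.8])
        draws = spec.sample(1000, np.random.default_rng(0))
        assert (draws > 0).all()

    def test_too_few_or_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fit_concentration([1.0, 2.0])
        with pytest.raises(ValueError):
            fit_concentration([1.0, -2.0, 3.0])


class TestMonteCarlo:
    def test_degenerate_distributions_reproduce_deterministic_pipeline(self):
        conc = {"As": _point(0.01)}
        tox = ToxicityRef(sf={"As": 1.5}, rfd={"As": 3e-4})
        model = _point_exposure()
        summary, _ = monte_carlo_risk(conc, model, tox, n_iter=200, seed=0)
        add_nc = add_dose(0.01, 2, 365, 30, 70, 30 * 365)
        add_ca = add_dose(0.01, 2, 365, 30, 70, 70 * 365)
        row = summary.loc[("As", "adult")]
        assert row["HQ_mean"] == pytest.approx(add_nc / 3e-4, abs=1e-12)
        assert row["CR_mean"] == pytest.approx(add_ca * 1.5, abs=1e-12)
        assert row["HQ_se"] == 0.0
        assert row["CR_se"] == 0.0

    def test_survival_fractions_monotone_in_threshold(self, exposure_model, toxicity):
        conc = {"As": DistributionSpec("lognormal", {"mu": -6.0, "sigma": 0.6})}
        summary, _ = monte_carlo_risk(conc, exposure_model, toxicity, n_iter=4000, seed=1)
        for _, row in summary.iterrows():
            assert row["P_CR_gt_1e4"] <= row["P_CR_gt_1e6"]

    def test_seed_reproducibility(self, exposure_model, toxicity):
        conc = {"Pb": DistributionSpec("lognormal", {"mu": -6.2, "sigma": 0.5})}
        s1, _ = monte_carlo_risk(conc, exposure_model, toxicity, n_iter=500, seed=3)
        s2, _ = monte_carlo_risk(conc, exposure_model, toxicity, n_iter=500, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_swapping_population_specs_swaps_results_exactly(self, toxicity):
        adult = {"IR": _point(2.0), "EF": _point(365.0), "ED": _point(30.0),
                 "BW": DistributionSpec("normal", {"mean": 60.0, "sd": 5.0}, truncate=(30, 100))}
        child = {"IR": _point(1.0), "EF": _point(365.0), "ED": _point(6.0),
                 "BW": DistributionSpec("normal", {"mean": 23.0, "sd": 4.0}, truncate=(8, 50))}
        conc = {"As": DistributionSpec("lognormal", {"mu": -6.5, "sigma": 0.4})}
        m1 = ExposureModel(populations={"adult": adult, "child": child})
        m2 = ExposureModel(populations={"adult": child, "child": adult})
        s1, _ = monte_carlo_risk(conc, m1, toxicity, n_iter=500, seed=9)
        s2, _ = monte_carlo_risk(conc, m2, toxicity, n_iter=500, seed=9)
        a1 = s1.loc[("As", "adult")].drop("n_iter")
        c2 = s2.loc[("As", "child")].drop("n_iter")
        pd.testing.assert_series_equal(a1, c2, check_names=False)

    def test_cr_linear_in_concentration_and_sf(self):
        model = _point_exposure()
        tox1 = ToxicityRef(sf={"As": 1.5}, rfd={"As": 3e-4})
        tox2 = ToxicityRef(sf={"As": 3.0}, rfd={"As": 6e-4})
        s1, _ = monte_carlo_risk({"As": _point(0.01)}, model, tox1, n_iter=10, seed=0)
        s2, _ = monte_carlo_risk({"As": _point(0.02)}, model, tox1, n_iter=10, seed=0)
        s3, _ = monte_carlo_risk({"As": _point(0.01)}, model, tox2, n_iter=10, seed=0)
        assert s2["CR_mean"].iloc[0] == pytest.approx(2 * s1["CR_mean"].iloc[0], rel=1e-12)
        assert s3["CR_mean"].iloc[0] == pytest.approx(2 * s1["CR_mean"].iloc[0], rel=1e-12)
        # HQ inverse-linear in RfD
        assert s3["HQ_mean"].iloc[0] == pytest.approx(s1["HQ_mean"].iloc[0] / 2, rel=1e-12)

    def test_lognormal_tail_matches_closed_form(self, toxicity):
        model = _point_exposure()
        conc = {"As": DistributionSpec("lognormal", {"mu": -6.8, "sigma": 0.8})}
        n = 10_000
        summary, _ = monte_carlo_risk(conc, model, toxicity, n_iter=n, seed=11)
        p_true = lognormal_cr_tail(conc["As"], model.populations["adult"], toxicity.sf["As"], 1e-6)
        p_hat = summary.loc[("As", "adult"), "P_CR_gt_1e6"]
        tol = 3 * np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) <= tol

    def test_exceedance_variance_halves_when_iterations_double(self, toxicity):
        # Monte Carlo rate: Var(p_hat) ~ 1/n across independent seeds
        model = _point_exposure()
        conc = {"As": DistributionSpec("lognormal", {"mu": -6.8, "sigma": 0.8})}
        def spread(n_iter):
            ps = [
                monte_carlo_risk(conc, model, toxicity, n_iter=n_iter, seed=s)[0]
                .loc[("As", "adult"), "P_CR_gt_1e6"]
                for s in range(50)
            ]
            return np.var(ps)
        v1, v2 = spread(250), spread(500)
        assert 1.3 < v1 / v2 < 3.2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("gamma", {"shape": 1.0})
        with pytest.raises(ValueError):
            DistributionSpec("normal", {"mean": 1.0})


class TestRanking:
    def _summary(self, means: dict) -> pd.DataFrame:
        df = pd.DataFrame(
            {"metal": list(means), "population": "adult",
             "CR_mean": list(means.values()), "HQ_mean": list(means.values())}
        )
        return df.set_index(["metal", "population"])

    def test_single_metal(self):
        assert risk_ranking(self._summary({"As": 1.0}))["CR"] == ["As"]

    def test_descending_sort(self):
        out = risk_ranking(self._summary({"As": 3.0, "Cd": 1.0, "Cr6": 2.0}))
        assert out["CR"] == ["As", "Cr6", "Cd"]

    def test_ties_break_alphabetically(self):
        out = risk_ranking(self._summary({"Pb": 1.0, "Cd": 1.0}))
        assert out["CR"] == ["Cd", "Pb"]

    def test_input_order_irrelevant(self):
        a = risk_ranking(self._summary({"As": 3.0, "Cd": 1.0}))
        b = risk_ranking(self._summary({"Cd": 1.0, "As": 3.0}))
        assert a == b
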