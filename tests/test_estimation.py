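import math

import numpy as np
import pandas as pd
import pytest

from reachat.errors import ConfigurationError, InsufficientDataError
from reachat.estimation import (
    FitDesign,
    IndividualFit,
    ObservationTable,
    PopulationModel,
    eb_fit,
    eta_shrinkage,
    fit_individual,
    iwres,
    pooled_fit,
    proportional_loglik,
    two_stage_population,
    vpc_band,
)
from reachat.synthetic_cohort import DesignSpec, default_population
from reachat.tumor_model import (
    DoseSignal,
    SubpopParams,
    TumorState,
    logistic_closed_form,
)


def logistic_table(ident="m1", r=0.35, K=2000.0, x0=250.0, n=12, horizon=30.0,
                   xi=0.0, seed=0) -> ObservationTable:
    t = np.linspace(0.0, horizon, n)
    f = logistic_closed_form(r, K, x0, t)
    rng = np.random.default_rng(seed)
    y = f * (1.0 + xi * rng.standard_normal(n)) if xi > 0 else f
    return ObservationTable(
        id=ident,
        data=pd.DataFrame({"t": t, "channel": "V", "y": np.maximum(y, 0.1)}),
        arm="mono_H_control",
        dose=DoseSignal.off(),
        init=TumorState(0.0, x0, 0.0),
    )


BASE = SubpopParams(r_h=0.35, r_a=0.30, K_h=2000.0, K_a=2000.0, a=0.8, h=1.2, E_osi=1.0)


class TestProportionalLoglik:
    def test_zero_residuals(self):
        obs = logistic_table()
        f = obs.data["y"].to_numpy()
        ll = proportional_loglik(obs, f, xi=0.1)
        expected = -np.sum(np.log(np.sqrt(2 * math.pi) * 0.1 * f))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_doubling_xi_at_zero_residuals(self):
        obs = logistic_table()
        f = obs.data["y"].to_numpy()
        n = len(obs)
        assert proportional_loglik(obs, f, 0.2) == pytest.approx(
            proportional_loglik(obs, f, 0.1) - n * math.log(2.0), rel=1e-12
        )

    def test_single_point_hand_value(self):
        obs = ObservationTable(
            id="x",
            data=pd.DataFrame({"t": [1.0], "channel": ["V"], "y": [110.0]}),
            init=TumorState(0, 100.0, 0.0),
        )
        ll = proportional_loglik(obs, [100.0], xi=0.1)
        assert ll == pytest.approx(-math.log(math.sqrt(2 * math.pi) * 10.0) - 0.5, rel=1e-12)

    def test_nonpositive_prediction_rejected(self):
        obs = logistic_table()
        with pytest.raises(ValueError):
            proportional_loglik(obs, np.zeros(len(obs)), 0.1)


class TestFitIndividual:
    def test_noise_free_logistic_recovery(self):
        obs = logistic_table(r=0.28, K=1700.0)
        design = FitDesign(base=BASE, fit_names=("r_h", "K_h"))
        fit = fit_individual(obs, design, n_starts=4)
        assert fit.phi["r_h"] == pytest.approx(0.28, rel=1e-3)
        assert fit.phi["K_h"] == pytest.approx(1700.0, rel=1e-3)

    def test_noisy_recovery_median_within_10pct(self):
        errs_r = []
        for seed in range(20):
            obs = logistic_table(r=0.35, K=2000.0, xi=0.1, seed=seed)
            design = FitDesign(base=BASE, fit_names=("r_h", "K_h"))
            fit = fit_individual(obs, design, n_starts=4, seed=seed)
            errs_r.append(abs(fit.phi["r_h"] - 0.35) / 0.35)
        assert np.median(errs_r) < 0.10

    def test_underdetermined_rejected(self):
        obs = ObservationTable(
            id="x",
            data=pd.DataFrame({"t": [3.0], "channel": ["V"], "y": [400.0]}),
            init=TumorState(0, 250.0, 0.0),
        )
        design = FitDesign(base=BASE, fit_names=("r_h", "K_h"))
        with pytest.raises(InsufficientDataError):
            fit_individual(obs, design)


class TestEbFit:
    def pop(self, omega=0.2):
        mu = {k: math.log(v) for k, v in BASE.to_dict().items()}
        return PopulationModel(mu=mu, omega={k: omega for k in mu}, xi=0.1)

    def test_prior_mode_without_data(self):
        pop = self.pop()
        design = FitDesign(base=BASE, fit_names=("r_h", "K_h"))
        fit = eb_fit(None, pop, design)
        for k, v in pop.typical().items():
            assert fit.phi[k] == pytest.approx(v, rel=1e-12)

    def test_flat_prior_limit_matches_individual_fit(self):
        design = FitDesign(base=BASE, fit_names=("r_h", "K_h"), xi=0.1)
        for seed in range(3):
            obs = logistic_table(r=0.4, K=2300.0, xi=0.08, seed=seed)
            flat = self.pop(omega=1e6)
            f_eb = eb_fit(obs, flat, design, n_starts=4, seed=seed)
            f_ind = fit_individual(obs, design, n_starts=4, seed=seed)
            assert f_eb.objective == pytest.approx(f_ind.objective, abs=1e-6)

    def test_sparse_design_recovers_resistant_growth_rate(self):
        # pre-treatment volume series plus one resistant-volume point
        from reachat.synthetic_cohort import generate_cohort_observations

        pop = default_population()
        log_errs = []
        for seed in range(20):
            animals, tables = generate_cohort_observations(
                pop, DesignSpec(arm="therapy_cohort", n=1), seed=seed
            )
            obs = tables[0]
            names = ("r_h", "r_a", "K_h", "K_a", "a", "h")
            design = FitDesign(base=pop.typical_params(), fit_names=names, xi=0.1)
            fit = eb_fit(obs, pop, design, n_starts=2, seed=seed)
            log_errs.append(abs(math.log(fit.phi["r_a"] / animals[0].phi.r_a)))
        assert np.median(log_errs) < math.log(1.25)


class TestTwoStage:
    def _fit(self, ident, phi):
        preds = pd.DataFrame({"t": [0.0], "channel": ["V"], "y": [100.0], "f": [100.0]})
        return IndividualFit(
            id=ident, phi=phi, eta={}, fitted=tuple(phi), objective=0.0, predictions=preds
        )

    def test_identical_individuals_zero_omega(self):
        phi = {"r_h": 0.35, "K_h": 2000.0}
        pop = two_stage_population([self._fit(f"m{i}", dict(phi)) for i in range(5)])
        assert pop.omega["r_h"] == 0.0 and pop.omega["K_h"] == 0.0
        assert math.exp(pop.mu["r_h"]) == pytest.approx(0.35, rel=1e-12)

    def test_too_few_fits_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_stage_population([self._fit("a", {"r_h": 0.3})] * 2)

    def test_lognormal_cohort_mean_within_standard_error(self, rng):
        mu_star, omega_star, n = math.log(0.35), 0.2, 24
        fits = [
            self._fit(f"m{i}", {"r_h": math.exp(mu_star + omega_star * rng.standard_normal())})
            for i in range(n)
        ]
        pop = two_stage_population(fits)
        assert abs(pop.mu["r_h"] - mu_star) < 2 * omega_star / math.sqrt(n)

    def test_permutation_invariance(self, rng):
        fits = [
            self._fit(f"m{i}", {"r_h": float(np.exp(rng.normal(-1, 0.2)))}) for i in range(8)
        ]
        p1 = two_stage_population(fits)
        p2 = two_stage_population(list(reversed(fits)))
        assert p1.mu == p2.mu and p1.omega == p2.omega


class TestDiagnostics:
    def test_iwres_values(self):
        obs = ObservationTable(
            id="x",
            data=pd.DataFrame({"t": [0.0, 1.0], "channel": ["V", "V"], "y": [100.0, 110.0]}),
            init=TumorState(0, 100.0, 0.0),
        )
        fit = IndividualFit(
            id="x", phi={}, eta={}, fitted=(), objective=0.0,
            predictions=obs.data.assign(f=[100.0, 100.0]),
        )
        res = iwres(obs, fit, xi=0.1)
        assert res.iloc[0] == pytest.approx(0.0) and res.iloc[1] == pytest.approx(1.0)

    def test_shrinkage_limits(self):
        mu = {"r_h": math.log(0.35)}
        pop = PopulationModel(mu=mu, omega={"r_h": 0.2}, xi=0.1)
        zero_eta = [
            IndividualFit(
                id=f"m{i}", phi={"r_h": 0.35}, eta={"r_h": 0.0}, fitted=("r_h",),
                objective=0.0, predictions=pd.DataFrame(columns=["t", "channel", "y", "f"]),
            )
            for i in range(6)
        ]
        assert eta_shrinkage(zero_eta, pop)["r_h"] == pytest.approx(100.0)
        rng = np.random.default_rng(1)
        etas = rng.standard_normal(2000) * 0.2
        etas = (etas - etas.mean()) / etas.std(ddof=1) * 0.2  # sd exactly omega
        spread = [
            IndividualFit(
                id=f"m{i}", phi={"r_h": 0.35}, eta={"r_h": float(e)}, fitted=("r_h",),
                objective=0.0, predictions=pd.DataFrame(columns=["t", "channel", "y", "f"]),
            )
            for i, e in enumerate(etas[:50])
        ]
        val = eta_shrinkage(spread, pop)["r_h"]
        assert abs(val) < 25.0  # near zero shrinkage when sd(eta) ~ omega

    def test_shrinkage_undefined_for_fixed_effect(self):
        pop = PopulationModel(mu={"E_osi": 0.0}, omega={"E_osi": 0.0}, xi=0.1)
        fits = [
            IndividualFit(
                id="m", phi={"E_osi": 1.0}, eta={"E_osi": 0.0}, fitted=("E_osi",),
                objective=0.0, predictions=pd.DataFrame(columns=["t", "channel", "y", "f"]),
            )
        ] * 3
        with pytest.warns(UserWarning):
            out = eta_shrinkage(fits, pop)
        assert "E_osi" not in out


class TestVpc:
    def test_band_collapses_without_variability(self):
        pop = default_population(xi=1e-9, omega=0.0)
        design = DesignSpec(arm="mono_H_control", n=100, grouping_window=(249.9999, 250.0001))
        band = vpc_band(pop, design, level=90.0, n_sim=100, seed=3)
        assert np.all((band["hi"] - band["lo"]) / band["median"] < 1e-6)

    def test_band_nesting(self):
        pop = default_population()
        design = DesignSpec(arm="mono_H_control", n=100)
        b50 = vpc_band(pop, design, level=50.0, n_sim=300, seed=5)
        b90 = vpc_band(pop, design, level=90.0, n_sim=300, seed=5)
        assert np.all(b90["lo"].to_numpy() <= b50["lo"].to_numpy() + 1e-9)
        assert np.all(b50["hi"].to_numpy() <= b90["hi"].to_numpy() + 1e-9)

    def test_small_simulation_rejected(self):
        pop = default_population()
        with pytest.raises(ConfigurationError):
            vpc_band(pop, DesignSpec(arm="mono_H_control", n=10), n_sim=10)


class TestPooledFit:
    def test_shared_parameters_from_several_individuals(self):
        tables = [logistic_table(f"m{i}", r=0.32, K=1900.0, xi=0.05, seed=i) for i in range(3)]
        design = FitDesign(base=BASE, fit_names=("r_h", "K_h"), xi=0.05)
        phi, obj = pooled_fit(tables, design, n_starts=2)
        assert phi["r_h"] == pytest.approx(0.32, rel=0.05)
        assert phi["K_h"] == pytest.approx(1900.0, rel=0.05)
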