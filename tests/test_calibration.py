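"""Likelihood, sampler and posterior-summary behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dphp_pbpk import calibration as cal
from dphp_pbpk import synthetic as syn
from dphp_pbpk.parameters import default_priors


def make_subject(times=(2.0, 4.0), concs=(0.5, 0.5), vols=(200.0, 200.0)) -> cal.SubjectData:
    blood = pd.DataFrame({"time_h": [1.0, 2.0], "CBlood_DPHP": [0.1, 0.2], "CBlood_MPHP": [0.05, 0.1]})
    urine = pd.DataFrame(
        {"time_h": times, "volume_ml": vols, "conc_OH": concs, "conc_cx": concs}
    )
    return cal.SubjectData("A", 83.0, 0.717, blood, urine)


class TestUrineRates:
    def test_hand_value(self):
        s = make_subject(times=(2.0,), concs=(0.5,), vols=(200.0,))
        with pytest.raises(ValueError):
            cal.urine_rates(s)  # a single void has no rate series
        s = make_subject()
        rates = cal.urine_rates(s)
        assert rates["RUrine_OH"].iloc[0] == pytest.approx(0.05)  # 0.5 mg/L * 0.2 L / 2 h

    def test_zero_concentration_zero_rate(self):
        s = make_subject(concs=(0.0, 0.0))
        assert np.all(cal.urine_rates(s)["RUrine_OH"] == 0.0)

    def test_merging_voids_conserves_excreted_mass(self):
        split = make_subject(times=(2.0, 4.0), concs=(0.6, 0.3), vols=(100.0, 400.0))
        r = cal.urine_rates(split)
        mass_split = float((r["RUrine_OH"] * r["interval_h"]).sum())
        mass_direct = (0.6 * 0.1) + (0.3 * 0.4)
        assert mass_split == pytest.approx(mass_direct, rel=1e-12)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            make_subject(times=(4.0, 2.0))


class TestTruncatedNormalLikelihood:
    def test_closed_form_value(self):
        # y = mu = 1, sigma = 1: -0.5 ln(2 pi) - ln Phi(1)
        assert cal.truncnorm_loglik(np.array([1.0]), np.array([1.0]), 1.0) == pytest.approx(
            -0.7462, abs=1e-4
        )

    def test_diverges_as_sigma_grows(self):
        y, mu = np.array([1.0]), np.array([1.0])
        assert cal.truncnorm_loglik(y, mu, 1e6) < cal.truncnorm_loglik(y, mu, 1.0) - 10

    def test_additivity_under_duplication(self):
        y = np.array([0.2, 0.5, 1.0])
        mu = np.array([0.3, 0.4, 0.9])
        single = cal.truncnorm_loglik(y, mu, 0.2)
        double = cal.truncnorm_loglik(np.tile(y, 2), np.tile(mu, 2), 0.2)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_invalid_sigma(self):
        assert cal.truncnorm_loglik(np.array([1.0]), np.array([1.0]), 0.0) == -math.inf


class TestSpecValidation:
    def test_overlapping_theta_omega_rejected(self):
        with pytest.raises(ValueError):
            cal.CalibrationSpec(theta_names=["K1_MOH"], omega_names=["K1_MOH"])

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            cal.CalibrationSpec(theta_names=["NotAParam"], omega_names=[])


@pytest.fixture(scope="module")
def tiny_dataset():
    design = syn.StudyDesign(subjects=("A", "B"))
    truths, _ = syn.perturb_truth(
        {"K1_MOH": 0.12}, {"FracDOSEHep": default_priors()["FracDOSEHep"]}, 2, seed=5
    )
    return syn.generate_dataset(design, truths, seed=5), truths


class TestSampler:
    def test_zero_iterations_returns_initial_state(self, tiny_dataset):
        ds, _ = tiny_dataset
        spec = cal.CalibrationSpec(theta_names=["K1_MOH"], omega_names=["FracDOSEHep"])
        ps = cal.mcmc_calibrate(spec, ds, iterations=0, seed=1)
        assert ps.n_draws == 1
        assert ps.theta["K1_MOH"].iloc[0] == pytest.approx(spec.priors["K1_MOH"].median())

    def test_prior_reproduced_when_likelihood_disabled(self):
        # with the data term removed the sampler must reproduce the prior
        spec = cal.CalibrationSpec(
            theta_names=["K1_MOH", "FracMetabOH"], omega_names=["FracDOSEHep"]
        )
        # thinned hard so the Kolmogorov-Smirnov test sees near-independent draws
        ps = cal.mcmc_calibrate(
            spec, cal.BMDataset([]), iterations=30000, thin=10, seed=3, use_likelihood=False
        )
        for name in ("K1_MOH", "FracMetabOH"):
            draws = ps.theta[name].to_numpy()
            lo, hi = spec.priors[name].support
            ks = stats.kstest(draws, stats.uniform(lo, hi - lo).cdf)
            assert ks.pvalue > 0.01, name

    def test_short_chain_recovers_truth_roughly(self, tiny_dataset):
        ds, truths = tiny_dataset
        spec = cal.CalibrationSpec(theta_names=["K1_MOH"], omega_names=["FracDOSEHep"])
        ps = cal.mcmc_calibrate(spec, ds, iterations=250, thin=1, seed=2)
        med = ps.theta["K1_MOH"].median()
        assert abs(med - 0.12) / 0.12 < 0.25
        for j, truth in enumerate(truths):
            med_j = ps.omegas[j]["FracDOSEHep"].median()
            assert abs(med_j - truth["FracDOSEHep"]) / truth["FracDOSEHep"] < 0.25


class TestSummaries:
    def test_constant_chain_collapses(self):
        ps = cal.PosteriorSample(
            theta=pd.DataFrame({"a": np.ones(200)}),
            omegas=[],
            sigmas=pd.DataFrame({s: np.ones(200) for s in cal.STREAMS}),
            logpost=np.zeros(200),
            subjects=[],
            iterations=200,
            thin=1,
            seed=0,
        )
        out = cal.posterior_summaries(ps)
        row = out[out.parameter == "a"].iloc[0]
        assert row["ci_lo"] == row["median"] == row["ci_hi"] == 1.0

    def test_normal_pseudo_draws_match_analytic_quantiles(self, rng):
        draws = rng.standard_normal(100_000)
        ps = cal.PosteriorSample(
            theta=pd.DataFrame({"z": draws}),
            omegas=[],
            sigmas=pd.DataFrame({s: np.ones_like(draws) for s in cal.STREAMS}),
            logpost=np.zeros_like(draws),
            subjects=[],
            iterations=0,
            thin=1,
            seed=0,
        )
        row = cal.posterior_summaries(ps).set_index("parameter").loc["z"]
        assert row["median"] == pytest.approx(0.0, abs=0.02)
        assert row.ci_lo == pytest.approx(-1.96, abs=0.03)
        assert row.ci_hi == pytest.approx(1.96, abs=0.03)

    def test_too_few_draws_rejected(self):
        ps = cal.PosteriorSample(
            theta=pd.DataFrame({"a": [1.0]}),
            omegas=[],
            sigmas=pd.DataFrame({s: [1.0] for s in cal.STREAMS}),
            logpost=np.zeros(1),
            subjects=[],
            iterations=1,
            thin=1,
            seed=0,
        )
        with pytest.raises(ValueError):
            cal.posterior_summaries(ps)

    def test_table_layout(self):
        ps = cal.PosteriorSample(
            theta=pd.DataFrame({"K1_MOH": np.linspace(0.05, 0.15, 150)}),
            omegas=[pd.DataFrame({"FracDOSEHep": np.linspace(0.02, 0.2, 150)})],
            sigmas=pd.DataFrame({s: np.ones(150) for s in cal.STREAMS}),
            logpost=np.zeros(150),
            subjects=["A"],
            iterations=150,
            thin=1,
            seed=0,
        )
        out = cal.posterior_summaries(ps)
        assert list(out.columns) == ["parameter", "median", "ci_lo", "ci_hi"]
        assert "A:FracDOSEHep" in set(out.parameter)


class TestCredibleBand:
    def test_single_draw_band_collapses_onto_curve(self, tiny_dataset):
        ds, _ = tiny_dataset
        spec = cal.CalibrationSpec(theta_names=["K1_MOH"], omega_names=["FracDOSEHep"])
        ps = cal.mcmc_calibrate(spec, ds, iterations=0, seed=1)
        grid = np.linspace(0.0, 24.0, 49)
        with pytest.warns(UserWarning):
            band = cal.credible_band(ps, spec, ds.subjects[0], 0, "RUrine_OH", grid)
        assert np.allclose(band["lo"], band["hi"])
        assert np.allclose(band["lo"], band["central"])

    def test_band_contains_median_curve(self, tiny_dataset):
        ds, _ = tiny_dataset
        spec = cal.CalibrationSpec(theta_names=["K1_MOH"], omega_names=["FracDOSEHep"])
        ps = cal.mcmc_calibrate(spec, ds, iterations=150, thin=1, seed=4)
        grid = np.linspace(0.0, 24.0, 25)
        band = cal.credible_band(ps, spec, ds.subjects[0], 0, "RUrine_OH", grid, max_draws=60)
        from dphp_pbpk import model
        from dphp_pbpk.parameters import ExposureScenario, build_subject_from_flat

        flat = {**ps.theta.median().to_dict(), **ps.omegas[0].median().to_dict()}
        scen = ExposureScenario(dose=ds.subjects[0].dose, BW=ds.subjects[0].BW, t_end=24.0)
        med_curve = model.simulate(
            build_subject_from_flat(flat, scen), scen, t_grid=grid, engine="rk4", dt=spec.dt
        ).series("RUrine_OH")
        inside = (med_curve >= band["lo"] - 1e-12) & (med_curve <= band["hi"] + 1e-12)
        assert inside.mean() >= 0.9


class TestDatasetIO:
    def test_round_trip_lossless(self, tiny_dataset, tmp_path):
        ds, _ = tiny_dataset
        path = tmp_path / "bm.csv"
        ds.to_csv(path)
        back = cal.BMDataset.from_csv(path)
        for a, b in zip(ds.subjects, back.subjects):
            assert a.subject == b.subject and a.BW == b.BW and a.dose == b.dose
            pd.testing.assert_frame_equal(a.blood, b.blood.astype(a.blood.dtypes))
            np.testing.assert_allclose(a.urine.to_numpy(), b.urine.to_numpy())

    def test_excluded_flag_round_trip(self, tmp_path):
        s = make_subject()
        s.excluded = True
        ds = cal.BMDataset([s])
        path = tmp_path / "bm.csv"
        ds.to_csv(path)
        back = cal.BMDataset.from_csv(path)
        assert back.subjects[0].excluded
        assert back.active() == []
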