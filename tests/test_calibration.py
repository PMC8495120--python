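"""Bayesian calibration: priors, likelihood, diagnostics, sampler, recovery."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from permpbpk import GestationalPhysiology, TKCalibration, gelman_rubin, generate_study
from permpbpk.calibration import log_likelihood, sample_posterior
from permpbpk.parameters import PRIORS, PriorSpec, posterior_mean_params
from permpbpk.study import StudyDesign


class TestPriors:
    def test_uniform_constant_inside_bounds(self):
        p = PriorSpec("uniform", lower=0.0, upper=6.0)
        assert p.logpdf(1.0) == p.logpdf(5.9) == pytest.approx(-math.log(6.0))

    def test_bound_violation_is_minus_inf(self):
        for p in (PRIORS["cis"]["cl_liv"], PRIORS["cis"]["sc_ktrans1"]):
            assert p.logpdf(p.lower - 1e-9) == -np.inf
            assert p.logpdf(p.upper + 1e-9) == -np.inf

    def test_truncnorm_density_ratio_matches_numeric_truncation(self):
        """Density ratio at the mean vs the upper bound equals the
        untruncated normal ratio; the normalizer checks out against
        numerical integration of the truncated density."""
        p = PRIORS["cis"]["cl_liv"]  # truncnorm(6.20, 3.10, [1, 15])
        ratio = math.exp(p.logpdf(6.20) - p.logpdf(15.0))
        expected = math.exp(0.5 * ((15.0 - 6.20) / 3.10) ** 2)
        assert ratio == pytest.approx(expected, rel=1e-10)
        total, _ = integrate.quad(lambda x: math.exp(p.logpdf(x)), 1.0, 15.0)
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_table_prior_families(self):
        assert PRIORS["cis"]["sc_ktrans1"].family == "uniform"
        assert PRIORS["cis"]["k_ai"].family == "fixed" and PRIORS["cis"]["k_ai"].value == 0.52
        assert PRIORS["trans"]["pc_kid"].value == 0.21
        cl = PRIORS["trans"]["cl_liv"]
        assert (cl.mean, cl.sd, cl.lower, cl.upper) == (24.30, 12.15, 1, 50)


class TestLikelihood:
    def test_perfect_predictions_maximize(self, phys, chem_cis_gd1):
        design = StudyDesign(n_per_group=2)
        ds = generate_study({"cis": chem_cis_gd1}, phys, design=design, sigma_log=0.0,
                            seed=0, gestational_days=[1])
        at_truth = log_likelihood(ds, {"cis": chem_cis_gd1}, phys)
        off = chem_cis_gd1.with_values(cl_liv=chem_cis_gd1.cl_liv * 1.3)
        assert at_truth > log_likelihood(ds, {"cis": off}, phys)

    def test_one_record_closed_form(self, phys, chem_cis_gd1):
        """A single record at prediction * e^0.15 scores exactly the
        lognormal density one log-sd from the mode."""
        import pandas as pd

        from permpbpk import DoseSchedule, PregnancyPBPK, TKDataset
        from permpbpk.study import _COLUMNS

        pbpk = PregnancyPBPK(chem_cis_gd1, phys)
        dose = DoseSchedule().dose_mg(phys, 1.0)
        states = pbpk.propagate_dosing([1.0], [dose], [6.0])
        pred = pbpk.concentration(states[6.0], 1.0 + 6.0 / 24.0, "blood")

        df = pd.DataFrame(
            [{"gd": 1, "time_h": 6.0, "matrix": "blood", "isomer": "cis",
              "animal_id": "a1", "concentration": pred * math.exp(0.15),
              "censor": "quantified", "loq": 1e-12}],
            columns=_COLUMNS,
        )
        ll = log_likelihood(TKDataset(df), {"cis": chem_cis_gd1}, phys, sigma_log=0.15)
        expected = stats.lognorm.logpdf(pred * math.exp(0.15), s=0.15, scale=pred)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_larger_sigma_lowers_density_at_mode(self, phys, chem_cis_gd1):
        ds = generate_study({"cis": chem_cis_gd1}, phys, design=StudyDesign(n_per_group=1),
                            sigma_log=0.0, seed=0, gestational_days=[1])
        tight = log_likelihood(ds, {"cis": chem_cis_gd1}, phys, sigma_log=0.15)
        loose = log_likelihood(ds, {"cis": chem_cis_gd1}, phys, sigma_log=0.30)
        assert tight > loose


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 10_000, 2))
        r = gelman_rubin(chains)
        assert np.all((r > 0.99) & (r < 1.01))

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(1, 500, 1))
        b = rng.normal(100, 1, size=(1, 500, 1))
        r = gelman_rubin(np.concatenate([a, b]))
        assert r[0] > 10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))

    def test_zero_variance_marked_undefined(self):
        chains = np.zeros((2, 50, 1))
        assert np.isnan(gelman_rubin(chains)[0])


class TestSampler:
    def test_conjugate_normal_posterior(self):
        """Normal likelihood x normal prior: posterior mean/sd match the
        closed-form conjugate result within Monte-Carlo error."""
        y, sigma_y, mu0, tau0 = 1.8, 0.5, 0.0, 2.0
        post_var = 1.0 / (1 / tau0**2 + 1 / sigma_y**2)
        post_mean = post_var * (mu0 / tau0**2 + y / sigma_y**2)

        def log_prob(z):
            x = z[0]
            return -0.5 * ((x - mu0) / tau0) ** 2 - 0.5 * ((y - x) / sigma_y) ** 2

        chains = sample_posterior(
            log_prob, lambda rng: np.array([rng.normal(mu0, tau0)]), ndim=1,
            n_chains=3, n_iter=3000, retain=1500, thin=2, seed=4,
        )
        draws = chains.reshape(-1)
        # tolerance ~3 MC standard errors of the ensemble mean
        assert draws.mean() == pytest.approx(post_mean, abs=0.04)
        assert draws.std() == pytest.approx(math.sqrt(post_var), rel=0.05)
        assert gelman_rubin(chains)[0] < 1.05

    def test_fixed_seed_reproducible(self):
        def log_prob(z):
            return -0.5 * float(z @ z)

        kw = dict(ndim=2, n_chains=2, n_iter=200, retain=100, thin=2, seed=9)
        a = sample_posterior(log_prob, lambda rng: rng.normal(size=2), **kw)
        b = sample_posterior(log_prob, lambda rng: rng.normal(size=2), **kw)
        np.testing.assert_array_equal(a, b)


class TestCalibrationModel:
    def test_gd1_mode_rejects_conceptus_data(self, phys, chem_cis_late):
        ds = generate_study({"cis": chem_cis_late}, phys, sigma_log=0.1, seed=0,
                            gestational_days=[20])
        with pytest.raises(ValueError, match="conceptus"):
            TKCalibration(ds, phys=phys, mode="gd1")

    def test_posterior_without_data_tracks_prior(self, phys, chem_cis_gd1):
        """Empty dataset: posterior means of truncated-normal parameters sit
        within 10% of their prior means."""
        import pandas as pd

        from permpbpk import TKDataset
        from permpbpk.study import _COLUMNS

        empty = TKDataset(pd.DataFrame(columns=_COLUMNS))
        params = ("cl_liv", "k_si", "pc_brain")
        cal = TKCalibration(empty, phys=phys, mode="gd1", isomers=("cis",),
                            params_to_estimate={"cis": params},
                            base_params={"cis": chem_cis_gd1})
        res = cal.fit(n_chains=2, n_iter=800, retain=400, thin=2, seed=2)
        for p in params:
            prior_mean = PRIORS["cis"][p].frozen_dist().mean()
            assert res.posterior_mean[f"cis.{p}"] == pytest.approx(prior_mean, rel=0.10)

    def test_draws_respect_prior_bounds(self, phys, chem_cis_gd1):
        ds = generate_study({"cis": chem_cis_gd1}, phys,
                            design=StudyDesign(n_per_group=1), sigma_log=0.15,
                            seed=6, gestational_days=[1])
        params = ("cl_liv", "k_fec")
        cal = TKCalibration(ds, phys=phys, mode="gd1", isomers=("cis",),
                            params_to_estimate={"cis": params},
                            base_params={"cis": chem_cis_gd1})
        res = cal.fit(n_chains=2, n_iter=400, retain=200, thin=2, seed=3)
        flat = res.chains.reshape(-1, 2)
        for j, p in enumerate(params):
            spec = PRIORS["cis"][p]
            assert flat[:, j].min() >= spec.lower and flat[:, j].max() <= spec.upper
        # summary table carries every sampled parameter
        s = res.summary()
        assert list(s.index) == ["cis.cl_liv", "cis.k_fec"]
        assert {"mean", "rhat"} <= set(s.columns)

    def test_sampled_fixed_parameter_rejected(self, phys, chem_cis_gd1):
        import pandas as pd

        from permpbpk import TKDataset
        from permpbpk.study import _COLUMNS

        empty = TKDataset(pd.DataFrame(columns=_COLUMNS))
        with pytest.raises(ValueError, match="fixed"):
            TKCalibration(empty, phys=phys, mode="gd1", isomers=("cis",),
                          params_to_estimate={"cis": ("k_ai",)})
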