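"""Posterior sampling: recovery, determinism, substantiality, diagnostics, PPC."""

import numpy as np
import pandas as pd
import pytest

import traitselect as ts
from traitselect.inference import (SamplerConfig, effective_sample_size, fit,
                                   fit_species_mean_model,
                                   posterior_predictive_check, split_rhat,
                                   substantiality)
from traitselect.model_builder import build

FAST = SamplerConfig(chains=2, warmup=300, samples=300)


class TestFit:
    def test_intercept_recovery(self, intercept_gamma_fit):
        """Posterior means within 3 posterior SDs of the generating values."""
        res = intercept_gamma_fit
        assert res.ok, res.warnings_
        b0 = res.flat("mu:beta0")
        g0 = res.flat("disp:gamma0")
        assert abs(b0.mean() - np.log(10.0)) < 3 * b0.std()
        assert abs(g0.mean() - np.log(0.2)) < 3 * g0.std()

    def test_determinism(self, intercept_gamma_data):
        spec = build("M_com0", "EL", intercept_gamma_data)
        a = fit(spec, FAST, seed=5)
        b = fit(spec, FAST, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_loglik_matrix_shape_and_diagnostics(self, intercept_gamma_fit):
        res = intercept_gamma_fit
        assert res.loglik.shape == (res.n_draws, res.spec.n_obs)
        assert set(res.rhat) == set(res.param_names)
        assert all(np.isfinite(v) for v in res.ess.values())

    def test_rhat_cross_check_against_arviz(self, intercept_gamma_fit):
        az = pytest.importorskip("arviz")
        res = intercept_gamma_fit
        j = res.param_names.index("mu:beta0")
        x = res.draws[:, :, j]
        ours = split_rhat(x)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(x[..., None]),
                                          method="split").x.values).squeeze())
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_ess_sane_for_iid_draws(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 500))
        ess = effective_sample_size(x)
        assert 1000 < ess <= 2000
        assert split_rhat(x) < 1.01


class TestSubstantiality:
    def _result_with_draws(self, spec, name_to_draws, base_result):
        res = base_result
        names = list(name_to_draws)
        c = 2
        draws = np.stack(
            [np.asarray(v).reshape(c, -1) for v in name_to_draws.values()], axis=2
        )
        return ts.inference.PosteriorResult(
            spec=spec, draws=draws, param_names=names,
            loglik=res.loglik, unconstrained=res.unconstrained,
            rhat={}, ess={}, divergences=0, mean_accept=1.0, seed=0,
            sampler_config=res.sampler_config,
        )

    def test_degenerate_and_oracle_cases(self, intercept_gamma_fit):
        spec = intercept_gamma_fit.spec
        rng = np.random.default_rng(3)
        normal = rng.normal(0.05, 0.01, size=4000)
        res = self._result_with_draws(
            spec,
            {
                "mu:beta1_E[a]": np.zeros(4000),
                "mu:beta1_E[b]": np.full(4000, np.log(1.105)),
                "mu:beta1_E[c]": normal,
            },
            intercept_gamma_fit,
        )
        zero, pos, rnd = substantiality(res, "mu:beta1_E")
        assert (zero.ci_low, zero.ci_high) == (1.0, 1.0)
        assert not zero.substantial and zero.sign == 0
        assert pos.substantial and pos.sign == 1
        assert pos.exp_median == pytest.approx(1.105)
        # quantile oracle: equal-tailed interval from sorted draws
        srt = np.sort(np.exp(normal))
        lo = srt[int(np.floor(0.05 * 4000))]
        hi = srt[int(np.ceil(0.95 * 4000)) - 1]
        assert rnd.ci_low == pytest.approx(lo, rel=1e-3)
        assert rnd.ci_high == pytest.approx(hi, rel=1e-3)

    def test_beta_precision_slopes_inverted(self, toy_records, intercept_gamma_fit):
        """phi-slope exp > 1 (more precision) reads as dispersion < 1."""
        spec = build("M_com0", "LDMC", toy_records)
        res = self._result_with_draws(
            spec, {"disp:gamma1_E[a]": np.full(4000, 0.2)}, intercept_gamma_fit
        )
        [ss] = substantiality(res, "disp:gamma1_E")
        assert ss.exp_median == pytest.approx(np.exp(-0.2))
        assert ss.sign == -1

    def test_invalid_level_rejected(self, intercept_gamma_fit):
        with pytest.raises(ValueError):
            substantiality(intercept_gamma_fit, "mu:beta0", level=1.5)
        with pytest.raises(KeyError):
            substantiality(intercept_gamma_fit, "mu:nonexistent")


class TestPosteriorPredictive:
    def test_self_consistency(self, intercept_gamma_fit):
        """Data generated from the fitted model itself: rank not extreme."""
        rep = posterior_predictive_check(intercept_gamma_fit, "mean", n_rep=200, seed=0)
        assert len(rep) == 1
        assert 0.01 < rep["rank"].iloc[0] < 0.99

    def test_outlier_community_flagged(self, intercept_gamma_fit):
        """A community whose mean is shifted 5x away from the fitted model
        gets an extreme posterior-predictive rank."""
        import dataclasses

        res = intercept_gamma_fit
        spec_out = dataclasses.replace(res.spec, y=res.spec.y * 5.0)
        res_out = dataclasses.replace(res, spec=spec_out)
        rep = posterior_predictive_check(res_out, "mean", n_rep=200, seed=0)
        rank = rep["rank"].iloc[0]
        assert rank > 0.99 or rank < 0.01

    def test_unknown_statistic(self, intercept_gamma_fit):
        with pytest.raises(ValueError):
            posterior_predictive_check(intercept_gamma_fit, "kurtosis")


class TestSpeciesMeanModel:
    def test_shrinking_fit_produces_per_cell_constants(self, toy_records):
        sub = toy_records[toy_records["ecosystem"] == "bog"]
        fitted, res = fit_species_mean_model(
            sub, "EL", sampler_config=SamplerConfig(chains=2, warmup=250, samples=250,
                                                    rhat_threshold=1.05), seed=3
        )
        assert set(fitted) >= set(
            zip(sub["species"], sub["campaign"])
        )
        out = ts.species_mean_dataset(sub, "EL", fitted)
        assert out.groupby(["species", "campaign"])["EL"].std().fillna(0).max() == 0
        # fitted cell means shrink toward the data, staying in a sane range
        assert 0.2 * sub["EL"].mean() < np.mean(list(fitted.values())) < 5 * sub["EL"].mean()
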