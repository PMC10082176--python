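"""Jack/Master classification and dispersion-density covariation."""

import numpy as np
import pytest

from traitselect.inference import SlopeSummary
from traitselect.strategy import (classify, dispersion_density_covariation,
                                  strategy_table)


def ss(exp_median, substantial=None, name="slope"):
    """SlopeSummary shorthand; interval inferred from the median and flag."""
    if substantial is None:
        substantial = abs(np.log(exp_median)) > 1e-9
    if substantial:
        lo, hi = (exp_median * 0.9, exp_median * 0.99) if exp_median < 1 else (
            exp_median * 1.01, exp_median * 1.1)
        if exp_median < 1:
            lo, hi = exp_median * 0.95, exp_median * 1.02
            hi = min(hi, 0.999)
        else:
            lo, hi = max(exp_median * 0.98, 1.001), exp_median * 1.05
    else:
        lo, hi = 0.95, 1.05
    sign = 0 if not substantial else (1 if exp_median > 1 else -1)
    return SlopeSummary(parameter=name, exp_median=exp_median, ci_low=lo, ci_high=hi,
                        substantial=substantial, sign=sign,
                        raw_ci_low=np.log(lo), raw_ci_high=np.log(hi))


class TestClassify:
    def test_worked_sign_patterns(self):
        """Fixed slope summaries reproduce the canonical calls: a declining
        species is Master regardless of trait signs; stable ones are Jack."""
        # declining density, SLA mean down / dispersion up -> Master
        call = classify(
            {"SLA": {"mu": ss(0.93), "disp": ss(1.08)}},
            ss(0.85), species="sp_master", ecosystem="bog",
        )
        assert call.label == "Master" and call.density_class == "Decrease"
        assert call.trait_signs["SLA"] == {"mu": -1, "disp": 1}

        # stable density with trait variation -> Jack
        call = classify(
            {"LA": {"mu": ss(1.06)}, "EL": {"disp": ss(1.05)}},
            ss(1.0, substantial=False), species="sp_jack",
        )
        assert call.label == "Jack" and call.density_class == "Stable"

        # stable density, no trait variation at all -> still Jack
        call = classify(
            {"LA": {"mu": ss(1.0, False)}, "EL": {"mu": ss(1.0, False)}},
            ss(1.0, substantial=False), species="sp_quiet",
        )
        assert call.label == "Jack"
        assert all(v == 0 for d in call.trait_signs.values() for v in d.values())

    def test_substantial_increase_maps_to_jack_with_warning(self):
        with pytest.warns(RuntimeWarning, match="no named strategy"):
            call = classify({}, ss(1.2), species="sp_up")
        assert call.label == "Jack" and call.density_class == "Increase"

    def test_missing_density_slope_rejected(self):
        with pytest.raises(ValueError):
            classify({}, None)

    def test_permutation_invariance(self):
        species = [("a", 0.8), ("b", 1.0), ("c", 1.3)]
        calls = {
            sp: classify({}, ss(m, substantial=(m != 1.0)), species=sp)
            for sp, m in species
        }
        reversed_calls = {
            sp: classify({}, ss(m, substantial=(m != 1.0)), species=sp)
            for sp, m in reversed(species)
        }
        for sp, _ in species:
            assert calls[sp].label == reversed_calls[sp].label


class TestCovariation:
    def _calls(self, pairs):
        out = []
        for i, (disp_slope, dens_slope) in enumerate(pairs):
            call = classify(
                {"angle": {"mu": ss(1.0, False), "disp": ss(disp_slope,
                                                            substantial=True)}},
                ss(dens_slope, substantial=abs(np.log(dens_slope)) > 1e-9),
                species=f"sp{i}",
            )
            out.append(call)
        return out

    def test_exact_negative_linear_relation(self):
        pairs = [(1.0, 1.2), (1.1, 1.1), (1.2, 1.0)]
        rep = dispersion_density_covariation(self._calls(pairs), "angle")
        assert rep.rho == pytest.approx(-1.0)
        assert rep.slope == pytest.approx(-1.0, rel=1e-6)

    def test_degenerate_zero_variance(self):
        rep = dispersion_density_covariation(self._calls([(1.1, 0.9)] * 4), "angle")
        assert rep.degenerate and np.isnan(rep.rho)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            dispersion_density_covariation(self._calls([(1.0, 1.0)] * 2), "angle")

    def test_simulated_negative_covariation_recovered(self):
        """Species with wider trait dispersion decline more steeply."""
        rng = np.random.default_rng(0)
        signs = []
        for _ in range(20):
            disp = rng.uniform(0.95, 1.2, size=8)
            dens = 2.0 - disp + 0.03 * rng.standard_normal(8)
            rep = dispersion_density_covariation(
                self._calls(list(zip(disp, dens))), "angle")
            signs.append(rep.rho < 0)
        assert np.mean(signs) >= 0.95

    def test_draw_wise_interval(self):
        pairs = [(1.0, 1.15), (1.08, 1.05), (1.15, 0.95)]
        calls = self._calls(pairs)
        rng = np.random.default_rng(1)
        paired = {
            c.species: (
                np.log(c.trait_slopes["angle"]["disp"].exp_median)
                + 0.01 * rng.standard_normal(500),
                np.log(c.density_mu_slope.exp_median)
                + 0.01 * rng.standard_normal(500),
            )
            for c in calls
        }
        rep = dispersion_density_covariation(calls, "angle", paired_draws=paired)
        assert rep.rho_ci is not None
        assert rep.rho_ci[0] <= rep.rho <= rep.rho_ci[1] or rep.rho_ci[0] < 0


def test_strategy_table_shape():
    calls = [
        classify({"LA": {"mu": ss(1.05), "disp": ss(0.9)}}, ss(0.8), species="m1",
                 ecosystem="fen"),
        classify({"LA": {"mu": ss(1.0, False), "disp": ss(1.0, False)}},
                 ss(1.0, substantial=False), species="j1", ecosystem="bog"),
    ]
    tab = strategy_table(calls)
    assert len(tab) == 4  # two rows (mu, sigma/phi) per species
    m1 = tab[(tab["species"] == "m1") & (tab["parameter"] == "mu")].iloc[0]
    assert m1["strategy"] == "Master" and m1["density"] == "Decrease"
    assert m1["LA"] == "+"
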