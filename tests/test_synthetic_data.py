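"""Study-design and generative-model structure of the synthetic data."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitselect as ts
from traitselect.synthetic_data import (TRAITS, nearest_point_distances,
                                        species_mean_dataset)
from conftest import toy_config


class TestDesign:
    def test_default_design_counts(self):
        d = ts.make_design(seed=0)
        assert d.n_communities == 31
        assert d.n_records == 31 * 80
        richness = [c.richness for c in d.communities]
        assert min(richness) == 2 and max(richness) == 16
        per_eco = pd.Series([c.ecosystem for c in d.communities]).value_counts()
        assert sorted(per_eco) == [7, 8, 8, 8]
        assert per_eco["meadow"] == 7

    def test_community_membership_invariants(self):
        d = ts.make_design(seed=1)
        for c in d.communities:
            assert len(c.species) == c.richness
            assert len(set(c.species)) == c.richness
            assert c.rel_density.sum() == pytest.approx(1.0)
            assert 20.0 <= c.area_m2 <= 25.0

    def test_minimal_design(self):
        cfg = ts.DesignConfig(ecosystems=("solo",), communities_per_ecosystem=(1,),
                              richness_range=(2, 2), n_per_community=10,
                              richness_min_per_ecosystem=None, pool_size=5)
        d = ts.make_design(cfg, seed=0)
        assert d.n_communities == 1
        assert len(d.communities[0].species) == 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ts.make_design(ts.DesignConfig(richness_range=(1, 20)), seed=0)
        with pytest.raises(ValueError):
            ts.make_design(ts.DesignConfig(n_per_community=0), seed=0)

    def test_determinism(self):
        a = ts.make_design(seed=9).community_table()
        b = ts.make_design(seed=9).community_table()
        sa, sb = io.StringIO(), io.StringIO()
        a.to_csv(sa, index=False)
        b.to_csv(sb, index=False)
        assert sa.getvalue() == sb.getvalue()


class TestSimulateTraits:
    def test_records_satisfy_domains(self, toy_records):
        for trait, fam in TRAITS.items():
            v = toy_records[trait]
            if fam == "gamma":
                assert (v > 0).all()
            else:
                assert ((v > 0) & (v < 1)).all()
        assert set(toy_records["harvester"]) == {1, 2}
        assert toy_records["campaign"].value_counts().tolist() == [120, 120]

    def test_determinism(self, toy_design, toy_params):
        a = ts.simulate_traits(toy_design, toy_params, seed=4)
        b = ts.simulate_traits(toy_design, toy_params, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_intercept_only_mean(self):
        """All slopes/deviations zero: the sample mean recovers exp(beta0)."""
        cfg = toy_config(communities_per_ecosystem=(2, 2), n_per_community=2000)
        d = ts.make_design(cfg, seed=0)
        tp = ts.TraitParams(family="gamma", beta0=np.log(10.0), gamma0=np.log(0.3))
        recs = ts.simulate_traits(d, {"EL": tp}, seed=1, traits=["EL"])
        n = len(recs)
        se = 0.3 * 10.0 / np.sqrt(n)
        assert recs["EL"].mean() == pytest.approx(10.0, abs=3 * se)

    def test_mu_slope_recovered_by_regression(self):
        """log community means regressed on richness recover the mu-slope."""
        slope = np.log(1.05)
        cfg = ts.DesignConfig(ecosystems=("e1",), communities_per_ecosystem=(8,),
                              richness_range=(2, 16), n_per_community=12_500,
                              richness_min_per_ecosystem=None)
        d = ts.make_design(cfg, seed=0)
        tp = ts.TraitParams(family="gamma", beta0=np.log(5.0), gamma0=np.log(0.25),
                            beta1_E={"e1": float(slope)})
        recs = ts.simulate_traits(d, {"EL": tp}, seed=2, traits=["EL"])
        g = recs.groupby("richness")["EL"].mean()
        fitted = np.polyfit(g.index.to_numpy(float), np.log(g.to_numpy()), 1)[0]
        # SE of the regression slope from per-community Monte-Carlo error
        se_pts = 0.25 / np.sqrt(12_500)
        D = g.index.to_numpy(float)
        se_slope = se_pts / np.sqrt(np.sum((D - D.mean()) ** 2))
        assert fitted == pytest.approx(slope, abs=3 * se_slope)

    def test_positive_disp_slope_raises_cv_across_richness(self):
        cfg = ts.DesignConfig(ecosystems=("e1",), communities_per_ecosystem=(8,),
                              richness_range=(2, 16), n_per_community=4000,
                              richness_min_per_ecosystem=None)
        d = ts.make_design(cfg, seed=0)
        tp = ts.TraitParams(family="gamma", beta0=np.log(5.0), gamma0=np.log(0.2),
                            gamma1_E={"e1": float(np.log(1.05))})
        recs = ts.simulate_traits(d, {"EL": tp}, seed=3, traits=["EL"])
        cv = recs.groupby("richness")["EL"].agg(lambda v: v.std() / v.mean())
        assert cv.loc[16] > cv.loc[8] > cv.loc[2]

    def test_nonfinite_predictor_rejected(self, toy_design):
        tp = ts.TraitParams(family="gamma", beta0=np.inf)
        with pytest.raises(ValueError, match="EL"):
            ts.simulate_traits(toy_design, {"EL": tp}, seed=0, traits=["EL"])


class TestDistances:
    def test_mean_matches_poisson_closed_form(self):
        """E[d] = 1/(2 sqrt(lambda)); lambda=100 -> 5 cm."""
        d = nearest_point_distances(100.0, 10_000, area_m2=25.0, rng=0)
        se = d.std() / np.sqrt(d.size)
        assert d.mean() == pytest.approx(5.0, abs=3 * se)

    def test_rayleigh_goodness_of_fit(self):
        lam = 100.0
        d_m = nearest_point_distances(lam, 5000, area_m2=25.0, rng=1) / 100.0
        sigma = 1.0 / np.sqrt(2 * np.pi * lam)
        p = stats.kstest(d_m, stats.rayleigh(scale=sigma).cdf).pvalue
        assert p > 0.01

    def test_high_intensity_limit(self):
        d = nearest_point_distances(1e5, 500, rng=2)
        assert d.mean() < 0.5  # cm

    def test_determinism_and_errors(self, toy_records, toy_design):
        a = ts.simulate_point_plant_distances(toy_records, toy_design, 200.0, seed=5)
        b = ts.simulate_point_plant_distances(toy_records, toy_design, 200.0, seed=5)
        np.testing.assert_array_equal(a["distance_cm"], b["distance_cm"])
        assert (a["distance_cm"] > 0).all()
        with pytest.raises(ValueError):
            ts.simulate_point_plant_distances(toy_records, toy_design, -1.0, seed=0)
        with pytest.raises(ValueError):
            nearest_point_distances(0.0, 10)


class TestSpeciesMeanDataset:
    def test_replacement_and_invariance(self, toy_records):
        fitted = {
            (sp, camp): 1.0 + i
            for i, (sp, camp) in enumerate(
                toy_records.groupby(["species", "campaign"]).groups
            )
        }
        out = species_mean_dataset(toy_records, "EL", fitted)
        assert out.groupby(["species", "campaign"])["EL"].std().fillna(0).max() == 0.0
        pd.testing.assert_frame_equal(out.drop(columns="EL"),
                                      toy_records.drop(columns="EL"))

    def test_missing_species_rejected(self, toy_records):
        with pytest.raises(ValueError, match="missing"):
            species_mean_dataset(toy_records, "EL", {})
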