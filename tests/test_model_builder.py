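"""Candidate-model construction: terms, contrasts, nesting, focal filter."""

import numpy as np
import pytest

from traitselect.model_builder import (COMMUNITY_MODELS, SPECIES_MODELS, build,
                                       focal_species_filter)


def has_slope(names):
    return any("1_E[" in nm for nm in names)


class TestCommunityModels:
    def test_m_com3_column_count(self, toy_records):
        """mu side: intercept + campaign + (E-1) sum-to-zero deviations + E slopes."""
        spec = build("M_com3", "EL", toy_records)
        E = toy_records["ecosystem"].nunique()
        C = toy_records["community"].nunique()
        assert spec.X_mu.shape[1] == 1 + 1 + (E - 1) + E
        assert spec.X_disp.shape[1] == 1 + 1 + (E - 1) + E
        by_side = {g.side: g for g in spec.groups}
        assert by_side["mu"].n_levels == C and by_side["disp"].n_levels == C

    @pytest.mark.parametrize(
        "name,mu_slope,disp_slope",
        [("M_com0", False, False), ("M_com1", True, False),
         ("M_com2", False, True), ("M_com3", True, True), ("M_com3p", True, True)],
    )
    def test_slope_terms_per_variant(self, toy_records, name, mu_slope, disp_slope):
        spec = build(name, "EL", toy_records)
        assert has_slope(spec.names_mu) is mu_slope
        assert has_slope(spec.names_disp) is disp_slope
        assert spec.species_block is None

    def test_sum_to_zero_contrasts(self, toy_records):
        spec = build("M_com3", "EL", toy_records)
        dev_cols = [j for j, nm in enumerate(spec.names_mu) if "_E[" in nm and "1_E[" not in nm]
        col = spec.X_mu[:, dev_cols[0]]
        assert set(np.unique(col)) <= {-1.0, 0.0, 1.0}
        # deviations of all ecosystems sum to zero row-wise by construction:
        # the implied last-level coefficient is minus the sum of the others
        assert abs(col.sum()) <= len(col)

    def test_nesting_zeroed_slopes_reproduce_smaller_model(self, toy_records):
        """M_com0's predictor equals M_com3's with slope coefficients at zero."""
        small = build("M_com0", "EL", toy_records)
        large = build("M_com3", "EL", toy_records)
        shared = [large.names_mu.index(nm) for nm in small.names_mu]
        rng = np.random.default_rng(0)
        b_small = rng.normal(size=small.X_mu.shape[1])
        b_large = np.zeros(large.X_mu.shape[1])
        b_large[shared] = b_small
        np.testing.assert_allclose(large.X_mu @ b_large, small.X_mu @ b_small)


class TestSpeciesModels:
    @pytest.mark.parametrize(
        "name,block_components,mu_eco,disp_eco",
        [
            ("M_sp0", {("mu", "dev"), ("disp", "dev")}, True, True),
            ("M_sp1", {("mu", "dev"), ("disp", "dev"), ("mu", "slope")}, False, True),
            ("M_sp2", {("mu", "dev"), ("disp", "dev"), ("disp", "slope")}, True, False),
            ("M_sp3", {("mu", "dev"), ("disp", "dev"), ("mu", "slope"),
                       ("disp", "slope")}, False, False),
        ],
    )
    def test_species_variants(self, toy_focal, name, block_components, mu_eco, disp_eco):
        records, _ = toy_focal
        spec = build(name, "EL", records)
        assert set(spec.species_block.components) == block_components
        assert has_slope(spec.names_mu) is mu_eco
        assert has_slope(spec.names_disp) is disp_eco

    def test_density_model_structure(self, toy_focal):
        records, _ = toy_focal
        dens = records.groupby(["ecosystem", "community", "species", "richness"],
                               as_index=False).size()
        dens["dens"] = 10.0 + dens["size"]
        spec = build("M_dens", "dens", dens)
        assert spec.family.name == "gamma"
        assert all("T2" not in nm for nm in spec.names_mu + spec.names_disp)
        assert set(spec.species_block.components) == {("mu", "dev"), ("disp", "dev"),
                                                      ("mu", "slope"), ("disp", "slope")}

    def test_too_few_species_rejected(self, toy_records):
        one_sp = toy_records[toy_records["species"] == toy_records["species"].iloc[0]]
        with pytest.raises(ValueError, match="focal species"):
            build("M_sp3", "EL", one_sp)


def test_unknown_model_and_trait_rejected(toy_records):
    with pytest.raises(ValueError, match="unknown model"):
        build("M_com9", "EL", toy_records)
    with pytest.raises(ValueError, match="unknown trait"):
        build("M_com0", "nope", toy_records)


def test_beta_clamping_counted(toy_records):
    data = toy_records.copy()
    data.loc[data.index[:3], "LDMC"] = 1.0
    spec = build("M_com0", "LDMC", data)
    assert spec.n_clamped == 3
    assert spec.y.max() < 1.0


class TestFocalFilter:
    def test_brute_force_oracle(self, toy_records):
        """Retained set equals an independent scan of the occurrence table."""
        _, retained = focal_species_filter(toy_records)
        expected = set()
        for eco in toy_records["ecosystem"].unique():
            sub = toy_records[toy_records["ecosystem"] == eco]
            lo, hi = sub["richness"].min(), sub["richness"].max()
            for sp in sub["species"].unique():
                rows = sub[sub["species"] == sp]
                coms = set(rows["community"])
                if len(coms) < 4:
                    continue
                if lo in set(rows["richness"]) and hi in set(rows["richness"]):
                    expected.add((eco, sp))
        assert set(retained) == expected

    def test_threshold_cases(self):
        import pandas as pd

        rows = []
        # species "rare" in 3 communities; "wide" in 5 spanning both extremes
        for i, D in enumerate([2, 4, 6, 8, 10]):
            rows.append(dict(ecosystem="e", community=f"c{i}", richness=D, species="wide"))
            if i < 3:
                rows.append(dict(ecosystem="e", community=f"c{i}", richness=D, species="rare"))
        recs = pd.DataFrame(rows)
        _, retained = focal_species_filter(recs)
        assert ("e", "wide") in retained
        assert ("e", "rare") not in retained
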