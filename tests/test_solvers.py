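"""Nested energy-balance solvers: PT initialization, radiometric
decomposition, conservation, recovery and the two-source limit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threeseb import (
    OpticsConfig,
    SyntheticScenario,
    align_canopy,
    generate_dataset,
    solve_3seb,
    solve_tseb,
)
from threeseb.canopy import beam_extinction_kb, fraction_viewed
from threeseb.solvers import compose_trad, decompose_trad, pt_canopy_flux


class TestPTCanopyFlux:
    def test_worked_arithmetic(self):
        # Rn=400, alpha=1.26, fg=1, Delta/(Delta+gamma)=0.7
        le, h = pt_canopy_flux(400.0, 1.0, 1.26, 0.7, 0.3)
        assert le == pytest.approx(352.8)
        assert h == pytest.approx(47.2)

    def test_senescent_layer(self):
        le, h = pt_canopy_flux(400.0, 0.0, 1.26, 0.7, 0.3)
        assert le == 0.0 and h == 400.0

    def test_alpha_floor(self):
        le, _ = pt_canopy_flux(400.0, 1.0, 0.0, 0.7, 0.3)
        assert le == 0.0

    def test_negative_rn_does_not_condense(self):
        le, h = pt_canopy_flux(-30.0, 1.0, 1.26, 0.7, 0.3)
        assert le == 0.0 and h == -30.0


class TestRadiometricDecomposition:
    def test_isothermal(self):
        assert compose_trad(0.5, 300.0, 300.0) == pytest.approx(300.0, abs=1e-12)

    def test_fourth_power_mean(self):
        assert compose_trad(0.5, 305.0, 295.0) == pytest.approx(300.1, abs=0.05)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        f=st.floats(0.0, 0.98),
        t_layer=st.floats(260.0, 330.0),
        t_below=st.floats(260.0, 330.0),
    )
    def test_roundtrip_identity(self, f, t_layer, t_below):
        t_comp = compose_trad(f, t_layer, t_below)
        back = decompose_trad(t_comp, f, t_layer)
        assert back == pytest.approx(t_below, abs=1e-9)

    def test_negative_radicand_raises(self):
        with pytest.raises(ValueError, match="radicand"):
            decompose_trad(280.0, 0.9, 340.0)

    def test_clip_mode_flags(self):
        t, bad = decompose_trad(np.array([280.0]), np.array([0.9]),
                                np.array([340.0]), clip=True)
        assert bad[0] and t[0] == pytest.approx(280.0)


def solve_summer(summer_scene, model="3seb"):
    scenario, met, _, canopy_h, scene, cfg = summer_scene
    fn = solve_3seb if model == "3seb" else solve_tseb
    return fn(met, scene["t_rad"].to_numpy(), canopy_h, cfg)


class TestSolve3SEB:
    def test_per_source_balance_closes(self, summer_scene):
        fx = solve_summer(summer_scene)
        m = fx["daytime"] & fx["converged"]
        assert np.abs(fx.loc[m, "rn_ov"] - fx.loc[m, "h_ov"] - fx.loc[m, "le_ov"]).max() <= 0.1
        assert np.abs(fx.loc[m, "rn_un"] - fx.loc[m, "h_un"] - fx.loc[m, "le_un"]).max() <= 0.1
        assert np.abs(
            fx.loc[m, "rn_soil"] - fx.loc[m, "h_soil"] - fx.loc[m, "g"] - fx.loc[m, "le_soil"]
        ).max() <= 0.1

    def test_radiometric_recomposition(self, summer_scene):
        scenario, met, _, canopy_h, scene, cfg = summer_scene
        fx = solve_summer(summer_scene)
        m = (fx["daytime"] & fx["converged"]).to_numpy()
        kb0 = float(beam_extinction_kb(0.0, cfg.structure.x_lad_vine))
        f_ov = np.clip(fraction_viewed(
            canopy_h["lai_vine"].to_numpy(), canopy_h["omega_vine"].to_numpy(), kb0
        ), 0, 0.99)
        f_un = np.clip(fraction_viewed(
            canopy_h["lai_cc"].to_numpy(), canopy_h["omega_cc"].to_numpy(), kb0
        ), 0, 0.99)
        t_sub = compose_trad(f_un[m], fx.loc[m, "t_un"], fx.loc[m, "t_soil"])
        t_back = compose_trad(f_ov[m], fx.loc[m, "t_ov"], t_sub)
        assert np.abs(t_back - scene.loc[m, "t_rad"].to_numpy()).max() <= 0.01

    def test_no_daytime_condensation(self, summer_scene):
        fx = solve_summer(summer_scene)
        m = fx["daytime"] & fx["converged"]
        le = fx.loc[m, ["le_ov", "le_un", "le_soil"]].to_numpy()
        assert le.min() >= -1e-6

    def test_alpha_bounded_by_default(self, summer_scene):
        fx = solve_summer(summer_scene)
        m = fx["daytime"]
        assert fx.loc[m, "alpha_ov"].max() <= 1.26 + 1e-12
        assert fx.loc[m, "alpha_un"].max() <= 1.26 + 1e-12
        assert fx.loc[m, "alpha_ov"].min() >= 0.0

    def test_bit_identical_determinism(self, summer_scene):
        fx1 = solve_summer(summer_scene)
        fx2 = solve_summer(summer_scene)
        pd.testing.assert_frame_equal(fx1, fx2)

    def test_night_rows_missing(self, summer_scene):
        fx = solve_summer(summer_scene)
        night = ~fx["daytime"]
        assert night.any()
        assert fx.loc[night, "le_ov"].isna().all()

    def test_forward_inverse_recovery(self, summer_scene):
        """Noiseless scenes are recovered within the solver tolerances."""
        scenario, met, _, canopy_h, scene, cfg = summer_scene
        fx = solve_summer(summer_scene)
        m = (fx["daytime"] & fx["converged"]).to_numpy()
        assert m.sum() > 200
        total = (
            fx.loc[m, ["le_ov", "le_un", "le_soil"]].sum(axis=1)
            - scene.loc[m, ["le_ov_true", "le_un_true", "le_soil_true"]].sum(axis=1)
        )
        assert total.abs().max() <= 5.0
        for mod_col, true_col in (
            ("le_ov", "le_ov_true"), ("le_un", "le_un_true"), ("le_soil", "le_soil_true")
        ):
            err = (fx.loc[m, mod_col] - scene.loc[m, true_col]).abs().max()
            assert err <= 10.0, mod_col


class TestZeroAvailableEnergy:
    def test_isothermal_dark_surface(self):
        """T_rad = T_A and zero absorbed energy gives zero fluxes."""
        scenario = SyntheticScenario(seed=5, days=2, start="2019-06-01")
        cfg = scenario.to_site_config()
        # optically dead surface: nothing absorbed in any band
        cfg.optics = OpticsConfig(
            leaf_abs_par=0.0, leaf_abs_nir=0.0, soil_albedo=1.0,
            emiss_veg=1.0, emiss_soil=1.0,
        )
        from threeseb.synthetic import generate_met, generate_lai_season, truth_canopy

        met = generate_met(scenario)
        t_a = met["t_a"].to_numpy()
        met["l_in"] = 5.670374419e-8 * t_a ** 4  # sky at air temperature
        canopy_d = truth_canopy(generate_lai_season(scenario), cfg)
        canopy_h = align_canopy(canopy_d, met["timestamp"])
        fx = solve_3seb(met, t_a.copy(), canopy_h, cfg)
        m = fx["daytime"] & fx["converged"]
        assert m.sum() > 0
        for col in ("h_ov", "h_un", "h_soil", "le_ov", "le_un", "le_soil"):
            assert fx.loc[m, col].abs().max() < 1e-3, col


class TestTwoSourceLimit:
    def test_tseb_equals_3seb_without_cover_crop(self):
        scenario = SyntheticScenario(seed=9, days=40, start="2019-05-01",
                                     cc_present=False)
        met, canopy_d, scene = generate_dataset(scenario)
        canopy_h = align_canopy(canopy_d, met["timestamp"])
        cfg = scenario.to_site_config()
        t_rad = scene["t_rad"].to_numpy()
        f3 = solve_3seb(met, t_rad, canopy_h, cfg)
        f2 = solve_tseb(met, t_rad, canopy_h, cfg)
        m = f3["daytime"].to_numpy()
        for col in ("le_ov", "le_un", "le_soil", "h_ov", "h_un", "h_soil", "g"):
            diff = np.abs(f3.loc[m, col].to_numpy() - f2.loc[m, col].to_numpy())
            assert np.nanmax(diff) <= 2.0, col

    def test_tseb_recovery_single_layer(self):
        scenario = SyntheticScenario(seed=10, days=20, start="2019-07-01",
                                     cc_present=False)
        met, canopy_d, scene = generate_dataset(scenario)
        canopy_h = align_canopy(canopy_d, met["timestamp"])
        cfg = scenario.to_site_config()
        fx = solve_tseb(met, scene["t_rad"].to_numpy(), canopy_h, cfg)
        m = (fx["daytime"] & fx["converged"]).to_numpy()
        total = (
            fx.loc[m, ["le_ov", "le_un", "le_soil"]].sum(axis=1)
            - scene.loc[m, ["le_ov_true", "le_un_true", "le_soil_true"]].sum(axis=1)
        )
        assert total.abs().max() <= 5.0

    def test_tseb_bare_dormant_surface(self):
        """Fully senesced surface (fg = 0 everywhere): no transpiration,
        the soil carries the whole turbulent exchange."""
        scenario = SyntheticScenario(seed=11, days=20, start="2019-01-01",
                                     cc_present=False)
        met, canopy_d, scene = generate_dataset(scenario)
        canopy_d = canopy_d.assign(fg_vine=0.0, fg_cc=0.0)
        canopy_h = align_canopy(canopy_d, met["timestamp"])
        fx = solve_tseb(met, scene["t_rad"].to_numpy(), canopy_h,
                        scenario.to_site_config())
        m = fx["daytime"] & fx["converged"]
        assert m.sum() > 0
        assert fx.loc[m, "le_ov"].abs().max() < 1e-9
        assert fx.loc[m, "le_un"].abs().max() < 1e-9
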