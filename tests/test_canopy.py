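"""LAI decomposition, phenology, extinction geometry and structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threeseb.canopy import (
    beam_extinction_kb,
    clumping_index,
    diffuse_transmittance,
    fraction_viewed,
    green_fraction,
    partition_lai,
    structural_params,
)
from threeseb.config import PhenologyConfig, StructureConfig


def daily_series(values, year=2019):
    idx = pd.date_range(f"{year}-01-01", periods=len(values), freq="1D")
    return pd.Series(values, index=idx)


class TestPartitionLai:
    def test_no_cover_crop(self):
        pheno = PhenologyConfig(cc_present=False)
        out = partition_lai(daily_series(np.full(365, 1.5)), pheno)
        assert np.all(out["lai_cc"] == 0.0)
        assert np.all(out["lai_vine"] == 1.5)

    def test_winter_floor(self):
        pheno = PhenologyConfig()
        out = partition_lai(daily_series(np.full(365, 0.6)), pheno)
        jan = out.iloc[10]
        assert jan["lai_cc"] == pytest.approx(0.6)
        assert jan["lai_vine"] == pytest.approx(0.4)  # woody floor

    def test_exponential_decay_closed_form(self):
        pheno = PhenologyConfig(decay_efolding_days=30.0)
        out = partition_lai(daily_series(np.full(365, 0.8)), pheno)
        doy = out.index.dayofyear
        at_bb = out.loc[doy == pheno.budbreak_doy, "lai_cc"].iloc[0]
        assert at_bb == pytest.approx(0.8, abs=1e-9)
        after = out.loc[doy == pheno.budbreak_doy + 30, "lai_cc"].iloc[0]
        assert after == pytest.approx(0.8 / np.e, abs=1e-6)

    def test_sum_invariant_and_floor_equality(self):
        rng = np.random.default_rng(0)
        eco = 0.5 + 1.5 * np.abs(np.sin(np.linspace(0, np.pi, 365))) + rng.normal(0, 0.05, 365)
        eco = np.clip(eco, 0.0, None)
        out = partition_lai(daily_series(eco), PhenologyConfig())
        total = out["lai_vine"] + out["lai_cc"]
        assert np.all(total >= out["lai_eco"] - 1e-12)
        floor_off = out["lai_vine"] > 0.4 + 1e-12
        np.testing.assert_allclose(
            total[floor_off], out["lai_eco"][floor_off], atol=1e-12
        )

    def test_continuity_at_transitions(self):
        pheno = PhenologyConfig()
        eco = 0.6 + 1.2 * np.exp(-((np.arange(365) - 200.0) / 60.0) ** 2)
        out = partition_lai(daily_series(eco), pheno)
        steps = np.abs(np.diff(out["lai_cc"].to_numpy()))
        # one daily decay step (of cc or of the regrowth gap eco - cc)
        # plus the ecosystem-LAI day-to-day change
        bound = np.abs(np.diff(eco)) + eco[:-1] / pheno.decay_efolding_days + 1e-9
        assert np.all(steps <= bound)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            partition_lai(daily_series([-0.1] * 365), PhenologyConfig())

    def test_partial_year_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            partition_lai(daily_series(np.full(60, 1.0)), PhenologyConfig())


class TestGreenFraction:
    def test_vine_seasonal_endpoints(self):
        pheno = PhenologyConfig()
        assert green_fraction(200, pheno, "vine") == pytest.approx(1.0, abs=0.01)
        assert green_fraction(15, pheno, "vine") == pytest.approx(0.0, abs=0.05)

    def test_cc_senescence_efolding(self):
        pheno = PhenologyConfig(cc_mow_doy=110, decay_efolding_days=21)
        fg = green_fraction(110 + 21, pheno, "cc")
        assert fg == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_bounds_everywhere(self):
        pheno = PhenologyConfig()
        doy = np.arange(1, 366)
        for layer in ("vine", "cc"):
            fg = green_fraction(doy, pheno, layer)
            assert np.all((fg >= 0) & (fg <= 1))

    def test_no_cc_means_zero(self):
        pheno = PhenologyConfig(cc_present=False)
        assert np.all(green_fraction(np.arange(1, 366), pheno, "cc") == 0.0)


def kb_quadrature_oracle(theta, x_lad, n=4000):
    """Brute-force mean projected leaf area of an ellipsoidal canopy.

    Integrates the Ross kernel over the ellipsoidal leaf-inclination
    density (normalized numerically), independent of the closed-form
    extinction formula.
    """
    alpha = (np.arange(n) + 0.5) * (np.pi / 2) / n
    dens = (
        2.0 * x_lad ** 3 * np.sin(alpha)
        / (np.cos(alpha) ** 2 + x_lad ** 2 * np.sin(alpha) ** 2) ** 2
    )
    dens /= np.sum(dens)

    def kernel(theta_s, a):
        cc = np.cos(theta_s) * np.cos(a)
        out = np.where(a <= np.pi / 2 - theta_s, cc, cc)
        graze = a > np.pi / 2 - theta_s
        if np.any(graze):
            with np.errstate(invalid="ignore", divide="ignore"):
                cosb = np.clip(1.0 / (np.tan(theta_s) * np.tan(a[graze])), -1, 1)
                b = np.arccos(cosb)
            out[graze] = cc[graze] * (1.0 + (2.0 / np.pi) * (np.tan(b) - b))
        return out

    g = np.sum(dens * kernel(theta, alpha.copy()))
    return g / np.cos(theta)


class TestBeamExtinction:
    def test_spherical_nadir(self):
        assert beam_extinction_kb(0.0, 1.0) == pytest.approx(0.4997, abs=5e-4)

    def test_strictly_increasing_in_theta(self):
        theta = np.linspace(0, 1.4, 50)
        kb = beam_extinction_kb(theta, 1.0)
        assert np.all(np.diff(kb) > 0)

    def test_below_horizon_rejected(self):
        with pytest.raises(ValueError):
            beam_extinction_kb(np.pi / 2, 1.0)

    @pytest.mark.parametrize("x_lad", [0.5, 1.0, 2.0])
    def test_angular_law_matches_quadrature(self, x_lad):
        """kb(theta) has the quadrature oracle's angular dependence to 1e-6.

        The closed form and the quadrature share the projected-area law
        up to the leaf-area normalization constant, so their ratio must
        be independent of zenith angle.
        """
        thetas = np.deg2rad([0.0, 20.0, 40.0, 60.0, 75.0])
        ratios = [
            float(beam_extinction_kb(t, x_lad)) / kb_quadrature_oracle(t, x_lad)
            for t in thetas
        ]
        assert np.max(ratios) / np.min(ratios) == pytest.approx(1.0, abs=1e-6)
        # absolute agreement is limited only by the published
        # normalization approximation (a few parts in 1e3)
        assert ratios[0] == pytest.approx(1.0, abs=5e-3)

    def test_spherical_60deg_value(self):
        # G = 0.5 for a spherical canopy: kb = 0.5 / cos(60 deg) = 1.0
        kb = beam_extinction_kb(np.deg2rad(60.0), 1.0)
        assert kb == pytest.approx(1.0, rel=2e-3)


class TestFractionViewed:
    @pytest.mark.parametrize(
        "lai,expected", [(0.0, 0.0), (2.0, 1.0 - np.exp(-1.0)), (1e4, 1.0)]
    )
    def test_closed_form_points(self, lai, expected):
        # kb * omega = 0.5 so kb*omega*F = lai/2
        assert fraction_viewed(lai, 1.0, 0.5) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        lai=st.floats(0, 10), omega=st.floats(0.01, 1.0), kb=st.floats(0.1, 3.0)
    )
    def test_bounds_and_monotonicity(self, lai, omega, kb):
        f = fraction_viewed(lai, omega, kb)
        assert 0.0 <= f < 1.0
        assert fraction_viewed(lai + 0.5, omega, kb) >= f


class TestDiffuseTransmittance:
    def test_zero_lai_transparent(self):
        assert diffuse_transmittance(0.0)[0] == pytest.approx(1.0, abs=1e-9)

    def test_monotone_decreasing(self):
        tau = diffuse_transmittance(np.linspace(0, 6, 30))
        assert np.all(np.diff(tau) < 0)

    def test_against_dense_quadrature(self):
        """10-node Gauss result matches a 2000-panel midpoint rule."""
        lai_eff = 1.7
        theta = (np.arange(2000) + 0.5) * (np.pi / 2) / 2000
        kb = beam_extinction_kb(np.minimum(theta, np.pi / 2 - 1e-9), 1.0)
        ref = 2.0 * np.sum(
            np.exp(-kb * lai_eff) * np.cos(theta) * np.sin(theta)
        ) * (np.pi / 2) / 2000
        assert diffuse_transmittance(lai_eff)[0] == pytest.approx(ref, rel=1e-4)


class TestStructure:
    def test_anchors_and_midpoint(self):
        st_cfg = StructureConfig()
        h_lo, w_lo = structural_params(0.4, st_cfg)
        h_hi, w_hi = structural_params(st_cfg.lai_vine_max, st_cfg)
        assert h_lo == pytest.approx(1.5) and h_hi == pytest.approx(2.2)
        assert w_lo == pytest.approx(st_cfg.wc_vine_min)
        mid_lai = 0.4 + (st_cfg.lai_vine_max - 0.4) / 2
        h_mid, _ = structural_params(mid_lai, st_cfg)
        assert h_mid == pytest.approx((1.5 + 2.2) / 2)

    def test_clipped_outside_anchors(self):
        st_cfg = StructureConfig()
        h, w = structural_params(10.0, st_cfg)
        assert h == pytest.approx(2.2) and w == pytest.approx(st_cfg.wc_vine_max)

    def test_clumping_homogeneous_limit(self):
        assert clumping_index(1.5, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_clumping_bounds_and_row_effect(self):
        omega_row = clumping_index(1.5, 0.4)
        assert 0.0 < omega_row < 1.0
        assert clumping_index(1.5, 0.8) > omega_row  # wider canopy less clumped
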