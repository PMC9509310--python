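"""Site, canopy and solver configuration.

Plain dataclasses with YAML (de)serialization.  Defaults describe a
semi-arid trellised vineyard with an east-west row system and a
perennial-grass interrow cover crop, the landscape the model targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PhenologyConfig:
    """Seasonal transition dates (day of year) and transition rates.

    The cover crop contributes all of the ecosystem LAI before vine
    bud-break and after vine leaf-off; in between it senesces with an
    exponential e-folding decay and regrows exponentially after
    leaf-off.  The vine LAI is floored at ``lai_vine_floor`` year-round
    to represent woody cordon/trunk elements.
    """

    budbreak_doy: int = 80
    leafoff_doy: int = 310
    cc_mow_doy: int = 110
    cc_regrow_doy: int = 310
    decay_efolding_days: float = 21.0
    lai_vine_floor: float = 0.4
    cc_present: bool = True

    def __post_init__(self):
        for name in ("budbreak_doy", "leafoff_doy", "cc_mow_doy", "cc_regrow_doy"):
            v = getattr(self, name)
            if not 1 <= v <= 366:
                raise ValueError(f"{name}={v} outside [1, 366]")
        if self.budbreak_doy >= self.leafoff_doy:
            raise ValueError("budbreak_doy must precede leafoff_doy")
        if self.decay_efolding_days <= 0:
            raise ValueError("decay_efolding_days must be positive")


@dataclass
class StructureConfig:
    """Canopy structural parameters and their LAI scaling anchors."""

    row_width: float = 3.35          # m, row spacing
    hc_vine_min: float = 1.5         # m, dormant (cordon) height
    hc_vine_max: float = 2.2         # m, peak-season height
    wc_vine_min: float = 0.15        # canopy-to-row-width fraction, woody minimum
    wc_vine_max: float = 0.55        # peak-season fraction
    lai_vine_max: float = 2.5        # LAI at which hc/wc reach their maxima
    hc_cc: float = 0.35              # m, cover-crop height
    wc_cc: float = 1.0               # cover crop spans the interrow
    x_lad_vine: float = 1.0          # ellipsoidal leaf-angle parameter (spherical)
    x_lad_cc: float = 1.0
    leaf_width_vine: float = 0.10    # m
    leaf_width_cc: float = 0.02      # m


@dataclass
class OpticsConfig:
    """Layer optical properties for the two-band radiative transfer."""

    par_fraction: float = 0.45       # PAR share of global shortwave
    leaf_abs_par: float = 0.85       # leaf absorptivity, visible band
    leaf_abs_nir: float = 0.20       # leaf absorptivity, near-infrared band
    soil_albedo: float = 0.15
    emiss_veg: float = 0.98          # for longwave exchange
    emiss_soil: float = 0.95
    emiss_trad: float = 1.0          # blackbody assumption for T_rad retrieval


@dataclass
class ResistanceConfig:
    """Monin-Obukhov and boundary-layer resistance coefficients."""

    d_ratio: float = 0.65            # displacement height / canopy height
    z0m_ratio: float = 0.125         # momentum roughness / canopy height
    kb_inv: float = 2.0              # kB^-1 = ln(z0m/z0h)
    c_prime: float = 90.0            # s^1/2 m^-1, bulk canopy coefficient
    leaf_size: float = 0.01          # m, effective leaf dimension in R_x
    b_coeff: float = 0.012           # forced-convection soil coefficient
    c_coeff: float = 0.0025          # free-convection soil coefficient
    u_floor: float = 0.1             # m s-1, wind speed floor
    l_min: float = 1.0               # m, |Obukhov length| floor


@dataclass
class SolverConfig:
    """Priestley-Taylor initialization and iteration controls."""

    alpha_pt_max: float = 1.26
    alpha_step: float = 0.1
    max_alpha_rounds: int = 35
    max_inner_iter: int = 20
    t_tol: float = 0.01              # K, component-temperature convergence
    l_rel_tol: float = 1.0e-3        # relative Obukhov-length convergence
    g_ratio: float = 0.35            # G = g_ratio * Rn_soil


@dataclass
class SiteConfig:
    """Full model set-up for one tower site."""

    latitude: float = 36.85
    longitude: float = -120.2
    z_u: float = 5.0                 # m, wind measurement height
    z_t: float = 5.0                 # m, temperature measurement height
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    resistance: ResistanceConfig = field(default_factory=ResistanceConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "SiteConfig":
        kwargs = dict(data)
        for name, sub in (
            ("phenology", PhenologyConfig),
            ("structure", StructureConfig),
            ("optics", OpticsConfig),
            ("resistance", ResistanceConfig),
            ("solver", SolverConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
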