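# Methods

## Model structure

`threeseb` solves the surface energy balance of a vineyard as three
coupled sources — overstory (vine foliage plus woody elements),
understory (interrow cover crop) and soil — in a nested framework.

**Parallel overstory step.** The overstory exchanges heat directly with
the air above the canopy: H_ov = ρc_p (T_ov − T_A)/R_A, with R_A from
Monin–Obukhov similarity (Dyer–Businger stability functions). Its
latent heat starts from the Priestley–Taylor form
LE_ov = α_PT f_g Δ/(Δ+γ) max(Rn_ov, 0); T_ov follows from H_ov, and the
substrate temperature T_sub is obtained by inverting the fourth-power
radiometric composition of T_rad given T_ov.

**Series substrate step.** The substrate (cover crop + soil) couples
through R_A + R_sub; its sensible heat fixes the canopy-air-space
temperature T_AC. The understory gets its own Priestley–Taylor flux and
a temperature through the bulk canopy resistance R_x; the soil
temperature follows from a second radiometric inversion of T_sub, its
sensible heat through R_s, and the soil latent heat closes the balance
as the residual LE_soil = Rn_soil − H_soil − G with G = 0.35 Rn_soil
(a measured-G passthrough mode exists).

**α iteration.** Both layers start at α_PT = 1.26. Whenever the
residual soil latent heat turns negative (daytime condensation), α of
the understory is reduced by 0.1 — the understory is reduced first
because its flux acts directly on the substrate balance; the overstory
follows once the understory reduction can no longer change the solution
(α at zero, or a senesced/unlit layer). If both α are exhausted and
LE_soil is still negative, LE_soil is pinned to zero, H_soil rebalanced,
and the record flagged (`reason = 1`). The α ordering is a documented
heuristic; nothing in the formulation dictates it.

Because T_sub and T_soil always come from the radiometric inversions,
the recomposition of the solved component temperatures reproduces the
input T_rad to machine precision on every converged record, and each
source's balance closes identically — the conservation tests assert
≤ 0.1 W/m² and ≤ 0.01 K but the construction is exact.

**TSEB baseline.** `solve_tseb` is the two-source specialization of the
same network: one bulk canopy (LAI summed over both layers, LAI-weighted
green fraction, structure rescaled through the same empirical maps) in
the overstory position, soil as the substrate, understory zeroed. This
choice — rather than an independently coded classical series TSEB —
makes the structural limit exact: with the cover crop absent, 3SEB and
TSEB agree bit-for-bit, which is the property the comparison tests rely
on, and the two models differ only by what the three-source structure
adds.

## Radiative transfer

Net radiation is partitioned with a layered Campbell–Norman-style
scheme: two shortwave bands (PAR fraction 0.45, leaf absorptivities
0.85/0.20, soil albedo 0.15), Beer's-law beam extinction with the
ellipsoidal k_b(θ) and a clumping index, hemispherical Gauss quadrature
(10 nodes) for the diffuse extinction, and single-scatter redistribution
(half up, half down) of non-absorbed intercepted radiation. Longwave
exchange uses the same interceptances with layer emissivities 0.98
(vegetation) and 0.95 (soil); the T_rad retrieval itself assumes a
blackbody (ε = 1, configurable). The final upward reflection residue
exits to the sky rather than bouncing again; this truncation keeps the
bookkeeping exact — the per-layer sum equals SW_in − SW_out + L_in −
L_out to machine precision — at the cost of (1−ε) ≈ 2 % errors absorbed
into the outgoing streams. The vine clumping index is derived from row
geometry by matching the gap probability of a rectangular hedgerow whose
foliage occupies the canopy-width fraction of the row; the cover crop is
treated as horizontally homogeneous (Ω = 1).

G = 0.35 Rn_soil is applied at all solved (daytime) hours; no diurnal
ground-heat-flux model is attempted, a known limitation of constant-
ratio formulations in semi-arid systems.

## Resistances

R_A follows the stability-corrected log law with d = 0.65 h_c,
z₀m = 0.125 h_c, kB⁻¹ = 2. R_x and R_s use the Kustas–Norman convective
forms with C′ = 90 s^½ m⁻¹, s = 0.01 m, b = 0.012, c = 0.0025; R_sub is
an R_s-type resistance evaluated with the wind at the substrate
(understory canopy top) level — the substrate resistance is defined in
the source formulation only by its role, so this form is a documented
substitution. In-canopy wind decays exponentially with a Goudriaan
attenuation coefficient (0.28 F^⅔ h^⅓ l_w^−⅓). Wind is floored at
0.1 m/s, |L| at 1 m; R_x is capped at 2000 s/m so that the understory
temperature offset H_un·R_x/ρc_p stays bounded as LAI_cc → 0 (H_un → 0
in that limit, so the cap never alters a resolved flux). The Obukhov
length iterates to a relative tolerance of 10⁻³ jointly with the flux
solution.

## Numerical behavior

The per-timestamp fixed point (radiation ↔ temperatures ↔ stability) is
solved vectorized over all daytime records with under-relaxation (0.6)
and a ±60/+80 K excursion clip on the canopy temperatures — both leave
the fixed point unchanged but suppress oscillations at low wind, where
the canopy-air coupling is stiff. Convergence requires component
temperatures stable to 0.01 K and the Obukhov length to 0.1 %; up to 35
α-adjustment rounds of up to 20 inner iterations each. Night-time rows
(SW ≤ 100 W/m², the strict daytime definition used throughout) are
skipped and reported missing. The solver is deterministic: identical
inputs give bit-identical output.

## LAI decomposition and phenology

Daily ecosystem LAI is split by phenology: the cover crop carries all of
LAI_eco before vine bud-break (default DOY 80) and after leaf-off
(DOY 310); from bud-break it decays exponentially (e-folding 21 d,
configurable — the transitions are exponential by design and the rate is
a site-tuning knob) until the day of maximum LAI_eco within the leaf-on
window ("peak summer", ties resolve to the latest day), holds its
senesced value, and regrows after leaf-off by exponential decay of the
gap LAI_eco − LAI_cc. LAI_vine is the remainder, floored at 0.4 m²/m²
year-round to represent woody elements; the floor feeds both the
radiative and the aerodynamic pathways. Green fractions are 1/0 with
exponential transitions on the same e-folding time; vine height and
width fraction interpolate linearly in LAI between dormant (1.5 m) and
peak (2.2 m) anchors; the cover crop is fixed at h_c = 0.35 m spanning
the interrow.

## Synthetic data

The generator emulates a semi-arid Central-Valley vineyard year:
a half-sine clear-sky shortwave course between sunrise and sunset
peaking at 950 W/m², air temperature as seasonal (±9 K) plus diurnal
(±7 K, lagged 2 h after solar noon) cosines around 290 K, near-constant
humidity (1 kPa) and wind (2.5 m/s) with instrument-scale Gaussian
noise (0.05 kPa, 0.3 m/s), Brutsaert clear-sky incoming longwave, and a
vine/cover-crop LAI climatology (vine peak 2.0, CC peak 0.8, winter
plateau 0.6 m²/m², 10 % multiplicative daily noise). All randomness is
seeded; series are bit-reproducible.

`forward_scene` closes the loop: given prescribed Priestley–Taylor
coefficients (default 1.26, unstressed) and a soil evaporative fraction
(default 0.3 of the soil's available energy), it solves the model's own
network equations forward for the component temperatures and composes
T_rad (emitted as L_out = σT_rad⁴), so that the solvers recover the
prescription on a noiseless scene to well under the stated 5/10 W/m²
bounds. The soil-temperature update is treated implicitly against the
soil's own thermal emission (d Rn_soil/d T_soil = −4εσT³): at low wind
the explicit fixed point has a loop gain of order 10–40 and diverges,
while the linearized-implicit update is unconditionally stable and
leaves the converged state exactly on the resistance equation. An
optional Gaussian perturbation of T_rad (0.5 K nominal) emulates
radiometer noise.

What the generator does **not** emulate: clouds and synoptic
variability, soil-moisture stress (α_PT is prescribed, not emergent),
advection from neighboring stands, energy-balance non-closure or flux
footprints of real eddy-covariance towers. Passing the recovery tests
therefore demonstrates that the inverse model is consistent with its
forward physics and robust to radiometric noise — not that it matches
real vineyard observations.

## Evaluation and aggregation

`compute_metrics` reports RMSD, mean bias (model − observed),
Nash–Sutcliffe efficiency and Pearson r with pairwise deletion.
Daily T/ET is the ratio of daily daytime sums (not the mean of hourly
ratios, which is unstable on low-ET days); seasonal aggregation uses
fixed DOY windows (≤ 90, 90–150, 150–330, > 330) and annual statistics
weight days equally. Volumetric ET integrates LE·Δt/λ(T_A) with the
temperature-dependent latent heat; missing (night) records contribute
zero flux.

The energy-balance closure ensemble for "observed" turbulent fluxes
averages, per timestamp, the unclosed fluxes, the residual-to-LE
correction, and the Bowen-ratio correction (skipped where LE = 0 or
β ≈ −1); per-timestamp rather than aggregate application is a
documented choice.

## Known limitations

- The constant G ratio and the leaf-area-based structural relations are
  site-tuned simplifications; both are config knobs.
- The substrate resistance formulation is by-role, not by-reference.
- Priestley–Taylor initialization cannot represent strong stomatal
  control under high vapor-pressure deficit; α only ever decreases from
  1.26, so stress appears as energy-balance violations rather than as
  physiology.
- The radiative transfer is one-dimensional per layer; row-resolving
  three-dimensional effects (sunlit/shaded interrow strips) are not
  represented beyond the clumping index and overstory shading of the
  understory.
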