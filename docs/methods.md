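# Methods

## The model

`scartherm` predicts the thermal response of hypertrophic scar (HPS) and
normal skin to a single pulsed-dye-laser exposure, and uses that
prediction to rank clinical dose settings.  It couples three standard
components:

1. **Volumetric heat source.**  The beam deposits heat as
   `Q(r, z, t) = mu_a (1 - R) Phi0 · G(r) · X(z) · E(t)`, with `G(r) =
   exp(-2 r^2 / w^2)` the radial profile of a Gaussian beam of 1/e^2
   radius `w = omega0 / 2`, `X(z) = exp(-mu_t z)` Beer–Lambert decay
   with the total attenuation coefficient `mu_t = mu_a + mu_s`, and
   `E(t)` a Gaussian pulse envelope centred at `t = tau`.  The peak flux
   is `Phi0 = 2P / (pi w^2)`, the on-axis peak of a Gaussian beam
   carrying power `P`.  A clinical dose `(q, tau, omega0)` converts to
   pulse energy `W = q s` (spot area `s = pi (omega0/2)^2`) and power
   `P = W / tau`.  Note these relations collapse to `Phi0 = 2 q / tau`:
   under fluence-specified dosing the on-axis flux — and hence the
   center temperature — does not depend on the spot diameter.
2. **Pennes bioheat transfer.**  `rho c dT/dt = div(k grad T) +
   rho_b c_b w_b (T_art - T) + Q` on an axisymmetric cylinder (20 mm
   diameter, 4 mm thick), with a convective top surface
   (`h = 10 W/(m^2 K)` to 25 °C ambient), fixed 37 °C bottom and outer
   boundaries, and a symmetry axis.  An enlarged vessel (1.0 mm
   diameter in scar, 0.6 mm in normal skin, 2.0 mm deep) is a coaxial
   cylinder carrying blood heat capacity; the perfusion sink acts
   everywhere.
3. **Arrhenius damage.**  `Omega(t) = ∫ A exp(-Ea / (R T)) dt` with
   `A = 4.575e72 s^-1`, `Ea = 4.71e5 J/mol`; burn degrees at
   Omega = 0.58 / 1.0 / 1e4.  The rate is evaluated in log space, so
   the huge frequency factor never overflows.

The dose study runs the factorial grid q ∈ {4, 7.5, 10} (printed unit
J/cm^3; numerically a fluence), tau ∈ {0.5, 4, 10} ms, omega0 ∈
{5, 6, 7} mm on the scar preset and selects the candidate maximizing
final scar damage subject to a 50 °C peak-temperature cap (the onset of
protein denaturation).  One-factor-at-a-time sweeps around the
reference dose (7.5, 4 ms, 7 mm) are available for trend studies.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| mu_a, mu_s, R (scar) | 5.574, 118.37 cm^-1, 0.2 | digitized tissue optics at the PDL wavelength |
| mu_a, mu_s, R (normal) | 1.395, 183.92 cm^-1, 0.58 | idem |
| rho, c, k (tissue closure) | 1200 kg/m^3, 3600 J/(kg K), 0.5 W/(m K) | standard dermal literature values; the optics table does not fix them, so they are user-overridable and a ±10% sensitivity generator ships with the package |
| rho_b, c_b, w_b | 1000, 4180, 6.4e-3 s^-1 | blood properties and perfusion rate of the Pennes sink |
| h | 10 W/(m^2 K) | natural convection in still air; nearly irrelevant at ≤1 s horizons |
| T0 = T_art, T1 | 37 °C, 25 °C | body and ambient temperature |
| damage threshold | Omega = 1.0 | conventional coagulation criterion for the thresholded volume fraction |
| selection threshold | 50 °C | protein-denaturation temperature cap |

Scar absorbs roughly 13× more of the incident beam than normal skin
(`mu_a (1-R)`: 4.46 vs 0.59 cm^-1), which is the selective-photothermolysis
mechanism the whole treatment rests on: the same dose that heats scar to
~50 °C raises normal skin by under 2 °C.

## Design choices where the design was open

**Pulse envelope normalization.**  A Gaussian envelope
`exp(-4 (t - tau)^2 / tau^2)` with amplitude `Phi0 = 2P/(pi w^2)` and
`P = W/tau` integrates to `sqrt(pi)/2 · tau ≈ 0.886 tau`, i.e. it
delivers only 88.6% of the prescribed pulse energy.  Because `q` is the
clinically dialled dose, the default envelope carries a `2/sqrt(pi)`
amplitude factor so one pulse delivers exactly `W`; the unnormalized
form (and a top-hat) remain available through `SourceOptions`, and the
energy bookkeeping routine reports the delivered fraction either way.
The choice matters: the admissible set of the 50 °C selection shifts
with an 11% energy rescaling, and only the energy-conserving default
reflects what the device label promises.

**Damage objective.**  At the temperatures this model reaches (≤ ~56 °C
for under a second), Omega peaks around 1e-4: no cell crosses the
coagulation threshold, so a thresholded damaged-volume fraction is
identically zero for every candidate and cannot rank doses.  The
thresholded fraction is still computed and reported, but the selection
objective and the damage traces use the continuous quantity the rate
law actually predicts — the volume-averaged denatured fraction
`mean(1 - exp(-Omega))` over the scar region.  It is strictly monotone
in the temperature history, so dose orderings are well defined even in
the sub-coagulative regime.  (Its absolute values include the tiny
baseline accrual ~2e-7/s that Arrhenius kinetics predict at 37 °C;
this common offset cancels in all comparisons.)

**Probe convention.**  "Center temperature" is read at the axis cell
that is hottest at the end of the pulse — in practice the surface cell,
where absorption is strongest.  This is reproducible and
grid-convergent, unlike a hard-coded depth.

**Mesh grading.**  The optical penetration depth `1/mu_t` is ~81 µm in
scar, so the default axial mesh is geometrically graded from a 5 µm
surface cell (120 cells over 4 mm); the radial mesh is uniform at
0.1 mm.  A uniform axial option exists and is what the convergence and
manufactured-solution tests use.

**Time stepping.**  Backward Euler with 250 uniform steps across the
pulse window `[0, 2.5 tau]`, then geometric step growth (×1.3 per step,
capped at 50 ms) to the 1 s horizon.  The envelope is integrated
exactly (in erf form) over each step, so deposited energy is step-size
independent.  The damage integral is accumulated trapezoidally at every
solver step.  An explicit scheme exists for cross-checks and refuses
steps beyond its stability bound.

**Vessel properties.**  The vessel carries blood `rho c` but tissue
optics and conductivity; the tabulated optics are tissue-level and
nothing in them distinguishes the lumen.  A chromophore-selective
vessel (blood absorbing far more strongly at 585 nm) is a known
extension this model deliberately does not attempt.

## What the model predicts — and what it cannot

With the default closure the high-dose scar exposure (q = 10, 4 ms,
7 mm) peaks near 53 °C on the axis and relaxes to ~39.5 °C after one
second, while normal skin peaks near 39 °C; the constrained selection
over the factorial grid returns (7.5, 4 ms, 7 mm).  Peak temperature
rises strictly with energy density, and total scar damage grows with
spot diameter (a wider beam at fixed fluence treats more volume without
raising the center temperature).

Two trends sometimes claimed for this treatment are *not* reproducible
by a linear conduction model with fluence-specified dosing, and the
package makes no attempt to force them:

* the center peak temperature is independent of spot diameter (to
  within millikelvins of radial-conduction effect), because
  `Phi0 = 2q/tau` carries no `omega0`;
* a 0.5 ms pulse deposits the same energy faster than a 4 ms pulse and
  therefore peaks slightly hotter and accrues slightly *more* Arrhenius
  damage — a damage maximum at intermediate pulse width cannot arise
  without nonlinearity (e.g. chromophore-selective vessel heating
  bounded by thermal relaxation, or optical property changes during the
  pulse).  The corresponding property tests assert the claimed trends
  and are left failing by design, as a record of the discrepancy.

## Numerical verification

* Manufactured solution `T* = 37 + beta(t)(1-(r/R)^2) sin(pi z/D)`
  recovers second-order spatial convergence of the finite-volume
  operator.
* Zero-source equilibria are exact fixed points; the discrete maximum
  principle holds without sources (backward Euler on an M-matrix).
* Constant-temperature damage matches the closed form
  `A t exp(-Ea/(R T))` to 1e-6 relative.
* Deposited energy matches independent quadrature of the point source
  to <1%.
* Temperature rise is exactly linear in q relative to the zero-dose
  baseline (the ambient boundary cools the surface a few hundredths of
  a degree regardless of dose).

## Problem sizes

The working resolution is 100 × 120 cells (graded axial mesh) with
~290 implicit steps per 1 s exposure — a few seconds per run; the full
factorial study is 27 runs.  Property tests run at 40 × 60 cells.
These sizes put every reported number within a desk-scale rerun.

## Known limitations

Single homogeneous tissue layer (no epidermis/dermis stratification);
optical and thermal properties constant during exposure; no
chromophore-specific vessel absorption, so selective vessel
photothermolysis is not represented; single pulse only (no multi-pass
or repetition-rate effects); axisymmetric geometry by construction.
Temperature values inherit the uncertainty of the thermophysical
closure; the shipped ±10% perturbation study moves the high-dose peak
only by tenths of a degree because the hottest (surface-axis) cell lies
in the vessel lumen, whose blood properties are fixed — deeper tissue
temperatures scale more directly with the closure.  Orderings between
doses are robust to the closure throughout.
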