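# Methods

## Scope and architecture

`shootphys` implements the shoot side of a crop simulation: leaf-level
coupled gas exchange and energy balance, canopy scaling, and a whole-plant
diurnal carbon budget.  Everything below the collar — soil water, root
architecture, xylem transport — is deliberately out of scope and is
represented by a single exogenous forcing, the collar water potential
Ψ_c(t).  A piecewise-linear response curve maps Ψ_c to a stress factor
S_w ∈ [0, 1] (1 = unstressed) whose default breakpoints are
(−3000, 1) → (−8000, 0.4) → (−12000, 0) hPa; users may supply any
non-decreasing curve.  S_w enters the stomatal conductance multiplicatively
and can optionally scale the potential growth sink.

## Leaf gas exchange

Photosynthesis follows the Farquhar–von Caemmerer–Berry minimum law with the
phosphate-limited rate assumed non-binding.  The C4 pathway uses the
bundle-sheath formulation: PEP carboxylation (Michaelis constant K_P, capped
by the regeneration rate V_pr) transports CO₂ from mesophyll to bundle
sheath, and the quantity γ* = 1/(2·S_c/o) — half the inverse RuBisCo
specificity — sets the bundle-sheath compensation term γ*·O_s.  The
light-limited C4 rate allocates a fraction (1 − x) of electron transport to
the bundle sheath, with denominator 3·C_s + 7·γ*·O_s.

Gas concentrations are quasi-steady states of the stomatal-diffusion /
assimilation balances.  For C3 they are explicit
(C_m = C_A − 1.6(A−R_d)/g_w, O_m = O_A + 1.25(A−R_d)/g_w); for C4 the
mesophyll/bundle-sheath pair is the solution of a 2×2 linear system (solved
with `numpy.linalg.solve`; the matrix is diagonally dominant for positive
conductances).  The equilibration time of leaf gas pools is seconds to
minutes, far below the simulation timestep (0.1 d), which justifies the
steady-state treatment; the test suite verifies each steady state against
direct ODE integration of the underlying balance equations.

All gas concentrations are held internally in μmol mol⁻¹.  Oxygen-side
quantities are *entered* in mmol mol⁻¹ (K_O25 = 146, O_A = 209.46), matching
how they are commonly tabulated, and converted once at construction — this
single conversion point is deliberate, as mixed O₂ units are the classic
silent 10³ error in FvCB implementations.

Stomatal conductance uses the Ball-Berry-Leuning form with the (1 +
VPD/VPD_ref)⁻¹ humidity term; VPD and VPD_ref are both in kPa (VPD_ref = 10
kPa, the usual magnitude of the Leuning D₀ parameter), so the ratio is
dimensionless.  The conductance is floored at the residual conductance
g_w0 = 0.017 mol m⁻² s⁻¹: the formula goes below g_w0 when A < R_d or under
full stress, and a conductance below residual is unphysical.

The C4 leaf-level compensation point is computed exactly in the form
Γ = (K_P/V_pmax)(g_s·Γ_s − R_m) and isolated in its own function
(`c4_compensation_point`); with the default constants it is slightly
negative (≈ −0.3 μmol mol⁻¹), which is harmless where it is used (C_A − Γ)
but looks typographically suspect — keeping it swappable documents the
doubt without silently "fixing" it.  The bundle-sheath compensation
denominator is likewise 1 + R_d/V_cmax as given (the C3 analogue has a
minus sign); both forms are implemented verbatim.

Mesophyll and bundle-sheath respiration default to R_m25 = R_s25 =
0.5·R_d25, the canonical even split of dark respiration in the C4 model
this formulation derives from; both are independently configurable.

## Temperature responses

Kinetic parameters carry their 25 °C value plus an Arrhenius activation
energy; J_max, V_pmax and g_s additionally carry deactivation energy D and
entropy factor S in the peaked form, whose correction factor equals one at
298.15 K exactly.  Note that V_cmax uses the simple (unpeaked) form, so it
keeps rising with temperature while J_max collapses above ~315 K; hot leaves
therefore become strongly electron-transport limited, which is visible in
the solved states.

## Energy balance and leaf temperature

The leaf is assumed in thermal steady state (its heat capacity corresponds
to minutes of net imbalance).  The balance sums solar absorption α·I (no
reflected-sunlight term), infrared absorption α_IR σ(T_surr⁴ + T_sky⁴) with
T_surr = T_a and T_sky = T_a − 40 K, two-sided infrared emission
2α_IR σT_L⁴, two-sided boundary-layer conduction 2K_air(T_L−T_a)/δ_bl, and
latent heat J_v·H_vap(T_a).  The boundary-layer thickness is
δ_bl = 10.97·√(d·ν(T_a)/v) — the square-root form is the only
dimensionally consistent reading, and the coefficient is configurable.

The air-property fits are linear over 0–50 °C: K_air = 0.0243 +
7·10⁻⁵·(T−273.15) W m⁻¹ K⁻¹, ν = (1.415 + 0.09·(T−273.15))·10⁻⁵ m² s⁻¹,
H_vap = 45060 − 425·(T−273.15) J mol⁻¹.  The ν slope (0.09) and H_vap slope
(425) give 25 °C values about 2.3× and 0.78× the physical ones
respectively; they are kept as configured defaults (possible typesetting
artefacts of 0.009 and 42.5) and every coefficient is overridable in the
config, so a user can restore physical values with two keys.

The temperature solve is Newton's method from T_L = T_a with the analytic
derivative (−8α_IRσT³ − 2K_air/δ_bl), guarded by bisection on a ±50 K
bracket; E(T_L) is strictly decreasing so the root is unique.  Inside the
coupled solver, the transpiration flux is re-evaluated at the trial
temperature (J_v = g_w(e_sat(T_L) − e_air)/P, Tetens saturation curve,
floored at zero): treating J_v as fixed during the temperature solve can
leave no root in the bracket when an iterate pairs a large latent load with
a cool trial temperature, whereas the coupled residual is monotone with a
guaranteed crossing.  Transpiration here is leaf-demand plumbing; in a full
plant model this flux would come from the root hydraulic network.

## The nested root finder

The coupled leaf system is posed as update maps x_i = F_i(x) over
[T_L, g_w, A, C_m] (bundle-sheath quantities are explicit functions of this
vector).  The solver nests univariate Newton iterations — solving variable
i re-solves all deeper variables before every residual evaluation — and
declares convergence only when every |F_i(x) − x_i| < ε_i simultaneously
(ε = 10⁻⁶ in native units by default).  After 40 unconverged outer sweeps
the previous timestep's state (or a night-state default: A = 0, g_w = g_w0,
C_m = C_A, T_L = T_a) is returned flagged unconverged.

Numerical choices that mattered in practice:

* **Nesting order.**  The gas concentration is innermost, assimilation
  above it, then conductance, then temperature.  With A innermost the C4
  assimilation map has several fixed points in A at frozen gas
  concentrations (the bundle-sheath balance has slope −1/g_s ≈ −350 in A),
  and univariate Newton can lock onto an unphysical branch; with the gas
  balance innermost each map is single-rooted along its own variable.
* **Derivatives.**  Forward differences with a coarse relative step (10⁻³):
  residuals are evaluated across nested inner solves that are themselves
  only accurate to ε, so a fine step would difference noise.
* **Safeguards.**  Newton steps are damped (halved while the residual
  grows) and clamped to physical bounds per variable; if Newton stalls, a
  13-point scan of the admissible interval locates a descending sign change
  of g(x) = F(x) − x — the stable fixed point — and bisection finishes.  A
  short damped simultaneous-substitution warm-up (λ = 0.5, halving on
  failure) precedes the first sweep to enter the Newton basin from cold
  starts.

The solver is deterministic, order-insensitive in its converged solution,
and agrees with an independent damped simultaneous iteration to 10⁻⁴
relative in A, g_w and T_L across randomized environments (enforced in the
test suite).  Cold solves take ~5 ms, warm restarts ~0.5 ms.

## Canopy scaling

A two-big-leaf sun/shade scheme: with spherical leaf angles the black-leaf
beam extinction is k_b = 0.5/cos θ_z and LAI_sun = (1 − e^(−k_b·LAI))/k_b.
Sunlit leaves receive k_b·I_beam plus the mean intercepted diffuse flux
I_diff(1 − e^(−k_d·LAI))/LAI (k_d = 0.7); shaded leaves receive the diffuse
term only.  This conserves leaf area exactly and never absorbs more light
than is incident.  The incident beam/diffuse split defaults to 0.85/0.15
(clear sky) and is configurable.  Solar geometry uses Cooper's declination
and the standard hour-angle construction; clear-sky irradiance is solar
constant × orbital eccentricity × τ^(1/cos θ_z) × cos θ_z with
transmittance τ = 0.75 by default.  The coupled leaf solver runs once per
fraction with warm starts from the previous timestep.

## Carbon budget

State is per plant in grams of carbon.  Available carbon C_a is the gross
canopy assimilation converted at 12.011 μg C μmol⁻¹; carbon costs C_c are a
maintenance-plus-exudation coefficient (0.03 g C g⁻¹ d⁻¹) times structural
biomass, covering all respiration including leaf dark respiration (which is
therefore *not* also subtracted from C_a, avoiding double counting).  The
potential growth sink C_g is logistic, rgr·B·(1 − B/B_max) with rgr = 0.25
d⁻¹ and B_max = 40 g C — a deliberately simple stand-in for an organ-level
potential-growth model.  Surplus flows to reserves (C_r = C_a − C_c − C_g);
deficits remobilize reserves subject to:

* night: C_r ≥ −0.95·C_p(nightfall)/t_n, fixed at night start, so a binding
  cap drains exactly 95 % of dusk reserves by dawn;
* day: C_r ≥ −C_p/2 per day;
* day hoarding: if C_p + C_r·t_s ≤ 1.1·C_cN (projected dusk reserves below
  110 % of the night's need C_cN = C_c·t_n), C_r is raised to
  min(C_a − C_c, (1.1·C_cN − C_p)/t_s) and growth yields.

The night rule supersedes the half-per-day rule at night; enforcing both
would cap the flagship 95 %-per-night behaviour at 50 % and contradict the
rule's construction.  Realized growth C_h = C_a − C_r − C_c clipped to
[0, C_g]; the seed is modelled as the initial reserve endowment (0.25 g C).
By construction C_a = C_c + C_h + C_r at every step, so the cumulative mass
balance closes to floating-point roundoff (the tests require < 10⁻⁸ g over
a 42-day run; observed ~10⁻¹⁴).

Leaf area couples growth back to light capture through a fixed specific
leaf area (0.05 m² per g shoot C) and the stand density (8 plants m⁻²,
typical maize): LAI = sla·(shoot C)·density, with 60 % of growth allocated
to shoot.

Nitrogen limitation is available as a pre-processing step: leaf nitrogen
content follows a three-branch piecewise map of plant nitrogen between
minimum and optimal bounds, and J_max25/V_cmax25 scale linearly with leaf
nitrogen concentration (slopes n1 = 149.8, n2 = 24.5 μmol s⁻¹ g⁻¹ N,
calibrated so the default optimal concentration of 2.0 g N m⁻² reproduces
the reference J_max25 = 299.6 and V_cmax25 = 49 μmol m⁻² s⁻¹ — the
proportionality constants themselves are not independently sourced).

## Synthetic forcing

The weather generator produces what the model needs and nothing more: a
sinusoidal diurnal temperature cycle T_mean ± T_amp peaking at 15:00 solar
time, clear-sky irradiance from the solar-geometry model, VPD tracking the
temperature excursion linearly up to VPD_max (default 2 kPa), constant wind
(1.5 m s⁻¹) and pressure.  Optional seeded Gaussian jitter is off by
default so constructed properties (exact temperature range, dark midnights)
hold exactly.  It does **not** emulate weather fronts, cloud fields, rain,
humidity memory, or temperature–irradiance decoupling; passing tests on
synthetic forcing therefore demonstrates internal consistency of the
physiology and bookkeeping, not predictive skill against field data.  The
terminal-drought schedule holds Ψ_c at −1000 hPa (unstressed) until an
onset day, then declines linearly to a terminal potential — a stylized
drying-down, not a soil-moisture simulation.

## Default problem sizes

The shipped checks use a 42-day season at a 0.1-d timestep (420 steps, two
leaf solves per daylight step), 100 randomized environments for the solver
cross-check, 50 randomized draws for the gas steady-state suite and 30–40
for the energy-balance battery — sizes chosen so the full suite exercises
every regime (night, full stress, hot leaves, deep shade) while remaining a
sub-minute desk run.

## Known limitations

* Ψ_c is exogenous: no feedback from transpiration to water supply, hence
  no midday hydraulic depression unless encoded in the schedule.
* The phosphate-limited assimilation rate is omitted; mesophyll conductance
  is implicit in the kinetic constants.
* The canopy is horizontally homogeneous (no rows, no clumping) and the
  within-canopy longwave field is reduced to the T_surr/T_sky split.
* Growth is a single logistic sink: no organs, no phenology, no
  temperature-dependent growth rate; the shoot/root split is a constant.
* The C4 leaf-level compensation point and two air-property slopes are
  implemented exactly as configured even where their magnitudes look
  typographically doubtful (see above); all are overridable.
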