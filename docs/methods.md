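# Methods

`alborun` is a desk-scale emulation of frontal plankton production in an
Alboran-like marginal basin: a four-compartment planktonic nitrogen model
(NPZD) transported by a prescribed, divergence-free meandering-jet /
double-gyre circulation. The package does not solve ocean dynamics; it
reproduces the *biological consequence* of a calibrated frontal flow — that
ageostrophic upwelling cells along a nonlinear jet can fertilize a
nutrient-starved euphotic layer with zero lateral nutrient supply — in a
form that is fast, conservative and testable.

## The biological model

Four pools in nitrogen currency (mmol N m⁻³): nitrate N, phytoplankton P,
zooplankton Z, detritus D. Local source–sink terms:

    dP/dt = r_P f(N) f(I) P − G_P − m_P P
    dZ/dt = γ (G_P + G_D) − μ_Z Z − m_Z Z²
    dN/dt = −r_P f(N) f(I) P + μ_Z Z + ε D
    dD/dt = m_P P + (1−γ)(G_P + G_D) + β m_Z Z² − G_D − ε D

with Michaelis–Menten nitrate limitation f(N) = N/(K_N+N), a saturating
exponential light response f(I) = 1 − exp(−α_I I), shared-saturation grazing
on two food sources

    G_P = r_Z Z a₁P / (K_Z + a₁P + a₂D),   G_D = r_Z Z a₂D / (…),

and a concentration-dependent detritus sinking speed w_D = w_Dmax D/(S_D+D).
Light decays with depth as I(z) = I_s exp(−∫(k_w + k_b P) dz′) (self-shading
included), evaluated at layer midpoints. The quadratic zooplankton mortality
is a closure for unresolved higher predators: a fraction β is recycled to
detritus, the remaining (1−β) is removed from the modelled nitrogen pool
("closure loss"). Summing the four equations gives the exact local identity

    d(N+P+Z+D)/dt = −(1−β) m_Z Z²,

which the implementation preserves to rounding error because every term is
computed once as an explicit inter-compartment flux. The light and grazing
response shapes are injectable (`light_fn`, `grazing_fn` arguments) so
alternative closures can be swapped in without touching any caller.

Default parameters (all rates per day): r_P=1.3, m_P=0.06, m_Z=0.10,
μ_Z=0.05, γ=0.7, β=0.5, ε=0.25, K_N=0.5, α_I=0.03 (W m⁻²)⁻¹, k_w=0.05 m⁻¹,
k_b=0.04 m² (mmol N)⁻¹, I_s=40 W m⁻², r_Z=0.5, K_Z=0.5, a₁=1.0, a₂=0.5,
S_D=0.2, w_Dmax=8 m day⁻¹. These are winter values for a diatom-dominated
herbivorous food web: growth is kept low in lieu of an explicit temperature
response, and the surface photosynthetically available radiation is the
winter mean (half of 80 W m⁻² shortwave). No multi-element stoichiometry,
no chlorophyll conversion, a single phytoplankton functional type.

## The synthetic circulation

What it emulates: an eastward buoyant jet ~15–20 km wide entering at the
western boundary with ~0.7 m s⁻¹ surface speed, meandering around two
anticyclonic gyres (WAG- and EAG-analogues), weakening to half its strength
by the EAG longitude and decaying with depth over ~50 m; localized
ageostrophic vertical-velocity cells on the jet flanks, up to 50 m day⁻¹ at
50 m depth, upward on the anticyclonic (south) flank on trough→crest
segments and downward on the cyclonic flank on crest→trough segments;
normalized relative vorticity reaching magnitudes of order 0.5 along the
jet (f-plane, f = 8.6×10⁻⁵ s⁻¹ at 36°N).

How it is built: the horizontal non-divergent part comes from a corner-point
streamfunction (tanh jet profile along a sinusoidal meander axis + Gaussian
gyre bumps, windowed to zero at the walls so the basin is closed); the
divergent part from Gaussian velocity-potential cells placed by the
half-wavelength rule above, multiplied by a vertical shape s(z) = dG/dz with
G(z) = (z/z_w)·exp(1−z/z_w) (the target w profile: zero at the rigid lid,
maximum at z_w = 50 m, a decaying tail reaching through the nitracline,
forced to zero at the bottom). Vertical velocity is then obtained by
discrete vertical integration of −∇·u_h from the surface, so *every* cell of
every generated field satisfies discrete continuity to rounding error, with
zero normal flow at walls, lid and bottom. Two scalar calibrations set the
maximum surface speed and the maximum |w| at the configured depth exactly.

What it does not emulate: geostrophic adjustment, meander growth and
propagation, frontal instabilities, or any time dependence (the default
flow is steady). Consequently the fertilization pattern is fixed in space,
whereas in a dynamical model the upwelling cells sweep through the basin.
A passing emulation therefore demonstrates the mechanism and its order of
magnitude, not the spatial detail of a primitive-equation solution.

`FlowConfig.gyre_w` can add weak downwelling over the gyre interiors (the
quasigeostrophic subduction a dynamical anticyclone exhibits). It is off by
default after testing showed the kinematic analogue inverts the mechanism:
in a prescribed flow the cells' surface convergence imports nutrient-rich
rim water into the cores and the compensating divergence ring places
upwelling inside the interior — whereas in the real gyres the cores are
isolated by the depressed isopycnals of the adjusted density field, which
no velocity field alone can represent.

## Transport and coupling

Tracers live on a rigid-lid z-coordinate C-grid (z positive down, layer 0
at the surface, cell-centred tracers). Advection is finite-volume
flux-form: first-order upwind plus a superbee-limited antidiffusive
correction clipped by a Zalesak flux-corrected-transport limiter. On a
closed domain this makes total mass conservation, uniform-field
preservation under divergence-free flow, and no-new-extrema (hence
positivity) exact. Diffusion is explicit flux-form with no-flux walls.
Detritus sinking is an upwind vertical flux with per-cell speed w_D(D),
internally sub-stepped, with the flux through the sea floor accumulated as
bottom export. Lateral boundaries are closed for all biological fields (no
nutrient import — the attribution device of the experiment).

Operator splitting per transport step (default 1800 s): advect → diffuse →
sink → biology, the biology integrated in Euler sub-steps of ≤ 0.01 day
with light recomputed from the evolving P column. Positivity in the biology
is enforced by a scaled-tendency limiter (all fluxes out of a pool are
scaled together when the pool would cross zero within a sub-step), so the
budget identity survives exactly rather than being restored by clamping.
The global check, verified at every snapshot, is

    Δ(total N) = −(bottom export + closure loss)

to ≤ 10⁻⁸ relative (measured: ~10⁻¹⁴ over 120 days).

Vertical diffusivity is a fixed profile: κ_v = 5×10⁻³ m² s⁻¹ in the upper
40 m with a 15-m tanh transition to an interior floor of 10⁻⁶ m² s⁻¹. The
profile is the package's stand-in for a turbulence closure: the winter
Alboran column is weakly stratified and sheared by the jet, so its surface
layer mixes vigorously, and without that pathway upwelled nitrate pools
below ~25 m (where w necessarily vanishes under a rigid lid) and never
reaches the well-lit zone — suppressing exactly the diffusive branch of the
diapycnal supply the experiment is about. The 5×10⁻³ m² s⁻¹ magnitude is
typical of level-2.5 closures in near-neutral shear layers; the floor is
the conventional interior minimum. Horizontal diffusivity is 10 m² s⁻¹
(half a constant 20 m² s⁻¹ viscosity, the usual Prandtl-number convention;
no flow-dependent part since the flow is prescribed).

## Scenario

Initial nitrate is exactly zero above 100 m, ramping linearly to a deep
value of 8.0 mmol N m⁻³ at 250 m. The deep value stands in for an
unpublished winter climatology and is treated as a sensitivity axis, not
truth: euphotic production scales roughly linearly with it, so conclusions
are stated as orders of magnitude. P and Z are seeded at 0.05 mmol N m⁻³
over the upper 100 m — small enough that seed biomass is negligible against
produced biomass by day 120 (the zero-flow control stays at or below seed
level throughout). Detritus starts at zero. Runs last 120 days with
snapshots at days 30/60/90/120.

## Problem sizes and numerical choices

The default reduced domain is 400×300 km at 10 km resolution with 20
geometrically stretched layers over 300 m (6 m at the surface) — the jet is
marginally resolved (~4 cells across its dynamical span; the generator
refuses coarser grids). A 5-km preset (nx=80, ny=60) is a config away. The
10-km default keeps a 120-day run at roughly four minutes on one core.
Reporting masks: jet core = columns with surface speed > 0.3 m s⁻¹; gyre
interior = columns within half a gyre radius of either gyre centre. The
reporting transect crosses the WAG-analogue diagonally and then runs
zonally across the EAG-analogue; its exact path is constructed from the
configured gyre geometry.

Degenerate inputs and tie-breaks: zero-length transect segments collapse to
a single column; grazing at zero food is exactly zero (no 0/0); the FCT
limiter treats land neighbours as inert; advection refuses CFL > 1 and
diffusion refuses stability numbers > 1 rather than silently sub-stepping,
except inside `sink`, which sub-steps internally because its speed is
state-dependent.

## Known limitations

Steady flow (no meander propagation, so fertilization is spatially fixed
and the approach to the productive state is slower than in a dynamical
model); rigid lid and flat bottom by default; a fixed diffusivity profile
instead of a turbulence closure; single-group NPZD with no temperature
response; the deep-nitrate value is a configurable stand-in.

The weakest point of the emulation is gyre-interior isolation. In the
dynamical system the anticyclone cores are sealed by their depressed
isopycnals and by weak interior subduction; a steady kinematic flow has
neither, so the bloom plume of a frontal upwelling cell adjacent to a gyre
drifts through the quiet zone bordering the interior disk and the interior
0–75 m biomass integral overshoots the strict oligotrophic bound at day
120 (the overshoot persists at 5 km resolution, i.e. it is advective, not
numerical). For the same reason the jet/interior biomass contrast comes
out inverted at day 120: the fast jet core flushes biomass into adjacent
quiet retention zones (an effect the dynamical system also shows for
zooplankton — strong along-front advection works against local biomass
accumulation), and those zones border the interior disks. The
corresponding acceptance check is deliberately left failing rather than
loosened. What the emulation does reproduce: production is attributable
entirely to the frontal vertical transport (the zero-flow control stays
at seed level), the euphotic nitrate build-up and jet-core biomass reach
the right order of magnitude, and the subsurface nitrate maximum appears
at the right depth and strength on the gyre-crossing transect. Tests
passing on the synthetic flow show the mechanism is implemented correctly
and conservatively — they do not validate the emulation against in-situ
data.
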