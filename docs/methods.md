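# Methods

`phantomlight` models the optics of homogeneous slab phantoms — epoxy-type
matrices loaded with scattering particles and molecular dye — and the
wavefront-shaping experiments performed through them.  This note records
the models, the numerical choices, and what the simulations do and do not
establish.

## Geometry, units and conventions

The slab occupies `z ∈ [0, d]` (mm), illuminated at `z = 0` by a unit-power
collimated beam at normal incidence; detection happens below `z = d`.  The
medium is characterized by the effective scattering coefficient
`μs′ = μs (1 − g)` and the absorption coefficient `μa` (both mm⁻¹), a
Henyey–Greenstein (HG) phase function with anisotropy `g ∈ [0, 1)`, and
refractive indices `n_slab` (default 1.552, an epoxy resin at 633 nm) and
`n_ambient` (default 1, air on both faces).  Derived scales: transport mean
free path `ℓ′ = 1/μs′`, transport optical thickness `τ = μs′ d`.  All
Fresnel coefficients are unpolarized (s/p averages): polarization optics in
the physical setup condition the modulator, not the transport.  Angles are
radians; direction cosines `μ` are measured against the slab normal.

The anisotropy of such phantoms is not part of an integrating-sphere
characterization and must always be supplied; the package default `g = 0.6`
is a mid-range value typical of micron-scale dielectric scatterers at
visible wavelengths, and every loader logs it when a configuration omits
`g`.  All predictions that separate ballistic from diffuse light depend on
`g` through `μs = μs′/(1 − g)`.

## P_N solution of the radiative transfer equation

The scattered (diffuse) radiance is expanded in Legendre moments
`ψ_l(z)`; with HG moments `g^l` the azimuthally symmetric moment system is

    (l+1) ψ′_{l+1} + l ψ′_{l−1} + (2l+1)(μt − μs g^l) ψ_l = (2l+1) q_l(z),

truncated at odd order `N` (`ψ_{N+1} = 0`).  The collimated beam is *not*
represented in the expansion (a delta cannot be): it is propagated in
closed form, including its specular internal reflections
(`C↓ = a e^{−μt z}`, `C↑ = b e^{μt(z−d)}`), and feeds the moment system
through the first-scatter source `q_l = μs g^l (C↓ + (−1)^l C↑)`.

The homogeneous solutions are exponential eigenmodes of a symmetrizable
generalized eigenproblem with a ± eigenvalue spectrum; each mode is
anchored at the face it decays away from, so every basis function is
bounded by one on the slab and the solve is stable at any optical
thickness.  Half-range Marshak conditions close the system: the odd
half-moments of `L_in − R_F(μ) L_out` vanish at both faces, with the exact
angle-dependent internal Fresnel reflectance under the integral.

### Hybrid boundary radiance

Summing the truncated Legendre series at a boundary rings (Gibbs
oscillations) and violates the boundary conditions.  Instead, the exiting
radiance is obtained by integrating the characteristic (integral) form of
the transport equation with the P_N-reconstructed source

    Q(z, μ) = (μs/2) Σ_l (2l+1) g^l ψ_l(z) P_l(μ) + first-scatter source,

where the first-scatter term uses the *exact* HG kernel rather than its
truncated expansion (the single-scattered radiance is then exact, which
matters for thin slabs and strongly forward scattering).  Because every
source term is a pure exponential in depth, the characteristic integrals
have closed forms and no depth quadrature appears anywhere.  The coupling
of the two faces through internal Fresnel reflection is a 2×2 linear
system per direction, solved exactly, so the returned radiance satisfies
`L_in(μ) = R_F(μ) L_out(μ)` to round-off — the package asserts a residual
below `1e-10·max L`.

### Observables

Fluxes are integrated in interior coordinates; Snell's law plus the `n²`
radiance transform map the exit radiance into ambient angles with exact
flux conservation.  Since the numerical aperture `n sin θ` is conserved
across the interface, the interior cutoff for a detection aperture NA is
`μ ≥ sqrt(1 − (NA/n_slab)²)`.  The unscattered component is closed-form:

    T_ball = T_F² e^{−μt d} / (1 − R_F² e^{−2 μt d}),

a delta in the forward direction that falls inside any positive aperture,
and the specular reflectance series complements it on the illumination
side.  The absorbed fraction is `μa` times the depth-integrated fluence
(diffuse `∫ψ_0` plus collimated), all in closed form.  Energy closure
`T + R + A = 1` is then a genuine accuracy diagnostic, not an identity.

### Numerical choices

* **Truncation order.**  Default `max(31, log(10⁻³)/log(g))`, odd, capped
  at 81: the order must resolve the HG moment decay `g^l` (67 at g = 0.9),
  and the floor of 31 keeps the closure defect near 10⁻⁴ for the slabs of
  interest (τ up to ~10).  At order 15 the defect sits at the 10⁻³ level;
  closure tightens roughly as N⁻² and reaches 7·10⁻⁷ at order 501 for a
  conservative matched slab (the solver remains stable there, ~0.5 s).
* **Critical-angle kink.**  The internal Fresnel reflectance is identically
  one below the TIR cosine (0.764 for n = 1.552 in air).  Both the Marshak
  half-range integrals and the hemispherical flux quadratures are split at
  that kink; integrating across it costs three orders of magnitude of
  accuracy.
* **Conservative media.**  `μa = 0` makes the moment system singular; the
  solver floors `μa` at 10⁻⁹ mm⁻¹, which perturbs transmittance at the
  10⁻⁸ level for millimetre slabs.
* **Degenerate inputs.**  `μs′ = 0` short-circuits to a zero diffuse field
  with closed-form ballistic transport; grazing directions (`μ → 0`) use
  the analytic limits of the characteristic integrals; accidental
  resonance of `μt` with an eigenmode rate falls back to least squares.
* **Failure modes.**  An ill-conditioned Marshak solve raises a diagnosed
  `PNSolverError` rather than returning silent garbage.

## Monte Carlo verification

An independent photon Monte Carlo serves as the oracle for the P_N solver
and as the stochastic forward engine for the look-up table.  A pencil beam
at normal incidence is equivalent, for the spatially integrated quantities
computed here, to plane-wave illumination with localized detection, so
both methods predict the same observables.  The state per photon packet is
depth and direction cosine only (the transverse coordinate never enters a
tally in a laterally infinite homogeneous slab).  Free paths are
exponential at rate `μt`; HG polar cosines come from the inverse CDF;
absorption uses implicit capture (weight × `μs/μt` per collision) with
Russian roulette below weight 10⁻⁴ (survival 0.1).  The net weight created
or destroyed by roulette is folded into the absorption tally — a zero-mean
correction that makes `T + R + A = 1` exact per run, so conservation is a
bookkeeping invariant and comparisons rest on the physics tallies.
Boundary crossings draw against the angle-dependent unpolarized Fresnel
reflectance; transmitted packets are binned by ambient exit angle
(90 uniform θ-bins by default, resolving the NA = 0.8 edge at 53.13°),
with packets that never scattered tallied separately as ballistic.
Standard errors come from per-photon sums of squares; the depth-binned
collision estimator of fluence (optional) accumulates per photon before
squaring, since its events are correlated within a photon.

The kernel is compiled with numba and is bit-reproducible for a given
seed.  10⁶ photons across the bundled phantoms take between one and thirty
seconds, the worst case being g = 0.9 (≈500 collisions per photon).

## Integrating-sphere look-up table

The sphere observables `(T, R)` — total hemispherical transmittance and
reflectance — are tabulated over a `(μs′, μa)` grid at fixed `(g, n, d)`;
the default axes are 31 linear nodes on [2, 5] mm⁻¹ and 31 log nodes on
[10⁻³, 10⁻¹] mm⁻¹, spanning the bundled phantoms with margin.  The default
forward engine is the deterministic P_N model (order 31); the Monte Carlo
engine mirrors a fully simulation-based table at the cost of grid noise.
Inversion is continuous 2-D root finding on the bilinearly interpolated
surfaces (bilinear in `(μs′, log μa)`): damped Newton with grid-scan
initialization from the three best-separated cells, an out-of-range error
naming the violated observable when `(T, R)` is infeasible or outside the
table, and an ambiguity error if distinct starting cells converge to
distinct roots.  Grid-node round trips recover the node to 10⁻⁹;
off-node phantoms observed with 10⁶-photon Monte Carlo are recovered with
median errors ≈0.15% in `μs′` and ≈0.5% in `μa` (20 phantoms, τ > 1,
T > 0.1%).  Accuracy at the smallest `μa` is intrinsically limited: the
absorbed fraction `≈ μa·⟨path⟩` is then below 1%, so a fixed absolute
noise on `(T, R)` is amplified into a large relative `μa` error — the
stated validity window exists for this reason.

## Wavefront-shaping simulation

Fully developed speckle is modelled as `N` independent channels
`t_n ~ CN(0, 1)`; the detected field under segment phases `φ_n` is
`E = Σ t_n e^{iφ_n}`.  The stepwise sequential algorithm sweeps one
segment over `K = 16` equispaced phases, commits the argmax (a cosine-fit
estimator is available), and proceeds; by default two full cycles run,
because a single pass aligns early segments against a rest-field that
later segments still change.  The peak intensity is the best value
*measured* during the final sweep — the max-statistic an experiment
records — and the background averages `M = 100` random patterns of the
same segmentation.  The expected enhancement for phase-only control is
`η = (π/4)(N − 1) + 1` (fractional `N` accepted, standing in for partially
illuminated segments); the simulated ensemble mean lands within a few
percent of it, the deficit being the `sinc²(π/K)` phase-quantization loss.
Two imperfections are modelled, both proportional to the channel power so
that a uniform attenuation of all `t_n` (absorption) leaves the PBR
exactly invariant: an uncontrollable background floor `β·Σ|t_n|²`
(`β = 0.056` mimics the residual amplitude modulation of a phase-only
modulator) and additive Gaussian detector noise.  With noise on, the
max-statistic peak biases the mean PBR above theory at `N = 1–2`,
reproducing the small-`N` exaggeration seen experimentally; the package
documents rather than corrects it.

The laser-power plan equalizes the detected signal across phantoms:
`factor_i = T_NA(ref)/T_NA(i)` with sample 1.2 as reference, so
`factor_i · T_NA(i)` is constant by construction.

## What the synthetic conditions do and do not show

The bundled six-phantom fixture reproduces the published characterization
of the two phantom sets (thicknesses 0.395–1.987 mm, `μs′` ≈ 2.7–3.8 mm⁻¹,
`μa` ≈ 0.002–0.06 mm⁻¹) and drives every cross-method test at full scale
(10⁶ photons, `g ∈ {0, 0.6, 0.9}`).  The speckle model assumes fully
developed, uncorrelated channels: it validates the enhancement statistics
and their absorption invariance, but not the partially-correlated regime
of optically thin samples (the thinnest phantom's ballistic and
little-scattered light), for which no quantitative model is attempted —
the solver instead quantifies how large that ballistic fraction is, and
its closed form crosses the 2% level within the plausible anisotropy range
`g ∈ [0.5, 0.7]` for the thinnest phantom.  Wavelength dependence,
polarized transport, layered media, time-resolved quantities and
instrument geometry (sphere ports, SLM pixelation, fiber coupling) are out
of scope.

## Problem sizes

Defaults keep the full suite at desk scale: P_N solves are milliseconds;
the 31×31 deterministic table builds in ~6 s; the inversion round-trip
study (20 phantoms × 10⁶ photons) takes ~90 s; the 18-combination
P_N ↔ Monte Carlo verification ~2.5 min; the enhancement-law ensembles
(50 realizations at N = 16, 64, 256) a few seconds.
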