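# Methods

## The problem

Small-angle neutron scattering (SANS) of a dilute protein solution measures
the orientationally averaged single-particle intensity I(Q) over momentum
transfer Q = 4π sin(θ)/λ.  For the cyanobacterial clock proteins this
package targets, two shape families cover the observed curves:

* **KaiC-like hexamers** — a double ring of two stacked hexameric lobes
  with a continuous central channel.  No standard analytic form factor
  describes this, so the package implements a bespoke *dumbbell* model:
  two identical coaxial ellipsoids of revolution (polar semi-axis *a*,
  equatorial semi-axes *r_eq*, centers *d* apart on the symmetry axis)
  pierced by an axial cylindrical hole of radius *R_h*.
* **KaiA-like chains/assemblies** — loosely packed particles well
  described by the polymer excluded-volume form factor parameterized by a
  radius of gyration R_g and a Porod exponent m.

## Dumbbell amplitude: two routes

**Closed route (approximation).**  Superposition of the closed-form
ellipsoid amplitude pair and a full-length cylinder:

    F(q, α) = 2 V_e A_ell(q, α) cos(½ q d cos α) − V_c A_cyl(q, α),

with V_e = (4/3)π a r_eq², V_c = π R_h² (d + 2a).  This double-counts any
lobe overlap and subtracts hole volume even beyond the ellipsoid caps.
Both reference geometries *do* overlap (2a > d), so the closed route is
kept only as a fast limit-check tool; using it on an overlapping geometry
logs a warning.

**Numeric route (reference).**  The amplitude of the indicator density of
the actual union-minus-hole body.  Exploiting axial symmetry and the
z-mirror plane,

    F(q, α) = 4π ∫₀^{z₁} cos(q z cos α) ∫_{R_h}^{r_max(z)} J₀(q r sin α) r dr dz,

where r_max(z) = r_eq √(1 − ((z − d/2)/a)²) is the union envelope for
z ≥ 0.  The radial integral is analytic, ∫ J₀(k r) r dr = r J₁(k r)/k,
which collapses the amplitude to a **single smooth 1-D z-integral** over
the support where the envelope is wider than the hole.  That integral is
evaluated by Gauss–Legendre quadrature (default 64 nodes; 40 inside
fits).  Because the integrand is smooth and at most a few oscillation
periods long over the experimental Q range, the quadrature is converged
to near machine precision at these orders — far better and far cheaper
than a 2-D grid over (r, z) would be, which is why the radial-analytic
reduction was adopted.  A self-check (`check=True`) compares against a
doubled rule and raises a diagnostic on disagreement.

Overlap is counted once and the hole removes only material inside an
ellipsoid, by construction.  Consequences worth knowing:

* At the degenerate point d = 0, a = r_eq = R, R_h = 0 the numeric route
  gives **one** sphere (amplitude V·A(qR)), while the closed route gives
  the superposed 2V·A(qR); both reduce to the same *normalized* sphere
  form factor, which is what the intensity uses.
* The forward amplitude F(0) equals the exact body volume, available in
  closed form (`DumbbellParams.volume`) and cross-checked by Monte Carlo.

**1-D intensity.**

    I(Q) = scale · ⟨|F|²⟩(Q) / ⟨|F(0)|²⟩ + A_up Q^(−p) + background.

The orientational average ⟨·⟩ uses Gauss–Legendre in α ∈ [0, π/2] with
the sin α Jacobian (default 76 nodes, self-checked by node doubling to
1e−4 relative).  The absolute scattering-length-density contrast of the
measurements is not published, so the model is normalized to its forward
value and `scale` = I(0) − background is a free intensity parameter.  The
additive power law A_up Q^(−p) represents the low-Q clustering upturn
seen in aggregating samples; p is conventionally bounded to [2, 4] in
fits.

**Polymer excluded-volume form factor.**  With ν = 1/m and
U = Q² R_g² (2ν+1)(2ν+2)/6,

    P(Q) = γ(1/(2ν), U)/(ν U^{1/(2ν)}) − γ(1/ν, U)/(ν U^{1/ν}),

γ the lower incomplete gamma function; P(0) = 1, P → Q^(−m) at high Q,
and m = 2 reduces exactly to the Debye Gaussian-coil function (verified
pointwise to 1e−8).  A three-term series replaces the incomplete-gamma
expression below U = 1e−5 where the subtraction loses precision.  R_g is
carried in nm (the unit used for reported values) and converted to Å
against the 1/Å Q grid internally.

## Guinier and Porod analysis

`guinier_fit` does the standard iterated weighted fit of ln I against Q²:
starting from the lower half of the grid, the window implied by the
fitted R_g (Q·R_g ≤ 1.3, a common convention) is re-applied until the
point set stabilizes; R_g = √(−3·slope).  Small starting windows are
avoided deliberately — with a few percent noise the decay is unresolvable
on five points.  `porod_exponent` is the negative weighted log–log slope
over a caller-chosen window.  For oscillatory dumbbell curves the "Porod
slope" is only meaningful averaged over at least one oscillation period;
over Q ∈ [0.15, 0.5] 1/Å the reference geometries give ≈ 3.7, consistent
with the nominal −4 of sharp-interface particles.  The CLI `analyze`
command estimates the slope only on points resolving the signal above 3σ
after background subtraction (noisy form-factor minima go negative
otherwise), and truncates a detected low-Q upturn (log-log slope < −1.5
below Q = 0.012 1/Å by default) before the Guinier fit; a sufficiently
strong upturn leaves no clean Guinier regime at all, which the report
states explicitly rather than quoting a contaminated R_g.

## Brute-force oracles

Every analytic/numeric result is validated against estimators that share
no code with the models:

* `sample_points` — uniform rejection sampling of the body inside its
  bounding cylinder, seed-deterministic.
* `mc_volume`, `mc_rg` — hit-fraction volume and RMS-distance radius of
  gyration with standard errors (defaults n = 10⁶).
* `debye_intensity` — the Debye sum I(q) = (1/N²) Σᵢⱼ sinc(q rᵢⱼ),
  accumulated as a fine pair-distance histogram (16384 bins, within-bin
  mean distance) so the O(N²) pair loop runs once, independent of the
  Q grid.  The textbook sum includes the i = j self-terms, which floor
  the result at 1/N; `include_self=False` switches to the unbiased pair
  average Σ_{i<j} sinc/(N(N−1)/2), required when the curve decays below
  ~10/N of its forward value.
* `debye_intensity_averaged` — mean of the pair average over independent
  seeded clouds.  The reference dumbbell curves span 4–5 decades over
  Q ∈ [0.005, 0.3] 1/Å, and near form-factor minima the relative
  Monte-Carlo error of a single 2×10⁴-point cloud reaches ~10%; averaging
  32 clouds of 5×10⁴ points brings the worst-case deviation from the
  numeric model to ≤ 1% for both reference geometries, which is the
  configuration the oracle-equivalence test uses.

## Particle-swarm fitting

The objective is χ² = Σ ((I_obs − I_model)/σ_I)² on linear intensity
(σ_I is part of reduced SANS data; fits are invariant under common
rescaling of I and σ_I).  The optimizer is a global-best PSO — the
dumbbell objective is multimodal in the geometry parameters, with a
strong d–a trade-off when the lobes overlap, and a population method
explores the bounded box without gradients:

    v ← w v + c₁ r₁ (pbest − x) + c₂ r₂ (gbest − x),  x ← clip(x + v)

with constricted defaults w = 0.72, c₁ = c₂ = 1.49, swarm 50, 500
iterations, 5 independently seeded restarts, velocity clamped to half the
box width, and velocity zeroing at clipped walls.  Everything is
deterministic given the seed.  Default bounds are ±50% around the initial
values; `bounds_hit` flags best-fit parameters pinned at a bound, the
signature of an identifiability problem.  Candidate geometries with the
hole wider than the equator score +∞; bounds that exclude every feasible
geometry raise an error up front.

The numeric amplitude is evaluated for the whole swarm per iteration in a
compiled kernel (numba; J₁ by dense table interpolation consistent with
scipy to ~2e−8), with a reduced but effectively converged quadrature
inside fits (32 orientation nodes, 40 z-nodes: ≤ ~1e−7 relative error for
reference-scale geometries, orders of magnitude below the 3% measurement
noise).  One swarm iteration costs ~0.1 s, so the full default budget
(50×500×5) fits one curve in ~4 minutes; the recovery experiments in the
acceptance script use swarm 40, 250 iterations, 2 restarts (~40 s per
fit), and the test suite uses swarm 30, 150 iterations, 1 restart —
convergence traces show the global best stagnant well before these
budgets on 6-parameter dumbbell fits, and recovered values change only in
the third digit between the reduced and full budgets.

Optional per-point Gaussian resolution smearing in Q (truncated at ±3σ_Q)
is expressed as a precomputed row-stochastic matrix on the curve's own
grid, so it costs one matrix multiply per objective evaluation; its
accuracy is set by the grid density relative to σ_Q.  Fits apply it
automatically when the data carry a σ_Q column.

## Synthetic data

`simulate_curve` adds Gaussian noise N(0, σ_I) with σ_I = f·I + floor to a
model curve on a log-spaced grid (default Q = 0.005–0.5 1/Å, 100 points —
a plausible reduced-data range for a 2.2–6.7 Å wavelength band; the true
measured range is not published).  Defaults f = 3%, floor = 10⁻⁴·I(0) are
a declared convention plausible for hour-scale measurement sessions; no
counting statistics are published.  The σ_I column stores exactly the
noise model's own σ — the generator is honest about its noise.

`fixture_suite` ships the four reference scenarios with published
parameters: dumbbell curves for KaiC (d = 50, a = 32.4, r_eq = 44.5,
R_h = 16.8 Å) and anKaiC (53, 35.4, 45.5, 17.4 Å), polymer curves for
KaiA (R_g = 3.4 nm) and anKaiA (8.6 nm) with m = 3 ("Porod factor close
to 3"), each as a noisy curve plus a noise-free twin carrying the same
σ_I column (so χ² at the generating parameters is exactly 0).  The
fixtures embed their generation parameters in their file headers.
Fixture scale = 1 and background = 10⁻³·I(0), a typical
incoherent-background level for protein SANS.

What the generator does **not** emulate: instrument-specific resolution
smearing (unless σ_Q is supplied), inter-particle structure factor,
oligomer mixtures (anKaiA's self-assembly enters only through its larger
R_g), wavelength-spread correlations, and detector-level artifacts.
Passing recovery tests therefore demonstrate that the pipeline inverts
its own forward model at realistic noise — not that fits to real reduced
data are unbiased against these unmodelled effects.

## Shape comparison

`compare_shapes` reports percent differences of *all* candidate size
measures between two dumbbell geometries — axial length d + 2a,
equatorial width, envelope volume (closed form), Monte-Carlo R_g — rather
than privileging one "size".  For the published geometries the axial
length difference is +7.8% (123.8 vs 114.8 Å), the volume difference
≈ +11%, and the MC-R_g difference ≈ +4.5%; a reported "about 9% longer"
is consistent with an axial-length-like measure, but since the measure is
not stated, none is asserted.

## Numerical choices and edge cases

* Å internally everywhere; R_g reported in nm.
* sinc and the sphere amplitude switch to series below ~1e−4 argument;
  J₁-based expressions switch to their 0/0 limits below 1e−8–1e−9.
* Degenerate geometries: hole ≥ equator is invalid at construction;
  rejection sampling raises once acceptance drops below 10⁻³.
* Guinier fits raise diagnostics rather than returning a biased R_g when
  no stable window exists (fewer than 5 points, non-negative slope, or
  non-stabilizing window).
* All Monte-Carlo and optimizer randomness flows from explicit integer
  seeds; repeated runs are bit-identical.

## Known limitations

* The closed-route dumbbell amplitude is wrong by design for overlapping
  lobes (tens of percent at intermediate Q); it exists for limit checks.
* The smearing operator cannot widen the model beyond the measured grid,
  so edge points are smeared against a truncated, renormalized window.
* PSO gives point estimates; no uncertainties on fitted parameters are
  produced (restart scatter and `bounds_hit` are the only diagnostics).
* The Porod exponent of an oscillatory curve depends on the window; the
  package reports the regression slope for the window asked for.
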