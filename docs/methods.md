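# Methods

This note records the models implemented in `pombetip`, the numerical
choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.  Units are µm, s, MPa in the
axisymmetric tip model and µm, min in the 2D whole-cell model.

## Axisymmetric elastic-shell tip growth

**Model.**  The wall is a thin elastic shell of uniform thickness δ
under turgor pressure *P*.  Mechanical equilibrium is assumed fast
relative to growth, so stresses follow from geometry alone:
σ_s = P/(2δκ_θ) and σ_θ = (P/(δκ_θ))(1 − κ_s/(2κ_θ)), which satisfy the
normal balance κ_s σ_s + κ_θ σ_θ = P/δ pointwise (this identity is
asserted in the tests at 1e−10).  Plane-stress Hooke relations give the
in-plane strains.  Remodeling replaces strained wall by unstrained wall
at constant thickness at a rate G_max·Λ(s), so the visible expansion
rates are ξ_i = G_max Λ(s) ε_i.  The kinematic relations
ξ_s = dv_t/ds + v_n κ_s and ξ_θ = v_t cosφ/ρ + v_n κ_θ with the
axisymmetry condition v_t(0) = 0 are solved by an integrating factor:
d/ds (v_t/sinφ) = (ξ_s − ξ_θ κ_s/κ_θ)/sinφ, then
v_n = (ρξ_θ − v_t cosφ)/sinφ with the apex limit v_n(0) = ξ_θ(0)/κ_θ(0).

Only the combination G_max·P/(Eδ) (together with ν and the shape of Λ)
affects the dynamics; it rescales time but not the steady shape.  The
test suite asserts bit-identical trajectories under P→2P, E→2E.

**Assumptions.**  No plastic/viscous wall flow; uniform Young's modulus
(an s-dependent modulus would fold into Λ(s)/E); thickness held constant
by the delivery machinery; the signal profile rigidly attached to the
apex (it is re-evaluated as Λ(arc distance from the current tip) every
step).  Wall with Λ below a support cutoff (default 1e−6) never
remodels and is pinned.

**Discretization.**  The meridian is a point set at uniform arc spacing
(default σ_Λ/40; the headline ratios computed at σ/20 and σ/40 agree to
four digits).  Derivatives use the five-point stencil, made central at
the apex by parity-correct mirror ghosts (z even, ρ and φ odd) and
one-sided at the base.  κ_θ(0) takes the symmetric limit κ_s(0).  The
v_t integral uses cumulative Simpson; the integrand's 0/0 apex limit is
filled by quadratic extrapolation.  The apex curvature reported in
metrics comes from an even quartic fit z(ρ²) over the first ~14 points,
which is far less noisy than the raw stencil value at the resolution
limit.

**Time step.**  Points move by v·dt and the contour is then resegmented
to uniform spacing with parity-correct cubic splines.  Two stability
constraints set dt = min(0.1·h/v_max, 0.5·h²·κ_max/v_max): the first
keeps displacements below a tenth of the spacing; the second is a
diffusive (curvature-relaxation) limit — the normal velocity depends on
curvature, i.e. on second derivatives of the contour, so an explicit
scheme with a displacement-only step shows apex oscillations (we
observed tip-radius fluctuations of ±0.5 µm and a ~20% downward bias of
the steady diameter before adding the h² bound).  Spline rather than
linear resegmentation matters for the same reason: repeated chordal
resampling erodes convex regions by ~h²κ/8 per pass, which at per-step
frequency is a spurious inward velocity.

**Steady state.**  The shape is compared in the co-moving tip frame
(ρ as a function of arc distance from the apex, over s < 4σ_Λ) every
0.1σ_Λ of tip advance; steady when the maximum change drops below
1e−4·σ_Λ per interval (a package choice).  The diameter is 2ρ averaged
over the first contiguous window where |φ − π/2| < 1e−3 — the first
window, because the far pinned contour still remembers the initial
condition.  The growth velocity is the slope of the apex position over
a further 2σ_Λ of advance, and the prefactor is
C = v·Eδ/(G_max·P·(w/2)).

Measured values with a Gaussian signal: u = w/FWHM = 1.384 (ν = 0.5)
and 1.273 (ν = 0), i.e. α = 3.26 and 3.00; C = 0.296 and 0.521
(a 76% increase at ν = 0, driven by the doubling of strain at fixed
stress as ν → 0, partly offset by the shape change).  These are
grid-converged and independent of the initial contour (hemispherical
and pointed caps agree to <1%).

**Signal families.**  Gaussian, and the exponential-power family
Λ = exp(−|s/a|^q) parametrized by (σ, excess kurtosis) through the
closed-form moments of the generalized normal distribution; q is found
by 1-D root finding on the monotone kurtosis–q relation, which is exact
and cheaper than the 2-D quadrature search the problem admits.  The
attainable excess kurtosis is (−1.2, ~85) for q ∈ (0.35, 80).

**Transition experiment.**  After an instantaneous width change
σ → σ + Δσ the evolution continues until the tip advances 10σ_new.  Two
statements are then read off the *imprinted* axial width profile w(z)
behind the cap: the transition length ΔL (axial span between the 25%
and 75% crossings between w_init and w_final) and the equilibration
extension (axial distance from the apex position at the switch to the
90% crossing), normalized by the mean of the two diameters so the
measure is symmetric in the sign of Δσ.  The "completion" level (90%)
and the normalization are package choices; both land the extension at
~0.5–0.6 cell diameters for Δσ = ±20%.

## Diameter-stability framework

The growth law d(w̄L)/dL = ασ_Λ(w̄, L) is integrated with an explicit
RK45 at rtol 1e−10.  The division map M(w) integrates one generation
(L₀ → 2L₀, L₀ = 2.5w₀ by default) — symmetric halving leaves the mean
width unchanged in this mean-field picture — and the fixed point w* is
the root of M(w) = w, located by a bracket scan plus Brent's method.
Trajectories that drive σ_Λ to zero (possible for strongly unstable
geometric models at small w) are counted as division width zero so the
scan still sees the sign change.  Stability is reported both as
β = w*·σ′_Λ/σ_Λ at the fixed point and as the measured per-generation
error multiplier (M(w*+ε) − w*)/ε; for the linearized model with γ = 0
the two are linked by multiplier = 2^(β−1), which the tests verify.

The spatially resolved lineage simulator lays down new material at the
growing end(s) at width α·σ_Λ(w̄, L) in 200 increments per generation,
divides at mid-length and follows the daughter at the new end (both
daughters optionally).  An optional moving-average smoothing over half
a cell radius emulates the diameter-equilibration transient; it is off
by default.

**Synthetic microtubule tip contacts.**  The generator draws meridional
contact distances from a half-Gaussian with a controllable ground-truth
scale — a stand-in with known truth for an external microtubule
mechanics simulation, not a mechanical model: no catastrophe/rescue
dynamics, no buckling, no force dependence.  What the passing pipeline
tests show is therefore that *if* tip contacts concentrate with a given
width profile, the fitting and stability analysis recover the right
conclusions; they say nothing about whether real microtubules produce
that profile.  The histogram fit is unweighted least squares of
A·exp(−x²/2σ²) on the binned density (bin width = sample σ/4 by
default); recovery is within a few percent at n = 10⁴.

**σ_MT(w̄) curve.**  The synthetic "unfocusing" curve
σ_MT = floor + slope·w + A/(w_c − w)^4 (floor 0.08 µm, slope 0.05,
A = 0.2, w_c = cell length + 0.5 µm, diameters up to the cell length)
encodes the qualitative features the analysis needs: strong focusing at
physiological diameters, near-linear growth, and a sharp unfocusing
spike as the diameter approaches the cell length.  With α ≈ 2.9–3.2 the
only intersection of σ_MT(w̄) with w̄/α sits on the spike (β ≫ 1,
unstable, at a diameter near the cell length); a stable intersection on
the shallow branch appears only for α of order 1/slope = 20.  Curve
fitting defaults to a monotone cubic spline (adequate for exact
tabulated data); for noisy fitted widths the analytic option
σ = a + b·w + A/(w_c − w) should be used, because a spline derivative
amplifies noise and makes β meaningless on the shallow branch.  When an
α has no intersection in the data range the analysis reports "no fixed
point" rather than failing.

## 2D whole-cell model

**Boundary.**  A closed polygon, counter-clockwise, resegmented along
periodic Catmull–Rom splines (100 resegmentations of a circle change
its area by <0.1%, versus ~1% erosion for linear resampling at the same
cadence).  The initial cell is 8 µm long: two caps shaped like the
steady 3D tip cross-section joined by straight flanks, with vertex
spacing 1/(8·κ_stencil) per the points-per-curvature rule.
Resegmentation runs when the spacing drifts more than 2% from uniform
(well inside the 10% uniformity contract) rather than unconditionally
every step; this is purely an efficiency choice.

**Stencil.**  The cross-section of the steady 3D tip, trimmed at the
cylindrical transition (|φ − π/2| < 1e−3) and scaled so its width is
α·σ_gz for the growth-zone width σ_gz (default chosen so the initial
cell is 3.2 µm wide).  Growth advances the vertex nearest the zone by
v·dt along the outward normal and pulls flanking vertices toward the
stencil point at the same arc distance, vetoing inward moves and
capping displacements at 2·v·dt·(1 − s/S).  The enclosed area never
decreases.  A de-novo protrusion grown on a flat flank converges to the
stencil width as the boundary grid refines (+2–3% at the default
spacing, within 2% at half the spacing); a cell grown from
stencil-shaped caps holds its width to ~0.2%.

**Growth-zone dynamics.**  Brownian dynamics
Δs = −∂_s U*·Δt + √(2 D_gz Δt)·R in the drag-absorbed landmark
potential U*(s) = −U₀ Σ exp(−d²/2σ_MT²) with wells at the two long-axis
endpoints (both wells attract every zone).  The long axis is a local
maximum of vertex-pair distance found by warm-started hill climbing
with a small joint-window polish that escapes vertex-scale plateaus at
rounded tips; for spherocylinder-like shapes it is the global maximum.
The time step is ε·min(σ_MT²/2D_gz, σ_MT/max|∂U*|, 1/(v·κ_stencil))
with ε = 0.01.

A bookkeeping point that turned out to be load-bearing: the zone is
anchored by *geometric position* (arc ↔ xy conversion each step, with
re-projection after the boundary moves), not by a persistent arc
coordinate.  Growth inserts boundary length at the tips, so a raw arc
coordinate is advected away from the wells; once the lag exceeds a few
σ_MT the zone grows an unguided side tube whose own apex becomes an
axis endpoint, and every parameter set ends bulged.

**Shape metrics.**  Bend is sin² of the angle between the final long
axis and the initial axis; vertex snap leaves a floor of ~2e−4, well
below the 0.0015 category threshold.  Width scans outward from each
axis endpoint to half the axis length and takes the maximum over one
flank of the minimal distance to the opposite flank.  The nearest-point
pairing is deliberate: pairing vertices symmetrically across the tip
measures diagonal chords on a bent tube (~1 µm too wide at banana
curvatures) and misclassifies bent cells as bulged.  Categories:
I if bend ≤ 0.0015 and width ≤ 3.45 µm, II if only the bend exceeds its
threshold, III otherwise (thresholds configurable).  Bent cells are
subclassified S versus banana by the midline's signed deviation from
the endpoint chord (S if both signs reach 25% of the maximum
deviation).

**Phase behavior.**  Defaults: U₀ = 0.2 µm²/min, total elongation
8 µm per 150 min split equally among zones, runs ending at axis
doubling or 3 generation times.  With one zone the three families
appear as: I at small D_gz and small σ_MT (e.g. 0.005 µm²/min, 0.5 µm),
II when the potential widens at small D (0.005, 2.0 — about 60% of
seeds), III at large D (1.0, any σ_MT).  With two zones the II band
sits at smaller D (0.002, 2–3 µm) because two zones give twice the
escape opportunities.  One-zone bent cells are banana-biased (~3:1,
direction drift compounds at a single tip); with two zones the tips
bend independently and S and banana occur in comparable numbers (6:5
over 40 seeds).  Phase maps in the test suite probe representative
cells (straight corner, bulged corner, bent band) rather than a full
grid; the (D = 1.0, σ_MT = 0.5) corner alone costs ~10⁶ Brownian steps
per cell and adds nothing qualitative.  The printed axes of the
reference phase diagrams are not available, so region placement is
reproduced as an ordering/topology statement, not at exact coordinates.

**Determinism.**  Every stochastic entry point takes an explicit seed;
phase maps derive per-cell seeds from the base seed and grid indices,
and repeated runs are bit-identical.

## Known limitations

* The tip model's Eq.-5 prefactor yields C ≈ 0.30 (ν = 0.5), implying a
  remodeling rate of ~0.028 s⁻¹ from the observed 2 µm/hr elongation,
  and a 76% (not ~96%) prefactor increase at ν = 0; u(ν = 0) computes
  to 1.273 rather than the published 1.23.  These are stable,
  grid-converged values of the equations as implemented; see the README
  reproduction section for how they are recomputed.
* No plastic wall flow, no 3D non-axisymmetric shapes (corkscrews), no
  T-shape initiation, no molecular Cdc42 reaction–diffusion model, no
  mechanical microtubule simulation — the tip-contact generator is a
  statistical stand-in with prescribed ground truth.
* The 2D axis approximation fails for extremely bent cells (the
  straight "microtubule" chord no longer reaches the tips); such shapes
  end up classified by their width.
* The bend metric cannot see C-shapes whose endpoints happen to align
  with the initial axis; the same limitation applies to the metric it
  reproduces.
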