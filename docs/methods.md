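# Methods

`crossbridge` implements two mechanokinetic models of the actomyosin
cross-bridge ensemble in striated muscle, both with switchable linear
(Hookean) or nonlinear cross-bridge elasticity, plus the steady-state
analyses built on them. The nonlinear option encodes the buckling of the
myosin subfragment-2 (S2) rod under compressive (drag-stroke) strain seen
in single-molecule optical-tweezers work: stiff for positive extension,
two orders of magnitude softer over most of the negative range.

Throughout, 1 kBT = 4 pN·nm (configurable), forces are in pN, extensions
in nm, and per-half-filament quantities convert to fibre tension through
294 myosin heads over a 2×10⁻¹⁵ m² lattice cross-section (200 pN ↔ 100 kPa).

## Elastic laws

Each attached biochemical state carries a piecewise-linear force-extension
law `F(e)` with `F(0) = 0`. The AM/AMD (rigor-like) law has positive-side
stiffness 2.8 pN/nm (2.5 pN/nm in the rigor model) and drag-stroke
segments with breakpoints at −4, −75 and −90 nm whose stiffnesses are
interpolated between the single-molecule extreme (c = 0) and the fully
linear law (c = 1):

    k_b(c)    = 0.308  + c (2.8 − 0.308)   pN/nm   (−4 < e < 0)
    S_low(c)  = 0.0326 + c (2.8 − 0.0326)  pN/nm   (−75 ≤ e < −4)
    k_d       = 2.8                        pN/nm   (−90 ≤ e < −75)

with obligate detachment below −90 nm. The standard nonlinear AM/AMD case
uses c = 0.0255 (S_low ≈ 0.10 pN/nm); the AMD_L and AMD_H states use a
single 0.12 pN/nm drag-stroke segment when nonlinear. Strain energies are
exact piecewise integrals. The rigor drag-stroke law reuses these segment
shapes rescaled by 2.5/2.8; the experimentally fitted cubic it stands in
for is unpublished, so an optional cubic mode accepts user coefficients.
This reconstruction is the dominant uncertainty in the rigor numbers and
is why rigor-level comparisons carry a ±15% band.

## Rigor model

Five actin sites per head (spacing 5.5 nm) compete for binding with
detachment `k_d = 0.0014·exp(|F| x_crit^R / kBT)` s⁻¹ (x_crit^R = 1.4 nm)
and attachment fixed by detailed balance against a −18 kBT rigor well,
capped at 10⁶ s⁻¹. Occupancies live on an 1100-point strain grid covering
one site spacing; sliding is a scalar strain offset shared by all heads; a
lumped linear series element (myofilament compliance, default k_se = 160
pN/nm) splits every imposed length change by the compliance ratio and is
re-balanced after each kinetic step via Δx = (k_se·x_se − ⟨F⟩)/(k_se+⟨S⟩).
Time stepping is per-point backward Euler, which is L-stable and conserves
probability exactly.

**Initial condition.** The fully relaxed (Boltzmann) distribution of this
model carries essentially no net force for *any* elasticity law: the
equilibrium average ⟨F e^(−E/kBT)⟩ is a boundary term. The isometric rigor
tension instead belongs to the kinetically trapped state formed when rigor
develops: heads attach in proportion to k_a within microseconds (the
strain dependence of k_d skews this distribution toward positive strain
for nonlinear laws), the series element is brought to force balance, and
subsequent redistribution is frozen on experimental timescales because
rigor detachment takes hundreds of seconds. `equilibrate(kind="induced")`
(default) returns this state; `kind="boltzmann"` returns the relaxed
distribution, which bears ~1 kPa and is used by the zero-force invariant
tests. With the default nonlinear law this yields ≈64 kPa rigor tension
and ≈49 kPa/nm probed sarcomere stiffness; the linear variant gives 0 kPa
and roughly twice the stiffness.

**k_se default.** The source range is 150–250 pN/nm. The default 160
pN/nm puts the myofilament share of half-sarcomere compliance at the
reported ≈2/3–70% at the rigor operating point; it is configurable.

**Stiffness probe.** A symmetric ±0.1 nm instantaneous length step with
frozen occupancies and restored series balance; the chord Δtension/Δlength
is reported. Sinusoidal probing at small amplitude is equivalent but not
deterministic to implement, so the chord is used.

## Active-contraction model

Five states per head — a detached MDP/AMDP pool (weak binding is a rapid
equilibrium K_w(x), nonzero only inside the attachment window
[−0.55, 16) nm), strongly bound AMD_L (pre-power-stroke), AMD_H
(post-power-stroke), a lumped AM/AMD state, and detached MT. Transition
rates are Kramers/Bell forms built from the elastic energies of the states
(Pi release with a symmetric energy split; power stroke with reversal
fixed at 2000 s⁻¹; a strain-gated nucleotide-pocket step k5; ATP-induced
detachment k_off combining k2(x) = k2(0)·exp(|F_AM| x_crit/kBT), ADP
release k6 and ATP binding K1; MT→MDP hydrolysis). Every rate is clamped
to [10⁻⁶, 10⁵] s⁻¹, the cap rising to 10⁶ s⁻¹ above 5000 nm/s.

Rate exponents use the local-quadratic elastic energy
`(k_s(x)/2)(x − x_j)²` with the tangent stiffness at x — identical to the
integrated energy for every single-segment law. For the multi-segment
nonlinear AM/AMD law the exactly integrated energy would flatten the
strain gate of k5 and leave drag-stroke AMD_H heads attached across the
whole span, contrary to the model's state distributions (attached AMD_L /
AMD_H vanish below −22 nm at all velocities); the local-quadratic form
preserves both the isometric rate limitation of k5 at positive strain and
its steep growth at negative strain. Forces, stiffnesses and observables
always use the true piecewise law.

Steady shortening at velocity v integrates da/dx = A(x)a/v from x = +14 nm
(attached states empty, detached states at their equilibrium split)
down to −91 nm with a stiff BDF solver and the exact Jacobian on a 0.05 nm
grid; halving the step changes ⟨F⟩ by <0.1%. The isometric limit solves
the per-x stationary distribution directly (states decouple at v = 0) and
matches the v = 1 nm/s solution to <1%. A periodic-boundary control
re-injects detached density exiting at −22 nm one 36 nm repeat up and
redirects detachment products born below that edge, iterated to
self-consistency, with attached AM/AMD tails retained in the extended
domain; at moderate velocities it agrees with the standard treatment to a
few per cent (the residual difference is the incomplete re-equilibration
of the MT/MDP split of re-entering heads).

Observables (per head): force, stiffness and attached fraction integrate
the attached states over the full span and normalize over one 36 nm
repeat; mean attached strain is the occupancy-weighted mean of (x − x_j);
ATP turnover integrates k_off·a_AM/AMD. The unloaded velocity V_max is the
zero crossing of ⟨F⟩(v), bracketed by doubling and bisected to 0.001
pN/head. K_M^v comes from a nonlinear least-squares fit of
v = V_max[T]/(K_M^v + [T]) (more robust than double-reciprocal
linearization). Thermodynamic efficiency is ⟨F⟩v/(⟨ATPase⟩·ΔG_ATP·kBT)
with ΔG_ATP = 25 kBT by default (an assumption; no value is fixed by the
source analyses, so efficiencies are comparative, not absolute).
Temperature enters only through Q10 scaling of the kinetic prefactors
(equilibrium constants unchanged), default Q10 = 2.9.

## Parameter provenance and calibration

The printed parameter set is incomplete: x1 = 7.7 nm, ΔG_w = 2.5 kBT, the
20 kBT depth of the AM/AMD state, kLH− = 2000 s⁻¹, k2(0) = 1800/1600 s⁻¹,
x_crit = 0.6/0 nm, the windows, caps and elasticity constants are printed;
the remaining kinetic constants (x2, x3, ksw, x_w, the ΔG split, kb0, K_C,
[P_i], k5 scale, k6, K1, hydrolysis) are not available and are
*reconstructed*: fixed by physical constraints (free-energy bookkeeping
summing to the printed 20 kBT; a ~1 nm second step, x2 − x3 = 1 nm;
standard actomyosin biochemistry for hydrolysis) and then calibrated so
the model reproduces printed steady-state outputs — the K_M^v bounds, the
isometric tension and strain, and the maximal-velocity anchors. The
packaged defaults file records the provenance of every entry.

The calibrated model reproduces the printed isometric mechanics (mean
attached strain 2.64/2.56 nm vs 2.43/2.54 nm; lattice-level tension
~175–215 kPa vs ~150 kPa), the K_M^v bounds (>0.3 mM nonlinear, <0.2 mM
for the high-k2 linear case, ~0.08 mM for the strain-dependent linear
standard), the qualitative orderings (attached-fraction ratios at V_max
0.13 < 0.17 < 0.37 for linear / AM/AMD-only / all-nonlinear), the drag
strains at V_max (−10.2 / −8.4 nm vs −10.83/−8.89 nm), the efficiency
maximum near 0.3 at intermediate load, and the *relative* effect of the
attachment-window edges on V_max to ~1%. The absolute velocity scale,
however, sits ≈20–30% below the printed anchors (e.g. ~14,400 vs 20,790
nm/s for the extreme nonlinear case): with the reconstructed detachment
pathway the saturating k_off cannot exceed ~1.2×10³ s⁻¹ once the K_M^v
bounds pin k6 and K1, and the isometric strain pins the power-stroke
depth, leaving no free parameter to raise the velocity level. This is a
genuine reconstruction limit, not a numerical issue, and the affected
comparisons are reported as such rather than re-tuned.

## Synthetic data

`synthetic` generates rectangular-hyperbola velocity-vs-[MgATP] curves and
piecewise-linear T1 (tension vs length-step) curves with known ground
truth and multiplicative Gaussian noise — proportional scatter mimicking
experimental variability; the generators are pure functions of
(parameters, seed). They emulate the *shape and noise structure* of such
experiments only: no instrument drift, no autocorrelated noise, no
sarcomere inhomogeneity. Passing recovery tests therefore demonstrates
correctness of the fitting code, not robustness to every artefact of real
recordings. A small table of printed experimental reference constants
(stiffness range 30–70 kPa/nm, rigor tension 30 ± 4 kPa, velocity range
13,000–18,000 nm/s, K_M^v ≈ 0.4 mM, active tension 150 kPa) is exposed for
comparison code.

## Numerical choices and limitations

- Backward Euler for rigor kinetics (probability-exact, L-stable); BDF
  with analytic Jacobian for the steady active system; per-x linear solve
  with a normalization row for the isometric limit.
- Problem sizes: 1100-point rigor grid, 2101-point active grid, ramps at
  1–1000 nm/s with ≤0.01 nm length increments — each full analysis runs in
  seconds to a couple of minutes on one core.
- Attachment-rate caps intentionally break detailed balance where binding
  is already effectively certain; results are insensitive while
  k_a ≫ k_d.
- The rigor model treats neighbouring sites as identical and ignores
  azimuthal geometry; the active model is one-site (one binding site per
  36 nm repeat), with the periodic control quantifying the error of that
  approximation.
- Not modelled: force transients (T1/T2 of active muscle), nonlinear
  myofilament elasticity, two-headed attachment kinetics in the active
  cycle, thin-filament regulation.
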