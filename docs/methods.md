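# Methods

`cytograd` models the spatial dynamics of interleukin-2 (IL-2) signaling
between T cells at three nested scales.  All three share one parameter set
(`cytograd.params.ModelParams`); concentrations are handled internally in
molecules/μm³ and converted with the exact Avogadro constant
(1 nM = 0.602214076 molecules/μm³).

## 1. Encounter time (units_params)

The characteristic time for a ligand to reach a receptor is the classical
two-stage estimate

    τ = 1/(4π D ρ c) + 1/(4 D d_R R c),

with diffusion constant D = 10 μm²/s, cell radius ρ = 5 μm, receptor
diameter d_R = 0.1 nm and R receptors per cell.  At c = 10 pM and R = 100
this gives τ ≈ 6.9 min — the quantitative seed of the whole analysis: bulk
picomolar concentrations are marginal for signaling, so local gradients
must carry the information.

## 2. Spherical-shell model (shell)

One secreting cell (radius ρ, secretion rate q, R receptors) sits at the
center; at steady state the extracellular concentration obeys Laplace's
equation, c(r) = A/r + B.  In the low-density scenario c → 0 at infinity;
in the high-density scenario N responder cells with R_resp receptors form
a concentrated Robin sink on the shell r = ρ + L (no shell thickness).
Binding enters through k_on c R with k_on = 111.6 (nM·h)⁻¹.  The flux
partition is J_auto = k_on c(ρ) R, J_para = q − J_auto; the two-equation
linear system for (A, B) is solved exactly, and a radial finite-difference
solve provides an independent oracle in the tests (for the low-density
case the outer boundary condition c′ + c/r = 0 is exact for decaying
solutions, so the oracle has no domain-truncation error).

The fast-diffusion (well-mixed) limit J_auto = q R/(R + N R_resp) is
provided separately; the exact solution converges to it as D → ∞.

## 3. Synapse model (synapse)

The immunological synapse is a cylinder: contact radius a = 2 μm, cleft
height l (20 nm for a tight synapse; 2 μm for "no synapse formed").  The
secreting cell is the z = 0 face, the opposed cell the z = l face, and the
rim r = a is absorbing (c = 0: escaped molecules do not return).
Secretion q and uptake k_on R c act on the faces; both are interpreted as
uniform flux densities over the contact discs (q/πa², k_on R c/πa²).
This is the reading that makes the face conditions dimensionally
consistent and r-independent, so the solution separates into Bessel modes

    c(r,z) = Σₙ fₙ(z) J₀(αₙ r/a),   J₀(αₙ) = 0,

with fₙ a combination of exp(−kₙz) and exp(−kₙ(l−z)) (kₙ = αₙ/a), kept in
this scaled basis so the 100:1 aspect ratio of a tight synapse never
overflows hyperbolic functions.  Each mode satisfies a 2×2 linear system
from the two Robin face conditions.

Truncation: the Bessel projection of the uniform source truncated at N
modes integrates to 4q·Σₙ αₙ⁻² < q (the Rayleigh sum converges to 1/4).
Disc uptake of mode n scales as g/(D kₙ) → 0, so the unrepresented
high-mode source content escapes through the rim; `flux_breakdown` adds
this closed-form tail to J_escape, after which J_auto + J_synapse +
J_escape = q holds to machine precision at any truncation.  The default
truncation (200 modes, doubled until the escape flux is stable to 10⁻⁴)
agrees with a fine axisymmetric finite-difference oracle to ≲10⁻⁴·q in
all three fluxes.

Two model predictions worth stating plainly, because they quantify the
geometry's power: a tight synapse between two receptor-poor cells reaches
nanomolar concentrations from a 10 molecules/s source, and a
receptor-rich (10⁴) opposed cell captures >80% of the secretion.  Under
the uniform-flux reading the escape flux from a tight synapse with an
upregulated (R = 4000) secretor is 6–11% of q depending on the opposed
cell; the often-quoted "≈20%" escape level is reached for receptor-poor
secretors or cleft heights ≳50 nm.  The tissue-scale default
q_eff = 7200 molecules/h (20% of q) is kept as the standard effective
secretion rate; `effective_secretion_rate` computes the model's own value
for any configuration.

Exact reflection symmetry between J_auto and J_synapse at R = R_resp is
impossible (the source sits on one face); the asymmetry is O(l/a), ~0.1%
for the tight synapse, and the tests verify both near-equality and the
decay of the asymmetry with l.

## 4. Receptor dynamics (kinetics)

Each non-secreting cell carries three pools — free surface receptors R_s,
surface complexes C, internalized receptors R_i — with

    dR_s/dt = v(C) − k_on c R_s + k_off C − k_iR R_s + k_rec R_i
    dC/dt   = k_on c R_s − (k_off + k_iC) C
    dR_i/dt = k_iR R_s + k_iC C − (k_rec + k_deg) R_i
    v(C)    = v0 + v1 C³/(K³ + C³)

Ligand is degraded when a complex is internalized, so the net extracellular
uptake is k_on c R_s − k_off C.  Expression parameters are the published
values (Th: v0 = 150, v1 = 3000; Treg: v0 = 1000, v1 = 8000 molecules/h;
K = 1000 complexes, Hill coefficient 3).

The trafficking rates are not printed in the source material; the package
defaults are a calibration with the following reasoning.  Dissociation
k_off = 0.83/h matches the ~10 pM equilibrium affinity of the
high-affinity receptor at k_on = 111.6 (nM·h)⁻¹.  Complex internalization
k_iC = 2.9/h corresponds to the measured 10–20 min surface half-life of
bound IL-2R.  Receptor recycling k_rec = 5/h with degradation
k_deg = 1/h means an internalized receptor is reused ~6 times before
destruction — without such a recycling multiplier the receptor supply cap
v0 + v1 ≈ 3150 receptors/h per cell could not absorb the population
secretion load at picomolar concentrations at all.  Free-receptor
turnover k_iR = 1.6/h places the basal Th surface level (v0·(k_rec+k_deg)
/(k_iR·k_deg) ≈ 560) between the basal (100) and upregulated (4000)
receptor numbers and gives deactivating cells an ~4 h relaxation time.
Jointly these rates put the cell's bistable window at ambient
concentrations of ≈4–33 pM (naive branch ignites above ≈33 pM during the
early transient; the activated branch persists down to ≈4 pM), which is
what converts a graded concentration field into the observed all-or-none
activation pattern.  All five rates are explicit, documented fields of
`ModelParams`/`CellKineticParams` and of every serialized configuration;
any study that has measured values should override them.

`steady_states` reduces the fixed-point problem to a scalar equation in
R_s on a log grid (the naive and induced branches differ by orders of
magnitude) and `hysteresis_scan` follows the stable branches up and down
a concentration ramp; the tests check the fixed points against long-time
ODE integration.

A cell counts as *activated* when its total surface receptor number
R_s + C exceeds 4000 (strictly); counting free receptors only is exposed
as an option.

## 5. Tissue simulator (tissue)

Geometry.  Cells are spheres (ρ = 5 μm) on a cubic lattice with
surface-to-surface spacing 5 μm (center pitch 15 μm).  A seeded generator
assigns roles — secretor, responder Th, Treg — in exact counts
(round(fraction·N)), and draws one uniform surface point per secretor as
its polarized secretion site.  Antigen-presenting cells are not
represented; the inter-cell space is freely diffusive medium.  The
largest centered lattice stands in for irregular counts (13³ = 2197 for
the ~2200-cell scenario, 17³ = 4913 for the pulse domain).

Discretization.  The extracellular field lives on a regular voxel grid
(default 2.5 μm = ρ/2; the voxelizer refuses anything coarser and
requires ≥30 surface voxels per cell).  Cells are excluded (no-flux)
voxel sets.  The outer boundary is closed by default (a dense culture in
a sealed volume); an absorbing option represents an open region and is
the default for the pulse experiment, where reflected ligand would
otherwise pile up artificially in the outermost cell layer.

Coupling.  Each cell's uptake k_on R_s c̄ is applied as a linear sink
spread uniformly over its surface voxels, with c̄ the surface-voxel
average; dissociation k_off C returns to the same voxels; polarized
secretion q_eff enters at the single voxel containing the secretion
point.  Receptor ODEs advance with c̄ as drive.

Time stepping.  Backward Euler for the field; the implicit system
(I + Δt(−DΔ + k_d + sink)) is symmetric positive definite and solved by
Jacobi-preconditioned conjugate gradients warm-started from the previous
step (relative tolerance 10⁻⁷), so the per-step change of the uptake coefficients
costs no refactorization.  The receptor ODEs use a vectorized linearly
implicit Euler step (the system matrix is Metzler, so the implicit step
preserves positivity; the Hill term is evaluated at the step start).
The step size grows geometrically from 2 ms toward Δt_max = 0.1 h and is
halved whenever any cell's surface receptor number moves by more than 8%
in one step, which resolves the early transient and coarsens the slow
relaxation.  A cumulative ledger (secreted = resident + taken up +
degraded + boundary outflux) is computed from the same discrete
operators and therefore closes to solver tolerance (~10⁻⁹ relative in
practice; the acceptance contract is 10⁻³).

Splitting error.  Uptake coefficients are frozen over a step while the
receptor states advance with the end-of-step field; the resulting error
is first order in Δt and is controlled by the step-size rule.  The tests
verify that halving the voxel size and tightening Δt_max moves the bulk
concentration by <5% and individual surface receptor numbers by <20% of
scale on a reference culture.

Pulse experiment.  The central cell releases one molecule-equivalent
uniformly over its surface for 7 s; all other cells hold fixed basal
receptor numbers and bind irreversibly.  Capture per cell, accumulated
as k_on R c̄ Δt, is the probability that the molecule travels that far;
binned over successive cubic (Chebyshev) cell layers it gives the
traveling-distance distribution.  The run ends when 99.9% of the release
is captured, degraded or absorbed at the boundary.  The homogenized
closed form P(travel ≤ r) = 1 − e^(−r/λ)(1 + r/λ), λ = √(D/k_hom),
k_hom = k_on R n_cell, is the comparison theory; with basal receptors
λ ≈ 81 μm ≈ 5.4 pitches, and the cubic-layer binning (a layer-ℓ cell
sits at mean Euclidean distance ≈1.3ℓ) puts the layer mode near 4.

## 6. Experiments layer

* `activation_summary` — activated/total per role at a time point.
* `treg_threshold_scan` — q_eff grid × seeds in a Th–Treg coculture;
  the suppression threshold is the midpoint between the largest q_eff
  with zero responder activation and the smallest with nonzero
  activation.  Without Tregs the same scan shows a graded response.
* `range_scan` / `fit_log_range` — single central secretor; the signal
  range is the distance from the domain center to the most distant
  activated cell in units of the 15 μm pitch, fitted to
  f(x) = a·ln(x/x₀) over nonzero ranges (zero ranges mean "nothing
  activated" and are excluded).  Synthetic-recovery tests require (a, x₀)
  back within 5% under 0.1-cell noise.
* `bulk_vs_local_report` — volume-averaged concentration time course,
  peak time, per-cell surface averages, local-to-bulk ratio.

## 7. What the simulations reproduce, and at what sizes

Default study conditions are the published ones: 216 cells with 54
secretors (q_eff = 7200 molecules/h, 30 h), optionally 54 Tregs; a
2197-cell domain for signaling range; a responder lattice for the pulse.
With the calibrated kinetics the package reproduces, without further
tuning: ~60–70 of 162 responders activated with a bimodal receptor
split and bulk ≈10 pM after a <10 h transient; complete suppression
(0/108) and a lower bulk with Tregs; a suppression threshold at
q_eff ≈ 2–3×10⁴ molecules/h with an all-or-none signature; ~70–85
activated cells around a q_eff = 10⁶ source with range growing as
ln(q_eff); and a traveling-distance mode 3–5 cell layers from the
source.  The test suite runs the 216-cell scenarios at full size and the
range/pulse scenarios at 7³–13³ lattices; these sizes are the package's
validation configurations, chosen so the whole suite stays desk-scale.

What the synthetic setups do **not** emulate: cell motility, division and
death; explicit antigen-presenting-cell geometry; synapse formation and
dissolution dynamics (the synapse enters only through q_eff and the
polarized source position); stochasticity of single-molecule transport
(concentrations are continuous fields, meaningful down to fractions of a
molecule per cell volume); and receptor heterogeneity within a cell type.
Passing tests therefore validate the reaction-diffusion/trafficking
mechanism, not cell-biological completeness.

## 8. Numerical edge cases

Zero secretion, zero receptors, and empty role classes are exact no-ops
(fields stay zero; fluxes are zero, not NaN).  Degenerate geometry
(overlapping cells, zero cleft height, unresolvable voxels) raises
immediately with the offending quantity named.  Concentration positivity
is guaranteed structurally (M-matrix implicit steps); the solver clips
solver-tolerance-level negatives and raises on anything larger.  The
synapse solver warns if doubling the truncation changes the escape flux
by >10⁻⁴ relative; the flux integrator raises if conservation is violated
beyond 10⁻⁶.
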