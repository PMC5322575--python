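# Methods

This note records the models, discretizations and numerical decisions behind
`rtetomo`, in the order data flows through the package.

## Forward model

Stationary radiative transfer on a convex 2D domain X (a disk of radius
10 mm unless configured otherwise):

    ω·∇u + (μa + μs) u = μs ∫ k(ω·ω′) u(·,ω′) dω′  in X × S¹,
    u = u_in on the inflow boundary {ω·ν < 0}.

Assumptions: μa, μs uniformly positive and bounded (enforced by validation
and, during inversion, by box projection); scattering by the 2D
Henyey–Greenstein kernel with anisotropy g ∈ (−1,1) (g = 0.9 in the standard
experiments — strongly forward-peaked, the tissue regime). Units are mm and
mm⁻¹ throughout.

### Angular discretization

Equispaced directions θ_p = 2πp/n_dir with midpoint weights 2π/n_dir; on an
equispaced grid this coincides with a mass-lumped linear angular FEM and
keeps the discrete kernel circulant. The kernel matrix k(ω_p·ω_q)·w_q is
row-renormalized to sum exactly to 1 so that conservative scattering
preserves intensity to machine precision (raw quadrature of the g = 0.9
kernel at 16–32 directions breaks conservation at the 1e-3 level, which a
photon-balance test would see). The lumped (rather than consistent) angular
mass matrix is a deliberate simplification: same convergence order, simpler
structure.

### Spatial discretization

Discontinuous Galerkin with a linear basis per triangle and upwind numerical
fluxes on interior edges; the inflow boundary condition enters weakly
through the boundary flux term. All element integrals (convection, edge
mass, element mass) are exact for polynomials, which matters below for the
adjoint. Per direction, unknowns are swept in a topological order of the
inter-element dependency graph (Kahn's algorithm; edges with |ω·n| ≤ 1e-12
do not couple; a cycle, should one survive, is broken at the smallest
centroid projection onto ω), so one sweep solves the advection–attenuation
operator exactly with one 3×3 solve per element.

### Scattering solve

The direction-coupled system is solved by source iteration — sweeps with the
scattering source lagged one iteration, algebraically a block Gauss–Seidel in
the direction blocks. In the experiments' regime the single-scattering albedo
μs/(μa+μs) ≈ 0.999 and plain source iteration contracts hopelessly slowly, so
by default the same fixed-point map is solved by LGMRES (`method="gmres"`,
tol 1e-8 relative residual, configurable); `method="source"` retains the
plain iteration with the residual measured as the relative max-norm change of
the scattering source. On a 60-element, 8-direction problem both agree with a
directly assembled-and-solved global sparse system to better than 1e-8
(tested). Within a reconstruction, solves are warm-started from the previous
outer iterate's fields.

### Meshes

Disk meshes are generated internally: M concentric rings, ring m carrying
about (target/M²)·m nodes, annuli triangulated by an angular zipper merge,
interior nodes jittered by 0.15 of the local spacing from a seeded generator
(so two meshes with different seeds or ring counts are genuinely different
discretizations). Element-count targets are hit exactly in the usual range;
total area converges to πR² from below as the polygon refines. With
`boundary_multiple=m`, the outer ring carries a multiple of m equispaced
nodes starting at angle 0 — used so that the nominal source/detector
positions are *exact boundary nodes of every mesh in an experiment*.

### Sources and detectors

Each source is a piecewise-linear hat peaked at its boundary node, supported
on the two adjacent boundary edges, collimated into the single grid direction
nearest the inward radial direction at the nominal angle, and normalized to
unit injected power (amplitude 2/support). Each detector reads the
hat-weighted average of the outgoing flux density around its node. Peak
normalization ("value 1 at the center node") is available, but the injected
power then scales with the local edge length — on two meshes of different
resolution the same "unit" source injects different energy, and the
cross-mesh inconsistency (measured at ~17% of the readings for our mesh
pairs) dwarfs the ~0.3% signal of small inclusions. Node anchoring plus
power normalization reduces the cross-mesh forward discrepancy to ~0.2%.

### Phantoms

Background plus circular inclusions, validated to lie inside the domain with
strictly positive coefficients. Two rasterizations: `centroid` (element value
= inclusion value iff the centroid is inside; the field is exactly
representable in the per-element basis — right for same-mesh studies) and
`exact` (partial-volume area-fraction blending by midpoint subdivision,
resolution 4⁻⁴). Dual-mesh experiments use `exact` on both the data and the
truth side: centroid rasterization quantizes an r = 0.5 mm inclusion
(2–3 elements) so coarsely that its integrated optical mass differs by tens
of percent between meshes, i.e. the two meshes would disagree about the
signal itself.

## Jacobian by adjoint transport

The sensitivity of reading j (source i) to μa on element k is
−∫_k ∫ u_i φ_j, with φ_j the adjoint radiance of detector j. By transport
reciprocity the adjoint problem is the forward problem with all directions
reversed; at the discrete level this is exact here: for upwind DG with
exactly integrated terms, transpose(T_ω) = T_{−ω} (Green's identity on each
element), and the symmetric circulant scatter matrix is reversal-invariant.
The detector functional, reversed, becomes inflow data w_q·(hat moments)/W
on the detector edges. Consequently the adjoint-based Jacobian matches
central finite differences of the discrete forward map to solver tolerance
(~1e-9 relative observed; the acceptance test requires 1e-3), entries are
nonpositive (more absorption, less transmitted light), and a full Jacobian
costs s forward solves (reused from the residual evaluation) plus d adjoint
solves, independent of the element count. The adjoint carries unit detector
weight — the alternative of weighting by the measured value would give the
derivative of ½M², not of M, and the finite-difference oracle pins the
convention down.

## Inversion

Split Bregman for J(μa) = ½ Σᵢ ‖Fᵢ(μa) − Mᵢ‖² + α TV(μa) + β‖μa‖₁, with
auxiliary variable D ≈ μa and Bregman variable b:

1. (Step 1*) μa ← argmin ½ Σ ‖Jᵢ δ + rᵢ‖² + α/2 ⟨L(μaⁿ)(μaⁿ+δ), μaⁿ+δ⟩
   + η/2 ‖Dⁿ − μaⁿ − δ − bⁿ‖², then projection onto [μ_min, μ_max]
   (default [1e-4, 1] mm⁻¹ — keeps the transport problem well-posed);
2. D ← shrink(μa + b, β/η) (soft thresholding componentwise);
3. b ← b + μa − D.

For piecewise-constant fields TV is the perimeter-weighted sum of
inter-element jumps, Σ_e |e|·|jump_e|; the smoothed version uses
√(jump² + ε²) (ε = 1e-6 in the experiments) and its lagged-diffusivity
linearization L(μaⁿ) is the edge-weighted graph Laplacian with weights
|e|/√(jump² + ε²), frozen once per outer iteration (one linear solve, no
inner Newton loop). The normal equations are derived directly from the
Step-1* objective and verified against an independently assembled quadratic
oracle. Initialization: μa⁰ = background, D⁰ = μa⁰, b⁰ = 0.

### Data-fidelity calibration

Residuals and Jacobian rows are calibrated per entry by the model's own
prediction at the initial (background) guess — fidelity on *relative*
misfits, with no further global scaling. This is standard referencing
practice in diffuse optical tomography and is essential in the dual-mesh
setting: systematic per-entry biases, including most of the discretization
difference between the data mesh and the inversion mesh, divide out (the
calibrated cross-mesh error is ~2e-4 per entry against a ~3e-3 signal,
versus a signal-to-model-error ratio of only ~1.4 on raw readings). Raw
("absolute") fidelity remains available but is not commensurate with the
default regularization weights, which assume readings of order one.

### Step control and stopping

Step 1* is a *damped* LM step: the damping λ starts at 0.1× the mean
Gauss–Newton diagonal, is multiplied by 10 whenever a trial step increases
the true inner objective (the Jacobian is reused; only the trial forward
evaluation is repeated) and divided by 3 on success. The accepted trial's
forward solves double as the next iteration's residual evaluation, so
accepted steps cost nothing extra. Without this control the weakly
regularized pure-L1 variant's first step is undamped Gauss–Newton on a
144-equation / ~1000-unknown system and diverges in solution space while
*decreasing* the misfit.

Stopping (the reference studies report iteration counts but no criterion):
relative iterate change below `stop_tol` (default 1e-4), an outer-iteration
cap, a divergence guard (objective up by >0.1% for 5 consecutive
iterations), and — in the dual-mesh experiment presets — a discrepancy-style
stop when the calibrated residual norm falls below 0.1× its initial value.
The last rule encodes "do not fit the data below the model's accuracy":
the measured cross-mesh model error (~0.2%) is about an order of magnitude
below the initial misfit (~2%), and in the noisy study the same rule stops
near the noise level. It is what terminates the semiconvergent pure-L1
iteration at its good iterate.

Error metrics follow the standard definitions
E_resi = ‖F(μaⁿ) − M‖₂/‖M‖₂ over all detector–source pairs and
E_mua = ‖μaⁿ − μa_true‖₂/‖μa_true‖₂ over elements, both as plain unweighted
Euclidean norms on the raw (uncalibrated) quantities.

## Synthetic experiments

The generator's defaults are the standard study conditions: disk radius
10 mm; 12 sources and 12 detectors, equispaced and interleaved; background
μa = 0.01, μs = 10 mm⁻¹ (multi-inclusion studies) or μa = 0.05, μs = 5 mm⁻¹
(high-absorption study); inclusion presets as named in
`rtetomo.phantom.PRESET_NAMES`; g = 0.9; 32 directions at full resolution;
noise M → M·(1 + δz), z i.i.d. standard normal, applied per entry. Data are
always synthesized on a finer mesh than the inversion uses (distinct ring
counts *and* jitter seeds), so the inversion never sees its own
discretization's data.

Problem sizes used by the test suite and the acceptance script — chosen once
to keep full runs in the minutes range on one CPU, and reported alongside
every result: 16 transport directions; multi-inclusion cases at half the
reference ring resolution (e.g. 1808-element data mesh / 1244-element
inversion mesh for the two-small-inclusion case); the high-absorption case
at its full 1288/856-element sizes. The white-box recovery test uses a
transport-regime background (μs = 2 mm⁻¹) so that 36 measurements carry
enough information for sub-10% recovery on a shared mesh.

What passing these experiments does and does not show: the synthetic data
share the solver's physics (a first-order 2D model, collimated impulse
sources, exact detector geometry, known μs). Real measurements add 3D
effects, refractive-index boundaries, source/detector coupling calibration
and model error far beyond the cross-mesh discrepancy emulated here, so the
error figures are best-case method comparisons, not clinical performance.

## Known limitations

- 2D only; μs is never reconstructed; frequency-domain and time-domain data
  are out of scope.
- First-order DG: collimated beams acquire crosswind diffusion; radiance can
  undershoot below zero by a small fraction of the peak near the source.
- The pure-L1 variant is stabilized by LM damping plus the discrepancy stop;
  run to full convergence it semiconverges (the fitted problem is badly
  underdetermined at 144 measurements).
- At desk-scale resolution the reconstruction errors of the multi-inclusion
  studies land below the full-resolution reference values (the discrepancy
  stop halts before speckle accumulates); the TV-L1 ≤ TV ≤ L1 ordering is
  the resolution-robust comparison.
- Angular collimation into a single discrete direction ties the incident
  field to the angular grid; comparing runs across different n_dir changes
  the injected direction slightly.
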