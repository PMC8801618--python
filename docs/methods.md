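# Methods

This note records the models, numerical choices and known limitations of
`luxtomo`, in the order the pipeline uses them.

## Transport models

**Diffusion (region 1).** Steady-state diffusion
`-∇·D∇Φ + μₐΦ = S`, `D = 1/(3(μₐ + (1−g)μₛ))`, with the Robin boundary
condition `Φ + 2AₙD ∂Φ/∂n = 0`.  P1 (linear) elements on tetrahedra; the
element stiffness, mass and boundary-face matrices use the closed-form linear
integrals (mass V/10 diagonal, V/20 off-diagonal; face mass area/6, area/12).
Optical properties are piecewise constant per element (organ-wise tables), so
no quadrature is needed anywhere in assembly.

**SP3 (region 2).** The third-order simplified spherical harmonics system in
the composite moments (φ₁, φ₂), with moment absorption coefficients
`μₐᵢ = μₐ + μₛ(1 − gⁱ)`, volume blocks

```
[ ∇·(1/3μₐ₁)∇ + μₐ          −(2/3)μₐ            ] [φ₁]   [  S     ]
[ −(2/3)μₐ                  ∇·(1/7μₐ₃)∇ + (4/9)μₐ + (5/9)μₐ₂ ] [φ₂] = [ −(2/3)S ]
```

and Marshak boundary terms `ξ₁₁,ξ₁₂` (φ₁ row) and `ξ₂₁,ξ₂₂` (φ₂ row) scaling
face mass matrices.  The physical fluence is `Φ = φ₁ − (2/3)φ₂` — this single
relation is isolated in one constant (`COMPOSITE_PHI2_WEIGHT`) because the
coupling, the right-hand side scaling {S, −(2/3)S} and the measurement
extraction must all use it consistently.  The −(2/3)μₐ volume coupling appears
in both off-diagonal blocks (the canonical symmetric weak form); a flag
restores the asymmetric variant for sensitivity studies.

**Boundary coefficients.** `Aₙ` uses the standard partial-current construction
from the Fresnel reflection moments `R_φ = ∫2μR(μ)dμ`, `R_j = ∫3μ²R(μ)dμ`:
`R_eff = (R_φ+R_j)/(2−R_φ+R_j)`, `Aₙ = (1+R_eff)/(1−R_eff)`.  The ξ table is
derived from the two odd-order (l = 1, 3) Marshak conditions applied to the P3
angular flux with partial Fresnel reflection, solved as a 2×2 system for the
normal-derivative terms.  All angular integrals use Gauss–Legendre panels
split at the total-internal-reflection angle, with a quadratic substitution on
the panel above it (the transmitted cosine behaves like √(μ−μ_c) there);
with this the table converges to machine precision by order 16.  The matched
boundary reduces to the closed forms ξ = [[1/2, −1/8], [−1/8, 7/24]], Aₙ = 1,
which the tests verify.  Default tissue refractive index: 1.37.

## Mesh regrouping and hybrid coupling

Region labels are a pure function of tissue (a tissue never straddles
regions).  `regroup_mesh` extracts the two region sub-meshes with *stable*
node renumbering (original relative order preserved — deterministic, and FEM
assembly is order-invariant), duplicating shared nodes into both sub-meshes by
copying coordinates.  Interface duplicates are therefore detected by exact
bitwise coordinate match (a tolerance mode exists for externally produced
meshes).  Sub-mesh boundary faces are the restriction of the *original outer*
boundary: interface faces are interior to the hybrid domain and never receive
Robin terms.

The hybrid system is the block diagonal diag(M_DE, M_SP3) with row layout
[Φ | φ₁ | φ₂] and dimension n₁ + 2n₂.  At each interface pair (d, s):

1. the φ₁ row of s is added into the Φ row of d (both are power balances at
   the same physical point; summing counts the interface flux once),
2. the φ₁ row is replaced by the constraint `φ₁ − Φ_d − (2/3)φ₂ = 0` (unit
   diagonal), and its F row is zeroed,
3. the φ₂ row of s is kept as an ordinary SP3 equation.

Which moment row to eliminate is not uniquely determined by physics; this
choice keeps the system square, preserves sparsity (pure row surgery), and is
validated by the two properties that *are* contractual: the hybrid reproduces
pure DE/SP3 exactly when one region is empty, and on a physically homogeneous
phantom split artificially into two regions its surface fluence tracks the
pure-model solutions to a few percent.  The uncoupled matrix is retained on
the result object so the surgery is unit-testable row by row.

## X-ray excitation

`S(r) = ε·X(r)·ρ(r)` with Beer–Lambert attenuation
`X = X₀ exp(−∫μ_t dl)` along a uniform parallel beam (the luminescence yield ε
is a free scale, default 1; the default μ_t = 0 models whole-domain
excitation, the usual phantom setting where S is placed directly).  Path
integrals use exact ray–tet face walking with 1e-12 parameter nudges; rays
lying exactly in lattice face planes are retried with a tiny perpendicular
jitter (≤1e-6 of the domain span, perturbing the integral by the same amount)
before a fine-step marching fallback.

## Forward solves and sensitivity

Sparse LU (SuperLU, COLAMD ordering) with a residual contract
‖Mx − b‖/‖b‖ < 1e-10 and an ILU-preconditioned GMRES fallback.  The
sensitivity matrix A = Q M⁻¹ F̃ (Q extracts composite fluence at measurable
boundary nodes, F̃ maps nodal source density through the mass blocks and the
{1, −2/3} field scaling) is built by blocks of adjoint (transpose) solves on
the same factorization — mathematically identical to forming M⁻¹F densely but
with one dense row per measurable node instead of a full dense inverse.
Multispectral systems stack per-wavelength blocks vertically, unweighted, with
the later wavelength first.

## Inverse problem

IVTCG for `min (1/2)‖AS − Φᵐ‖² + τ‖S‖₁, S ≥ 0`: variables enter the active
set one per outer iteration by largest negative-gradient violation
(gⱼ + τ < 0), a truncated CG pass (relative tolerance 1e-3) solves the
restricted normal equations warm-started from the current iterate, and the
step is projected to S ≥ 0 with backtracking so the objective never increases;
variables hitting zero leave the active set.  Outer stop: relative objective
change < 1e-6 with no remaining violations, or 50 outer iterations.  All
settings are arguments.  L1 is the default norm (it is what this solver family
is built for); ridge (L2) is available.

Two practical choices that the bare objective leaves open:

* **Column normalization (depth compensation).** Sensitivity columns of deep
  nodes are orders of magnitude weaker than superficial ones; un-normalized L1
  selection then places sources near the surface (we measured ~3 mm
  surface-ward bias on the six-organ phantom).  `column_normalize=True`
  rescales columns to unit norm before solving and undoes it afterwards — a
  weighted-L1 instance of the same objective and standard practice in optical
  tomography.  The pipeline and the recovery experiments use it.
* **τ heuristic.** τ = 10⁻³ · ‖AᵀΦᵐ‖∞ (on the normalized system), a fixed
  fraction of the smallest τ for which S = 0 is optimal.  Configurable.

Metrics: ARE = meanᵢ|simᵢ − refᵢ| / maxᵢ refᵢ (a single global maximum, not
nodewise); LE = distance of the energy-weighted centroid from the true centre;
Dice on the node set with S ≥ 30 % of max(S) (threshold configurable); CNR
with node-count weights and population variances, reporting ∞ when the pooled
variance vanishes with nonzero contrast.

## Synthetic phantoms

Structured-lattice meshing: the bounding box is cut into cubes of the target
element size and each cube into six Kuhn tetrahedra (face-consistent across
cubes).  Curved phantoms map the lattice onto the ball/disk by a blended radial
scaling (identity at the centre, `p → p·‖p‖∞/‖p‖₂` at the surface), so
boundary nodes lie exactly on the analytic surface — a smooth chordal boundary
instead of a voxel staircase, which matters whenever surface exitance is
compared against an analytic-geometry reference.  A `surface="voxel"` variant
keeps the masked staircase (cheaper interiors) for experiments that never look
at the surface.  Tissues are assigned per element by centroid-inside tests;
positivity of all element volumes is validated after mapping.

The six-organ phantom is a 35 mm tall, 10 mm radius cylinder (adipose
background; heart, two lungs, liver, stomach, two kidneys as spheres/an
ellipsoid) with a 1 mm radius, unit-density source inside the liver at
(3, 1, 14.5) mm.  It is a geometric stand-in: it reproduces the tissue set,
the published 610/630 nm optical parameters, the organ-wise DE/SP3 split and
the source geometry of a mouse-torso study, but none of the anatomy.  Passing
the recovery tests therefore demonstrates the method's correctness and noise
robustness on realistic optics and scale — not performance on real anatomy,
real detector physics, or free-space camera coupling.

The default region rule (diffusive when `μₛ(1−g) ≥ 10 μₐ`) assigns adipose,
stomach and kidneys to the diffusion region and heart, liver and lungs to the
SP3 region at both wavelengths, matching the published organ split; an
explicit override map is accepted everywhere.

## Reference oracles

* Analytic: `Φ(r) = exp(−μ_eff r)/(4πDr)`, the infinite-medium diffusion
  Green's function.
* Monte Carlo: photon-weight random walk (exponential steps with
  μ_t = μₐ + μₛ, Henyey–Greenstein scattering, absorption by weight
  attenuation, Russian roulette at weight 1e-4 with survival 0.1, Fresnel
  partial reflection at refractive boundaries) on *analytic* geometries
  (sphere, slab, infinite medium) — deliberately independent of the FEM mesh.
  Interior fluence uses the absorption estimator on radial shells; sphere
  exitance is binned on a (cosθ, φ) grid.  The weight bookkeeping is exact:
  absorbed + exited + net-roulette-terminated equals launched to rounding
  (asserted at 1e-10).  Fixed seed ⇒ bit-identical results.

## Experiment sizes and tolerances

Chosen so the whole suite runs on one desktop core in a few minutes:

* Green's-function benchmark: homogeneous sphere R = 16 mm, μₐ = 0.05,
  μₛ′ = 1.05 mm⁻¹ (transport length 0.95 mm), h = 1.28 → 0.64 mm
  (~9k → 71k nodes).  Comparison over 3–10 transport lengths in 14 radial
  shells; the radius leaves >6 transport-length buffer so the boundary's
  influence on the compared shells is well under the 5 % band.  Measured:
  5.4 % (coarse) → 1.1 % (fine).
* MC cross-validation: sphere R = 10 mm, μₐ = 0.01, μₛ = 1 mm⁻¹, g = 0,
  matched boundary, central isotropic source, 10⁶ photons, 10×10 surface
  bins; DE exitance `J = Φ/(2Aₙ)` binned per face.  ARE over top-decile bins
  measured ≈ 0.03 (MC per-bin relative standard error ≈ 0.01).
* Recovery: forward mesh h = 0.8 mm (~28k nodes), reconstruction mesh
  h = 1.0 mm (~16k nodes, mean edge 1.19 mm), every second boundary node
  measurable, 5 % multiplicative Gaussian noise, three seeds.  Measured LE
  0.2–0.6 mm, Dice ≈ 0.67, CNR ≫ 1 per wavelength; multispectral LE never
  above the worse single wavelength.

## Numerical details and degenerate inputs

* Tets are canonically reoriented to positive volume on construction;
  degenerate (zero-volume) tets and repeated vertices are rejected with the
  offending index.
* Assembly iterates elements in mesh order with duplicate-summing COO
  accumulation — repeated runs are bit-identical.
* An empty region short-circuits regrouping (the other sub-mesh is the input,
  no interface pairs), so the hybrid path is total.
* All-zero measurements reconstruct to S = 0; all-zero reconstructions report
  LE/Dice as undefined (None) rather than inventing a centre.
* P1 diffusion has no discrete maximum principle: small negative fluence
  values can appear far from sources on strongly absorbing phantoms.  They are
  not clamped; a spot check on a benign diffusive phantom asserts
  non-negativity, and the limitation is accepted elsewhere.

## Limitations

* The interface row-elimination choice (φ₁ absorbed into the DE row) is one of
  several consistent possibilities; it is validated through limit equivalence
  and continuity, not derived uniquely.
* The Monte Carlo oracle covers homogeneous analytic geometries only — it
  validates the transport solvers, not heterogeneous-anatomy forward accuracy.
* No free-space propagation, camera model, or CT-derived attenuation maps;
  X-ray excitation defaults to an unattenuated uniform beam.
* SP5/SP7, non-tet elements, mesh generation from segmentations, and
  regularization-parameter selection (L-curve etc.) are out of scope; τ is a
  user (or heuristic) choice.
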