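# luxtomo

Hybrid diffusion/SP3 finite-element light transport and source reconstruction
for X-ray luminescence computed tomography (XLCT).

## The problem

In XLCT an X-ray beam excites nanophosphors (e.g. Eu³⁺-based particles
emitting at 610/630 nm) inside tissue; the emitted optical photons diffuse to
the surface, where a camera measures the fluence, and the internal source
distribution must be reconstructed.  The forward model — how light travels
from the source to the surface — dominates both the accuracy and the cost of
the reconstruction:

* the **diffusion equation (DE)**, `-∇·D∇Φ + μₐΦ = S` with
  `D = 1/(3(μₐ + (1−g)μₛ))` and Robin boundary condition
  `Φ + 2AₙD ∂Φ/∂n = 0`, is cheap (one unknown per mesh node) but valid only
  where scattering dominates absorption;
* the **SP3 approximation** — two coupled composite moments (φ₁, φ₂) per node
  with physical fluence `Φ = φ₁ − (2/3)φ₂` — stays accurate in
  low-scattering, high-absorption organs (liver, heart, lungs at 610 nm) but
  doubles the unknowns everywhere.

`luxtomo` implements a **mesh-regrouping hybrid model**: the tetrahedral mesh
is split into a diffusion region and an SP3 region *by tissue* (diffusive when
`μₛ(1−g) ≥ 10 μₐ`), each region becomes its own sub-mesh with its own
independently assembled finite-element system, and the two systems are coupled
row-by-row at the interface nodes that were duplicated into both sub-meshes,
enforcing fluence continuity `Φ = φ₁ − (2/3)φ₂` there.  The coupled system

```
M Φ = F S,     dimension n₁ + 2 n₂
```

is smaller than a global SP3 system (2n) whenever most of the anatomy is
diffusive, and it contains the pure DE and pure SP3 models exactly as special
cases.  Sources are reconstructed from surface fluence by minimizing

```
(1/2) ‖A S − Φᵐ‖² + τ ‖S‖₁ ,   S ≥ 0
```

with an incomplete-variables truncated conjugate-gradient (IVTCG) scheme,
where `A` is the sensitivity matrix built from the factorized hybrid system by
adjoint solves, optionally stacked over multiple emission wavelengths.

The package also ships everything needed to exercise the method without any
external data: a deterministic phantom factory (including a six-organ
mouse-torso stand-in with the published 610/630 nm organ optics), a Monte
Carlo photon-transport reference, the analytic diffusion Green's function, an
X-ray excitation model (Beer–Lambert `S = ε·X·ρ`), and the standard evaluation
metrics (ARE, location error, Dice, CNR).

## Worked example

```python
from luxtomo import pipeline as pl

report = pl.run_pipeline({"model": "mrhm", "wavelengths": [610, 630],
                          "noise": 0.05, "seed": 1}, outdir="demo")
```

This builds the six-organ cylinder phantom twice (a fine forward mesh and a
coarser reconstruction mesh, so the inversion never sees its own
discretization), simulates the 1 mm spherical liver source with the hybrid
model at both wavelengths, adds 5 % measurement noise, reconstructs with
IVTCG on the stacked multispectral system, and reports

```json
{"LE": 0.296, "Dice": 0.5, "CNR": 323.0,
 "recon_center": [2.76, 1.03, 14.68], "true_center": [3.0, 1.0, 14.5]}
```

— the reconstructed energy-weighted centre sits 0.30 mm from the true source
centre (about a quarter of the mesh edge length), half of the thresholded
reconstruction overlaps the true source nodes, and the source contrast is two
orders of magnitude above the background noise.

The same stages are available as a CLI:

```bash
luxtomo phantom --element-size 1.0 --out phantom.vtk
luxtomo regroup --mesh phantom.vtk --out regrouped.vtk
luxtomo forward --mesh phantom.vtk --model mrhm --wavelength 610 --out meas.csv
luxtomo pipeline --config run.yaml --out results/
```

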