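# myofem

Finite-element modelling of skeletal muscle with **epimuscular myofascial
force transmission** — the transmission of muscle force through
connective-tissue pathways other than the tendons.

`myofem` implements a linked fiber–matrix dual-mesh model of a
unipennate (rat-EDL-like) muscle: two coincident meshes of 8-node
hexahedra represent the intracellular (myofiber) and extracellular-matrix
(ECM) domains, rigidly joined at the myotendinous junctions and tied
elastically everywhere else by zero-initial-length trans-sarcolemmal
links.  Spring elements connect the matrix mesh to mechanical ground
(extramuscular connections, e.g. the neurovascular tract) or to an
adjacent synergist muscle (intermuscular connections).  The package is
built to study a specific question: **how do myofascial loads create
fiber-direction strain distributions that locally oppose the globally
imposed length change** — shortened regions inside a passively
lengthened muscle, lengthened regions inside an isometrically
contracting one?

## Model

All stresses are second Piola–Kirchhoff, work-conjugate to the
Green–Lagrange strain `E` in a total-Lagrangian large-deformation
formulation, `S = dW/dE`.

* **ECM element** — anisotropic strain energy per local component
  (1 = cross-fiber, 2 = fiber, 3 = thickness):
  `W_ij(ε) = k (exp(a_ij ε) − a_ij ε)` with `k = 0.05`,
  `a11 = a33 = 8`, `a22 = 6`, `a12 = a23 = a31 = 6`; asymmetric in the
  normal directions, odd stress in shear.  A two-part volume penalty
  `W2 = Ss (I3 − 1)² + Sf (I3avg − 1)²` (`Ss = 5`, `Sf = 20`) treats the
  solid structures (pointwise) and the freely redistributing
  intracellular fluid (element mean) separately.
* **Myofiber element** — uniaxial Cauchy stress along the local fiber
  direction only: active part `b3·exp(b2 ε²)` (lengthening) /
  `b3·exp(b1 ε³)` (shortening) with `b1 = 30`, `b2 = −6`, peak 1.0 at
  zero strain; plus the intracellular passive (titin) parabola
  `t1 ε² + t2 ε + t3` (`0.522, 0.019, −0.002`), zero in shortening.
* **Aponeurosis element** — two-parameter Mooney–Rivlin law on reduced
  invariants, `W = a10 (Ī1 − 3) + a01 (Ī2 − 3) + κ/2 (Ī3 − 1)²`,
  `κ = 2(a10 + a01)/(1 − 2ν)`.
* **Links** — uniaxial linear springs: stiff/compliant extramuscular
  anchors (`k = 0.25` / `0.033` unit force/mm, the 7 most proximal
  stiff), intermuscular links (`k = 0.2`), and high-stiffness
  fiber–matrix ties.

The default muscle is 28.7 mm long; 3 elements in series form a fascicle
and 16 fascicles in parallel form the muscle (one element through the
slice thickness), giving the 4 fascicle sections × 17 fascicle
interfaces sampling grid used in all strain reports.

Three boundary-condition cases are encoded: **Case I** (passive
isometric with 2 mm distal position shift of both tendon ends),
**Case II** (Case I followed by 2 mm distal lengthening), and
**Case III** (Case I position shift, then activation ramped to maximal),
each runnable for the isolated, extramuscularly connected, or
epimuscularly connected (target + synergist) model.

## Worked example

```python
import numpy as np
from myofem import ScenarioSpec, run_case, fiber_strain_report

res = run_case(ScenarioSpec(model_variant="extramuscular", case="II"))
grid = fiber_strain_report(res).grid          # (face, section, interface)
sec1 = grid[0, 0]                             # lateral face, section I
print(np.round(100 * sec1[:7], 1))
print(f"grid min {100*grid.min():.1f}%  max {100*grid.max():.1f}%")
```

prints

```
[-6.5 -5.5 -5.9 -5.9 -5.6 -5.  -3.8]
grid min -6.5%  max 14.7%
```

— a muscle that was *lengthened* by 2 mm nevertheless *shortens* by up
to 6.5% in fascicle section I at interfaces 1–7, because the proximally
directed extramuscular loads (stiff neurovascular-tract links) beat the
imposed stretch locally, while the distal sections lengthen by up to
~15%.  The same pipeline drives the command line:

```bash
myofem run --model extra --case 2 --out out/extra_case2
myofem material-rig --out out/rig     # stress-strain curves as CSV
myofem verify                         # invariant self-checks
```

Each run directory receives the strain grid and per-section summary
(CSV), the myofascial load table, a proximo-distal force-balance
summary, a legacy-VTK snapshot of the deformed mesh and a JSON manifest
with the resolved configuration.

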