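# phaserestore

Curvature-based restoration of damaged binary interfaces with
boundary-controlled phase-field flows.

Segmentation masks of ring-like anatomical structures (a skull
cross-section in CT, a vessel wall, an annular tissue boundary) often come
back broken: part of the narrow band is missing and the downstream geometry
is useless until the interface is closed. `phaserestore` fills such gaps in
two steps, both running on the plain pixel grid of the mask — no meshing:

1. **Capture.** An Allen–Cahn (mean-curvature) flow, with the surviving
   feature pinned at order parameter φ = 1 through a binary boundary-control
   function G, relaxes a seed contour onto the feature and closes the gap
   with its convex hull. The steady state ψ̃ has area V₀.
2. **Reconstruction.** A Cahn–Hilliard flow — exactly mass-conserving in
   its discrete form — redistributes a supplemented area βV₀, injected as
   tanh disks, into the gap while the feature stays pinned. Sweeping β and
   scoring each steady contour by the curvature variation

   D_κ = ∮_Γ (dκ/ds)² ds

   (zero for a circle) identifies the supplement at which the restoration
   becomes circle-like.

The library surface is a model/results pair: `InterfaceRestoration` holds
the damaged mask and solver configuration, `fit()` runs
capture → β sweep → selection and returns a `RestorationResults` with the
captured field, the per-β steady fields and contours, the D_κ table and a
`summary()`. A thin `phaserestore` CLI wraps the same pipeline.

## Worked example

```python
import phaserestore as pr

model = pr.InterfaceRestoration.from_preset("half_circle", n=128)
res = model.fit([0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
print(res.summary())
```

```
Interface restoration results
================================================================
grid: 128 x 128 on 1 x 1  (h = 0.0078125)
epsilon: 0.0075047   supplement recipe: half_circle (1 disk(s))
capture: converged in 20164 steps (final diff-norm 4.984e-07)
captured area V0 = 0.108477
----------------------------------------------------------------
    beta        D_kappa         area      steps  conv
   0.200          12722     0.130463     204963  yes
   0.400         4544.1     0.152158     358978  yes
   0.600         1892.6     0.173854     532589  yes  <== selected
   0.800         1076.8     0.195549     686163  yes
   1.000         814.61     0.217244     812333  yes
   1.200         649.33     0.238940     938142  yes
----------------------------------------------------------------
selected beta = 0.6 (plateau rule, threshold 0.5)
```

The preset is the half-circle damage scenario: of a ring of radii
0.2/0.24 centred in the unit square only the lower half survives. The
capture step pins those cells and shrinks a seed circle (R₀ = 0.35) onto
them, closing the top with a straight chord (area V₀ ≈ 0.108). Each β row
is one conservative reconstruction carrying βV₀ of extra area: the enclosed
area grows linearly in β (mass conservation at work) while D_κ falls
monotonically as the junction corners round out — from 1.3·10⁴ at β = 0.2
to ~6.5·10² at β = 1.2, where the contour's isoperimetric ratio P²/(4πA)
is within ~3% of a circle's. The plateau rule proposes the smallest β whose
D_κ drop to the next entry falls below 50%; the full table is always
printed so the choice can be overridden.

The same pipeline runs from files:

```bash
phaserestore restore --mask damaged_ring.csv -n 128 --betas 0.2:1.2:0.2 \
    --outdir out/
phaserestore validate convergence --grids 32,64,128 --reference 256
phaserestore validate circle --r0 0.35
```

`restore` writes the captured field, per-β fields and contours (CSV), the
sweep table, and a provenance block sufficient to re-run bit-identically
(the solvers are deterministic — no randomness anywhere).

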