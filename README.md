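# vertexmech

Discrete-calculus mechanics of the planar vertex model for confluent
epithelia: monolayer topology via incidence matrices, area–perimeter
elasticity, Maxwell–Cremona force networks, the discrete Airy stress
function on kites, fabric tensors and the stress–geometry condition, and
the torque-balance (orthogonality + orthocentre) constraints with a
self-consistent dual-network constructor.

## Who this is for

Tissue-mechanics researchers who simulate epithelial monolayers with the
vertex model, or who infer stress from segmented microscopy, and want the
*full* mechanical bookkeeping — not just vertex force balance, but the
torque balances that standard implementations silently skip, and the
potentials (vector and scalar) that make stress fields exact on the mesh.

## The model

Cells are polygons tiling a simply connected patch of the plane, with
vertex positions `r_k` as degrees of freedom. Topology lives in two signed
incidence matrices, `A` (edges × vertices) and `B` (cells × edges), with
`BA = 0` expressing closed cell boundaries. Each cell carries the standard
mechanical energy

    U_i = ½ K_A (A_i − A₀)² + ½ Γ_L (L_i − L₀)²,

giving a pressure `P_i = K_A(A_i − A₀)`, a cortical tension
`T_i = Γ_L(L_i − L₀)`, per-(cell,vertex) forces `f_ik = ∂U_i/∂r_k`, and
the cell stress `σ_i = P_i I + (T_i L_i/A_i) Q_i` with effective pressure
`P_eff,i = P_i + T_i L_i/2A_i`. Under an isotropic boundary stress
`P_ext` (tension positive) any equilibrium obeys the conservation law
`Σ_i A_i P_eff,i = A P_ext`.

At equilibrium the forces rotated by π/2 close into a reciprocal network
whose vertices `h_j` (one per edge) form a vector force potential; a
scalar potential — the discrete Airy stress function `ψ_ik`, one value per
*kite* (the quadrilateral spanned by a cell centre, two adjacent edge
centroids and a shared vertex) — exists exactly when, additionally, all
torques balance. Torque balance is a geometric condition: each cell-centre
link `T_j` must cross its edge `t_j` orthogonally, and each interior
vertex must sit at the orthocentre of the triangle of its neighbouring
edge centroids. The fabric tensor `F_k` of the three-kite *tristar* around
each interior vertex then constrains the local stress orientation through
`F_k ε σ_k = 0`. The package computes every one of these objects, checks
all routes against each other, constructs orthocentric dual networks where
they exist, and quantifies the violation where they do not.

## Worked example

Relax a randomly perturbed 19-cell honeycomb under boundary tension with
the orthocentre constraints enforced, then interrogate the result:

```python
import numpy as np
from vertexmech import (ConstitutiveParams, build_incidence, partition,
                        primal_geometry, vertex_forces, relax_constrained,
                        construct_centres)
from vertexmech.fixtures import honeycomb, perturb
from vertexmech.stress import cell_stress_constitutive, global_stress
from vertexmech.dual import orthocentre_residuals
from vertexmech.geometry import vertex_triangles

mesh = perturb(honeycomb(2), amplitude=0.05, seed=7, freeze_boundary=False)
inc = partition(build_incidence(mesh))
params = ConstitutiveParams(K_A=1.0, A0=2.3383, Gamma_L=0.1, L0=5.4, P_ext=0.05)

state = relax_constrained(mesh, inc, params)
geom = primal_geometry(state.mesh, inc)
vertex_triangles(geom)
fs = vertex_forces(geom, params)

print(f"constraint residual : {state.constraint_residual:.2e}")
print(f"force residual      : {state.force_residual:.2e}")
print(f"orthocentre residual: {orthocentre_residuals(geom)['max_g']:.2e}")
sig = cell_stress_constitutive(geom, params)
print(f"P_eff (interior)    : {sig.P_eff[inc.cell_label == 1].mean():.6f}")
gl = global_stress(fs, geom)
print(f"sum A_i P_eff / A   : {gl['sum_A_Peff'] / gl['area']:.6f}  (P_ext = 0.05)")
dn = construct_centres(geom)
print(f"max |t.T| angle defect: {np.nanmax(np.abs(dn.orthogonality)):.2e}")
```

Output:

```
constraint residual : 1.97e-14
force residual      : 1.03e-13
orthocentre residual: 1.99e-14
P_eff (interior)    : 0.050000
sum A_i P_eff / A   : 0.050000  (P_ext = 0.05)
max |t.T| angle defect: 2.40e-14
```

The constrained minimization lands on the torque-balance manifold: every
interior vertex sits at the orthocentre of its edge-centroid triangle, a
fully orthogonal dual network of cell centres exists, and the mean
effective pressure reproduces the applied boundary stress exactly — the
conservation law is a virial identity, so its residual measures solver
quality, not modelling error. From here `build_potential`, `solve_airy`,
`tristar_stress` and `stress_geometry_check` give the force network, the
per-kite Airy scalars and the intercellular stress field; on a disordered
monolayer (try `fixtures.voronoi_monolayer(20, box=20**0.5, seed=42)`)
the same diagnostics report the generic *violation* of torque balance —
link–edge angles scatter around π/2 and no orthogonal dual exists.

A CLI mirrors the pipeline for shell use:

```bash
vertexmech generate --kind voronoi --n-cells 20 --box 4.47 --seed 42 -o mesh.json
vertexmech relax mesh.json --a0 1.0 --gamma-l 0 --p-ext 0.1 -o out/
vertexmech stress out/relaxed.json --a0 1.0 --gamma-l 0 --p-ext 0.1 -o out/
vertexmech check out/relaxed.json -o out/
vertexmech angles mesh.json -o out/
```

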