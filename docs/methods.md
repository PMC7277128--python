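# Methods

`vertexmech` implements the planar vertex model of a confluent epithelial
monolayer in the language of discrete calculus: signed incidence matrices
play the role of difference (coboundary) operators, and every mechanical
statement — force balance, torque balance, stress potentials — becomes an
exact linear identity on the mesh. This note records the model, the
conventions, the numerical choices, and what the synthetic test
conditions do and do not demonstrate.

## The primal network and its conventions

A monolayer is a simply connected patch of `N_c` polygonal cells with
vertices `r_k` (N_v of them) and straight oriented edges `t_j` (N_e). All
interior vertices are trijunctions; topological rearrangements (T1
neighbour exchanges, division, extrusion) are outside the model's scope —
the topology is fixed for the lifetime of a computation, and the
relaxation dynamics abort with an explicit error if an edge shrinks to
the degeneracy threshold rather than silently producing an invalid mesh.

Two incidence matrices encode the topology: `A` (edges × vertices, +1
into the head, −1 out of the tail) and `B` (cells × edges, +1 when the
edge runs with the cell's anticlockwise loop). `B A = 0` is the discrete
statement that cell boundaries close. Vertices, edges and cells are
partitioned into peripheral/interior, peripheral/border/interior and
border/interior classes respectively, giving the block forms of `A`, `B`
and the cell–vertex adjacency `C = B̄Ā/2`.

Rotation conventions, fixed once and used everywhere: `ε = [[0,1],[−1,0]]`
is the clockwise π/2 rotation generator (`εε = −I`); cells carry
orientation `ϵ_i = −ε` (anticlockwise), vertex triangles `ϵ_k = +ε`. With
these, the outward normal of cell i at edge j is `n_ij = −ϵ_i B_ij t_j`,
the oriented area satisfies `A_i ϵ_i = Σ_j B_ij t_j ⊗ c_j` (whose trace
gives the exact per-cell identity `Σ_j B_ij t_j·c_j = 0`), and the area
gradient is the outward-normal half-sum `∂A_i/∂r_k = +½ Σ_j n_ij Ā_jk`.
Every gradient in the package is validated against central finite
differences; where a printed formula in the source literature conflicts
with the finite-difference oracle, the oracle wins.

## Constitutive model and sign of the boundary load

Each cell has energy `U_i = ½K_A(A_i−A_0)² + ½Γ_L(L_i−L_0)²`, defining a
pressure `P_i = K_A(A_i−A_0)` and cortical tension `Γ_L(L_i−L_0)`. The
per-(cell,vertex) force is stored as the energy gradient
`f_ik = ∂U_i/∂r_k`; the restoring (Newtonian) force on the vertex is its
negative. With this convention the cell stress
`σ_i = P_i I + (T_i L_i/A_i) Q_i` (with the unit-trace structure tensor
`Q_i`) and the effective pressure `P_eff,i = P_i + T_i L_i/2A_i` come out
with tension counted positive.

The boundary stress `P_ext` is **tension positive**: a positive value
pulls the periphery outward, equilibrium minimizes `U − P_ext·A` (A the
monolayer area), and the conservation law

    Σ_i A_i P_eff,i = A · P_ext

holds *exactly* at any equilibrium (it is the virial identity
`Σ_k r_k · (net force)_k = 0`, so its residual measures the solver
tolerance, not modelling error). The opposite (compression-positive)
convention flips the signs of `σ`, `P_eff` and the law simultaneously;
we chose the branch in which the constitutive stress and the
conservation law are stated without minus signs.

## Force network and the Airy function

At equilibrium the forces rotated anticlockwise by π/2 close into
triangles around interior vertices and polygons around cells, so a
potential `h_j` (one 2-vector per edge) exists with
`h_{j_in} − h_{j_out} = −ε f_ik` per kite. We integrate it
breadth-first over the kite graph from the lowest-index peripheral edge
(pinned at the origin) and report the worst loop-closure defect; a state
that is not force balanced is rejected, because `h` would be path
dependent. Per-cell torque `Σ_j B_ij h_j·t_j` vanishes identically for
the area–perimeter family (σ_i is symmetric by construction); the
per-vertex torque `Σ_j A_jk h_j·T_j` against the dual links is the
quantity that generic simulations leave nonzero.

The discrete Airy function assigns one scalar `ψ_ik` per kite, with jumps
`h_j·t_j` across edge centroids (within a cell) and `h_j·T_j` across
edges (within a tristar). We solve the full over-determined jump system
in dense least squares with a gauge row (anchor kite at ψ = 0) rather
than integrating over a tree, so that any torque imbalance appears as a
quantified residual instead of path dependence. The system is consistent
exactly when all cell and vertex torque scalars vanish; reconstruction
of `h` from ψ (the curl over the four spokes around an edge centroid)
additionally requires the link–edge orthogonality `t_j·T_j = 0` and is
flagged invalid, with the per-edge orthogonality defect attached, where
that fails. Monolayers in this package are a few hundred kites at most,
so dense `lstsq` is both simplest and numerically safest; a sparse
solver would be the first change for larger meshes.

## Torque balance, the orthocentric dual, and the constrained solver

Torque balance forces two geometric conditions: every cell-centre link
must cross its edge at a right angle, and every interior vertex must sit
at the orthocentre of the triangle of its three neighbouring edge
centroids (`t_j · s_ik = 0` for the edge radiating outward from cell i).
Counting degrees of freedom, `2N_c` centre coordinates face `N_e − N_p`
orthogonality conditions, so large disordered monolayers generically
admit **no** orthogonal dual — the package treats that as a diagnosis,
not a failure: `construct_centres` raises with the defect attached, and
the angle histogram quantifies how far from π/2 the intersections sit.

`construct_centres` solves the similarity system `T_j(R) = A_jk μ_k s_ik`
(links antiparallel-to-far-side with one unknown scale μ_k per interior
vertex) as the non-translational null vector of a homogeneous linear
system via SVD. Both the tristar area `E_k` (linear in the centres,
because the links close around interior vertices) and `√(a_k U_k)` scale
linearly with the centre network, so the consistency relation
`E_k = 2√(a_k U_k)` is scale-free: it validates the solution but cannot
pin its size. The residual uniform scale is a genuine gauge of the dual
network; we fix it, together with the translation, by least-squares
proximity to the vertex centroids (on a regular lattice this returns the
exact hexagon centres).

The constrained relaxation realizes "minimize U subject to the
orthocentre constraints" as an augmented Lagrangian: L-BFGS inner solves
with the analytic gradient, multiplier updates `λ ← λ − ρ g`, and
ten-fold penalty escalation while the worst constraint stagnates. When
the converged multipliers are negligible — the constrained optimum is
also an unconstrained force balance — a damped-Newton polish (with a
finite-difference Hessian of the analytic gradient, pseudo-inverted
because rigid-body modes are soft) tightens the state to ~1e−13, and is
kept only if it preserves the constraints. At a constrained optimum with
*active* constraints the constitutive forces balance only against
constraint reactions, which the theory does not partition into
per-(cell,vertex) contributions; the force-network and Airy consistency
demonstrations therefore use study conditions whose constrained optimum
is a genuine force balance (below).

## Study conditions: what the synthetic tests show

The generators produce three families, all deterministic under a seed:

* **Honeycombs** (`n_rings` rings of side-`s` regular hexagons). Every
  closed-form value is known: `A = 3√3/2 s²`, `L = 6s`, kite area
  `√3/4 s²`, centroid-triangle area `3√3/16 s²`, tristar and
  centre-triangle areas `3√3/4 s²`, vanishing fabric tensor, `Q = I/2`.
* **Bounded Voronoi monolayers** (`n` uniform seeds in a box, mirrored
  across the walls so the cells tile the box exactly). The standard
  disordered fixture is 20 cells, seed 42, box `√20` (unit mean area).
* **Perturbations** (i.i.d. uniform vertex displacements, boundary
  optionally frozen, simplicity re-checked).

Two equilibrium conditions recur:

1. *Orthocentric with nonzero stress.* The perturbed two-ring honeycomb
   under `K_A = 1, A_0 = 0.9·(3√3/2), Γ_L = 0.1, L_0 = 5.4,
   P_ext = 0.05` relaxes (drag flow or constrained minimization alike)
   to a uniformly scaled *regular* lattice — a state with nonzero
   pressure and tension that satisfies every torque-balance condition to
   machine precision. All orthocentric-manifold claims (Airy
   consistency, h↔ψ round trip, `σ_k = εM_kᵀε`, stress–geometry, tristar
   consistency) are verified there at 1e−8 or better. Because the
   lattice is regular, its fabric tensor vanishes, so the
   stress–geometry condition holds vacuously at this state; the
   condition's *machinery* is additionally exercised with synthetic
   torque-balanced force fields (random `h` projected onto the zero-torque
   subspace) that carry generic nonzero stress.
2. *Disordered, torque-unbalanced.* The 20-cell Voronoi fixture relaxes
   in the pressure-dominated family (`K_A = 1, A_0 = 1, Γ_L = 0,
   P_ext = 0.1`). Any uniform positive cortical tension drives the
   fixture's shortest edge (length ≈ 0.03) through a neighbour exchange,
   which the fixed-topology model excludes, and the test suite asserts
   exactly that abort; the pressure-dominated family is the uniform
   parameter choice under which this disordered geometry has a
   fixed-topology equilibrium. This state is the negative control: force
   balanced to 1e−13 yet with orthogonality defects of order 10⁻¹ rad
   and no admissible orthogonal dual.

What passing these tests does *not* show about real epithelia: cells
here have straight edges, identical mechanical parameters, no internal
dissipation, and no topological plasticity; the disordered fixture's
pressure-dominated equilibrium has uniform cell pressure, which real
tissues with heterogeneous tension do not. The machinery itself (stress
routes, potentials, dual construction) is constitutive-independent and
applies to segmented data through the polygon-ingestion path.

## Numerical choices

* Degeneracy: edge lengths below `1e−12 ×` the monolayer diameter, and
  collinear centroid triangles at the squared threshold, raise immediately.
* Drag dynamics: explicit Euler with backtracking (step halved until the
  enthalpy does not increase, then gently re-grown), so the recorded
  energy trace is non-increasing by construction.
* Edge orientation is tail = lower vertex index; cell loops are stored
  anticlockwise and normalized on input; all per-kite quantities live in
  flat corner tables indexed by (cell, vertex) incidence.
* Force-network loop tolerance defaults to `1e−8 × max|f| × diameter`
  (scale aware); the dual-construction null-space threshold is
  `1e−7 × σ_max` with translations projected out explicitly.
* The acceptance script applies a seed-controlled random rigid motion to
  the fixtures before evaluating the trace identity, so the reported
  value also witnesses frame indifference.

## Known limitations

* At a constrained optimum with genuinely active constraints the
  Maxwell–Cremona construction needs a reaction-force partition that the
  theory leaves open; the package reports the torque residuals rather
  than inventing one.
* `construct_centres` assumes a single similarity mode; meshes with
  several independent orthocentric modes (possible in small or highly
  symmetric cases) would need the null-space basis inspected instead of
  its leading vector.
* Dense linear algebra throughout caps practical problem sizes at a few
  thousand kites; all study conditions here are well below that.
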