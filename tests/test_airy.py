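"""The discrete Airy stress function: jump system, reconstruction,
Laplacian pressures and the intracellular jump scale."""

import numpy as np
import pytest

from conftest import HONEY_PARAMS, make_inc
from vertexmech import fixtures
from vertexmech.airy import (intracellular_jump_scale, laplacian_operators,
                             laplacian_pressures, reconstruct_potential,
                             shape_tensor_D, solve_airy, stress_from_airy)
from vertexmech.constitutive import ConstitutiveParams
from vertexmech.dual import build_dual, centroid_centres
from vertexmech.force_network import build_potential
from vertexmech.geometry import primal_geometry, vertex_triangles
from vertexmech.stress import (cell_stress_constitutive, tristar_stress)


@pytest.fixture(scope="module")
def synthetic_airy(hc19):
    """A nontrivial torque-balanced force field on the regular lattice.

    The Airy jump system built from a potential h is consistent exactly
    when every cell torque ``sum_j B_ij h_j . t_j`` and every vertex
    torque ``sum_j A_jk h_j . T_j`` vanish, so a random h projected onto
    that linear subspace (synthetic: not produced by any constitutive
    model) gives a consistent field with generic, nonzero stress.  The
    induced forces ``f = -sum eps_i B h A`` balance identically.
    """
    mesh, inc = hc19
    g = primal_geometry(mesh, inc)
    vertex_triangles(g)
    dn = build_dual(g, centroid_centres(mesh, inc))
    rng = np.random.default_rng(11)
    h = rng.normal(size=(inc.n_edges, 2))
    # project onto zero cell/vertex torques: rows of constraints in h
    rows = []
    for i, ed in enumerate(inc.cell_edges):
        row = np.zeros(2 * inc.n_edges)
        for j, sg in ed:
            row[2 * j:2 * j + 2] = sg * g.t_vec[j]
        rows.append(row)
    for k in inc.interior_vertices:
        row = np.zeros(2 * inc.n_edges)
        for j in inc.vertex_edges[k]:
            row[2 * j:2 * j + 2] = int(inc.A[j, k]) * dn.T[j]
        rows.append(row)
    Mc = np.array(rows)
    x = h.ravel()
    h = (x - Mc.T @ np.linalg.lstsq(Mc @ Mc.T, Mc @ x, rcond=None)[0]).reshape(-1, 2)
    f = np.empty((inc.n_corners, 2))
    from vertexmech.topology import EPS
    for cid in range(inc.n_corners):
        f[cid] = EPS @ (h[inc.corner_jin[cid]] - h[inc.corner_jout[cid]])
    fp = build_potential(f, inc, g)
    # align the integrated gauge with the synthetic h before comparing
    fp.h = fp.h + (h[fp.anchor] - fp.h[fp.anchor])
    assert np.abs(fp.h - h).max() < 1e-10
    return {"mesh": mesh, "inc": inc, "geom": g, "dn": dn, "fp": fp, "h": h}


def test_synthetic_jump_system_consistent(synthetic_airy):
    """With all torque scalars projected out, the over-determined jump
    system is consistent: both residual families vanish, and the stress it
    encodes is nonzero (the test is not vacuous)."""
    st = synthetic_airy
    af = solve_airy(st["fp"], st["geom"], st["dn"].T)
    assert af.residual_cell < 1e-10
    assert af.residual_vertex < 1e-10
    assert np.abs(af.psi).max() > 1e-3


def test_jump_symmetry_across_edges(synthetic_airy):
    """The jump in psi across an edge is the same at both endpoints
    (the symmetric-jump identity)."""
    st = synthetic_airy
    inc = st["inc"]
    af = solve_airy(st["fp"], st["geom"], st["dn"].T)
    for j in inc.nonperipheral_edges:
        (i1, s1), (i2, s2) = inc.edge_cells[j]
        k1, k2 = (int(v) for v in inc.edges[j])
        d1 = af.psi[inc.corner_index[(i1, k1)]] - af.psi[inc.corner_index[(i2, k1)]]
        d2 = af.psi[inc.corner_index[(i1, k2)]] - af.psi[inc.corner_index[(i2, k2)]]
        assert abs(d1 - d2) < 1e-10


def test_collapsed_h_gives_constant_psi(hc7):
    """With zero forces the network collapses (h identical everywhere):
    all jumps vanish and psi is the gauge constant with zero Laplacian
    pressures.  A nonzero uniform h instead encodes the linear gauge field
    (jumps h . t), which still carries zero stress."""
    mesh, inc = hc7
    g = primal_geometry(mesh, inc)
    vertex_triangles(g)
    dn = build_dual(g, centroid_centres(mesh, inc))
    fp = build_potential(np.zeros((inc.n_corners, 2)), inc, g)
    af = solve_airy(fp, g, dn.T)
    assert np.abs(af.psi).max() < 1e-12
    lp = laplacian_pressures(af, dn.T)
    assert np.nanmax(np.abs(lp["cell"])) < 1e-12
    assert np.nanmax(np.abs(lp["vertex"])) < 1e-12

    fp.h = fp.h + np.array([0.7, -0.2])  # uniform potential, zero curl
    af2 = solve_airy(fp, g, dn.T)
    assert af2.residual_cell < 1e-10 and af2.residual_vertex < 1e-10
    assert np.abs(af2.psi).max() > 1e-3  # linear, not constant
    lp2 = laplacian_pressures(af2, dn.T)
    assert np.nanmax(np.abs(lp2["cell"])) < 1e-10
    assert np.nanmax(np.abs(lp2["vertex"])) < 1e-10


def test_potential_round_trip(synthetic_airy):
    """psi -> h (curl form) reproduces the input h on every non-peripheral
    edge, the projection decomposition agrees with the curl form, and no
    edge is flagged on the orthogonal lattice."""
    st = synthetic_airy
    inc = st["inc"]
    af = solve_airy(st["fp"], st["geom"], st["dn"].T)
    rec = reconstruct_potential(af, st["dn"].T)
    ie = inc.nonperipheral_edges
    assert np.nanmax(np.abs(rec["h"][ie] - st["fp"].h[ie])) < 1e-9
    assert np.nanmax(np.abs(rec["h_projection"][ie] - rec["h"][ie])) < 1e-9
    assert rec["flagged_edges"] == []


def test_airy_on_constitutive_equilibrium(honey_state):
    """On the orthocentric constitutive equilibrium the full chain holds:
    consistent jump system, h round trip, Laplacian pressures equal to the
    constitutive and tristar traces, and full tensors from psi equal the
    direct routes."""
    st = honey_state
    inc, g, fp, dn, par = st["inc"], st["geom"], st["fp"], st["dn"], st["params"]
    af = solve_airy(fp, g, dn.T)
    assert af.residual_cell < 1e-9 and af.residual_vertex < 1e-9
    rec = reconstruct_potential(af, dn.T)
    ie = inc.nonperipheral_edges
    assert np.nanmax(np.abs(rec["h"][ie] - fp.h[ie])) < 1e-8

    lp = laplacian_pressures(af, dn.T)
    s_c = cell_stress_constitutive(g, par)
    icells = np.flatnonzero(inc.cell_label == 1)
    assert np.abs(lp["cell"][icells] - s_c.P_eff[icells]).max() < 1e-8
    ts = tristar_stress(fp, g, dn.T, f=st["fs"].f)
    ki = inc.interior_vertices
    assert np.abs(lp["vertex"][ki] - ts["link"].P_eff).max() < 1e-8

    sa = stress_from_airy(af, dn.T)
    assert np.abs(sa["cell"][icells] - s_c.sigma[icells]).max() < 1e-8
    assert max(np.abs(sa["vertex"][k] - ts["link"].sigma[m]).max()
               for m, k in enumerate(ki)) < 1e-8
    assert np.nanmax(np.abs(sa["v_closure"])) < 1e-10


def test_shape_tensor_D_symmetry_and_trig_form(synthetic_airy):
    """D_i from the solved jumps: the direct and double-angle forms agree
    and the antisymmetric part vanishes (a consequence of
    sum_j v_ij = 0)."""
    st = synthetic_airy
    inc = st["inc"]
    af = solve_airy(st["fp"], st["geom"], st["dn"].T)
    for i in np.flatnonzero(inc.cell_label == 1):
        D = shape_tensor_D(af, i)
        assert np.abs(D["direct"] - D["trig"]).max() < 1e-10
        assert D["asymmetry"] < 1e-10


def test_nonorthogonal_reconstruction_degrades(voronoi_state):
    """On the disordered equilibrium with centroid centres the jump system
    is inconsistent (positive residual) and reconstruction error per edge
    grows with the orthogonality defect |that . That|."""
    st = voronoi_state
    inc, g, fp, dn = st["inc"], st["geom"], st["fp"], st["dn"]
    af = solve_airy(fp, g, dn.T)
    fscale = np.abs(fp.h).max()
    assert af.residual_norm > 1e-6 * fscale
    rec = reconstruct_potential(af, dn.T, orth_tol=np.inf)
    ie = inc.nonperipheral_edges
    err = np.hypot(*(rec["h"][ie] - fp.h[ie]).T)
    orth = rec["orthogonality"][ie]
    # rank correlation between defect and error must be clearly positive
    from scipy.stats import spearmanr
    rho, _ = spearmanr(orth, err)
    assert rho > 0.3


def test_intracellular_jump_scale(honey_state):
    """Within-cell psi variation scales with T_i L_i: zero tension gives
    zero jumps; doubling the tension (frozen geometry) doubles the
    minimum-norm jump set solved from the deviatoric matching; on the
    regular lattice the deviatoric matching residual vanishes."""
    st = honey_state
    g, fp, dn = st["geom"], st["fp"], st["dn"]
    af = solve_airy(fp, g, dn.T)
    res = intracellular_jump_scale(af, st["params"])
    assert np.nanmax(res["match_residual"]) < 1e-9

    # frozen geometry, zero tension: L0 set to the actual perimeters
    par0 = ConstitutiveParams(K_A=1.0, A0=st["params"].A0, Gamma_L=0.0,
                              L0=0.0, P_ext=st["params"].P_ext)
    res0 = intracellular_jump_scale(af, par0)
    for i, v in res0["v_solved"].items():
        assert np.abs(v).max() < 1e-12
    # doubling Gamma_L doubles T_i, hence the solved jumps
    par2 = ConstitutiveParams(K_A=1.0, A0=st["params"].A0,
                              Gamma_L=2 * st["params"].Gamma_L,
                              L0=st["params"].L0, P_ext=st["params"].P_ext)
    res2 = intracellular_jump_scale(af, par2)
    for i in res["v_solved"]:
        assert np.abs(res2["v_solved"][i] - 2 * res["v_solved"][i]).max() < 1e-10


def test_laplacian_operator_factorizations(honey_state):
    """The exposed weighted operators are built from the incidence
    matrices with diagonal Hodge weights and have the constant field in
    their kernel (Laplacian of a constant is zero)."""
    st = honey_state
    ops = laplacian_operators(st["geom"], st["dn"].T)
    Lv = ops["vertex_laplacian"]
    const = np.ones(Lv.shape[1])
    assert np.abs(Lv @ const).max() < 1e-10
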