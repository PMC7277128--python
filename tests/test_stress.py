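"""Cell and tristar stress: route equivalence, conservation, geometry."""

import numpy as np
import pytest

from conftest import VOR_PARAMS
from vertexmech.constitutive import ConstitutiveParams, vertex_forces
from vertexmech.geometry import primal_geometry, kites, fabric_tensor, vertex_triangles
from vertexmech.force_network import build_potential
from vertexmech.stress import (cell_stress_constitutive, cell_stress_from_forces,
                               cell_stress_from_potential,
                               effective_pressure,
                               effective_pressure_divergence,
                               force_triangle_area, global_stress,
                               map_stress_relation, stress_geometry_check,
                               stress_orientation, structure_tensor,
                               tristar_stress, tristar_stress_from_map,
                               vertex_map)
from vertexmech.topology import EPS, polygon_area

SQRT3 = np.sqrt(3.0)
HEX_PAR = ConstitutiveParams(K_A=1.0, A0=2.0, Gamma_L=0.1, L0=5.0)


def test_single_hexagon_stress_closed_form(hex1):
    """Isolated regular hexagon: Q_i = I/2 exactly, sigma = (P + 2T/sqrt3) I
    and P_eff = P + T L/(2A) = 0.713546 for the reference parameters."""
    mesh, inc = hex1
    g = primal_geometry(mesh, inc)
    fs = vertex_forces(g, HEX_PAR)
    Q = structure_tensor(g)
    assert np.abs(Q[0] - 0.5 * np.eye(2)).max() < 1e-12
    s_f = cell_stress_from_forces(fs, g)
    s_c = cell_stress_constitutive(g, HEX_PAR)
    P, T = fs.P[0], fs.T[0]
    expected = (P + 2.0 / SQRT3 * T) * np.eye(2)
    assert np.abs(s_f.sigma[0] - expected).max() < 1e-10
    assert np.abs(s_c.sigma[0] - expected).max() < 1e-12
    assert effective_pressure(g, HEX_PAR)[0] == pytest.approx(0.713546, abs=1e-6)
    # Q commutes with the shape tensor (both isotropic here)
    kites(g, mesh.vertices.mean(axis=0, keepdims=True))
    shape = sum(np.outer(g.q[c], g.q[c]) for c in range(inc.n_corners))
    assert np.abs(Q[0] @ shape - shape @ Q[0]).max() < 1e-12


def test_zero_forces_zero_stress(hc7):
    mesh, inc = hc7
    g = primal_geometry(mesh, inc)
    ref = ConstitutiveParams(K_A=1.0, A0=3 * SQRT3 / 2, Gamma_L=0.1, L0=6.0)
    fs = vertex_forces(g, ref)
    assert np.abs(cell_stress_from_forces(fs, g).sigma).max() < 1e-12


def test_spoke_form_equals_position_form(voronoi_state):
    """The spoke (q_ik) form equals the position (r_k) form whenever per-cell closure
    holds, for any choice of centres."""
    g, fs, dn = voronoi_state["geom"], voronoi_state["fs"], voronoi_state["dn"]
    s_r = cell_stress_from_forces(fs, g)
    s_q = cell_stress_from_forces(fs, g, centres=dn.centres)
    assert np.abs(s_r.sigma - s_q.sigma).max() < 1e-12


@pytest.mark.parametrize("state_name", ["honey_state", "voronoi_state"])
def test_cell_stress_route_equivalence(state_name, request):
    """sigma_i by forces, by the force potential and by the constitutive
    form agree to 1e-9 at any relaxed equilibrium; the divergence form of
    P_eff matches the half trace."""
    st = request.getfixturevalue(state_name)
    g, fs, fp, par = st["geom"], st["fs"], st["fp"], st["params"]
    s_f = cell_stress_from_forces(fs, g)
    s_h = cell_stress_from_potential(fp, g)
    s_c = cell_stress_constitutive(g, par)
    assert np.abs(s_f.sigma - s_c.sigma).max() < 1e-9
    assert np.abs(s_h.sigma - s_c.sigma).max() < 1e-9
    assert np.abs(effective_pressure_divergence(fp, g) - s_h.P_eff).max() < 1e-12
    assert s_h.asymmetry.max() < 1e-9


def test_potential_gauge_invariance(honey_state):
    """sigma_i from h is unchanged by a constant shift of h (the cell loop
    of edges closes)."""
    g, fp = honey_state["geom"], honey_state["fp"]
    base = cell_stress_from_potential(fp, g).sigma.copy()
    fp.h = fp.h + np.array([3.0, -7.0])
    try:
        shifted = cell_stress_from_potential(fp, g).sigma
    finally:
        fp.h = fp.h - np.array([3.0, -7.0])
    assert np.abs(base - shifted).max() < 1e-10


def test_tristar_stress_routes(honey_state):
    """Both printed forms of the tristar stress (spoke-force sum and
    T (x) h curl) agree, as do the divergence and trace forms of P_eff,k."""
    st = honey_state
    ts = tristar_stress(st["fp"], st["geom"], st["dn"].T, f=st["fs"].f)
    assert np.abs(ts["spoke"].sigma - ts["link"].sigma).max() < 1e-10
    ki = st["inc"].interior_vertices
    assert np.abs(ts["P_eff_divergence"][ki] - ts["link"].P_eff).max() < 1e-12
    assert ts["link"].asymmetry.max() < 1e-10


def test_vertex_map_action_and_map_stress(honey_state):
    """M_k sends each link s_ik to the rotated force -eps f_ik; on the
    orthocentric equilibrium sigma_k = eps M_k^T eps and the fabric route
    (eps E - F) M^T eps / E agrees with the direct routes."""
    st = honey_state
    g, inc, fs, fp = st["geom"], st["inc"], st["fs"], st["fp"]
    M = vertex_map(fp, g)
    for k in inc.interior_vertices:
        for c in g.tri_corners[k]:
            err = np.abs(M[int(k)] @ g.s[c] - (-EPS @ fs.f[c])).max()
            assert err < 1e-10
    ts = tristar_stress(fp, g, st["dn"].T, f=fs.f)
    assert map_stress_relation(M, ts["link"]).max() < 1e-9
    sm = tristar_stress_from_map(M, g)
    assert np.abs(sm.sigma - ts["link"].sigma).max() < 1e-9


def test_zero_forces_zero_map(hc7):
    mesh, inc = hc7
    g = primal_geometry(mesh, inc)
    vertex_triangles(g)
    fp = build_potential(np.zeros((inc.n_corners, 2)), inc, g)
    M = vertex_map(fp, g)
    assert max(np.abs(M[int(k)]).max() for k in inc.interior_vertices) == 0.0


def test_force_triangle_determinant_property(honey_state):
    """The force-network triangle at each interior vertex has signed area
    det(M_k) times the edge-centroid triangle area."""
    st = honey_state
    g, fp = st["geom"], st["fp"]
    M = vertex_map(fp, g)
    for k in st["inc"].interior_vertices:
        area_h = force_triangle_area(fp, g, int(k))
        assert area_h == pytest.approx(np.linalg.det(M[int(k)]) * g.a_k[k],
                                       abs=1e-12 + 1e-9 * abs(area_h))


@pytest.mark.parametrize("state_name", ["honey_state", "voronoi_state"])
def test_global_conservation_law(state_name, request):
    """At equilibrium under isotropic boundary stress the monolayer stress
    is P_ext I: sum_i A_i P_eff,i = A P_ext and the global deviatoric part
    vanishes."""
    st = request.getfixturevalue(state_name)
    gl = global_stress(st["fs"], st["geom"])
    assert abs(gl["relative_conservation_residual"]) < 1e-8
    scale = max(abs(st["params"].P_ext), 1e-3)
    assert gl["deviatoric_norm"] < 1e-8 * scale
    assert np.abs(gl["sigma"] - st["params"].P_ext * np.eye(2)).max() < 1e-8 * scale


def test_conservation_trivially_zero_without_load(hc19):
    """A stress-free reference honeycomb at P_ext = 0 has
    sum_i A_i P_eff,i = 0."""
    mesh, inc = hc19
    par = ConstitutiveParams(K_A=1.0, A0=3 * SQRT3 / 2, Gamma_L=0.1, L0=6.0)
    g = primal_geometry(mesh, inc)
    fs = vertex_forces(g, par)
    gl = global_stress(fs, g)
    assert abs(gl["sum_A_Peff"]) < 1e-10


def test_stress_geometry_condition(honey_state, voronoi_state):
    """F_k eps sigma_k vanishes on the orthocentric equilibrium (where the
    regular lattice in fact has F_k = 0: the condition is vacuous there)
    and is generically nonzero on the disordered equilibrium with centroid
    centres."""
    st = honey_state
    ts = tristar_stress(st["fp"], st["geom"], st["dn"].T, f=st["fs"].f)
    res = stress_geometry_check(st["geom"], ts["link"])
    assert res.max() < 1e-10
    assert np.abs(st["geom"].fabric[st["inc"].interior_vertices]).max() < 1e-9

    sv = voronoi_state
    kites(sv["geom"], sv["dn"].centres)
    fabric_tensor(sv["geom"])
    tsv = tristar_stress(sv["fp"], sv["geom"], sv["dn"].T, f=sv["fs"].f)
    resv = stress_geometry_check(sv["geom"], tsv["link"])
    scale = np.abs(sv["geom"].fabric).max() * np.abs(tsv["link"].sigma).max()
    assert resv.max() > 1e-3 * scale


def test_stress_orientation_reporting(voronoi_state):
    """Orientation inference runs on the disordered state: near-degenerate
    fabric tensors are flagged rather than raised on, alignment angles are
    finite, and the antisymmetric defect is reported."""
    sv = voronoi_state
    kites(sv["geom"], sv["dn"].centres)
    fabric_tensor(sv["geom"])
    tsv = tristar_stress(sv["fp"], sv["geom"], sv["dn"].T, f=sv["fs"].f)
    recs = stress_orientation(sv["geom"], tsv["link"])
    assert len(recs) == len(sv["inc"].interior_vertices)
    for rec in recs:
        assert np.isfinite(rec["alignment_angle"])
        assert rec["asymmetry"] >= 0.0
        assert isinstance(rec["degenerate_fabric"], (bool, np.bool_))
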