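"""Shared fixtures: canonical meshes and equilibrated states.

Two study conditions recur throughout the suite:

* ``eq_honeycomb`` -- the 19-cell perturbed honeycomb relaxed under a
  tension-positive boundary stress.  Its equilibrium is the uniformly
  scaled regular lattice, which is orthocentric with nonzero pressure and
  tension: the canonical state on the torque-balance manifold.
* ``eq_voronoi`` -- the 20-cell random Voronoi monolayer (seed 42)
  relaxed in the pressure-dominated model (no perimeter stiffness: with
  uniform cortical tension the fixture's shortest edge undergoes a
  neighbour exchange, which is outside the fixed-topology model).  The
  canonical disordered, non-orthocentric equilibrium.
"""

import numpy as np
import pytest

from vertexmech import constitutive as cons
from vertexmech import dual as dual_mod
from vertexmech import fixtures
from vertexmech import force_network as fnet
from vertexmech.geometry import fabric_tensor, kites, primal_geometry, vertex_triangles
from vertexmech.topology import build_incidence, partition

A_HEX = 3.0 * np.sqrt(3.0) / 2.0  # area of the unit regular hexagon

HONEY_PARAMS = cons.ConstitutiveParams(
    K_A=1.0, A0=0.9 * A_HEX, Gamma_L=0.1, L0=5.4, P_ext=0.05)
VOR_PARAMS = cons.ConstitutiveParams(
    K_A=1.0, A0=1.0, Gamma_L=0.0, L0=0.0, P_ext=0.1)


def make_inc(mesh):
    return partition(build_incidence(mesh))


@pytest.fixture(scope="session")
def hex1():
    mesh = fixtures.honeycomb(0)
    return mesh, make_inc(mesh)


@pytest.fixture(scope="session")
def hc7():
    mesh = fixtures.honeycomb(1)
    return mesh, make_inc(mesh)


@pytest.fixture(scope="session")
def hc19():
    mesh = fixtures.honeycomb(2)
    return mesh, make_inc(mesh)


@pytest.fixture(scope="session")
def vor20():
    mesh = fixtures.voronoi_monolayer(20, box=np.sqrt(20.0), seed=42)
    return mesh, make_inc(mesh)


@pytest.fixture(scope="session")
def wobbly19():
    """Perturbed 19-cell honeycomb (all vertices displaced)."""
    mesh = fixtures.perturb(fixtures.honeycomb(2), 0.05, seed=7,
                            freeze_boundary=False)
    return mesh, make_inc(mesh)


@pytest.fixture(scope="session")
def eq_honeycomb(wobbly19):
    """Orthocentric equilibrium with nonzero pressure and tension."""
    mesh, inc = wobbly19
    relaxed, _ = cons.relax_drag(mesh, inc, HONEY_PARAMS, tol=1e-3,
                                 max_steps=50_000, dt0=0.02)
    relaxed = cons.equilibrate(relaxed, inc, HONEY_PARAMS, tol=1e-13)
    return relaxed, inc


@pytest.fixture(scope="session")
def eq_voronoi(vor20):
    """Disordered pressure-dominated equilibrium under boundary tension."""
    mesh, inc = vor20
    relaxed, _ = cons.relax_drag(mesh, inc, VOR_PARAMS, tol=1e-4,
                                 max_steps=50_000, dt0=0.02)
    relaxed = cons.equilibrate(relaxed, inc, VOR_PARAMS, tol=1e-13)
    return relaxed, inc


@pytest.fixture(scope="session")
def honey_state(eq_honeycomb):
    """Fully assembled pipeline state on the orthocentric equilibrium."""
    mesh, inc = eq_honeycomb
    geom = primal_geometry(mesh, inc)
    vertex_triangles(geom)
    fs = cons.vertex_forces(geom, HONEY_PARAMS)
    fp = fnet.build_potential(fs, inc, geom)
    dn = dual_mod.construct_centres(geom)
    kites(geom, dn.centres)
    fabric_tensor(geom)
    return {"mesh": mesh, "inc": inc, "geom": geom, "fs": fs, "fp": fp,
            "dn": dn, "params": HONEY_PARAMS}


@pytest.fixture(scope="session")
def voronoi_state(eq_voronoi):
    """Assembled pipeline state on the disordered equilibrium, with
    centroid centres (the generic, non-orthocentric choice)."""
    mesh, inc = eq_voronoi
    geom = primal_geometry(mesh, inc)
    vertex_triangles(geom)
    fs = cons.vertex_forces(geom, VOR_PARAMS)
    fp = fnet.build_potential(fs, inc, geom)
    cen = dual_mod.centroid_centres(mesh, inc)
    dn = dual_mod.build_dual(geom, cen)
    fabric_tensor(geom)
    return {"mesh": mesh, "inc": inc, "geom": geom, "fs": fs, "fp": fp,
            "dn": dn, "params": VOR_PARAMS}
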