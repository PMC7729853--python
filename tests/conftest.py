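import numpy as np
import pytest

from epiboundary.core_geometry import CellPoly, Junction, MeshFrame, TissueTimeSeries
from epiboundary.synthetic_data import SimParams, make_lattice, run_simulation


def make_square_mesh(rows=3, cols=4, split=2, side=1.0, compartments=None):
    """Square-cell lattice: cells (r, c), left of `split` labelled A.

    A straight vertical A/P interface with 180-degree boundary angles —
    the hand-checkable counterpart of the hexagonal generator lattice.
    `compartments` overrides labels per cell id.
    """
    def vid(r, c):
        return r * (cols + 1) + c

    vertices = {vid(r, c): np.array([c * side, r * side])
                for r in range(rows + 1) for c in range(cols + 1)}
    cells = []
    rings = {}
    for r in range(rows):
        for c in range(cols):
            cid = r * cols + c
            ring = (vid(r, c), vid(r, c + 1), vid(r + 1, c + 1), vid(r + 1, c))
            rings[cid] = ring
            comp = "A" if c < split else "P"
            if compartments and cid in compartments:
                comp = compartments[cid]
            cells.append(CellPoly(cid, comp, ring))
    edge_cells = {}
    for cid, ring in rings.items():
        for a, b in zip(ring, ring[1:] + ring[:1]):
            edge_cells.setdefault(frozenset((a, b)), set()).add(cid)
    junctions = []
    for jid, edge in enumerate(sorted(edge_cells, key=sorted)):
        a, b = sorted(edge)
        junctions.append(Junction(jid, a, b,
                                  np.array([vertices[a], vertices[b]]),
                                  frozenset(edge_cells[edge])))
    return MeshFrame(0.0, vertices, junctions, cells)


def static_series(frame, n_frames=7, dt=0.5):
    """Repeat one frame: every dynamic statistic must vanish on this."""
    frames = []
    for i in range(n_frames):
        frames.append(MeshFrame(i * dt,
                                {v: np.array(p) for v, p in frame.vertices.items()},
                                [Junction(j.id, j.v1, j.v2, np.array(j.polyline), j.cells)
                                 for j in frame.junctions],
                                [CellPoly(c.id, c.compartment, c.ring) for c in frame.cells]))
    return TissueTimeSeries(frames, dt=dt)


@pytest.fixture(scope="session")
def square_mesh():
    return make_square_mesh()


@pytest.fixture(scope="session")
def hex_frame():
    return make_lattice(SimParams(n_protrusions=0))


@pytest.fixture(scope="session")
def small_run():
    """One short biased simulation shared by read-only tests."""
    params = SimParams(rows=6, cols=6, duration=16.0, adhesion_bias=0.4, seed=11)
    series, log = run_simulation(params)
    return params, series, log
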