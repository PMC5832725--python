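"""Arterial-ring geometry, structured hexahedral meshing and file I/O.

The isometric myograph specimen is an annular segment (inner/outer diameter
0.7/0.8 mm, 2 mm wide) mounted on two 0.25 mm steel hooks pulling along x.
Symmetry about the x, y and z planes reduces the model to one-eighth of the
ring: a quarter of the circumference (theta in [0, pi/2], theta = 0 on the
hook side) and half of the axial width (z in [0, w/2], vessel axis = z).

Hook contact is replaced by a prescribed-displacement node strip: the inner
surface nodes within the arc subtended by the hook radius at the symmetry
plane.  Each hexahedral element doubles as one smooth muscle cell; the cell
adjacency graph is the face-sharing graph of the mesh.

File formats: legacy-ASCII VTK unstructured grids, Gmsh MSH (v2.2 writer,
v2.2/v4.1 reader, hexahedra only) and CSV time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingGeometry",
    "RingMesh",
    "build_ring_mesh",
    "build_full_ring_mesh",
    "build_strip_mesh",
    "cell_graph_from_mesh",
    "circumferential_fibre",
    "write_vtk",
    "write_msh",
    "read_msh",
    "write_timeseries_csv",
    "MeshParseError",
]

TIMESERIES_COLUMNS = ("t", "cell_id", "chi", "zeta", "eta",
                      "n_M", "n_Mp", "n_AMp", "n_AM")


class MeshParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))
        self.line = line


@dataclass
class RingGeometry:
    """Myograph ring dimensions (mm)."""

    inner_diameter: float = 0.7
    outer_diameter: float = 0.8
    axial_width: float = 2.0
    hook_diameter: float = 0.25

    def __post_init__(self):
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 < inner_diameter < outer_diameter")
        if self.axial_width <= 0:
            raise ValueError("axial_width must be positive")

    @property
    def hook_arc(self) -> float:
        """Half-angle (rad) of the hook contact arc on the inner surface."""
        return math.asin(min(1.0, self.hook_diameter / self.inner_diameter))


@dataclass
class RingMesh:
    """Hexahedral mesh with tagged node sets and the cell adjacency graph."""

    nodes: np.ndarray                     # (nn, 3) mm
    elements: np.ndarray                  # (nel, 8)
    node_sets: dict = field(default_factory=dict)
    cell_of_element: np.ndarray = None    # element -> cell id (identity map)
    adjacency: list = None
    symmetry_factor: float = 1.0

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.cell_of_element is None:
            self.cell_of_element = np.arange(self.elements.shape[0])
        if self.adjacency is None:
            self.adjacency = cell_graph_from_mesh(self)

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def volume(self) -> float:
        """Total reference volume via the 8-point quadrature."""
        from .continuum_fe import _DNDXI, _det3
        xe = self.nodes[self.elements]
        j0 = np.einsum("eai,qaj->eqij", xe, _DNDXI)
        return float(_det3(j0).sum())


def _structured_hexes(nr: int, nc: int, na: int):
    """Connectivity of an (nr, nc, na) structured node grid."""
    def nid(ir, ic, iz):
        return (iz * (nc + 1) + ic) * (nr + 1) + ir

    hexes = []
    for iz in range(na):
        for ic in range(nc):
            for ir in range(nr):
                hexes.append([
                    nid(ir, ic, iz), nid(ir + 1, ic, iz),
                    nid(ir + 1, ic + 1, iz), nid(ir, ic + 1, iz),
                    nid(ir, ic, iz + 1), nid(ir + 1, ic, iz + 1),
                    nid(ir + 1, ic + 1, iz + 1), nid(ir, ic + 1, iz + 1)])
    return np.array(hexes, dtype=int)


def build_ring_mesh(geom: RingGeometry,
                    resolution: tuple[int, int, int] = (2, 24, 5)) -> RingMesh:
    """Structured one-eighth ring mesh with symmetry and hook node sets.

    ``resolution`` = (n_radial, n_circumferential, n_axial) elements; the
    element count is their product.  Node sets:

    * ``sym_y``: theta = 0 plane (y = 0), u_y constrained
    * ``sym_x``: theta = pi/2 plane (x = 0), u_x constrained
    * ``sym_z``: z = 0 mid-plane, u_z constrained
    * ``hook_contact``: inner-surface nodes with theta <= hook arc
    """
    nr, nc, na = resolution
    if nr < 1 or nc < 4 or na < 1:
        raise ValueError("resolution must be at least (1, 4, 1)")
    r_i, r_o = geom.inner_diameter / 2, geom.outer_diameter / 2
    radii = np.linspace(r_i, r_o, nr + 1)
    thetas = np.linspace(0.0, math.pi / 2, nc + 1)
    zs = np.linspace(0.0, geom.axial_width / 2, na + 1)
    nodes = np.array([[r * math.cos(t), r * math.sin(t), z]
                      for z in zs for t in thetas for r in radii])
    hexes = _structured_hexes(nr, nc, na)

    def nid(ir, ic, iz):
        return (iz * (nc + 1) + ic) * (nr + 1) + ir

    theta_hook = geom.hook_arc
    hook, sym_x, sym_y, sym_z = [], [], [], []
    for iz in range(na + 1):
        for ic in range(nc + 1):
            for ir in range(nr + 1):
                n = nid(ir, ic, iz)
                if ic == 0:
                    sym_y.append(n)
                if ic == nc:
                    sym_x.append(n)
                if iz == 0:
                    sym_z.append(n)
                if ir == 0 and thetas[ic] <= theta_hook + 1e-12:
                    hook.append(n)
    mesh = RingMesh(nodes=nodes, elements=hexes,
                    node_sets={"hook_contact": np.array(hook),
                               "sym_x": np.array(sym_x),
                               "sym_y": np.array(sym_y),
                               "sym_z": np.array(sym_z)},
                    symmetry_factor=4.0)
    return mesh


def build_full_ring_mesh(geom: RingGeometry,
                         resolution_octant: tuple[int, int, int] = (1, 6, 2)
                         ) -> RingMesh:
    """Full annulus mesh mirroring the one-eighth resolution per octant.

    Used to validate the symmetry reduction: two hook strips at theta ~ 0 and
    ~ pi (prescribed +/- x), ``mid_z`` (u_z = 0) and ``axis_y`` (u_y = 0 on
    the theta = 0/pi node lines) pin the symmetric rigid modes.
    """
    nr, nc8, na8 = resolution_octant
    # the one-eighth model spans a quarter circumference and half the width
    nc, na = 4 * nc8, 2 * na8
    r_i, r_o = geom.inner_diameter / 2, geom.outer_diameter / 2
    radii = np.linspace(r_i, r_o, nr + 1)
    thetas = np.linspace(0.0, 2 * math.pi, nc + 1)[:-1]
    zs = np.linspace(-geom.axial_width / 2, geom.axial_width / 2, na + 1)
    nodes = np.array([[r * math.cos(t), r * math.sin(t), z]
                      for z in zs for t in thetas for r in radii])

    def nid(ir, ic, iz):
        return (iz * nc + (ic % nc)) * (nr + 1) + ir

    hexes = []
    for iz in range(na):
        for ic in range(nc):
            for ir in range(nr):
                hexes.append([
                    nid(ir, ic, iz), nid(ir + 1, ic, iz),
                    nid(ir + 1, ic + 1, iz), nid(ir, ic + 1, iz),
                    nid(ir, ic, iz + 1), nid(ir + 1, ic, iz + 1),
                    nid(ir + 1, ic + 1, iz + 1), nid(ir, ic + 1, iz + 1)])
    theta_hook = geom.hook_arc
    hook_px, hook_mx, mid_z, axis_y = [], [], [], []
    for iz in range(na + 1):
        for ic in range(nc):
            for ir in range(nr + 1):
                n = nid(ir, ic, iz)
                t = thetas[ic]
                d0 = min(t, 2 * math.pi - t)          # distance to theta=0
                dpi = abs(t - math.pi)
                if ir == 0 and d0 <= theta_hook + 1e-12:
                    hook_px.append(n)
                if ir == 0 and dpi <= theta_hook + 1e-12:
                    hook_mx.append(n)
                if iz == na // 2:
                    mid_z.append(n)
                if d0 < 1e-12 or dpi < 1e-12:
                    axis_y.append(n)
    return RingMesh(nodes=nodes, elements=np.array(hexes, dtype=int),
                    node_sets={"hook_px": np.array(sorted(set(hook_px))),
                               "hook_mx": np.array(sorted(set(hook_mx))),
                               "mid_z": np.array(sorted(set(mid_z))),
                               "axis_y": np.array(sorted(set(axis_y)))},
                    symmetry_factor=1.0)


def build_strip_mesh(nx: int = 1, ny: int = 1, nz: int = 1,
                     lengths: tuple[float, float, float] = (1.0, 1.0, 1.0)
                     ) -> RingMesh:
    """Uniaxial test strip: a box of hexes, loaded along x.

    Node sets: ``fix_x`` (x=0), ``fix_y`` (y=0), ``fix_z`` (z=0) and
    ``hook_contact`` = loaded face x = Lx.
    """
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    nodes = np.array([[x, y, z] for z in zs for y in ys for x in xs])
    hexes = _structured_hexes(nx, ny, nz)
    idx = np.arange(nodes.shape[0])
    sets = {
        "fix_x": idx[np.isclose(nodes[:, 0], 0)],
        "fix_y": idx[np.isclose(nodes[:, 1], 0)],
        "fix_z": idx[np.isclose(nodes[:, 2], 0)],
        "hook_contact": idx[np.isclose(nodes[:, 0], lx)],
    }
    return RingMesh(nodes=nodes, elements=hexes, node_sets=sets,
                    symmetry_factor=1.0)


def myograph_bcs(mesh: RingMesh) -> dict:
    """Symmetry and hook-clamp boundary conditions: {(node, comp): value}.

    Symmetry planes constrain their normal components; the hook-contact
    strip is clamped in the loading plane (u_y = 0; u_x is prescribed by the
    loading phase), reflecting that the ring is clamped at the hooks.
    """
    comp_of = {"sym_x": 0, "sym_y": 1, "sym_z": 2,
               "fix_x": 0, "fix_y": 1, "fix_z": 2}
    bcs = {}
    for name, comp in comp_of.items():
        for n in mesh.node_sets.get(name, ()):
            bcs[(int(n), comp)] = 0.0
    if "sym_x" in mesh.node_sets:       # ring meshes: clamp the hook strip
        for n in mesh.node_sets.get("hook_contact", ()):
            bcs[(int(n), 1)] = 0.0
    return bcs


def cell_graph_from_mesh(mesh: "RingMesh", mode: str = "face") -> list:
    """Cell adjacency from shared element faces (or edges/vertices).

    ``mode='face'`` (default, gap junctions across shared membranes) links
    elements sharing a quadrilateral face; ``mode='vertex'`` links elements
    sharing any node.
    """
    faces_of_hex = ((0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                    (3, 2, 6, 7), (0, 3, 7, 4), (1, 2, 6, 5))
    nel = mesh.elements.shape[0]
    adjacency = [set() for _ in range(nel)]
    if mode == "face":
        seen: dict = {}
        for e, conn in enumerate(mesh.elements):
            for f in faces_of_hex:
                key = tuple(sorted(conn[list(f)]))
                if key in seen:
                    o = seen[key]
                    adjacency[e].add(o)
                    adjacency[o].add(e)
                else:
                    seen[key] = e
    elif mode == "vertex":
        by_node: dict = {}
        for e, conn in enumerate(mesh.elements):
            for n in conn:
                by_node.setdefault(n, []).append(e)
        for elems in by_node.values():
            for a in elems:
                for b in elems:
                    if a != b:
                        adjacency[a].add(b)
    else:
        raise ValueError("mode must be 'face' or 'vertex'")
    return [sorted(s) for s in adjacency]


def circumferential_fibre(mesh: RingMesh) -> np.ndarray:
    """Unit circumferential fibre direction at each Gauss point, (nel, 8, 3)."""
    from .continuum_fe import _GP, shape_values
    xe = mesh.nodes[mesh.elements]                  # (nel, 8, 3)
    out = np.empty((mesh.n_elements, 8, 3))
    for q, xi in enumerate(_GP):
        nvals = shape_values(xi)                    # (8,)
        x = np.einsum("a,eai->ei", nvals, xe)
        r = np.hypot(x[:, 0], x[:, 1])
        out[:, q, 0] = -x[:, 1] / r
        out[:, q, 1] = x[:, 0] / r
        out[:, q, 2] = 0.0
    return out


# --- file I/O -----------------------------------------------------------------

def write_vtk(mesh: RingMesh, fields: dict | None, path) -> None:
    """Legacy-ASCII VTK unstructured grid with optional cell/point data.

    ``fields`` maps names to arrays: length n_elements -> CELL_DATA, length
    n_nodes (or (n_nodes, 3)) -> POINT_DATA.
    """
    fields = fields or {}
    lines = ["# vtk DataFile Version 3.0", "vasoring output", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {9 * mesh.n_elements}")
    lines += ["8 " + " ".join(str(int(i)) for i in conn) for conn in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["12"] * mesh.n_elements
    cell_fields = {k: np.asarray(v) for k, v in fields.items()
                   if np.asarray(v).shape[0] == mesh.n_elements
                   and np.asarray(v).ndim == 1}
    point_fields = {k: np.asarray(v) for k, v in fields.items()
                    if k not in cell_fields}
    if cell_fields:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, arr in cell_fields.items():
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [f"{v:.17g}" for v in arr]
    if point_fields:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_fields.items():
            if arr.ndim == 2 and arr.shape == (mesh.n_nodes, 3):
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.17g}" for v in row) for row in arr]
            elif arr.shape == (mesh.n_nodes,):
                lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                lines += [f"{v:.17g}" for v in arr]
            else:
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected "
                                 f"({mesh.n_nodes},), ({mesh.n_nodes}, 3) or "
                                 f"({mesh.n_elements},)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_msh(mesh: RingMesh, path) -> None:
    """Gmsh MSH v2.2 ASCII writer (hexahedra, physical group 1)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat",
             "$Nodes", str(mesh.n_nodes)]
    lines += [f"{i + 1} " + " ".join(f"{v:.17g}" for v in p)
              for i, p in enumerate(mesh.nodes)]
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    lines += [f"{e + 1} 5 2 1 1 " + " ".join(str(int(i) + 1) for i in conn)
              for e, conn in enumerate(mesh.elements)]
    lines += ["$EndElements"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> RingMesh:
    """Read a Gmsh MSH file (v2.2 or v4.1 ASCII; hexahedral elements only)."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    try:
        i_fmt = raw.index("$MeshFormat")
    except ValueError:
        raise MeshParseError("missing $MeshFormat section", 1)
    version = raw[i_fmt + 1].split()[0]
    if version.startswith("2"):
        return _read_msh_v2(raw)
    if version.startswith("4"):
        return _read_msh_v4(raw)
    raise MeshParseError(f"unsupported MSH version {version}", i_fmt + 2)


def _read_msh_v2(raw: list) -> RingMesh:
    i_n = raw.index("$Nodes")
    n_nodes = int(raw[i_n + 1])
    nodes = np.empty((n_nodes, 3))
    ids = {}
    for k in range(n_nodes):
        parts = raw[i_n + 2 + k].split()
        if len(parts) != 4:
            raise MeshParseError("malformed node line", i_n + 3 + k)
        ids[int(parts[0])] = k
        nodes[k] = [float(v) for v in parts[1:]]
    i_e = raw.index("$Elements")
    n_elem = int(raw[i_e + 1])
    hexes = []
    for k in range(n_elem):
        line_no = i_e + 3 + k
        parts = raw[i_e + 2 + k].split()
        if len(parts) < 2:
            raise MeshParseError("malformed element line", line_no)
        etype = int(parts[1])
        if etype != 5:          # skip non-hex elements (surface tags etc.)
            continue
        ntags = int(parts[2])
        conn = parts[3 + ntags:]
        if len(conn) != 8:
            raise MeshParseError("hexahedron needs 8 nodes", line_no)
        hexes.append([ids[int(c)] for c in conn])
    if not hexes:
        raise MeshParseError("no hexahedral elements found")
    return RingMesh(nodes=nodes, elements=np.array(hexes, dtype=int))


def _read_msh_v4(raw: list) -> RingMesh:
    i_n = raw.index("$Nodes")
    header = raw[i_n + 1].split()
    n_blocks, n_nodes = int(header[0]), int(header[1])
    nodes = np.empty((n_nodes, 3))
    ids = {}
    row, k = i_n + 2, 0
    for _ in range(n_blocks):
        blk = raw[row].split()
        n_in_block = int(blk[3])
        tags = [int(raw[row + 1 + j]) for j in range(n_in_block)]
        for j in range(n_in_block):
            parts = raw[row + 1 + n_in_block + j].split()
            ids[tags[j]] = k
            nodes[k] = [float(v) for v in parts[:3]]
            k += 1
        row += 1 + 2 * n_in_block
    i_e = raw.index("$Elements")
    header = raw[i_e + 1].split()
    n_blocks = int(header[0])
    hexes = []
    row = i_e + 2
    for _ in range(n_blocks):
        blk = raw[row].split()
        etype, n_in_block = int(blk[2]), int(blk[3])
        for j in range(n_in_block):
            if etype == 5:
                parts = raw[row + 1 + j].split()
                hexes.append([ids[int(c)] for c in parts[1:9]])
        row += 1 + n_in_block
    if not hexes:
        raise MeshParseError("no hexahedral elements found")
    return RingMesh(nodes=nodes[:k], elements=np.array(hexes, dtype=int))


def write_timeseries_csv(records, path) -> None:
    """Per-cell state time series as CSV with the documented column schema."""
    df = pd.DataFrame(records, columns=list(TIMESERIES_COLUMNS))
    df.to_csv(path, index=False)
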