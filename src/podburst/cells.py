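"""Finite-element membrane model of pressurized exocarp cells.

Cells are rectangular boxes of turgid protoplast bounded by thin
orthotropic walls.  Walls are membrane-only (no bending stiffness):
each triangular element carries a St. Venant–Kirchhoff plane-stress
energy in a local material frame aligned with the global fruit axes
(x = length, y = width, z = depth), so the wall can be stiffer along
the fruit than across it — the anisotropy produced by longitudinal
cellulose microfibril alignment.  Turgor enters as a pressure potential
``-P V`` on the enclosed volume; equilibria are energy minima found by
quasi-Newton descent under an incremental pressure ramp.

This single model supports every cell-scale computation: free
inflation, osmotic steps (pressure end-states), CFM-style sphere
indentation, calibration of wall moduli against measured shape changes,
and the pulling force of a cell file held at its in-planta length —
the quantity compared across scales with the organ-level model.

The counter-intuitive headline behaviour is captured here: a shallow,
square cell (50 × 50 × 20 μm) with walls much stiffer along the fruit
axis *shortens* when pressurized, because the bulging top/bottom walls
pull the stiff longitudinal walls inward, while volume, width and depth
all grow.

Geometry inputs in μm and moduli in MPa (the natural units of the data);
the mesh and all energies are SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CellGeom", "WallMaterial", "CellMesh", "OsmoticResponse",
    "IndentationResult", "build_cell", "build_file", "inflate",
    "osmotic_response", "indentation_stiffness", "calibrate",
    "file_tension_force",
]

_UM = 1e-6
_MPA = 1e6

# face labels: 0 bottom (z-lo), 1 top (z-hi), 2 y-lo, 3 y-hi, 4 x-lo,
# 5 x-hi, 6 internal transverse walls; bounding faces per axis:
_AXIS_FACES = ((4, 5), (2, 3), (0, 1))


@dataclass(frozen=True)
class CellGeom:
    """Box cell: length × width × depth plus wall thickness (μm)."""

    length: float
    width: float
    depth: float
    wall_thickness: float = 1.0

    def __post_init__(self):
        if min(self.length, self.width, self.depth,
               self.wall_thickness) <= 0:
            raise ValueError("all cell dimensions must be positive")

    @property
    def dims(self) -> tuple:
        return (self.length, self.width, self.depth)


@dataclass(frozen=True)
class WallMaterial:
    """Orthotropic wall moduli (MPa) along the fruit's principal axes.

    ``E_length`` acts along x on every wall containing x; ``E_width``
    along y; ``E_depth`` along z on the side walls (defaults to
    ``E_width``).  A single Poisson ratio ``nu`` is used with the
    symmetric normalisation ``nu_12 = nu sqrt(E1/E2)`` so the compliance
    stays symmetric for any modulus ratio.
    """

    E_length: float
    E_width: float
    E_depth: float | None = None
    nu: float = 0.3
    model: str = "orthotropic"

    def __post_init__(self):
        if self.E_depth is None:
            object.__setattr__(self, "E_depth", self.E_width)
        if min(self.E_length, self.E_width, self.E_depth) <= 0:
            raise ValueError("moduli must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.model not in ("isotropic", "orthotropic"):
            raise ValueError("model must be isotropic or orthotropic")
        if self.model == "isotropic" and not (
                self.E_length == self.E_width == self.E_depth):
            raise ValueError("isotropic material requires equal moduli")

    @classmethod
    def isotropic(cls, E: float, nu: float = 0.3) -> "WallMaterial":
        return cls(E, E, E, nu, "isotropic")

    @property
    def axis_moduli(self) -> np.ndarray:
        """Moduli indexed by global axis (Pa)."""
        return np.array([self.E_length, self.E_width, self.E_depth]) * _MPA


@dataclass
class CellMesh:
    """Triangulated wall mesh (SI).

    ``axes[m]`` are the two global axes spanned by element ``m`` (its
    orthotropic frame); ``thickness[m]`` its wall thickness;
    ``envelope[m]`` marks outer-surface elements (they feel pressure and
    bound the enclosed volume; internal shared walls do not).
    """

    nodes: np.ndarray             # (N, 3) m
    tris: np.ndarray              # (M, 3) int
    axes: np.ndarray              # (M, 2) int
    thickness: np.ndarray         # (M,) m
    envelope: np.ndarray          # (M,) bool
    face: np.ndarray              # (M,) int label
    rest_nodes: np.ndarray = None  # (N, 3) m
    Dm_inv: np.ndarray = field(default=None, repr=False)
    area0: np.ndarray = field(default=None, repr=False)
    flip_v: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.rest_nodes is None:
            self.rest_nodes = self.nodes.copy()
        if self.Dm_inv is None:
            self._build_rest_metric()

    def _build_rest_metric(self):
        """Local 2D rest frames: the first material direction is the
        element's primary global axis projected onto its plane, the
        second its in-plane normal complement, so orthotropy follows a
        gently bowed wall."""
        X = self.rest_nodes
        t = self.tris
        e1 = X[t[:, 1]] - X[t[:, 0]]
        e2 = X[t[:, 2]] - X[t[:, 0]]
        n = np.cross(e1, e2)
        n_norm = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(n_norm < 1e-30):
            raise ValueError("degenerate rest triangle")
        n_hat = n / n_norm
        M = len(t)
        a1_vec = np.zeros((M, 3))
        a1_vec[np.arange(M), self.axes[:, 0]] = 1.0
        u = a1_vec - np.einsum("mi,mi->m", a1_vec, n_hat)[:, None] * n_hat
        u_norm = np.linalg.norm(u, axis=1, keepdims=True)
        bad = u_norm[:, 0] < 1e-8
        if np.any(bad):                      # wall normal ~ material axis
            alt = np.zeros((M, 3))
            alt[np.arange(M), self.axes[:, 1]] = 1.0
            u[bad] = alt[bad] - np.einsum(
                "mi,mi->m", alt[bad], n_hat[bad])[:, None] * n_hat[bad]
            u_norm = np.linalg.norm(u, axis=1, keepdims=True)
        u_hat = u / u_norm
        v_hat = np.cross(n_hat, u_hat)
        Dm = np.empty((M, 2, 2))
        Dm[:, 0, 0] = np.einsum("mi,mi->m", e1, u_hat)
        Dm[:, 0, 1] = np.einsum("mi,mi->m", e2, u_hat)
        Dm[:, 1, 0] = np.einsum("mi,mi->m", e1, v_hat)
        Dm[:, 1, 1] = np.einsum("mi,mi->m", e2, v_hat)
        det = np.linalg.det(Dm)
        if np.any(np.abs(det) < 1e-30):
            raise ValueError("degenerate rest triangle")
        self.Dm_inv = np.linalg.inv(Dm)
        self.area0 = 0.5 * np.abs(det)
        self.flip_v = np.sign(det)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def bounding_dims(self) -> np.ndarray:
        """Axis-aligned extents (m) of the deformed mesh."""
        return self.nodes.max(axis=0) - self.nodes.min(axis=0)

    def _junction_sel(self, axis: int):
        # junction nodes belong to >= 2 distinct wall faces (topological
        # edges of the box, robust to initial wall bowing)
        n_faces = int(self.face.max()) + 1
        member = np.zeros((self.n_nodes, n_faces), dtype=bool)
        for f in range(n_faces):
            member[self.tris[self.face == f].ravel(), f] = True
        on_edge = member.sum(axis=1) >= 2
        lo_face, hi_face = _AXIS_FACES[axis]
        sel_lo = on_edge & member[:, lo_face]
        sel_hi = on_edge & member[:, hi_face]
        return sel_lo, sel_hi

    def junction_extent(self, axis: int) -> float:
        """Distance (m) between the mean wall-junction rings on ``axis``.

        In tissue the visible cell boundary is the shared wall, so cell
        length/width are junction-to-junction distances; the free bulge
        of an unshared wall does not count.
        """
        sel_lo, sel_hi = self._junction_sel(axis)
        return float(self.nodes[sel_hi, axis].mean()
                     - self.nodes[sel_lo, axis].mean())

    def measured_dims(self) -> np.ndarray:
        """Cell dimensions as imaged in tissue (m).

        Length and width are junction-frame distances (cells abut their
        neighbours there); depth is the full z extent (top surface to
        bottom, including the outer-wall bulge seen in side view).
        """
        return np.array([self.junction_extent(0), self.junction_extent(1),
                         self.bounding_dims()[2]])

    def enclosed_volume(self, nodes: np.ndarray | None = None) -> float:
        x = self.nodes if nodes is None else nodes
        t = self.tris[self.envelope]
        x0, x1, x2 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
        return float(np.einsum("ij,ij->", x0, np.cross(x1, x2)) / 6.0)

    def surface_area(self) -> float:
        x = self.nodes
        t = self.tris[self.envelope]
        n = np.cross(x[t[:, 1]] - x[t[:, 0]], x[t[:, 2]] - x[t[:, 0]])
        return float(0.5 * np.linalg.norm(n, axis=1).sum())

    def min_angle_deg(self) -> float:
        x = self.nodes
        t = self.tris
        angs = []
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            u = x[t[:, b]] - x[t[:, a]]
            v = x[t[:, c]] - x[t[:, a]]
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
            angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angs))


# ---------------------------------------------------------------------------
# meshing


def _face_grid(origin, e1, e2, n1, n2, axis_pair, thickness, face_id,
               envelope=True):
    """Vertices and outward-wound triangles of one rectangular face."""
    verts = []
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            verts.append(origin + e1 * (i / n1) + e2 * (j / n2))
    verts = np.asarray(verts)
    tris = []
    for i in range(n1):
        for j in range(n2):
            a = i * (n2 + 1) + j
            b = (i + 1) * (n2 + 1) + j
            tris.append((a, b, b + 1))
            tris.append((a, b + 1, a + 1))
    tris = np.asarray(tris, dtype=int)
    M = len(tris)
    return (verts, tris, np.tile(axis_pair, (M, 1)),
            np.full(M, thickness), np.full(M, envelope, dtype=bool),
            np.full(M, face_id, dtype=int))


def _assemble(pieces, tol=1e-12):
    """Merge face grids, deduplicating shared edge nodes."""
    all_nodes = []
    tri_parts, ax_parts, th_parts, env_parts, face_parts = [], [], [], [], []
    node_map = {}
    idx_of = []
    for verts, tris, axes, th, env, face in pieces:
        local = np.empty(len(verts), dtype=int)
        for i, v in enumerate(verts):
            key = tuple(np.round(v / tol).astype(np.int64))
            if key not in node_map:
                node_map[key] = len(all_nodes)
                all_nodes.append(v)
            local[i] = node_map[key]
        tri_parts.append(local[tris])
        ax_parts.append(axes)
        th_parts.append(th)
        env_parts.append(env)
        face_parts.append(face)
    return (np.asarray(all_nodes), np.concatenate(tri_parts),
            np.concatenate(ax_parts), np.concatenate(th_parts),
            np.concatenate(env_parts), np.concatenate(face_parts))


def _box_divisions(dims_um, refinement):
    base = max(min(dims_um) / 2.0, 1e-9)
    return [max(1, round(d / base)) * refinement for d in dims_um]


def _apply_bulge(nodes: np.ndarray, dims: tuple, sag: float) -> np.ndarray:
    """Bow every face outward by a biquadratic sag profile.

    ``sag`` is the crest height as a fraction of the face's short
    semi-span.  Living cells are never flat-walled — even plasmolyzed
    cells keep rounded outlines — and an initially bowed wall is what
    lets further bulging contract the cell at first order (the
    air-muscle geometry).  The rest metric is computed on the bowed
    shape, so the bulged cell is unstressed.
    """
    if sag == 0.0:
        return nodes
    x = nodes.copy()
    lo = nodes.min(axis=0)
    hi = nodes.max(axis=0)
    span = hi - lo
    for axis in range(3):
        a1, a2 = [a for a in range(3) if a != axis]
        for side, sign in ((lo[axis], -1.0), (hi[axis], 1.0)):
            on = np.abs(nodes[:, axis] - side) < 1e-12
            u = (nodes[on, a1] - lo[a1]) / span[a1]
            v = (nodes[on, a2] - lo[a2]) / span[a2]
            h = sag * 0.5 * min(span[a1], span[a2])
            x[on, axis] += sign * h * 4 * u * (1 - u) * 4 * v * (1 - v)
    return x


def build_cell(geom: CellGeom, refinement: int = 2,
               shared_walls: bool = True,
               outer_wall_factor: float = 4.0,
               bulge: float = 0.2) -> CellMesh:
    """Triangulated box for a single exocarp cell.

    ``shared_walls`` doubles the side, transverse and bottom wall
    thickness to emulate walls shared with neighbours and the subtending
    mesocarp (each neighbour contributes one wall's worth).  The top
    (outer, cuticularized) epidermal wall is ``outer_wall_factor`` times
    the base thickness — outer periclinal walls of epidermal cells are
    characteristically much thicker than the internal walls.  Element
    count scales with ``refinement**2``.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    L, W, D = (d * _UM for d in geom.dims)
    t = geom.wall_thickness * _UM
    t_side = 2.0 * t if shared_walls else t
    t_top = outer_wall_factor * t
    nx, ny, nz = _box_divisions(geom.dims, refinement)
    ex, ey, ez = (np.array([L, 0, 0]), np.array([0, W, 0]),
                  np.array([0, 0, D]))
    o = np.zeros(3)
    pieces = [
        # z faces: bottom (inner, shared with mesocarp) and top (outer)
        _face_grid(o, ey, ex, ny, nx, (0, 1), t_side, 0),
        _face_grid(o + ez, ex, ey, nx, ny, (0, 1), t_top, 1),
        # y faces (long side walls)
        _face_grid(o, ex, ez, nx, nz, (0, 2), t_side, 2),
        _face_grid(o + ey, ez, ex, nz, nx, (0, 2), t_side, 3),
        # x faces (transverse end walls)
        _face_grid(o, ez, ey, nz, ny, (1, 2), t_side, 4),
        _face_grid(o + ex, ey, ez, ny, nz, (1, 2), t_side, 5),
    ]
    nodes, tris, axes, th, env, face = _assemble(pieces)
    nodes = _apply_bulge(nodes, geom.dims, bulge)
    mesh = CellMesh(nodes, tris, axes, th, env, face)
    if mesh.enclosed_volume() < 0:
        raise RuntimeError("mesh orientation error: negative volume")
    return mesh


def build_file(geom: CellGeom, n_cells: int, refinement: int = 2,
               outer_wall_factor: float = 4.0) -> CellMesh:
    """A file of ``n_cells`` boxes along x with shared transverse walls.

    The envelope is the outer box of the whole file, with the same wall
    model as the single-cell mesh: thick outer (top) wall, doubled
    bottom/side/end walls shared with the mesocarp and the neighbouring
    files; internal transverse walls are explicit membrane elements at
    the cell-cell interfaces (single thickness: one wall per interface).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    L, W, D = (d * _UM for d in geom.dims)
    t = geom.wall_thickness * _UM
    nx, ny, nz = _box_divisions(geom.dims, refinement)
    ex, ey, ez = (np.array([L * n_cells, 0, 0]), np.array([0, W, 0]),
                  np.array([0, 0, D]))
    exc = np.array([L, 0, 0])
    o = np.zeros(3)
    pieces = [
        _face_grid(o, ey, ex, ny, nx * n_cells, (0, 1), 2 * t, 0),
        _face_grid(o + ez, ex, ey, nx * n_cells, ny, (0, 1),
                   outer_wall_factor * t, 1),
        _face_grid(o, ex, ez, nx * n_cells, nz, (0, 2), 2 * t, 2),
        _face_grid(o + ey, ez, ex, nz, nx * n_cells, (0, 2), 2 * t, 3),
        _face_grid(o, ez, ey, nz, ny, (1, 2), 2 * t, 4),
        _face_grid(o + ex, ey, ez, ny, nz, (1, 2), 2 * t, 5),
    ]
    for c in range(1, n_cells):
        pieces.append(_face_grid(o + exc * c, ey, ez, ny, nz, (1, 2), t,
                                 6, envelope=False))
    nodes, tris, axes, th, env, face = _assemble(pieces)
    return CellMesh(nodes, tris, axes, th, env, face)


# ---------------------------------------------------------------------------
# membrane energy


def _element_stiffness(mesh: CellMesh, material: WallMaterial):
    Eax = material.axis_moduli
    E1 = Eax[mesh.axes[:, 0]]
    E2 = Eax[mesh.axes[:, 1]]
    nu = material.nu
    denom = 1.0 - nu ** 2
    Q11 = E1 / denom
    Q22 = E2 / denom
    Q12 = nu * np.sqrt(E1 * E2) / denom
    G = np.sqrt(E1 * E2) / (2.0 * (1.0 + nu))
    return Q11, Q22, Q12, G


def _strain_state(x: np.ndarray, mesh: CellMesh):
    t = mesh.tris
    Ds = np.stack([x[t[:, 1]] - x[t[:, 0]], x[t[:, 2]] - x[t[:, 0]]],
                  axis=2)                       # (M, 3, 2)
    F = Ds @ mesh.Dm_inv                        # (M, 3, 2)
    C = np.einsum("mia,mib->mab", F, F)
    e11 = 0.5 * (C[:, 0, 0] - 1.0)
    e22 = 0.5 * (C[:, 1, 1] - 1.0)
    e12 = 0.5 * C[:, 0, 1]
    return F, e11, e22, e12


def wrinkle_state(x: np.ndarray, mesh: CellMesh, Q) -> tuple:
    """Per-element tension-field branch: (wrinkled-1, wrinkled-2, slack).

    A membrane wall cannot carry compressive stress along a material
    axis — it folds.  Branch 1 folds across axis 1 (axis-1 stress would
    be negative while axis 2 is stretched), branch 2 the converse; a
    doubly unstretched element is slack.
    """
    Q11, Q22, Q12, G = Q
    _, e11, e22, e12 = _strain_state(x, mesh)
    S11 = Q11 * e11 + Q12 * e22
    S22 = Q12 * e11 + Q22 * e22
    w1 = (S11 < 0.0) & (e22 > 0.0)
    w2 = (S22 < 0.0) & (e11 > 0.0)
    slack = ((S11 < 0.0) & (e22 <= 0.0)) | ((S22 < 0.0) & (e11 <= 0.0))
    return w1, w2, slack


def _membrane_energy_grad(x: np.ndarray, mesh: CellMesh, Q,
                          branch: tuple | None = None) -> tuple:
    """Membrane energy (J) and gradient wrt node positions.

    Plane-stress SVK per element; with ``branch`` (masks from
    :func:`wrinkle_state`) the element stiffness is replaced by the
    tension-field relaxation of that branch: zero stress across a fold,
    uniaxially condensed stiffness along it, nothing in slack elements
    (plus ~0.1% residual stiffness so the energy stays definite).  The
    branch is frozen during each solve and updated in an outer loop —
    the standard wrinkling iteration for membrane finite elements.
    """
    Q11, Q22, Q12, G = Q
    t = mesh.tris
    F, e11, e22, e12 = _strain_state(x, mesh)
    if branch is None:
        S11 = Q11 * e11 + Q12 * e22
        S22 = Q12 * e11 + Q22 * e22
        S12 = 2.0 * G * e12
    else:
        w1, w2, slack = branch
        taut = ~(w1 | w2 | slack)
        Q22u = Q22 - Q12 ** 2 / Q11
        Q11u = Q11 - Q12 ** 2 / Q22
        eta = 1e-3 * np.minimum(Q11, Q22)
        S11 = np.where(taut, Q11 * e11 + Q12 * e22,
                       np.where(w2, Q11u * e11, 0.0)) + eta * e11
        S22 = np.where(taut, Q12 * e11 + Q22 * e22,
                       np.where(w1, Q22u * e22, 0.0)) + eta * e22
        S12 = np.where(slack, eta * e12, 2.0 * G * e12)
    w = mesh.thickness * mesh.area0
    psi = 0.5 * (S11 * e11 + S22 * e22 + 2.0 * S12 * e12)
    E = float(np.sum(w * psi))
    S = np.empty((len(t), 2, 2))
    S[:, 0, 0] = S11
    S[:, 1, 1] = S22
    S[:, 0, 1] = S[:, 1, 0] = S12
    P = F @ S                                   # (M, 3, 2) first PK
    dDs = np.einsum("m,mia,mba->mib", w, P, mesh.Dm_inv)  # (M, 3, 2)
    G_nodes = np.zeros_like(x)
    np.add.at(G_nodes, t[:, 1], dDs[:, :, 0])
    np.add.at(G_nodes, t[:, 2], dDs[:, :, 1])
    np.add.at(G_nodes, t[:, 0], -(dDs[:, :, 0] + dDs[:, :, 1]))
    return E, G_nodes


def _volume_grad(x: np.ndarray, mesh: CellMesh) -> tuple:
    t = mesh.tris[mesh.envelope]
    x0, x1, x2 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    V = float(np.einsum("ij,ij->", x0, np.cross(x1, x2)) / 6.0)
    g = np.zeros_like(x)
    np.add.at(g, t[:, 0], np.cross(x1, x2) / 6.0)
    np.add.at(g, t[:, 1], np.cross(x2, x0) / 6.0)
    np.add.at(g, t[:, 2], np.cross(x0, x1) / 6.0)
    return V, g


def total_energy_grad(x, mesh, Q, pressure, branch=None):
    Em, Gm = _membrane_energy_grad(x, mesh, Q, branch)
    V, Gv = _volume_grad(x, mesh)
    return Em - pressure * V, Gm - pressure * Gv


def inflate(mesh: CellMesh, material: WallMaterial, P: float,
            n_ramp: int = 10, fixed_dof: dict | None = None,
            extra_energy=None, gtol_rel: float = 1e-8,
            maxiter: int = 20000, tension_field: bool = True) -> CellMesh:
    """Quasi-static equilibrium at internal pressure ``P`` (MPa).

    Minimizes membrane energy minus ``P V`` with the pressure ramped in
    ``n_ramp`` increments.  ``fixed_dof`` maps node index -> boolean
    (3,) mask of coordinates to hold (used for file-end constraints and
    to pin rigid modes where needed); ``extra_energy`` is an optional
    callable ``(x) -> (E, grad)`` added to the objective (indentation).
    Raises on non-convergence with the residual gradient norm.
    """
    if P < 0:
        raise ValueError("pressure must be >= 0")
    P_si = P * _MPA
    x = mesh.nodes.copy()
    Q = _element_stiffness(mesh, material)

    mask = np.ones(x.shape, dtype=bool)
    if fixed_dof:
        for idx, m in fixed_dof.items():
            mask[idx] = ~np.asarray(m, dtype=bool)
    free = mask.reshape(-1)

    # characteristic nodal force for the convergence test: pressure load
    # per node (or a membrane scale at zero pressure)
    F_char = max(P_si, 0.01 * _MPA) * mesh.area0.sum() / mesh.n_nodes

    def objective(y, p, branch=None):
        xx = x_base.copy()
        xx.reshape(-1)[free] = y
        E, G = total_energy_grad(xx, mesh, Q, p, branch)
        if extra_energy is not None:
            Ee, Ge = extra_energy(xx)
            E, G = E + Ee, G + Ge
        return E, G.reshape(-1)[free]

    x_base = x
    steps = np.linspace(P_si / n_ramp, P_si, n_ramp) if P_si > 0 else [0.0]
    y = x.reshape(-1)[free].copy()
    opts = {"maxiter": maxiter, "maxfun": 2 * maxiter, "ftol": 1e-18,
            "gtol": max(gtol_rel * F_char, 1e-18)}

    def solve_at(y, p, branch):
        res = minimize(objective, y, args=(p, branch), jac=True,
                       method="L-BFGS-B", options=opts)
        return res.x, float(np.max(np.abs(res.jac))), res.message

    def x_of(y):
        xx = x_base.copy()
        xx.reshape(-1)[free] = y
        return xx

    for i, p in enumerate(steps):
        # smooth full-SVK solve at every ramp step (continuation), then
        # the wrinkling iteration at the target pressure: freeze each
        # element's tension-field branch, solve the smooth frozen
        # problem, update branches; repeat until the active set is
        # stable.  Intermediate ramp states only provide the path, so
        # they skip the costly branch iteration.
        y, gnorm, msg = solve_at(y, p, None)
        if tension_field and i == len(steps) - 1:
            branch = wrinkle_state(x_of(y), mesh, Q)
            for _ in range(15):
                y, gnorm, msg = solve_at(y, p, branch)
                new_branch = wrinkle_state(x_of(y), mesh, Q)
                changed = int(sum(np.sum(a != b) for a, b in
                                  zip(branch, new_branch)))
                branch = new_branch
                if changed == 0:
                    break
        if gnorm > 5e-3 * F_char:
            # polish with L-BFGS restarts (fresh Hessian often buys
            # another order of magnitude before machine-precision stall)
            br = (wrinkle_state(x_of(y), mesh, Q) if tension_field
                  else None)
            last = np.inf
            for _ in range(4):
                y, gnorm, msg = solve_at(y, p, br)
                if gnorm <= 5e-3 * F_char or gnorm >= last * 0.9:
                    break
                last = gnorm
        if gnorm > 5e-2 * F_char:
            raise RuntimeError(
                f"inflation did not converge at p={p / _MPA:.3f} MPa: "
                f"|grad|_max = {gnorm:.3e} vs tolerance "
                f"{5e-3 * F_char:.3e} N ({msg})")
    out = x_base.copy()
    out.reshape(-1)[free] = y
    return replace(mesh, nodes=out, rest_nodes=mesh.rest_nodes,
                   Dm_inv=mesh.Dm_inv, area0=mesh.area0,
                   flip_v=mesh.flip_v)


# ---------------------------------------------------------------------------
# measurements on the model


@dataclass(frozen=True)
class OsmoticResponse:
    """Shape change between a low- and a high-turgor state."""

    dims_low: tuple               # μm
    dims_high: tuple              # μm
    percent_change: tuple         # (length, width, depth) %
    volume_percent_change: float

    @property
    def length_change(self) -> float:
        return self.percent_change[0]

    @property
    def depth_change(self) -> float:
        return self.percent_change[2]


def osmotic_response(geom: CellGeom, material: WallMaterial,
                     P_low: float, P_high: float, refinement: int = 2,
                     shared_walls: bool = True) -> OsmoticResponse:
    """Inflate at both pressures (MPa) and report percent shape changes.

    Emulates the plasmolysis/turgid comparison: the low-turgor state is
    the reference (a 1 M salt bath takes the cell to ~zero pressure),
    the high-turgor state is full turgor in water.
    """
    if not P_high > P_low or P_low < 0:
        raise ValueError("require P_high > P_low >= 0")
    mesh = build_cell(geom, refinement, shared_walls)
    lo = inflate(mesh, material, P_low) if P_low > 0 else mesh
    hi = inflate(mesh, material, P_high)
    d_lo = lo.measured_dims() / _UM
    d_hi = hi.measured_dims() / _UM
    v_lo = lo.enclosed_volume()
    v_hi = hi.enclosed_volume()
    return OsmoticResponse(
        dims_low=tuple(d_lo), dims_high=tuple(d_hi),
        percent_change=tuple((d_hi / d_lo - 1.0) * 100.0),
        volume_percent_change=(v_hi / v_lo - 1.0) * 100.0)


@dataclass(frozen=True)
class IndentationResult:
    depth_um: np.ndarray
    force_uN: np.ndarray
    stiffness: float              # N/m, slope on the fit window

    def __post_init__(self):
        w = (self.depth_um >= 0.2 * self.depth_um.max()) & \
            (self.depth_um <= 0.8 * self.depth_um.max())
        F = self.force_uN[w]
        # allow solver-noise dips of up to 2% of the force scale
        if np.any(np.diff(F) < -0.02 * np.abs(F).max()):
            raise ValueError("force must be non-decreasing in the fit "
                             "window")


def indentation_stiffness(geom: CellGeom, material: WallMaterial, P: float,
                          tip_radius: float = 2.0, max_depth: float = 2.0,
                          n_steps: int = 8, refinement: int = 2,
                          shared_walls: bool = True) -> IndentationResult:
    """CFM-style indentation of the inflated cell's top face.

    A rigid sphere (radius μm) is advanced into the centre of the top
    face in steps, re-equilibrating the membrane at each depth through a
    penalty contact; the apparent stiffness (N/m) is the slope of a
    linear force–depth fit over the 20–80% depth window.
    """
    mesh0 = build_cell(geom, refinement, shared_walls)
    # the cell sits on the subtending tissue: hold the bottom face so the
    # indenter deforms the cell instead of translating it rigidly
    bottom = np.unique(mesh0.tris[mesh0.face == 0].ravel())
    fixed = {int(i): (False, False, True) for i in bottom}
    corner = int(bottom[np.lexsort((mesh0.nodes[bottom, 1],
                                    mesh0.nodes[bottom, 0]))[0]])
    fixed[corner] = (True, True, True)
    far = int(bottom[np.lexsort((-mesh0.nodes[bottom, 0],
                                 mesh0.nodes[bottom, 1]))[0]])
    fixed[far] = (False, True, True)
    inflated = inflate(mesh0, material, P, fixed_dof=fixed)
    R = tip_radius * _UM
    top = inflated.nodes[:, 2].max()
    centre_xy = 0.5 * (inflated.nodes.max(axis=0)[:2]
                       + inflated.nodes.min(axis=0)[:2])
    # penalty scaled to wall stiffness
    k_c = float(np.mean(material.axis_moduli) * np.mean(inflated.thickness)
                * 50.0)

    depths = np.linspace(max_depth / n_steps, max_depth, n_steps) * _UM
    forces = []
    current = inflated
    tris = inflated.tris
    # contact is sampled at the nodes and at barycentric points inside
    # each triangle, so the sphere cannot slip between mesh nodes
    bary = np.array([[1/3, 1/3, 1/3], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5],
                     [0.5, 0.0, 0.5]])

    def penalty(x, c):
        E = 0.0
        G = np.zeros_like(x)
        f_z = 0.0
        d = x - c
        r = np.linalg.norm(d, axis=1)
        pen = np.maximum(R - r, 0.0)
        act = pen > 0
        E += 0.5 * k_c * float(np.sum(pen ** 2))
        G[act] -= k_c * (pen[act] / r[act])[:, None] * d[act]
        f_z += k_c * float(np.sum(pen * (-d[:, 2])
                                  / np.maximum(r, 1e-30)))
        for wgt in bary:
            p = np.einsum("k,mki->mi", wgt, x[tris])
            d = p - c
            r = np.linalg.norm(d, axis=1)
            pen = np.maximum(R - r, 0.0)
            act = np.where(pen > 0)[0]
            if len(act) == 0:
                continue
            E += 0.5 * k_c * float(np.sum(pen[act] ** 2))
            g = -k_c * (pen[act] / r[act])[:, None] * d[act]
            for k in range(3):
                np.add.at(G, tris[act, k], wgt[k] * g)
            f_z += k_c * float(np.sum(pen[act] * (-d[act, 2])
                                      / r[act]))
        return E, G, f_z

    for depth in depths:
        c = np.array([centre_xy[0], centre_xy[1], top + R - depth])

        def contact(x, c=c):
            E, G, _ = penalty(x, c)
            return E, G

        current = inflate(current, material, P, n_ramp=1,
                          fixed_dof=fixed, extra_energy=contact)
        _, _, f_z = penalty(current.nodes, c)
        forces.append(f_z)
    if max(forces) <= 0:
        raise RuntimeError("contact never established")
    depth_um = depths / _UM
    force_uN = np.asarray(forces) * 1e6
    w = (depth_um >= 0.2 * max_depth) & (depth_um <= 0.8 * max_depth)
    if w.sum() < 2:
        w = slice(None)
    coef = np.polyfit(depth_um[w], force_uN[w], 1)
    return IndentationResult(depth_um, force_uN, float(coef[0]))
    # stiffness: μN/μm == N/m


# ---------------------------------------------------------------------------
# calibration and the cross-scale force


def calibrate(targets: dict, geom: CellGeom, free: tuple = ("E_width",
                                                            "E_length"),
              P: float = 0.7, material0: WallMaterial | None = None,
              refinement: int = 2, weights: dict | None = None,
              sensitivity: bool = False) -> dict:
    """Fit wall moduli (and optionally P) to observed percent changes.

    ``targets`` maps observable -> value among ``length``, ``width``,
    ``depth`` (percent change, high vs low turgor), ``volume`` (percent)
    and optionally ``stiffness`` (N/m, CFM).  ``free`` lists the fitted
    parameters among ``E_length``, ``E_width``, ``E_depth``, ``P``
    (``E_depth`` follows ``E_width`` unless fitted separately).
    Weighted least squares on log-scaled parameters; returns fitted
    material, pressure, residuals, and (optionally) a ±15% local
    sensitivity table.
    """
    from scipy.optimize import least_squares

    allowed = {"length", "width", "depth", "volume", "stiffness"}
    if not set(targets) <= allowed:
        raise ValueError(f"unknown targets {set(targets) - allowed}")
    if len(targets) < len(free):
        raise ValueError(
            f"non-identifiable: {len(free)} free parameters but only "
            f"{len(targets)} targets ({sorted(targets)})")
    shape_targets = set(targets) - {"stiffness"}
    if len(free) > 1 and shape_targets <= {"volume"}:
        raise ValueError("non-identifiable: a volume target alone cannot "
                         "separate two moduli; add a shape target")
    if material0 is None:
        material0 = WallMaterial(100.0, 30.0)

    weights = weights or {}
    names = list(free)

    def build(params):
        vals = dict(E_length=material0.E_length, E_width=material0.E_width,
                    E_depth=None, P=P)
        explicit_depth = "E_depth" in names
        if not explicit_depth and material0.E_depth != material0.E_width:
            vals["E_depth"] = material0.E_depth
        for nm, v in zip(names, params):
            vals[nm] = float(np.exp(v))
        mat = WallMaterial(vals["E_length"], vals["E_width"],
                           vals["E_depth"], material0.nu)
        return mat, vals["P"]

    def observables(mat, p):
        resp = osmotic_response(geom, mat, 0.0, p, refinement)
        out = {"length": resp.percent_change[0],
               "width": resp.percent_change[1],
               "depth": resp.percent_change[2],
               "volume": resp.volume_percent_change}
        if "stiffness" in targets:
            out["stiffness"] = indentation_stiffness(
                geom, mat, p, refinement=refinement).stiffness
        return out

    keys = sorted(targets)

    def resid(params):
        mat, p = build(params)
        obs = observables(mat, p)
        return np.array([
            (obs[k] - targets[k]) / max(abs(targets[k]), 1.0)
            * weights.get(k, 1.0) for k in keys])

    x0 = []
    start = dict(E_length=material0.E_length, E_width=material0.E_width,
                 E_depth=material0.E_depth, P=P)
    x0 = np.log([start[nm] for nm in names])
    fit = least_squares(resid, x0, diff_step=0.05, xtol=1e-10, ftol=1e-12)
    mat, p = build(fit.x)
    obs = observables(mat, p)
    report = {"material": mat, "P": p, "observables": obs,
              "residuals": {k: obs[k] - targets[k] for k in keys},
              "success": fit.status > 0}
    if sensitivity:
        report["sensitivity"] = sensitivity_table(geom, mat, p, refinement)
    return report


def sensitivity_table(geom: CellGeom, material: WallMaterial, P: float,
                      refinement: int = 2, frac: float = 0.15) -> dict:
    """Effect of ±15% in P and in the E_width:E_length ratio.

    Mirrors the model sensitivity analysis: the output is the percent
    volume change (and length change) at the perturbed parameter, from
    which one sees that the model responds far more strongly to turgor
    pressure than to the stiff-direction modulus.
    """
    base = osmotic_response(geom, material, 0.0, P, refinement)
    rows = {}
    for s in (-frac, frac):
        r = osmotic_response(geom, material, 0.0, P * (1 + s), refinement)
        rows[f"P{'+' if s > 0 else '-'}15%"] = {
            "volume": r.volume_percent_change,
            "length": r.percent_change[0]}
    for s in (-frac, frac):
        mat = replace(material, E_length=material.E_length * (1 + s))
        r = osmotic_response(geom, mat, 0.0, P, refinement)
        rows[f"E_length{'+' if s > 0 else '-'}15%"] = {
            "volume": r.volume_percent_change,
            "length": r.percent_change[0]}
    rows["base"] = {"volume": base.volume_percent_change,
                    "length": base.percent_change[0]}
    return rows


def file_tension_force(geom: CellGeom, material: WallMaterial, P: float,
                       n_cells: int = 3, n_files: float | None = None,
                       constrained_length_um: float | None = None,
                       refinement: int = 2) -> dict:
    """Pulling force of a turgid exocarp cell file held at in-planta length.

    The file is inflated at ``P`` (MPa) with its end faces constrained in
    x to the in-planta (flat-valve) length — by default the rest length,
    since the attached valve holds the cells at the dimensions they had
    before turgor-driven shortening.  The reaction force (N) is the sum
    of x-gradients over one constrained end face; scaled by ``n_files``
    (valve width / cell width) it gives the total exocarp force.
    """
    L_free = geom.length * n_cells
    target = (constrained_length_um if constrained_length_um is not None
              else L_free)
    if target < 0:
        raise ValueError("constrained length must be non-negative")
    mesh = build_file(geom, n_cells, refinement)
    stretch = target / L_free
    x = mesh.nodes.copy()
    x[:, 0] *= stretch
    mesh = replace(mesh, nodes=x, rest_nodes=mesh.rest_nodes,
                   Dm_inv=mesh.Dm_inv, area0=mesh.area0, flip_v=mesh.flip_v)
    xmax = mesh.nodes[:, 0].max()
    left = np.where(mesh.nodes[:, 0] < 1e-12)[0]
    right = np.where(np.abs(mesh.nodes[:, 0] - xmax) < 1e-12)[0]
    fixed = {int(i): (True, False, False) for i in np.concatenate(
        [left, right])}
    # pin rigid modes: one left-bottom corner fully, plus y of another
    corner = int(left[np.lexsort((mesh.nodes[left, 2],
                                  mesh.nodes[left, 1]))[0]])
    fixed[corner] = (True, True, True)
    other = int(right[np.lexsort((mesh.nodes[right, 2],
                                  mesh.nodes[right, 1]))[0]])
    fixed[other] = (True, True, False)
    eq = inflate(mesh, material, P, fixed_dof=fixed)
    Q = _element_stiffness(eq, material)
    _, G = total_energy_grad(eq.nodes, eq, Q, P * _MPA)  # noqa: tension_field default
    # reaction on the right end = d(total energy)/d(uniform +x shift)
    force_per_file = float(G[right, 0].sum())
    out = {"force_per_file": force_per_file, "mesh": eq}
    if n_files is not None:
        out["total_force"] = force_per_file * n_files
    return out
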