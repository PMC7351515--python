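"""Parameterized unipennate muscle geometry and dual-mesh construction.

The muscle belly is an extruded longitudinal slice of an EDL-like
unipennate muscle.  Global axes: X = proximo-distal (distal positive),
Y = in-plane axis across the belly, Z = slice thickness.  The proximal
aponeurosis runs along the top contour, the distal aponeurosis along the
bottom contour, and fascicles (chains of ``n_series`` elements) run
obliquely between them, their distal insertion shifted distally by the
pennation offset.

Two coincident hexahedral meshes fill the belly: the ECM (matrix) mesh
and the myofiber (fiber) mesh.  They share nodes only on the aponeurosis
junction planes (myotendinous connections); at interior fascicle planes
the fiber mesh has its own coincident nodes, tied to the matrix nodes by
zero-initial-length elastic links (trans-sarcolemmal attachments).
Single layers of aponeurosis elements (thickness growing toward the
tendon ends) close the belly at top and bottom; their inner nodes are
the shared junction nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "GeometryParams",
    "LinkParams",
    "SpringLink",
    "MuscleMesh",
    "build_muscle_mesh",
    "add_fiber_matrix_links",
    "attach_extramuscular",
    "build_epimuscular_pair",
    "local_fiber_frame",
    "check_watertight",
]

# standard trilinear corner signs, (8, 3): bottom face CCW then top face
HEX_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent mesh geometry."""


@dataclass
class GeometryParams:
    """Parameters of the EDL-like slice geometry (lengths in mm).

    ``contour_top`` / ``contour_bottom`` are control points
    ``(t, y)`` with ``t`` the normalized position along the aponeurosis
    span; a polynomial through them defines the gently curved
    aponeurosis lines.  ``pennation_offset`` shifts each fascicle's
    distal insertion distally, producing the unipennate fiber obliquity.
    """

    initial_length: float = 28.7
    n_series: int = 3
    n_parallel: int = 16
    slice_thickness: float = 2.0
    pennation_offset: float = 5.0
    tendon_arm: float = 1.2
    contour_top: tuple = ((0.0, 3.85), (0.5, 4.1), (1.0, 3.7))
    contour_bottom: tuple = ((0.0, 0.0), (0.5, 0.15), (1.0, 0.0))
    apo_thickness_base: float = 0.12
    apo_thickness_factor: float = 3.0

    def validate(self) -> list[str]:
        problems = []
        if not self.initial_length > 0:
            problems.append("geometry.initial_length must be > 0")
        if self.n_series < 1:
            problems.append("geometry.n_series must be >= 1")
        if self.n_parallel < 1:
            problems.append("geometry.n_parallel must be >= 1")
        if not self.slice_thickness > 0:
            problems.append("geometry.slice_thickness must be > 0")
        if not 0 <= self.pennation_offset < self.initial_length:
            problems.append(
                "geometry.pennation_offset must be in [0, initial_length)"
            )
        if self.tendon_arm < 0:
            problems.append("geometry.tendon_arm must be >= 0")
        if not self.apo_thickness_base > 0:
            problems.append("geometry.apo_thickness_base must be > 0")
        if not self.apo_thickness_factor >= 1:
            problems.append("geometry.apo_thickness_factor must be >= 1")
        return problems


@dataclass
class LinkParams:
    """Stiffness constants of the spring links (unit force/mm).

    The seven most proximal extramuscular links (the neurovascular-tract
    path) are stiffer than the rest; fiber-matrix link stiffness is high
    (near-rigid non-pathological trans-sarcolemmal ties), defaulting to
    100x the stiff extramuscular value.
    """

    k_extra_stiff: float = 0.25
    k_extra_compliant: float = 0.033
    k_inter: float = 0.2
    n_stiff_proximal: int = 7
    k_fiber_matrix: float = 25.0

    def validate(self) -> list[str]:
        problems = []
        for name in ("k_extra_stiff", "k_extra_compliant", "k_inter", "k_fiber_matrix"):
            if not getattr(self, name) > 0:
                problems.append(f"links.{name} must be > 0")
        if self.k_extra_stiff <= self.k_extra_compliant:
            problems.append("links.k_extra_stiff must exceed links.k_extra_compliant")
        if self.n_stiff_proximal < 0:
            problems.append("links.n_stiff_proximal must be >= 0")
        return problems


@dataclass
class SpringLink:
    """Uniaxial linear spring between two nodes or a node and ground.

    ``node_b < 0`` marks a grounded link whose anchor sits at ``anchor``
    (the linked node's reference position, so the reference elongation is
    zero).  ``face``/``interface`` tag the attachment for reporting.
    """

    kind: str  # fiber_matrix | extramuscular | intermuscular
    node_a: int
    node_b: int = -1
    anchor: np.ndarray | None = None
    stiffness: float = 1.0
    ref_length: float = 0.0
    face: str = ""
    interface: int = -1
    muscle: int = 0  # 0 target, 1 synergist


@dataclass
class MuscleMesh:
    """Dual-mesh muscle model: nodes, element families, links, node sets.

    ``fascicle_grid[face, section, interface]`` maps the strain-sampling
    grid (face 0 = lateral, 1 = medial; sections are the proximal-to-
    distal nodal planes along each fascicle) to fiber-mesh node ids;
    ``matrix_grid`` is the analogous map into the matrix mesh.
    """

    nodes: np.ndarray
    ecm_elements: np.ndarray
    myofiber_elements: np.ndarray
    apo_elements: np.ndarray
    ecm_frames: np.ndarray
    myofiber_frames: np.ndarray
    fascicle_grid: np.ndarray
    matrix_grid: np.ndarray
    node_sets: dict
    n_series: int
    n_parallel: int
    slice_thickness: float
    links: list = field(default_factory=list)
    ecm_muscle: np.ndarray | None = None       # per-element muscle id
    myofiber_muscle: np.ndarray | None = None
    apo_muscle: np.ndarray | None = None
    is_pair: bool = False
    syn_fascicle_grid: np.ndarray | None = None
    syn_matrix_grid: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_interfaces(self) -> int:
        return self.n_parallel + 1

    @property
    def n_sections(self) -> int:
        return self.n_series + 1

    def links_of(self, kind: str) -> list:
        return [ln for ln in self.links if ln.kind == kind]


def _contour_poly(points) -> np.poly1d:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise GeometryError("contour needs at least two (t, y) control points")
    t, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) <= 0):
        raise GeometryError("contour control points must have increasing t")
    return np.poly1d(np.polyfit(t, y, deg=len(t) - 1))


def build_muscle_mesh(g: GeometryParams) -> MuscleMesh:
    """Build the dual hexahedral muscle mesh plus aponeurosis layers.

    With default parameters: 48 ECM + 48 coincident myofiber hexahedra
    (16 fascicles x 3 in series, one element through the thickness), 16
    aponeurosis elements on each aponeurosis, 17 fascicle interfaces and
    4 fascicle sections, end-to-end length 28.7 mm.
    """
    problems = g.validate()
    if problems:
        raise GeometryError("; ".join(problems))

    L = g.initial_length
    s = g.pennation_offset
    arm = g.tendon_arm
    nS, nP = g.n_series, g.n_parallel
    n_if, n_sec = nP + 1, nS + 1
    tz = g.slice_thickness
    span = L - s - 2.0 * arm
    if span <= 0:
        raise GeometryError(
            "pennation offset plus tendon arms leave no aponeurosis span"
        )

    top = _contour_poly(g.contour_top)
    bot = _contour_poly(g.contour_bottom)
    tgrid = np.linspace(0.0, 1.0, n_if)
    x_top = arm + span * tgrid
    x_bot = x_top + s
    y_top = top(tgrid)
    y_bot = bot(tgrid)
    if np.any(y_top - y_bot <= 0):
        raise GeometryError("contours intersect: top line must stay above bottom")

    # fascicle node planes: linear interpolation top -> bottom per interface
    frac = np.linspace(0.0, 1.0, n_sec)
    px = x_top[:, None] + frac[None, :] * (x_bot - x_top)[:, None]  # (n_if, n_sec)
    py = y_top[:, None] + frac[None, :] * (y_bot - y_top)[:, None]

    nodes = []

    def new_node(x, y, z) -> int:
        nodes.append((x, y, z))
        return len(nodes) - 1

    # matrix mesh grid: (n_if, n_sec, 2)
    mgrid = np.empty((n_if, n_sec, 2), dtype=int)
    for i in range(n_if):
        for j in range(n_sec):
            for kz, z in enumerate((0.0, tz)):
                mgrid[i, j, kz] = new_node(px[i, j], py[i, j], z)

    # fiber mesh grid: shares junction planes (j = 0 and j = nS)
    fgrid = np.empty_like(mgrid)
    fgrid[:, 0, :] = mgrid[:, 0, :]
    fgrid[:, nS, :] = mgrid[:, nS, :]
    for j in range(1, nS):
        for i in range(n_if):
            for kz, z in enumerate((0.0, tz)):
                fgrid[i, j, kz] = new_node(px[i, j], py[i, j], z)

    # aponeurosis sheets: a single element layer whose thickness grows
    # toward the tendon end (proximal end for the top sheet, distal for
    # the bottom); a short free tendon arm extends each sheet beyond the
    # outermost fascicle so the grip is not applied directly at a
    # myotendinous junction
    sheet_len = arm + span

    def thickness(dist_from_tendon_end):
        f = g.apo_thickness_factor
        return g.apo_thickness_base * (f - (f - 1.0) * dist_from_tendon_end / sheet_len)

    # top sheet columns: optional arm column at x=0, then the junctions
    top_x = np.concatenate([[0.0], x_top]) if arm > 0 else x_top
    top_y = np.concatenate([[y_top[0]], y_top]) if arm > 0 else y_top
    bot_x = np.concatenate([x_bot, [L]]) if arm > 0 else x_bot
    bot_y = np.concatenate([y_bot, [y_bot[-1]]]) if arm > 0 else y_bot
    n_top = len(top_x)

    top_inner = np.empty((n_top, 2), dtype=int)
    bot_inner = np.empty((n_top, 2), dtype=int)
    off = 1 if arm > 0 else 0
    for kz in range(2):
        top_inner[off:, kz] = mgrid[:, 0, kz]
        bot_inner[: n_if, kz] = mgrid[:, nS, kz]
    if arm > 0:
        for kz, z in enumerate((0.0, tz)):
            top_inner[0, kz] = new_node(top_x[0], top_y[0], z)
            bot_inner[-1, kz] = new_node(bot_x[-1], bot_y[-1], z)

    top_outer = np.empty((n_top, 2), dtype=int)
    bot_outer = np.empty((n_top, 2), dtype=int)
    for i in range(n_top):
        for kz, z in enumerate((0.0, tz)):
            top_outer[i, kz] = new_node(
                top_x[i], top_y[i] + thickness(top_x[i]), z
            )
            bot_outer[i, kz] = new_node(
                bot_x[i], bot_y[i] - thickness(L - bot_x[i]), z
            )

    nodes = np.asarray(nodes, dtype=float)

    def hex_of(c00, c01, c11, c10):
        """Corners of the z=0 face in CCW order (viewed from +Z), then z=t."""
        return [c00[0], c01[0], c11[0], c10[0], c00[1], c01[1], c11[1], c10[1]]

    ecm = []
    myo = []
    for i in range(nP):
        for j in range(nS):
            ecm.append(
                hex_of(mgrid[i, j], mgrid[i, j + 1], mgrid[i + 1, j + 1], mgrid[i + 1, j])
            )
            myo.append(
                hex_of(fgrid[i, j], fgrid[i, j + 1], fgrid[i + 1, j + 1], fgrid[i + 1, j])
            )
    apo = []
    for i in range(n_top - 1):  # proximal (top) sheet
        apo.append(
            hex_of(top_inner[i], top_inner[i + 1], top_outer[i + 1], top_outer[i])
        )
    for i in range(n_top - 1):  # distal (bottom) sheet
        apo.append(
            hex_of(bot_outer[i], bot_outer[i + 1], bot_inner[i + 1], bot_inner[i])
        )

    ecm = np.asarray(ecm, dtype=int)
    myo = np.asarray(myo, dtype=int)
    apo = np.asarray(apo, dtype=int)

    for name, conn in (("ecm", ecm), ("myofiber", myo), ("aponeurosis", apo)):
        _check_positive_jacobians(nodes, conn, name)

    muscle_frames = _fascicle_frames(nodes, ecm)
    mesh = MuscleMesh(
        nodes=nodes,
        ecm_elements=ecm,
        myofiber_elements=myo,
        apo_elements=apo,
        ecm_frames=muscle_frames,
        myofiber_frames=_fascicle_frames(nodes, myo),
        fascicle_grid=np.stack([fgrid[:, :, 0].T, fgrid[:, :, 1].T]),  # (2, n_sec, n_if)
        matrix_grid=np.stack([mgrid[:, :, 0].T, mgrid[:, :, 1].T]),
        node_sets={},
        n_series=nS,
        n_parallel=nP,
        slice_thickness=tz,
        ecm_muscle=np.zeros(len(ecm), dtype=int),
        myofiber_muscle=np.zeros(len(myo), dtype=int),
        apo_muscle=np.zeros(len(apo), dtype=int),
    )

    mesh.node_sets["proximal_end"] = np.array(
        [top_inner[0, 0], top_inner[0, 1], top_outer[0, 0], top_outer[0, 1]]
    )
    mesh.node_sets["distal_end"] = np.array(
        [bot_inner[-1, 0], bot_inner[-1, 1], bot_outer[-1, 0], bot_outer[-1, 1]]
    )
    mesh.node_sets["lateral_face"] = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
    mesh.node_sets["medial_face"] = np.flatnonzero(np.isclose(nodes[:, 2], tz))
    interm = fgrid[:, 1:nS, :]
    mesh.node_sets["intermediate_lateral"] = np.sort(interm[:, :, 0].ravel())
    mesh.node_sets["intermediate_medial"] = np.sort(interm[:, :, 1].ravel())

    # sanity on the stated length definition
    pe = nodes[mesh.node_sets["proximal_end"]][:, 0].mean()
    de = nodes[mesh.node_sets["distal_end"]][:, 0].mean()
    if not np.isclose(de - pe, L):
        raise GeometryError("end-to-end distance does not match initial_length")
    return mesh


def _check_positive_jacobians(nodes, conn, name):
    """Corner-wise Jacobian sign check for every hexahedron."""
    from .fem import shape_gradients, GAUSS_POINTS

    dN = shape_gradients(GAUSS_POINTS)  # (8, 8, 3)
    X = nodes[conn]  # (ne, 8, 3)
    J = np.einsum("eak,gad->egkd", X, dN)
    det = np.linalg.det(J)
    if np.any(det <= 0):
        raise GeometryError(f"degenerate {name} element: non-positive Jacobian")


def _fascicle_frames(nodes, conn) -> np.ndarray:
    """Local (cross-fiber, fiber, thickness) triad per muscle element.

    The fiber axis (column 2) follows the element's aponeurosis-to-
    aponeurosis edges (local xi direction, nodes 0->1 and 3->2), the
    thickness axis (column 3) is the slice normal, and column 1
    completes the right-handed triad.
    """
    X = nodes[conn]
    e2 = (X[:, 1] - X[:, 0]) + (X[:, 2] - X[:, 3]) + (X[:, 5] - X[:, 4]) + (X[:, 6] - X[:, 7])
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    # orient the fiber axis distally (positive X component) for reporting
    flip = e2[:, 0] < 0
    e2[flip] *= -1.0
    e3 = np.zeros_like(e2)
    e3[:, 2] = 1.0
    e1 = np.cross(e2, e3)
    n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    if np.any(n1 < 1e-12):
        raise GeometryError("degenerate element: fiber direction parallel to thickness")
    e1 /= n1
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=2)  # columns are the local axes


def local_fiber_frame(element: int, mesh: MuscleMesh, family: str = "myofiber") -> np.ndarray:
    """Orthonormal local triad (columns: cross-fiber, fiber, thickness)."""
    frames = mesh.myofiber_frames if family == "myofiber" else mesh.ecm_frames
    return frames[element]


def add_fiber_matrix_links(mesh: MuscleMesh, lp: LinkParams) -> MuscleMesh:
    """Tie every interior fiber node to its coincident matrix node.

    One zero-initial-length link per pair: (n_series - 1) interior planes
    x (n_parallel + 1) interfaces per face — 34 per face with defaults.
    """
    nS = mesh.n_series
    if nS < 2:
        return mesh  # no interior planes, meshes fully share nodes
    for face, fname in ((0, "lateral"), (1, "medial")):
        for j in range(1, nS):
            for i in range(mesh.n_interfaces):
                na = mesh.matrix_grid[face, j, i]
                nb = mesh.fascicle_grid[face, j, i]
                if na == nb:
                    raise GeometryError("interior fiber node not distinct from matrix node")
                if not np.allclose(mesh.nodes[na], mesh.nodes[nb]):
                    raise GeometryError("paired fiber/matrix nodes are not coincident")
                mesh.links.append(
                    SpringLink(
                        kind="fiber_matrix",
                        node_a=na,
                        node_b=nb,
                        stiffness=lp.k_fiber_matrix,
                        face=fname,
                        interface=i,
                    )
                )
    return mesh


def _anchor_section(n_series: int) -> int:
    """Interior fascicle plane nearest one-third from the proximal side."""
    if n_series < 2:
        raise GeometryError(
            "extramuscular attachment needs an interior fascicle plane (n_series >= 2)"
        )
    return int(np.clip(round(n_series / 3.0), 1, n_series - 1))


def attach_extramuscular(
    mesh: MuscleMesh, lp: LinkParams, face: str = "lateral", muscle: int = 0
) -> MuscleMesh:
    """Ground the matrix mesh at one-third of the fascicle length.

    One grounded link per fascicle interface on the given face, anchored
    at the node's reference position; the ``n_stiff_proximal``
    most-proximal links carry the stiff (neurovascular-tract) stiffness.
    """
    if face not in ("lateral", "medial"):
        raise GeometryError(f"unknown face {face!r}")
    fidx = 0 if face == "lateral" else 1
    grid = mesh.matrix_grid if muscle == 0 else mesh.syn_matrix_grid
    if grid is None:
        raise GeometryError("mesh has no matrix grid for the requested muscle")
    j = _anchor_section(mesh.n_series)
    node_ids = grid[fidx, j, :]
    order = np.argsort(mesh.nodes[node_ids, 0])  # proximal -> distal
    for rank, idx in enumerate(order):
        nid = int(node_ids[idx])
        k = lp.k_extra_stiff if rank < lp.n_stiff_proximal else lp.k_extra_compliant
        mesh.links.append(
            SpringLink(
                kind="extramuscular",
                node_a=nid,
                node_b=-1,
                anchor=mesh.nodes[nid].copy(),
                stiffness=k,
                face=face,
                interface=int(idx),
                muscle=muscle,
            )
        )
    return mesh


def build_epimuscular_pair(g: GeometryParams, lp: LinkParams) -> MuscleMesh:
    """Target + synergist muscles, intermuscularly linked at their
    adjacent (medial) faces and each grounded extramuscularly on its
    outer (lateral) face.

    The synergist is an identical mesh offset by one slice thickness, so
    corresponding medial-face matrix nodes coincide and the
    intermuscular links have zero reference elongation.
    """
    target = build_muscle_mesh(g)
    add_fiber_matrix_links(target, lp)
    syn = build_muscle_mesh(g)
    add_fiber_matrix_links(syn, lp)

    off = target.n_nodes
    tz = g.slice_thickness
    syn_nodes = syn.nodes.copy()
    syn_nodes[:, 2] += tz

    combined = MuscleMesh(
        nodes=np.vstack([target.nodes, syn_nodes]),
        ecm_elements=np.vstack([target.ecm_elements, syn.ecm_elements + off]),
        myofiber_elements=np.vstack([target.myofiber_elements, syn.myofiber_elements + off]),
        apo_elements=np.vstack([target.apo_elements, syn.apo_elements + off]),
        ecm_frames=np.vstack([target.ecm_frames, syn.ecm_frames]),
        myofiber_frames=np.vstack([target.myofiber_frames, syn.myofiber_frames]),
        fascicle_grid=target.fascicle_grid,
        matrix_grid=target.matrix_grid,
        node_sets={},
        n_series=g.n_series,
        n_parallel=g.n_parallel,
        slice_thickness=tz,
        links=list(target.links),
        ecm_muscle=np.concatenate([target.ecm_muscle, np.ones(len(syn.ecm_elements), int)]),
        myofiber_muscle=np.concatenate(
            [target.myofiber_muscle, np.ones(len(syn.myofiber_elements), int)]
        ),
        apo_muscle=np.concatenate([target.apo_muscle, np.ones(len(syn.apo_elements), int)]),
        is_pair=True,
        syn_fascicle_grid=syn.fascicle_grid + off,
        syn_matrix_grid=syn.matrix_grid + off,
    )
    for ln in syn.links:
        combined.links.append(
            replace(ln, node_a=ln.node_a + off, node_b=ln.node_b + off, muscle=1)
        )
    for name, ids in target.node_sets.items():
        combined.node_sets[name] = ids
    for name, ids in syn.node_sets.items():
        combined.node_sets["syn_" + name] = ids + off

    # intermuscular links: target medial face <-> synergist adjacent face,
    # one per fascicle-grid matrix node (n_sections x n_interfaces)
    tgt_medial = combined.matrix_grid[1]            # (n_sec, n_if)
    syn_adjacent = combined.syn_matrix_grid[0]      # synergist z-low face
    for j in range(combined.n_sections):
        for i in range(combined.n_interfaces):
            na, nb = int(tgt_medial[j, i]), int(syn_adjacent[j, i])
            if not np.allclose(combined.nodes[na], combined.nodes[nb]):
                raise GeometryError("intermuscular node correspondence mismatch")
            combined.links.append(
                SpringLink(
                    kind="intermuscular",
                    node_a=na,
                    node_b=nb,
                    stiffness=lp.k_inter,
                    face="medial",
                    interface=i,
                )
            )

    attach_extramuscular(combined, lp, face="lateral", muscle=0)
    # synergist's outward face is index 1 of its own grid (z = 2t)
    fidx_store = combined.syn_matrix_grid
    j = _anchor_section(combined.n_series)
    node_ids = fidx_store[1, j, :]
    order = np.argsort(combined.nodes[node_ids, 0])
    for rank, idx in enumerate(order):
        nid = int(node_ids[idx])
        k = lp.k_extra_stiff if rank < lp.n_stiff_proximal else lp.k_extra_compliant
        combined.links.append(
            SpringLink(
                kind="extramuscular",
                node_a=nid,
                node_b=-1,
                anchor=combined.nodes[nid].copy(),
                stiffness=k,
                face="lateral",
                interface=int(idx),
                muscle=1,
            )
        )
    return combined


def check_watertight(mesh: MuscleMesh) -> bool:
    """Every interior quad face is shared by exactly two elements of the
    same mesh family (boundary faces by exactly one)."""
    FACES = [
        (0, 1, 2, 3),
        (4, 5, 6, 7),
        (0, 1, 5, 4),
        (3, 2, 6, 7),
        (0, 3, 7, 4),
        (1, 2, 6, 5),
    ]
    for conn in (mesh.ecm_elements, mesh.myofiber_elements, mesh.apo_elements):
        counts: dict = {}
        for el in conn:
            for f in FACES:
                key = tuple(sorted(int(el[a]) for a in f))
                counts[key] = counts.get(key, 0) + 1
        if any(c > 2 for c in counts.values()):
            return False
    return True
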