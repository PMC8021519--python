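"""Synthetic splenic red pulp microvasculature phantoms.

The phantom emulates the acquisition this package is built for: a block of
red pulp cut into serial sections (0.5 µm/pixel in plane, nominally 7 µm
thick), triple-immunostained in brightfield.  Every section carries SMA
(brown, smooth muscle of arterioles) and CD34 (blue, endothelium of every
vessel class except sinuses); alternating sections add CD271 (red, stromal
capillary-sheath cells) or CD20 (red, B lymphocytes).

Ground truth is a vessel centerline graph with per-edge radii and structure
classes:

* ``arteriole_stem`` / ``arteriole_branch`` — terminal arterioles, SMA+CD34;
* ``sheathed_capillary`` — post-arteriolar capillaries wrapped by a CD271
  sheath covering one to four sequential dichotomous bifurcations;
* ``side_branch_open`` — short branches that cross the sheath and end freely
  at its surface (one degree-1 endpoint by construction);
* ``network_capillary`` — the open red pulp capillary network fed by
  post-sheath capillaries;
* ``bypass_capillary`` — the rare non-sheathed arteriole-to-network
  connections;
* ``venule`` — a CD34+ venule contacted by a small number of network
  capillaries.

Sheaths are thick CD271 shells around their covered edges; B cells are CD20
spheres scattered over sheath surfaces.

Two generator properties are deliberate design choices rather than
randomness:

* Arteriole trees are instantiated in point-symmetric pairs (the second
  member of a pair is the first reflected through the domain axis) and the
  stems and venules run close to the z axis.  Serial-section registration is
  blind to a net in-plane anatomical drift (it is indistinguishable from
  misalignment), so a registrable phantom must not carry one; statistical
  isotropy of the microvasculature is the realistic assumption and the
  symmetric pairing enforces its finite-sample version exactly.
* One sheath in the first tree (when ``long_sheath`` is set) is a
  constructed four-bifurcation sheathed path whose centerline is longer than
  300 µm, the elongated-sheath regime reported for human spleen; it gives
  downstream geodesic measurements a known ground-truth length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import EuclideanTransform, warp

from .stain import STAIN_ORDER, StainModel

__all__ = [
    "PhantomError",
    "PhantomSpec",
    "Edge",
    "Sheath",
    "PhantomGroundTruth",
    "SectionImage",
    "STRUCTURE_STAINS",
    "STAIN_AMPLITUDES",
    "build_phantom",
    "voxelize_ground_truth",
    "render_sections",
    "apply_section_artifacts",
]


class PhantomError(ValueError):
    """A phantom spec is infeasible; the message names the constraint."""


# structure class -> set of stains carried by its lumen/wall
STRUCTURE_STAINS = {
    "arteriole_stem": frozenset({"SMA", "CD34"}),
    "arteriole_branch": frozenset({"SMA", "CD34"}),
    "sheathed_capillary": frozenset({"CD34"}),
    "side_branch_open": frozenset({"CD34"}),
    "network_capillary": frozenset({"CD34"}),
    "bypass_capillary": frozenset({"CD34"}),
    "venule": frozenset({"CD34"}),
}

#: optical-density amplitude per µm of stained path, per marker
STAIN_AMPLITUDES = {"SMA": 0.12, "CD34": 0.15, "CD271": 0.12, "CD20": 0.15}

#: marker -> row of the stain OD matrix
MARKER_TO_ROW = {"SMA": "brown", "CD34": "blue", "CD271": "red", "CD20": "red"}


@dataclass
class PhantomSpec:
    """Generation parameters; defaults are the desk-scale study conditions."""

    domain_size_um: tuple[float, float, float] = (160.0, 160.0, 280.0)
    pixel_size_um: float = 0.5
    section_thickness_um: float = 7.0
    n_arterioles: int = 2
    branches_per_arteriole: tuple[int, int] = (2, 3)
    sheath_bifurcation_depth: tuple[int, int] = (1, 3)
    side_branches_per_sheath: tuple[int, int] = (1, 2)
    n_bypass_capillaries: int = 3
    n_venule_contacts: int = 2
    bcell_density: int = 5
    jitter_translation_px: tuple[float, float] = (0.0, 10.0)
    jitter_rotation_deg: tuple[float, float] = (0.0, 2.0)
    lost_section_indices: tuple[int, ...] = ()
    noise_sd: float = 3.0
    seed: int = 0
    # geometry details (µm)
    arteriole_radius_um: float = 5.0
    capillary_radius_um: float = 3.0
    network_radius_um: float = 2.5
    side_branch_radius_um: float = 2.0
    sheath_radius_um: float = 8.0
    venule_radius_um: float = 10.0
    bcell_radius_um: float = 3.5
    stem_segments: tuple[int, int] = (1, 2)
    stem_segment_um: tuple[float, float] = (22.0, 30.0)
    branch_segment_um: tuple[float, float] = (16.0, 24.0)
    sheath_segment_um: tuple[float, float] = (14.0, 20.0)
    network_segments: tuple[int, int] = (1, 2)
    network_segment_um: tuple[float, float] = (14.0, 22.0)
    long_sheath: bool = True
    long_sheath_bifurcations: int = 4
    long_sheath_segment_um: float = 32.0  # 2 segments per bifurcation + ends
    n_network_trees: int = 240  # scattered red pulp capillary chains
    network_vertical_fraction: float = 0.85  # share running nearly along z
    red_parity_start: str = "CD271"  # stain on section 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise PhantomError("pixel size and section thickness must be positive")
        if any(d <= 0 for d in self.domain_size_um):
            raise PhantomError("domain extents must be positive")
        for name in ("n_arterioles", "n_bypass_capillaries", "n_venule_contacts",
                     "bcell_density"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be non-negative")
        lo, hi = self.sheath_bifurcation_depth
        if hi > 4:
            raise PhantomError("sheath_bifurcation_depth must be at most 4")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be non-negative")

    @property
    def anisotropy_factor(self) -> float:
        return self.section_thickness_um / self.pixel_size_um

    @property
    def n_sections(self) -> int:
        return int(round(self.domain_size_um[2] / self.section_thickness_um))

    @property
    def image_shape(self) -> tuple[int, int]:
        ny = int(round(self.domain_size_um[1] / self.pixel_size_um))
        nx = int(round(self.domain_size_um[0] / self.pixel_size_um))
        return ny, nx


@dataclass
class Edge:
    u: int
    v: int
    radius_um: float
    structure_class: str


@dataclass
class Sheath:
    edge_ids: list[int]
    outer_radius_um: float
    entry_node: int
    exit_node: int
    n_bifurcations: int
    main_path_edge_ids: list[int]


@dataclass
class PhantomGroundTruth:
    """Vessel centerline graph with radii, sheaths, B cells, stain map."""

    nodes: np.ndarray  # N x 3 positions, µm
    edges: list[Edge]
    sheaths: list[Sheath]
    bcells: list[tuple[np.ndarray, float]]
    stain_map: dict = field(default_factory=lambda: dict(STRUCTURE_STAINS))
    venule_contact_nodes: list[int] = field(default_factory=list)
    long_path: dict | None = None  # sheath_id, entry/exit nodes, length_um

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.structure_class] = counts.get(e.structure_class, 0) + 1
        return counts

    def edges_of_class(self, cls: str) -> list[int]:
        return [i for i, e in enumerate(self.edges) if e.structure_class == cls]

    def path_length(self, edge_ids: list[int]) -> float:
        return float(
            sum(
                np.linalg.norm(self.nodes[self.edges[i].v] - self.nodes[self.edges[i].u])
                for i in edge_ids
            )
        )


@dataclass
class SectionImage:
    """One RGB section with physical geometry and stain-set tag."""

    pixels: np.ndarray  # H x W x 3
    pixel_size_um: float
    section_index: int
    z_um: float
    stain_set: frozenset
    focus_ok: bool = True
    jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)  # theta_deg, tx_px, ty_px


# ---------------------------------------------------------------------------
# graph construction


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise PhantomError("zero-length direction")
    return v / n


def _tilt_from(direction: np.ndarray, angle_rad: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``angle_rad`` from ``direction`` in azimuth ``azimuth``."""
    d = _unit(direction)
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, a))
    e2 = np.cross(d, e1)
    return _unit(
        np.cos(angle_rad) * d
        + np.sin(angle_rad) * (np.cos(azimuth) * e1 + np.sin(azimuth) * e2)
    )


class _Builder:
    """Accumulates nodes/edges, with local-template instancing for mirroring."""

    def __init__(self) -> None:
        self.nodes: list[np.ndarray] = []
        self.edges: list[Edge] = []
        self.sheaths: list[Sheath] = []
        self.bcells: list[tuple[np.ndarray, float]] = []

    def add_node(self, pos: np.ndarray) -> int:
        self.nodes.append(np.asarray(pos, dtype=float))
        return len(self.nodes) - 1

    def add_edge(self, u: int, v: int, r: float, cls: str) -> int:
        self.edges.append(Edge(u, v, r, cls))
        return len(self.edges) - 1


def _uniform(rng, lohi):
    lo, hi = lohi
    return float(rng.uniform(lo, hi))


def _randint(rng, lohi):
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1))


def _grow_tree_template(spec: PhantomSpec, rng, make_long: bool):
    """Grow one arteriole tree in local coordinates (base at the origin).

    Returns a dict of local nodes/edges/sheaths/bcells and the local ids of
    network leaves (candidates for venule contacts / bypass targets).
    """
    b = _Builder()
    base = b.add_node(np.zeros(3))
    pos = np.zeros(3)
    # terminal arterioles enter the block nearly perpendicular to the
    # cutting plane (penicillar orientation)
    direction = _tilt_from(
        np.array([0.0, 0.0, 1.0]), np.deg2rad(rng.uniform(0.0, 3.0)),
        rng.uniform(0, 2 * np.pi),
    )
    node = base
    n_stem = 1 if make_long else _randint(rng, spec.stem_segments)
    for _ in range(n_stem):
        seg = _uniform(rng, spec.stem_segment_um)
        pos = pos + direction * seg
        nxt = b.add_node(pos)
        b.add_edge(node, nxt, spec.arteriole_radius_um, "arteriole_stem")
        node = nxt
        direction = _tilt_from(direction, np.deg2rad(rng.uniform(0, 4)),
                               rng.uniform(0, 2 * np.pi))

    n_branches = 2 if make_long else _randint(rng, spec.branches_per_arteriole)
    leaves: list[int] = []
    azim0 = rng.uniform(0, 2 * np.pi)
    for ib in range(n_branches):
        azim = azim0 + 2 * np.pi * ib / max(n_branches, 1)
        bdir = _tilt_from(direction, np.deg2rad(rng.uniform(25, 45)), azim)
        bpos = np.asarray(b.nodes[node])
        bnode = node
        for _ in range(1 + int(rng.integers(0, 2))):
            seg = _uniform(rng, spec.branch_segment_um)
            bpos = bpos + bdir * seg
            nxt = b.add_node(bpos)
            b.add_edge(bnode, nxt, spec.arteriole_radius_um * 0.8, "arteriole_branch")
            bnode = nxt
            bdir = _tilt_from(bdir, np.deg2rad(rng.uniform(0, 8)),
                              rng.uniform(0, 2 * np.pi))
        long_here = make_long and ib == 0
        leaves += _grow_sheathed(spec, rng, b, bnode, bdir, long_here)
    return b, leaves


def _grow_sheathed(spec: PhantomSpec, rng, b: _Builder, entry: int,
                   direction: np.ndarray, long_sheath: bool) -> list[int]:
    """A sheathed capillary starting at ``entry`` (end of the arteriole)."""
    sheath_edges: list[int] = []
    main_path: list[int] = []
    leaves: list[int] = []

    if long_sheath:
        depth = spec.long_sheath_bifurcations
        # gentle helix: long centerline in a bounded footprint with small
        # per-node direction changes, so the surface geodesic tracks the
        # centerline length instead of cutting corners at sharp bends
        n_seg = 2 * depth + 2
        tilt = np.deg2rad(55.0)
        d_az = np.deg2rad(49.0)
        az0 = rng.uniform(0, 2 * np.pi)
        bif_nodes = {2 * (i + 1) for i in range(depth)}  # after segments 2,4,..
    else:
        depth = _randint(rng, spec.sheath_bifurcation_depth)
        n_seg = depth + 1
        bif_nodes = set(range(1, depth + 1))

    node = entry
    d = _unit(direction)
    for k in range(1, n_seg + 1):
        if long_sheath:
            az = az0 + (k - 1) * d_az + rng.uniform(-0.05, 0.05)
            d = np.array([
                np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az),
                np.cos(tilt),
            ])
            seg = spec.long_sheath_segment_um
        else:
            seg = _uniform(rng, spec.sheath_segment_um)
        pos = np.asarray(b.nodes[node]) + d * seg
        nxt = b.add_node(pos)
        eid = b.add_edge(node, nxt, spec.capillary_radius_um, "sheathed_capillary")
        sheath_edges.append(eid)
        main_path.append(eid)
        if k in bif_nodes and k < n_seg:
            # dichotomous bifurcation at nxt: secondary child, one sheathed
            # segment, then leaves the sheath into the network
            sdir = _tilt_from(d, np.deg2rad(rng.uniform(35, 55)),
                              rng.uniform(0, 2 * np.pi))
            sdir = _unit(sdir * np.array([1.0, 1.0, 0.5]))  # keep children shallow
            spos = pos + sdir * _uniform(rng, spec.sheath_segment_um)
            snode = b.add_node(spos)
            sid = b.add_edge(nxt, snode, spec.capillary_radius_um,
                             "sheathed_capillary")
            sheath_edges.append(sid)
            leaves += _grow_network(spec, rng, b, snode, sdir)
        if not long_sheath:
            d = _tilt_from(d, np.deg2rad(rng.uniform(5, 15)),
                           rng.uniform(0, 2 * np.pi))
        node = nxt

    exit_node = node
    leaves += _grow_network(spec, rng, b, exit_node, d)
    sheath = Sheath(
        edge_ids=sheath_edges,
        outer_radius_um=spec.sheath_radius_um,
        entry_node=entry,
        exit_node=exit_node,
        n_bifurcations=depth,
        main_path_edge_ids=main_path,
    )
    b.sheaths.append(sheath)
    _add_side_branches(spec, rng, b, sheath)
    _add_bcells(spec, rng, b, sheath)
    return leaves


def _add_side_branches(spec: PhantomSpec, rng, b: _Builder, sheath: Sheath) -> None:
    """Open-ended side branches crossing the sheath, ending at its surface."""
    n = _randint(rng, spec.side_branches_per_sheath)
    candidates = sheath.main_path_edge_ids
    for _ in range(n):
        eid = candidates[int(rng.integers(0, len(candidates)))]
        e = b.edges[eid]
        t = rng.uniform(0.3, 0.7)
        start_pos = (1 - t) * b.nodes[e.u] + t * b.nodes[e.v]
        axis = _unit(np.asarray(b.nodes[e.v]) - np.asarray(b.nodes[e.u]))
        out = _tilt_from(axis, np.deg2rad(rng.uniform(70, 95)),
                         rng.uniform(0, 2 * np.pi))
        # end just at the sheath surface (within outer radius + one capillary
        # radius of the covered edge, honoring the ground-truth invariant)
        length = sheath.outer_radius_um + rng.uniform(-1.0, spec.capillary_radius_um)
        start = b.add_node(start_pos)
        end = b.add_node(np.asarray(start_pos) + out * length)
        b.add_edge(start, end, spec.side_branch_radius_um, "side_branch_open")
        # tie the side-branch root into the graph along the covered edge
        b.add_edge(e.u, start, e.radius_um, "sheathed_capillary")
        sheath.edge_ids.append(len(b.edges) - 1)


def _add_bcells(spec: PhantomSpec, rng, b: _Builder, sheath: Sheath) -> None:
    for _ in range(spec.bcell_density):
        eid = sheath.edge_ids[int(rng.integers(0, len(sheath.edge_ids)))]
        e = b.edges[eid]
        t = rng.uniform(0, 1)
        on_axis = (1 - t) * b.nodes[e.u] + t * b.nodes[e.v]
        axis = _unit(np.asarray(b.nodes[e.v]) - np.asarray(b.nodes[e.u]))
        out = _tilt_from(axis, np.deg2rad(90.0), rng.uniform(0, 2 * np.pi))
        center = np.asarray(on_axis) + out * (
            sheath.outer_radius_um + spec.bcell_radius_um * rng.uniform(0.6, 1.1)
        )
        b.bcells.append((center, spec.bcell_radius_um))


def _grow_network(spec: PhantomSpec, rng, b: _Builder, start: int,
                  direction: np.ndarray) -> list[int]:
    """Open capillary network continuation; returns leaf node ids."""
    node = start
    d = _unit(direction)
    for _ in range(_randint(rng, spec.network_segments)):
        d = _tilt_from(d, np.deg2rad(rng.uniform(10, 40)),
                       rng.uniform(0, 2 * np.pi))
        d = _unit(d * np.array([1.0, 1.0, 0.5]))  # red pulp net spreads in-plane
        pos = np.asarray(b.nodes[node]) + d * _uniform(rng, spec.network_segment_um)
        nxt = b.add_node(pos)
        b.add_edge(node, nxt, spec.network_radius_um, "network_capillary")
        node = nxt
    return [node]


def _instantiate(template: _Builder, gt: _Builder, base: np.ndarray,
                 mirror: bool = False,
                 signs: tuple[float, float] | None = None) -> tuple[list[int], list[int]]:
    """Place a local template at ``base``.

    ``mirror`` negates both in-plane offsets (point reflection); ``signs``
    gives explicit per-axis signs for reflection instances.  Returns
    (node id map, edge id map).
    """
    if signs is None:
        signs = (-1.0, -1.0) if mirror else (1.0, 1.0)
    sx, sy = signs
    node_map: list[int] = []
    for p in template.nodes:
        q = np.array([base[0] + sx * p[0], base[1] + sy * p[1], base[2] + p[2]])
        node_map.append(gt.add_node(q))
    edge_map: list[int] = []
    for e in template.edges:
        edge_map.append(
            gt.add_edge(node_map[e.u], node_map[e.v], e.radius_um, e.structure_class)
        )
    for s in template.sheaths:
        gt.sheaths.append(
            Sheath(
                edge_ids=[edge_map[i] for i in s.edge_ids],
                outer_radius_um=s.outer_radius_um,
                entry_node=node_map[s.entry_node],
                exit_node=node_map[s.exit_node],
                n_bifurcations=s.n_bifurcations,
                main_path_edge_ids=[edge_map[i] for i in s.main_path_edge_ids],
            )
        )
    for c, r in template.bcells:
        q = np.array([base[0] + sx * c[0], base[1] + sy * c[1], base[2] + c[2]])
        gt.bcells.append((q, r))
    return node_map, edge_map


def _check_bounds(spec: PhantomSpec, nodes: np.ndarray, margin: float) -> None:
    if len(nodes) == 0:
        return
    dx, dy, dz = spec.domain_size_um
    lo = nodes.min(axis=0)
    hi = nodes.max(axis=0)
    if lo[0] < margin or lo[1] < margin or hi[0] > dx - margin or hi[1] > dy - margin:
        raise PhantomError(
            "phantom does not fit the domain in x/y (margin "
            f"{margin} µm violated; extents {lo} .. {hi})"
        )
    if lo[2] < 0 or hi[2] > dz:
        raise PhantomError("phantom does not fit the domain in z")


def build_phantom(spec: PhantomSpec, max_retries: int = 100) -> PhantomGroundTruth:
    """Generate ground truth for the given parameters; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    gt_builder = _Builder()
    venule_axis: list[tuple[np.ndarray, np.ndarray]] = []  # (p0, p1) per venule

    dx, dy, dz = spec.domain_size_um
    center = np.array([dx / 2, dy / 2])

    if spec.n_arterioles > 0:
        margin = spec.sheath_radius_um + spec.capillary_radius_um + 1.0
        n_pairs = (spec.n_arterioles + 1) // 2
        placed = 0
        for ip in range(n_pairs):
            want_two = placed + 1 < spec.n_arterioles or spec.n_arterioles % 2 == 0
            pair_done = False
            last_err: PhantomError | None = None
            for attempt in range(max_retries + 1):
                sub = np.random.default_rng(rng.integers(0, 2**31))
                template, leaves = _grow_tree_template(
                    spec, sub, make_long=(spec.long_sheath and ip == 0)
                )
                tnodes = np.asarray(template.nodes)
                ext = tnodes.max(axis=0) - tnodes.min(axis=0)
                if ext[2] > dz - 2 * spec.section_thickness_um:
                    last_err = PhantomError(
                        f"tree z-extent {ext[2]:.0f} µm exceeds the domain depth"
                    )
                    continue
                # base placement: offset from the center, mirrored partner at
                # the point reflection through the domain axis
                shrink = 1.0 - 0.5 * attempt / max(max_retries, 1)
                r_off = sub.uniform(0.05, 0.15) * min(dx, dy) * shrink
                ang = 2 * np.pi * ip / max(n_pairs, 1) + sub.uniform(-0.4, 0.4)
                off = np.array([r_off * np.cos(ang), r_off * np.sin(ang)])
                z0 = sub.uniform(
                    spec.section_thickness_um * 0.5,
                    max(dz - ext[2] - spec.section_thickness_um * 0.5,
                        spec.section_thickness_um * 0.5 + 1e-6),
                )
                base = np.array([center[0] + off[0], center[1] + off[1], z0])
                trial = _Builder()
                trial.nodes = list(gt_builder.nodes)
                trial.edges = list(gt_builder.edges)
                trial.sheaths = list(gt_builder.sheaths)
                trial.bcells = list(gt_builder.bcells)
                n_before = len(trial.nodes)
                _instantiate(template, trial, base, mirror=False)
                if want_two:
                    mbase = np.array([2 * center[0] - base[0],
                                      2 * center[1] - base[1], base[2]])
                    _instantiate(template, trial, mbase, mirror=True)
                try:
                    _check_bounds(spec, np.asarray(trial.nodes[n_before:]), margin)
                except PhantomError as err:
                    last_err = err
                    continue
                gt_builder = trial
                placed += 2 if want_two else 1
                pair_done = True
                break
            if not pair_done:
                raise PhantomError(
                    f"could not place arteriole tree pair {ip} after "
                    f"{max_retries} retries: {last_err}"
                )
            if placed >= spec.n_arterioles:
                break

        # venule: a z-spanning tube off to one side, plus its mirror twin
        if spec.n_venule_contacts > 0:
            vx = center[0] + 0.32 * dx
            vy = center[1]
            if vx > dx - spec.venule_radius_um - 2:
                raise PhantomError("domain too small for the venule")
            for mirror in (False, True):
                x = 2 * center[0] - vx if mirror else vx
                y = 2 * center[1] - vy if mirror else vy
                p0 = np.array([x, y, 0.0])
                p1 = np.array([x, y, dz])
                u = gt_builder.add_node(p0)
                v = gt_builder.add_node(p1)
                gt_builder.add_edge(u, v, spec.venule_radius_um, "venule")
                venule_axis.append((p0, p1))

    # scattered red pulp capillary network: short chains everywhere, in
    # 4-fold symmetric quadruplets (identity, point reflection, and both
    # axis reflections through the domain axis) — the dense CD34+ network
    # that fills real red pulp, with zero net in-plane drift AND zero net
    # curl, so the stack carries no spurious translation or rotation trend
    if spec.n_arterioles > 0 and spec.n_network_trees > 0:
        margin_net = spec.network_radius_um + 2.0
        for _ in range(spec.n_network_trees // 4):
            for attempt in range(30):
                sub = np.random.default_rng(rng.integers(0, 2**31))
                chain = _Builder()
                start = chain.add_node(np.zeros(3))
                # a sizeable subpopulation runs nearly perpendicular to the
                # cutting plane (long z-extent), the rest is isotropic
                vertical = sub.uniform() < spec.network_vertical_fraction
                if vertical:
                    d = _tilt_from(np.array([0.0, 0.0, 1.0]),
                                   np.deg2rad(sub.uniform(0, 8)),
                                   sub.uniform(0, 2 * np.pi))
                    n_seg, seg_lo, seg_hi, wobble = 4, 18.0, 30.0, 5.0
                else:
                    d = _unit(np.array([sub.normal(), sub.normal(),
                                        sub.normal() * 0.7]))
                    n_seg, seg_lo, seg_hi, wobble = 3, 16.0, 26.0, 25.0
                node = start
                for _ in range(int(sub.integers(2, n_seg + 1))):
                    d = _tilt_from(d, np.deg2rad(sub.uniform(0, wobble)),
                                   sub.uniform(0, 2 * np.pi))
                    pos = np.asarray(chain.nodes[node]) + d * sub.uniform(seg_lo, seg_hi)
                    node = chain.add_node(pos)
                    chain.add_edge(node - 1, node, spec.network_radius_um,
                                   "network_capillary")
                cn = np.asarray(chain.nodes)
                ext = cn.max(axis=0) - cn.min(axis=0)
                # chains may overhang the block in z: the tissue continues
                # beyond the first and last section, so end sections keep a
                # realistic structure density
                mx = max(-cn[:, 0].min(), cn[:, 0].max())
                my = max(-cn[:, 1].min(), cn[:, 1].max())
                if (2 * mx >= dx - 2 * margin_net
                        or 2 * my >= dy - 2 * margin_net):
                    continue
                base = np.array([
                    sub.uniform(margin_net + mx, dx - margin_net - mx),
                    sub.uniform(margin_net + my, dy - margin_net - my),
                    sub.uniform(4.0 - cn[:, 2].max(), dz - 4.0 - cn[:, 2].min()),
                ])
                for sx, sy in ((1.0, 1.0), (-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0)):
                    bx = base[0] if sx > 0 else 2 * center[0] - base[0]
                    by = base[1] if sy > 0 else 2 * center[1] - base[1]
                    _instantiate(chain, gt_builder,
                                 np.array([bx, by, base[2]]), signs=(sx, sy))
                break

    gt = PhantomGroundTruth(
        nodes=np.asarray(gt_builder.nodes).reshape(-1, 3),
        edges=gt_builder.edges,
        sheaths=gt_builder.sheaths,
        bcells=gt_builder.bcells,
    )

    # venule contacts: extend network leaves to the nearest venule surface
    if venule_axis and spec.n_venule_contacts > 0:
        leaf_ids = [
            i for i in range(len(gt.nodes))
            if _node_degree(gt, i) == 1
            and any(
                e.structure_class == "network_capillary"
                and i in (e.u, e.v)
                for e in gt.edges
            )
        ]
        # nearest venule axis distance per leaf
        def vdist(i):
            p = gt.nodes[i]
            return min(_point_seg_dist(p, a, bb) for a, bb in venule_axis)

        leaf_ids.sort(key=vdist)
        new_nodes = list(gt.nodes)
        for i in leaf_ids[: spec.n_venule_contacts]:
            p = np.asarray(gt.nodes[i])
            a, bb = min(venule_axis,
                        key=lambda ab: _point_seg_dist(p, ab[0], ab[1]))
            foot = _closest_on_seg(p, a, bb)
            direction = _unit(p - foot) if np.linalg.norm(p - foot) > 0 else np.array([1.0, 0, 0])
            contact = foot + direction * spec.venule_radius_um
            new_nodes.append(contact)
            cid = len(new_nodes) - 1
            gt.edges.append(Edge(i, cid, spec.network_radius_um, "network_capillary"))
            gt.venule_contact_nodes.append(cid)
        gt.nodes = np.asarray(new_nodes).reshape(-1, 3)

    # bypass capillaries: arteriole branch node -> nearby network node
    if spec.n_bypass_capillaries > 0 and spec.n_arterioles > 0:
        art_nodes = sorted(
            {e.v for e in gt.edges if e.structure_class == "arteriole_branch"}
            | {e.u for e in gt.edges if e.structure_class == "arteriole_branch"}
        )
        net_nodes = sorted(
            {e.v for e in gt.edges if e.structure_class == "network_capillary"}
        )
        if art_nodes and net_nodes:
            made = 0
            tries = 0
            while made < spec.n_bypass_capillaries and tries < 50 * spec.n_bypass_capillaries:
                tries += 1
                a = art_nodes[int(rng.integers(0, len(art_nodes)))]
                candidates = sorted(
                    net_nodes,
                    key=lambda n: np.linalg.norm(gt.nodes[n] - gt.nodes[a]),
                )
                n = candidates[int(rng.integers(0, min(4, len(candidates))))]
                d = np.linalg.norm(gt.nodes[n] - gt.nodes[a])
                if d < 10.0 or d > 120.0:
                    continue
                gt.edges.append(Edge(a, n, spec.network_radius_um, "bypass_capillary"))
                made += 1
            if made < spec.n_bypass_capillaries:
                raise PhantomError(
                    "could not place the requested bypass capillaries "
                    "(no arteriole/network node pair at a feasible distance)"
                )

    if spec.long_sheath and gt.sheaths:
        longest = max(
            range(len(gt.sheaths)),
            key=lambda i: gt.path_length(gt.sheaths[i].main_path_edge_ids),
        )
        s = gt.sheaths[longest]
        gt.long_path = {
            "sheath_id": longest,
            "entry_node": s.entry_node,
            "exit_node": s.exit_node,
            "length_um": gt.path_length(s.main_path_edge_ids),
        }
    return gt


def _node_degree(gt: PhantomGroundTruth, i: int) -> int:
    return sum(1 for e in gt.edges if i in (e.u, e.v))


def _closest_on_seg(p, a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-30), 0.0, 1.0)
    return a + t * ab


def _point_seg_dist(p, a, b) -> float:
    return float(np.linalg.norm(np.asarray(p) - _closest_on_seg(p, a, b)))


# ---------------------------------------------------------------------------
# voxelization


def _capsule_mask(grid_origin, spacing, shape, a, b, radius, out):
    """OR into ``out`` the voxels whose centers lie within the capsule."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    i0 = np.maximum(((lo - grid_origin) / spacing - 0.5).astype(int), 0)
    i1 = np.minimum(((hi - grid_origin) / spacing + 0.5).astype(int) + 1, shape)
    if np.any(i0 >= i1):
        return
    ax = [grid_origin[k] + (np.arange(i0[k], i1[k]) + 0.5) * spacing[k] for k in range(3)]
    X, Y, Z = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    ab = b - a
    denom = max(float(ab @ ab), 1e-30)
    t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d2 = np.sum((P - closest) ** 2, axis=-1)
    out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= radius * radius


def _sphere_mask(grid_origin, spacing, shape, c, radius, out):
    _capsule_mask(grid_origin, spacing, shape, c, c, radius, out)


def voxelize_ground_truth(
    gt: PhantomGroundTruth,
    spacing: tuple[float, float, float],
    domain_size_um: tuple[float, float, float] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    shape: tuple[int, int, int] | None = None,
    stains: tuple[str, ...] = ("SMA", "CD34", "CD271", "CD20"),
) -> dict[str, np.ndarray]:
    """Per-stain occupancy volumes in [0, 1] on a voxel-center grid.

    A voxel is occupied iff its center lies inside an edge capsule, a sheath
    shell, or a B-cell sphere assigned that stain.  The grid covers
    ``domain_size_um`` (or an explicit ``origin``/``shape`` box); world
    position of voxel ``(i, j, k)`` is ``origin + (index + 1/2) * spacing``.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if shape is None:
        if domain_size_um is None:
            raise ValueError("need domain_size_um or shape")
        shape = tuple(int(round(domain_size_um[k] / spacing[k])) for k in range(3))
    shape = np.asarray(shape, dtype=int)
    origin = np.asarray(origin, dtype=float)

    min_radius = min(
        [e.radius_um for e in gt.edges] + [r for _, r in gt.bcells],
        default=np.inf,
    )
    if np.isfinite(min_radius) and np.max(spacing) > min_radius:
        import warnings

        warnings.warn(
            "voxel spacing is coarser than the smallest structure radius; "
            "structures may vanish",
            stacklevel=2,
        )

    out = {s: np.zeros(tuple(shape), dtype=bool) for s in stains}
    for e in gt.edges:
        a, b = gt.nodes[e.u], gt.nodes[e.v]
        for s in gt.stain_map[e.structure_class]:
            if s in out:
                _capsule_mask(origin, spacing, shape, a, b, e.radius_um, out[s])
    if "CD271" in out and gt.sheaths:
        shell = np.zeros(tuple(shape), dtype=bool)
        lumen = np.zeros(tuple(shape), dtype=bool)
        for s in gt.sheaths:
            for eid in s.edge_ids:
                e = gt.edges[eid]
                _capsule_mask(origin, spacing, shape, gt.nodes[e.u], gt.nodes[e.v],
                              s.outer_radius_um, shell)
                _capsule_mask(origin, spacing, shape, gt.nodes[e.u], gt.nodes[e.v],
                              e.radius_um, lumen)
        out["CD271"] |= shell & ~lumen
    if "CD20" in out:
        for c, r in gt.bcells:
            _sphere_mask(origin, spacing, shape, c, r, out["CD20"])
    return {s: v.astype(np.float64) for s, v in out.items()}


# ---------------------------------------------------------------------------
# rendering


def _section_stains(spec: PhantomSpec, k: int) -> tuple[str, frozenset]:
    first, other = (
        ("CD271", "CD20") if spec.red_parity_start == "CD271" else ("CD20", "CD271")
    )
    red = first if k % 2 == 0 else other
    return red, frozenset({"SMA", "CD34", red})


def _jitter_transform(theta_deg: float, tx: float, ty: float,
                      shape: tuple[int, int]) -> EuclideanTransform:
    """Rigid map (ideal -> jittered pixel coords) about the image center."""
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    center = np.array([cx, cy])
    t = np.deg2rad(theta_deg)
    shift = EuclideanTransform(translation=-center)
    rot = EuclideanTransform(rotation=t)
    back = EuclideanTransform(translation=center + np.array([tx, ty]))
    return shift + rot + back


def render_sections(
    gt: PhantomGroundTruth,
    stain_model: StainModel,
    spec: PhantomSpec,
    quantize: bool = True,
    subslab_um: float = 1.0,
) -> list[SectionImage]:
    """Render triple-stained serial sections with jitter and noise.

    Transmitted intensity per pixel follows Beer–Lambert through the 7 µm
    slab: the per-stain column density is the stained path length through
    the slab times the stain's OD amplitude per µm.  Odd/even sections
    alternate the red stain; per-section rigid jitter and Gaussian noise are
    applied last.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(0, 2**31))
    ny, nx = spec.image_shape
    thickness = spec.section_thickness_um
    nz_sub = max(int(round(thickness / subslab_um)), 1)
    dz = thickness / nz_sub
    amplitudes = dict(STAIN_AMPLITUDES)
    amplitudes.update(stain_model.concentration_scale)

    sections: list[SectionImage] = []
    for k in range(spec.n_sections):
        red, stain_set = _section_stains(spec, k)
        markers = ("SMA", "CD34", red)
        occ = voxelize_ground_truth(
            gt,
            spacing=(spec.pixel_size_um, spec.pixel_size_um, dz),
            origin=(0.0, 0.0, k * thickness),
            shape=(nx, ny, nz_sub),
            stains=markers,
        )
        dens = np.zeros((ny, nx, 3))
        for m in markers:
            col = occ[m].sum(axis=2) * dz * amplitudes[m]  # x, y
            row = STAIN_ORDER.index(MARKER_TO_ROW[m])
            dens[..., row] += col.T  # to (row=y, col=x)
        rgb = np.clip(stain_model.transmit(dens), 0.0, 255.0)

        t_lo, t_hi = spec.jitter_translation_px
        r_lo, r_hi = spec.jitter_rotation_deg
        mag = rng.uniform(t_lo, t_hi)
        ang = rng.uniform(0, 2 * np.pi)
        tx, ty = mag * np.cos(ang), mag * np.sin(ang)
        theta = rng.uniform(r_lo, r_hi) * (1 if rng.uniform() < 0.5 else -1)
        if mag > 0 or theta != 0:
            T = _jitter_transform(theta, tx, ty, (ny, nx))
            rgb = warp(rgb, T.inverse, order=1, cval=255.0, mode="constant",
                       preserve_range=True)
        if spec.noise_sd > 0:
            rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
        rgb = np.clip(rgb, 0.0, 255.0)
        if quantize:
            rgb = np.rint(rgb).astype(np.uint8)
        sections.append(
            SectionImage(
                pixels=rgb,
                pixel_size_um=spec.pixel_size_um,
                section_index=k,
                z_um=k * thickness,
                stain_set=stain_set,
                jitter=(theta, tx, ty),
            )
        )
    return sections


def apply_section_artifacts(
    sections: list[SectionImage],
    lost_section_indices: tuple[int, ...] = (),
    defocus_indices: tuple[int, ...] = (),
    defocus_sigma: float = 3.0,
) -> list[SectionImage]:
    """Remove lost sections and blur defocused ones.

    Surviving sections keep their original ``section_index`` and ``z_um``, so
    gaps remain visible to downstream stages.  Defocused sections are
    Gaussian-blurred in-plane and flagged ``focus_ok=False``.  Lost and
    defocused index sets may overlap; out-of-range indices raise.
    """
    from scipy.ndimage import gaussian_filter

    n = len(sections)
    for idx in tuple(lost_section_indices) + tuple(defocus_indices):
        if not (0 <= idx < n):
            raise IndexError(f"section index {idx} out of range (stack of {n})")
    lost = set(lost_section_indices)
    defocus = set(defocus_indices)
    out: list[SectionImage] = []
    for s in sections:
        if s.section_index in lost:
            continue
        if s.section_index in defocus:
            px = s.pixels.astype(float)
            px = gaussian_filter(px, sigma=(defocus_sigma, defocus_sigma, 0))
            px = np.clip(px, 0, 255)
            if s.pixels.dtype == np.uint8:
                px = np.rint(px).astype(np.uint8)
            s = dataclasses.replace(s, pixels=px, focus_ok=False)
        out.append(s)
    return out
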