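"""3-D virtual-tissue building blocks: polygonization, extrusion, cuboids.

The pipeline mirrors how a segmented histology slice becomes a
simulation substrate:

1. :func:`polygonize` traces each cell's pixel boundary as an exact
   "crack" polygon (area equals pixel count x pixel area) and simplifies
   it with Douglas-Peucker at sub-half-pixel tolerance, so polygons of
   neighbouring cells can never overlap.
2. :func:`extrude_block` extrudes each footprint along the local cell
   axis (z') into a closed, outward-oriented triangulated prism with an
   independently drawn uniform length, placed at a random axial offset
   inside the block depth — the uncovered ends stand in for
   intercalated-disc gaps.  An optional sinusoidal z'-displacement of
   the vertices (period = block width) breaks straight extra-cellular
   channels along x'.
3. :func:`make_cuboid_block` builds the idealised counterpart: a regular
   grid of square-section cuboids matching a mean cross-sectional area,
   with a single inter-cell gap solved by bisection to meet a target
   extra-cellular volume fraction to 0.1 percentage points.

Blocks carry a flat axis-aligned-bounding-box hierarchy (BVH) over all
triangles, consumed by the random-walk kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .raster import LabelRaster

__all__ = [
    "GeometryError",
    "Footprint",
    "CellPrism",
    "BuildingBlock",
    "polygonize",
    "extrude_block",
    "make_cuboid_block",
    "audit_block",
    "save_block_hdf5",
    "load_block_hdf5",
    "export_block_mesh",
]


class GeometryError(ValueError):
    """Invalid polygon/mesh input or unsatisfiable geometric target."""


@dataclass(frozen=True)
class Footprint:
    """Simple 2-D cell cross-section polygon in micrometres (CCW)."""

    polygon: np.ndarray  # (V, 2) float, open ring (last != first)
    cell_id: int
    sheetlet_id: int

    @property
    def area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class CellPrism:
    """Extruded cell: footprint polygon, axial length and offset (um)."""

    polygon: np.ndarray
    length: float
    z_offset: float
    cell_id: int
    sheetlet_id: int

    @property
    def footprint_area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def volume(self) -> float:
        return self.footprint_area * self.length


@dataclass
class BuildingBlock:
    """One meshed tissue block, replicated by the lattice to fill a voxel.

    ``triangles``: (T, 3, 3) vertex coordinates; ``tri_cell``: (T,) cell
    id per triangle; ``extent``: (Lx', Ly, Lz') block dimensions so that
    the canonical domain is [0, Lx) x [0, Ly) x [0, Lz).  A flat BVH
    over the triangles accelerates ray queries.
    """

    prisms: list[CellPrism]
    extent: tuple[float, float, float]
    triangles: np.ndarray
    tri_cell: np.ndarray
    bvh: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self.bvh is None:
            self.bvh = build_bvh(self.triangles)

    @property
    def n_cells(self) -> int:
        return len(self.prisms)

    @property
    def cell_volume(self) -> float:
        return float(sum(p.volume for p in self.prisms))

    @property
    def ecv(self) -> float:
        """Analytic 3-D extra-cellular volume fraction of the block."""
        lx, ly, lz = self.extent
        return 1.0 - self.cell_volume / (lx * ly * lz)


# ---------------------------------------------------------------------------
# pixel-boundary polygons

# directed crack edges keeping the cell interior on the left, per
# outside-neighbour direction (dr, dc) -> (start corner, end corner)
_EDGE_RULES = {
    (-1, 0): ((0, 0), (0, 1)),   # top side
    (0, 1): ((0, 1), (1, 1)),    # right side
    (1, 0): ((1, 1), (1, 0)),    # bottom side
    (0, -1): ((1, 0), (0, 0)),   # left side
}


def _trace_crack(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a 4-connected pixel mask as a closed lattice
    polygon (vertices at pixel corners, (row, col) units)."""
    rows, cols = np.nonzero(mask)
    edges: dict[tuple, list] = {}
    n_edges = 0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    for r, c in zip(rows, cols):
        for (dr, dc), (a, b) in _EDGE_RULES.items():
            if not padded[r + 1 + dr, c + 1 + dc]:
                start = (r + a[0], c + a[1])
                end = (r + b[0], c + b[1])
                edges.setdefault(start, []).append((end, (r, c)))
                n_edges += 1

    # walk loops; at pinch vertices prefer continuing along the same
    # pixel's boundary so loops never cross
    loops = []
    consumed = 0
    while consumed < n_edges:
        start = min(v for v, opts in edges.items() if opts)
        end, pix = edges[start].pop(0)
        consumed += 1
        loop = [start]
        while end != start:
            loop.append(end)
            options = edges[end]
            same = [o for o in options if o[1] == pix]
            choice = same[0] if same else options[0]
            options.remove(choice)
            consumed += 1
            end, pix = choice
        loops.append(np.asarray(loop))

    # keep the loop with the largest absolute area (the outer boundary;
    # interior holes in a cell cross-section are ignored)
    def ring_area(v):
        x, y = v[:, 1].astype(float), v[:, 0].astype(float)
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    return max(loops, key=lambda v: abs(ring_area(v)))


def _simplify_ring(ring_um: np.ndarray, max_vertices: int,
                   tol_cap: float) -> np.ndarray:
    """Douglas-Peucker simplification of a closed ring, bounded by
    ``tol_cap`` so neighbouring cells (>= 1 px apart) cannot overlap."""
    poly = Polygon(ring_um)
    if not poly.is_valid:
        poly = poly.buffer(0)
    # remove collinear vertices first
    best = poly.simplify(1e-9, preserve_topology=True)
    if len(best.exterior.coords) - 1 <= max_vertices:
        out = best
    else:
        lo, hi = 0.0, tol_cap
        out = best.simplify(tol_cap, preserve_topology=True)
        if len(out.exterior.coords) - 1 <= max_vertices:
            # binary search the smallest tolerance meeting the budget
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                cand = best.simplify(mid, preserve_topology=True)
                if len(cand.exterior.coords) - 1 <= max_vertices:
                    hi, out = mid, cand
                else:
                    lo = mid
        # else: the tolerance cap wins over the vertex budget — keep the
        # unsimplifiable boundary rather than risk overlap
    coords = np.asarray(out.exterior.coords[:-1], dtype=float)
    if coords.shape[0] < 3:
        coords = np.asarray(poly.exterior.coords[:-1], dtype=float)
    # ensure CCW orientation (positive shoelace area)
    x, y = coords[:, 0], coords[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        coords = coords[::-1]
    return coords


def polygonize(raster: LabelRaster, max_vertices: int = 320) -> list[Footprint]:
    """Trace every cell's pixel boundary as a simple polygon (um).

    The crack boundary follows pixel edges exactly, so the polygon area
    equals ``pixel count * pixel_size**2``.  Douglas-Peucker
    simplification is applied down to ``max_vertices`` but never with a
    tolerance above 0.45 px, preserving the inter-cell gaps; polygons of
    distinct cells therefore never overlap.  Raster row -> y, column ->
    x'.
    """
    px = raster.pixel_size
    out = []
    for cid in raster.cell_ids:
        mask = raster.labels == int(cid)
        ring = _trace_crack(mask)  # (V, 2) in (row, col) corner units
        ring_um = np.column_stack([ring[:, 1] * px, ring[:, 0] * px])
        coords = _simplify_ring(ring_um, max_vertices, tol_cap=0.45 * px)
        out.append(Footprint(polygon=coords, cell_id=int(cid),
                             sheetlet_id=raster.sheetlet_of[int(cid)]))
    return out


# ---------------------------------------------------------------------------
# extrusion

def _triangulate_footprint(coords: np.ndarray) -> np.ndarray:
    """Triangulate a simple polygon; returns (F, 3) indices into coords."""
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"footprint polygon is not simple/valid")
    tris = shapely.constrained_delaunay_triangles(poly)
    index = {(round(xx, 9), round(yy, 9)): i
             for i, (xx, yy) in enumerate(coords)}
    faces = []
    for tri in tris.geoms:
        c = np.asarray(tri.exterior.coords[:-1])
        if not poly.contains(tri.representative_point()):
            continue  # triangle in a concavity
        try:
            idx = [index[(round(xx, 9), round(yy, 9))] for xx, yy in c]
        except KeyError as exc:  # Steiner point: should not happen
            raise GeometryError("triangulation introduced new vertices") from exc
        # orient CCW in the plane
        a, b, cc = (coords[i] for i in idx)
        if (b[0] - a[0]) * (cc[1] - a[1]) - (b[1] - a[1]) * (cc[0] - a[0]) < 0:
            idx = idx[::-1]
        faces.append(idx)
    if not faces:
        raise GeometryError("empty triangulation")
    return np.asarray(faces, dtype=np.int64)


def _prism_mesh(prism: CellPrism, cap_faces: np.ndarray,
                sin_amplitude: float = 0.0,
                sin_wavelength: float = np.inf,
                side_segment: float | None = None) -> np.ndarray:
    """Closed triangle soup (T, 3, 3) for one prism, outward normals.

    The optional sinusoidal z-displacement shifts every vertex by
    ``A * sin(2 pi x / wavelength)`` — a volume-preserving shear that
    staggers cell ends and bends the extra-cellular channels, identical
    in every tile when the wavelength divides the block width.

    ``side_segment`` tessellates the side walls into axial rings of at
    most that height (um).  The surface is unchanged; the point is
    tight triangle bounding boxes — full-length wall triangles overlap
    every z and degrade the bounding-volume hierarchy badly on blocks
    with many cells.
    """
    v2 = prism.polygon
    n = v2.shape[0]
    z0 = prism.z_offset
    shift = (sin_amplitude * np.sin(2.0 * np.pi * v2[:, 0] / sin_wavelength)
             if sin_amplitude != 0.0 else np.zeros(n))
    n_ring = (1 if side_segment is None
              else max(1, int(np.ceil(prism.length / side_segment))))
    z_levels = z0 + np.linspace(0.0, prism.length, n_ring + 1)
    rings = [np.column_stack([v2, z + shift]) for z in z_levels]

    tris = []
    # bottom cap: normal -z (reverse CCW cap faces)
    for f in cap_faces:
        tris.append(rings[0][[f[0], f[2], f[1]]])
    # top cap: normal +z
    for f in cap_faces:
        tris.append(rings[-1][[f[0], f[1], f[2]]])
    # side walls: CCW footprint => outward quad normals
    for r in range(n_ring):
        bot, top = rings[r], rings[r + 1]
        for i in range(n):
            j = (i + 1) % n
            tris.append(np.stack([bot[i], bot[j], top[j]]))
            tris.append(np.stack([bot[i], top[j], top[i]]))
    return np.stack(tris)


def extrude_block(footprints: list[Footprint],
                  length_range: tuple[float, float] = (114.0, 126.0),
                  seed: int = 0,
                  extent_xy: tuple[float, float] | None = None,
                  depth: float | None = None,
                  axial_margin: float = 0.0,
                  sin_amplitude: float = 0.0,
                  sin_wavelength: float | None = None,
                  side_segment: float | None = None) -> BuildingBlock:
    """Extrude cell footprints into a meshed 3-D building block.

    Each footprint becomes a closed triangulated prism with an
    independently drawn uniform length from ``length_range`` and a
    uniform axial offset placing it inside the block depth (default:
    the maximum cell length plus twice ``axial_margin``), which leaves
    extra-cellular gaps at the cell ends — the impermeable stand-in for
    intercalated discs.

    ``axial_margin`` reserves space at both axial ends of every cell so
    that a later sinusoidal z'-displacement of up to that amplitude
    (:func:`myowalk.lattice.apply_sinusoid`) cannot push any vertex
    outside the canonical tile — membranes crossing tile boundaries
    would break the periodic fold.
    """
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise GeometryError("invalid length range")
    if axial_margin < 0:
        raise GeometryError("axial margin must be non-negative")
    depth = float(hi + 2 * axial_margin if depth is None else depth)
    if depth < hi + 2 * axial_margin:
        raise GeometryError("block depth must admit the longest cell "
                            "plus the axial margins")
    if extent_xy is None:
        allv = np.vstack([f.polygon for f in footprints])
        extent_xy = (float(allv[:, 0].max()), float(allv[:, 1].max()))
    if sin_wavelength is None:
        sin_wavelength = extent_xy[0]

    rng = np.random.default_rng(seed)
    prisms = []
    tri_list = []
    cell_list = []
    for fp in footprints:
        if fp.area <= 0 or not Polygon(fp.polygon).is_valid:
            raise GeometryError(f"cell {fp.cell_id}: non-simple polygon")
        length = float(rng.uniform(lo, hi))
        z_off = float(rng.uniform(axial_margin,
                                  depth - length - axial_margin))
        prism = CellPrism(polygon=fp.polygon, length=length, z_offset=z_off,
                          cell_id=fp.cell_id, sheetlet_id=fp.sheetlet_id)
        cap = _triangulate_footprint(fp.polygon)
        mesh = _prism_mesh(prism, cap, sin_amplitude, sin_wavelength,
                           side_segment=side_segment)
        prisms.append(prism)
        tri_list.append(mesh)
        cell_list.append(np.full(mesh.shape[0], fp.cell_id, dtype=np.int32))

    triangles = np.concatenate(tri_list)
    tri_cell = np.concatenate(cell_list)
    extent = (extent_xy[0], extent_xy[1], depth)
    return BuildingBlock(prisms=prisms, extent=extent,
                         triangles=triangles, tri_cell=tri_cell)


# ---------------------------------------------------------------------------
# idealised cuboid block

def _square(cx: float, cy: float, side: float) -> np.ndarray:
    h = side / 2.0
    return np.array([[cx - h, cy - h], [cx + h, cy - h],
                     [cx + h, cy + h], [cx - h, cy + h]])


def make_cuboid_block(mean_area: float = 110.0,
                      length_range: tuple[float, float] = (114.0, 126.0),
                      target_ecv: float = 0.25) -> BuildingBlock:
    """Regular lattice of uniform square-section cuboids at a target ECV.

    The idealised counterpart of the histology block: one cuboid of
    side sqrt(mean_area) and length equal to the mid-range cell length,
    with a single gap g separating cells both laterally and axially.
    The gap is solved by bisection of the analytic volume fraction

        ECV(g) = 1 - s^2 L / ((s + g)^2 (L + g))

    to within 0.1 percentage points of the target.  The periodic cell
    (pitch s+g laterally, L+g axially) is the building block; the
    lattice stagger offsets the axial gap planes of neighbouring
    columns by half a block.
    """
    if not 0.0 < target_ecv < 1.0:
        raise GeometryError("target ECV must be in (0, 1)")
    side = float(np.sqrt(mean_area))
    length = 0.5 * (length_range[0] + length_range[1])

    def ecv_of(g):
        return 1.0 - (side * side * length) / ((side + g) ** 2 * (length + g))

    if ecv_of(0.0) >= target_ecv:
        raise GeometryError(
            f"target ECV {target_ecv} needs a non-positive gap "
            f"(zero-gap ECV is {ecv_of(0.0):.4f})")
    g_lo, g_hi = 0.0, side
    while ecv_of(g_hi) < target_ecv:
        g_hi *= 2.0
        if g_hi > 1e4:
            raise GeometryError("no gap reaches the target ECV")
    for _ in range(100):
        g = 0.5 * (g_lo + g_hi)
        if ecv_of(g) < target_ecv:
            g_lo = g
        else:
            g_hi = g
    g = 0.5 * (g_lo + g_hi)
    if abs(ecv_of(g) - target_ecv) > 1e-3:
        raise GeometryError("bisection failed to reach the target ECV")

    pitch = side + g
    slot = length + g
    poly = _square(0.5 * pitch, 0.5 * pitch, side)
    prism = CellPrism(polygon=poly, length=length, z_offset=0.5 * g,
                      cell_id=1, sheetlet_id=0)
    cap = np.array([[0, 1, 2], [0, 2, 3]])
    mesh = _prism_mesh(prism, cap)
    block = BuildingBlock(prisms=[prism], extent=(pitch, pitch, slot),
                          triangles=mesh,
                          tri_cell=np.full(mesh.shape[0], 1, np.int32))
    if abs(block.ecv - target_ecv) > 1e-3:
        raise GeometryError(
            f"achieved ECV {block.ecv:.4f} misses target {target_ecv:.4f}")
    return block


# ---------------------------------------------------------------------------
# BVH over triangles (flat arrays, consumed by the numba kernels)

def build_bvh(triangles: np.ndarray, leaf_size: int = 4) -> dict:
    """Median-split AABB hierarchy.  Returns flat arrays: per node the
    bounds, children (-1 for leaves) and the triangle index range into
    ``order``; leaf triangle indices keep ascending original order so
    intersection ties break deterministically."""
    n = triangles.shape[0]
    lo = triangles.min(axis=1)
    hi = triangles.max(axis=1)
    cent = triangles.mean(axis=1)

    node_min, node_max = [], []
    node_left, node_right = [], []
    node_start, node_count = [], []
    order = np.arange(n)

    def new_node():
        node_min.append(np.zeros(3)); node_max.append(np.zeros(3))
        node_left.append(-1); node_right.append(-1)
        node_start.append(0); node_count.append(0)
        return len(node_left) - 1

    stack = [(new_node(), 0, n)]
    while stack:
        ni, a, b = stack.pop()
        idx = order[a:b]
        node_min[ni] = lo[idx].min(axis=0)
        node_max[ni] = hi[idx].max(axis=0)
        if b - a <= leaf_size:
            node_start[ni], node_count[ni] = a, b - a
            order[a:b] = np.sort(idx)
            continue
        axis = int(np.argmax(node_max[ni] - node_min[ni]))
        key = cent[idx, axis]
        half = (b - a) // 2
        part = np.argpartition(key, half)
        order[a:b] = idx[part]
        li, ri = new_node(), new_node()
        node_left[ni], node_right[ni] = li, ri
        stack.append((li, a, a + half))
        stack.append((ri, a + half, b))

    return {
        "node_min": np.asarray(node_min, dtype=np.float64),
        "node_max": np.asarray(node_max, dtype=np.float64),
        "node_left": np.asarray(node_left, dtype=np.int64),
        "node_right": np.asarray(node_right, dtype=np.int64),
        "node_start": np.asarray(node_start, dtype=np.int64),
        "node_count": np.asarray(node_count, dtype=np.int64),
        "order": order.astype(np.int64),
    }


# ---------------------------------------------------------------------------
# audits and I/O

def _as_trimesh(block: BuildingBlock, cell_id: int):
    import trimesh

    sel = block.tri_cell == cell_id
    tris = block.triangles[sel]
    verts = tris.reshape(-1, 3)
    faces = np.arange(verts.shape[0]).reshape(-1, 3)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True,
                           validate=False)
    mesh.merge_vertices()
    return mesh


def audit_block(block: BuildingBlock) -> dict:
    """Mesh soundness report: per-prism watertightness, winding, and the
    match between enclosed mesh volume and the analytic prism volume."""
    report = {"n_cells": block.n_cells, "watertight": True,
              "max_volume_error": 0.0}
    for prism in block.prisms:
        mesh = _as_trimesh(block, prism.cell_id)
        if not mesh.is_watertight:
            report["watertight"] = False
            report.setdefault("leaky_cells", []).append(prism.cell_id)
            continue
        err = abs(abs(mesh.volume) - prism.volume) / prism.volume
        report["max_volume_error"] = max(report["max_volume_error"], err)
    return report


def save_block_hdf5(block: BuildingBlock, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["extent"] = block.extent
        f.create_dataset("triangles", data=block.triangles)
        f.create_dataset("tri_cell", data=block.tri_cell)
        g = f.create_group("prisms")
        for p in block.prisms:
            gp = g.create_group(str(p.cell_id))
            gp.create_dataset("polygon", data=p.polygon)
            gp.attrs.update(length=p.length, z_offset=p.z_offset,
                            sheetlet_id=p.sheetlet_id)


def load_block_hdf5(path) -> BuildingBlock:
    import h5py

    with h5py.File(path, "r") as f:
        extent = tuple(float(v) for v in f.attrs["extent"])
        triangles = f["triangles"][()]
        tri_cell = f["tri_cell"][()]
        prisms = []
        for cid, gp in f["prisms"].items():
            prisms.append(CellPrism(
                polygon=gp["polygon"][()], length=float(gp.attrs["length"]),
                z_offset=float(gp.attrs["z_offset"]), cell_id=int(cid),
                sheetlet_id=int(gp.attrs["sheetlet_id"])))
    prisms.sort(key=lambda p: p.cell_id)
    return BuildingBlock(prisms=prisms, extent=extent,
                         triangles=triangles, tri_cell=tri_cell)


def export_block_mesh(block: BuildingBlock, path) -> None:
    """Export the full block as PLY/OFF (by extension) for inspection."""
    import trimesh

    verts = block.triangles.reshape(-1, 3)
    faces = np.arange(verts.shape[0]).reshape(-1, 3)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.export(path)
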