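"""3D/2D shape features of segmented cells.

Five reported features per cell mask: surface-area-to-volume ratio,
sphericity, the smallest semi-axis of the fitted inertia ellipsoid, the
longest shortest path of the 2D skeleton, and the total skeleton length.

Conventions (pinned for determinism): surface area from a marching-cubes
isosurface at the 0.5 level (voxel-face counting overestimates a sphere's
area by ~50 %); inertia semi-axes √(5λ) from the second central moments
(the solid-ellipsoid relation); skeletons from topology-preserving 2D
thinning of the maximum intensity projection with 8-connected foreground,
edge lengths 1 (axial) and √2 (diagonal) pixel steps scaled by pixel size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.morphology import skeletonize

from .core_model import CellMask


@dataclass
class MorphometricFeatures:
    volume: float                 # µm³
    surface_area: float           # µm²
    sa_to_vol: float              # µm⁻¹
    sphericity: float             # (0, 1] up to mesh tolerance
    ellipsoid_radii: tuple[float, float, float]  # semi-axes µm, descending
    longest_shortest_path: float  # µm
    total_skeleton_length: float  # µm
    touches_boundary: bool = False


def volume_and_surface(mask: CellMask) -> tuple[float, float]:
    """(volume µm³, surface area µm²): voxel count × voxel volume, and the
    area of the 0.5-level marching-cubes isosurface (anisotropy respected)."""
    vol = float(mask.voxels.sum()) * mask.voxel_volume
    # light Gaussian presmoothing (0.8 voxel) removes the staircase bias of a
    # binary isosurface, which otherwise overestimates a sphere's area by ~8 %
    padded = np.pad(mask.voxels.astype(float), 3)
    smoothed = gaussian_filter(padded, sigma=0.8)
    if smoothed.max() < 0.5:  # blobs of a few voxels smooth away entirely
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5,
                                                spacing=mask.voxel_size)
    area = float(measure.mesh_surface_area(verts, faces))
    return vol, area


def sphericity(volume: float, surface_area: float) -> float:
    """π^(1/3)·(6V)^(2/3)/A — 1 for a perfect sphere."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return math.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface_area


def inertia_ellipsoid_radii(mask: CellMask) -> tuple[float, float, float]:
    """Semi-axes (µm, descending) of the ellipsoid with the mask's second
    central moments: eigenvalues λ of the covariance of voxel-center
    coordinates, semi-axes √(5λ) (solid-ellipsoid moment relation)."""
    zz, yy, xx = np.nonzero(mask.voxels)
    if len(zz) < 4:
        raise ValueError("need ≥ 4 voxels for an inertia ellipsoid")
    dz, dy, dx = mask.voxel_size
    pts = np.column_stack([xx * dx, yy * dy, zz * dz])
    cov = np.cov(pts.T, bias=True)
    lam = np.linalg.eigvalsh(cov)
    if lam[0] < 1e-12 * max(lam[-1], 1.0):
        raise ValueError("degenerate (coplanar) mask")
    radii = np.sqrt(5.0 * lam)[::-1]
    return tuple(float(r) for r in radii)


# ---------------------------------------------------------------------------
# 2D skeleton on the maximum intensity projection

_AXIAL = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _pixel_graph(skel: np.ndarray, pixel_size: tuple[float, float]) -> nx.Graph:
    """8-connected pixel graph; a diagonal edge is dropped when its two
    endpoints already share an axial skeleton neighbor (avoids double
    counting path length through right-angle triangles)."""
    dy, dx = pixel_size
    on = set(zip(*np.nonzero(skel)))
    g = nx.Graph()
    g.add_nodes_from(on)
    for (r, c) in on:
        for (drr, dcc) in _AXIAL:
            nb = (r + drr, c + dcc)
            if nb in on:
                g.add_edge((r, c), nb,
                           weight=abs(drr) * dy + abs(dcc) * dx)
        for (drr, dcc) in _DIAG:
            nb = (r + drr, c + dcc)
            if nb in on:
                if ((r + drr, c) in on) or ((r, c + dcc) in on):
                    continue  # axial detour exists: skip the diagonal
                g.add_edge((r, c), nb,
                           weight=math.hypot(drr * dy, dcc * dx))
    return g


def _condense(g: nx.Graph) -> nx.MultiGraph:
    """Contract degree-2 chains: nodes become endpoints/junctions, edge
    weights become geodesic chain lengths."""
    special = [n for n in g.nodes if g.degree(n) != 2]
    if not special and g.number_of_nodes():
        special = [min(g.nodes)]  # pure cycle: pin one anchor
    cg = nx.MultiGraph()
    cg.add_nodes_from(special)
    seen: set[frozenset] = set()
    for s in special:
        for nb in g.neighbors(s):
            first = frozenset((s, nb))
            if first in seen:
                continue
            path_edges = [first]
            w = g.edges[s, nb]["weight"]
            prev, cur = s, nb
            while cur not in special:
                nxt = next(x for x in g.neighbors(cur) if x != prev)
                path_edges.append(frozenset((cur, nxt)))
                w += g.edges[cur, nxt]["weight"]
                prev, cur = cur, nxt
            seen.update(path_edges)
            cg.add_edge(s, cur, weight=w)
    return cg


def mip_skeleton(mask: CellMask) -> nx.MultiGraph:
    """Skeleton graph of the z maximum intensity projection.

    Nodes are endpoint/junction pixels; edges carry the geodesic pixel-path
    length in µm.  Isolated single pixels yield isolated nodes.
    """
    mip = mask.voxels.any(axis=0)
    if not mip.any():
        raise ValueError("empty projection")
    skel = skeletonize(mip)
    if not skel.any():
        # thinning of a single-pixel-scale blob can vanish; keep its centre
        rr, cc = np.nonzero(mip)
        skel = np.zeros_like(mip)
        skel[int(np.round(rr.mean())), int(np.round(cc.mean()))] = True
    _dz, dy, dx = mask.voxel_size
    return _condense(_pixel_graph(skel, (dy, dx)))


def skeleton_stats(graph: nx.MultiGraph) -> tuple[float, float]:
    """(total skeleton length, longest shortest path), both µm.

    Total = sum of edge weights; the longest shortest path is the graph
    diameter over endpoint/junction nodes (per connected component; the
    maximum across components is reported for fragmented skeletons).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty skeleton graph")
    total = float(sum(d["weight"] for _, _, d in graph.edges(data=True)))
    diam = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(graph, weight="weight"))
    for src, dsts in lengths.items():
        m = max(dsts.values(), default=0.0)
        diam = max(diam, float(m))
    return total, diam


def extract_features(mask: CellMask) -> MorphometricFeatures:
    """All five reported features of one cell mask."""
    vol, area = volume_and_surface(mask)
    graph = mip_skeleton(mask)
    total, lsp = skeleton_stats(graph)
    return MorphometricFeatures(
        volume=vol, surface_area=area, sa_to_vol=area / vol,
        sphericity=sphericity(vol, area),
        ellipsoid_radii=inertia_ellipsoid_radii(mask),
        longest_shortest_path=lsp, total_skeleton_length=total,
        touches_boundary=mask.touches_boundary())
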