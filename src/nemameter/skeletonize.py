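"""Reduce a worm mask to one ordered medial path.

Topological thinning gives a 1-px-wide skeleton; for a clean worm this is a
single open curve, but noise and non-worm objects produce side branches.
The skeleton pixels are therefore treated as a weighted graph (orthogonal
steps weigh 1, diagonal steps √2) which must be a tree — a cycle means the
worm touches itself and the object is rejected.  The longest
endpoint-to-endpoint path through the tree is the pruned skeleton; the
ratio of its length to the total skeleton length flags spurious, heavily
branched objects.  Finally the path is extended from each tip along its
local tangent to the mask boundary, so that it spans the whole animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage import morphology

__all__ = [
    "SkeletonPath",
    "SkeletonCycleError",
    "thin_mask",
    "skeleton_graph",
    "prune_to_path",
    "ratio_filter",
    "extend_to_edges",
    "path_length",
]

_SQRT2 = float(np.sqrt(2.0))


class SkeletonCycleError(RuntimeError):
    """Skeleton contains a cycle (self-touching worm): object auto-fails."""


@dataclass
class SkeletonPath:
    """Ordered medial path, tip to tip.

    ``points`` may contain subpixel coordinates after tangent extension.
    ``prune_ratio`` is pruned length / total skeleton length (1 for a
    branchless skeleton).
    """

    points: np.ndarray  # (n, 2) float (row, col)
    length_px: float
    prune_ratio: float

    def __len__(self):
        return len(self.points)


def thin_mask(mask: np.ndarray) -> np.ndarray:
    """1-px topological thinning (Lee's method) of a single component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot thin an empty mask")
    return morphology.skeletonize(mask, method="lee").astype(bool)


def skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    """Pixel adjacency graph of skeleton pixels.

    Orthogonal neighbors connect with weight 1, diagonal with √2.  A
    diagonal edge is suppressed when either of its two orthogonal bridging
    pixels is itself on the skeleton: otherwise every corner of a thinned
    curve would form a spurious 3-cycle.
    """
    pix = set(map(tuple, np.argwhere(skeleton)))
    g = nx.Graph()
    g.add_nodes_from(pix)
    for (r, c) in pix:
        if (r, c + 1) in pix:
            g.add_edge((r, c), (r, c + 1), weight=1.0)
        if (r + 1, c) in pix:
            g.add_edge((r, c), (r + 1, c), weight=1.0)
        for dc in (-1, 1):
            q = (r + 1, c + dc)
            if q in pix and (r + 1, c) not in pix and (r, c + dc) not in pix:
                g.add_edge((r, c), q, weight=_SQRT2)
    return g


def _farthest(g: nx.Graph, source, candidates):
    dist = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    best, best_d = None, -1.0
    for node in candidates:
        d = dist.get(node, -1.0)
        # tie-break deterministically on (row, col)
        if d > best_d + 1e-12 or (abs(d - best_d) <= 1e-12 and best is not None
                                  and node < best):
            best, best_d = node, d
    return best, best_d


def prune_to_path(skeleton: np.ndarray) -> SkeletonPath:
    """Longest tip-to-tip path through the skeleton tree.

    Uses the double-sweep (farthest-from-farthest) method, exact on trees.
    Raises :class:`SkeletonCycleError` for cyclic skeletons (self-touching
    worms) or skeletons without endpoints.
    """
    g = skeleton_graph(np.asarray(skeleton, dtype=bool))
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton")
    if g.number_of_nodes() == 1:
        node = next(iter(g.nodes))
        return SkeletonPath(points=np.array([node], dtype=float),
                            length_px=0.0, prune_ratio=1.0)
    if not nx.is_connected(g):
        raise ValueError("skeleton pixels are not a single connected component")
    if g.number_of_edges() >= g.number_of_nodes():  # connected => cycle
        raise SkeletonCycleError("skeleton contains a cycle (self-touching worm)")
    endpoints = sorted(n for n in g.nodes if g.degree(n) == 1)
    if not endpoints:
        raise SkeletonCycleError("skeleton has no endpoints")

    u, _ = _farthest(g, endpoints[0], endpoints)
    v, _ = _farthest(g, u, endpoints)
    # deterministic orientation: start at the smaller (row, col) endpoint
    a, b = (u, v) if u <= v else (v, u)
    nodes = nx.shortest_path(g, a, b, weight="weight")
    pts = np.array(nodes, dtype=float)
    plen = path_length(pts)
    total = g.size(weight="weight")
    return SkeletonPath(points=pts, length_px=plen,
                        prune_ratio=plen / total if total > 0 else 1.0)


def smooth_path(path: SkeletonPath, half_window: int = 2) -> SkeletonPath:
    """Moving-average smoothing of the path coordinates.

    An 8-connected pixel path overestimates the arclength of the smooth
    curve it digitizes by several percent (staircase bias); averaging each
    coordinate over a ±``half_window`` neighborhood (window shrinking
    symmetrically at the ends, so the tips stay put) removes most of the
    bias and stabilizes tangent estimates.  ``prune_ratio`` is preserved:
    it describes the pre-smoothing skeleton topology.
    """
    pts = np.asarray(path.points, dtype=float)
    n = len(pts)
    out = pts.copy()
    for i in range(n):
        k = min(half_window, i, n - 1 - i)
        out[i] = pts[i - k:i + k + 1].mean(axis=0)
    return SkeletonPath(points=out, length_px=path_length(out),
                        prune_ratio=path.prune_ratio)


def ratio_filter(path: SkeletonPath, prune_ratio_min: float) -> bool:
    """Pass iff the pruned/original skeleton length ratio is large enough."""
    if not 0 <= prune_ratio_min <= 1:
        raise ValueError("prune_ratio_min must lie in [0, 1]")
    return path.prune_ratio >= prune_ratio_min


def _inside(mask: np.ndarray, point) -> bool:
    r = int(np.floor(point[0] + 0.5))  # half-up, not banker's rounding
    c = int(np.floor(point[1] + 0.5))
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]


def _tip_direction(points: np.ndarray, window: int) -> np.ndarray:
    """Outward unit direction at the end of ``points`` (PCA of the last
    ``window + 1`` points, oriented toward the tip)."""
    tail = points[-(window + 1):]
    centered = tail - tail.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, tail[-1] - tail[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def extend_to_edges(path: SkeletonPath, mask: np.ndarray,
                    extension_window_px: int = 5) -> SkeletonPath:
    """Extend both tips along their tangents to the mask boundary.

    The direction at each tip is fitted to the last ``extension_window_px``
    path steps; the tip marches outward in 0.5-px steps until the first
    sample falls outside the mask, appending the traversed subpixel
    points.  A tip already on the boundary is left untouched.
    """
    pts = np.asarray(path.points, dtype=float)
    if len(pts) < extension_window_px + 1:
        raise ValueError("path too short for tangent extension")
    max_steps = 4 * max(mask.shape)

    def extension(points_oriented):
        tip = points_oriented[-1]
        d = _tip_direction(points_oriented, extension_window_px)
        new = []
        for k in range(1, max_steps):
            p = tip + 0.5 * k * d
            if not _inside(mask, p):
                break
            new.append(p)
        return new

    head_ext = extension(pts[::-1])  # marching out of the head end
    tail_ext = extension(pts)
    parts = [np.array(head_ext[::-1]).reshape(-1, 2), pts,
             np.array(tail_ext).reshape(-1, 2)]
    out = np.vstack([p for p in parts if len(p)])
    return SkeletonPath(points=out, length_px=path_length(out),
                        prune_ratio=path.prune_ratio)


def path_length(points) -> float:
    """Polyline length: Euclidean sum of consecutive steps (chain code for
    pixel steps: 1 orthogonal, √2 diagonal)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())
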