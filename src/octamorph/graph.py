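"""Vessel graph extraction and Horton-Strahler ordering.

The averaged angiogram is binarized with a deterministic multiscale ridge
enhancer (Sato vesselness) followed by hysteresis thresholding, thinned to
1-px centerlines, and converted to a graph whose nodes are junctions and
endpoints and whose edges carry the centerline polyline and a mean calibre
from the distance transform. Each connected component is reduced to a
shortest-path spanning tree rooted near the image border at its widest
vessel and ordered by the Horton-Strahler rule; edges of order 2-4 are
classified as arterioles/venules, everything else as capillary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .containers import BinaryVesselMask, EnFaceImage, SkeletonMask
from .synth import rasterize_polylines

__all__ = [
    "VesselGraph",
    "binarize_vessels",
    "skeletonize_mask",
    "build_graph",
    "consolidate_junctions",
    "prune_spurs",
    "strahler_order",
    "classify_vessels",
    "av_mask_from_graph",
    "graph_to_json",
    "extract_vessel_graph",
]

AV_ORDER_BAND = (2, 4)  # arteriole/venule Strahler orders, inclusive

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class VesselGraph:
    """Vessel network wrapper around an undirected networkx multigraph.

    Node attributes: ``coords`` (row, col), ``kind`` (endpoint | junction |
    border). Edge attributes: ``polyline`` (N,2 array), ``length_px``,
    ``mean_width_px``, and after ordering ``strahler_order`` and
    ``vessel_class``.
    """

    g: nx.MultiGraph
    pixel_size_mm: float
    shape: tuple[int, int]
    meta: dict[str, Any] = field(default_factory=dict)

    def edges(self) -> Iterable[tuple[int, int, int, dict]]:
        return self.g.edges(keys=True, data=True)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def copy(self) -> "VesselGraph":
        return VesselGraph(self.g.copy(), self.pixel_size_mm, self.shape,
                           dict(self.meta))


# --------------------------------------------------------------------------
# Segmentation and thinning
# --------------------------------------------------------------------------

def binarize_vessels(image: EnFaceImage,
                     sigmas: Iterable[float] = (0.8, 1.2, 1.8, 2.6),
                     low_factor: float = 1.0,
                     high_factor: float = 1.3,
                     min_size: int = 10,
                     hole_area: int = 40) -> BinaryVesselMask:
    """Multiscale ridge enhancement + hysteresis threshold + size filter.

    The hysteresis levels are `low_factor` and `high_factor` times the Otsu
    threshold of the vesselness response, which keeps them meaningful
    across images with very different vessel coverage. Deterministic for
    fixed parameters; raises if no vessel pixel survives.
    """
    px = image.pixels.astype(float)
    if px.max() <= px.min():
        raise ValueError("image is constant; no vessels to segment")
    ridge = filters.sato(px, sigmas=list(sigmas), black_ridges=False)
    pos = ridge[ridge > 0]
    if pos.size == 0:
        raise ValueError("ridge filter produced no positive response")
    t = filters.threshold_otsu(ridge)
    low = low_factor * t
    high = max(high_factor * t, low * (1 + 1e-9))
    mask = filters.apply_hysteresis_threshold(ridge, low, high)
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    if hole_area > 0:
        # ridge filters respond weakly at the center of wide bifurcations,
        # punching small holes that turn junctions into spurious loops
        mask = morphology.remove_small_holes(mask, max_size=hole_area)
    if not mask.any():
        raise ValueError("segmentation produced an empty vessel mask")
    return BinaryVesselMask(mask, image.pixel_size_mm)


def skeletonize_mask(mask: BinaryVesselMask) -> SkeletonMask:
    """Topology-preserving thinning to 1-px centerlines."""
    if not mask.pixels.any():
        raise ValueError("empty mask")
    skel = morphology.skeletonize(mask.pixels)
    return SkeletonMask(skel, mask.pixel_size_mm)


# --------------------------------------------------------------------------
# Graph construction
# --------------------------------------------------------------------------

def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def build_graph(skeleton: SkeletonMask,
                mask: BinaryVesselMask | None = None) -> VesselGraph:
    """Junction/endpoint nodes, junction-free centerline runs as edges.

    Contiguous junction pixels collapse into a single node. Pure cycles
    (no node pixel) get one anchor node and a self-loop edge. Edge mean
    width is sampled from twice the Euclidean distance transform of the
    vessel mask along the polyline.
    """
    skel = skeleton.pixels
    h, w = skel.shape
    ncount = _neighbor_count(skel) * skel
    node_px = skel & (ncount != 2)

    # group adjacent node pixels into nodes
    labels, n_labels = ndimage.label(node_px, structure=np.ones((3, 3)))
    g = nx.MultiGraph()
    node_of_pixel: dict[tuple[int, int], int] = {}
    for lab in range(1, n_labels + 1):
        ys, xs = np.nonzero(labels == lab)
        coords = (float(ys.mean()), float(xs.mean()))
        deg = int(ncount[ys, xs].max())
        on_border = bool((ys == 0).any() or (xs == 0).any()
                         or (ys == h - 1).any() or (xs == w - 1).any())
        kind = "border" if on_border else ("junction" if deg >= 3 else "endpoint")
        g.add_node(lab - 1, coords=coords, kind=kind, degree_hint=deg)
        for y, x in zip(ys, xs):
            node_of_pixel[(int(y), int(x))] = lab - 1

    dist = None
    if mask is not None:
        dist = ndimage.distance_transform_edt(mask.pixels)

    def width_along(path: np.ndarray) -> float:
        if dist is None:
            return float("nan")
        ys = np.clip(path[:, 0].astype(int), 0, h - 1)
        xs = np.clip(path[:, 1].astype(int), 0, w - 1)
        return float(2.0 * dist[ys, xs].mean())

    visited_steps: set[tuple[int, int, int, int]] = set()

    def trace(from_px: tuple[int, int], to_px: tuple[int, int]) -> None:
        """Walk from a node pixel into a degree-2 run until the next node."""
        step = (from_px[0], from_px[1], to_px[0], to_px[1])
        if step in visited_steps:
            return
        visited_steps.add(step)
        path = [from_px, to_px]
        prev, cur = from_px, to_px
        while cur not in node_of_pixel:
            nxt = None
            for dy, dx in _NEIGHBORS:
                cand = (cur[0] + dy, cur[1] + dx)
                if cand == prev:
                    continue
                if 0 <= cand[0] < h and 0 <= cand[1] < w and skel[cand]:
                    # do not step between two diagonal pixels that are both
                    # adjacent to prev (avoids doubling corners)
                    nxt = cand
                    break
            if nxt is None:
                break
            visited_steps.add((cur[0], cur[1], nxt[0], nxt[1]))
            path.append(nxt)
            prev, cur = cur, nxt
        if cur in node_of_pixel:
            visited_steps.add((cur[0], cur[1], prev[0], prev[1]))
            poly = np.asarray(path, dtype=float)
            u = node_of_pixel[from_px]
            v = node_of_pixel[cur]
            length = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
            g.add_edge(u, v, polyline=poly, length_px=length,
                       mean_width_px=width_along(poly))

    for (y, x), node in list(node_of_pixel.items()):
        for dy, dx in _NEIGHBORS:
            ny, nx_ = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx_ < w) or not skel[ny, nx_]:
                continue
            if (ny, nx_) in node_of_pixel:
                # direct node-node adjacency within the same cluster: skip
                if node_of_pixel[(ny, nx_)] == node:
                    continue
                step = (y, x, ny, nx_)
                rstep = (ny, nx_, y, x)
                if step in visited_steps or rstep in visited_steps:
                    continue
                visited_steps.add(step)
                visited_steps.add(rstep)
                poly = np.asarray([(y, x), (ny, nx_)], dtype=float)
                g.add_edge(node, node_of_pixel[(ny, nx_)], polyline=poly,
                           length_px=float(np.hypot(dy, dx)),
                           mean_width_px=width_along(poly))
            else:
                trace((y, x), (ny, nx_))

    # pure cycles: every pixel degree 2, no node pixel
    covered = np.zeros_like(skel, dtype=bool)
    for (y, x) in node_of_pixel:
        covered[y, x] = True
    for _, _, data in g.edges(data=True):
        pts = data["polyline"].astype(int)
        covered[pts[:, 0], pts[:, 1]] = True
    remaining = skel & ~covered
    lab_cyc, n_cyc = ndimage.label(remaining, structure=np.ones((3, 3)))
    for lab in range(1, n_cyc + 1):
        ys, xs = np.nonzero(lab_cyc == lab)
        if len(ys) < 3:
            continue
        start = (int(ys[0]), int(xs[0]))
        nid = g.number_of_nodes()
        g.add_node(nid, coords=(float(start[0]), float(start[1])),
                   kind="junction", degree_hint=2)
        # walk the cycle
        path = [start]
        prev: tuple[int, int] | None = None
        cur = start
        while True:
            nxt = None
            for dy, dx in _NEIGHBORS:
                cand = (cur[0] + dy, cur[1] + dx)
                if cand == prev or not (0 <= cand[0] < h and 0 <= cand[1] < w):
                    continue
                if remaining[cand] and (cand not in path[1:]):
                    nxt = cand
                    break
            if nxt is None or nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
        poly = np.asarray(path + [start], dtype=float)
        length = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        g.add_edge(nid, nid, polyline=poly, length_px=length,
                   mean_width_px=width_along(poly))

    return VesselGraph(g, skeleton.pixel_size_mm, skel.shape)


# --------------------------------------------------------------------------
# Pruning and junction consolidation
# --------------------------------------------------------------------------

def consolidate_junctions(graph: VesselGraph, max_len_px: float = 6.0) -> VesselGraph:
    """Contract short junction-junction edges and tiny self-loops.

    Thinning splits a single anatomical bifurcation into a cluster of
    nearby nodes joined by few-pixel edges (with parallel variants); those
    artifacts create spurious cycles that destroy Strahler ordering.
    Contracting them restores one node per bifurcation.
    """
    out = graph.copy()
    g = out.g
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if not g.has_edge(u, v, k):
                continue
            if d["length_px"] >= max_len_px:
                continue
            if u == v:
                g.remove_edge(u, v, k)
                changed = True
                continue
            if g.degree(u) < 3 or g.degree(v) < 3:
                continue
            # contract v into u
            cu = np.asarray(g.nodes[u]["coords"])
            cv = np.asarray(g.nodes[v]["coords"])
            g.nodes[u]["coords"] = tuple((cu + cv) / 2.0)
            if g.nodes[v]["kind"] == "border":
                g.nodes[u]["kind"] = "border"
            elif g.nodes[u]["kind"] == "endpoint":
                g.nodes[u]["kind"] = "junction"
            g.remove_edge(u, v, k)
            for a, b, kk, dd in list(g.edges(v, keys=True, data=True)):
                other = b if a == v else a
                g.remove_edge(a, b, kk)
                if other == v:      # self-loop at v
                    g.add_edge(u, u, **dd)
                else:
                    g.add_edge(u, other, **dd)
            g.remove_node(v)
            changed = True
    return out


def prune_spurs(graph: VesselGraph, min_len_px: float) -> VesselGraph:
    """Iteratively drop endpoint-terminated edges shorter than `min_len_px`,
    then merge through any degree-2 nodes created. Idempotent at fix point."""
    if min_len_px < 0:
        raise ValueError("min_len_px must be >= 0")
    out = graph.copy()
    g = out.g
    if min_len_px == 0:
        return out
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if g.degree(node) == 1:
                (u, v, k) = next(iter(g.edges(node, keys=True)))
                data = g.edges[u, v, k]
                if data["length_px"] < min_len_px:
                    g.remove_edge(u, v, k)
                    g.remove_node(node)
                    changed = True
        _merge_degree2(g)
    return out


def _merge_degree2(g: nx.MultiGraph) -> None:
    """Merge pairs of edges through pass-through (degree-2) junction nodes."""
    merged = True
    while merged:
        merged = False
        for node in list(g.nodes):
            if g.degree(node) != 2:
                continue
            inc = list(g.edges(node, keys=True, data=True))
            if len(inc) != 2:
                continue  # self-loop counts twice
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            a = v1 if u1 == node else u1
            b = v2 if u2 == node else u2
            if a == node or b == node:
                continue
            p1 = d1["polyline"]
            if not np.allclose(p1[-1], g.nodes[node]["coords"], atol=1.5):
                p1 = p1[::-1]
            p2 = d2["polyline"]
            if not np.allclose(p2[0], g.nodes[node]["coords"], atol=1.5):
                p2 = p2[::-1]
            poly = np.vstack([p1, p2[1:]])
            w1, w2 = d1.get("mean_width_px"), d2.get("mean_width_px")
            l1, l2 = d1["length_px"], d2["length_px"]
            width = np.nan
            if w1 == w1 and w2 == w2:  # both non-NaN
                width = (w1 * l1 + w2 * l2) / max(l1 + l2, 1e-9)
            g.remove_edge(u1, v1, k1)
            g.remove_edge(u2, v2, k2)
            g.remove_node(node)
            g.add_edge(a, b, polyline=poly, length_px=l1 + l2,
                       mean_width_px=width)
            merged = True


# --------------------------------------------------------------------------
# Strahler ordering and classification
# --------------------------------------------------------------------------

def strahler_order(graph: VesselGraph,
                   roots: list[int] | str = "auto") -> VesselGraph:
    """Assign Horton-Strahler orders on a spanning tree of each component.

    Cycle chords are dropped for ordering only and assigned order 1. With
    ``roots="auto"`` each component is rooted at the endpoint of its widest
    edge closest to the image border. Leaves are order 1; a parent whose
    children attain max order k gets k+1 if at least two do, else k; an
    edge inherits the order of its distal node.
    """
    out = graph.copy()
    g = out.g
    h, w = out.shape

    def border_distance(node: int) -> float:
        y, x = g.nodes[node]["coords"]
        return min(y, x, h - 1 - y, w - 1 - x)

    root_set: dict[int, int] = {}  # component representative -> root node
    components = list(nx.connected_components(g))
    chosen_roots: list[int] = []
    if roots == "auto":
        for comp in components:
            # a vessel tree is entered where its trunk meets the field of
            # view: prefer the degree-1 tip whose incident edge is widest,
            # ties broken toward the image border
            candidates = []
            for node in comp:
                if g.degree(node) != 1:
                    continue
                (_, _, d) = next(iter(g.edges(node, data=True)))
                width = d.get("mean_width_px", float("nan"))
                candidates.append((width if width == width else -1.0,
                                   -border_distance(node), node))
            if not candidates:   # cycle-only component
                for u, v, k, d in g.edges(comp, keys=True, data=True):
                    width = d.get("mean_width_px", float("nan"))
                    candidates.append((width if width == width else -1.0,
                                       -border_distance(u), u))
            if not candidates:
                chosen_roots.append(next(iter(comp)))
                continue
            candidates.sort()
            chosen_roots.append(candidates[-1][2])
    else:
        chosen_roots = list(roots)
        covered = set()
        for r in chosen_roots:
            for comp in components:
                if r in comp:
                    covered.add(frozenset(comp))
        if len(covered) < len(components):
            missing = [c for c in components if frozenset(c) not in covered]
            raise ValueError(
                f"{len(missing)} component(s) without a root; first has "
                f"nodes {sorted(list(missing[0]))[:5]}")

    for comp in components:
        root = next(r for r in chosen_roots if r in comp)
        sub_edges = list(g.edges(comp, keys=True, data=True))
        # shortest-path spanning tree by centerline length
        dist_map, paths = nx.single_source_dijkstra(
            g.subgraph(comp), root, weight="length_px")
        tree_distal: dict[tuple, int] = {}  # edge key -> child-side node
        parent: dict[int, int] = {}
        for node, path in paths.items():
            for a, b in zip(path[:-1], path[1:]):
                if b in parent:
                    continue
                best_k = min(
                    (k for k in g[a][b]),
                    key=lambda k: g.edges[a, b, k]["length_px"])
                parent[b] = a
                tree_distal[_ekey(a, b, best_k)] = b

        children: dict[int, list[int]] = {n: [] for n in comp}
        for node, par in parent.items():
            children[par].append(node)

        node_order: dict[int, int] = {}

        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                kids = children[node]
                if not kids:
                    node_order[node] = 1
                else:
                    orders = [node_order[c] for c in kids]
                    top = max(orders)
                    node_order[node] = top + 1 if orders.count(top) >= 2 else top
            else:
                stack.append((node, True))
                for c in children[node]:
                    stack.append((c, False))

        for u, v, k, d in sub_edges:
            key = _ekey(u, v, k)
            if key in tree_distal:
                d["strahler_order"] = node_order.get(tree_distal[key], 1)
                d["on_spanning_tree"] = True
            else:
                d["strahler_order"] = 1  # chord of a capillary loop
                d["on_spanning_tree"] = False
    out.meta["root_policy"] = "auto" if roots == "auto" else "explicit"
    out.meta["roots"] = chosen_roots
    return out


def _ekey(u: int, v: int, k: int) -> tuple:
    return (min(u, v), max(u, v), k)


def classify_vessels(graph: VesselGraph,
                     av_mask: BinaryVesselMask | None = None) -> VesselGraph:
    """AV iff Strahler order in the 2-4 band; or, when a user-supplied AV
    mask is given (mirroring interactive delineation), iff the majority of
    the edge centerline lies on that mask."""
    out = graph.copy()
    lo, hi = AV_ORDER_BAND
    for _, _, _, d in out.edges():
        if av_mask is not None:
            pts = d["polyline"].astype(int)
            ys = np.clip(pts[:, 0], 0, av_mask.shape[0] - 1)
            xs = np.clip(pts[:, 1], 0, av_mask.shape[1] - 1)
            is_av = av_mask.pixels[ys, xs].mean() > 0.5
        else:
            order = d.get("strahler_order")
            if order is None:
                raise ValueError("run strahler_order before classify_vessels")
            is_av = lo <= order <= hi
        d["vessel_class"] = "av" if is_av else "capillary"
    out.meta["av_classification"] = ("user_mask" if av_mask is not None
                                     else f"strahler_{lo}_{hi}")
    return out


def av_mask_from_graph(graph: VesselGraph) -> BinaryVesselMask:
    """Stamp AV-classified edges with their widths into a pixel mask."""
    polys, widths = [], []
    for _, _, _, d in graph.edges():
        if d.get("vessel_class") == "av":
            polys.append(d["polyline"])
            width = d.get("mean_width_px", 3.0)
            widths.append(width if width == width else 3.0)
    mask = rasterize_polylines(polys, widths, graph.shape)
    return BinaryVesselMask(mask, graph.pixel_size_mm)


def graph_to_json(graph: VesselGraph) -> dict:
    """JSON-serializable dump: nodes, edges with polylines, metadata."""
    nodes = [{"id": int(n), "coords": list(map(float, d["coords"])),
              "kind": d["kind"]} for n, d in graph.g.nodes(data=True)]
    edges = []
    for u, v, k, d in graph.edges():
        edges.append({
            "nodes": [int(u), int(v)], "key": int(k),
            "polyline": np.asarray(d["polyline"]).tolist(),
            "length_px": float(d.get("length_px", float("nan"))),
            "mean_width_px": float(d.get("mean_width_px", float("nan"))),
            "strahler_order": d.get("strahler_order"),
            "vessel_class": d.get("vessel_class"),
        })
    return {"pixel_size_mm": graph.pixel_size_mm,
            "shape": list(graph.shape), "meta": dict(graph.meta),
            "nodes": nodes, "edges": edges}


def extract_vessel_graph(image: EnFaceImage,
                         min_spur_px: float = 6.0,
                         av_mask: BinaryVesselMask | None = None,
                         **binarize_kwargs: Any,
                         ) -> tuple[VesselGraph, BinaryVesselMask, SkeletonMask]:
    """Convenience chain: binarize -> skeletonize -> graph -> prune ->
    order -> classify."""
    mask = binarize_vessels(image, **binarize_kwargs)
    skel = skeletonize_mask(mask)
    graph = build_graph(skel, mask)
    graph = consolidate_junctions(graph)
    graph = prune_spurs(graph, min_spur_px)
    graph = strahler_order(graph)
    graph = classify_vessels(graph, av_mask=av_mask)
    return graph, mask, skel
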