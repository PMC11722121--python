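"""Synthetic data: vascular phantoms, noisy frame stacks, and cohort tables.

Three generators live here.

* :func:`generate_vessel_phantom` draws a 3 x 3 mm en face angiogram phantom:
  recursively bifurcating arteriole/venule trees, a space-filling capillary
  lattice, and an avascular elliptical FAZ, all with exact ground truth
  (sub-pixel centerlines, widths, Horton-Strahler orders, per-segment
  tortuosity, FAZ geometry).
* :func:`generate_frame_stack` emulates a burst of 8-10 consecutive scans:
  the reference warped by known rigid motions plus speckle and sensor noise.
* :func:`generate_cohort` emulates a 48-eye / 33-patient clinical table with
  group-wise means, SDs and prevalences, a shared patient intercept for
  within-patient correlation, and controlled missingness.

Vessel tortuosity is injected as a sinusoidal displacement normal to each
straight segment, so the generating arc-chord ratio is known to quadrature
accuracy from the stored dense polyline itself.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy import ndimage
from scipy.stats import norm

from .containers import EnFaceImage, FrameStack

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "CohortSpec",
    "VariableDef",
    "DEFAULT_COHORT_VARIABLES",
    "DEFAULT_MISSINGNESS",
    "generate_vessel_phantom",
    "generate_frame_stack",
    "generate_cohort",
    "inject_missingness",
    "rasterize_polylines",
    "make_mixed_logistic_table",
    "make_lmm_table",
    "save_phantom",
    "load_ground_truth",
]


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of a vascular phantom.

    Defaults emulate a 3 x 3 mm full-retinal-slab scan at a density of
    304 x 304 samples with a foveal avascular zone whose area and
    eccentricity sit near the middle of the reported clinical range
    (area ~0.36 mm^2, eccentricity ~0.66).
    """

    grid_size: tuple[int, int] = (304, 304)
    field_mm: float = 3.0
    n_trees: int = 4
    branch_depth: int = 4
    capillary_density_target: float = 0.35
    faz_axes: tuple[float, float] = (0.39, 0.29)  # mm semi-axes (a >= b)
    faz_center: tuple[float, float] | None = None  # px (row, col)
    tortuosity_amp: float = 0.12
    av_tortuosity_amp: float | None = None
    capillary_tortuosity_amp: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_mm <= 0:
            raise ValueError("field_mm must be positive")
        if self.tortuosity_amp < 0:
            raise ValueError("tortuosity_amp must be >= 0")
        if self.n_trees < 0 or self.branch_depth < 1:
            raise ValueError("n_trees >= 0 and branch_depth >= 1 required")
        a_px = self.faz_axes[0] / self.pixel_size_mm
        b_px = self.faz_axes[1] / self.pixel_size_mm
        cy, cx = self.faz_center_px
        h, w = self.grid_size
        if (cy - b_px < 0 or cy + b_px >= h or cx - a_px < 0 or cx + a_px >= w
                or a_px <= 0 or b_px <= 0):
            raise ValueError("FAZ ellipse must lie fully inside the grid")

    @property
    def pixel_size_mm(self) -> float:
        return self.field_mm / self.grid_size[0]

    @property
    def faz_center_px(self) -> tuple[float, float]:
        if self.faz_center is not None:
            return self.faz_center
        return (self.grid_size[0] / 2.0, self.grid_size[1] / 2.0)

    @property
    def faz_axes_px(self) -> tuple[float, float]:
        return (self.faz_axes[0] / self.pixel_size_mm,
                self.faz_axes[1] / self.pixel_size_mm)

    def amp_for_class(self, vessel_class: str) -> float:
        if vessel_class == "av" and self.av_tortuosity_amp is not None:
            return self.av_tortuosity_amp
        if vessel_class == "capillary" and self.capillary_tortuosity_amp is not None:
            return self.capillary_tortuosity_amp
        return self.tortuosity_amp


@dataclass
class PhantomGroundTruth:
    """Exact generating geometry of a phantom."""

    centerlines: list[np.ndarray]          # (N,2) float arrays, (row, col)
    widths_px: list[float]
    strahler_order: list[int | None]       # None for mesh capillaries
    vessel_class: list[str]                # "av" | "capillary"
    segment_kind: list[str]                # "tree" | "mesh" | "ring"
    tortuosity_m1: list[float]
    tree_topology: list[dict[str, Any]]    # per tree-edge: id, tree, parent
    faz_center_px: tuple[float, float]
    faz_axes_px: tuple[float, float]
    faz_area_mm2: float
    faz_eccentricity: float
    faz_perimeter_mm: float
    pixel_size_mm: float
    grid_size: tuple[int, int]
    frame_transforms: list[dict[str, Any]] | None = None

    def vessel_mask(self) -> np.ndarray:
        """Rasterize centerlines with widths; reproduces the phantom mask."""
        return rasterize_polylines(self.centerlines, self.widths_px, self.grid_size)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _sine_segment(p0: np.ndarray, p1: np.ndarray, amp_rel: float,
                  halfwaves: int, phase_sign: float,
                  step_px: float = 0.75) -> np.ndarray:
    """Dense polyline from p0 to p1 with sinusoidal normal displacement.

    The displacement is ``amp_rel * L * sin(halfwaves * pi * s)`` along the
    unit normal, zero at both ends so junctions stay exact.
    """
    chord = p1 - p0
    length = float(np.linalg.norm(chord))
    if length < 1e-9:
        return np.vstack([p0, p1])
    n_pts = max(int(math.ceil(length / step_px)) + 1, 8)
    s = np.linspace(0.0, 1.0, n_pts)
    tangent = chord / length
    normal = np.array([-tangent[1], tangent[0]])
    disp = phase_sign * amp_rel * length * np.sin(halfwaves * math.pi * s)
    pts = p0[None, :] + s[:, None] * chord[None, :] + disp[:, None] * normal[None, :]
    return pts


def _ellipse_value(points: np.ndarray, center: tuple[float, float],
                   axes: tuple[float, float], margin: float) -> np.ndarray:
    """<1 inside the ellipse grown by `margin` px on both semi-axes."""
    cy, cx = center
    a, b = axes  # a along columns, b along rows
    dy = (points[..., 0] - cy) / (b + margin)
    dx = (points[..., 1] - cx) / (a + margin)
    return dy ** 2 + dx ** 2


def _clip_polyline_faz(points: np.ndarray, spec: PhantomSpec,
                       width: float) -> list[np.ndarray]:
    """Split a polyline into pieces lying outside the FAZ exclusion zone."""
    margin = width / 2.0 + 1.5
    inside = _ellipse_value(points, spec.faz_center_px, spec.faz_axes_px, margin) < 1.0
    pieces: list[np.ndarray] = []
    start = None
    for i, flag in enumerate(~inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= 4:
                pieces.append(points[start:i])
            start = None
    if start is not None and len(points) - start >= 4:
        pieces.append(points[start:])
    return pieces


def rasterize_polylines(polylines: Sequence[np.ndarray],
                        widths: Sequence[float],
                        shape: tuple[int, int]) -> np.ndarray:
    """Stamp each polyline with its width: pixel on iff its center lies
    within width/2 of some segment of that polyline (exact Euclidean test)."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for pts, width in zip(polylines, widths):
        r = width / 2.0
        pad = int(math.ceil(r)) + 1
        for k in range(len(pts) - 1):
            p, q = pts[k], pts[k + 1]
            r0 = max(int(math.floor(min(p[0], q[0]))) - pad, 0)
            r1 = min(int(math.ceil(max(p[0], q[0]))) + pad, h - 1)
            c0 = max(int(math.floor(min(p[1], q[1]))) - pad, 0)
            c1 = min(int(math.ceil(max(p[1], q[1]))) + pad, w - 1)
            if r1 < r0 or c1 < c0:
                continue
            yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
            d = _point_segment_distance(yy.astype(float), xx.astype(float), p, q)
            sub = mask[r0:r1 + 1, c0:c1 + 1]
            sub |= d <= r
    return mask


def _point_segment_distance(yy: np.ndarray, xx: np.ndarray,
                            p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Euclidean distance from pixel centers (yy, xx) to segment p-q."""
    v = q - p
    vv = float(v @ v)
    if vv < 1e-18:
        return np.hypot(yy - p[0], xx - p[1])
    t = ((yy - p[0]) * v[0] + (xx - p[1]) * v[1]) / vv
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p[0] + t * v[0]), xx - (p[1] + t * v[1]))


# --------------------------------------------------------------------------
# Tree + capillary mesh construction
# --------------------------------------------------------------------------

def _width_for_order(order: int) -> float:
    # calibre grows with order; order-1 twigs approach capillary calibre
    return 2.0 + 0.95 * order


_CAPILLARY_WIDTH = 2.3


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec,
               start: np.ndarray, angle: float, level: int,
               tree_id: int, edges: list[dict[str, Any]],
               parent_id: int | None, wedge_half: float) -> int | None:
    """Recursively grow one subtree; returns edge id of the created segment.

    `level` counts down; it sets geometric depth only — true Strahler
    orders are computed afterwards from the realized topology. Each node
    owns an angular wedge of half-width `wedge_half` around its direction;
    the two children split it, so sibling branches diverge instead of
    crossing and neighbouring trees stay disjoint in the raster.
    """
    h, w = spec.grid_size
    base_len = 0.07 * min(h, w)
    length = base_len * (0.80 + 0.40 * level) * rng.uniform(0.9, 1.1)
    margin = 4.0
    end = None
    for _ in range(6):
        cand = start + length * np.array([math.sin(angle), math.cos(angle)])
        if (margin <= cand[0] < h - margin
                and margin <= cand[1] < w - margin):
            end = cand
            break
        length *= 0.7
    if end is None:
        return None
    amp = spec.amp_for_class("av")
    # arterioles/venules bend gently: one half-wave per segment keeps the
    # injected curvature resolvable after rasterization and thinning
    pts = _sine_segment(start, end, amp, halfwaves=1,
                        phase_sign=float(rng.choice([-1.0, 1.0])))
    # truncate at the FAZ exclusion zone; a truncated branch stops growing
    width_guess = _width_for_order(level)
    inside = _ellipse_value(pts, spec.faz_center_px, spec.faz_axes_px,
                            width_guess / 2.0 + 1.5) < 1.0
    truncated = bool(inside.any())
    if truncated:
        first = int(np.argmax(inside))
        if first < 30:  # a shorter stub is not a resolvable vessel
            return None
        pts = pts[:first]
        end = pts[-1]
    edge_id = len(edges)
    edges.append({
        "id": edge_id, "tree": tree_id, "parent": parent_id,
        "points": pts, "level": level, "children": [],
    })
    if parent_id is not None:
        edges[parent_id]["children"].append(edge_id)
    if level > 1 and not truncated:
        for sign in (+1.0, -1.0):
            if level < spec.branch_depth and rng.random() < 0.08:
                continue  # occasional lost child -> non-perfect trees
            half_angle = max(wedge_half * rng.uniform(0.45, 0.6),
                             math.radians(rng.uniform(14, 22)))
            child_angle = angle + sign * half_angle
            _grow_tree(rng, spec, np.asarray(end, dtype=float), child_angle,
                       level - 1, tree_id, edges, edge_id,
                       wedge_half=wedge_half / 2.0)
    return edge_id


def _trim_tree_collisions(edges: list[dict[str, Any]],
                          clearance_px: float = 9.0,
                          junction_radius_px: float = 14.0,
                          min_samples: int = 30) -> list[dict[str, Any]]:
    """Keep the drawn vasculature non-self-intersecting in the raster.

    Edges are accepted in creation order (parents before children). A
    branch that comes within `clearance_px` of any previously accepted
    centerline — other than near its own origin junction — is truncated at
    the first offending sample and its descendants are dropped; a branch
    truncated below `min_samples` is removed outright, since a few-pixel
    stub is not a resolvable vessel.
    """
    from scipy.spatial import cKDTree

    kept: dict[int, dict[str, Any]] = {}
    accepted: list[np.ndarray] = []
    by_id = {e["id"]: e for e in edges}
    removed: set[int] = set()

    for e in sorted(edges, key=lambda e: e["id"]):
        if e["id"] in removed:
            continue
        if e["parent"] is not None and e["parent"] not in kept:
            removed.add(e["id"])
            removed.update(_descendants(by_id, e["id"]))
            continue
        pts = e["points"]
        if accepted:
            kd = cKDTree(np.vstack(accepted))
            d, _ = kd.query(pts)
            near_origin = np.linalg.norm(pts - pts[0], axis=1) <= junction_radius_px
            hit = (d < clearance_px) & ~near_origin
            if hit.any():
                first = int(np.argmax(hit))
                removed.update(_descendants(by_id, e["id"]))
                if first < min_samples:
                    removed.add(e["id"])
                    continue
                e = dict(e)
                e["points"] = pts[:first]
                e["children"] = []
        kept[e["id"]] = e
        accepted.append(e["points"])

    out = []
    for e in kept.values():
        e = dict(e)
        e["children"] = [c for c in e.get("children", []) if c in kept]
        if e["parent"] is not None and e["parent"] not in kept:
            continue
        out.append(e)
    return out


def _descendants(by_id: dict[int, dict[str, Any]], eid: int) -> set[int]:
    out: set[int] = set()
    stack = list(by_id[eid]["children"])
    while stack:
        cur = stack.pop()
        out.add(cur)
        stack.extend(by_id[cur]["children"])
    return out


def _strahler_from_topology(edges: list[dict[str, Any]]) -> dict[int, int]:
    """Recursive Horton-Strahler order of each tree edge from its subtree."""
    orders: dict[int, int] = {}
    by_id = {e["id"]: e for e in edges}

    def visit(eid: int) -> int:
        kids = by_id[eid]["children"]
        if not kids:
            orders[eid] = 1
            return 1
        child_orders = [visit(k) for k in kids]
        top = max(child_orders)
        orders[eid] = top + 1 if child_orders.count(top) >= 2 else top
        return orders[eid]

    for e in edges:
        if e["parent"] is None:
            visit(e["id"])
    return orders


def _capillary_mesh(rng: np.random.Generator, spec: PhantomSpec,
                    tree_tips: list[np.ndarray],
                    tree_points: np.ndarray | None = None
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Jittered triangular lattice of short capillary links avoiding the FAZ.

    The mesh keeps clear of the arteriole/venule trees (it connects to them
    only through their terminal tips), so AV centerline runs stay
    junction-free in the rasterized image.
    """
    from scipy.spatial import cKDTree

    tree_kd = cKDTree(tree_points) if tree_points is not None \
        and len(tree_points) else None
    tree_clearance = 6.0
    h, w = spec.grid_size
    # coverage ~ width * length_density; Delaunay length density ~ 3/h_spacing
    # constant tuned so realized pixel coverage tracks the requested target
    # (clearance zones around trees and the FAZ eat into the nominal value)
    spacing = 2.55 * _CAPILLARY_WIDTH / max(spec.capillary_density_target, 1e-3)
    margin = 4.0
    pts = []
    row_h = spacing * math.sqrt(3) / 2
    n_rows = int((h - 2 * margin) / row_h) + 1
    n_cols = int((w - 2 * margin) / spacing) + 2
    for i in range(n_rows):
        for j in range(n_cols):
            y = margin + i * row_h + rng.uniform(-0.28, 0.28) * row_h
            x = margin + (j + (0.5 if i % 2 else 0.0)) * spacing \
                + rng.uniform(-0.28, 0.28) * spacing
            if not (margin <= y < h - margin and margin <= x < w - margin):
                continue
            if _ellipse_value(np.array([[y, x]]), spec.faz_center_px,
                              spec.faz_axes_px, _CAPILLARY_WIDTH / 2 + 2.0)[0] < 1.0:
                continue
            if tree_kd is not None and tree_kd.query([y, x])[0] < tree_clearance:
                continue
            pts.append((y, x))
    nodes = np.array(pts)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    if len(nodes) >= 4:
        tri = Delaunay(nodes)
        seen = set()
        for simplex in tri.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                key = tuple(sorted((int(simplex[a]), int(simplex[b]))))
                if key in seen:
                    continue
                seen.add(key)
                pa, pb = nodes[key[0]], nodes[key[1]]
                if np.linalg.norm(pa - pb) <= 1.7 * spacing:
                    segments.append((pa, pb))
    # connect tree tips into the mesh
    connector_start = len(segments)
    if len(nodes) and tree_tips:
        for tip in tree_tips:
            d = np.linalg.norm(nodes - tip[None, :], axis=1)
            j = int(np.argmin(d))
            if d[j] < 2.5 * spacing:
                segments.append((tip, nodes[j]))
    amp = spec.amp_for_class("capillary")
    polylines = []
    for si, (pa, pb) in enumerate(segments):
        pts_ = _sine_segment(pa, pb, amp, halfwaves=int(rng.integers(1, 3)),
                             phase_sign=float(rng.choice([-1.0, 1.0])))
        is_connector = si >= connector_start
        for piece in _clip_polyline_faz(pts_, spec, _CAPILLARY_WIDTH):
            if tree_kd is not None and not is_connector:
                d, _ = tree_kd.query(piece)
                if (d < tree_clearance).any():
                    # keep sub-pieces clear of the trees
                    keep = d >= tree_clearance
                    start = None
                    for i, flag in enumerate(keep):
                        if flag and start is None:
                            start = i
                        elif not flag and start is not None:
                            if i - start >= 4:
                                polylines.append(piece[start:i])
                            start = None
                    if start is not None and len(piece) - start >= 4:
                        polylines.append(piece[start:])
                    continue
            polylines.append(piece)
    return polylines, nodes


def _terminal_ring(rng: np.random.Generator, spec: PhantomSpec,
                   mesh_nodes: np.ndarray | None) -> list[np.ndarray]:
    """Closed capillary ring bounding the FAZ, with radial connectors.

    The ring centerline sits half a capillary width outside the FAZ
    ellipse so the stamped ring's inner edge coincides with the ellipse —
    the avascular area then equals the generating pi*a*b.
    """
    cy, cx = spec.faz_center_px
    a, b = spec.faz_axes_px
    off = _CAPILLARY_WIDTH / 2.0

    def ring_point(ang: float) -> np.ndarray:
        return np.array([cy + (b + off) * math.sin(ang),
                         cx + (a + off) * math.cos(ang)])

    # attachment angles of the radial connectors; the ring is stored as the
    # arc pieces between them (that is also how a skeleton graph sees it)
    attach = []
    connectors = []
    if mesh_nodes is not None and len(mesh_nodes):
        for ang in np.arange(0.0, 2 * math.pi, math.radians(30.0)):
            ang = ang + rng.uniform(-0.15, 0.15)
            p = ring_point(ang)
            d = np.linalg.norm(mesh_nodes - p[None, :], axis=1)
            j = int(np.argmin(d))
            if 1.0 < d[j] < 30.0:
                attach.append(ang % (2 * math.pi))
                connectors.append(np.vstack([p, mesh_nodes[j]]))
    polylines = list(connectors)
    step = 1.2 / max(a, b)  # ~1.2 px sampling along the arc
    if len(attach) >= 2:
        attach = sorted(attach)
        for a0, a1 in zip(attach, attach[1:] + [attach[0] + 2 * math.pi]):
            n = max(int((a1 - a0) / step), 4)
            ts = np.linspace(a0, a1, n + 1)
            polylines.append(np.vstack([ring_point(t) for t in ts]))
    else:
        ts = np.arange(0.0, 2 * math.pi + step, step)
        polylines.append(np.vstack([ring_point(t) for t in ts]))
    return polylines


def _faz_truth(spec: PhantomSpec) -> tuple[float, float, float]:
    a_mm, b_mm = max(spec.faz_axes), min(spec.faz_axes)
    area = math.pi * a_mm * b_mm
    ecc = math.sqrt(1.0 - (b_mm / a_mm) ** 2)
    # Ramanujan's second approximation for the ellipse perimeter
    h = ((a_mm - b_mm) / (a_mm + b_mm)) ** 2
    perim = math.pi * (a_mm + b_mm) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    return area, ecc, perim


def generate_vessel_phantom(spec: PhantomSpec) -> tuple[EnFaceImage, PhantomGroundTruth]:
    """Build a noise-free reference angiogram and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.grid_size

    tree_edges: list[dict[str, Any]] = []
    cy, cx = spec.faz_center_px
    for t in range(spec.n_trees):
        theta = 2 * math.pi * (t + rng.uniform(0.1, 0.35)) / max(spec.n_trees, 1)
        start = np.array([
            cy + 0.52 * h * math.sin(theta),
            cx + 0.52 * w * math.cos(theta),
        ])
        start[0] = float(np.clip(start[0], 2, h - 3))
        start[1] = float(np.clip(start[1], 2, w - 3))
        inward = math.atan2(cy - start[0], cx - start[1]) + rng.normal(0, 0.08)
        sector_half = 0.8 * math.pi / max(spec.n_trees, 1)
        _grow_tree(rng, spec, start, inward, spec.branch_depth, t, tree_edges,
                   None, wedge_half=sector_half)

    tree_edges = _trim_tree_collisions(tree_edges)
    orders = _strahler_from_topology(tree_edges)

    centerlines: list[np.ndarray] = []
    widths: list[float] = []
    strahler: list[int | None] = []
    vclass: list[str] = []
    kinds: list[str] = []
    topology: list[dict[str, Any]] = []
    tips: list[np.ndarray] = []
    for e in tree_edges:
        order = orders[e["id"]]
        centerlines.append(np.asarray(e["points"], dtype=float))
        widths.append(_width_for_order(order))
        strahler.append(order)
        kinds.append("tree")
        vclass.append("av" if 2 <= order <= 4 else "capillary")
        topology.append({"id": e["id"], "tree": e["tree"], "parent": e["parent"],
                         "order": order})
        if not e["children"]:
            tips.append(np.asarray(e["points"][-1], dtype=float))

    if spec.capillary_density_target > 0:
        tree_pts = np.vstack(centerlines) if centerlines else None
        mesh_polys, mesh_nodes = _capillary_mesh(rng, spec, tips, tree_pts)
        ring_polys = _terminal_ring(rng, spec, mesh_nodes)
        for pts, kind in ([(p, "mesh") for p in mesh_polys]
                          + [(p, "ring") for p in ring_polys]):
            centerlines.append(pts)
            widths.append(_CAPILLARY_WIDTH)
            strahler.append(None)
            vclass.append("capillary")
            kinds.append(kind)

    tort = []
    for pts in centerlines:
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        tort.append(_polyline_length(pts) / chord if chord > 1e-9 else float("nan"))

    mask = rasterize_polylines(centerlines, widths, spec.grid_size)
    img = 0.10 + 0.80 * ndimage.gaussian_filter(mask.astype(float), 0.5)
    image = EnFaceImage(pixels=img, pixel_size_mm=spec.pixel_size_mm,
                        device_meta={"signal_strength_index": 70.0,
                                     "quality_score": 9.0,
                                     "synthetic": True},
                        provenance="raw")
    area, ecc, perim = _faz_truth(spec)
    truth = PhantomGroundTruth(
        centerlines=centerlines, widths_px=widths, strahler_order=strahler,
        vessel_class=vclass, segment_kind=kinds, tortuosity_m1=tort,
        tree_topology=topology,
        faz_center_px=spec.faz_center_px, faz_axes_px=spec.faz_axes_px,
        faz_area_mm2=area, faz_eccentricity=ecc, faz_perimeter_mm=perim,
        pixel_size_mm=spec.pixel_size_mm, grid_size=spec.grid_size,
    )
    return image, truth


# --------------------------------------------------------------------------
# Frame stacks
# --------------------------------------------------------------------------

def generate_frame_stack(reference: EnFaceImage, n_frames: int,
                         motion_sd: float, noise_sd: float, seed: int,
                         speckle_sd: float = 0.0,
                         rotation_sd_deg: float = 0.0) -> FrameStack:
    """Warp + degrade the reference into a burst of frames with known motion.

    Each frame is the reference shifted by a Normal(0, motion_sd) translation
    (optionally rotated), multiplied by unit-mean gamma speckle and summed
    with additive Gaussian noise. True transforms are recorded.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames: list[EnFaceImage] = []
    transforms: list[dict[str, Any]] = []
    for i in range(n_frames):
        shift = rng.normal(0.0, motion_sd, size=2) if motion_sd > 0 else np.zeros(2)
        rot = rng.normal(0.0, rotation_sd_deg) if rotation_sd_deg > 0 else 0.0
        px = reference.pixels
        if rot != 0.0:
            px = ndimage.rotate(px, rot, reshape=False, order=1, mode="nearest")
        if shift.any():
            px = ndimage.shift(px, shift, order=1, mode="nearest")
        else:
            px = px.copy()
        if speckle_sd > 0:
            shape = 1.0 / speckle_sd ** 2
            px = px * rng.gamma(shape, 1.0 / shape, size=px.shape)
        if noise_sd > 0:
            px = px + rng.normal(0.0, noise_sd, size=px.shape)
        px = np.clip(px, 0.0, None)
        meta = dict(reference.device_meta)
        meta.update({"signal_strength_index": float(60 + rng.uniform(0, 20)),
                     "quality_score": float(8.5 + rng.uniform(0, 1.5))})
        frames.append(EnFaceImage(px, reference.pixel_size_mm, meta, "raw"))
        transforms.append({"translation": [float(shift[0]), float(shift[1])],
                           "rotation_deg": float(rot)})
    return FrameStack(frames=frames, reference_index=0, true_transforms=transforms)


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

@dataclass
class VariableDef:
    """Definition of one cohort variable.

    For numeric variables `params` is ((mean_present, sd_present),
    (mean_absent, sd_absent)); for binary, (prevalence_present,
    prevalence_absent); for ordinal, (probs_present, probs_absent) with
    `levels` naming the categories.
    """

    name: str
    kind: str  # numeric | binary | ordinal
    params: tuple
    levels: tuple[str, ...] | None = None


# Group-wise summaries of the 48-eye DME cohort (PNP present n=22 first,
# absent n=26 second). Prevalences use the printed counts over group size.
DEFAULT_COHORT_VARIABLES: list[VariableDef] = [
    VariableDef("age", "numeric", ((52, 15), (59, 12))),
    VariableDef("visual_acuity", "numeric", ((69.1, 16.1), (76.5, 11.3))),
    VariableDef("duration_dm", "numeric", ((22, 7.5), (18.8, 9.4))),
    VariableDef("hba1c", "numeric", ((9.3, 2.2), (8.2, 2.0))),
    VariableDef("egfr", "numeric", ((78.5, 21.2), (67.7, 22.9))),
    VariableDef("creatinine", "numeric", ((83.2, 42.3), (117.3, 110.5))),
    VariableDef("ldl", "numeric", ((2.8, 0.8), (2.6, 1.2))),
    VariableDef("hdl", "numeric", ((1.3, 0.4), (1.2, 0.4))),
    VariableDef("axial_length", "numeric", ((23.4, 1.02), (23.7, 0.94))),
    VariableDef("crt_1mm", "numeric", ((403.1, 129.8), (375.4, 120.4))),
    VariableDef("crt_3mm", "numeric", ((383.5, 144.0), (388.2, 88.7))),
    VariableDef("crt_6mm", "numeric", ((358.2, 230.0), (366.4, 126.0))),
    VariableDef("tortuosity_m1_arterioles", "numeric", ((1.66, 0.11), (1.67, 0.06))),
    VariableDef("tortuosity_m1_venules", "numeric", ((1.66, 0.11), (1.67, 0.06))),
    VariableDef("tortuosity_m1_capillaries", "numeric", ((1.67, 0.07), (1.68, 0.05))),
    VariableDef("tortuosity_m2_arterioles", "numeric", ((1.06, 0.12), (1.06, 0.11))),
    VariableDef("tortuosity_m2_venules", "numeric", ((1.05, 0.14), (1.06, 0.12))),
    VariableDef("tortuosity_m2_capillaries", "numeric", ((1.04, 0.15), (1.025, 0.07))),
    VariableDef("perfusion_density", "numeric", ((0.41, 0.05), (0.45, 0.06))),
    VariableDef("vessel_density", "numeric", ((0.097, 0.014), (0.106, 0.014))),
    VariableDef("vessel_diameter_mm", "numeric", ((0.024, 0.002), (0.023, 0.002))),
    VariableDef("fractal_dimension", "numeric", ((1.88, 0.01), (1.89, 0.01))),
    VariableDef("faz_min_distance_mm", "numeric", ((0.49, 0.14), (0.45, 0.13))),
    VariableDef("faz_max_distance_mm", "numeric", ((0.82, 0.21), (0.81, 0.22))),
    VariableDef("faz_area_mm2", "numeric", ((0.36, 0.15), (0.35, 0.16))),
    VariableDef("faz_eccentricity", "numeric", ((0.65, 0.14), (0.67, 0.12))),
    VariableDef("faz_axis_ratio", "numeric", ((1.73, 0.32), (1.86, 0.42))),
    VariableDef("faz_perimeter_mm", "numeric", ((3.37, 1.17), (3.43, 1.39))),
    VariableDef("faz_acircularity", "numeric", ((1.61, 0.29), (1.67, 0.45))),
    VariableDef("sex_male", "binary", (12 / 22, 20 / 26)),
    VariableDef("dm_type2", "binary", (14 / 22, 22 / 26)),
    VariableDef("insulin", "binary", (18 / 22, 14 / 26)),
    VariableDef("smoking", "binary", (6 / 22, 6 / 26)),
    VariableDef("lipid_lowering", "binary", (9 / 22, 18 / 26)),
    VariableDef("hypertension", "binary", (15 / 22, 20 / 26)),
    VariableDef("ischemic_heart_disease", "binary", (2 / 22, 7 / 26)),
    VariableDef("stroke", "binary", (0 / 22, 3 / 26)),
    VariableDef("prp", "binary", (20 / 22, 10 / 26)),
    VariableDef("pseudophakic", "binary", (5 / 22, 7 / 26)),
    VariableDef("past_anti_vegf", "binary", (10 / 22, 9 / 26)),
    VariableDef("past_steroids", "binary", (1 / 22, 1 / 26)),
    VariableDef("previous_vitrectomy", "binary", (1 / 22, 0 / 26)),
    VariableDef("hard_exudates", "binary", (11 / 22, 14 / 26)),
    VariableDef("subretinal_fluid", "binary", (10 / 22, 2 / 26)),
    VariableDef("cystoid_inl", "binary", (14 / 22, 19 / 26)),
    VariableDef("cystoid_onl", "binary", (19 / 22, 26 / 26)),
    VariableDef("intact_ellipsoid_zone", "binary", (19 / 22, 26 / 26)),
    VariableDef("dril", "binary", (5 / 22, 9 / 26)),
    VariableDef("intact_capillary_ring", "binary", (4 / 22, 10 / 26)),
    VariableDef("perifoveal_capillary_loss", "binary", (19 / 22, 25 / 26)),
    VariableDef("microaneurysms", "ordinal",
                ((0.0, 12 / 22, 10 / 22), (0.0, 5 / 28, 23 / 28)),
                levels=("none", "lt10", "ge10")),
    VariableDef("leakage_pattern", "ordinal",
                ((3 / 22, 4 / 22, 15 / 22), (12 / 28, 7 / 28, 9 / 28)),
                levels=("focal", "intermediate", "diffuse")),
    VariableDef("hrf_count", "ordinal",
                ((6 / 22, 6 / 22, 4 / 22, 6 / 22),
                 (3 / 26, 11 / 26, 5 / 26, 7 / 26)),
                levels=("0", "lt10", "10to20", "gt20")),
]

DEFAULT_MISSINGNESS: dict[str, int] = {
    "hba1c": 1,
    "duration_dm": 2,
    "ldl": 2,
    "hdl": 2,
    "past_anti_vegf": 2,
    "past_steroids": 2,
}


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic per-eye cohort table.

    `patient_random_sd` is the between-patient share of each variable's
    marginal SD (the latent value is rho*z_patient + sqrt(1-rho^2)*z_eye, so
    printed SDs are preserved and the intraclass correlation is rho^2).
    """

    n_patients: int = 33
    n_bilateral: int = 15
    group_sizes: tuple[int, int] = (22, 26)  # (PNP present, absent)
    variable_defs: list[VariableDef] = field(
        default_factory=lambda: list(DEFAULT_COHORT_VARIABLES))
    patient_random_sd: float = 0.6
    missingness: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bilateral > self.n_patients:
            raise ValueError("n_bilateral cannot exceed n_patients")
        if sum(self.group_sizes) != self.total_eyes:
            raise ValueError("group sizes must sum to the total eye count")
        if not 0 <= self.patient_random_sd < 1:
            raise ValueError("patient_random_sd must be in [0, 1)")

    @property
    def total_eyes(self) -> int:
        return self.n_patients + self.n_bilateral


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per eye with group-conditional values and patient correlation."""
    rng = np.random.default_rng(spec.seed)
    rho = spec.patient_random_sd
    eye_rows: list[tuple[str, str]] = []
    bilateral = rng.choice(spec.n_patients, size=spec.n_bilateral, replace=False)
    bilateral_set = set(int(b) for b in bilateral)
    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        eye_rows.append((pid, "OD"))
        if p in bilateral_set:
            eye_rows.append((pid, "OS"))
    n = len(eye_rows)
    assert n == spec.total_eyes

    # group-size-exact PNP assignment
    present_idx = rng.choice(n, size=spec.group_sizes[0], replace=False)
    pnp = np.zeros(n, dtype=bool)
    pnp[present_idx] = True

    patients = sorted({pid for pid, _ in eye_rows})
    pat_index = {pid: i for i, pid in enumerate(patients)}

    data: dict[str, Any] = {
        "Patient-ID": [pid for pid, _ in eye_rows],
        "Eye": [eye for _, eye in eye_rows],
        "PNP_present": np.where(pnp, "Y", "N"),
    }
    lam = math.sqrt(max(0.0, 1.0 - rho ** 2))
    for var in spec.variable_defs:
        z_pat = rng.normal(size=len(patients))
        z_eye = rng.normal(size=n)
        latent = np.array([rho * z_pat[pat_index[pid]] for pid, _ in eye_rows]) \
            + lam * z_eye
        if var.kind == "numeric":
            (m1, s1), (m0, s0) = var.params
            mean = np.where(pnp, m1, m0)
            sd = np.where(pnp, s1, s0)
            data[var.name] = mean + sd * latent
        elif var.kind == "binary":
            p1, p0 = var.params
            thresh = norm.ppf(np.clip(np.where(pnp, p1, p0), 1e-12, 1 - 1e-12))
            data[var.name] = (latent < thresh).astype(int)
        elif var.kind == "ordinal":
            probs1, probs0 = var.params
            out = []
            for i in range(n):
                probs = np.asarray(probs1 if pnp[i] else probs0, dtype=float)
                probs = probs / probs.sum()
                cum = np.cumsum(probs)
                u = norm.cdf(latent[i])
                k = int(np.searchsorted(cum, u, side="right"))
                k = min(k, len(probs) - 1)
                out.append(var.levels[k] if var.levels else str(k))
            data[var.name] = out
        else:  # pragma: no cover - spec validation
            raise ValueError(f"unknown variable kind {var.kind!r}")

    table = pd.DataFrame(data)
    if spec.missingness:
        table = inject_missingness(table, spec.missingness,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
    return table


def inject_missingness(table: pd.DataFrame, plan: dict[str, int],
                       seed: int) -> pd.DataFrame:
    """Delete the requested number of cells per variable completely at random."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for var, count in plan.items():
        if var not in out.columns:
            raise KeyError(f"unknown variable {var!r}")
        if count > len(out):
            raise ValueError(f"cannot delete {count} cells from {len(out)} rows")
        if count <= 0:
            continue
        rows = rng.choice(len(out), size=count, replace=False)
        col = out.columns.get_loc(var)
        if pd.api.types.is_numeric_dtype(out[var]):
            out[var] = out[var].astype(float)
        out.iloc[rows, col] = np.nan
    return out


# --------------------------------------------------------------------------
# Simulation helpers for the statistics chain
# --------------------------------------------------------------------------

def make_mixed_logistic_table(n_patients: int, coefs: dict[str, float],
                              seed: int, eyes_per_patient: int = 2,
                              intercept: float = 0.0, random_sd: float = 1.0,
                              n_noise: int = 0,
                              response: str = "PNP_present") -> pd.DataFrame:
    """Eyes nested in patients with a logistic outcome and known effects."""
    rng = np.random.default_rng(seed)
    n = n_patients * eyes_per_patient
    pid = np.repeat([f"P{i:04d}" for i in range(n_patients)], eyes_per_patient)
    u = np.repeat(rng.normal(0.0, random_sd, n_patients), eyes_per_patient)
    eta = np.full(n, float(intercept)) + u
    cols: dict[str, Any] = {"Patient-ID": pid}
    for name, beta in coefs.items():
        x = rng.normal(size=n)
        cols[name] = x
        eta = eta + beta * x
    for j in range(n_noise):
        cols[f"noise_{j + 1}"] = rng.normal(size=n)
    p = 1.0 / (1.0 + np.exp(-eta))
    cols[response] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


def make_lmm_table(n_patients: int, seed: int, eyes_per_patient: int = 2,
                   fixed_effect: float = 1.0, random_sd: float = 1.0,
                   resid_sd: float = 1.0, response: str = "y") -> pd.DataFrame:
    """Gaussian response with a patient random intercept and a group effect."""
    rng = np.random.default_rng(seed)
    n = n_patients * eyes_per_patient
    pid = np.repeat([f"P{i:04d}" for i in range(n_patients)], eyes_per_patient)
    group = np.repeat((np.arange(n_patients) % 2), eyes_per_patient)
    u = np.repeat(rng.normal(0.0, random_sd, n_patients), eyes_per_patient)
    y = fixed_effect * group + u + rng.normal(0.0, resid_sd, n)
    return pd.DataFrame({"Patient-ID": pid,
                         "PNP_present": np.where(group == 1, "Y", "N"),
                         response: y})


# --------------------------------------------------------------------------
# Persistence (16-bit TIFF phantom + JSON ground truth, CSV cohorts)
# --------------------------------------------------------------------------

def save_phantom(image: EnFaceImage, truth: PhantomGroundTruth,
                 tiff_path: str, truth_path: str) -> None:
    import tifffile

    scaled = np.clip(image.pixels, 0.0, None)
    top = scaled.max() if scaled.max() > 0 else 1.0
    tifffile.imwrite(tiff_path, (scaled / top * 65535).astype(np.uint16),
                     resolution=(1.0 / image.pixel_size_mm,
                                 1.0 / image.pixel_size_mm))
    payload = {
        "pixel_size_mm": truth.pixel_size_mm,
        "grid_size": list(truth.grid_size),
        "faz": {"center_px": list(truth.faz_center_px),
                "axes_px": list(truth.faz_axes_px),
                "area_mm2": truth.faz_area_mm2,
                "eccentricity": truth.faz_eccentricity,
                "perimeter_mm": truth.faz_perimeter_mm},
        "polylines": [
            {"points": cl.tolist(), "width_px": wd,
             "strahler_order": so, "vessel_class": vc,
             "segment_kind": sk, "tortuosity_m1": tm}
            for cl, wd, so, vc, sk, tm in zip(
                truth.centerlines, truth.widths_px, truth.strahler_order,
                truth.vessel_class, truth.segment_kind, truth.tortuosity_m1)
        ],
        "tree_topology": truth.tree_topology,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh)


def load_ground_truth(truth_path: str) -> PhantomGroundTruth:
    with open(truth_path) as fh:
        payload = json.load(fh)
    polys = payload["polylines"]
    return PhantomGroundTruth(
        centerlines=[np.asarray(p["points"], dtype=float) for p in polys],
        widths_px=[p["width_px"] for p in polys],
        strahler_order=[p["strahler_order"] for p in polys],
        vessel_class=[p["vessel_class"] for p in polys],
        segment_kind=[p.get("segment_kind", "mesh") for p in polys],
        tortuosity_m1=[p["tortuosity_m1"] for p in polys],
        tree_topology=payload["tree_topology"],
        faz_center_px=tuple(payload["faz"]["center_px"]),
        faz_axes_px=tuple(payload["faz"]["axes_px"]),
        faz_area_mm2=payload["faz"]["area_mm2"],
        faz_eccentricity=payload["faz"]["eccentricity"],
        faz_perimeter_mm=payload["faz"]["perimeter_mm"],
        pixel_size_mm=payload["pixel_size_mm"],
        grid_size=tuple(payload["grid_size"]),
    )
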