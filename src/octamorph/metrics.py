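"""Quantitative vascular metrics of an averaged en face angiogram.

Perfusion density (PD) is the vessel-pixel fraction of the field and vessel
density (VD) its skeleton analogue, both computed after excluding the
arteriole/venule (AV) pixels so they describe the capillary bed. Mean
vessel calibre comes from the distance transform sampled on the skeleton,
the fractal dimension from dyadic box counting, and two tortuosity indices
are provided: the arc-chord ratio, and a composite index combining the
spread of the tangent-angle sequence, the number of inflection points, the
relative amplitude of the oscillations between them, and the arc-chord
ratio (0 for a straight centerline, increasing with both oscillation
amplitude and frequency).

Both the diameter and fractal-dimension estimators are reconstructions —
the clinical protocol names the quantities but not the estimators — and
results carry decision flags saying so (see ``DECISION_FLAGS``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import BinaryVesselMask, SkeletonMask
from .graph import VesselGraph

__all__ = [
    "VascularMetrics",
    "DECISION_FLAGS",
    "perfusion_density",
    "vessel_density",
    "mean_vessel_diameter",
    "fractal_dimension",
    "tortuosity_m1",
    "tortuosity_m2",
    "aggregate_tortuosity",
    "compute_vascular_metrics",
]

# machine-readable markers for quantities whose estimator had to be chosen
DECISION_FLAGS = {
    "mean_diameter_mm": "distance-transform estimator (protocol silent)",
    "fractal_dimension": "dyadic box counting 2-64 px (protocol silent)",
    "tortuosity_m2": "composite angle/inflection index, 0.1 normalization",
    "pd_exclusion": "AV pixels removed from numerator and denominator",
}


@dataclass
class VascularMetrics:
    perfusion_density: float
    vessel_density: float
    mean_diameter_mm: float
    fractal_dimension: float
    tortuosity_m1: dict[str, float]
    tortuosity_m2: dict[str, float]

    def as_row(self) -> dict[str, float]:
        row = {
            "perfusion_density": self.perfusion_density,
            "vessel_density": self.vessel_density,
            "vessel_diameter_mm": self.mean_diameter_mm,
            "fractal_dimension": self.fractal_dimension,
        }
        for cls, val in self.tortuosity_m1.items():
            row[f"tortuosity_m1_{cls}"] = val
        for cls, val in self.tortuosity_m2.items():
            row[f"tortuosity_m2_{cls}"] = val
        return row


def _density(numerator_mask: np.ndarray, av_pixels: np.ndarray | None,
             exclusion: str) -> float:
    total = numerator_mask.size
    if av_pixels is None:
        av_pixels = np.zeros_like(numerator_mask, dtype=bool)
    n_av = int(av_pixels.sum())
    if n_av == total:
        raise ValueError("AV mask covers the entire image")
    num = int((numerator_mask & ~av_pixels).sum())
    if exclusion == "both":
        return num / (total - n_av)
    if exclusion == "numerator":
        return num / total
    raise ValueError("exclusion must be 'both' or 'numerator'")


def perfusion_density(mask: BinaryVesselMask,
                      av_mask: BinaryVesselMask | None = None,
                      exclusion: str = "both") -> float:
    """Vessel-pixel fraction excluding arterioles/venules.

    With ``exclusion='both'`` (default) AV pixels leave both the numerator
    and the denominator, i.e. PD is the capillary coverage of the non-AV
    field; ``'numerator'`` keeps the full field as denominator.
    """
    av = None if av_mask is None else av_mask.pixels
    if av is not None and av.shape != mask.shape:
        raise ValueError("mask shapes differ")
    return _density(mask.pixels, av, exclusion)


def vessel_density(skeleton: SkeletonMask,
                   av_mask: BinaryVesselMask | None = None,
                   exclusion: str = "both") -> float:
    """Skeleton-pixel fraction excluding arterioles/venules (width-free)."""
    av = None if av_mask is None else av_mask.pixels
    if av is not None and av.shape != skeleton.shape:
        raise ValueError("mask shapes differ")
    return _density(skeleton.pixels, av, exclusion)


def mean_vessel_diameter(mask: BinaryVesselMask,
                         skeleton: SkeletonMask) -> float:
    """Mean local calibre over skeleton pixels, in mm.

    The Euclidean distance transform measures pixel centers, so the local
    diameter is 2*EDT - 1 px (never below 1 px for a 1-px line).
    """
    if not skeleton.pixels.any():
        raise ValueError("empty skeleton")
    if mask.shape != skeleton.shape:
        raise ValueError("mask shapes differ")
    dist = ndimage.distance_transform_edt(mask.pixels)
    diam_px = np.maximum(2.0 * dist[skeleton.pixels] - 1.0, 1.0)
    return float(diam_px.mean() * mask.pixel_size_mm)


def fractal_dimension(skeleton: SkeletonMask,
                      box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)) -> float:
    """Box-counting dimension of the skeleton over dyadic box sizes."""
    px = skeleton.pixels
    if not px.any():
        raise ValueError("empty skeleton")
    counts = []
    sizes = []
    h, w = px.shape
    for s in box_sizes:
        if s >= min(h, w):
            continue
        hh = -(-h // s) * s
        ww = -(-w // s) * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = px
        blocks = padded.reshape(hh // s, s, ww // s, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
        sizes.append(s)
    if len(sizes) < 3:
        raise ValueError("fewer than 3 usable box scales")
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                          np.log(np.asarray(counts, dtype=float)), 1)
    return float(slope)


# --------------------------------------------------------------------------
# Tortuosity
# --------------------------------------------------------------------------

def _as_polyline(polyline: np.ndarray) -> np.ndarray:
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    return pts


def tortuosity_m1(polyline: np.ndarray) -> float:
    """Arc length over chord length; >= 1, equal to 1 for straight lines."""
    pts = _as_polyline(polyline)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-9:
        raise ValueError("closed loop: coincident endpoints have no chord")
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return arc / chord


def _resample(pts: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Uniform arc-length resampling (linear interpolation)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < spacing * 2:
        return pts
    n = max(int(total / spacing) + 1, 5)
    grid = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(grid, s, pts[:, 0]),
                            np.interp(grid, s, pts[:, 1])])


def tortuosity_m2(polyline: np.ndarray, smooth_sigma: float = 2.0) -> float:
    """Composite tortuosity index of a vessel centerline.

    With theta the tangent-angle sequence of the arc-length resampled
    centerline, N the number of curvature sign changes (critical points),
    M the mean amplitude of the oscillation between consecutive critical
    points relative to the local chord, and L_a/L_c the arc-chord ratio:

        VTI = 0.1 * sd(theta) * N * M * (L_a / L_c)

    A straight centerline scores 0; the index grows with both the
    amplitude and the frequency of the oscillations.
    """
    pts = _as_polyline(polyline)
    if len(pts) < 5:
        raise ValueError("tortuosity_m2 needs at least 5 points")
    pts = _resample(pts)
    d = np.diff(pts, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
    if smooth_sigma > 0:
        theta_s = ndimage.gaussian_filter1d(theta, smooth_sigma, mode="nearest")
    else:
        theta_s = theta
    sd_theta = float(np.std(theta_s))
    dtheta = np.diff(theta_s)
    signs = np.sign(dtheta)
    signs = signs[np.abs(dtheta) > 1e-9]
    crit = int(np.sum(signs[1:] * signs[:-1] < 0)) if len(signs) > 1 else 0
    if crit == 0 or sd_theta < 1e-12:
        return 0.0
    # split at curvature sign changes, measure normal deviation per piece
    change_idx = np.nonzero(np.sign(dtheta[1:]) * np.sign(dtheta[:-1]) < 0)[0] + 1
    bounds = [0, *change_idx.tolist(), len(pts) - 1]
    amps = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        piece = pts[a:b + 1]
        chord = piece[-1] - piece[0]
        clen = np.linalg.norm(chord)
        if clen < 1e-9:
            continue
        normal = np.array([-chord[1], chord[0]]) / clen
        dev = np.abs((piece - piece[0]) @ normal)
        amps.append(dev.max() / clen)
    mean_amp = float(np.mean(amps)) if amps else 0.0
    arc_chord = tortuosity_m1(pts)
    return 0.1 * sd_theta * crit * mean_amp * arc_chord


def aggregate_tortuosity(graph: VesselGraph, method: str = "m1",
                         min_len_px: float = 10.0,
                         min_chord_px: float = 5.0,
                         smooth_sigma: float = 0.0,
                         class_attr: str = "vessel_class") -> dict[str, float]:
    """Unweighted per-class mean tortuosity over qualifying edges.

    Edges shorter than `min_len_px`, closed or near-closed runs (chord
    below `min_chord_px` — arc/chord diverges as the endpoints meet), and
    degenerate centerlines are excluded; a class with no qualifying edge
    maps to NaN. `smooth_sigma` (in samples) optionally Gaussian-smooths
    each centerline first, suppressing 1-px staircase noise on short
    skeleton edges.
    """
    if method not in ("m1", "m2"):
        raise ValueError("method must be 'm1' or 'm2'")
    fn = tortuosity_m1 if method == "m1" else tortuosity_m2
    values: dict[str, list[float]] = {}
    for _, _, _, d in graph.edges():
        if d.get("length_px", 0.0) < min_len_px:
            continue
        poly = d["polyline"]
        if np.linalg.norm(poly[-1] - poly[0]) < min_chord_px:
            continue
        if smooth_sigma > 0 and len(poly) > 4:
            poly = np.column_stack([
                ndimage.gaussian_filter1d(poly[:, 0], smooth_sigma,
                                          mode="nearest"),
                ndimage.gaussian_filter1d(poly[:, 1], smooth_sigma,
                                          mode="nearest")])
        cls = d.get(class_attr, "unclassified")
        try:
            val = fn(poly)
        except ValueError:
            continue
        values.setdefault(cls, []).append(val)
    out: dict[str, float] = {}
    for cls in ("av", "capillary"):
        vals = values.get(cls, [])
        out[cls] = float(np.mean(vals)) if vals else float("nan")
    for cls, vals in values.items():
        if cls not in out:
            out[cls] = float(np.mean(vals))
    return out


def compute_vascular_metrics(mask: BinaryVesselMask, skeleton: SkeletonMask,
                             graph: VesselGraph,
                             av_mask: BinaryVesselMask | None = None,
                             exclusion: str = "both",
                             min_len_px: float = 10.0) -> VascularMetrics:
    """All scalar metrics of one eye from the segmented angiogram."""
    return VascularMetrics(
        perfusion_density=perfusion_density(mask, av_mask, exclusion),
        vessel_density=vessel_density(skeleton, av_mask, exclusion),
        mean_diameter_mm=mean_vessel_diameter(mask, skeleton),
        fractal_dimension=fractal_dimension(skeleton),
        tortuosity_m1=aggregate_tortuosity(graph, "m1", min_len_px),
        tortuosity_m2=aggregate_tortuosity(graph, "m2", min_len_px),
    )
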