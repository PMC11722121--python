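"""Foveal avascular zone segmentation, shape metrics and magnification.

The FAZ is the avascular connected region containing the fovea after a
morphological closing of the vessel mask. Shape descriptors follow the
standard digital-morphometry estimators: area from the pixel count,
perimeter from a smoothed marching-squares contour, eccentricity from the
second central moments, the axis ratio from the axis-aligned bounding box,
the acircularity index perimeter / (2*sqrt(pi*area)) (1 for a circle), and
minimum/maximum Feret (caliper) diameters from the convex hull of the
contour.

Linear metrics are corrected for ocular magnification with the modified
Littmann-Bennett relation q = 0.01306 * (axial length - 1.82): an eye
longer than the device's assumed axial length projects a bigger retina
onto the same scan angle, so measured lengths scale by
q_eye / q_device and areas by its square.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .containers import BinaryVesselMask, EnFaceImage

__all__ = [
    "FAZRegion",
    "FAZMetrics",
    "MagnificationParams",
    "segment_faz",
    "faz_metrics",
    "magnification_scale",
    "apply_magnification",
]

BENNETT_SLOPE = 0.01306        # per mm of axial length
BENNETT_OFFSET_MM = 1.82
DEVICE_ASSUMED_AL_MM = 23.95


@dataclass
class FAZRegion:
    """Connected avascular region with its traced boundary."""

    pixel_set: np.ndarray            # boolean mask of the region
    boundary: np.ndarray             # (N,2) closed contour, subpixel (row,col)
    centroid: tuple[float, float]
    pixel_size_mm: float


@dataclass
class FAZMetrics:
    area_mm2: float
    perimeter_mm: float
    eccentricity: float
    axis_ratio: float
    acircularity_index: float
    min_feret_mm: float
    max_feret_mm: float
    corrected: bool = False


@dataclass
class MagnificationParams:
    """Ocular biometry for the Littmann-Bennett scaling.

    Optional keratometry/refraction support a three-variable variant; by
    default only the axial length drives the correction.
    """

    axial_length_mm: float
    device_assumed_al_mm: float = DEVICE_ASSUMED_AL_MM
    bennett_slope: float = BENNETT_SLOPE
    bennett_offset_mm: float = BENNETT_OFFSET_MM
    keratometry_D: float | None = None
    refraction_D: float | None = None

    def __post_init__(self) -> None:
        if self.axial_length_mm <= self.bennett_offset_mm:
            raise ValueError("axial length must exceed the Bennett offset")


def segment_faz(source: EnFaceImage | BinaryVesselMask,
                fovea_point: tuple[int, int] | None = None,
                closing_radius: int = 5) -> FAZRegion:
    """Avascular connected component at the fovea.

    The vessel mask (segmented on the fly when an image is given) is closed
    with a disk of `closing_radius` px to seal inter-capillary gaps; the
    4-connected avascular component containing `fovea_point` (default:
    image center) is the FAZ. Deterministic.
    """
    if isinstance(source, BinaryVesselMask):
        mask = source.pixels
        pixel_size = source.pixel_size_mm
    else:
        from .graph import binarize_vessels

        vm = binarize_vessels(source)
        mask = vm.pixels
        pixel_size = source.pixel_size_mm
    h, w = mask.shape
    if fovea_point is None:
        fovea_point = (h // 2, w // 2)
    fy, fx = int(fovea_point[0]), int(fovea_point[1])
    if not (0 <= fy < h and 0 <= fx < w):
        raise ValueError("fovea_point outside the image")
    closed = morphology.closing(mask, morphology.disk(closing_radius))
    avascular = ~closed
    if not avascular[fy, fx]:
        raise ValueError("no avascular region at seed: fovea point lies on "
                         "a vessel after closing")
    labels, _ = ndimage.label(avascular,
                              structure=np.array([[0, 1, 0],
                                                  [1, 1, 1],
                                                  [0, 1, 0]]))
    region = labels == labels[fy, fx]
    contours = measure.find_contours(region.astype(float), 0.5)
    boundary = max(contours, key=len)
    ys, xs = np.nonzero(region)
    return FAZRegion(pixel_set=region, boundary=boundary,
                     centroid=(float(ys.mean()), float(xs.mean())),
                     pixel_size_mm=pixel_size)


def _smooth_closed_contour(contour: np.ndarray, window: int = 7) -> np.ndarray:
    """Circular moving average removing marching-squares staircase."""
    pts = contour
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    if n < window + 2:
        return contour
    kernel = np.ones(window) / window
    out = np.empty_like(pts)
    for dim in range(2):
        padded = np.concatenate([pts[-(window // 2):, dim], pts[:, dim],
                                 pts[:window // 2, dim]])
        out[:, dim] = np.convolve(padded, kernel, mode="valid")
    return np.vstack([out, out[:1]])


def _feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Min/max caliper diameters from the convex hull (rotating calipers)."""
    from scipy.spatial import ConvexHull

    if len(points) < 3:
        d = float(np.linalg.norm(points[-1] - points[0]))
        return d, d
    hull = points[ConvexHull(points).vertices]
    # max Feret: max pairwise hull distance
    diff = hull[:, None, :] - hull[None, :, :]
    dmax = float(np.sqrt((diff ** 2).sum(-1)).max())
    # min Feret: smallest width over hull edge directions
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 1e-12
    normals = np.column_stack([-edges[good, 1], edges[good, 0]]) / \
        lengths[good, None]
    proj = hull @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), dmax


def faz_metrics(region: FAZRegion, pixel_size_mm: float | None = None) -> FAZMetrics:
    """Shape descriptors of a segmented FAZ (uncorrected scale)."""
    if not region.pixel_set.any():
        raise ValueError("empty FAZ region")
    p = pixel_size_mm if pixel_size_mm is not None else region.pixel_size_mm
    props = measure.regionprops(region.pixel_set.astype(np.uint8))[0]
    area = float(region.pixel_set.sum()) * p ** 2
    contour = _smooth_closed_contour(region.boundary)
    perim = float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))) * p
    ecc = float(props.eccentricity)
    minr, minc, maxr, maxc = props.bbox
    side_a, side_b = maxr - minr, maxc - minc
    axis_ratio = max(side_a, side_b) / max(min(side_a, side_b), 1)
    acirc = perim / (2.0 * np.sqrt(np.pi * area))
    fmin, fmax = _feret_diameters(region.boundary)
    return FAZMetrics(area_mm2=area, perimeter_mm=perim, eccentricity=ecc,
                      axis_ratio=float(axis_ratio),
                      acircularity_index=float(acirc),
                      min_feret_mm=fmin * p, max_feret_mm=fmax * p,
                      corrected=False)


def magnification_scale(params: MagnificationParams) -> float:
    """Littmann-Bennett linear scale factor q_eye / q_device."""
    q_eye = params.bennett_slope * (params.axial_length_mm
                                    - params.bennett_offset_mm)
    q_dev = params.bennett_slope * (params.device_assumed_al_mm
                                    - params.bennett_offset_mm)
    return q_eye / q_dev


def apply_magnification(metrics: FAZMetrics, s: float) -> FAZMetrics:
    """Scale linear fields by s and the area by s^2; dimensionless shape
    descriptors are unchanged. Refuses to correct twice."""
    if metrics.corrected:
        raise ValueError("metrics already magnification-corrected")
    return replace(metrics,
                   area_mm2=metrics.area_mm2 * s ** 2,
                   perimeter_mm=metrics.perimeter_mm * s,
                   min_feret_mm=metrics.min_feret_mm * s,
                   max_feret_mm=metrics.max_feret_mm * s,
                   corrected=True)
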