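"""Frame-stack preprocessing: gate, flat-field, register, normalize, average.

A burst of consecutive en face frames is reduced to one image with improved
signal-to-noise: frames failing the device quality gate are dropped, the
rest are corrected for slow intensity inhomogeneity, aligned to a reference
frame by a translation -> affine -> elastic cascade, intensity-matched to
the reference, and combined by pixelwise mean (default) or maximum.

The alignment dissimilarity score is the negative normalized
cross-correlation (NCC); each stage must not worsen it, and a frame whose
translation stage fails to improve the score beyond a configurable epsilon
is excluded as non-overlapping.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .containers import EnFaceImage, FrameStack, TransformEstimate

__all__ = [
    "RegistrationError",
    "quality_gate",
    "correct_inhomogeneity",
    "register_frame",
    "normalize_intensity",
    "average_stack",
    "preprocess_stack",
]

DEFAULT_STAGES = ("translation", "affine", "elastic")


class RegistrationError(RuntimeError):
    """Raised when a moving frame cannot be aligned to the reference."""


def quality_gate(meta: dict) -> bool:
    """Device gate: signal strength index > 50 or quality score > 8.

    Both inequalities are strict; at least one score must be present.
    """
    ssi = meta.get("signal_strength_index")
    score = meta.get("quality_score")
    if ssi is None and score is None:
        raise ValueError("device_meta carries neither signal_strength_index "
                         "nor quality_score")
    if ssi is not None and ssi > 50:
        return True
    if score is not None and score > 8:
        return True
    return False


def correct_inhomogeneity(image: EnFaceImage, kernel_mm: float = 0.5) -> EnFaceImage:
    """Divide out a heavily smoothed background estimate, preserving the mean.

    `kernel_mm` is the Gaussian sigma of the background model; it must be
    much larger than the vessel spacing so vessels do not bleed into the
    background estimate.
    """
    if not kernel_mm > 0:
        raise ValueError("kernel_mm must be positive")
    sigma_px = kernel_mm / image.pixel_size_mm
    px = image.pixels
    background = ndimage.gaussian_filter(px, sigma_px)
    background = np.maximum(background, 1e-8 * max(px.max(), 1.0))
    out = px / background
    mean = out.mean()
    if mean > 0:
        out = out * (px.mean() / mean)
    return image.copy(pixels=out, provenance="corrected")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    return -_ncc(a, b)


def _affine_matrix(theta: float, log_sx: float, log_sy: float, shear: float,
                   ty: float, tx: float, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/col affine about the image center: output coords -> input coords."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    scale = np.diag([math.exp(log_sy), math.exp(log_sx)])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    mat = rot @ scale @ sh
    offset = center - mat @ center + np.array([ty, tx])
    return mat, offset


def _warp(moving: np.ndarray, mat: np.ndarray, offset: np.ndarray,
          elastic: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Single-interpolation-pass warp of the composed transform."""
    h, w = moving.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    src_y = mat[0, 0] * yy + mat[0, 1] * xx + offset[0]
    src_x = mat[1, 0] * yy + mat[1, 1] * xx + offset[1]
    if elastic is not None:
        src_y = src_y + elastic[0]
        src_x = src_x + elastic[1]
    return ndimage.map_coordinates(moving, [src_y, src_x], order=1,
                                   mode="nearest")


def _estimate_translation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=20,
                                          normalization=None)
    return np.asarray(shift, dtype=float)


def _estimate_affine(moving: np.ndarray, fixed: np.ndarray,
                     init_shift: np.ndarray) -> np.ndarray:
    """Powell search of (theta, log_sx, log_sy, shear, ty, tx) on NCC."""
    center = (np.asarray(moving.shape, dtype=float) - 1) / 2.0

    def cost(params: np.ndarray) -> float:
        mat, offset = _affine_matrix(*params, center=center)
        warped = _warp(moving, mat, offset)
        return _dissimilarity(warped, fixed)

    x0 = np.array([0.0, 0.0, 0.0, 0.0, -init_shift[0], -init_shift[1]])
    res = optimize.minimize(cost, x0, method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-5,
                                     "maxfev": 600})
    return np.asarray(res.x, dtype=float)


def _estimate_elastic(moving_warped: np.ndarray, fixed: np.ndarray,
                      grid_spacing: int = 32, n_iter: int = 8,
                      step: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Coarse free-form displacement on a control grid, demons-style.

    The residual-driven force field is averaged over control cells,
    smoothed, and upsampled with cubic interpolation (a coarse B-spline
    displacement model). Returns dense (dy, dx) sampled per pixel.
    """
    h, w = fixed.shape
    gy = max(h // grid_spacing, 2)
    gx = max(w // grid_spacing, 2)
    ctrl = np.zeros((2, gy, gx))
    best = (_dissimilarity(moving_warped, fixed), ctrl.copy())
    for _ in range(n_iter):
        dense = _upsample_ctrl(ctrl, (h, w))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        warped = ndimage.map_coordinates(
            moving_warped, [yy + dense[0], xx + dense[1]], order=1, mode="nearest")
        resid = fixed - warped
        gyy, gxx = np.gradient(warped)
        force_y = resid * gyy
        force_x = resid * gxx
        norm = max(np.abs(np.stack([force_y, force_x])).max(), 1e-12)
        fy = _block_mean(force_y, gy, gx) / norm
        fx = _block_mean(force_x, gy, gx) / norm
        cand = ctrl + step * np.stack([ndimage.gaussian_filter(fy, 0.7),
                                       ndimage.gaussian_filter(fx, 0.7)])
        dense_c = _upsample_ctrl(cand, (h, w))
        warped_c = ndimage.map_coordinates(
            moving_warped, [yy + dense_c[0], xx + dense_c[1]], order=1,
            mode="nearest")
        score = _dissimilarity(warped_c, fixed)
        if score < best[0]:
            best = (score, cand.copy())
            ctrl = cand
        else:
            break
    return _upsample_ctrl(best[1], (h, w)), best[1]  # type: ignore[return-value]


def _block_mean(arr: np.ndarray, gy: int, gx: int) -> np.ndarray:
    h, w = arr.shape
    ys = np.linspace(0, h, gy + 1).astype(int)
    xs = np.linspace(0, w, gx + 1).astype(int)
    out = np.zeros((gy, gx))
    for i in range(gy):
        for j in range(gx):
            out[i, j] = arr[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean()
    return out


def _upsample_ctrl(ctrl: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    gy, gx = ctrl.shape[1:]
    zy, zx = h / gy, w / gx
    return np.stack([
        ndimage.zoom(ctrl[0], (zy, zx), order=3, mode="nearest", grid_mode=True),
        ndimage.zoom(ctrl[1], (zy, zx), order=3, mode="nearest", grid_mode=True),
    ])


def register_frame(moving: EnFaceImage, fixed: EnFaceImage,
                   stages: Sequence[str] = DEFAULT_STAGES,
                   fail_epsilon: float = 0.0,
                   ) -> tuple[EnFaceImage, list[TransformEstimate]]:
    """Align `moving` onto `fixed` through the requested stage cascade.

    Stages run in order; each estimate is kept only if it does not worsen
    the NCC dissimilarity. The final image is produced by one interpolation
    pass of the composed transform. A translation stage that fails to
    improve the score by more than `fail_epsilon` raises RegistrationError
    (non-overlapping content).
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed frames must share shape")
    unknown = set(stages) - {"translation", "affine", "elastic"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    mov = moving.pixels
    fix = fixed.pixels
    center = (np.asarray(mov.shape, dtype=float) - 1) / 2.0
    base_score = _dissimilarity(mov, fix)

    mat = np.eye(2)
    offset = np.zeros(2)
    elastic_dense: tuple[np.ndarray, np.ndarray] | None = None
    estimates: list[TransformEstimate] = []
    current_score = base_score

    for stage in stages:
        if stage == "translation":
            shift = _estimate_translation(_warp(mov, mat, offset), fix)
            cand_offset = offset - shift  # output->input sampling offset
            warped = _warp(mov, mat, cand_offset)
            score = _dissimilarity(warped, fix)
            improvement = current_score - score
            if improvement <= fail_epsilon and abs(shift).max() > 0:
                if score > current_score:
                    raise RegistrationError(
                        "translation stage failed to improve alignment "
                        f"(score {score:.4f} vs {current_score:.4f})")
            if score <= current_score:
                offset = cand_offset
                current_score = score
                est_shift = tuple(float(v) for v in shift)
            else:
                est_shift = (0.0, 0.0)
            estimates.append(TransformEstimate(
                "translation", {"shift": est_shift}, current_score))
        elif stage == "affine":
            init_shift = -offset  # current pure-translation estimate
            params = _estimate_affine(mov, fix, init_shift)
            cand_mat, cand_offset = _affine_matrix(*params, center=center)
            warped = _warp(mov, cand_mat, cand_offset)
            score = _dissimilarity(warped, fix)
            if score <= current_score:
                mat, offset = cand_mat, cand_offset
                current_score = score
            estimates.append(TransformEstimate(
                "affine",
                {"theta": float(params[0]), "log_sx": float(params[1]),
                 "log_sy": float(params[2]), "shear": float(params[3]),
                 "ty": float(params[4]), "tx": float(params[5])},
                current_score))
        elif stage == "elastic":
            pre = _warp(mov, mat, offset)
            dense, ctrl = _estimate_elastic(pre, fix)
            warped = _warp(mov, mat, offset, elastic=(dense[0], dense[1]))
            score = _dissimilarity(warped, fix)
            if score <= current_score:
                elastic_dense = (dense[0], dense[1])
                current_score = score
            estimates.append(TransformEstimate(
                "elastic", {"control_grid": np.asarray(ctrl).shape[1:]},
                current_score))

    final = _warp(mov, mat, offset, elastic=elastic_dense)
    out = moving.copy(pixels=final, provenance="corrected")
    return out, estimates


def normalize_intensity(image: EnFaceImage, reference: EnFaceImage) -> EnFaceImage:
    """Match mean and SD of `image` to those of `reference`."""
    if image.shape != reference.shape:
        raise ValueError("image and reference must share shape")
    sd = image.pixels.std()
    if sd < 1e-12:
        raise ValueError("zero-variance image cannot be normalized")
    ref_sd = reference.pixels.std()
    out = (image.pixels - image.pixels.mean()) / sd * ref_sd \
        + reference.pixels.mean()
    return image.copy(pixels=out)


def average_stack(stack: FrameStack, mode: str = "mean") -> EnFaceImage:
    """Pixelwise mean (default) or max across the frames of a stack."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    arr = np.stack([f.pixels for f in stack.frames])
    out = arr.mean(axis=0) if mode == "mean" else arr.max(axis=0)
    return stack.frames[stack.reference_index].copy(pixels=out,
                                                    provenance="averaged")


def preprocess_stack(stack: FrameStack, mode: str = "mean",
                     stages: Sequence[str] = DEFAULT_STAGES,
                     kernel_mm: float = 0.5,
                     apply_gate: bool = True) -> EnFaceImage:
    """Full chain: gate -> flat-field -> register to reference -> normalize
    -> average. The reference is the gated frame with the highest quality
    score (ties: lowest index)."""
    frames = list(stack.frames)
    if apply_gate:
        frames = [f for f in frames if quality_gate(f.device_meta)]
    if not frames:
        raise ValueError("no frame passes the quality gate")
    scores = [f.device_meta.get("quality_score",
                                f.device_meta.get("signal_strength_index", 0.0))
              for f in frames]
    ref_idx = int(np.argmax(scores))
    corrected = [correct_inhomogeneity(f, kernel_mm) for f in frames]
    reference = corrected[ref_idx]
    aligned: list[EnFaceImage] = []
    for i, frame in enumerate(corrected):
        if i == ref_idx:
            aligned.append(frame)
            continue
        try:
            reg, _ = register_frame(frame, reference, stages=stages)
        except RegistrationError:
            continue
        aligned.append(reg)
    normalized = [normalize_intensity(f, reference) for f in aligned]
    out_stack = FrameStack(frames=normalized, reference_index=0)
    return average_stack(out_stack, mode=mode)
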