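"""Alignment scoring: rigid MSE registration, modified LNCC, layer sweep.

The similarity score is a local normalized cross-correlation in which each
window's NCC is taken in absolute value before averaging:

    LNCC(I, J) = 1/|N_W| * sum_k | sum_i (I_i - Ibar_k)(J_i - Jbar_k)
                 / sqrt(sum_i (I_i - Ibar_k)^2 * sum_i (J_i - Jbar_k)^2) |

over all fully interior square windows W_k (no padding: the heatmap is
smaller than the input by window - 1 per axis).  The absolute value
prevents cancellation between locally correlated and anti-correlated
regions, making the score robust to local contrast inversion between
modalities.  Windows where either image is constant have undefined NCC and
contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter
from skimage import transform as sktransform

from .volume import VoxelVolume

__all__ = ["RigidTransform2D", "LNCCResult", "RegistrationParams", "rigid_register",
           "apply_rigid", "lncc", "lncc_layer_sweep", "overlay_checkerboard"]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (deg, CCW about the image center) + translation (px) + optional scale."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def as_matrix(self, shape: tuple[int, int]) -> sktransform.SimilarityTransform:
        """Forward map moving→fixed pixel coordinates, rotating about the image center."""
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        t = (sktransform.SimilarityTransform(translation=(-cx, -cy))
             + sktransform.SimilarityTransform(rotation=np.radians(self.rotation),
                                               scale=self.scale)
             + sktransform.SimilarityTransform(translation=(cx + self.translation[0],
                                                            cy + self.translation[1])))
        return t

    def inverse(self) -> "RigidTransform2D":
        th = np.radians(self.rotation)
        s = self.scale
        tx, ty = self.translation
        # invert: x' = s R x + t  →  x = (1/s) R^-1 (x' - t)
        c, si = np.cos(-th), np.sin(-th)
        itx = -(c * tx - si * ty) / s
        ity = -(si * tx + c * ty) / s
        return RigidTransform2D(rotation=-self.rotation, translation=(itx, ity), scale=1.0 / s)


def apply_rigid(moving: np.ndarray, t: RigidTransform2D,
                output_shape: tuple[int, int] | None = None,
                cval: float = np.nan, order: int = 1) -> np.ndarray:
    """Resample ``moving`` into the fixed frame under transform ``t``."""
    moving = np.asarray(moving, dtype=np.float64)
    if output_shape is None:
        output_shape = moving.shape
    tf = t.as_matrix(moving.shape)
    return sktransform.warp(moving, tf.inverse, output_shape=output_shape,
                            order=order, cval=cval, preserve_range=True)


class EmptyOverlapError(ValueError):
    pass


def _overlap_mse(moving: np.ndarray, fixed: np.ndarray, t: RigidTransform2D,
                 fixed_mask: np.ndarray | None = None) -> float:
    warped = apply_rigid(moving, t, output_shape=fixed.shape, cval=np.nan)
    mask = np.isfinite(warped)
    if fixed_mask is not None:
        mask &= fixed_mask
    if not mask.any():
        return np.inf
    return float(np.mean((fixed[mask] - warped[mask]) ** 2))


@dataclass(frozen=True)
class RegistrationParams:
    """Search ranges of the multi-resolution MSE optimizer (full-resolution units)."""

    rotation_range: float = 6.0      # deg, +/- around the initial guess
    rotation_step: float = 1.0       # deg, coarse grid
    translation_range: float = 12.0  # px, +/- around the initial guess
    levels: int = 3                  # pyramid levels (factor-2 downsampling)
    smoothing_sigma: float = 1.0     # px Gaussian pre-smoothing of both images
    allow_scale: bool = False


def rigid_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: RigidTransform2D = RigidTransform2D(),
    params: RegistrationParams = RegistrationParams(),
    fixed_mask: np.ndarray | None = None,
) -> RigidTransform2D:
    """Find the rigid transform minimizing the mean squared intensity difference.

    ``fixed_mask`` optionally restricts the metric to a region of the fixed
    image (e.g. the tissue portion of a section, excluding markers that
    extend beyond the scanned field of view).

    Both images are lightly Gaussian-smoothed (resampling a noisy image at
    subpixel offsets attenuates its noise, which would otherwise bias the
    MSE minimum toward spurious subpixel rotations) and min-max normalized
    internally.  A coarse exhaustive grid over rotation and translation at
    the coarsest pyramid level is followed by Powell refinement at each
    finer level; the procedure is deterministic for fixed parameters.  The
    MSE is evaluated over the overlap region only.
    """
    mov = np.asarray(moving, dtype=np.float64)
    fix = np.asarray(fixed, dtype=np.float64)
    if params.smoothing_sigma > 0:
        mov = gaussian_filter(mov, params.smoothing_sigma)
        fix = gaussian_filter(fix, params.smoothing_sigma)
    for name, img in (("moving", mov), ("fixed", fix)):
        span = img.max() - img.min()
        if span == 0:
            raise ValueError(f"{name} image is constant; MSE registration undefined")
    mov = (mov - mov.min()) / (mov.max() - mov.min())
    fix = (fix - fix.min()) / (fix.max() - fix.min())
    msk = None if fixed_mask is None else np.asarray(fixed_mask, dtype=bool)
    if np.isinf(_overlap_mse(mov, fix, init, msk)):
        raise EmptyOverlapError("no overlap between images at the initial transform")

    levels = max(int(params.levels), 1)
    pyramids = [(mov, fix, msk)]
    for _ in range(levels - 1):
        m, f, k = pyramids[-1]
        if min(m.shape) <= 32 or min(f.shape) <= 32:
            break
        pyramids.append((sktransform.rescale(m, 0.5, anti_aliasing=True),
                         sktransform.rescale(f, 0.5, anti_aliasing=True),
                         None if k is None
                         else sktransform.rescale(k.astype(float), 0.5) > 0.5))
    n_levels = len(pyramids)

    # coarse exhaustive search at the coarsest level
    factor = 2 ** (n_levels - 1)
    m, f, k = pyramids[-1]
    rots = init.rotation + np.arange(-params.rotation_range, params.rotation_range + 1e-9,
                                     params.rotation_step)
    tr = params.translation_range / factor
    txs = init.translation[0] / factor + np.arange(-np.ceil(tr), np.ceil(tr) + 1e-9, 1.0)
    tys = init.translation[1] / factor + np.arange(-np.ceil(tr), np.ceil(tr) + 1e-9, 1.0)
    best = (np.inf, init.rotation, init.translation[0] / factor, init.translation[1] / factor)
    for rot in rots:
        for tx in txs:
            for ty in tys:
                mse = _overlap_mse(m, f, RigidTransform2D(rot, (tx, ty)), k)
                if mse < best[0]:
                    best = (mse, rot, tx, ty)
    rot, tx, ty = best[1], best[2], best[3]
    scale = 1.0

    # refine through the pyramid
    for level in range(n_levels - 1, -1, -1):
        m, f, k = pyramids[level]
        if level < n_levels - 1:
            tx, ty = tx * 2, ty * 2

        def cost(x):
            t = RigidTransform2D(x[0], (x[1], x[2]),
                                 scale=x[3] if params.allow_scale else 1.0)
            return _overlap_mse(m, f, t, k)

        x0 = [rot, tx, ty] + ([1.0] if params.allow_scale else [])
        res = optimize.minimize(cost, np.array(x0, dtype=float), method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-10, "maxiter": 200})
        rot, tx, ty = res.x[0], res.x[1], res.x[2]
        scale = float(res.x[3]) if params.allow_scale else 1.0
    return RigidTransform2D(rotation=float(rot), translation=(float(tx), float(ty)),
                            scale=scale if params.allow_scale else 1.0)


@dataclass
class LNCCResult:
    """Heatmap of per-window |NCC| scores plus summary statistics."""

    heatmap: np.ndarray
    window: int
    mean_lncc: float
    max_lncc: float


def _window_sums(a: np.ndarray, w: int) -> np.ndarray:
    """Sums of every fully interior w x w window via an integral image."""
    s = np.cumsum(np.cumsum(a, axis=0), axis=1)
    s = np.pad(s, ((1, 0), (1, 0)))
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def lncc(I: np.ndarray, J: np.ndarray, window: int = 45) -> LNCCResult:
    """Modified local normalized cross-correlation over all interior windows.

    The default 45 px window matches the validated configuration.  Heatmap
    shape is ``input - window + 1`` per axis; zero-variance windows score 0;
    every score lies in [0, 1] and the mean of the heatmap is the LNCC.
    """
    I = np.asarray(I, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    if I.shape != J.shape:
        raise ValueError(f"image shapes differ: {I.shape} vs {J.shape}")
    if I.ndim != 2:
        raise ValueError("lncc expects 2D images")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if min(I.shape) < window:
        raise ValueError(f"window {window} larger than image {I.shape}")

    # subtract global means so constant windows cancel exactly
    Ic = I - I.mean()
    Jc = J - J.mean()
    n = window * window
    sI = _window_sums(Ic, window)
    sJ = _window_sums(Jc, window)
    sII = _window_sums(Ic * Ic, window)
    sJJ = _window_sums(Jc * Jc, window)
    sIJ = _window_sums(Ic * Jc, window)
    cov = sIJ - sI * sJ / n
    varI = sII - sI * sI / n
    varJ = sJJ - sJ * sJ / n
    scaleI = float((Ic * Ic).mean()) + 1e-300
    scaleJ = float((Jc * Jc).mean()) + 1e-300
    degenerate = (varI <= 1e-10 * n * scaleI) | (varJ <= 1e-10 * n * scaleJ)
    denom = np.sqrt(np.maximum(varI, 0) * np.maximum(varJ, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.abs(cov) / denom
    heat = np.where(degenerate, 0.0, np.clip(ncc, 0.0, 1.0))
    return LNCCResult(heatmap=heat, window=window,
                      mean_lncc=float(heat.mean()), max_lncc=float(heat.max()))


def lncc_layer_sweep(
    volume: VoxelVolume | np.ndarray,
    section: np.ndarray,
    window: int = 45,
) -> tuple[np.ndarray, int]:
    """LNCC of the section against every flat z-layer; returns (scores, argmax).

    Section and layers are center-cropped to their common size.  The first
    layer attaining the maximum wins ties.  Validates an extracted plane:
    for a flat ground-truth cut the best layer should be the cut layer, and
    an oblique extraction should beat every flat layer.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("layer sweep needs a non-empty 3D volume")
    sec = np.asarray(section, dtype=np.float64)
    h = min(sec.shape[0], data.shape[1])
    w = min(sec.shape[1], data.shape[2])

    def crop(img, th, tw):
        r0 = (img.shape[0] - th) // 2
        c0 = (img.shape[1] - tw) // 2
        return img[r0:r0 + th, c0:c0 + tw]

    sec_c = crop(sec, h, w)
    scores = np.empty(data.shape[0])
    for k in range(data.shape[0]):
        scores[k] = lncc(crop(data[k].astype(np.float64), h, w), sec_c, window).mean_lncc
    return scores, int(np.argmax(scores))


def overlay_checkerboard(a: np.ndarray, b: np.ndarray, tile: int) -> np.ndarray:
    """Alternate ``tile`` x ``tile`` blocks of two equally sized images (corner from a)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if tile < 1:
        raise ValueError("tile must be >= 1")
    rows = np.arange(a.shape[0]) // tile
    cols = np.arange(a.shape[1]) // tile
    take_b = (rows[:, None] + cols[None, :]) % 2 == 1
    return np.where(take_b, b, a)
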