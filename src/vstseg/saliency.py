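"""Visual-saliency map: the network's second input.

The map combines two stages computed on low-level features:

* **Local stage** — the image is decomposed into ``n_scales`` levels of a
  Gaussian pyramid (5-tap binomial kernel [1,4,6,4,1]/16, downsample by 2).
  On every level three centre–surround contrast maps are computed (intensity,
  texture = local entropy, and a colour proxy built from three fixed
  window/level presets of the single CT channel), giving ``n_scales x 3``
  maps (18 at the default six scales).  Per feature the maps are upsampled
  back to full resolution by repeated 2x bilinear interpolation and summed
  into the fused feature maps IFM', TFM', CFM'.  The local saliency is the
  sum of squares of the min–max-normalised fused maps:
  ``S_local = N(IFM')^2 + N(TFM')^2 + N(CFM')^2``.

* **Global stage** — for every pixel, the sum over all other pixels of the
  Euclidean distance between their patch feature vectors:
  ``S_global(k) = sum_j dis(p_k, p_j)``.  Patch features concatenate the
  patch across three affine intensity windows.  Because the exact computation
  is quadratic in pixel count, the default path runs it on a copy downsampled
  to a maximum side of 64 and upsamples the result; ``exact=True`` skips the
  downsampling.

The two stages are fused through a weighting matrix
``omega = theta * N(S_local) + (1 - theta) * N(S_global)`` (theta = 0.5 by
default) and the final map is ``SM = omega * S_global``.

Normalisation ``N(.)`` is min–max to [0, 1]; a constant map normalises to
all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .grid import ImageGrid

#: 5-tap binomial approximation of a Gaussian, used for pyramid smoothing
PYRAMID_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: (lower, upper) bounds of the three intensity window presets, on the
#: per-image min-max normalised scale; chosen to emphasise dark, mid and
#: bright tissue respectively
WINDOW_PRESETS = ((0.0, 0.6), (0.2, 0.8), (0.4, 1.0))

#: centre-surround annulus radii in pixels (inner, outer)
ANNULUS_RADII = (1, 4)

#: window half-size for the local-entropy texture feature (5x5 window)
ENTROPY_RADIUS = 2

#: maximum side length of the image used by the fast global stage
GLOBAL_MAX_SIDE = 64


@dataclass
class SaliencyConfig:
    n_scales: int = 6
    theta: float = 0.5
    patch_size: int = 3
    n_features: int = 3

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be a positive odd number")
        if self.n_features != 3:
            raise ValueError("the pipeline uses exactly 3 features")


@dataclass
class ContrastMapSet:
    """Per-scale contrast maps and the full-resolution fused feature maps."""

    maps: list[list[np.ndarray]]  # maps[scale][feature], native resolutions
    fused_feature_maps: tuple[np.ndarray, np.ndarray, np.ndarray]  # IFM', TFM', CFM'

    @property
    def n_maps(self) -> int:
        return sum(len(per_scale) for per_scale in self.maps)


@dataclass
class SaliencyMap:
    s_local: np.ndarray
    s_global: np.ndarray
    omega: np.ndarray
    sm: np.ndarray


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant map maps to all zeros."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo == 0.0:
        return np.zeros_like(x, dtype=np.float64)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------

def _smooth(img: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(img, PYRAMID_KERNEL, axis=0, mode="reflect")
    return ndimage.correlate1d(out, PYRAMID_KERNEL, axis=1, mode="reflect")


def gaussian_pyramid(image: ImageGrid | np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Level 0 is the input; each next level is smoothed and decimated by 2."""
    img = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("the saliency pipeline operates on 2-D slices")
    min_side = 2 ** (n_scales - 1)
    if min(img.shape) < min_side:
        raise ValueError(
            f"image of shape {img.shape} too small for {n_scales} pyramid scales "
            f"(needs at least {min_side} per axis)"
        )
    levels = [img.astype(np.float64)]
    for _ in range(n_scales - 1):
        levels.append(_smooth(levels[-1])[::2, ::2])
    return levels


# ---------------------------------------------------------------------------
# local stage
# ---------------------------------------------------------------------------

def _annulus_kernel() -> np.ndarray:
    inner, outer = ANNULUS_RADII
    y, x = np.mgrid[-outer : outer + 1, -outer : outer + 1]
    r2 = y * y + x * x
    ring = (r2 > inner * inner) & (r2 <= outer * outer)
    return ring / ring.sum()


_ANNULUS = _annulus_kernel()


def _center_surround(feature: np.ndarray) -> np.ndarray:
    """|value - mean of surrounding annulus| per pixel."""
    surround = ndimage.convolve(feature, _ANNULUS, mode="reflect")
    return np.abs(feature - surround)


def _local_entropy(img: np.ndarray) -> np.ndarray:
    """Shannon entropy of 16-bin intensity histograms over a 5x5 window."""
    n_bins = 16
    norm = minmax_normalize(img)
    bins = np.minimum((norm * n_bins).astype(np.intp), n_bins - 1)
    size = 2 * ENTROPY_RADIUS + 1
    counts = np.stack(
        [ndimage.uniform_filter((bins == b).astype(np.float64), size=size)
         for b in range(n_bins)]
    )
    p = np.clip(counts, 1e-12, None)
    return -(p * np.log2(p)).sum(axis=0)


def _color_channels(img: np.ndarray, clip: bool = True,
                    normalize: bool = True) -> list[np.ndarray]:
    """Three pseudo-channels from fixed window presets of the CT channel.

    With ``normalize=False`` the windows act on raw intensities as pure
    affine maps, so channel differences remain proportional to intensity
    differences (needed by the homogeneous global stage).
    """
    norm = minmax_normalize(img) if normalize else img
    out = []
    for lo, hi in WINDOW_PRESETS:
        ch = (norm - lo) / (hi - lo)
        out.append(np.clip(ch, 0.0, 1.0) if clip else ch)
    return out


def _upsample_to(maps: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Repeated 2x bilinear upsampling, with a final exact-fit resize."""
    out = maps
    while out.shape[0] * 2 <= target_shape[0] and out.shape[1] * 2 <= target_shape[1]:
        out = resize(out, (out.shape[0] * 2, out.shape[1] * 2), order=1,
                     mode="reflect", anti_aliasing=False)
    if out.shape != tuple(target_shape):
        out = resize(out, target_shape, order=1, mode="reflect", anti_aliasing=False)
    return out


def local_contrast_maps(pyramid: list[np.ndarray],
                        config: SaliencyConfig | None = None) -> ContrastMapSet:
    """Per-scale centre–surround maps and their cross-scale fusion."""
    if not pyramid:
        raise ValueError("pyramid must be nonempty")
    full_shape = pyramid[0].shape
    per_scale: list[list[np.ndarray]] = []
    for level in pyramid:
        intensity = _center_surround(level)
        texture = _center_surround(_local_entropy(level))
        color = np.mean(
            [_center_surround(ch) for ch in _color_channels(level)], axis=0
        )
        per_scale.append([intensity, texture, color])
    fused = []
    for f in range(3):
        acc = np.zeros(full_shape, dtype=np.float64)
        for maps in per_scale:
            acc += _upsample_to(maps[f], full_shape)
        fused.append(acc)
    return ContrastMapSet(maps=per_scale, fused_feature_maps=tuple(fused))


def fuse_local(contrast: ContrastMapSet) -> np.ndarray:
    """S_local = N(IFM')^2 + N(TFM')^2 + N(CFM')^2 (sum of squares as stated)."""
    ifm, tfm, cfm = contrast.fused_feature_maps
    if not (ifm.shape == tfm.shape == cfm.shape):
        raise ValueError("fused feature maps must share shape")
    return (
        minmax_normalize(ifm) ** 2
        + minmax_normalize(tfm) ** 2
        + minmax_normalize(cfm) ** 2
    )


# ---------------------------------------------------------------------------
# global stage
# ---------------------------------------------------------------------------

def _patch_features(img: np.ndarray, patch_size: int) -> np.ndarray:
    """(n_pixels, 3*patch^2) feature matrix of windowed patches.

    The three windows are affine (no clipping), so patch-difference
    distances scale linearly with the image: dis(c*p_k, c*p_j) = c*dis(p_k,p_j).
    """
    r = patch_size // 2
    channels = _color_channels(img, clip=False, normalize=False)
    feats = []
    for ch in channels:
        padded = np.pad(ch, r, mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(padded, (patch_size, patch_size))
        feats.append(win.reshape(img.shape[0] * img.shape[1], patch_size**2))
    return np.concatenate(feats, axis=1)


def global_saliency(image: ImageGrid | np.ndarray, patch_size: int = 3) -> np.ndarray:
    """S_global(k) = sum over all pixels j of ||p_k - p_j||, patch features."""
    img = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    if min(img.shape) < patch_size:
        raise ValueError(f"patch_size {patch_size} does not fit image {img.shape}")
    feats = _patch_features(img, patch_size)
    n = feats.shape[0]
    out = np.zeros(n, dtype=np.float64)
    # blocked exact pairwise distances; O(n^2) time, O(block*n) memory
    block = 1024
    from scipy.spatial.distance import cdist

    for start in range(0, n, block):
        d = cdist(feats[start : start + block], feats)
        out[start : start + block] = d.sum(axis=1)
    return out.reshape(img.shape)


# ---------------------------------------------------------------------------
# fusion and the full pipeline
# ---------------------------------------------------------------------------

def combine(s_local: np.ndarray, s_global: np.ndarray, theta: float = 0.5) -> SaliencyMap:
    """omega = theta*N(S_local) + (1-theta)*N(S_global); SM = omega * S_global."""
    if s_local.shape != s_global.shape:
        raise ValueError("local and global maps must share shape")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    omega = theta * minmax_normalize(s_local) + (1.0 - theta) * minmax_normalize(s_global)
    return SaliencyMap(
        s_local=s_local, s_global=s_global, omega=omega, sm=omega * s_global
    )


def compute_saliency(image: ImageGrid | np.ndarray,
                     config: SaliencyConfig | None = None,
                     exact: bool = False) -> SaliencyMap:
    """Full pipeline: pyramid -> local fusion -> global stage -> combination."""
    config = config or SaliencyConfig()
    img = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    pyramid = gaussian_pyramid(img, config.n_scales)
    s_local = fuse_local(local_contrast_maps(pyramid, config))
    if exact or max(img.shape) <= GLOBAL_MAX_SIDE:
        s_global = global_saliency(img, config.patch_size)
    else:
        scale = GLOBAL_MAX_SIDE / max(img.shape)
        small_shape = (max(1, round(img.shape[0] * scale)),
                       max(1, round(img.shape[1] * scale)))
        small = resize(img, small_shape, order=1, mode="reflect", anti_aliasing=True)
        s_small = global_saliency(small, config.patch_size)
        s_global = resize(s_small, img.shape, order=1, mode="reflect",
                          anti_aliasing=False)
    return combine(s_local, s_global, config.theta)
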