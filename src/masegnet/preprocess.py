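"""Fundus image preparation: crop, resize, green channel, CLAHE, gamma,
non-local-means denoising, patch extraction/stitching and augmentation.

The full chain, in order, is

    crop_border -> resize(512) -> extract_green -> apply_clahe
    -> apply_gamma(0.9) -> denoise_nlm

after which the 512x512 single-channel image is cut into a non-overlapping
grid of 64x64 patches (64 per image) and the training patches are expanded
x4 by rotate-90, horizontal flip and vertical flip.

All intensities are kept on the [0, 255] uint8-compatible scale throughout;
every stage returns float64 in [0, R_max] unless noted.  The green channel
carries the highest lesion/background contrast in fundus photographs, which
is why the chain collapses to a single channel there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, restoration, transform

R_MAX = 255.0

__all__ = [
    "PatchSet",
    "AugmentSpec",
    "PreprocessConfig",
    "crop_border",
    "resize",
    "extract_green",
    "apply_clahe",
    "apply_gamma",
    "denoise_nlm",
    "extract_patches",
    "stitch_patches",
    "augment",
    "preprocess",
    "preprocess_mask",
]


@dataclass
class PatchSet:
    """Ordered non-overlapping tiles of one image with grid coordinates.

    ``coords[k] = (row, col)`` is the 0-based grid index of ``patches[k]``;
    placement is defined by the coordinates, not by list order, so a
    permuted PatchSet still stitches back correctly.
    """

    patches: list[np.ndarray]
    coords: list[tuple[int, int]]
    source_size: tuple[int, int]
    patch_size: int

    def __len__(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class AugmentSpec:
    """Deterministic expansion spec: each patch yields itself (when
    ``keep_original``) plus one copy per op, in op order."""

    ops: tuple[str, ...] = ("rotate90", "hflip", "vflip")
    keep_original: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = {"rotate90", "hflip", "vflip"}
        bad = set(self.ops) - allowed
        if bad:
            raise ValueError(f"unknown augmentation ops: {sorted(bad)}")


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 512
    crop_threshold: float = 10.0
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 2.0
    gamma: float = 0.9
    nlm_strength: float = 10.0
    nlm_template_window: int = 7
    nlm_search_window: int = 21
    patch_size: int = 64


def crop_border(image: np.ndarray, threshold: float = 10.0) -> np.ndarray:
    """Crop the tight bounding box of pixels whose max-channel value
    exceeds ``threshold`` — removes the black frame around the field of
    view that raw fundus photographs carry."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = np.asarray(image, dtype=float)
    content = arr.max(axis=2) > threshold if arr.ndim == 3 else arr > threshold
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    if rows.size == 0:
        raise ValueError("image is entirely below the crop threshold")
    return image[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def resize(image: np.ndarray, size: tuple[int, int], *,
           order: int = 1) -> np.ndarray:
    """Resize to exactly ``size`` (H', W').  Bilinear (order=1) for images,
    nearest-neighbour (order=0) for masks so they stay binary."""
    h, w = size
    if h < 1 or w < 1:
        raise ValueError(f"target size must be positive, got {size}")
    arr = np.asarray(image, dtype=float)
    out = transform.resize(
        arr, (h, w) + arr.shape[2:], order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, R_MAX)


def extract_green(image: np.ndarray) -> np.ndarray:
    """Return the green channel (index 1 of r,g,b), the channel where
    microaneurysm/background contrast is highest."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {arr.shape}")
    return arr[..., 1].astype(float)


def apply_clahe(gray: np.ndarray, tiles: tuple[int, int] = (8, 8),
                clip_limit: float = 2.0) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an (8, 8) grid
    of non-overlapping tiles with bilinear inter-tile blending.

    ``clip_limit`` follows the common histogram-count convention (default
    2.0); it is normalized by the 256-bin histogram internally.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    arr = np.asarray(gray, dtype=float)
    if arr.ndim != 2:
        raise ValueError("apply_clahe expects a single-channel image")
    if arr.max() == arr.min():
        return arr.copy()  # no contrast to stretch
    nbins = 256
    kernel = (max(1, arr.shape[0] // tiles[0]), max(1, arr.shape[1] // tiles[1]))
    out = exposure.equalize_adapthist(
        arr / R_MAX, kernel_size=kernel, clip_limit=clip_limit / nbins,
        nbins=nbins,
    )
    return out * R_MAX


def apply_gamma(gray: np.ndarray, gamma: float = 0.9,
                r_max: float = R_MAX) -> np.ndarray:
    """Power-law remap ``((R / R_max) ** gamma) * R_max`` pixelwise.

    gamma < 1 brightens (non-decreasing pixelwise), gamma = 1 is identity,
    and R_max is a fixed point for every gamma.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    arr = np.asarray(gray, dtype=float)
    return np.power(arr / r_max, gamma) * r_max


def denoise_nlm(gray: np.ndarray, strength: float = 10.0,
                template_window: int = 7, search_window: int = 21) -> np.ndarray:
    """Fast non-local-means denoising.

    ``strength`` is the filtering parameter h on the [0, 255] scale;
    ``template_window`` and ``search_window`` are odd full widths of the
    similarity patch and of the search neighbourhood.
    """
    if template_window % 2 == 0 or search_window % 2 == 0:
        raise ValueError("window sizes must be odd")
    if search_window <= template_window:
        raise ValueError("search_window must exceed template_window")
    arr = np.asarray(gray, dtype=float)
    out = restoration.denoise_nl_means(
        arr / R_MAX,
        h=strength / R_MAX,
        patch_size=template_window,
        patch_distance=(search_window - 1) // 2,
        fast_mode=True,
    )
    return np.clip(out * R_MAX, 0.0, R_MAX)


def extract_patches(image: np.ndarray, patch_size: int = 64) -> PatchSet:
    """Cut a non-overlapping ``patch_size`` grid in row-major order.

    A 512x512 image at P=64 yields the primary grid of 64 patches.
    Residual margins where P does not divide a dimension are dropped.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    p = patch_size
    if p > min(h, w):
        raise ValueError(f"patch_size {p} exceeds image size {(h, w)}")
    patches, coords = [], []
    for r in range(h // p):
        for c in range(w // p):
            patches.append(arr[r * p:(r + 1) * p, c * p:(c + 1) * p].copy())
            coords.append((r, c))
    return PatchSet(patches=patches, coords=coords, source_size=(h, w),
                    patch_size=p)


def stitch_patches(patchset: PatchSet) -> np.ndarray:
    """Reassemble a full image from a PatchSet; exact inverse of
    ``extract_patches`` when the patch size divides both dimensions."""
    p = patchset.patch_size
    h, w = patchset.source_size
    n_rows, n_cols = h // p, w // p
    expected = {(r, c) for r in range(n_rows) for c in range(n_cols)}
    got = set(patchset.coords)
    missing = expected - got
    if missing:
        raise ValueError(f"missing patches at grid coords {sorted(missing)}")
    sample = np.asarray(patchset.patches[0])
    out = np.zeros((n_rows * p, n_cols * p) + sample.shape[2:], dtype=sample.dtype)
    for patch, (r, c) in zip(patchset.patches, patchset.coords):
        out[r * p:(r + 1) * p, c * p:(c + 1) * p] = patch
    return out


_AUG_FUNCS = {
    "rotate90": lambda a: np.rot90(a),
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1, :],
}


def augment(patches: PatchSet, masks: PatchSet,
            spec: AugmentSpec = AugmentSpec()) -> tuple[PatchSet, PatchSet]:
    """Expand aligned image/mask patches by the spec's geometric ops.

    Every op is applied to every patch (deterministic expansion), and
    identically to the paired mask, so the default three-op spec turns N
    pairs into 4N — e.g. 4096 training patches into 16384.
    """
    if len(patches) != len(masks):
        raise ValueError(
            f"patches ({len(patches)}) and masks ({len(masks)}) misaligned"
        )
    out_p, out_m, out_c = [], [], []
    for img, msk, coord in zip(patches.patches, masks.patches, patches.coords):
        variants = [(img, msk)] if spec.keep_original else []
        for op in spec.ops:
            f = _AUG_FUNCS[op]
            variants.append((f(img).copy(), f(msk).copy()))
        for vi, vm in variants:
            out_p.append(vi)
            out_m.append(vm)
            out_c.append(coord)
    aug_p = PatchSet(out_p, out_c, patches.source_size, patches.patch_size)
    aug_m = PatchSet(out_m, out_c, masks.source_size, masks.patch_size)
    return aug_p, aug_m


def preprocess(image: np.ndarray,
               config: PreprocessConfig = PreprocessConfig(),
               *, log: list | None = None) -> np.ndarray:
    """Run the full six-stage chain on one RGB fundus image.

    Returns the denoised single-channel ``target_size`` image in
    [0, 255].  ``log``, if given, records stage names in execution order.
    """

    def note(stage: str) -> None:
        if log is not None:
            log.append(stage)

    out = crop_border(image, config.crop_threshold)
    note("crop")
    out = resize(out, (config.target_size, config.target_size))
    note("resize")
    out = extract_green(out)
    note("green")
    out = apply_clahe(out, config.clahe_tiles, config.clahe_clip)
    note("clahe")
    out = apply_gamma(out, config.gamma)
    note("gamma")
    out = denoise_nlm(out, config.nlm_strength, config.nlm_template_window,
                      config.nlm_search_window)
    note("nlm")
    return out


def preprocess_mask(mask: np.ndarray,
                    config: PreprocessConfig = PreprocessConfig(),
                    *, crop_like: np.ndarray | None = None) -> np.ndarray:
    """Bring a binary mask through the same geometry as its image:
    crop to the image's content box, nearest-neighbour resize, then
    re-threshold at 0.5 to restore binarity."""
    m = np.asarray(mask, dtype=float)
    if crop_like is not None:
        arr = np.asarray(crop_like, dtype=float)
        content = arr.max(axis=2) > config.crop_threshold if arr.ndim == 3 \
            else arr > config.crop_threshold
        rows = np.flatnonzero(content.any(axis=1))
        cols = np.flatnonzero(content.any(axis=0))
        m = m[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    m = resize(m * R_MAX, (config.target_size, config.target_size), order=0)
    return (m / R_MAX > 0.5).astype(np.uint8)
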