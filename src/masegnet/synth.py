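"""Seeded synthetic fundus images with ground-truth microaneurysm masks.

Real microaneurysms are tiny (15-60 um, a handful of pixels at 512x512)
dark-red round blobs scattered sparsely over a textured orange background,
easily confused with the capillaries they bud from.  The generator emulates
exactly those statistics — a circular field of view on black, low-frequency
background texture with radial brightness falloff, curvilinear dark vessel
strokes as distractors, and sparse small circular lesions rendered with the
strongest contrast drop in the green channel — so every downstream stage
(green-channel selection, CLAHE, patching, training, pixel metrics) is
exercised meaningfully without any real dataset.

Vessels are deliberately NOT in the mask: only the lesion disks are
positive pixels, which reproduces the extreme class imbalance (well under
1% positive pixels at the defaults) that motivates patch-based training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SynthConfig", "generate_fundus", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic fundus image.

    Ranges are inclusive ``(low, high)`` tuples sampled uniformly per image.
    ``lesion_contrast`` is the fractional intensity drop of a lesion below
    its local background (0.1 = barely visible, 0.4 = prominent).
    """

    image_size: int = 512
    n_lesions: tuple[int, int] = (3, 20)
    lesion_radius: tuple[float, float] = (1.0, 4.0)
    lesion_contrast: tuple[float, float] = (0.1, 0.4)
    n_vessels: tuple[int, int] = (4, 10)
    vessel_width: tuple[float, float] = (2.0, 6.0)
    fov_radius_frac: float = 0.95
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError(
                f"image_size must be >= 64 (one patch); got {self.image_size}"
            )
        for name in ("n_lesions", "lesion_radius", "lesion_contrast",
                     "n_vessels", "vessel_width"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must be in (0, 1]")


def _fov_disk(size: int, radius: float) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _background(rng: np.random.Generator, size: int, radius: float) -> np.ndarray:
    """Reddish-orange base with low-frequency texture and radial falloff."""
    base = np.array([175.0, 95.0, 45.0])  # r, g, b means of a fundus photo
    img = np.empty((size, size, 3))
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) / max(radius, 1.0)
    falloff = 1.0 - 0.25 * np.clip(rho, 0.0, 1.0) ** 2
    for ch in range(3):
        texture = gaussian_filter(rng.standard_normal((size, size)), size / 16.0)
        texture *= 12.0 / max(texture.std(), 1e-9)
        img[..., ch] = (base[ch] + texture) * falloff
    return img


def _bezier_points(rng: np.random.Generator, size: int, radius: float,
                   n: int = 200) -> np.ndarray:
    """Sample points of a random quadratic Bezier stroke inside the disk."""
    c = (size - 1) / 2.0

    def rand_pt(rmax: float) -> np.ndarray:
        ang = rng.uniform(0, 2 * np.pi)
        r = rmax * np.sqrt(rng.uniform())
        return np.array([c + r * np.sin(ang), c + r * np.cos(ang)])

    p0 = rand_pt(radius * 0.95)
    p2 = rand_pt(radius * 0.95)
    p1 = rand_pt(radius * 0.7)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _stamp_disk(buf: np.ndarray, cy: float, cx: float, r: float) -> None:
    size = buf.shape[0]
    y0, y1 = max(0, int(cy - r) - 1), min(size, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(size, int(cx + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    hit = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    buf[y0:y1, x0:x1][hit] = 1.0


def generate_fundus(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one fundus-like image and its binary lesion mask.

    Returns
    -------
    image : uint8 array, shape (size, size, 3), RGB channel order
    mask : uint8 array, shape (size, size), 1 at lesion pixels, 0 elsewhere

    The same ``config`` (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    fov_radius = config.fov_radius_frac * (size / 2.0)
    fov = _fov_disk(size, fov_radius)

    img = _background(rng, size, fov_radius)

    # Vessels: darken all channels along quadratic Bezier strokes.
    n_vessels = int(rng.integers(config.n_vessels[0], config.n_vessels[1] + 1))
    vessel = np.zeros((size, size))
    for _ in range(n_vessels):
        width = rng.uniform(*config.vessel_width)
        pts = _bezier_points(rng, size, fov_radius)
        for cy, cx in pts:
            _stamp_disk(vessel, cy, cx, width / 2.0)
    vessel = gaussian_filter(vessel, 0.6)
    # vessels drop green the most, like real blood columns
    img[..., 0] *= 1.0 - 0.30 * vessel
    img[..., 1] *= 1.0 - 0.45 * vessel
    img[..., 2] *= 1.0 - 0.20 * vessel

    # Lesions: small disks, strongest drop in green; mask marks exactly them.
    mask = np.zeros((size, size))
    n_lesions = int(rng.integers(config.n_lesions[0], config.n_lesions[1] + 1))
    r_hi = config.lesion_radius[1]
    c = (size - 1) / 2.0
    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * r_hi + 3.0
    placed = 0
    attempts = 0
    while placed < n_lesions and attempts < 10000:
        attempts += 1
        ang = rng.uniform(0, 2 * np.pi)
        rr = (fov_radius - r_hi - 2.0) * np.sqrt(rng.uniform())
        cy, cx = c + rr * np.sin(ang), c + rr * np.cos(ang)
        if any((cy - py) ** 2 + (cx - px) ** 2 < min_sep**2 for py, px in centers):
            continue
        radius = rng.uniform(*config.lesion_radius)
        contrast = rng.uniform(*config.lesion_contrast)
        blob = np.zeros((size, size))
        _stamp_disk(blob, cy, cx, radius)
        mask[blob > 0] = 1.0
        img[..., 0] *= 1.0 - 0.5 * contrast * blob
        img[..., 1] *= 1.0 - contrast * blob
        img[..., 2] *= 1.0 - 0.3 * contrast * blob
        centers.append((cy, cx))
        placed += 1

    img += rng.normal(0.0, config.noise_sigma, img.shape)
    img[~fov] = 0.0
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, mask.astype(np.uint8)


def generate_dataset(
    n_train: int,
    n_test: int,
    config: SynthConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write ``n_train + n_test`` image/mask PNG pairs plus a JSON manifest.

    Image ``i`` is generated with seed ``config.seed + i`` so the dataset is
    reproducible pair-by-pair.  Refuses to clobber an existing manifest
    unless ``overwrite`` is set.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace"
        )
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    entries = []
    for i in range(n_train + n_test):
        cfg_i = SynthConfig(**{**asdict(config), "seed": config.seed + i})
        image, mask = generate_fundus(cfg_i)
        split = "train" if i < n_train else "test"
        image_id = f"{split}_{i:04d}"
        img_rel = f"images/{image_id}.png"
        mask_rel = f"masks/{image_id}.png"
        iio.imwrite(out_dir / img_rel, image)
        iio.imwrite(out_dir / mask_rel, (mask * 255).astype(np.uint8))
        entries.append(
            {"id": image_id, "image": img_rel, "mask": mask_rel,
             "split": split, "seed": cfg_i.seed}
        )

    manifest = {
        "n_train": n_train,
        "n_test": n_test,
        "image_size": config.image_size,
        "base_seed": config.seed,
        "entries": entries,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
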