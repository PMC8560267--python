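"""Synthetic brain-slice phantoms with tubular vessel structures.

Real cerebrovascular MRI exhibits bright, thin, curvilinear vessels over a
tissue-like background, corrupted by acquisition noise and a smooth intensity
inhomogeneity ("bias field").  The phantoms here emulate exactly those
features — random-walk tube centerlines of per-vessel constant radius, a broad
multiplicative Gaussian-bump bias field, and additive Gaussian noise — while
providing the exact ground-truth mask that patient data never has.

All intensities live on [0, 1].  Generation is bit-reproducible from
``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


class PhantomConfigError(ValueError):
    """Raised when a :class:`PhantomConfig` violates its invariants."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic brain-slice phantom.

    Parameters
    ----------
    image_size
        Pixels per side of the square image; at least 32.
    n_vessels
        Number of tubular structures drawn (may be 0 for a blank control).
    radius_range
        ``(min, max)`` tube radius in pixels; each vessel draws one constant
        radius uniformly from this range.
    vessel_intensity, background_intensity
        Foreground / background mean intensity on [0, 1]; must differ.
    noise_sigma
        Standard deviation of additive Gaussian noise.
    bias_amplitude
        Peak-to-peak amplitude of the smooth multiplicative bias field
        (0 disables it).
    seed
        RNG seed; identical config + seed gives a bit-identical phantom.
    """

    image_size: int = 64
    n_vessels: int = 3
    radius_range: tuple[float, float] = (2.0, 4.0)
    vessel_intensity: float = 0.8
    background_intensity: float = 0.3
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise PhantomConfigError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_vessels < 0:
            raise PhantomConfigError(f"n_vessels must be >= 0, got {self.n_vessels}")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise PhantomConfigError(f"radius_range must satisfy 0 < min <= max, got {self.radius_range}")
        if rmax >= self.image_size / 4:
            raise PhantomConfigError(
                f"radius_range max {rmax} must be < image_size/4 = {self.image_size / 4}"
            )
        if self.vessel_intensity == self.background_intensity:
            raise PhantomConfigError(
                "vessel_intensity must differ from background_intensity "
                f"(both are {self.vessel_intensity})"
            )
        if self.noise_sigma < 0:
            raise PhantomConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.bias_amplitude < 0:
            raise PhantomConfigError(f"bias_amplitude must be >= 0, got {self.bias_amplitude}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radius_range"] = list(self.radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "radius_range" in d:
            d["radius_range"] = tuple(d["radius_range"])
        return cls(**d)


@dataclass(frozen=True)
class Phantom:
    """One generated phantom: image, exact ground-truth mask and its config.

    ``tubes`` records the generating geometry — one ``(centerline, radius)``
    pair per vessel — so the mask can be verified independently.
    """

    image: np.ndarray  # float64 in [0, 1], shape (H, W)
    mask: np.ndarray  # uint8 in {0, 1}, shape (H, W)
    config: PhantomConfig
    tubes: tuple = ()

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


# Named difficulty presets: radius and noise control how hard the vessels are
# to separate from background.
PRESETS: dict[str, PhantomConfig] = {
    "easy": PhantomConfig(
        image_size=64,
        n_vessels=3,
        radius_range=(2.0, 4.0),
        vessel_intensity=0.8,
        background_intensity=0.3,
        noise_sigma=0.04,
        bias_amplitude=0.08,
    ),
    "medium": PhantomConfig(
        image_size=64,
        n_vessels=4,
        radius_range=(1.5, 3.0),
        vessel_intensity=0.7,
        background_intensity=0.35,
        noise_sigma=0.08,
        bias_amplitude=0.15,
    ),
    "hard": PhantomConfig(
        image_size=64,
        n_vessels=5,
        radius_range=(1.0, 2.0),
        vessel_intensity=0.6,
        background_intensity=0.4,
        noise_sigma=0.12,
        bias_amplitude=0.25,
    ),
}


def _random_walk_centerline(
    rng: np.random.Generator, size: int, n_steps: int, step: float = 1.0
) -> np.ndarray:
    """Smooth random-walk polyline staying inside the image.

    Heading evolves by small Gaussian turns, which yields gently curving tubes
    rather than jagged paths.
    """
    margin = 2.0
    pos = rng.uniform(margin, size - margin, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.25)
        delta = step * np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + delta
        # reflect off image borders
        for axis in (0, 1):
            if nxt[axis] < margin or nxt[axis] > size - margin:
                delta[axis] = -delta[axis]
                heading = np.arctan2(-np.sin(heading), np.cos(heading)) if axis == 1 else np.pi - heading
                nxt = pos + delta
        pos = np.clip(nxt, margin, size - margin)
        pts.append(pos.copy())
    return np.asarray(pts)


def _rasterize_tube(size: int, centerline: np.ndarray, radius: float) -> np.ndarray:
    """Binary mask of all pixels within ``radius`` of the polyline.

    Distance from every pixel center to each segment of the polyline, computed
    exactly via point-to-segment projection.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    pix = np.stack([yy.ravel(), xx.ravel()], axis=1)  # (P, 2)
    mindist = np.full(pix.shape[0], np.inf)
    a = centerline[:-1]
    b = centerline[1:]
    ab = b - a
    ab_len2 = np.einsum("ij,ij->i", ab, ab)
    for k in range(a.shape[0]):
        ap = pix - a[k]
        if ab_len2[k] < 1e-12:
            d2 = np.einsum("ij,ij->i", ap, ap)
        else:
            t = np.clip(ap @ ab[k] / ab_len2[k], 0.0, 1.0)
            proj = a[k] + t[:, None] * ab[k]
            diff = pix - proj
            d2 = np.einsum("ij,ij->i", diff, diff)
        np.minimum(mindist, d2, out=mindist)
    return (np.sqrt(mindist) <= radius).reshape(size, size)


def _bias_field(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative bias: 1 + broad Gaussian bump, peak-to-peak ``amplitude``."""
    if amplitude == 0:
        return np.ones((size, size))
    cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
    sigma = rng.uniform(0.4, 0.8) * size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    bump = (bump - bump.min()) / max(bump.max() - bump.min(), 1e-12)  # [0, 1]
    return 1.0 + amplitude * (bump - 0.5)


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate one phantom: ``image = bias × (background + vessels) + noise``.

    The mask marks every pixel whose center lies within a tube's radius of its
    centerline.  Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size

    mask = np.zeros((size, size), dtype=bool)
    rmin, rmax = config.radius_range
    tubes = []
    for _ in range(config.n_vessels):
        radius = rng.uniform(rmin, rmax)
        n_steps = int(rng.integers(size // 2, size))
        centerline = _random_walk_centerline(rng, size, n_steps)
        mask |= _rasterize_tube(size, centerline, radius)
        tubes.append((centerline, radius))

    clean = np.where(mask, config.vessel_intensity, config.background_intensity)
    bias = _bias_field(rng, size, config.bias_amplitude)
    image = bias * clean
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, mask=mask.astype(np.uint8), config=config, tubes=tuple(tubes))


def derive_seed(master_seed: int, index: int) -> int:
    """Per-image seed derived deterministically from a master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(
    config: PhantomConfig, n_images: int, seed: int | None = None, val_fraction: float = 0.25
) -> tuple[list[Phantom], dict[str, list[int]]]:
    """Generate ``n_images`` phantoms plus a train/validation index split.

    Per-image seeds derive from the master ``seed`` (default: ``config.seed``),
    so the whole dataset is reproducible from ``(config, seed)``.
    """
    if n_images < 1:
        raise PhantomConfigError(f"n_images must be >= 1, got {n_images}")
    master = config.seed if seed is None else seed
    phantoms = []
    for i in range(n_images):
        cfg_i = dataclasses.replace(config, seed=derive_seed(master, i))
        phantoms.append(generate_phantom(cfg_i))
    n_val = int(round(val_fraction * n_images))
    split = {"train": list(range(n_images - n_val)), "val": list(range(n_images - n_val, n_images))}
    return phantoms, split


def save_phantom(phantom: Phantom, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write image (16-bit PNG), mask (8-bit 0/255 PNG) and a JSON sidecar."""
    from vesselseg.io import write_image, write_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}_image.png",
        "mask": out_dir / f"{stem}_mask.png",
        "sidecar": out_dir / f"{stem}.json",
    }
    write_image(phantom.image, paths["image"])
    write_mask(phantom.mask, paths["mask"])
    paths["sidecar"].write_text(json.dumps(phantom.config.to_dict(), indent=2) + "\n")
    return paths
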