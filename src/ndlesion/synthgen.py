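"""Seeded dermoscopy-like phantom generator with exact ground truth.

Phantoms emulate the hard cases of lesion border detection: a roughly
uniform skin-colored background with per-channel Gaussian noise, one
darker lesion blob with an irregular, optionally fuzzy (blurred) border,
optionally low lesion/skin contrast, and optional dark hair-like strokes
running from the lesion interior to an image edge.

The ground-truth mask is the lesion shape *before* blurring and noise, so
it is exact by construction and any evaluation error is attributable to
the segmentation, mirroring evaluation against crisp manually drawn
borders.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .img_io import BinaryMask, RGBImage, write_mask
from .preprocess import _LUMA

#: Difficulty presets: contrast is the ratio of the skin/lesion mean
#: luminance gap to the per-channel noise sigma.
PRESETS: dict[str, dict] = {
    "easy": dict(contrast=15.0, fuzziness=1.0, irregularity=0.25, n_hairs=0),
    "low-contrast": dict(
        lesion_color=(160, 114, 93),
        contrast=5.0,
        fuzziness=2.5,
        irregularity=0.35,
        n_hairs=0,
    ),
    "hairy": dict(contrast=15.0, fuzziness=1.0, irregularity=0.25, n_hairs=3),
}

_HAIR_COLOR = np.array([45.0, 32.0, 28.0])


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one phantom; identical configs render identically."""

    seed: int
    width: int = 96
    height: int = 96
    skin_color: tuple[int, int, int] = (224, 172, 138)
    lesion_color: tuple[int, int, int] = (96, 56, 48)
    contrast: float = 15.0  # luminance gap / noise sigma
    fuzziness: float = 1.0  # border blur radius, px
    irregularity: float = 0.25  # radial-harmonic amplitude, 0-1
    noise_sigma: float | None = None  # override; default derived from contrast
    n_hairs: int = 0
    hair_darkness: float = 0.75

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("phantom size must be at least 32x32")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        for c in (*self.skin_color, *self.lesion_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit RGB")

    @property
    def luminance_gap(self) -> float:
        skin = float(np.dot(self.skin_color, _LUMA))
        lesion = float(np.dot(self.lesion_color, _LUMA))
        return skin - lesion

    @property
    def sigma(self) -> float:
        return self.noise_sigma if self.noise_sigma is not None else self.luminance_gap / self.contrast


def make_lesion_shape(cfg: PhantomConfig) -> BinaryMask:
    """Star-shaped lesion mask r(θ) = r0·(1 + Σ_k a_k sin(kθ + φ_k)).

    Harmonics up to k = 8 with amplitudes scaled by ``irregularity``; the
    radius is clamped so the shape stays fully interior and its area lands
    in [5%, 60%] of the image for any irregularity in [0, 1].
    """
    rng = np.random.default_rng([cfg.seed, 0])
    w, h = cfg.width, cfg.height
    s = min(w, h)
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    r0 = s * rng.uniform(0.24, 0.30)
    ks = np.arange(2, 9)
    amps = cfg.irregularity * rng.uniform(-0.5, 0.5, ks.size) / ks
    phases = rng.uniform(0, 2 * np.pi, ks.size)

    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    theta = np.arctan2(dy, dx)
    rr = r0 * (1.0 + np.sum(amps[:, None, None] * np.sin(ks[:, None, None] * theta + phases[:, None, None]), axis=0))
    rr = np.clip(rr, 0.15 * s, 0.45 * s)
    mask = (dx * dx + dy * dy) <= rr * rr
    return BinaryMask(mask.astype(np.uint8), foreground_label="lesion")


def _draw_hairs(img: np.ndarray, mask: np.ndarray, cfg: PhantomConfig, rng) -> None:
    """Dark anti-aliased strokes from inside the lesion to an image edge."""
    h, w = img.shape[:2]
    inside = np.argwhere(mask > 0)
    for _ in range(cfg.n_hairs):
        y0, x0 = inside[rng.integers(len(inside))]
        edge = rng.integers(4)
        if edge == 0:
            x1, y1 = rng.integers(w), 0
        elif edge == 1:
            x1, y1 = rng.integers(w), h - 1
        elif edge == 2:
            x1, y1 = 0, rng.integers(h)
        else:
            x1, y1 = w - 1, rng.integers(h)
        # gentle quadratic bend via a perpendicular control-point offset
        mx, my = (x0 + x1) / 2, (y0 + y1) / 2
        nx, ny = -(y1 - y0), (x1 - x0)
        norm = np.hypot(nx, ny) or 1.0
        bend = rng.uniform(-0.15, 0.15) * norm
        px, py = mx + bend * nx / norm, my + bend * ny / norm
        t = np.linspace(0, 1, 24)
        bx = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * px + t**2 * x1
        by = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * py + t**2 * y1
        alpha = np.zeros((h, w))
        for i in range(len(t) - 1):
            rr, cc, val = line_aa(
                int(round(by[i])), int(round(bx[i])), int(round(by[i + 1])), int(round(bx[i + 1]))
            )
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            alpha[rr[keep], cc[keep]] = np.maximum(alpha[rr[keep], cc[keep]], val[keep])
        a = (cfg.hair_darkness * alpha)[..., None]
        img[:] = (1 - a) * img + a * _HAIR_COLOR


def render_phantom(cfg: PhantomConfig) -> tuple[RGBImage, BinaryMask]:
    """Render one phantom; returns the image and its exact pre-blur mask."""
    truth = make_lesion_shape(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    img = np.empty((cfg.height, cfg.width, 3), np.float64)
    img[:] = cfg.skin_color
    img[truth.data > 0] = cfg.lesion_color
    if cfg.fuzziness > 0:
        img = gaussian_filter(img, sigma=(cfg.fuzziness, cfg.fuzziness, 0))
    if cfg.n_hairs > 0:
        _draw_hairs(img, truth.data, cfg, rng)
    if cfg.sigma > 0:
        img = img + rng.normal(0.0, cfg.sigma, img.shape)
    return RGBImage(np.clip(np.rint(img), 0, 255).astype(np.uint8)), truth


def make_suite(
    n: int, base_seed: int, difficulty: str = "easy", **overrides
) -> tuple[list[tuple[RGBImage, BinaryMask]], list[PhantomConfig]]:
    """Generate n phantoms with per-item seeds base_seed + i."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in PRESETS:
        raise ValueError(f"unknown difficulty {difficulty!r}; options: {sorted(PRESETS)}")
    preset = {**PRESETS[difficulty], **overrides}
    configs = [PhantomConfig(seed=base_seed + i, **preset) for i in range(n)]
    return [render_phantom(c) for c in configs], configs


def write_suite(
    out_dir: str | Path,
    pairs: list[tuple[RGBImage, BinaryMask]],
    configs: list[PhantomConfig],
) -> Path:
    """Write images, truth masks and a regeneration manifest; returns manifest path."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ((img, mask), cfg) in enumerate(zip(pairs, configs)):
        img_name, mask_name = f"phantom_{i:03d}.png", f"truth_{i:03d}.png"
        Image.fromarray(img.pixels).save(out / img_name)
        write_mask(mask, out / mask_name)
        entries.append(
            {"image": img_name, "truth": mask_name, "config": dataclasses.asdict(cfg)}
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"items": entries}, indent=2))
    return manifest


def suite_from_manifest(manifest_path: str | Path) -> tuple[list[tuple[RGBImage, BinaryMask]], list[PhantomConfig]]:
    """Regenerate a suite exactly from its manifest."""
    listing = json.loads(Path(manifest_path).read_text())
    configs = []
    for item in listing["items"]:
        d = dict(item["config"])
        for key in ("skin_color", "lesion_color"):
            d[key] = tuple(d[key])
        configs.append(PhantomConfig(**d))
    return [render_phantom(c) for c in configs], configs
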