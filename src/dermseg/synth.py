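"""Synthetic dermoscopy-like images with exact ground-truth masks.

Real dermoscopy lesions are darker, roughly elliptical-but-irregular
regions on lighter skin, with a smooth intensity gradient ("fuzzy")
border, sensor noise, and frequently thin dark hairs crossing the field
of view.  The generator emulates exactly these features with a
star-convex radial model

    r(θ) = e(θ) · (1 + w(θ)),

where e(θ) is an ellipse radius (semi-axes a, b, rotated by
``axis_angle``) and w(θ) a bounded mixture of up to five seeded
sinusoids, so the exact lesion mask {dist ≤ r(θ)} is computable
analytically per pixel.  The ground truth is defined pre-noise and
pre-hair: the "manual border" outlines the lesion, not the artifacts.

Defaults produce a 160×160 image with a 45×35-pixel lesion, a luminance
contrast of about 120 gray levels and mild noise (σ=5) — an easy,
high-contrast specimen of the kind benchmark tables are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import BinaryMask, RasterImage

__all__ = [
    "SynthConfig",
    "PRESETS",
    "preset_config",
    "generate_lesion",
    "generate_binary_blobs",
    "random_mask",
]


@dataclass(frozen=True)
class SynthConfig:
    shape: tuple[int, int] = (160, 160)
    lesion_center: tuple[float, float] = (80.0, 80.0)
    lesion_axes: tuple[float, float] = (45.0, 35.0)
    axis_angle: float = 0.4  # radians
    boundary_irregularity: float = 4.0  # radial sinusoid amplitude, pixels
    edge_softness: float = 8.0  # border gradient width, pixels
    lesion_color: tuple[int, int, int] = (70, 40, 30)
    skin_color: tuple[int, int, int] = (200, 160, 140)
    noise_sd: float = 5.0  # per-channel Gaussian std
    n_hairs: int = 0
    hair_width: float = 2.0
    hair_color: tuple[int, int, int] = (30, 25, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for color in (self.lesion_color, self.skin_color, self.hair_color):
            if any(not 0 <= v <= 255 for v in color):
                raise ValueError("colors must be valid RGB triples")
        h, w = self.shape
        cy, cx = self.lesion_center
        a, b = self.lesion_axes
        reach = max(a, b) * (1.0 + self.boundary_irregularity / min(a, b)) + self.edge_softness
        if (
            cy - reach < 0 or cx - reach < 0
            or cy + reach > h - 1 or cx + reach > w - 1
        ):
            raise ValueError(
                "lesion (axes + irregularity) must fit inside the image with "
                "at least edge_softness margin"
            )


PRESETS: dict[str, dict] = {
    # high contrast, mild noise, gentle boundary — the benchmark regime
    "easy": dict(boundary_irregularity=4.0, edge_softness=8.0, noise_sd=5.0, n_hairs=0),
    # wide intensity gradient and stronger irregularity/noise
    "fuzzy": dict(boundary_irregularity=8.0, edge_softness=18.0, noise_sd=8.0, n_hairs=0),
    # easy lesion plus dark hair strokes crossing the field
    "hairy": dict(boundary_irregularity=4.0, edge_softness=8.0, noise_sd=5.0, n_hairs=4),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(SynthConfig(seed=seed), **{**PRESETS[name], **overrides})


def _boundary_radius(cfg: SynthConfig, rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    a, b = cfg.lesion_axes
    ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if cfg.boundary_irregularity > 0:
        n_modes = int(rng.integers(2, 6))  # up to 5 sinusoids
        amps = rng.random(n_modes)
        amps *= cfg.boundary_irregularity / max(amps.sum(), 1e-12)
        freqs = rng.integers(2, 8, size=n_modes)
        phases = rng.random(n_modes) * 2 * np.pi
        wobble = sum(
            amp * np.sin(f * theta + ph) for amp, f, ph in zip(amps, freqs, phases)
        )
        ellipse = ellipse * (1.0 + wobble / min(a, b))
    return ellipse


def generate_lesion(cfg: SynthConfig | None = None) -> tuple[RasterImage, BinaryMask]:
    """Render one synthetic lesion image and its exact ground-truth mask.

    Fully reproducible for a fixed config (all randomness flows from
    ``cfg.seed``).  The mask is the pre-noise, pre-hair star-convex
    region; the image blends lesion over skin color linearly across
    ``edge_softness`` pixels, then adds hairs and clipped Gaussian
    noise.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    cy, cx = cfg.lesion_center

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    # rotate into the lesion frame
    ca, sa = np.cos(cfg.axis_angle), np.sin(cfg.axis_angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    dist = np.hypot(u, v)
    theta = np.arctan2(v, u)
    r_bound = _boundary_radius(cfg, rng, theta)

    mask = dist <= r_bound

    if cfg.edge_softness > 0:
        alpha = np.clip((r_bound - dist) / cfg.edge_softness + 0.5, 0.0, 1.0)
    else:
        alpha = mask.astype(np.float64)
    lesion = np.asarray(cfg.lesion_color, dtype=np.float64)
    skin = np.asarray(cfg.skin_color, dtype=np.float64)
    img = skin[None, None, :] + alpha[:, :, None] * (lesion - skin)[None, None, :]

    for _ in range(cfg.n_hairs):
        _draw_hair(img, cfg, rng)

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RasterImage(img), BinaryMask(mask)


def _draw_hair(img: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> None:
    """Paint one dark quadratic Bézier stroke spanning the image.

    Endpoints sit on opposite image borders so a typical hair crosses
    the (centered) lesion, the configuration in which hairs show up as
    false positives of a lesion segmenter.
    """
    h, w = img.shape[:2]
    if rng.random() < 0.5:  # left-right hair
        p0 = np.array([rng.uniform(0.2 * h, 0.8 * h), 0.0])
        p2 = np.array([rng.uniform(0.2 * h, 0.8 * h), w - 1.0])
    else:  # top-bottom hair
        p0 = np.array([0.0, rng.uniform(0.2 * w, 0.8 * w)])
        p2 = np.array([h - 1.0, rng.uniform(0.2 * w, 0.8 * w)])
    mid = 0.5 * (p0 + p2)
    p1 = mid + rng.uniform(-0.15, 0.15, size=2) * np.array([h, w])

    t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    radius = cfg.hair_width / 2.0
    color = np.asarray(cfg.hair_color, dtype=np.float64)
    rr = np.rint(pts[:, 0]).astype(int)
    cc = np.rint(pts[:, 1]).astype(int)
    r_int = max(int(np.ceil(radius)), 0)
    stencil = [
        (dr, dc)
        for dr in range(-r_int, r_int + 1)
        for dc in range(-r_int, r_int + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    for dr, dc in stencil:
        r2 = np.clip(rr + dr, 0, h - 1)
        c2 = np.clip(cc + dc, 0, w - 1)
        img[r2, c2] = color


def generate_binary_blobs(
    shape: tuple[int, int],
    blob_specs: Sequence[tuple],
    seed: int | None = None,
) -> BinaryMask:
    """Union of exact solid shapes, as unit-test fixtures for clustering.

    Each spec is ``("disc", (row, col), radius)`` or
    ``("rect", (top, left), (height, width))``.  ``seed`` is accepted
    for interface symmetry; the shapes themselves are deterministic.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    rows, cols = np.mgrid[0:h, 0:w]
    for spec in blob_specs:
        kind = spec[0]
        if kind == "disc":
            (cy, cx), radius = spec[1], spec[2]
            mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
        elif kind == "rect":
            (top, left), (bh, bw) = spec[1], spec[2]
            mask[top : top + bh, left : left + bw] = True
        else:
            raise ValueError(f"unknown blob kind {kind!r}")
    return BinaryMask(mask)


def random_mask(
    shape: tuple[int, int], density: float, seed: int
) -> BinaryMask:
    """Bernoulli(density) random mask — raw material for property tests."""
    rng = np.random.default_rng(seed)
    return BinaryMask(rng.random(shape) < density)
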