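"""Deterministic synthetic phantoms emulating complementary imaging modalities.

Real multimodal pairs (e.g. CT + MR brain slices) share anatomy but highlight
disjoint structures: CT shows the dense skull rim and calcifications as bright
sharp regions on a dark, nearly featureless interior; MR shows smoothly
textured soft tissue inside a dark rim. The generators here reproduce exactly
that complementarity on a shared head geometry:

* ``ct_like`` — piecewise-constant: bright ring (skull) plus a few sharp dense
  blobs over a faint uniform interior. Salient gradients live on the rim and
  blob boundaries.
* ``mr_like`` — smooth interior built from low-frequency Gaussian bumps and an
  oriented sinusoidal texture, tapering to a dark rim. Salient gradients live
  in the interior texture.

Both modes share the same seed-derived head geometry, so a pair is
co-registered by construction and zero outside the common support disk.
Additive Gaussian noise (clipped to [0, 255]) is applied inside the support
only, mimicking atlas images with masked air. Everything is a pure function of
the spec: the RNG is numpy's PCG64 seeded from ``(seed, stream)`` tuples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_pair",
    "support_mask",
    "fixture_suite",
]

MODES = ("ct_like", "mr_like")

# stream tags separating geometry and per-mode noise draws
_GEOMETRY_STREAM = 101
_NOISE_STREAM = {"ct_like": 201, "mr_like": 202}


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one phantom image."""

    size: int = 128
    seed: int = 0
    mode: str = "ct_like"
    noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"phantom size must be >= 32, got {self.size}")
        if self.mode not in MODES:
            raise ValueError(f"unknown phantom mode {self.mode!r}; choose from {MODES}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def _geometry(seed: int, size: int) -> dict:
    """Seed-derived head layout shared by both modalities of a pair."""
    rng = np.random.default_rng([int(seed), _GEOMETRY_STREAM])
    cx = size / 2.0 + rng.uniform(-0.02, 0.02) * size
    cy = size / 2.0 + rng.uniform(-0.02, 0.02) * size
    r_out = 0.42 * size * rng.uniform(0.97, 1.03)
    ring_w = 0.055 * size
    n_blobs = int(rng.integers(3, 6))
    blob_r_in = r_out - ring_w
    blobs = []
    for _ in range(n_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.1, 0.6) * blob_r_in
        radius = rng.uniform(0.02, 0.045) * size
        blobs.append((cy + rad * np.sin(ang), cx + rad * np.cos(ang), radius))
    n_bumps = int(rng.integers(4, 8))
    bumps = []
    for _ in range(n_bumps):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.55) * blob_r_in
        sigma = rng.uniform(0.08, 0.18) * size
        amp = rng.uniform(30.0, 60.0) * rng.choice([-1.0, 1.0])
        bumps.append((cy + rad * np.sin(ang), cx + rad * np.cos(ang), sigma, amp))
    texture_angle = rng.uniform(0, np.pi)
    texture_wavelength = rng.uniform(7.0, 13.0)
    texture_phase = rng.uniform(0, 2 * np.pi)
    return {
        "cx": cx,
        "cy": cy,
        "r_out": r_out,
        "ring_w": ring_w,
        "blobs": blobs,
        "bumps": bumps,
        "texture_angle": texture_angle,
        "texture_wavelength": texture_wavelength,
        "texture_phase": texture_phase,
    }


def support_mask(seed: int, size: int) -> np.ndarray:
    """Boolean head-support disk shared by both modalities of a pair."""
    geo = _geometry(seed, size)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    r = np.hypot(yy - geo["cy"], xx - geo["cx"])
    return r <= geo["r_out"]


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom as an 8-bit grayscale image."""
    geo = _geometry(spec.seed, spec.size)
    size = spec.size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    r = np.hypot(yy - geo["cy"], xx - geo["cx"])
    support = r <= geo["r_out"]
    r_in = geo["r_out"] - geo["ring_w"]

    img = np.zeros((size, size), dtype=np.float64)
    if spec.mode == "ct_like":
        img[support] = 40.0  # faint uniform interior tissue
        ring = (r >= r_in) & support
        img[ring] = 230.0
        for by, bx, radius in geo["blobs"]:
            blob = np.hypot(yy - by, xx - bx) <= radius
            img[blob & support] = 255.0
    else:  # mr_like
        soft = np.full((size, size), 120.0)
        for by, bx, sigma, amp in geo["bumps"]:
            soft += amp * np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sigma**2))
        k = 2 * np.pi / geo["texture_wavelength"]
        phase = k * (
            np.cos(geo["texture_angle"]) * xx + np.sin(geo["texture_angle"]) * yy
        )
        # texture confined to the deep interior so its gradients stay clear
        # of the rim where the CT phantom is salient
        taper = _smoothstep((r_in * 0.9 - r) / (0.15 * r_in))
        soft += 22.0 * np.sin(phase + geo["texture_phase"]) * taper
        # smooth fade from soft tissue down to the dark rim value
        rim_fade = _smoothstep((r_in - r) / (0.12 * size))
        img = np.where(support, 18.0 + (soft - 18.0) * rim_fade, 0.0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng([int(spec.seed), _NOISE_STREAM[spec.mode]])
        noise = rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = img + np.where(support, noise, 0.0)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_pair(
    seed: int, size: int = 128, noise_sigma: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Co-registered (ct_like, mr_like) phantom pair sharing one head layout."""
    ct = make_phantom(PhantomSpec(size=size, seed=seed, mode="ct_like", noise_sigma=noise_sigma))
    mr = make_phantom(PhantomSpec(size=size, seed=seed, mode="mr_like", noise_sigma=noise_sigma))
    return ct, mr


def fixture_suite(size: int = 32) -> dict[str, np.ndarray]:
    """Named degenerate images exercising edge cases of every stage.

    ``size`` must be divisible by 4 so the level fractions are exact.
    """
    if size % 4 != 0 or size < 4:
        raise ValueError(f"fixture size must be a positive multiple of 4, got {size}")
    shape = (size, size)
    yy, xx = np.mgrid[0:size, 0:size]

    single = np.zeros(shape, dtype=np.uint8)
    single[size // 2, size // 2] = 255

    half01 = np.zeros(shape, dtype=np.uint8)
    half01[:, size // 2 :] = 255

    levels = np.array([0, 85, 170, 255], dtype=np.uint8)
    uniform4 = levels[(xx // (size // 4)) % 4].astype(np.uint8)

    checker = (((yy + xx) % 2) * 255).astype(np.uint8)

    return {
        "const0": np.zeros(shape, dtype=np.uint8),
        "const128": np.full(shape, 128, dtype=np.uint8),
        "const255": np.full(shape, 255, dtype=np.uint8),
        "single_pixel": single,
        "half01": half01,
        "uniform4": uniform4,
        "checkerboard": checker,
    }
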