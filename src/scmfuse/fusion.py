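"""Local-energy-gated weighted fusion of two co-registered grayscale images.

The fused intensity at each pixel is a convex combination of the two source
intensities. The *gate* is the local energy of the firing-mapping images (the
patch sum of squared firing times): the source with larger local energy is
considered dominant. The *weight* ``omega`` is the product of the entropy
similarity and the WLD similarity of the two SCM responses; the dominant
source receives weight ``omega`` (close to 1 where the patches agree) and the
other source the complement::

    U = omega * I_A + (1 - omega) * I_B   where E_A >  E_B
    U = (1 - omega) * I_A + omega * I_B   where E_A <= E_B

Fusion arithmetic runs on the original 8-bit intensity scale; the SCM itself
consumes the normalized copy. Output stays floating point and is quantized to
8 bits only on save.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import (
    PatchSpec,
    SimilarityConstants,
    SimilarityMap,
    differential_excitation,
    entropy_similarity,
    patch_entropy_series,
    wld_similarity,
)
from .scm import ScmParams, firing_map, normalize_image, run_scm
from scipy import ndimage

__all__ = [
    "FusionConfig",
    "FusionResult",
    "local_energy",
    "combine_weights",
    "fuse_pixels",
    "scm_m_fuse",
    "scm_m_fuse_detailed",
    "quantize_to_u8",
]

_PAD_MODE = "reflect"


@dataclass(frozen=True)
class FusionConfig:
    """Complete parameter set of one fusion run; drives both SCMs identically.

    If ``constants`` is None, the defaults tied to ``scm.n_max``
    (``cs1 = 3*n_max``, ``cs2 = 5*pi``) are used.
    """

    scm: ScmParams = field(default_factory=ScmParams)
    patch: PatchSpec = field(default_factory=PatchSpec)
    constants: Optional[SimilarityConstants] = None

    def resolved_constants(self) -> SimilarityConstants:
        if self.constants is not None:
            return self.constants
        return SimilarityConstants.defaults(self.scm.n_max)


@dataclass
class FusionResult:
    """Fused image plus the intermediate fields, for inspection and debugging."""

    fused: np.ndarray
    weights: np.ndarray
    energy_a: np.ndarray
    energy_b: np.ndarray
    firing_a: np.ndarray
    firing_b: np.ndarray
    s_entropy: np.ndarray
    s_wld: np.ndarray
    pulses_a: np.ndarray
    pulses_b: np.ndarray


def local_energy(fmap: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Patch sum of squared firing times (mirror-padded at borders).

    Nonnegative; zero exactly where every firing time in the patch is zero.
    """
    T = np.asarray(fmap, dtype=np.float64)
    if T.ndim != 2:
        raise ValueError(f"firing map must be 2-D, got shape {T.shape}")
    kernel = np.ones((spec.side, spec.side), dtype=np.float64)
    return ndimage.correlate(T * T, kernel, mode=_PAD_MODE)


def combine_weights(s_en: SimilarityMap, s_wld: SimilarityMap) -> np.ndarray:
    """Fusion weight ``omega = S_En * S_WLD`` (pointwise product)."""
    if s_en.kind != "entropy" or s_wld.kind != "wld":
        raise ValueError(
            f"expected kinds ('entropy', 'wld'), got ({s_en.kind!r}, {s_wld.kind!r})"
        )
    if s_en.values.shape != s_wld.values.shape:
        raise ValueError(
            f"similarity map shapes differ: {s_en.values.shape} vs {s_wld.values.shape}"
        )
    return s_en.values * s_wld.values


def fuse_pixels(
    image_a: np.ndarray,
    image_b: np.ndarray,
    energy_a: np.ndarray,
    energy_b: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Apply the energy-gated weighted fusion rule pixelwise.

    Where ``E_A > E_B`` the fused value is ``w*I_A + (1-w)*I_B``; on the tie
    and where ``E_A <= E_B`` it is ``(1-w)*I_A + w*I_B``. Returned in floating
    point on the input intensity scale.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    shapes = {a.shape, b.shape, np.shape(energy_a), np.shape(energy_b), np.shape(weights)}
    if len(shapes) != 1:
        raise ValueError(f"all five grids must share one shape, got {shapes}")
    w = np.asarray(weights, dtype=np.float64)
    a_dominant = np.asarray(energy_a) > np.asarray(energy_b)
    return np.where(a_dominant, w * a + (1.0 - w) * b, (1.0 - w) * a + w * b)


def quantize_to_u8(values: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to [0, 255]."""
    v = np.asarray(values, dtype=np.float64)
    rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def scm_m_fuse_detailed(
    image_a: np.ndarray, image_b: np.ndarray, config: Optional[FusionConfig] = None
) -> FusionResult:
    """Run the full SCM-M pipeline, returning all intermediate fields.

    Steps: (1) run the SCM on both normalized sources; (2) entropy feature
    fields and entropy similarity; (3) firing maps, local energies,
    differential excitations and WLD similarity; (4) combined weight;
    (5) energy-gated weighted fusion. Deterministic.
    """
    config = config or FusionConfig()
    a = np.asarray(image_a)
    b = np.asarray(image_b)
    if a.shape != b.shape:
        raise ValueError(f"source image shapes differ: {a.shape} vs {b.shape}")

    oa = normalize_image(a)
    ob = normalize_image(b)
    pulses_a = run_scm(oa, config.scm)
    pulses_b = run_scm(ob, config.scm)

    constants = config.resolved_constants()
    va = patch_entropy_series(pulses_a, config.patch)
    vb = patch_entropy_series(pulses_b, config.patch)
    s_en = entropy_similarity(va, vb, constants)

    ta = firing_map(pulses_a)
    tb = firing_map(pulses_b)
    ea = local_energy(ta, config.patch)
    eb = local_energy(tb, config.patch)
    xa = differential_excitation(ta, config.patch)
    xb = differential_excitation(tb, config.patch)
    s_wld = wld_similarity(xa, xb, constants)

    w = combine_weights(s_en, s_wld)
    fused = fuse_pixels(a.astype(np.float64), b.astype(np.float64), ea, eb, w)
    return FusionResult(
        fused=fused,
        weights=w,
        energy_a=ea,
        energy_b=eb,
        firing_a=ta,
        firing_b=tb,
        s_entropy=s_en.values,
        s_wld=s_wld.values,
        pulses_a=pulses_a,
        pulses_b=pulses_b,
    )


def scm_m_fuse(
    image_a: np.ndarray, image_b: np.ndarray, config: Optional[FusionConfig] = None
) -> np.ndarray:
    """Fuse two co-registered 8-bit grayscale images; returns the float image."""
    return scm_m_fuse_detailed(image_a, image_b, config).fused
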