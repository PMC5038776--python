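"""Per-pixel similarity features driving the fusion weight.

Two complementary patch descriptors are extracted from the SCM outputs of the
two source images:

* **Entropy feature** — for every pixel and iteration, the binary Shannon
  entropy of the (2*l_p*+1)² patch of the pulse image; across iterations these
  form a feature vector describing the local gray-level distribution. The
  entropy similarity is ``S_En = 1 - ||V_A - V_B|| / CS1``.
* **WLD differential excitation** — the salience component of the Weber local
  descriptor applied to the firing-mapping image:
  ``xi = arctan(sum_patch(T_neighbor - T_center) / T_center)``, a
  Laplacian-like ratio bounded by the arctangent. The WLD similarity is
  ``S_WLD = 1 - |xi_A - xi_B| / CS2``.

All patch operations use symmetric (mirror) padding at the borders so that
homogeneous regions stay exactly homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PatchSpec",
    "SimilarityConstants",
    "SimilarityMap",
    "patch_entropy_series",
    "entropy_similarity",
    "differential_excitation",
    "wld_similarity",
]

#: denominator floor for zero-firing centres in the differential excitation
WLD_EPS = 1e-6

_PAD_MODE = "reflect"  # scipy's 'reflect' == numpy's 'symmetric' (edge repeated)


@dataclass(frozen=True)
class PatchSpec:
    """Square patch geometry: half-width ``l_p``, side ``2*l_p + 1``."""

    l_p: int = 1

    def __post_init__(self) -> None:
        if self.l_p < 1:
            raise ValueError(f"patch half-width l_p must be >= 1, got {self.l_p}")

    @property
    def side(self) -> int:
        return 2 * self.l_p + 1

    @property
    def area(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class SimilarityConstants:
    """Normalizers of the two similarity maps.

    ``cs1`` divides the Euclidean distance between entropy feature vectors,
    ``cs2`` divides the absolute differential-excitation difference. The
    defaults tie them to the iteration count: ``cs1 = 3 * n_max`` and
    ``cs2 = 5 * pi``, which bound the similarities to roughly (0.92, 1] and
    (0.8, 1] respectively.
    """

    cs1: float
    cs2: float

    def __post_init__(self) -> None:
        if self.cs1 <= 0 or self.cs2 <= 0:
            raise ValueError("similarity normalizers cs1, cs2 must be positive")

    @classmethod
    def defaults(cls, n_max: int) -> "SimilarityConstants":
        return cls(cs1=3.0 * n_max, cs2=5.0 * np.pi)


@dataclass(frozen=True)
class SimilarityMap:
    """A per-pixel similarity field tagged by its origin ('entropy' or 'wld')."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("entropy", "wld"):
            raise ValueError(f"unknown similarity kind {self.kind!r}")


def _patch_sum(field: np.ndarray, spec: PatchSpec) -> np.ndarray:
    kernel = np.ones((spec.side, spec.side), dtype=np.float64)
    return ndimage.correlate(field, kernel, mode=_PAD_MODE)


def binary_entropy(p1: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of a Bernoulli(p1) source, with 0*log2(0) = 0."""
    p1 = np.asarray(p1, dtype=np.float64)
    p0 = 1.0 - p1
    out = np.zeros_like(p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(p1 > 0, -p1 * np.log2(np.where(p1 > 0, p1, 1.0)), 0.0)
        term0 = np.where(p0 > 0, -p0 * np.log2(np.where(p0 > 0, p0, 1.0)), 0.0)
    out = term1 + term0
    return out


def patch_entropy_series(pulses: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Per-pixel, per-iteration binary patch entropy of a pulse series.

    For every pixel and iteration ``n``, count the ones ``K`` in the
    surrounding patch of the binary pulse image, set ``P1 = K / area`` and
    return the binary Shannon entropy in bits. Output shape ``(n_max, H, W)``
    with every entry in [0, 1]; homogeneous patches give exactly 0.
    """
    arr = np.asarray(pulses)
    if arr.ndim != 3:
        raise ValueError(f"expected pulse stack (n, H, W), got shape {arr.shape}")
    out = np.empty(arr.shape, dtype=np.float64)
    for n in range(arr.shape[0]):
        counts = np.rint(_patch_sum(arr[n].astype(np.float64), spec))
        out[n] = binary_entropy(counts / spec.area)
    return out


def entropy_similarity(
    field_a: np.ndarray, field_b: np.ndarray, constants: SimilarityConstants
) -> SimilarityMap:
    """Entropy-based patch similarity ``S_En = 1 - ||V_A - V_B||_2 / cs1``.

    The per-pixel feature vectors are the entropy series along the iteration
    axis; their Euclidean distance is divided by ``cs1``. No clamping is
    applied: with default constants the values lie in
    ``[1 - sqrt(n_max)/cs1, 1]``.
    """
    va = np.asarray(field_a, dtype=np.float64)
    vb = np.asarray(field_b, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError(f"entropy field shapes differ: {va.shape} vs {vb.shape}")
    dist = np.sqrt(((va - vb) ** 2).sum(axis=0))
    return SimilarityMap(values=1.0 - dist / constants.cs1, kind="entropy")


def differential_excitation(fmap: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """WLD differential excitation of a firing map.

    ``R`` sums the neighbour-minus-centre differences over the patch (the
    centre term is identically zero) and ``xi = arctan(R / T_center)``. Zero
    firing times in the denominator are floored at ``WLD_EPS`` so that the
    output stays finite and inside (-pi/2, pi/2).
    """
    T = np.asarray(fmap, dtype=np.float64)
    if T.ndim != 2:
        raise ValueError(f"firing map must be 2-D, got shape {T.shape}")
    R = _patch_sum(T, spec) - spec.area * T
    denom = np.maximum(T, WLD_EPS)
    return np.arctan(R / denom)


def wld_similarity(
    xi_a: np.ndarray, xi_b: np.ndarray, constants: SimilarityConstants
) -> SimilarityMap:
    """WLD-based similarity ``S_WLD = 1 - |xi_A - xi_B| / cs2``."""
    xa = np.asarray(xi_a, dtype=np.float64)
    xb = np.asarray(xi_b, dtype=np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"excitation field shapes differ: {xa.shape} vs {xb.shape}")
    return SimilarityMap(values=1.0 - np.abs(xa - xb) / constants.cs2, kind="wld")
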