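"""Spiking cortical model (SCM) on a 2-D image lattice.

The SCM is a single-layer, locally connected network derived from visual-cortex
models (Eckhorn family): one neuron per pixel receives the normalized intensity
``O`` as feeding input plus linking input from its neighbours' previous pulses,
accumulates a leaky internal activity ``F``, and emits a binary pulse ``Y``
whenever ``F`` exceeds a decaying dynamic threshold ``Theta``. One iteration
updates, in order::

    F[n]     = f * F[n-1] + O + O * (W (*) Y[n-1])     # (*) = correlation
    Y[n]     = 1  where  F[n] > Theta[n-1]  else 0
    Theta[n] = g * Theta[n-1] + h * Y[n-1]

with ``f, g`` decay constants below 1, ``h`` a large refractory magnitude and
``W`` the inverse-squared-distance linking kernel. All state starts at zero,
so every neuron with positive stimulus fires on the first iteration.

The temporal pulse series carries segment/edge structure of the input; its
per-pixel sum is the firing-mapping image (FMI) used downstream for fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ScmParams",
    "normalize_image",
    "linking_kernel",
    "run_scm",
    "firing_map",
    "scale_fmi",
]


@dataclass(frozen=True)
class ScmParams:
    """Parameters of the spiking cortical model.

    Attributes
    ----------
    f : float
        Feeding (internal activity) decay constant, in (0, 1).
    g : float
        Threshold decay constant, in (0, 1).
    h : float
        Threshold refractory magnitude added after a pulse; large values
        silence a neuron for several iterations.
    n_max : int
        Number of iterations, i.e. length of the pulse series.
    link_radius : int
        Radius of the linking neighbourhood in pixels (kernel side
        ``2*link_radius + 1``).
    threshold_uses_current_pulse : bool
        If True, the threshold is charged by the *current* pulse
        (``Theta[n] = g*Theta[n-1] + h*Y[n]``), a common alternative update
        order in SCM/PCNN implementations. Default False: the threshold lags
        one iteration behind the pulse, following the literal index scheme of
        the printed model.
    """

    f: float = 0.9
    g: float = 0.3
    h: float = 20.0
    n_max: int = 20
    link_radius: int = 1
    threshold_uses_current_pulse: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise ValueError(f"feeding decay f must lie in (0, 1), got {self.f}")
        if not (0.0 < self.g < 1.0):
            raise ValueError(f"threshold decay g must lie in (0, 1), got {self.g}")
        if self.h <= 0:
            raise ValueError(f"refractory magnitude h must be positive, got {self.h}")
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if self.link_radius < 1:
            raise ValueError(f"link_radius must be >= 1, got {self.link_radius}")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map an 8-bit grayscale image to the [0, 1] stimulus scale (divide by 255).

    Raises ``ValueError`` for non-2-D (e.g. multi-channel) input or values
    outside [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel 2-D image, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("8-bit image values must lie in [0, 255]")
    return arr / 255.0


def linking_kernel(link_radius: int) -> np.ndarray:
    """Inverse-squared-distance synaptic weight kernel.

    Entry at offset ``(dk, dl)`` equals ``1 / (dk**2 + dl**2)``; the centre is
    zero (a neuron does not link to itself). Side ``2*link_radius + 1``.
    """
    if link_radius < 1:
        raise ValueError(f"link_radius must be >= 1, got {link_radius}")
    offsets = np.arange(-link_radius, link_radius + 1, dtype=np.float64)
    d2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    with np.errstate(divide="ignore"):
        kernel = np.where(d2 > 0, 1.0 / np.where(d2 > 0, d2, 1.0), 0.0)
    return kernel


def run_scm(stimulus: np.ndarray, params: ScmParams) -> np.ndarray:
    """Iterate the SCM on a normalized stimulus.

    Parameters
    ----------
    stimulus : ndarray
        2-D array of normalized intensities in [0, 1].
    params : ScmParams

    Returns
    -------
    ndarray of uint8, shape ``(n_max, H, W)``
        The binary pulse series ``Y[1..n_max]``.

    Notes
    -----
    The linking term is a correlation of the previous pulse image with the
    linking kernel, zero-padded at the borders (neurons outside the image
    never fire). The firing comparison is strict: ties do not fire.
    """
    O = np.asarray(stimulus, dtype=np.float64)
    if O.ndim != 2:
        raise ValueError(f"stimulus must be 2-D, got shape {O.shape}")
    if not np.all(np.isfinite(O)) or O.min() < 0.0 or O.max() > 1.0:
        raise ValueError("stimulus values must be finite and lie in [0, 1]")

    W = linking_kernel(params.link_radius)
    F = np.zeros_like(O)
    theta = np.zeros_like(O)
    Y = np.zeros_like(O)
    pulses = np.empty((params.n_max,) + O.shape, dtype=np.uint8)

    for n in range(params.n_max):
        link = ndimage.correlate(Y, W, mode="constant", cval=0.0)
        F = params.f * F + O + O * link
        if params.threshold_uses_current_pulse:
            Y_new = (F > theta).astype(np.float64)
            theta = params.g * theta + params.h * Y_new
        else:
            Y_new = (F > theta).astype(np.float64)
            theta = params.g * theta + params.h * Y  # charged by Y[n-1]
        Y = Y_new
        pulses[n] = Y.astype(np.uint8)
    return pulses


def firing_map(pulses: np.ndarray) -> np.ndarray:
    """Firing-mapping image (FMI): per-pixel count of pulses over iterations.

    Returns an integer 2-D array with values in ``[0, n_max]``.
    """
    arr = np.asarray(pulses)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError(
            f"expected a non-empty pulse stack of shape (n, H, W), got {arr.shape}"
        )
    return arr.sum(axis=0, dtype=np.int64)


def scale_fmi(fmap: np.ndarray) -> np.ndarray:
    """Linearly rescale a firing map to [0, 255] for display.

    The minimum maps to 0 and the maximum to 255; a constant map (degenerate
    range) maps to all zeros. Rounding is half-away-from-zero. Downstream
    computation always uses the raw firing times; this is visualization only.
    """
    T = np.asarray(fmap, dtype=np.float64)
    lo, hi = T.min(), T.max()
    if hi == lo:
        return np.zeros(T.shape, dtype=np.uint8)
    scaled = (T - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)
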