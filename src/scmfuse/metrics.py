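"""Fusion-quality metrics scoring a fused image against its two sources.

Six established measures, each taking the triple ``(A, B, U)`` of 8-bit
grayscale images (``U`` may be unquantized floating point):

* ``q_m``  — mutual information ``MI(A,U) + MI(B,U)`` from 256-bin joint
  histograms (bits). Higher = more source information retained.
* ``q_e``  — Xydeas–Petrović edge-preservation index: Sobel edge strength and
  orientation preservation, sigmoid-scored and weighted by source edge
  strength; normalized so that perfect transfer scores 1.
* ``q_s``  — SSIM-based index: per sliding window, a salience-weighted
  combination of ``SSIM(A,U)`` and ``SSIM(B,U)`` when the sources agree
  (``SSIM(A,B) >= 0.75``), else the maximum of the two.
* ``q_l``  — fusion quality index: saliency-weighted SSIM combination on the
  intensity images times the same on Sobel edge-magnitude images.
* ``q_t``  — fusion similarity metric: per window, universal-image-quality
  scores against each source mixed by the covariance ratio
  ``sim = cov(A,U) / (cov(A,U) + cov(B,U))`` clipped to [0, 1].
* ``std_metric`` — sample standard deviation of the fused image (contrast).

SSIM/UIQI computations run on intensities normalized to [0, 1] with
stabilizers ``C1 = C2 = 2e-6``; window statistics use the unbiased (N-1)
normalization. The default sliding window is 8x8 with stride 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "SlidingWindowSpec",
    "MetricReport",
    "q_m",
    "q_e",
    "local_ssim",
    "q_s",
    "q_l",
    "q_t",
    "std_metric",
    "metric_report",
]

#: stabilizing constants for SSIM/UIQI on [0, 1] intensities
SSIM_C1 = 2e-6
SSIM_C2 = 2e-6

#: Xydeas–Petrović sigmoid constants for the edge-preservation index
QE_GAMMA_G = 0.9994
QE_KAPPA_G = -15.0
QE_SIGMA_G = 0.5
QE_GAMMA_A = 0.9879
QE_KAPPA_A = -22.0
QE_SIGMA_A = 0.8


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Sliding-window geometry for the SSIM/UIQI-based metrics."""

    side: int = 8
    step: int = 1

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError(f"window side must be >= 2, got {self.side}")
        if self.step < 1:
            raise ValueError(f"window step must be >= 1, got {self.step}")


@dataclass
class MetricReport:
    """The six quality scores for one (A, B, fused) triple."""

    q_m: float
    q_e: float
    q_s: float
    q_l: float
    q_t: float
    std: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, payload: str) -> "MetricReport":
        return cls(**json.loads(payload))


# ---------------------------------------------------------------------------
# helpers


def _check_triple(a, b, u):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if not (a.shape == b.shape == u.shape) or a.ndim != 2:
        raise ValueError(
            f"images must share one 2-D shape, got {a.shape}, {b.shape}, {u.shape}"
        )
    return a, b, u


def _windows(img: np.ndarray, win: SlidingWindowSpec) -> np.ndarray:
    """Flattened sliding windows, shape (n_windows, side*side)."""
    v = sliding_window_view(img, (win.side, win.side))[:: win.step, :: win.step]
    return v.reshape(-1, win.side * win.side)


def _moments(w: np.ndarray):
    """Window mean and unbiased variance."""
    m = w.mean(axis=1)
    var = ((w - m[:, None]) ** 2).sum(axis=1) / (w.shape[1] - 1)
    return m, var


def _cov(wa, ma, wb, mb):
    return ((wa - ma[:, None]) * (wb - mb[:, None])).sum(axis=1) / (wa.shape[1] - 1)


def _ssim_from_stats(ma, mb, va, vb, cov):
    num = (2.0 * ma * mb + SSIM_C1) * (2.0 * cov + SSIM_C2)
    den = (ma * ma + mb * mb + SSIM_C1) * (va + vb + SSIM_C2)
    return num / den


def _sobel_grad(img: np.ndarray):
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return gx, gy


def _edge_magnitude(img: np.ndarray) -> np.ndarray:
    gx, gy = _sobel_grad(img)
    return np.hypot(gx, gy)


# ---------------------------------------------------------------------------
# metrics


def q_m(image_a, image_b, fused) -> float:
    """Mutual-information score ``MI(A,U) + MI(B,U)`` in bits (256 bins)."""
    a, b, u = _check_triple(image_a, image_b, fused)
    return _mutual_information(a, u) + _mutual_information(b, u)


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    hist, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=256, range=[[0, 256], [0, 256]]
    )
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    outer = px[:, None] * py[None, :]
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def _qe_preservation(g_src, a_src, g_fus, a_fus):
    """Per-pixel edge strength+orientation preservation, peak-normalized to 1."""
    num = np.minimum(g_src, g_fus)
    den = np.maximum(g_src, g_fus)
    G = np.divide(num, den, out=np.ones_like(den), where=den > 0)
    # orientations are axial (mod pi): take the wrapped angular distance
    delta = np.abs(a_src - a_fus)
    delta = np.minimum(delta, np.pi - delta)
    A = 1.0 - delta / (np.pi / 2.0)
    qg = QE_GAMMA_G / (1.0 + np.exp(QE_KAPPA_G * (G - QE_SIGMA_G)))
    qa = QE_GAMMA_A / (1.0 + np.exp(QE_KAPPA_A * (A - QE_SIGMA_A)))
    peak = (QE_GAMMA_G / (1.0 + np.exp(QE_KAPPA_G * (1.0 - QE_SIGMA_G)))) * (
        QE_GAMMA_A / (1.0 + np.exp(QE_KAPPA_A * (1.0 - QE_SIGMA_A)))
    )
    return qg * qa / peak


def _orientation(gx, gy):
    """Gradient orientation folded into (-pi/2, pi/2]."""
    alpha = np.arctan2(gy, gx)
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return alpha


def q_e(image_a, image_b, fused) -> float:
    """Edge-preservation (Qabf-style) index, in [0, 1]."""
    a, b, u = _check_triple(image_a, image_b, fused)
    gxa, gya = _sobel_grad(a)
    gxb, gyb = _sobel_grad(b)
    gxu, gyu = _sobel_grad(u)
    ga, gb, gu = np.hypot(gxa, gya), np.hypot(gxb, gyb), np.hypot(gxu, gyu)
    aa, ab, au = _orientation(gxa, gya), _orientation(gxb, gyb), _orientation(gxu, gyu)
    q_au = _qe_preservation(ga, aa, gu, au)
    q_bu = _qe_preservation(gb, ab, gu, au)
    wsum = ga + gb
    total = wsum.sum()
    if total == 0:
        return 0.0
    return float((q_au * ga + q_bu * gb).sum() / total)


def local_ssim(window_a: np.ndarray, window_b: np.ndarray) -> float:
    """SSIM of two equal-size windows of [0, 1]-normalized intensities."""
    wa = np.asarray(window_a, dtype=np.float64).ravel()
    wb = np.asarray(window_b, dtype=np.float64).ravel()
    if wa.shape != wb.shape:
        raise ValueError("windows must have equal size")
    ma, mb = wa.mean(), wb.mean()
    n = wa.size - 1
    va = ((wa - ma) ** 2).sum() / n
    vb = ((wb - mb) ** 2).sum() / n
    cov = ((wa - ma) * (wb - mb)).sum() / n
    return float(_ssim_from_stats(ma, mb, va, vb, cov))


def _window_stats(a, b, u, win):
    wa, wb, wu = _windows(a, win), _windows(b, win), _windows(u, win)
    ma, va = _moments(wa)
    mb, vb = _moments(wb)
    mu, vu = _moments(wu)
    return (wa, ma, va), (wb, mb, vb), (wu, mu, vu)


def _lam(va, vb):
    """Local-variance salience ratio; 0.5 where both windows are flat."""
    den = va + vb
    return np.divide(va, den, out=np.full_like(va, 0.5), where=den > 0)


def q_s(image_a, image_b, fused, win: Optional[SlidingWindowSpec] = None) -> float:
    """SSIM-based fusion index with the 0.75 source-agreement gate."""
    win = win or SlidingWindowSpec()
    a, b, u = _check_triple(image_a, image_b, fused)
    a, b, u = a / 255.0, b / 255.0, u / 255.0
    (wa, ma, va), (wb, mb, vb), (wu, mu, vu) = _window_stats(a, b, u, win)
    ssim_ab = _ssim_from_stats(ma, mb, va, vb, _cov(wa, ma, wb, mb))
    ssim_au = _ssim_from_stats(ma, mu, va, vu, _cov(wa, ma, wu, mu))
    ssim_bu = _ssim_from_stats(mb, mu, vb, vu, _cov(wb, mb, wu, mu))
    lam = _lam(va, vb)
    combined = lam * ssim_au + (1.0 - lam) * ssim_bu
    per_window = np.where(ssim_ab >= 0.75, combined, np.maximum(ssim_au, ssim_bu))
    return float(per_window.mean())


def _piella_q(a, b, u, win) -> float:
    """Saliency-weighted SSIM combination over sliding windows."""
    (wa, ma, va), (wb, mb, vb), (wu, mu, vu) = _window_stats(a, b, u, win)
    ssim_au = _ssim_from_stats(ma, mu, va, vu, _cov(wa, ma, wu, mu))
    ssim_bu = _ssim_from_stats(mb, mu, vb, vu, _cov(wb, mb, wu, mu))
    lam = _lam(va, vb)
    combined = lam * ssim_au + (1.0 - lam) * ssim_bu
    saliency = np.maximum(va, vb)
    total = saliency.sum()
    if total == 0:
        return float(combined.mean())
    return float((saliency * combined).sum() / total)


def q_l(image_a, image_b, fused, win: Optional[SlidingWindowSpec] = None) -> float:
    """Fusion quality index: intensity factor times edge-image factor."""
    win = win or SlidingWindowSpec()
    a, b, u = _check_triple(image_a, image_b, fused)
    a, b, u = a / 255.0, b / 255.0, u / 255.0
    q_int = _piella_q(a, b, u, win)
    ea, eb, eu = _edge_magnitude(a), _edge_magnitude(b), _edge_magnitude(u)
    peak = max(ea.max(), eb.max(), eu.max())
    if peak > 0:
        ea, eb, eu = ea / peak, eb / peak, eu / peak
    q_edge = _piella_q(ea, eb, eu, win)
    return float(q_int * q_edge)


def q_t(image_a, image_b, fused, win: Optional[SlidingWindowSpec] = None) -> float:
    """Fusion similarity metric mixing per-window quality by covariance ratio."""
    win = win or SlidingWindowSpec()
    a, b, u = _check_triple(image_a, image_b, fused)
    a, b, u = a / 255.0, b / 255.0, u / 255.0
    (wa, ma, va), (wb, mb, vb), (wu, mu, vu) = _window_stats(a, b, u, win)
    cov_au = _cov(wa, ma, wu, mu)
    cov_bu = _cov(wb, mb, wu, mu)
    q_au = _ssim_from_stats(ma, mu, va, vu, cov_au)
    q_bu = _ssim_from_stats(mb, mu, vb, vu, cov_bu)
    den = cov_au + cov_bu
    sim = np.divide(cov_au, den, out=np.full_like(den, 0.5), where=den != 0)
    sim = np.clip(sim, 0.0, 1.0)
    return float((sim * q_au + (1.0 - sim) * q_bu).mean())


def std_metric(fused) -> float:
    """Sample standard deviation (N-1 denominator) of the fused image."""
    u = np.asarray(fused, dtype=np.float64)
    if u.size < 2:
        raise ValueError("standard deviation needs more than one pixel")
    return float(u.std(ddof=1))


def metric_report(
    image_a, image_b, fused, win: Optional[SlidingWindowSpec] = None
) -> MetricReport:
    """Compute all six quality scores for one (A, B, fused) triple."""
    win = win or SlidingWindowSpec()
    return MetricReport(
        q_m=q_m(image_a, image_b, fused),
        q_e=q_e(image_a, image_b, fused),
        q_s=q_s(image_a, image_b, fused, win),
        q_l=q_l(image_a, image_b, fused, win),
        q_t=q_t(image_a, image_b, fused, win),
        std=std_metric(fused),
        params={"window_side": win.side, "window_step": win.step},
    )
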