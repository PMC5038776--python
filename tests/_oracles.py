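"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain per-pixel / per-window Python loops with
no vectorized tricks, deliberately mirroring the model definitions rather
than the package's optimized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def scm_scalar(stimulus: np.ndarray, f: float, g: float, h: float, n_max: int,
               link_radius: int = 1) -> np.ndarray:
    """Per-pixel scalar-loop SCM iteration (zero padding outside the image)."""
    O = np.asarray(stimulus, dtype=float)
    H, W = O.shape
    F = np.zeros((H, W))
    theta = np.zeros((H, W))
    Y = np.zeros((H, W))
    out = np.zeros((n_max, H, W), dtype=np.uint8)
    for n in range(n_max):
        F_new = np.zeros((H, W))
        Y_new = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                link = 0.0
                for dk in range(-link_radius, link_radius + 1):
                    for dl in range(-link_radius, link_radius + 1):
                        if dk == 0 and dl == 0:
                            continue
                        k, l = i + dk, j + dl
                        if 0 <= k < H and 0 <= l < W:
                            link += Y[k, l] / (dk * dk + dl * dl)
                F_new[i, j] = f * F[i, j] + O[i, j] + O[i, j] * link
                Y_new[i, j] = 1.0 if F_new[i, j] > theta[i, j] else 0.0
        theta = g * theta + h * Y
        F, Y = F_new, Y_new
        out[n] = Y.astype(np.uint8)
    return out


def _sym_pad(img: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(img, pad, mode="symmetric")


def entropy_scalar(pulses: np.ndarray, l_p: int) -> np.ndarray:
    """Brute-force patch counting plus direct binary-entropy evaluation."""
    arr = np.asarray(pulses)
    n_it, H, W = arr.shape
    area = (2 * l_p + 1) ** 2
    out = np.zeros((n_it, H, W))
    for n in range(n_it):
        padded = _sym_pad(arr[n].astype(float), l_p)
        for i in range(H):
            for j in range(W):
                k = padded[i : i + 2 * l_p + 1, j : j + 2 * l_p + 1].sum()
                p1 = k / area
                p0 = 1.0 - p1
                h = 0.0
                if p1 > 0:
                    h -= p1 * math.log2(p1)
                if p0 > 0:
                    h -= p0 * math.log2(p0)
                out[n, i, j] = h
    return out


def local_energy_scalar(fmap: np.ndarray, l_p: int) -> np.ndarray:
    T = np.asarray(fmap, dtype=float)
    H, W = T.shape
    padded = _sym_pad(T, l_p)
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            patch = padded[i : i + 2 * l_p + 1, j : j + 2 * l_p + 1]
            out[i, j] = (patch**2).sum()
    return out


def excitation_scalar(fmap: np.ndarray, l_p: int, eps: float = 1e-6) -> np.ndarray:
    T = np.asarray(fmap, dtype=float)
    H, W = T.shape
    padded = _sym_pad(T, l_p)
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            patch = padded[i : i + 2 * l_p + 1, j : j + 2 * l_p + 1]
            r = (patch - T[i, j]).sum()
            out[i, j] = math.atan(r / max(T[i, j], eps))
    return out


def pipeline_scalar(image_a: np.ndarray, image_b: np.ndarray,
                    f=0.9, g=0.3, h=20.0, n_max=20, l_p=1,
                    cs1=None, cs2=None) -> np.ndarray:
    """Straight-line scalar reimplementation of the five fusion steps."""
    cs1 = 3.0 * n_max if cs1 is None else cs1
    cs2 = 5.0 * math.pi if cs2 is None else cs2
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    pa = scm_scalar(a / 255.0, f, g, h, n_max)
    pb = scm_scalar(b / 255.0, f, g, h, n_max)
    va = entropy_scalar(pa, l_p)
    vb = entropy_scalar(pb, l_p)
    H, W = a.shape
    ta = pa.sum(axis=0).astype(float)
    tb = pb.sum(axis=0).astype(float)
    ea = local_energy_scalar(ta, l_p)
    eb = local_energy_scalar(tb, l_p)
    xa = excitation_scalar(ta, l_p)
    xb = excitation_scalar(tb, l_p)
    fused = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            d = math.sqrt(sum((va[n, i, j] - vb[n, i, j]) ** 2 for n in range(n_max)))
            s_en = 1.0 - d / cs1
            s_wld = 1.0 - abs(xa[i, j] - xb[i, j]) / cs2
            w = s_en * s_wld
            if ea[i, j] > eb[i, j]:
                fused[i, j] = w * a[i, j] + (1.0 - w) * b[i, j]
            else:
                fused[i, j] = (1.0 - w) * a[i, j] + w * b[i, j]
    return fused


# ---------------------------------------------------------------------------
# per-window metric loops

C1 = C2 = 2e-6


def _win_ssim(wa: np.ndarray, wb: np.ndarray) -> float:
    ma, mb = wa.mean(), wb.mean()
    n = wa.size - 1
    va = ((wa - ma) ** 2).sum() / n
    vb = ((wb - mb) ** 2).sum() / n
    cov = ((wa - ma) * (wb - mb)).sum() / n
    return ((2 * ma * mb + C1) * (2 * cov + C2)) / (
        (ma * ma + mb * mb + C1) * (va + vb + C2)
    )


def _iter_windows(H, W, side, step):
    for i in range(0, H - side + 1, step):
        for j in range(0, W - side + 1, step):
            yield i, j


def qs_loop(a, b, u, side=8, step=1) -> float:
    a, b, u = (np.asarray(x, dtype=float) / 255.0 for x in (a, b, u))
    vals = []
    for i, j in _iter_windows(*a.shape, side, step):
        wa = a[i : i + side, j : j + side]
        wb = b[i : i + side, j : j + side]
        wu = u[i : i + side, j : j + side]
        s_ab = _win_ssim(wa, wb)
        s_au = _win_ssim(wa, wu)
        s_bu = _win_ssim(wb, wu)
        va = wa.var(ddof=1)
        vb = wb.var(ddof=1)
        lam = va / (va + vb) if va + vb > 0 else 0.5
        if s_ab >= 0.75:
            vals.append(lam * s_au + (1 - lam) * s_bu)
        else:
            vals.append(max(s_au, s_bu))
    return float(np.mean(vals))


def _piella_loop(a, b, u, side, step) -> float:
    num = den = 0.0
    fallback = []
    for i, j in _iter_windows(*a.shape, side, step):
        wa = a[i : i + side, j : j + side]
        wb = b[i : i + side, j : j + side]
        wu = u[i : i + side, j : j + side]
        va = wa.var(ddof=1)
        vb = wb.var(ddof=1)
        lam = va / (va + vb) if va + vb > 0 else 0.5
        comb = lam * _win_ssim(wa, wu) + (1 - lam) * _win_ssim(wb, wu)
        c = max(va, vb)
        num += c * comb
        den += c
        fallback.append(comb)
    return num / den if den > 0 else float(np.mean(fallback))


def _sobel_mag(img: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def ql_loop(a, b, u, side=8, step=1) -> float:
    a, b, u = (np.asarray(x, dtype=float) / 255.0 for x in (a, b, u))
    q1 = _piella_loop(a, b, u, side, step)
    ea, eb, eu = _sobel_mag(a), _sobel_mag(b), _sobel_mag(u)
    peak = max(ea.max(), eb.max(), eu.max())
    if peak > 0:
        ea, eb, eu = ea / peak, eb / peak, eu / peak
    q2 = _piella_loop(ea, eb, eu, side, step)
    return q1 * q2


def qt_loop(a, b, u, side=8, step=1) -> float:
    a, b, u = (np.asarray(x, dtype=float) / 255.0 for x in (a, b, u))
    vals = []
    for i, j in _iter_windows(*a.shape, side, step):
        wa = a[i : i + side, j : j + side]
        wb = b[i : i + side, j : j + side]
        wu = u[i : i + side, j : j + side]
        n = wa.size - 1
        cov_au = ((wa - wa.mean()) * (wu - wu.mean())).sum() / n
        cov_bu = ((wb - wb.mean()) * (wu - wu.mean())).sum() / n
        den = cov_au + cov_bu
        sim = cov_au / den if den != 0 else 0.5
        sim = min(max(sim, 0.0), 1.0)
        vals.append(sim * _win_ssim(wa, wu) + (1 - sim) * _win_ssim(wb, wu))
    return float(np.mean(vals))


def std_two_pass(img: np.ndarray) -> float:
    x = np.asarray(img, dtype=float).ravel()
    mean = x.sum() / x.size
    return math.sqrt(((x - mean) ** 2).sum() / (x.size - 1))
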