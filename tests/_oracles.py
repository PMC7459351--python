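"""Independent reference implementations used as test oracles.

Deliberately naive (per-pixel loops, textbook formulas) and kept separate
from the package so that each check exercises two independent routes.
"""

import numpy as np


def naive_equalize(px: np.ndarray) -> np.ndarray:
    """Per-pixel double-loop histogram equalization: h(v)=round(255*cdf(v)/MN)."""
    px = np.asarray(px)
    mn = px.size
    out = np.empty_like(px, dtype=np.uint8)
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            v = px[i, j]
            cdf_v = int((px <= v).sum())
            out[i, j] = np.rint(255.0 * cdf_v / mn)
    return out


def naive_zhang_suen(mask: np.ndarray) -> np.ndarray:
    """Textbook Zhang–Suen thinning, per-pixel loop transcription."""
    img = np.pad(np.asarray(mask, bool).astype(np.uint8), 1)
    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_del = []
            ys, xs = np.nonzero(img)
            for y, x in zip(ys, xs):
                p = [
                    img[y - 1, x], img[y - 1, x + 1], img[y, x + 1],
                    img[y + 1, x + 1], img[y + 1, x], img[y + 1, x - 1],
                    img[y, x - 1], img[y - 1, x - 1],
                ]
                b = sum(p)
                if not 2 <= b <= 6:
                    continue
                a = sum(1 for i in range(8) if p[i] == 0 and p[(i + 1) % 8] == 1)
                if a != 1:
                    continue
                if step == 0:
                    if p[0] * p[2] * p[4] != 0 or p[2] * p[4] * p[6] != 0:
                        continue
                else:
                    if p[0] * p[2] * p[6] != 0 or p[0] * p[4] * p[6] != 0:
                        continue
                to_del.append((y, x))
            if to_del:
                changed = True
                for y, x in to_del:
                    img[y, x] = 0
    return img[1:-1, 1:-1].astype(bool)


def naive_convolve2d(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded 'same' 2-D convolution by explicit loops."""
    h, w = field.shape
    L = kernel.shape[0]
    r = L // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += field[ii, jj] * kernel[r + di, r + dj]
            out[i, j] = acc
    return out


def partial_corr_by_inversion(x, y, z) -> float:
    """Partial correlation via the inverse correlation matrix:
    r_xy.z = -P01 / sqrt(P00 * P11) with P = inv(corr([x, y, z]))."""
    m = np.column_stack([x, y, np.asarray(z)])
    p = np.linalg.inv(np.corrcoef(m, rowvar=False))
    return float(-p[0, 1] / np.sqrt(p[0, 0] * p[1, 1]))


def pooled_t_textbook(x, y):
    """Pooled two-sample t statistic and two-tailed p, direct formulas."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, p
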