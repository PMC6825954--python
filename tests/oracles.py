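"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: set arithmetic over pixel
coordinates for the morphology, and textbook sums-of-squares formulas for
the statistics.  None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


# --- binary morphology on pixel sets --------------------------------------

def diamond_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if abs(dr) + abs(dc) <= radius
    ]


def _to_set(mask: np.ndarray) -> set[tuple[int, int]]:
    return set(zip(*np.nonzero(mask)))


def _to_mask(pixels: set[tuple[int, int]], shape) -> np.ndarray:
    out = np.zeros(shape, bool)
    for r, c in pixels:
        out[r, c] = True
    return out


def erode_bf(mask: np.ndarray, offsets) -> np.ndarray:
    h, w = mask.shape
    pix = _to_set(mask)
    kept = {
        (r, c)
        for r in range(h)
        for c in range(w)
        if all(
            0 <= r + dr < h and 0 <= c + dc < w and (r + dr, c + dc) in pix
            for dr, dc in offsets
        )
    }
    return _to_mask(kept, mask.shape)


def dilate_bf(mask: np.ndarray, offsets) -> np.ndarray:
    h, w = mask.shape
    out = set()
    for r, c in _to_set(mask):
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out.add((rr, cc))
    return _to_mask(out, mask.shape)


def opening_bf(mask: np.ndarray, offsets) -> np.ndarray:
    return dilate_bf(erode_bf(mask, offsets), offsets)


def fill_holes_bf(mask: np.ndarray) -> np.ndarray:
    """Flood the background from the border with 4-connectivity; anything
    unreached becomes foreground."""
    h, w = mask.shape
    reached = np.zeros((h, w), bool)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]
    ]
    for p in stack:
        reached[p] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                stack.append((rr, cc))
    return mask | ~reached


def largest_component_bf(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component; ties broken by the earliest first
    pixel in row-major scan order."""
    h, w = mask.shape
    seen = np.zeros((h, w), bool)
    best: set | None = None
    best_key = None  # (-size, first_pixel_scan_index)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = {(r, c)}
            seen[r, c] = True
            stack = [(r, c)]
            while stack:
                y, x = stack.pop()
                for yy in (y - 1, y, y + 1):
                    for xx in (x - 1, x, x + 1):
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            comp.add((yy, xx))
                            stack.append((yy, xx))
            first = min(y * w + x for y, x in comp)
            key = (-len(comp), first)
            if best_key is None or key < best_key:
                best_key = key
                best = comp
    assert best is not None
    return _to_mask(best, mask.shape)


def random_blob_mask(rng: np.random.Generator, shape=(48, 48)) -> np.ndarray:
    """Random blobby mask: union of random ellipses and lines on an empty
    grid, occasionally with carved holes."""
    h, w = shape
    mask = np.zeros(shape, bool)
    yy, xx = np.mgrid[:h, :w]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        ry, rx = rng.uniform(2, h / 4), rng.uniform(2, w / 4)
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    for _ in range(rng.integers(0, 3)):  # thin structures
        r0 = rng.integers(0, h)
        c0, c1 = sorted(rng.integers(0, w, 2))
        mask[r0, c0:c1 + 1] = True
    for _ in range(rng.integers(0, 2)):  # holes
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        rr = rng.uniform(1, 4)
        mask &= ~(((yy - cy) ** 2 + (xx - cx) ** 2) <= rr**2)
    return mask


# --- statistics ------------------------------------------------------------

def pearson_bf(x, y) -> tuple[float, float]:
    """Pearson r via the covariance formula; two-sided p from the exact t
    transform on n−2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * float(sps.t.sf(abs(t), n - 2))
    return r, p


def rm_anova_f_bf(values: np.ndarray) -> float:
    """One-way within-subject F from an explicit SS decomposition."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.mean()
    ss_subj = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ss_time = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum(
        (values[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_total - ss_subj - ss_time
    return (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


def mixed_between_f_bf(groups: list[np.ndarray]) -> float:
    """Between-subject F of a balanced split-plot design: group effect
    tested against subject-within-group variation, computed from subject
    means."""
    k = groups[0].shape[1]
    subj_means = [g.mean(axis=1) for g in groups]
    grand = np.concatenate(subj_means).mean()
    n_total = sum(len(m) for m in subj_means)
    g = len(groups)
    ss_geno = sum(k * len(m) * (m.mean() - grand) ** 2 for m in subj_means)
    ss_subj_within = sum(
        k * ((m - m.mean()) ** 2).sum() for m in subj_means
    )
    return (ss_geno / (g - 1)) / (ss_subj_within / (n_total - g))
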