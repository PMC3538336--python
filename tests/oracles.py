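"""Independent reference implementations used only to check the package.

These are deliberately naive (loops, recursion-free flood fill,
longhand sums of squares) and share no code with the implementation
they verify.
"""

from __future__ import annotations

import numpy as np


def otsu_brute_force(pixels: np.ndarray) -> int | None:
    """Exhaustive Otsu: try every cut t in 1..255, maximize between-class
    variance of the classes [0, t) and [t, 255]; lowest t wins ties."""
    hist = np.bincount(np.asarray(pixels).ravel(), minlength=256).astype(float)
    if (hist > 0).sum() < 2:
        return None
    levels = np.arange(256, dtype=float)
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum() / total
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            continue
        mu0 = (hist[:t] * levels[:t]).sum() / hist[:t].sum()
        mu1 = (hist[t:] * levels[t:]).sum() / hist[t:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Partition a boolean mask into 8-connected components by an
    explicit-stack flood fill; returned in row-major first-pixel order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def anova_oneway_longhand(groups: list[np.ndarray]) -> dict:
    """Spreadsheet-style one-way ANOVA sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    a, n = len(groups), len(allv)
    return {
        "ss_total": ss_total,
        "ss_between": ss_between,
        "ss_within": ss_within,
        "ms_model": ss_between / (a - 1),
        "ms_error": ss_within / (n - a),
        "df_model": a - 1,
        "df_error": n - a,
    }


def digital_disk(radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius`` of the
    origin, padded by one background pixel on each side."""
    n = int(np.ceil(radius)) + 2
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx**2 + yy**2) <= radius**2


def digital_ellipse(semi_major: float, semi_minor: float, angle: float = 0.0) -> np.ndarray:
    """Boolean mask of an axis-aligned (or rotated) filled digital ellipse."""
    n = int(np.ceil(max(semi_major, semi_minor))) + 2
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    u = xx * np.cos(angle) + yy * np.sin(angle)
    v = -xx * np.sin(angle) + yy * np.cos(angle)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
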