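"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's data structures and algorithms:
the watershed oracle is a bucketed frontier scan (no heap), the ANOVA
oracle is a regression-projection decomposition (no cell-mean formulas),
and the median oracle sorts raw neighborhoods.
"""
from __future__ import annotations

import numpy as np


def median_oracle(values: np.ndarray, radius: int) -> np.ndarray:
    """Median of each (2r+1)³ neighborhood via explicit sort, edge padding."""
    pad = np.pad(values, radius, mode="edge")
    out = np.empty_like(values, dtype=float)
    nz, ny, nx = values.shape
    w = 2 * radius + 1
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                block = pad[z: z + w, y: y + w, x: x + w].ravel()
                out[z, y, x] = np.sort(block)[block.size // 2]
    return out


def flood_oracle(landscape: np.ndarray, mask: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Marker flood popping the lowest-priority, oldest queue entry.

    Queued entries live in per-priority FIFO lists; each step picks the
    smallest priority key and the earliest-appended entry in that bucket
    (the insertion-age tie-break).  Markers are enqueued first in
    lexicographic (z, y, x) scan order.  Semantics match the documented
    flood rule but share no code or data structure with the package
    implementation.
    """
    nz, ny, nx = mask.shape
    out = np.zeros(mask.shape, dtype=np.int64)
    buckets: dict[float, list[tuple[int, int]]] = {}
    cursor: dict[float, int] = {}

    def push(idx: int, label: int) -> None:
        key = float(landscape.flat[idx])
        buckets.setdefault(key, []).append((idx, label))
        cursor.setdefault(key, 0)

    for idx in np.flatnonzero(markers.ravel() > 0):
        push(int(idx), int(markers.flat[idx]))

    neigh = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while buckets:
        key = min(buckets)
        idx, label = buckets[key][cursor[key]]
        cursor[key] += 1
        if cursor[key] == len(buckets[key]):
            del buckets[key]
            del cursor[key]
        if out.flat[idx]:
            continue
        out.flat[idx] = label
        z, rem = divmod(idx, ny * nx)
        y, x = divmod(rem, nx)
        for dz, dy, dx in neigh:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                j = (zz * ny + yy) * nx + xx
                if mask.flat[j] and not out.flat[j]:
                    push(j, label)
    return out


def anova_projection_oracle(a, b, y) -> dict[str, float]:
    """Sequential regression decomposition for a balanced two-factor design.

    RSS differences between nested dummy-coded models; for balanced designs
    the sequential sums of squares equal the cell-means decomposition.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    y = np.asarray(y, dtype=float)
    a_levels = sorted(set(a.tolist()), key=str)
    b_levels = sorted(set(b.tolist()), key=str)

    def dummies(values, levels):
        return np.column_stack([(values == l).astype(float) for l in levels[1:]])

    da, db = dummies(a, a_levels), dummies(b, b_levels)
    dab = np.column_stack(
        [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
    ) if da.shape[1] and db.shape[1] else np.empty((len(y), 0))
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0 = rss(ones)
    rss_a = rss(np.hstack([ones, da]))
    rss_ab = rss(np.hstack([ones, da, db]))
    rss_full = rss(np.hstack([ones, da, db, dab]))
    return {
        "ss_total": rss0,
        "ss_a": rss0 - rss_a,
        "ss_b": rss_a - rss_ab,
        "ss_effect": rss_ab - rss_full,
        "ss_error": rss_full,
    }


def random_blob_mask(rng: np.random.Generator, shape, n_blobs=3, r_range=(3, 7)) -> np.ndarray:
    """Union of a few random balls, for randomized watershed instances."""
    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.indices(shape)
    for _ in range(n_blobs):
        r = rng.integers(*r_range)
        c = [rng.integers(r, s - r) for s in shape]
        mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
    return mask
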