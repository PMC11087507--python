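"""Independent brute-force oracles used to check the package implementation.

These deliberately avoid the code paths under test: the 3D contact oracle is
a plain breadth-first search over the 6-connected voxel graph (vs the
package's iterative scipy dilation), and the 2D oracles are direct
nearest-pixel scans by broadcasting (vs the Euclidean distance transform).
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def shell_mask_bruteforce(labels: np.ndarray) -> np.ndarray:
    """Shell voxels: labeled voxels with a 6-neighbour of a different label
    (out-of-volume counts as background)."""
    shell = np.zeros(labels.shape, dtype=bool)
    shape = labels.shape
    for z, y, x in np.argwhere(labels > 0):
        own = labels[z, y, x]
        for dz, dy, dx in NEIGHBORS_6:
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                shell[z, y, x] = True
                break
            if labels[nz, ny, nx] != own:
                shell[z, y, x] = True
                break
    return shell


def bfs_contact_distances(
    mito_labels: np.ndarray, partner_mask: np.ndarray, max_steps: int
) -> np.ndarray:
    """Geodesic city-block distance from the partner to every voxel.

    Multi-source BFS over the 6-connected voxel graph starting at partner
    voxels (distance 0), never traversing mitochondrial interiors (object
    minus shell), truncated at ``max_steps``. Returns an int array with -1
    where unreached.
    """
    shell = shell_mask_bruteforce(mito_labels)
    interior = (mito_labels > 0) & ~shell
    dist = np.full(mito_labels.shape, -1, dtype=np.int32)
    queue: deque = deque()
    for z, y, x in np.argwhere(partner_mask & ~interior):
        dist[z, y, x] = 0
        queue.append((z, y, x))
    shape = mito_labels.shape
    while queue:
        z, y, x = queue.popleft()
        d = dist[z, y, x]
        if d >= max_steps:
            continue
        for dz, dy, dx in NEIGHBORS_6:
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                continue
            if dist[nz, ny, nx] != -1 or interior[nz, ny, nx]:
                continue
            dist[nz, ny, nx] = d + 1
            queue.append((nz, ny, nx))
    return dist


def bfs_band_counts(
    mito_labels: np.ndarray,
    partner_mask: np.ndarray,
    band_iters: list[tuple[int, int]],
) -> dict[int, list[int]]:
    """Per-mitochondrion exclusive band contact counts by brute force.

    ``band_iters`` gives (inner_excl, outer_incl) dilation-step bounds per
    band, e.g. [(0, 3), (3, 7)] for 0-24 / 25-56 nm at 8 nm pitch, where a
    shell voxel at BFS distance d belongs to the band with inner < d <= outer
    (distance 0 voxels, partner on the shell, belong to the innermost band).
    """
    max_steps = max(hi for _, hi in band_iters)
    dist = bfs_contact_distances(mito_labels, partner_mask, max_steps)
    shell = shell_mask_bruteforce(mito_labels)
    # partner voxels lying on the shell are distance 0 regardless of BFS start
    overlap = partner_mask & shell
    counts: dict[int, list[int]] = {}
    for z, y, x in np.argwhere(shell):
        lab = int(mito_labels[z, y, x])
        counts.setdefault(lab, [0] * len(band_iters))
        d = dist[z, y, x]
        if overlap[z, y, x]:
            d = 0
        if d == -1:
            continue
        for b, (lo, hi) in enumerate(band_iters):
            inner_ok = d > lo or (lo == 0 and d == 0)
            if inner_ok and d <= hi:
                counts[lab][b] += 1
                break
    return counts


def nearest_distance_2d(points_from: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """For each (y, x) row of ``points_from``, min Euclidean pixel distance to
    any True pixel of ``target_mask``, by direct broadcasting."""
    targets = np.argwhere(target_mask).astype(float)
    pts = np.asarray(points_from, dtype=float)
    d2 = ((pts[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


def exhaustive_two_sided_p(a, b) -> float:
    """Exact two-sided permutation p-value for |difference of means| by
    enumerating every split of the pooled values."""
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)
    obs = abs(np.mean(a) - np.mean(b))
    total = 0
    exceed = 0
    idx = range(len(pooled))
    for keep in combinations(idx, n_a):
        keep = set(keep)
        xa = [pooled[i] for i in keep]
        xb = [pooled[i] for i in idx if i not in keep]
        t = abs(np.mean(xa) - np.mean(xb))
        exceed += t >= obs - 1e-12
        total += 1
    return exceed / total
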