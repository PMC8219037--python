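"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (full enumeration, explicit loops) and
shares no code path with the package.
"""

import numpy as np


def brute_force_les(labels: np.ndarray, label: int, spacing) -> float:
    """LES diameter by all-pairs distance: for every cell voxel, the minimum
    center-to-center distance to any non-cell voxel (including a one-voxel
    exterior shell); diameter is twice the maximum of those minima."""
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(labels, 1, constant_values=0)
    cell = np.argwhere(padded == label).astype(float)
    other = np.argwhere(padded != label).astype(float)
    dmax = 0.0
    for v in cell:
        d = np.sqrt((((other - v) * spacing) ** 2).sum(axis=1)).min()
        dmax = max(dmax, d)
    return 2.0 * dmax


def brute_force_contact_faces(labels: np.ndarray, background=0):
    """Every shared face between 6-adjacent voxels of different labels,
    enumerated voxel by voxel.  Returns dict (a, b) -> list of
    (axis, voxel_a, voxel_b) with a < b."""
    out = {}
    nz, ny, nx = labels.shape
    steps = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                la = labels[z, y, x]
                if la == background:
                    continue
                for axis, (dz, dy, dx) in enumerate(steps):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if z2 >= nz or y2 >= ny or x2 >= nx:
                        continue
                    lb = labels[z2, y2, x2]
                    if lb == background or lb == la:
                        continue
                    va, vb = (z, y, x), (z2, y2, x2)
                    a, b = la, lb
                    if a > b:
                        a, b = b, a
                        va, vb = vb, va
                    out.setdefault((int(a), int(b)), []).append((axis, va, vb))
    return out


def brute_force_patch_count(faces) -> int:
    """Connected components of faces by O(F²) pairwise testing: two faces
    are connected when both their voxel pairs are within Chebyshev
    distance 1 on their respective sides."""
    n = len(faces)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ai = np.array(faces[i][1])
            aj = np.array(faces[j][1])
            bi = np.array(faces[i][2])
            bj = np.array(faces[j][2])
            if np.abs(ai - aj).max() <= 1 and np.abs(bi - bj).max() <= 1:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi
    return len({find(i) for i in range(n)})


def facet_divergence_hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume as a divergence sum of signed facet tetrahedra
    against an interior point (hull vertices come from Qhull, the volume
    computation does not)."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    c = points[hull.vertices].mean(axis=0)
    total = 0.0
    for simplex in hull.simplices:
        v0, v1, v2 = points[simplex]
        total += abs(np.dot(v0 - c, np.cross(v1 - c, v2 - c))) / 6.0
    return total


def kruskal_wallis_oracle(groups):
    """Tie-corrected H from the textbook rank formula, computed directly."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    N = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    i = 0
    sorted_vals = pooled[order]
    while i < N:
        j = i
        while j + 1 < N and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # mid-ranks
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        r = ranks[start : start + ni]
        h += r.sum() ** 2 / ni
        start += ni
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (N**3 - N)
    return h / correction if correction > 0 else 0.0
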