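"""Independent brute-force reference implementations used only by the tests.

Each oracle re-derives a quantity from first principles, avoiding the code
path (and usually the algorithm) of the implementation it checks.
"""

import numpy as np

from dfgflip.pocket_analysis import SCAN_DIRECTIONS, WATER_LATTICE_CONSTANT


def quaternion_superpose_rmsd(P, Q):
    """Optimal superposition RMSD via the quaternion eigen-decomposition.

    Independent of the SVD/Kabsch route: builds the 4x4 key matrix of the
    quaternion method and reads the minimum RMSD off its largest eigenvalue.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    sq = (np.sum(P0 ** 2) + np.sum(Q0 ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def psp_counts_walking(protein):
    """PSP counts by literally walking each scan ray from every solvent point."""
    nx, ny, nz = protein.shape
    counts = np.zeros(protein.shape, dtype=int)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if protein[i, j, k]:
                    continue
                c = 0
                for dx, dy, dz in SCAN_DIRECTIONS:
                    hit_fwd = hit_bwd = False
                    x, y, z = i + dx, j + dy, k + dz
                    while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                        if protein[x, y, z]:
                            hit_fwd = True
                            break
                        x, y, z = x + dx, y + dy, z + dz
                    x, y, z = i - dx, j - dy, k - dz
                    while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                        if protein[x, y, z]:
                            hit_bwd = True
                            break
                        x, y, z = x - dx, y - dy, z - dz
                    if hit_fwd and hit_bwd:
                        c += 1
                counts[i, j, k] = c
    return counts


def occupied_waters_enumeration(grid, mask, cutoff=1.6):
    """Water count by direct lattice enumeration (no spatial index).

    Same definition as the implementation: a 1 g/ml cubic lattice anchored at
    the grid origin; a water counts iff its nearest masked grid point is
    within `cutoff` and the voxel it falls in is masked.
    """
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return 0
    pts = grid.origin + idx * grid.spacing
    a = WATER_LATTICE_CONSTANT
    lo = np.floor((pts.min(axis=0) - cutoff - grid.origin) / a).astype(int)
    hi = np.ceil((pts.max(axis=0) + cutoff - grid.origin) / a).astype(int)
    dims = mask.shape
    count = 0
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                w = grid.origin + a * np.array([i, j, k], float)
                d2 = np.sum((pts - w) ** 2, axis=1)
                if d2.min() > cutoff ** 2:
                    continue
                node = np.rint((w - grid.origin) / grid.spacing).astype(int)
                if np.any(node < 0) or np.any(node >= dims):
                    continue
                if mask[tuple(node)]:
                    count += 1
    return count


def connected_components_bfs(dist_matrix, threshold):
    """Cluster membership as BFS connected components of the <=threshold graph."""
    n = len(dist_matrix)
    comp = [-1] * n
    current = 0
    for seed in range(n):
        if comp[seed] != -1:
            continue
        queue = [seed]
        comp[seed] = current
        while queue:
            u = queue.pop()
            for v in range(n):
                if comp[v] == -1 and dist_matrix[u][v] <= threshold:
                    comp[v] = current
                    queue.append(v)
        current += 1
    return comp


def pairwise_auc(energies_labels):
    """AUC as the fraction of (active, decoy) pairs ranked correctly.

    `energies_labels` is a list of (energy, is_active). Lower energy ranks
    better; ties count 1/2.
    """
    actives = [e for e, act in energies_labels if act]
    decoys = [e for e, act in energies_labels if not act]
    wins = 0.0
    for ea in actives:
        for ed in decoys:
            if ea < ed:
                wins += 1.0
            elif ea == ed:
                wins += 0.5
    return wins / (len(actives) * len(decoys))


def tm_score_seed_scan(P, Q, d0, seed_len=7):
    """TM-score lower bound from exhaustive contiguous superposition seeds."""
    from dfgflip.dfg_classifier import superpose

    L = len(P)
    best = 0.0
    for start in range(0, L - seed_len + 1):
        sel = slice(start, start + seed_len)
        try:
            R, t, _ = superpose(P[sel], Q[sel])
        except ValueError:
            continue
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
    # also the global superposition seed
    R, t, _ = superpose(P, Q)
    d = np.linalg.norm(P @ R.T + t - Q, axis=1)
    best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
    return best
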