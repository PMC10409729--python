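"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive quantities from their definitions (triple
loops, pairwise distance matrices) rather than calling the implementations
they check.
"""

import numpy as np
from scipy.spatial.distance import cdist

DISPLACEMENTS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def mind_bruteforce(vol: np.ndarray, eps_scale: float = 1e-6) -> np.ndarray:
    """Triple-loop MIND: squared neighbour differences per voxel
    (edge-replicated), then 3x3x3 patch means (edge-replicated), Gaussian
    weighting with the mean-distance variance floored at eps, per-voxel
    max normalisation."""
    D, H, W = vol.shape
    eps = eps_scale * max(np.ptp(vol) ** 2, 1e-30)

    def clip(i, j, k):
        return min(max(i, 0), D - 1), min(max(j, 0), H - 1), min(max(k, 0), W - 1)

    diff_fields = []
    for r in DISPLACEMENTS:
        jf = np.zeros_like(vol)
        for i in range(D):
            for j in range(H):
                for k in range(W):
                    jf[i, j, k] = (vol[i, j, k] - vol[clip(i + r[0], j + r[1], k + r[2])]) ** 2
        diff_fields.append(jf)
    out = np.zeros((6, D, H, W))
    for i in range(D):
        for j in range(H):
            for k in range(W):
                dps = []
                for jf in diff_fields:
                    acc = 0.0
                    for pi in (-1, 0, 1):
                        for pj in (-1, 0, 1):
                            for pk in (-1, 0, 1):
                                acc += jf[clip(i + pi, j + pj, k + pk)]
                    dps.append(acc / 27.0)
                dps = np.array(dps)
                v = max(dps.mean(), eps)
                c = np.exp(-dps / v)
                out[:, i, j, k] = c / c.max()
    return out


def brute_force_hd_mcd(u, c):
    """O(|U||C|) pairwise Hausdorff and mean contour distance in mm."""
    d = cdist(u.points_mm, c.points_mm)
    d_uc = d.min(axis=1)
    d_cu = d.min(axis=0)
    return max(d_uc.max(), d_cu.max()), np.concatenate([d_uc, d_cu]).mean()
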