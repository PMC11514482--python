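"""Independent exhaustive-enumeration oracle for the fragment aligner.

Enumerates *every* monotone matching between molecule and reference labels
(index subsets of equal size k, k >= 1; the monotone pairing of two ordered
subsets is unique) and scores each one directly from the scoring
definition.  The per-k enumeration is vectorized with numpy over all
subset pairs, which keeps 8x8 instances (C(16,8)-1 = 12869 matchings)
cheap, but shares no code with the DP implementation it checks.
"""

from itertools import combinations

import numpy as np


def trailing_free_count(mol, ref, i_last, j_last, s):
    proj_end = mol[j_last] + (ref[-1] - ref[i_last]) / s
    return int(np.sum(mol > proj_end))


def leading_free_count(mol, ref, i_first, j_first, s):
    proj_start = mol[j_first] - (ref[i_first] - ref[0]) / s
    return int(np.sum(mol < proj_start))


def brute_force_best(mol, ref, s, params):
    """Best score over all non-empty monotone matchings at fixed stretch."""
    mol = np.asarray(mol, float)
    ref = np.asarray(ref, float)
    n, m = ref.size, mol.size
    sd2 = params.sizing_sd_kb_per_sqrt_kb**2
    # end penalty tables: unmatched molecule labels outside the projected
    # reference span are free on both sides
    trail = np.empty((n, m))
    lead = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            trail[i, j] = (m - 1 - j) - trailing_free_count(mol, ref, i, j, s)
            lead[i, j] = j - leading_free_count(mol, ref, i, j, s)
    best = -np.inf
    for k in range(1, min(n, m) + 1):
        subsets_i = np.array(list(combinations(range(n), k)))
        subsets_j = np.array(list(combinations(range(m), k)))
        ri = ref[subsets_i]  # (CI, k)
        mj = mol[subsets_j]  # (CJ, k)
        base = np.full((subsets_i.shape[0], subsets_j.shape[0]),
                       k * params.match_reward)
        if k > 1:
            dr = np.diff(ri, axis=1)  # (CI, k-1)
            dm = np.diff(mj, axis=1)  # (CJ, k-1)
            # (dr - s*dm)^2/dr = dr - 2 s dm + s^2 dm^2/dr, summed over steps
            i_term = dr.sum(axis=1)
            j_term = -2.0 * s * dm.sum(axis=1)
            cross = (1.0 / dr) @ (dm**2).T * s**2
            base -= (i_term[:, None] + j_term[None, :] + cross) / (2.0 * sd2)
            gaps_i = (np.diff(subsets_i, axis=1) - 1).sum(axis=1)
            gaps_j = (np.diff(subsets_j, axis=1) - 1).sum(axis=1)
            base -= params.miss_penalty * gaps_i[:, None]
            base -= params.false_penalty * gaps_j[None, :]
        base -= params.false_penalty * lead[
            np.ix_(subsets_i[:, 0], subsets_j[:, 0])
        ]
        base -= params.false_penalty * trail[
            np.ix_(subsets_i[:, -1], subsets_j[:, -1])
        ]
        best = max(best, float(base.max()))
    return best
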