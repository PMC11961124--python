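"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different route from the implementation it
verifies: quaternion eigen-solution instead of SVD for superposition,
Monte-Carlo rejection sampling instead of a deterministic lattice for
accessible area, exhaustive enumeration instead of tree-accelerated search.
"""

import numpy as np


def quaternion_superposition_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigen-solution."""
    p = moving - moving.mean(axis=0)
    q = fixed - fixed.mean(axis=0)
    sxx, sxy, sxz = (p[:, 0] * q[:, 0]).sum(), (p[:, 0] * q[:, 1]).sum(), (p[:, 0] * q[:, 2]).sum()
    syx, syy, syz = (p[:, 1] * q[:, 0]).sum(), (p[:, 1] * q[:, 1]).sum(), (p[:, 1] * q[:, 2]).sum()
    szx, szy, szz = (p[:, 2] * q[:, 0]).sum(), (p[:, 2] * q[:, 1]).sum(), (p[:, 2] * q[:, 2]).sum()
    key = np.array([
        [sxx + syy + szz, syz - szy,       szx - sxz,       sxy - syx],
        [syz - szy,       sxx - syy - szz, sxy + syx,       szx + sxz],
        [szx - sxz,       sxy + syx,       syy - sxx - szz, syz + szy],
        [sxy - syx,       szx + sxz,       syz + szy,       szz - sxx - syy],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    sq = (p ** 2).sum() + (q ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / len(p)))


def monte_carlo_asa(centers: np.ndarray, radii: np.ndarray, probe: float,
                    n_samples: int, seed: int) -> float:
    """Total accessible area by rejection sampling on each expanded sphere."""
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    total = 0.0
    for i in range(len(centers)):
        u = rng.normal(size=(n_samples, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = centers[i] + expanded[i] * u
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - centers[j], axis=1) >= expanded[j]
        total += 4.0 * np.pi * expanded[i] ** 2 * free.mean()
    return total


def monte_carlo_buried_area(centers: np.ndarray, radii: np.ndarray,
                            chain_ids, probe: float, n_samples: int,
                            seed: int) -> float:
    """Buried area ASA_A + ASA_B - ASA_AB with common random numbers.

    Each atom's surface is sampled once; a point contributes to buried area
    when it is accessible within the atom's own chain but occluded in the
    complex.  Differencing identical samples removes the large common
    variance of the three separate ASA estimates.
    """
    rng = np.random.default_rng(seed)
    chain_ids = np.asarray(chain_ids)
    expanded = radii + probe
    buried = 0.0
    for i in range(len(centers)):
        u = rng.normal(size=(n_samples, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = centers[i] + expanded[i] * u
        free_own = np.ones(n_samples, dtype=bool)
        blocked_other = np.zeros(n_samples, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            inside = np.linalg.norm(pts - centers[j], axis=1) < expanded[j]
            if chain_ids[j] == chain_ids[i]:
                free_own &= ~inside
            else:
                blocked_other |= inside
        buried += 4.0 * np.pi * expanded[i] ** 2 * \
            (free_own & blocked_other).mean()
    return buried


def exhaustive_disulfide_pairs(sg_sites, cutoff: float):
    """Greedy nearest-first SG pairing by full pair enumeration.

    ``sg_sites`` is a list of ((chain, resnum), position) tuples.
    """
    cands = []
    for i in range(len(sg_sites)):
        for j in range(i + 1, len(sg_sites)):
            d = float(np.linalg.norm(sg_sites[i][1] - sg_sites[j][1]))
            if d <= cutoff:
                cands.append((d, sg_sites[i][0], sg_sites[j][0]))
    cands.sort()
    used, pairs = set(), []
    for _, a, b in cands:
        if a not in used and b not in used:
            used |= {a, b}
            pairs.append(tuple(sorted((a, b))))
    return sorted(pairs)


def least_squares_line(x: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression via the normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_force_medoid(coord_sets: np.ndarray) -> int:
    """First index minimizing summed pairwise RMSD, by direct double loop."""
    m = len(coord_sets)
    sums = []
    for i in range(m):
        s = 0.0
        for j in range(m):
            if i != j:
                s += np.sqrt(((coord_sets[i] - coord_sets[j]) ** 2)
                             .sum(axis=1).mean())
        sums.append(s)
    return int(np.argmin(sums))
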