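"""Seeded generators for every input class the pipeline consumes.

Each generator is deterministic for a given parameter set and seed (one
private NumPy ``Generator`` per call, no global state) and plants a ground
truth that is echoed into the output's ``metadata["truth"]`` so recovery
tests can score results without re-deriving anything.

The toy coordinates are geometrically plausible — poly-alanine backbones on
a smooth helical curve, cysteine pairs at exactly requested thiol-thiol
separations, occlusion cages that bury a thiol — but not physically
minimized.  They exercise the geometry, accessibility, and classification
code paths; they do not emulate crystallographic noise models or real
protein packing.

Default parameters mirror the conditions the pipeline targets: a 20-residue
mobile motif (residues 112–131) riding on a stable core with an abrupt
concerted transition, and three-species chromatograms with areas in the
10:53:37 tetramer:dimer:monomer proportion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, Chromatogram, Residue, Structure, Trajectory

__all__ = [
    "CysPlacement", "make_toy_structure", "make_homolog_pair",
    "make_loop_trajectory", "make_chromatogram",
    "DEFAULT_MOTIF_RESIDUES", "DEFAULT_SEC_PEAKS",
]

#: Mobile-motif residue numbers used by the trajectory defaults.
DEFAULT_MOTIF_RESIDUES = tuple(range(112, 132))

#: Default three-species SEC peaks: (center mL, sigma mL, area) for
#: tetramer, dimer, and the later-eluting monomer shoulder, areas in the
#: 10:53:37 proportion.
DEFAULT_SEC_PEAKS = ((12.2, 0.45, 1.0), (14.6, 0.50, 5.3), (15.9, 0.55, 3.7))


@dataclass
class CysPlacement:
    """A cysteine substitution, optionally paired to a partner cysteine.

    ``partner`` names another (chain, resnum) that also becomes a cysteine;
    ``distance`` is the exact SG–SG separation (Å) to realize for the pair.
    ``occluded`` surrounds the SG with a cage of carbon atoms so that its
    accessible area is ~0 (a buried thiol).
    """

    chain: str
    resnum: int
    partner: tuple[str, int] | None = None
    distance: float | None = None
    occluded: bool = False


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _backbone_curve(n: int, chain_offset: np.ndarray) -> np.ndarray:
    """CA positions on a wide helix: ~3.8 Å consecutive spacing, no clashes."""
    i = np.arange(n)
    radius, rise, per_turn = 12.0, 1.8, 22.0
    theta = 2.0 * np.pi * i / per_turn
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            rise * i]) + chain_offset


def _build_residue(chain_id: str, number: int, ca: np.ndarray,
                   tangent: np.ndarray, serial_start: int,
                   name: str = "ALA") -> Residue:
    t = tangent / np.linalg.norm(tangent)
    # an arbitrary frame perpendicular to the chain direction
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(t, up)) > 0.9:
        up = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(t, up)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    offsets = {
        "N": -1.46 * t + 0.3 * n1,
        "CA": np.zeros(3),
        "C": 1.52 * t + 0.3 * n1,
        "O": 1.9 * t + 1.2 * n1,
        "CB": 1.2 * n2 + 0.8 * n1,
    }
    atoms = []
    for k, (atom_name, off) in enumerate(offsets.items()):
        element = atom_name[0]
        atoms.append(AtomRecord(serial=serial_start + k, name=atom_name,
                                element=element, alt_loc="", occupancy=1.0,
                                b_factor=20.0, position=ca + off))
    return Residue(chain_id=chain_id, number=number, insertion_code="",
                   name=name, atoms=atoms)


def _fold_hairpin(s: Structure, a, b, target_gap: float) -> None:
    """Re-place residues between ``a`` and ``b`` on a hairpin arc.

    Brings CA(b) to ``target_gap`` Å of CA(a) and lays the intervening CA
    atoms on a circular arc of ~3.8 Å steps bulging radially outward from
    the backbone curve, so a loop-closing disulfide becomes geometrically
    feasible.
    """
    from scipy.optimize import brentq

    if a[0] != b[0]:
        raise ValueError(f"cannot fold a hairpin across chains {a} and {b}")
    chain = s.chains[a[0]]
    numbers = [r.number for r in chain]
    i, j = numbers.index(a[1]), numbers.index(b[1])
    if i > j:
        i, j = j, i
    n_seg = j - i
    if not 2 <= n_seg <= 12:
        raise ValueError(f"infeasible placement {a}-{b}: hairpin needs "
                         f"2-12 residue separation, got {n_seg}")
    p0 = chain[i].atom("CA").position
    arc_len = 3.8 * n_seg
    chord = target_gap
    # arc angle theta from arc length and chord: L/theta = c / (2 sin(theta/2))
    theta = brentq(lambda t: chord / (2 * np.sin(t / 2)) - arc_len / t,
                   1e-6, 2 * np.pi - 1e-6)
    radius = arc_len / theta
    # bulge outward: radial direction from the helix axis (z)
    out = p0.copy()
    out[2] = 0.0
    out = _unit(out)
    tang = np.cross(np.array([0.0, 0.0, 1.0]), out)
    # arc spans from p0 to p0 + chord*tang in the (out, tang) plane,
    # bulging along +out; circle center sits behind the chord midpoint
    end = p0 + chord * tang
    mid = 0.5 * (p0 + end)
    sagitta = radius * (1 - np.cos(theta / 2))
    center = mid + (radius - sagitta) * (-out)
    # angles of p0 and end around the center in the (out, tang) plane
    def _angle(p):
        v = p - center
        return np.arctan2(np.dot(v, tang), np.dot(v, out))
    a0, a1 = _angle(p0), _angle(end)
    if a1 < a0:
        a1 += 2 * np.pi
    for k in range(1, n_seg):
        ang = a0 + (a1 - a0) * k / n_seg
        ca_new = center + radius * (np.cos(ang) * out + np.sin(ang) * tang)
        old_ca = chain[i + k].atom("CA").position.copy()
        shift = ca_new - old_ca
        for atom in chain[i + k].atoms:
            atom.position = atom.position + shift
    # translate the closing residue onto the arc end point
    shift = end - chain[j].atom("CA").position
    for atom in chain[j].atoms:
        atom.position = atom.position + shift


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_toy_structure(n_chains: int = 1, residues_per_chain: int = 30,
                       cys_placements: list[CysPlacement] | None = None,
                       seed: int = 0, start_number: int = 101,
                       chain_offset: tuple[float, float, float] = (40.0, 0.0, 0.0),
                       b_factors: dict | None = None,
                       jitter: float = 0.0) -> Structure:
    """Poly-alanine chains on a smooth curve with planted cysteines.

    Cysteine SG atoms of a pair are placed symmetrically on the axis
    between their CA atoms so the requested SG–SG distance is realized
    exactly; an infeasible request (SG farther than ~3.5 Å from its CA)
    raises.  ``b_factors`` maps (chain, resnum) -> b to plant disorder
    profiles; ``jitter`` adds seeded Gaussian coordinate noise.
    """
    placements = list(cys_placements or [])
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    s = Structure(id=f"toy-{seed}")
    serial = 1
    for ci, chain_id in enumerate(chain_ids):
        cas = _backbone_curve(residues_per_chain,
                              np.asarray(chain_offset, dtype=float) * ci)
        for j in range(residues_per_chain):
            lo = max(j - 1, 0)
            hi = min(j + 1, residues_per_chain - 1)
            tangent = (cas[hi] - cas[lo]) if hi != lo else np.array([1.0, 0.0, 0.0])
            res = _build_residue(chain_id, start_number + j, cas[j], tangent,
                                 serial)
            serial += len(res.atoms)
            s.chains.setdefault(chain_id, []).append(res)

    cys_targets: dict[tuple[str, int], CysPlacement] = {}
    pairs: list[tuple[tuple[str, int], tuple[str, int], float]] = []
    for p in placements:
        key = (p.chain, p.resnum)
        cys_targets[key] = p
        if p.partner is not None:
            if p.distance is None:
                raise ValueError(f"placement {key}: partner given without distance")
            partner = tuple(p.partner)
            cys_targets.setdefault(partner,
                                   CysPlacement(chain=partner[0], resnum=partner[1]))
            pairs.append((key, partner, float(p.distance)))

    def _residue(key):
        return s.residue(key[0], key[1])

    # substitute cysteines: rename, add a default SG off the CB
    for key, p in cys_targets.items():
        res = _residue(key)
        res.name = "CYS"
        cb = res.atom("CB")
        ca = res.atom("CA")
        direction = cb.position - ca.position
        direction /= np.linalg.norm(direction)
        sg_pos = cb.position + 1.8 * direction
        res.atoms.append(AtomRecord(serial=serial, name="SG", element="S",
                                    alt_loc="", occupancy=1.0, b_factor=20.0,
                                    position=sg_pos))
        serial += 1

    # realize exact SG-SG separations along the CA-CA axis; when the base
    # curve keeps the two CA atoms too far apart, fold the intervening
    # stretch into a hairpin first (the natural geometry of a loop-closing
    # disulfide)
    max_ca_sg = 3.5
    for a, b, dist in pairs:
        ra, rb = _residue(a), _residue(b)
        gap = np.linalg.norm(rb.atom("CA").position - ra.atom("CA").position)
        if gap > dist + 2.0 * max_ca_sg:
            _fold_hairpin(s, a, b, target_gap=max(5.0, dist + 2.0))
        ca_a = ra.atom("CA").position
        ca_b = rb.atom("CA").position
        axis = ca_b - ca_a
        gap = np.linalg.norm(axis)
        axis = axis / gap
        mid = 0.5 * (ca_a + ca_b)
        sg_a = mid - 0.5 * dist * axis
        sg_b = mid + 0.5 * dist * axis
        if (np.linalg.norm(sg_a - ca_a) > max_ca_sg
                or np.linalg.norm(sg_b - ca_b) > max_ca_sg):
            raise ValueError(
                f"infeasible placement {a}-{b}: requested SG-SG {dist} Å puts "
                f"an SG more than {max_ca_sg} Å from its CA "
                f"(CA-CA separation {gap:.1f} Å)")
        ra.atom("SG").position = sg_a
        rb.atom("SG").position = sg_b

    # occlusion cages: carbon shells burying the SG
    occluded = []
    for key, p in cys_targets.items():
        if not p.occluded:
            continue
        res = _residue(key)
        sg = res.atom("SG")
        for k, d in enumerate(_fibonacci_directions(40)):
            res.atoms.append(AtomRecord(
                serial=serial, name=f"X{k:02d}", element="C", alt_loc="",
                occupancy=1.0, b_factor=20.0, position=sg.position + 3.0 * d))
            serial += 1
        occluded.append(list(key))

    if b_factors:
        for (chain, num), b in b_factors.items():
            for a in s.residue(chain, num).atoms:
                a.b_factor = float(b)
    if jitter > 0:
        for _, a in s.iter_atoms():
            a.position = a.position + rng.normal(0.0, jitter, 3)

    bond_like = [p for p in pairs if p[2] <= 2.3]
    s.metadata["truth"] = {
        "cysteines": sorted(list(k) for k in cys_targets),
        "pairs": [[list(a), list(b), d] for a, b, d in pairs],
        "disulfides": [[list(a), list(b)] for a, b, _ in bond_like],
        "free_thiols": sorted(list(k) for k in cys_targets
                              if not any(k in (a, b) for a, b, _ in bond_like)),
        "occluded": occluded,
        "seed": seed,
    }
    return s


def make_homolog_pair(base: Structure, axis=(0.0, 0.0, 1.0),
                      angle_deg: float = 90.0,
                      translation=(5.0, -3.0, 2.0),
                      noise_sigma: float = 0.0, seed: int = 0):
    """A rigidly moved, optionally noise-perturbed copy of ``base``.

    Returns ``(base, moved, truth)`` where truth records the planted
    rotation/translation and the realized all-atom RMSD after optimal
    re-superposition of the noisy copy onto the original (zero when
    ``noise_sigma`` is 0).
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg)
                               * np.asarray(axis, float)
                               / np.linalg.norm(axis)).as_matrix()
    trans = np.asarray(translation, dtype=float)
    moved = copy.deepcopy(base)
    orig_coords, new_coords = [], []
    for _, a in moved.iter_atoms():
        orig_coords.append(a.position.copy())
        pos = rot @ a.position + trans
        if noise_sigma > 0:
            pos = pos + rng.normal(0.0, noise_sigma, 3)
        a.position = pos
        new_coords.append(pos)
    from .geometry import superpose      # deferred: geometry imports structio
    sup = superpose(np.array(new_coords), np.array(orig_coords))
    truth = {
        "rotation": rot, "translation": trans, "noise_sigma": noise_sigma,
        "realized_rmsd": sup.rmsd, "seed": seed,
    }
    moved.metadata["truth"] = truth
    moved.id = base.id + "-moved"
    return base, moved, truth


def make_loop_trajectory(n_frames: int = 200, dt: float = 0.1,
                         core_size: int = 40,
                         motif_residues=DEFAULT_MOTIF_RESIDUES,
                         transition_time: float = 6.0,
                         amplitudes=None, noise_sigma: float = 0.1,
                         seed: int = 0, chain: str = "A",
                         global_motion: bool = False) -> Trajectory:
    """A rigid core plus a motif that steps to a new conformation.

    The chain covers the motif plus ``core_size`` flanking residues.  At
    ``transition_time`` (µs) every motif residue jumps by its amplitude
    along a fixed random direction; Gaussian jitter of ``noise_sigma`` Å is
    added to all atoms in all frames.  With ``global_motion`` a random
    rigid rotation+translation is additionally applied per frame, to be
    removed by core superposition.

    Defaults plant the concerted-transition scenario: a 20-residue motif
    (112–131) stepping abruptly at 6 µs on a 20 µs clock.
    """
    motif = sorted(int(r) for r in motif_residues)
    if amplitudes is None:
        # graded jumps from 3 to 15 Å, flat first/last residues: the flanks
        # of the motif are anchored to the helices and barely move
        amplitudes = np.concatenate([[0.0],
                                     np.linspace(3.0, 15.0, len(motif) - 2),
                                     [0.0]])
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(amplitudes) != len(motif):
        raise ValueError(f"{len(amplitudes)} amplitudes for {len(motif)} "
                         f"motif residues")
    times = dt * np.arange(n_frames)
    if not times[0] <= transition_time <= times[-1]:
        raise ValueError(f"transition time {transition_time} outside the "
                         f"trajectory span [{times[0]}, {times[-1]}] µs")
    rng = np.random.default_rng(seed)
    lo = motif[0] - (core_size + 1) // 2
    hi = motif[-1] + core_size // 2
    n_res = hi - lo + 1
    topo = make_toy_structure(n_chains=1, residues_per_chain=n_res,
                              start_number=lo, seed=seed)
    topo.chains = {chain: [Residue(chain_id=chain, number=r.number,
                                   insertion_code=r.insertion_code,
                                   name=r.name, atoms=r.atoms)
                           for r in topo.chains["A"]]}
    base = np.array([a.position for _, a in topo.iter_atoms()])
    rows_per_residue: dict[int, list[int]] = {}
    for i, (res, _) in enumerate(topo.iter_atoms()):
        rows_per_residue.setdefault(res.number, []).append(i)
    directions = {r: d for r, d in zip(
        motif, _fibonacci_directions(max(len(motif), 4))[:len(motif)])}
    amp = dict(zip(motif, amplitudes))
    frames = []
    for t in times:
        coords = base + rng.normal(0.0, noise_sigma, base.shape)
        if t >= transition_time:
            for r in motif:
                coords[rows_per_residue[r]] += amp[r] * directions[r]
        if global_motion:
            g = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix()
            coords = coords @ g.T + rng.normal(0.0, 20.0, 3)
        frames.append(coords)
    truth = {
        "transition_time": float(transition_time),
        "transition_frame": int(np.searchsorted(times, transition_time)),
        "amplitudes": {int(r): float(a) for r, a in amp.items()},
        "directions": {int(r): directions[r].tolist() for r in motif},
        "motif": motif, "noise_sigma": noise_sigma, "seed": seed,
        "chain": chain,
    }
    return Trajectory(topology=topo, frames=frames, times=times,
                      metadata={"truth": truth})


def make_chromatogram(peaks=DEFAULT_SEC_PEAKS, baseline: float = 0.0,
                      noise_sigma: float | None = None,
                      volume=None, seed: int = 0) -> Chromatogram:
    """Sum-of-Gaussians chromatogram with baseline and Gaussian noise.

    ``peaks`` is a list of (center mL, sigma mL, area); ``noise_sigma``
    defaults to 1% of the maximum noiseless signal (0 disables noise).
    Truth records the planted peaks and the area percentages.
    """
    for _, w, _ in peaks:
        if w <= 0:
            raise ValueError("peak widths must be positive")
    if volume is None:
        volume = np.arange(8.0, 24.0, 0.02)
    volume = np.asarray(volume, dtype=float)
    signal = np.full_like(volume, float(baseline))
    for c, w, a in peaks:
        signal += a / (w * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((volume - c) / w) ** 2)
    if noise_sigma is None:
        noise_sigma = 0.01 * float(np.max(signal - baseline, initial=0.0))
    rng = np.random.default_rng(seed)
    noisy = signal + (rng.normal(0.0, noise_sigma, volume.shape)
                      if noise_sigma > 0 else 0.0)
    total_area = sum(a for _, _, a in peaks)
    truth = {
        "peaks": [list(map(float, p)) for p in peaks],
        "areas": [float(a) for _, _, a in peaks],
        "percentages": [100.0 * a / total_area for _, _, a in peaks]
        if total_area > 0 else [],
        "baseline": float(baseline), "noise_sigma": float(noise_sigma),
        "seed": seed,
    }
    return Chromatogram(volume=volume, absorbance=noisy,
                        metadata={"truth": truth})
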