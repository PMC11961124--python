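"""Trajectory analytics for a mobile motif on a stable core.

The workflow mirrors how an MD ensemble of a loop/hairpin motif is read:

1. :func:`core_superpose` removes global tumbling by fitting every frame
   onto the first over the *core* CA atoms (by default every CA outside the
   mobile motif and its flanking helices), so later per-residue deviations
   measure internal motion only.
2. :func:`residue_rmsd_series` tracks each motif residue's heavy-atom RMSD
   against a reference frame; :func:`pair_distance_series` tracks a single
   atom-pair distance (e.g. the two thiol sulfurs of a reduced disulfide);
   :func:`rmsf` summarizes positional fluctuation.
3. :func:`detect_transitions` finds abrupt mean shifts per residue by
   binary segmentation and groups transition times across residues into
   events; an event is *concerted* when a sufficient fraction of motif
   residues jump within a short window, the signature distinguishing a
   collective conformational change from residue-by-residue drift.
4. :func:`block_representative` extracts a representative conformation of
   an equilibrated time block as the medoid under pairwise heavy-atom RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import superpose
from .structio import Structure, Trajectory

__all__ = [
    "SeriesResult", "ChangePointResult", "TransitionEvent",
    "BlockRepresentative", "core_superpose", "residue_rmsd_series",
    "pair_distance_series", "rmsf", "detect_transitions",
    "block_representative", "default_core_selection",
    "DEFAULT_EXCLUDED_FROM_CORE",
]

#: Residue range excluded from the default superposition core: the mobile
#: motif plus its flanking helices.
DEFAULT_EXCLUDED_FROM_CORE = (109, 148)


@dataclass
class SeriesResult:
    """Per-residue RMSD (Å) against a reference frame, one row per frame."""

    residue_ids: list[tuple[str, int]]
    times: np.ndarray
    matrix: np.ndarray            # (n_frames, n_residues)
    reference_frame: int
    core: list[tuple[str, int]] = field(default_factory=list)

    def series(self, chain: str, number: int) -> np.ndarray:
        return self.matrix[:, self.residue_ids.index((chain, number))]

    def to_table(self) -> str:
        header = "time_us\t" + "\t".join(f"{c}:{n}" for c, n in self.residue_ids)
        rows = ["\t".join([f"{t:.6g}"] + [f"{x:.4f}" for x in row])
                for t, row in zip(self.times, self.matrix)]
        return "\n".join([header] + rows) + "\n"


@dataclass
class TransitionEvent:
    time: float                       # µs, median of member transitions
    participants: list[tuple[str, int]]
    fraction: float                   # of mobile residues participating
    concerted: bool
    mean_jump: float                  # Å


@dataclass
class ChangePointResult:
    per_residue: dict[tuple[str, int], list[dict]]   # {time, jump}
    events: list[TransitionEvent]
    min_jump: float
    min_segment: int
    concert_window: float
    concert_fraction: float

    @property
    def concerted_events(self) -> list[TransitionEvent]:
        return [e for e in self.events if e.concerted]


@dataclass
class BlockRepresentative:
    window: tuple[float, float]       # µs
    medoid_frame: int                 # global frame index
    medoid_time: float
    mean_intra_block_rmsd: float


def default_core_selection(topology: Structure,
                           excluded=DEFAULT_EXCLUDED_FROM_CORE):
    """All CA atoms outside the excluded residue range, as (chain, resnum)."""
    lo, hi = excluded
    return [(res.chain_id, res.number) for res in topology.iter_residues()
            if res.atom("CA") is not None and not lo <= res.number <= hi]


def _atom_rows(t: Trajectory, residues, atom_name: str | None = None):
    """Frame-row indices for the given (chain, resnum) residues."""
    rows: dict[tuple[str, int], list[int]] = {}
    i = 0
    wanted = set(residues)
    for res, a in t.topology.iter_atoms():
        key = (res.chain_id, res.number)
        if key in wanted and (atom_name is None or a.name == atom_name):
            rows.setdefault(key, []).append(i)
        i += 1
    missing = [k for k in residues if k not in rows]
    if missing:
        raise KeyError(f"residues missing from topology: {missing}")
    return rows


def core_superpose(t: Trajectory, core=None) -> Trajectory:
    """Superpose every frame onto frame 0 by core CA atoms.

    Returns a new trajectory; per-frame core RMSD is stored under
    ``metadata['core_rmsd']`` and the core selection under
    ``metadata['core']``.
    """
    if core is None:
        core = default_core_selection(t.topology)
    rows = _atom_rows(t, core, atom_name="CA")
    idx = np.array([rows[k][0] for k in core])
    if len(idx) < 3:
        raise ValueError(f"core has {len(idx)} CA atoms; need >= 3")
    ref = t.frames[0]
    new_frames = [ref.copy()]
    core_rmsd = [0.0]
    for frame in t.frames[1:]:
        sup = superpose(frame[idx], ref[idx])
        new_frames.append(frame @ sup.rotation.T + sup.translation)
        core_rmsd.append(sup.rmsd)
    meta = dict(t.metadata)
    meta["core"] = list(core)
    meta["core_rmsd"] = np.array(core_rmsd)
    return Trajectory(topology=t.topology, frames=new_frames,
                      times=t.times.copy(), metadata=meta)


def residue_rmsd_series(t: Trajectory, residues, reference_frame: int = 0
                        ) -> SeriesResult:
    """Per-residue heavy-atom RMSD of an aligned trajectory vs a reference frame.

    No re-fitting per residue: frames are assumed core-aligned, so the
    series reflects genuine displacement of each residue.
    """
    residues = [tuple(r) for r in residues]
    rows = _atom_rows(t, residues)
    if not 0 <= reference_frame < t.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = t.frames[reference_frame]
    mat = np.empty((t.n_frames, len(residues)))
    for j, key in enumerate(residues):
        idx = np.array(rows[key])
        ref_xyz = ref[idx]
        for i, frame in enumerate(t.frames):
            d = frame[idx] - ref_xyz
            mat[i, j] = np.sqrt(np.mean((d ** 2).sum(axis=1)))
    return SeriesResult(residue_ids=residues, times=t.times.copy(), matrix=mat,
                        reference_frame=reference_frame,
                        core=list(t.metadata.get("core", [])))


def pair_distance_series(t: Trajectory, atom_a: str, atom_b: str) -> np.ndarray:
    """Per-frame distance (Å) between two ``chain:resnum:atom`` selections."""
    index = t.atom_index()

    def _row(sel: str) -> int:
        c, n, name = sel.split(":")
        key = (c, int(n), "", name)
        if key not in index:
            raise KeyError(f"atom {sel!r} not in trajectory topology")
        return index[key]

    ia, ib = _row(atom_a), _row(atom_b)
    return np.array([float(np.linalg.norm(f[ia] - f[ib])) for f in t.frames])


def rmsf(t: Trajectory, residues, window: tuple[int, int] | None = None
         ) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (Å) over a frame window of an aligned trajectory.

    Per atom: root-mean-square deviation from the window-mean position;
    per residue: mean over its heavy atoms.
    """
    residues = [tuple(r) for r in residues]
    rows = _atom_rows(t, residues)
    lo, hi = (0, t.n_frames) if window is None else window
    frames = np.array(t.frames[lo:hi])
    if frames.shape[0] == 0:
        raise ValueError("empty frame window")
    mean_pos = frames.mean(axis=0)
    fluct = np.sqrt(((frames - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return {key: float(np.mean(fluct[np.array(rows[key])])) for key in residues}


# ---------------------------------------------------------------------------
# change points

def _binary_segmentation(x: np.ndarray, min_segment: int, min_jump: float,
                         offset: int = 0) -> list[tuple[int, float]]:
    """Recursive mean-shift change points: (index, jump) with jump >= min_jump.

    The change point index is the first frame of the new regime.  Split
    quality is the reduction in summed squared error of a piecewise-constant
    mean model; a candidate is kept when the mean shift is at least
    ``min_jump``.
    """
    n = len(x)
    if n < 2 * min_segment:
        return []
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(i, j):      # over x[i:j]
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        m = j - i
        return s2 - s * s / m

    total = sse(0, n)
    best_k, best_gain = -1, 0.0
    for k in range(min_segment, n - min_segment + 1):
        gain = total - sse(0, k) - sse(k, n)
        if gain > best_gain:
            best_gain, best_k = gain, k
    if best_k < 0:
        return []
    mean_l = (csum[best_k]) / best_k
    mean_r = (csum[n] - csum[best_k]) / (n - best_k)
    jump = abs(mean_r - mean_l)
    if jump < min_jump:
        return []
    left = _binary_segmentation(x[:best_k], min_segment, min_jump, offset)
    right = _binary_segmentation(x[best_k:], min_segment, min_jump,
                                 offset + best_k)
    return sorted(left + [(offset + best_k, jump)] + right)


def detect_transitions(s: SeriesResult, min_jump: float = 1.0,
                       min_segment: int = 5, concert_window: float = 0.5,
                       concert_fraction: float = 0.75) -> ChangePointResult:
    """Per-residue change points and concerted global events.

    Per residue, binary segmentation on the RMSD series yields mean-shift
    transitions of magnitude >= ``min_jump`` Å with segments of at least
    ``min_segment`` frames.  Transition times across residues are then
    clustered: times within ``concert_window`` µs of the running cluster
    form one event, and the event is *concerted* when the participating
    residues are at least ``concert_fraction`` of all residues in the
    series.
    """
    if min_segment < 2:
        raise ValueError("min_segment must be >= 2")
    n_frames = s.matrix.shape[0]
    if n_frames < 2 * min_segment:
        raise ValueError(f"series of {n_frames} frames too short for "
                         f"min_segment={min_segment}")
    per_residue: dict[tuple[str, int], list[dict]] = {}
    all_transitions = []       # (time, residue, jump)
    for j, key in enumerate(s.residue_ids):
        cps = _binary_segmentation(s.matrix[:, j], min_segment, min_jump)
        entries = []
        for k, jump in cps:
            time = float(s.times[k])
            entries.append({"time": time, "jump": float(jump)})
            all_transitions.append((time, key, float(jump)))
        per_residue[key] = entries
    all_transitions.sort(key=lambda t: t[0])
    events: list[TransitionEvent] = []
    cluster: list[tuple[float, tuple[str, int], float]] = []
    n_mobile = len(s.residue_ids)

    def _flush():
        if not cluster:
            return
        times = [c[0] for c in cluster]
        participants = sorted({c[1] for c in cluster})
        jumps = [c[2] for c in cluster]
        frac = len(participants) / n_mobile
        events.append(TransitionEvent(
            time=float(np.median(times)), participants=participants,
            fraction=frac, concerted=frac >= concert_fraction,
            mean_jump=float(np.mean(jumps))))

    for tr in all_transitions:
        if cluster and tr[0] - cluster[-1][0] > concert_window:
            _flush()
            cluster = []
        cluster.append(tr)
    _flush()
    return ChangePointResult(per_residue=per_residue, events=events,
                             min_jump=min_jump, min_segment=min_segment,
                             concert_window=concert_window,
                             concert_fraction=concert_fraction)


def block_representative(t: Trajectory, window: tuple[float, float],
                         residues=None) -> BlockRepresentative:
    """Medoid frame of a time window under pairwise heavy-atom RMSD.

    The medoid minimizes the summed RMSD to every other frame in the
    window; ties break to the earliest frame.  ``residues`` restricts the
    atom set (default: all atoms).
    """
    lo, hi = window
    sel = np.where((t.times >= lo) & (t.times <= hi))[0]
    if len(sel) == 0:
        raise ValueError(f"no frames in window [{lo}, {hi}] µs")
    if residues is None:
        idx = np.arange(t.frames[0].shape[0])
    else:
        rows = _atom_rows(t, [tuple(r) for r in residues])
        idx = np.array(sorted(i for v in rows.values() for i in v))
    coords = np.array([t.frames[i][idx] for i in sel])
    m = len(sel)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = np.sqrt(np.mean(((coords[i] - coords[j]) ** 2).sum(axis=1)))
            dist[i, j] = dist[j, i] = d
    sums = dist.sum(axis=1)
    best = int(np.argmin(sums))       # argmin takes the first minimum: earliest
    mean_rmsd = float(sums.sum() / (m * (m - 1))) if m > 1 else 0.0
    return BlockRepresentative(
        window=(float(lo), float(hi)),
        medoid_frame=int(sel[best]),
        medoid_time=float(t.times[sel[best]]),
        mean_intra_block_rmsd=mean_rmsd)
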