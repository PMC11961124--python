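"""Reading and writing the coordinate, trajectory, and chromatogram formats.

Coordinates come in as PDB or mmCIF text and are held in a light
model -> chain -> residue -> atom hierarchy (:class:`Structure`).  Parsing is
backed by gemmi; writing emits plain PDB text with explicit control over
column widths and rounding so that round-trips are reproducible to format
precision.  Conformational ensembles are carried as multi-model PDB
(:class:`Trajectory`) and size-exclusion traces as two-column delimited text
(:class:`Chromatogram`).

Conventions
-----------
* Hydrogens (and deuteriums) are dropped on parse: the crystal structures
  this package targets are at ~3 Å resolution and contain none, and solvent
  accessibility is defined over heavy atoms.
* Alternate locations are resolved at parse time; the default policy keeps
  the highest-occupancy conformer (ties break to file order).
* Water, ions and any other non-amino-acid residue are routed to
  ``Structure.solvent`` and excluded from polymer chains.  Crystallographic
  waters such as W401 remain reachable there by residue number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "Trajectory",
    "Chromatogram",
    "StructureFormatError",
    "parse_structure",
    "write_structure",
    "parse_trajectory",
    "write_trajectory",
    "parse_chromatogram",
    "write_chromatogram",
]

#: Residue names treated as polymer (protein) residues.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureFormatError(ValueError):
    """Raised when coordinate/chromatogram text cannot be interpreted."""


@dataclass
class AtomRecord:
    """One heavy atom: identity, occupancy/b-factor, Cartesian position (Å)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    b_factor: float
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    """A residue identified by (chain, author number, insertion code)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Structure:
    """Polymer chains plus solvent/heteroatoms from one coordinate file."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    solvent: list[Residue] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- census ---------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_polymer_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        """Non-hydrogen atom count over polymer and solvent."""
        n = sum(len(res.atoms) for r in self.chains.values() for res in r)
        return n + sum(len(res.atoms) for res in self.solvent)

    @property
    def n_waters(self) -> int:
        return sum(1 for res in self.solvent if res.name in WATER_NAMES)

    # -- access ---------------------------------------------------------
    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not in structure "
                           f"(have {sorted(self.chains)})") from None

    def residue(self, chain_id: str, number: int, insertion_code: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.number == number and res.insertion_code == insertion_code:
                return res
        raise KeyError(f"residue {chain_id}:{number}{insertion_code} not found")

    def solvent_residue(self, number: int, chain_id: str | None = None,
                        name: str | None = None) -> Residue:
        for res in self.solvent:
            if res.number != number:
                continue
            if chain_id is not None and res.chain_id != chain_id:
                continue
            if name is not None and res.name != name:
                continue
            return res
        raise KeyError(f"solvent/het residue {number} not found")

    def iter_residues(self):
        for residues in self.chains.values():
            yield from residues

    def iter_atoms(self):
        """Yield (residue, atom) over polymer then solvent."""
        for res in self.iter_residues():
            for a in res.atoms:
                yield res, a
        for res in self.solvent:
            for a in res.atoms:
                yield res, a

    def select_atom(self, selection: str) -> tuple[Residue, AtomRecord]:
        """Resolve a ``chain:resnum:atomname`` selection to a single atom.

        The chain field may be empty (``:401:O``) to search solvent and all
        chains by residue number, which is how crystallographic waters are
        addressed.
        """
        parts = selection.split(":")
        if len(parts) != 3:
            raise ValueError(f"selection {selection!r}: expected 'chain:resnum:atom'")
        chain_id, num_s, atom_name = parts
        try:
            number = int(num_s)
        except ValueError:
            raise ValueError(f"selection {selection!r}: residue number not an integer") from None
        hits: list[tuple[Residue, AtomRecord]] = []
        pool: list[Residue] = []
        if chain_id:
            if chain_id in self.chains:
                pool.extend(self.chains[chain_id])
            pool.extend(r for r in self.solvent if r.chain_id == chain_id)
        else:
            pool.extend(self.iter_residues())
            pool.extend(self.solvent)
        for res in pool:
            if res.number != number:
                continue
            a = res.atom(atom_name)
            if a is not None:
                hits.append((res, a))
        if not hits:
            raise KeyError(f"selection {selection!r} matched no atom")
        if len(hits) > 1:
            raise KeyError(f"selection {selection!r} ambiguous ({len(hits)} atoms)")
        return hits[0]

    def subset(self, chain_ids) -> "Structure":
        """New structure containing only the given polymer chains (no solvent)."""
        chain_ids = list(chain_ids)
        missing = [c for c in chain_ids if c not in self.chains]
        if missing:
            raise KeyError(f"chains {missing} not in structure")
        return Structure(
            id=self.id,
            chains={c: self.chains[c] for c in chain_ids},
            metadata=dict(self.metadata),
        )


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology, time-stamped in µs."""

    topology: Structure
    frames: list[np.ndarray]
    times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.n_atoms
        for i, f in enumerate(self.frames):
            self.frames[i] = np.asarray(f, dtype=float)
            if self.frames[i].shape != (n, 3):
                raise ValueError(f"frame {i}: expected {n} atoms, got {self.frames[i].shape[0]}")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.topology.iter_residues()) + \
            sum(len(res.atoms) for res in self.topology.solvent)

    def atom_index(self) -> dict[tuple[str, int, str, str], int]:
        """Map (chain, resnum, icode, atom name) -> row in each frame."""
        idx: dict[tuple[str, int, str, str], int] = {}
        i = 0
        for res, a in self.topology.iter_atoms():
            idx[(res.chain_id, res.number, res.insertion_code, a.name)] = i
            i += 1
        return idx


@dataclass
class Chromatogram:
    """A size-exclusion trace: elution volume (mL) vs absorbance (a.u.)."""

    volume: np.ndarray
    absorbance: np.ndarray
    v0: float | None = None       # void volume, mL
    vc: float | None = None       # geometric column volume, mL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.volume.ndim != 1 or self.volume.shape != self.absorbance.shape:
            raise ValueError("volume and absorbance must be 1-D series of equal length")
        if len(self.volume) < 2:
            raise ValueError("chromatogram needs at least 2 rows")
        if not np.all(np.diff(self.volume) > 0):
            raise ValueError("elution volume must be strictly increasing")


# ---------------------------------------------------------------------------
# parsing

def _validate_pdb_atom_lines(content: str) -> None:
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureFormatError(f"line {lineno}: truncated atom record")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError:
            raise StructureFormatError(
                f"line {lineno}: unparseable coordinates in atom record") from None


def _looks_like_cif(content: str) -> bool:
    head = content.lstrip()[:2000]
    return head.startswith("data_") or "_atom_site." in head


def _read_gemmi(content: str) -> gemmi.Structure:
    if not content.strip():
        raise StructureFormatError("empty input: no atom records")
    if _looks_like_cif(content):
        try:
            doc = gemmi.cif.read_string(content)
            return gemmi.make_structure_from_block(doc.sole_block())
        except (RuntimeError, ValueError) as exc:
            raise StructureFormatError(f"mmCIF parse failed: {exc}") from None
    _validate_pdb_atom_lines(content)
    try:
        return gemmi.read_pdb_string(content)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"PDB parse failed: {exc}") from None


def _resolve_alt_locs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown alt-loc policy {policy!r}")
    by_name: dict[str, AtomRecord] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif policy == "highest_occupancy" and a.occupancy > prev.occupancy:
            by_name[a.name] = a
        # 'first' and occupancy ties: keep the earlier record
    return list(by_name.values())


def _convert_model(model: gemmi.Model, alt_loc_policy: str) -> Structure:
    out = Structure()
    for chain in model:
        for gres in chain:
            atoms: list[AtomRecord] = []
            for ga in gres:
                if ga.element.name in ("H", "D"):
                    continue
                # gemmi stores occupancy as float32; round off the cast noise
                occ = round(min(max(float(ga.occ), 0.0), 1.0), 4)
                atoms.append(AtomRecord(
                    serial=int(ga.serial),
                    name=ga.name,
                    element=ga.element.name or "X",
                    alt_loc=(ga.altloc or "").strip("\x00"),
                    occupancy=occ,
                    b_factor=float(ga.b_iso),
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                ))
            if not atoms:
                continue
            atoms = _resolve_alt_locs(atoms, alt_loc_policy)
            res = Residue(
                chain_id=chain.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name.strip(),
                atoms=atoms,
            )
            if res.name in AMINO_ACIDS:
                out.chains.setdefault(chain.name, []).append(res)
            else:
                out.solvent.append(res)
    # duplicate-residue check
    seen: set[tuple[str, int, str]] = set()
    for res in out.iter_residues():
        if res.key in seen:
            raise StructureFormatError(
                f"duplicate residue {res.chain_id}:{res.number}{res.insertion_code}")
        seen.add(res.key)
    return out


def parse_structure(content: str, alt_loc_policy: str = "highest_occupancy",
                    structure_id: str = "") -> Structure:
    """Parse PDB or mmCIF text into a :class:`Structure`.

    Hydrogens are dropped; alternate locations resolved per policy
    (``highest_occupancy`` or ``first``); non-amino-acid residues go to
    ``solvent``.
    """
    st = _read_gemmi(content)
    if len(st) == 0:
        raise StructureFormatError("no models in input")
    out = _convert_model(st[0], alt_loc_policy)
    if out.n_atoms == 0:
        raise StructureFormatError("no atom records in input")
    out.id = structure_id or st.name or ""
    return out


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(serial: int, a: AtomRecord, res: Residue, hetatm: bool,
                      position=None) -> str:
    if len(res.chain_id) > 1:
        raise StructureFormatError(
            f"chain id {res.chain_id!r} too long for PDB format (1 character)")
    pos = a.position if position is None else position
    name = a.name
    # standard PDB alignment: element symbols of one letter start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    record = "HETATM" if hetatm else "ATOM  "
    return (f"{record}{serial:5d} {name:<4s}{a.alt_loc or ' ':1s}{res.name:>3s} "
            f"{res.chain_id:1s}{res.number:4d}{res.insertion_code or ' ':1s}   "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
            f"{a.element:>2s}")


def _structure_lines(s: Structure, coords=None) -> list[str]:
    lines: list[str] = []
    serial = 0
    i = 0
    for chain_id, residues in s.chains.items():
        for res in residues:
            for a in res.atoms:
                pos = None if coords is None else coords[i]
                i += 1
                serial += 1
                lines.append(_format_atom_line(serial, a, res, hetatm=False, position=pos))
        lines.append(f"TER   {serial + 1:5d}      "
                     f"{residues[-1].name:>3s} {chain_id:1s}{residues[-1].number:4d}")
        serial += 1
    for res in s.solvent:
        for a in res.atoms:
            pos = None if coords is None else coords[i]
            i += 1
            serial += 1
            lines.append(_format_atom_line(serial, a, res, hetatm=True, position=pos))
    return lines


def write_structure(s: Structure) -> str:
    """Serialize a structure as PDB text (3-decimal coordinates, 2-decimal b)."""
    if s.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    return "\n".join(_structure_lines(s) + ["END"]) + "\n"


def write_trajectory(t: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text."""
    lines: list[str] = []
    for m, frame in enumerate(t.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        lines.extend(_structure_lines(t.topology, coords=frame))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def parse_trajectory(content: str, times=None, total_duration: float | None = None,
                     alt_loc_policy: str = "highest_occupancy") -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    Parameters
    ----------
    times : array-like, optional
        Explicit per-frame time stamps (µs).
    total_duration : float, optional
        If given (and ``times`` is not), frames are stamped uniformly from 0
        to ``total_duration`` µs.  The file format itself carries no time.
    """
    st = _read_gemmi(content)
    if len(st) == 0:
        raise StructureFormatError("no models in input")
    models = [_convert_model(m, alt_loc_policy) for m in st]
    topo = models[0]
    n = topo.n_atoms
    if n == 0:
        raise StructureFormatError("no atom records in input")
    frames = []
    for i, m in enumerate(models):
        coords = np.array([a.position for _, a in m.iter_atoms()], dtype=float)
        if coords.shape[0] != n:
            raise StructureFormatError(
                f"model {i + 1}: atom count {coords.shape[0]} differs from model 1 ({n})")
        frames.append(coords)
    if times is None:
        if total_duration is not None:
            times = (np.linspace(0.0, float(total_duration), len(frames))
                     if len(frames) > 1 else np.array([0.0]))
        else:
            times = np.arange(len(frames), dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(frames):
        raise ValueError(f"{len(times)} time stamps for {len(frames)} frames")
    return Trajectory(topology=topo, frames=frames, times=times)


# ---------------------------------------------------------------------------
# chromatograms

def parse_chromatogram(table: str, v0: float | None = None,
                       vc: float | None = None) -> Chromatogram:
    """Parse two-column (volume, absorbance) delimited text.

    Comma, tab, semicolon, or whitespace delimited; an optional single header
    row is skipped.
    """
    if not table.strip():
        raise StructureFormatError("empty chromatogram table")
    try:
        df = pd.read_csv(io.StringIO(table), sep=None, engine="python",
                         header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise StructureFormatError(f"cannot parse chromatogram table: {exc}") from None
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise StructureFormatError("expected two columns (volume, absorbance)")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise StructureFormatError("non-numeric values in chromatogram body")
    if len(df) < 2:
        raise StructureFormatError("chromatogram needs at least 2 data rows")
    vol = df.iloc[:, 0].to_numpy(float)
    if not np.all(np.diff(vol) > 0):
        raise StructureFormatError("elution volume not strictly increasing")
    return Chromatogram(volume=vol, absorbance=df.iloc[:, 1].to_numpy(float),
                        v0=v0, vc=vc)


def write_chromatogram(c: Chromatogram) -> str:
    """Serialize a chromatogram as CSV with a header row."""
    lines = ["volume_mL,absorbance"]
    lines += [f"{v:.6g},{a:.8g}" for v, a in zip(c.volume, c.absorbance)]
    return "\n".join(lines) + "\n"
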