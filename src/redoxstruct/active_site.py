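"""Catalytic-pocket mapping by homolog-ligand proximity, and PTM-site distances.

A target apo structure inherits its pocket from a holo homolog: the holo
chain is superposed onto the target (CA atoms, sequence-alignment pairing,
iterative trim), the ligand's atoms are carried through the fitted rigid
motion into the target frame, and every target residue with any heavy atom
within the cutoff (default 4 Å) of any ligand atom is reported.  Residue
identity always travels through the chain alignment, so a numbering offset
between homologs cannot corrupt the reported pocket.

Distances from named residue groups (e.g. clusters of phosphorylation
sites) to a reference atom — typically the oxygen of a catalytic-pocket
water — are summarized per group over CA atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

from .geometry import Superposition, apply_superposition, superpose_chains, DEFAULT_TRIM
from .structio import Structure

__all__ = ["PocketMap", "SiteDistanceReport", "map_pocket_from_holo",
           "site_distances"]


@dataclass
class PocketResidue:
    number: int
    insertion_code: str
    one_letter: str
    min_distance: float


@dataclass
class PocketMap:
    ligand_id: tuple[str, int, str]     # chain, resnum, resname in holo
    cutoff: float
    residues: list[PocketResidue]
    superposition_used: Superposition
    target_chain: str = ""

    def numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def labels(self) -> list[str]:
        """Residue labels like 'E155', sorted by target numbering."""
        return [f"{r.one_letter}{r.number}" for r in self.residues]

    def to_dict(self) -> dict:
        return {
            "ligand": list(self.ligand_id),
            "cutoff_A": self.cutoff,
            "target_chain": self.target_chain,
            "superposition_rmsd_A": self.superposition_used.rmsd,
            "residues": [
                {"number": r.number, "icode": r.insertion_code,
                 "code": r.one_letter, "min_distance_A": round(r.min_distance, 3)}
                for r in self.residues
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_bed(self) -> str:
        """BED-like tab table of contiguous residue ranges."""
        nums = sorted(self.numbers())
        ranges = []
        for n in nums:
            if ranges and n == ranges[-1][1] + 1:
                ranges[-1][1] = n
            else:
                ranges.append([n, n])
        lines = [f"{self.target_chain}\t{a}\t{b}" for a, b in ranges]
        return "\n".join(lines) + "\n" if lines else ""


@dataclass
class SiteDistanceReport:
    reference_atom: str
    groups: dict[str, dict] = field(default_factory=dict)
    # each group: {"residues": [...], "missing": [...], "min": .., "mean": .., "max": ..}

    def to_dict(self) -> dict:
        return {"reference_atom": self.reference_atom, "groups": self.groups}


def map_pocket_from_holo(target: Structure, target_chain: str,
                         holo: Structure, holo_chain: str,
                         ligand_id: tuple[str, int, str] | str,
                         cutoff: float = 4.0,
                         trim: dict | None = DEFAULT_TRIM) -> PocketMap:
    """Map the holo ligand's contact shell onto the target chain.

    ``ligand_id`` is ``(chain, resnum, resname)`` or a ``"B:401:FBP"``
    string naming a het residue of the holo structure.
    """
    if isinstance(ligand_id, str):
        parts = ligand_id.split(":")
        if len(parts) != 3:
            raise ValueError(f"ligand id {ligand_id!r}: expected 'chain:resnum:resname'")
        ligand_id = (parts[0], int(parts[1]), parts[2])
    lig_chain, lig_num, lig_name = ligand_id
    try:
        ligand = holo.solvent_residue(lig_num, chain_id=lig_chain or None,
                                      name=lig_name or None)
    except KeyError:
        raise KeyError(f"ligand {ligand_id} not found among holo het residues") from None
    if not ligand.atoms:
        raise ValueError(f"ligand {ligand_id} has no atoms")
    sup = superpose_chains(holo, holo_chain, target, target_chain, trim=trim)
    lig_coords = apply_superposition(
        np.array([a.position for a in ligand.atoms]), sup)
    residues = []
    for res in target.chain(target_chain):
        coords = np.array([a.position for a in res.atoms])
        d = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
        dmin = float(d.min())
        if dmin <= cutoff:
            residues.append(PocketResidue(
                number=res.number, insertion_code=res.insertion_code,
                one_letter=res.one_letter, min_distance=dmin))
    residues.sort(key=lambda r: (r.number, r.insertion_code))
    return PocketMap(ligand_id=ligand_id, cutoff=cutoff, residues=residues,
                     superposition_used=sup, target_chain=target_chain)


def site_distances(s: Structure, reference_atom: str,
                   groups: dict[str, list], chain: str | None = None,
                   atom_name: str = "CA") -> SiteDistanceReport:
    """Min/mean/max CA distance from each named residue group to a reference.

    ``groups`` maps a group name to residue numbers (ints, searched in
    ``chain``) or ``"A:112"`` chain-qualified strings.  Residues missing
    from the model are reported and excluded; a group with no modeled
    residue raises.
    """
    _, ref = s.select_atom(reference_atom)
    report = SiteDistanceReport(reference_atom=reference_atom)
    for name, members in groups.items():
        dists, found, missing = [], [], []
        for m in members:
            if isinstance(m, str) and ":" in m:
                c, num = m.split(":")
                num = int(num)
            else:
                c, num = chain, int(m)
            if c is None:
                raise ValueError(f"group {name!r}: member {m!r} has no chain "
                                 f"(pass chain= or qualify as 'A:112')")
            try:
                res = s.residue(c, num)
            except KeyError:
                missing.append(f"{c}:{num}")
                continue
            a = res.atom(atom_name)
            if a is None:
                missing.append(f"{c}:{num}")
                continue
            dists.append(float(np.linalg.norm(a.position - ref.position)))
            found.append(f"{c}:{num}")
        if not dists:
            raise ValueError(f"group {name!r}: no member residue modeled")
        report.groups[name] = {
            "residues": found, "missing": missing,
            "min": float(np.min(dists)), "mean": float(np.mean(dists)),
            "max": float(np.max(dists)),
        }
    return report
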