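"""Cysteine redox-site census and the thiol-titration / activity arithmetic.

Each cysteine in a structure is classified into exactly one of:

* ``disulfide`` — its SG lies within the bond cutoff (default 2.3 Å,
  covalent S–S ≈ 2.05 Å plus coordinate error at ~3 Å resolution) of a
  partner SG;
* ``exposed_free`` — free thiol whose SG accessible area exceeds the
  exposure threshold;
* ``buried_free`` — free thiol shielded from solvent;
* ``unresolved`` — the SG atom is missing from the model.

Free thiols additionally get dithiol/disulfide *exchange candidates*: other
free thiols within the ``direct`` tier (default <= 5 Å, close enough for
exchange with modest side-chain motion) or the ``rearrangement`` tier
(default <= 11 Å, requiring main-chain rearrangement).  The tier cutoffs are
a construction of this package, configurable, and every candidate is
reported with its raw distance so a conclusion never hinges on the default.

The predicted count of reactive cysteines (the exposed free thiols) is
reconciled against a DTNB (Ellman) titration with a two-standard-deviation
consistency rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .sasa import SasaTable
from .structio import Structure

__all__ = [
    "CysteineEntry", "CysteineReport", "TitrationResult", "ActivityResult",
    "detect_disulfides", "cysteine_report", "dtnb_stoichiometry",
    "reconcile_titration", "specific_activity",
    "DEFAULT_BOND_CUTOFF", "DEFAULT_DIRECT_EXCHANGE_CUTOFF",
    "DEFAULT_REARRANGEMENT_CUTOFF",
]

DEFAULT_BOND_CUTOFF = 2.3            # Å, SG-SG covalent bond detection
DEFAULT_DIRECT_EXCHANGE_CUTOFF = 5.0   # Å, direct thiol-disulfide exchange
DEFAULT_REARRANGEMENT_CUTOFF = 11.0    # Å, exchange needing rearrangement
DEFAULT_SG_EXPOSURE_THRESHOLD = 0.05   # Å², strict

#: Default TNB- molar extinction coefficient at 412 nm, mM^-1 cm^-1.
EPSILON_TNB = 14.15
#: Default NADPH molar extinction coefficient at 340 nm, mM^-1 cm^-1.
EPSILON_NADPH = 6.22


@dataclass
class CysteineEntry:
    chain: str
    number: int
    sg_present: bool
    disulfide_partner: tuple[str, int] | None
    nearest_thiol: tuple[str, int] | None
    nearest_thiol_distance: float | None
    exchange_candidates: list[dict]       # {partner, distance, tier}
    sg_asa: float | None
    cysteine_class: str                   # disulfide/exposed_free/buried_free/unresolved


@dataclass
class CysteineReport:
    entries: list[CysteineEntry]
    bond_cutoff: float
    direct_exchange_cutoff: float
    rearrangement_cutoff: float
    sg_exposure_threshold: float

    def per_chain(self, chain: str) -> list[CysteineEntry]:
        return [e for e in self.entries if e.chain == chain]

    @property
    def summary(self) -> dict[str, int]:
        counts = {"disulfide": 0, "exposed_free": 0, "buried_free": 0,
                  "unresolved": 0}
        for e in self.entries:
            counts[e.cysteine_class] += 1
        counts["total"] = len(self.entries)
        return counts

    def predicted_reactive(self, chain: str | None = None) -> int:
        """Count of exposed free thiols (per chain, or whole structure)."""
        pool = self.entries if chain is None else self.per_chain(chain)
        return sum(1 for e in pool if e.cysteine_class == "exposed_free")

    def disulfide_pairs(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        pairs = set()
        for e in self.entries:
            if e.disulfide_partner is not None:
                pairs.add(tuple(sorted([(e.chain, e.number), e.disulfide_partner])))
        return sorted(pairs)

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "bond_cutoff_A": self.bond_cutoff,
                "direct_exchange_cutoff_A": self.direct_exchange_cutoff,
                "rearrangement_cutoff_A": self.rearrangement_cutoff,
                "sg_exposure_threshold_A2": self.sg_exposure_threshold,
            },
            "cysteines": [asdict(e) for e in self.entries],
            "summary": self.summary,
            "predicted_reactive_per_structure": self.predicted_reactive(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"{'chain':<5} {'res':>4} {'class':<14} {'partner':<10} "
                 f"{'SG ASA':>8} nearest-thiol"]
        for e in self.entries:
            partner = (f"{e.disulfide_partner[0]}{e.disulfide_partner[1]}"
                       if e.disulfide_partner else "-")
            asa = f"{e.sg_asa:.3f}" if e.sg_asa is not None else "-"
            near = (f"{e.nearest_thiol[0]}{e.nearest_thiol[1]} "
                    f"({e.nearest_thiol_distance:.1f} A)"
                    if e.nearest_thiol else "-")
            lines.append(f"{e.chain:<5} {e.number:>4} {e.cysteine_class:<14} "
                         f"{partner:<10} {asa:>8} {near}")
        s = self.summary
        lines.append(f"classes: {s['disulfide']} disulfide, "
                     f"{s['exposed_free']} exposed free, "
                     f"{s['buried_free']} buried free, "
                     f"{s['unresolved']} unresolved "
                     f"(of {s['total']}); predicted reactive = "
                     f"{self.predicted_reactive()}")
        return "\n".join(lines)


@dataclass
class TitrationResult:
    A412: float
    path_length: float
    protein_conc: float
    epsilon_TNB: float
    thiols_per_monomer: float


@dataclass
class ActivityResult:
    dA340_per_min: float
    epsilon_NADPH: float
    path_length: float
    assay_volume: float
    enzyme_mass: float
    specific_activity: float     # µmol(NADPH) min^-1 mg^-1


def _sg_atoms(s: Structure):
    """All cysteine SG atoms as (chain, resnum, position)."""
    out = []
    for res in s.iter_residues():
        if res.name == "CYS":
            a = res.atom("SG")
            if a is not None:
                out.append((res.chain_id, res.number, a.position))
    return out


def detect_disulfides(s: Structure, bond_cutoff: float = DEFAULT_BOND_CUTOFF):
    """Greedy nearest-first pairing of SG atoms within the bond cutoff.

    Returns sorted symmetric pairs ``((chain, resnum), (chain, resnum))``,
    intra- and inter-chain alike; each SG joins at most one pair.
    """
    if bond_cutoff <= 0:
        raise ValueError("bond cutoff must be positive")
    sgs = _sg_atoms(s)
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][2] - sgs[j][2]))
            if d <= bond_cutoff:
                candidates.append((d, (sgs[i][0], sgs[i][1]), (sgs[j][0], sgs[j][1])))
    candidates.sort(key=lambda c: c[0])
    used: set[tuple[str, int]] = set()
    pairs = []
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append(tuple(sorted((a, b))))
    return sorted(pairs)


def cysteine_report(s: Structure, t: SasaTable,
                    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
                    direct_exchange_cutoff: float = DEFAULT_DIRECT_EXCHANGE_CUTOFF,
                    rearrangement_cutoff: float = DEFAULT_REARRANGEMENT_CUTOFF,
                    sg_exposure_threshold: float = DEFAULT_SG_EXPOSURE_THRESHOLD,
                    ) -> CysteineReport:
    """Full per-cysteine census of a structure.

    The SASA table must have been computed on (a superset of) the same
    structure; a cysteine SG missing from the table raises.
    """
    bonded = {}
    for a, b in detect_disulfides(s, bond_cutoff):
        bonded[a] = b
        bonded[b] = a
    sgs = _sg_atoms(s)
    sg_pos = {(c, n): p for c, n, p in sgs}
    free = [(c, n) for c, n, _ in sgs if (c, n) not in bonded]
    entries: list[CysteineEntry] = []
    table_residues = set(t.residue_keys())
    for res in s.iter_residues():
        if res.name != "CYS":
            continue
        key = (res.chain_id, res.number)
        sg = res.atom("SG")
        if sg is None:
            entries.append(CysteineEntry(
                chain=res.chain_id, number=res.number, sg_present=False,
                disulfide_partner=None, nearest_thiol=None,
                nearest_thiol_distance=None, exchange_candidates=[],
                sg_asa=None, cysteine_class="unresolved"))
            continue
        if (res.chain_id, res.number, res.insertion_code) not in table_residues:
            raise ValueError(f"SASA table does not cover cysteine "
                             f"{res.chain_id}:{res.number}; recompute on this structure")
        sg_asa = t.named_atom_area(res.chain_id, res.number, "SG",
                                   res.insertion_code)
        if sg_asa is None:
            raise ValueError(f"SASA table lacks SG area for {res.chain_id}:{res.number}")
        # nearest thiol neighbor (any other SG)
        others = [(k, float(np.linalg.norm(sg.position - p)))
                  for k, p in sg_pos.items() if k != key]
        nearest = min(others, key=lambda kv: kv[1]) if others else (None, None)
        partner = bonded.get(key)
        if partner is not None:
            cls = "disulfide"
            cands: list[dict] = []
        else:
            cls = ("exposed_free" if sg_asa > sg_exposure_threshold
                   else "buried_free")
            cands = []
            for other in free:
                if other == key:
                    continue
                d = float(np.linalg.norm(sg_pos[other] - sg.position))
                if d <= direct_exchange_cutoff:
                    tier = "direct"
                elif d <= rearrangement_cutoff:
                    tier = "rearrangement"
                else:
                    continue
                cands.append({"partner": list(other), "distance": round(d, 3),
                              "tier": tier})
            cands.sort(key=lambda c: c["distance"])
        entries.append(CysteineEntry(
            chain=res.chain_id, number=res.number, sg_present=True,
            disulfide_partner=partner,
            nearest_thiol=nearest[0], nearest_thiol_distance=nearest[1],
            exchange_candidates=cands, sg_asa=sg_asa, cysteine_class=cls))
    return CysteineReport(entries=entries, bond_cutoff=bond_cutoff,
                          direct_exchange_cutoff=direct_exchange_cutoff,
                          rearrangement_cutoff=rearrangement_cutoff,
                          sg_exposure_threshold=sg_exposure_threshold)


def dtnb_stoichiometry(A412: float, path_length: float, protein_conc: float,
                       epsilon: float = EPSILON_TNB) -> TitrationResult:
    """Free reactive thiols per protein monomer from a DTNB titration.

    [TNB-] = A412 / (ε l) in mM; thiols per monomer = [TNB-] / [protein].
    Concentrations in mM, path length in cm, ε in mM^-1 cm^-1.
    """
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if path_length <= 0:
        raise ValueError("path length must be positive")
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    thiols = A412 / (epsilon * path_length * protein_conc)
    return TitrationResult(A412=A412, path_length=path_length,
                           protein_conc=protein_conc, epsilon_TNB=epsilon,
                           thiols_per_monomer=thiols)


def reconcile_titration(r: CysteineReport, measured: float, sd: float,
                        chain: str | None = None) -> dict:
    """Compare predicted reactive-cysteine count with a titration.

    Consistent iff the predicted count falls within measured ± 2·sd.
    """
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    predicted = r.predicted_reactive(chain)
    lo, hi = measured - 2.0 * sd, measured + 2.0 * sd
    return {
        "predicted_reactive": predicted,
        "measured": measured,
        "sd": sd,
        "interval_2sd": [lo, hi],
        "verdict": "consistent" if lo <= predicted <= hi else "inconsistent",
    }


def specific_activity(dA340_per_min: float, epsilon_NADPH: float = EPSILON_NADPH,
                      path_length: float = 1.0, assay_volume: float = 1.0,
                      enzyme_mass: float = 1.0) -> ActivityResult:
    """Specific activity of a coupled assay followed at 340 nm.

    slope/(ε l) is the NADPH production rate in mM·min⁻¹ = µmol·mL⁻¹·min⁻¹;
    times the assay volume (mL) gives µmol·min⁻¹; per mg enzyme gives
    µmol(NADPH)·min⁻¹·mg⁻¹.
    """
    if enzyme_mass <= 0:
        raise ValueError("enzyme mass must be positive")
    if path_length <= 0 or epsilon_NADPH <= 0 or assay_volume <= 0:
        raise ValueError("epsilon, path length and volume must be positive")
    slope = dA340_per_min
    if slope < 0:
        warnings.warn("negative A340 slope clipped to zero", stacklevel=2)
        slope = 0.0
    rate_umol_per_min = slope / (epsilon_NADPH * path_length) * assay_volume
    return ActivityResult(
        dA340_per_min=dA340_per_min, epsilon_NADPH=epsilon_NADPH,
        path_length=path_length, assay_volume=assay_volume,
        enzyme_mass=enzyme_mass,
        specific_activity=rate_umol_per_min / enzyme_mass)
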