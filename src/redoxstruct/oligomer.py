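"""Interfaces, assemblies, SEC calibration/deconvolution, mass and ε280.

Interface size follows the PISA convention: buried area of a chain pair is
ASA(A) + ASA(B) − ASA(AB), i.e. the accessible area lost by both chains on
complex formation, computed with identical probe/lattice parameters for the
three terms.  Chains whose pairwise buried area reaches an assembly
threshold (default 500 Å², well above crystal-packing contacts) are joined
into connected components labeled by size (monomer/dimer/.../tetramer).

Size-exclusion chromatography support covers column calibration
(log10 mass vs elution volume, or vs the partition coefficient
Kav = (Ve−V0)/(Vc−V0) when column volumes are known), sum-of-Gaussians
peak deconvolution with a constant baseline, and conversion of fitted peak
areas into a percentage repartition of oligomeric species — peak *area*,
not height, is mass-proportional for equal-extinction species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .sasa import SasaTable, shrake_rupley
from .structio import Chromatogram, Structure

__all__ = [
    "InterfaceReport", "AssemblyGraph", "CalibrationCurve", "Peak",
    "PeakModel", "SpeciesRepartition",
    "buried_area", "detect_assemblies", "sec_calibrate", "apparent_mass",
    "elution_volume", "deconvolve", "repartition", "mass_extinction",
    "DEFAULT_ASSEMBLY_THRESHOLD",
]

DEFAULT_ASSEMBLY_THRESHOLD = 500.0   # Å² buried area
DEFAULT_CONTACT_CUTOFF = 4.5         # Å any-atom contact distance

#: Average residue masses (Da) of amino acids in a peptide chain.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: ε280 contributions, M^-1 cm^-1 (Trp, Tyr, cystine).
EPS_TRP, EPS_TYR, EPS_CYSTINE = 5500.0, 1490.0, 125.0


@dataclass
class InterfaceReport:
    chain_a: str
    chain_b: str
    asa_a: float
    asa_b: float
    asa_complex: float
    buried_area: float
    contribution_a: float
    contribution_b: float
    contacting_residues: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chains": [self.chain_a, self.chain_b],
            "asa_isolated_A2": [self.asa_a, self.asa_b],
            "asa_complex_A2": self.asa_complex,
            "buried_area_A2": self.buried_area,
            "per_chain_contribution_A2": [self.contribution_a, self.contribution_b],
            "contacting_residues": [list(r) for r in self.contacting_residues],
        }


@dataclass
class AssemblyGraph:
    chains: list[str]
    edges: list[tuple[str, str, float]]     # chain, chain, buried area
    threshold: float
    components: list[list[str]]

    LABELS = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
              5: "pentamer", 6: "hexamer", 8: "octamer"}

    def component_of(self, chain: str) -> list[str]:
        for comp in self.components:
            if chain in comp:
                return comp
        raise KeyError(f"chain {chain!r} not in graph")

    def labeled_components(self) -> list[tuple[str, list[str]]]:
        return [(self.LABELS.get(len(c), f"{len(c)}-mer"), c)
                for c in self.components]

    def to_dict(self) -> dict:
        return {
            "threshold_A2": self.threshold,
            "edges": [{"chains": [a, b], "buried_area_A2": w}
                      for a, b, w in self.edges],
            "components": [{"label": lab, "chains": c}
                           for lab, c in self.labeled_components()],
        }


@dataclass
class CalibrationCurve:
    """Linear fit of log10(mass/kDa) against Ve (or Kav when volumes given)."""

    slope: float
    intercept: float
    r_squared: float
    v0: float | None = None
    vc: float | None = None
    warning: str | None = None

    @property
    def uses_kav(self) -> bool:
        return self.v0 is not None and self.vc is not None

    def _x(self, ve: float) -> float:
        if self.uses_kav:
            return (ve - self.v0) / (self.vc - self.v0)
        return ve


@dataclass
class Peak:
    center: float     # mL
    width: float      # Gaussian sigma, mL
    area: float       # a.u. * mL


@dataclass
class PeakModel:
    peaks: list[Peak]
    baseline: float
    residual_norm: float
    converged: bool

    def evaluate(self, volume: np.ndarray) -> np.ndarray:
        v = np.asarray(volume, dtype=float)
        y = np.full_like(v, self.baseline)
        for p in self.peaks:
            y += (p.area / (p.width * np.sqrt(2.0 * np.pi))
                  * np.exp(-0.5 * ((v - p.center) / p.width) ** 2))
        return y

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])


@dataclass
class SpeciesRepartition:
    labels: list[str]
    percentages: list[float]

    def to_dict(self) -> dict:
        return dict(zip(self.labels, self.percentages))

    def __str__(self) -> str:
        return ":".join(f"{p:.0f}" for p in self.percentages) + \
            " (" + ":".join(self.labels) + ")"


# ---------------------------------------------------------------------------
# interfaces and assemblies

def buried_area(s: Structure, chain_a: str, chain_b: str,
                probe_radius: float = 1.4, n_points: int = 960,
                contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                sasa_tables: dict | None = None) -> InterfaceReport:
    """PISA-style buried area of a chain pair.

    Three SASA computations with identical parameters: each chain alone and
    the two-chain complex; buried = ASA_A + ASA_B − ASA_AB (clipped at 0).
    Precomputed tables can be passed via ``sasa_tables`` keyed by
    ``chain_a``, ``chain_b``, ``(chain_a, chain_b)``.
    """
    if chain_a == chain_b:
        raise ValueError("interface requires two distinct chains")
    tables = sasa_tables or {}

    def _table(key, chains):
        if key in tables:
            return tables[key]
        return shrake_rupley(s.subset(chains), probe_radius=probe_radius,
                             n_points=n_points)

    t_a = _table(chain_a, [chain_a])
    t_b = _table(chain_b, [chain_b])
    t_ab = _table((chain_a, chain_b), [chain_a, chain_b])
    asa_a, asa_b, asa_ab = t_a.total, t_b.total, t_ab.total

    def _chain_total(t: SasaTable, chain: str) -> float:
        return float(sum(v for (c, _, _, _), v in t.per_atom.items() if c == chain))

    contrib_a = asa_a - _chain_total(t_ab, chain_a)
    contrib_b = asa_b - _chain_total(t_ab, chain_b)
    # contacting residues by any-atom distance
    contacts: list[tuple[str, int]] = []
    ra = [(res, np.array([a.position for a in res.atoms]))
          for res in s.chain(chain_a)]
    rb = [(res, np.array([a.position for a in res.atoms]))
          for res in s.chain(chain_b)]
    for res_a, ca in ra:
        for res_b, cb in rb:
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            if d.min() <= contact_cutoff:
                if (chain_a, res_a.number) not in contacts:
                    contacts.append((chain_a, res_a.number))
                if (chain_b, res_b.number) not in contacts:
                    contacts.append((chain_b, res_b.number))
    return InterfaceReport(
        chain_a=chain_a, chain_b=chain_b, asa_a=asa_a, asa_b=asa_b,
        asa_complex=asa_ab,
        buried_area=max(asa_a + asa_b - asa_ab, 0.0),
        contribution_a=max(contrib_a, 0.0), contribution_b=max(contrib_b, 0.0),
        contacting_residues=sorted(contacts))


def detect_assemblies(s: Structure,
                      threshold: float = DEFAULT_ASSEMBLY_THRESHOLD,
                      probe_radius: float = 1.4, n_points: int = 960,
                      ) -> AssemblyGraph:
    """Score all chain pairs and join chains by buried-area threshold."""
    chains = list(s.chains)
    if not chains:
        raise ValueError("structure has no chains")
    tables = {c: shrake_rupley(s.subset([c]), probe_radius=probe_radius,
                               n_points=n_points) for c in chains}
    edges = []
    adjacency: dict[str, set[str]] = {c: set() for c in chains}
    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            rep = buried_area(s, a, b, probe_radius=probe_radius,
                              n_points=n_points, sasa_tables=tables)
            if rep.buried_area >= threshold:
                edges.append((a, b, rep.buried_area))
                adjacency[a].add(b)
                adjacency[b].add(a)
    # connected components, chain order preserved
    seen: set[str] = set()
    components = []
    for c in chains:
        if c in seen:
            continue
        stack, comp = [c], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(sorted(adjacency[x] - seen))
        components.append(sorted(comp))
    return AssemblyGraph(chains=chains, edges=edges, threshold=threshold,
                         components=components)


# ---------------------------------------------------------------------------
# SEC

def sec_calibrate(standards, v0: float | None = None,
                  vc: float | None = None) -> CalibrationCurve:
    """Least-squares line of log10(mass kDa) on Ve (or Kav).

    ``standards`` is a sequence of ``(Ve mL, mass kDa)`` pairs.  On a valid
    column larger species elute earlier, so the slope is negative; a
    positive slope is flagged, not fatal.
    """
    standards = [(float(v), float(m)) for v, m in standards]
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    ve = np.array([v for v, _ in standards])
    if len(np.unique(ve)) != len(ve):
        raise ValueError("duplicate elution volumes among standards")
    mass = np.array([m for _, m in standards])
    if np.any(mass <= 0):
        raise ValueError("standard masses must be positive")
    use_kav = v0 is not None and vc is not None
    x = (ve - v0) / (vc - v0) if use_kav else ve
    y = np.log10(mass)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    warning = "positive calibration slope" if slope >= 0 else None
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, v0=v0 if use_kav else None,
                            vc=vc if use_kav else None, warning=warning)


def apparent_mass(c: CalibrationCurve, ve: float) -> float:
    """Apparent molecular mass (kDa) at elution volume ``ve``."""
    return float(10.0 ** (c.slope * c._x(ve) + c.intercept))


def elution_volume(c: CalibrationCurve, mass_kda: float) -> float:
    """Inverse of :func:`apparent_mass`."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    x = (np.log10(mass_kda) - c.intercept) / c.slope
    if c.uses_kav:
        return float(c.v0 + x * (c.vc - c.v0))
    return float(x)


def estimate_baseline(c: Chromatogram, flank_fraction: float = 0.05) -> float:
    """Baseline level as the mean absorbance over the trace's flanks.

    Uses the first and last ``flank_fraction`` of the points; unbiased when
    the flanks are signal-free, which the caller must judge.
    """
    n = len(c.absorbance)
    k = max(int(round(n * flank_fraction)), 3)
    return float(np.concatenate([c.absorbance[:k], c.absorbance[-k:]]).mean())


def deconvolve(c: Chromatogram, n_peaks: int, init_centers,
               init_widths=None, baseline: str | float = "fit",
               max_nfev: int = 20000) -> PeakModel:
    """Fit a sum of Gaussians plus constant baseline to a chromatogram.

    The constant baseline is co-fitted by default (``baseline="fit"``, the
    maximum-likelihood treatment); passing a number instead holds the
    baseline fixed at that value (e.g. from :func:`estimate_baseline` when
    the flanks are known clean).  Non-negative areas and positive widths
    are enforced through bounds.  Non-convergence is flagged on the result,
    never raised.
    """
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    init_centers = [float(x) for x in init_centers]
    if len(init_centers) != n_peaks:
        raise ValueError(f"{len(init_centers)} init centers for {n_peaks} peaks")
    vmin, vmax = float(c.volume[0]), float(c.volume[-1])
    for x in init_centers:
        if not vmin <= x <= vmax:
            raise ValueError(f"init center {x} outside volume range [{vmin}, {vmax}]")
    span = vmax - vmin
    if init_widths is None:
        init_widths = [span / 20.0] * n_peaks
    v, y = c.volume, c.absorbance
    fit_baseline = baseline == "fit"
    fixed_base = None if fit_baseline else float(baseline)
    base0 = fixed_base if not fit_baseline else float(np.percentile(y, 5))
    areas0 = []
    for x0, w0 in zip(init_centers, init_widths):
        h = max(float(np.interp(x0, v, y)) - base0, 1e-12)
        areas0.append(h * w0 * np.sqrt(2 * np.pi))

    def unpack(p):
        centers = p[0:n_peaks]
        widths = p[n_peaks:2 * n_peaks]
        areas = p[2 * n_peaks:3 * n_peaks]
        base = p[-1] if fit_baseline else fixed_base
        return centers, widths, areas, base

    def model(p):
        centers, widths, areas, base = unpack(p)
        out = np.full_like(v, base)
        for x0, w, a in zip(centers, widths, areas):
            out += a / (w * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((v - x0) / w) ** 2)
        return out

    p0 = init_centers + list(init_widths) + areas0
    wmin = max(span * 1e-4, np.min(np.diff(v)) / 4.0)
    lower = [vmin] * n_peaks + [wmin] * n_peaks + [0.0] * n_peaks
    upper = [vmax] * n_peaks + [span] * n_peaks + [np.inf] * n_peaks
    if fit_baseline:
        p0, lower, upper = p0 + [base0], lower + [-np.inf], upper + [np.inf]
    p0, lower, upper = (np.array(p0), np.array(lower), np.array(upper))
    p0 = np.clip(p0, lower + 1e-12, np.where(np.isfinite(upper), upper - 1e-12, p0))
    res = least_squares(lambda p: model(p) - y, p0, bounds=(lower, upper),
                        max_nfev=max_nfev)
    centers, widths, areas, base = unpack(res.x)
    order = np.argsort(centers)
    peaks = [Peak(center=float(centers[i]), width=float(widths[i]),
                  area=float(areas[i])) for i in order]
    return PeakModel(peaks=peaks, baseline=float(base),
                     residual_norm=float(np.linalg.norm(res.fun)),
                     converged=bool(res.status > 0))


def repartition(p: PeakModel, species_labels) -> SpeciesRepartition:
    """Percentages of total fitted peak area, one species label per peak."""
    labels = list(species_labels)
    if len(labels) != len(p.peaks):
        raise ValueError(f"{len(labels)} labels for {len(p.peaks)} peaks")
    areas = p.areas()
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("zero total peak area; repartition undefined")
    return SpeciesRepartition(labels=labels,
                              percentages=[100.0 * a / total for a in areas])


# ---------------------------------------------------------------------------
# sequence-derived quantities

def mass_extinction(sequence: str) -> dict:
    """Average mass and ε280 of a protein sequence.

    Mass is the sum of average residue masses plus one water.  ε280 follows
    the standard 5500·nTrp + 1490·nTyr convention, with a second variant
    adding 125 per cystine (assuming all cysteines pairwise oxidized).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    unknown = sorted(set(seq) - set(RESIDUE_MASSES))
    if unknown:
        raise ValueError(f"unknown residue letter(s): {', '.join(unknown)}")
    mass = sum(RESIDUE_MASSES[r] for r in seq) + WATER_MASS
    n_trp = seq.count("W")
    n_tyr = seq.count("Y")
    n_cys = seq.count("C")
    eps_red = EPS_TRP * n_trp + EPS_TYR * n_tyr
    return {
        "average_mass_da": mass,
        "epsilon280_reduced": eps_red,
        "epsilon280_cystines": eps_red + EPS_CYSTINE * (n_cys // 2),
        "n_trp": n_trp, "n_tyr": n_tyr, "n_cys": n_cys,
        "length": len(seq),
    }
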