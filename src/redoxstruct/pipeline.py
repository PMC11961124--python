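"""One-config orchestration of the full structure-to-report run.

A single mapping (YAML/JSON file or dict) names the inputs and per-module
parameter overrides; :func:`run_report` executes every stage whose inputs
are present — census, chain superpositions, accessibility, cysteine redox
census, pocket mapping, interfaces/assemblies, SEC, trajectory analytics,
and the titration/activity arithmetic — and writes a machine-readable JSON
report plus a text rendering and tab-separated tables.  Stages with missing
inputs are marked skipped; a stage failure is isolated and recorded while
the remaining stages still run.  The same config and seed produce a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .active_site import map_pocket_from_holo, site_distances
from .geometry import bfactor_profile, radius_of_gyration, superpose_chains
from .oligomer import (buried_area, deconvolve, detect_assemblies,
                       mass_extinction, repartition, sec_calibrate,
                       apparent_mass)
from .redox import cysteine_report, dtnb_stoichiometry, reconcile_titration, \
    specific_activity
from .sasa import shrake_rupley
from .structio import parse_chromatogram, parse_structure, parse_trajectory
from . import trajectory as traj_mod

log = logging.getLogger("redoxstruct")

__all__ = ["RunConfig", "run_report", "validate_report", "load_schema"]

_TOP_KEYS = {
    "structure", "holo", "ligand", "trajectory", "chromatogram", "standards",
    "sequence", "titration", "activity", "params", "outdir", "seed",
}
_PARAM_KEYS = {"sasa", "redox", "superpose", "pocket", "assembly", "sec",
               "trajectory"}


class RunConfig:
    """Validated run configuration.

    Unknown keys are rejected; every referenced path must exist at
    validation time.
    """

    def __init__(self, mapping: dict, base_dir: Path | None = None):
        if not isinstance(mapping, dict):
            raise ValueError("config must be a mapping")
        unknown = set(mapping) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        params = mapping.get("params") or {}
        unknown = set(params) - _PARAM_KEYS
        if unknown:
            raise ValueError(f"unknown params section(s): {sorted(unknown)}")
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        self.raw = mapping
        self.params = params
        for key in ("structure", "holo", "trajectory", "chromatogram"):
            p = mapping.get(key)
            if p is not None and not self._path(p).exists():
                raise FileNotFoundError(f"config {key!r}: no such file: {p}")
        std = mapping.get("standards")
        if isinstance(std, str) and not self._path(std).exists():
            raise FileNotFoundError(f"config 'standards': no such file: {std}")
        self.seed = int(mapping.get("seed", 0))
        self.outdir = mapping.get("outdir")

    def _path(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        return cls(mapping or {}, base_dir=path.parent)

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def param(self, section: str, key: str, default=None):
        return (self.params.get(section) or {}).get(key, default)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _stage(report: dict, name: str, fn):
    try:
        report["stages"][name] = fn()
        log.info("stage %s: done", name)
    except Exception as exc:      # isolate stage failures
        log.error("stage %s failed: %s", name, exc)
        report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}


def run_report(config, outdir=None) -> dict:
    """Execute all runnable stages and write the report bundle.

    ``config`` is a :class:`RunConfig`, a mapping, or a path to a YAML/JSON
    config file.  Returns the report dict; files are written when an output
    directory is configured (``outdir`` argument or config key).
    """
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_file(config)
    elif isinstance(config, RunConfig):
        cfg = config
    else:
        cfg = RunConfig(config)
    outdir = outdir or cfg.outdir
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "effective_params": _round_floats(cfg.params),
        "stages": {},
    }

    structure = None
    if cfg.get("structure"):
        text = cfg._path(cfg.get("structure")).read_text()
        structure = parse_structure(text)

    sasa_params = {
        "probe_radius": float(cfg.param("sasa", "probe_radius", 1.4)),
        "n_points": int(cfg.param("sasa", "n_points", 960)),
    }

    # ---- structure-derived stages
    if structure is None:
        for name in ("census", "superposition", "sasa", "cysteines",
                     "interfaces"):
            report["stages"][name] = {"skipped": "no structure input"}
    else:
        s = structure

        def census():
            chains = {c: len(r) for c, r in s.chains.items()}
            return {
                "chains": chains,
                "n_chains": s.n_chains,
                "n_polymer_residues": s.n_polymer_residues,
                "n_atoms": s.n_atoms,
                "n_waters": s.n_waters,
                "radius_of_gyration_A": _round_floats(radius_of_gyration(s)),
                "b_factor_mean_per_chain": _round_floats({
                    c: float(np.mean(bfactor_profile(s, c)[1]))
                    for c in s.chains}),
            }
        _stage(report, "census", census)

        def superposition():
            chains = list(s.chains)
            if len(chains) < 2:
                return {"skipped": "fewer than two chains"}
            ref = chains[0]
            out = {}
            for c in chains[1:]:
                sup = superpose_chains(s, c, s, ref,
                                       mode=cfg.param("superpose", "mode",
                                                      "by_sequence"))
                out[f"{c}->{ref}"] = {
                    "rmsd_A": sup.rmsd, "rmsd_all_A": sup.rmsd_all,
                    "n_atoms": sup.n_atoms,
                    "retained_fraction": sup.retained_fraction,
                }
            return _round_floats(out)
        _stage(report, "superposition", superposition)

        sasa_table = None

        def sasa_stage():
            nonlocal sasa_table
            sasa_table = shrake_rupley(s, **sasa_params)
            return _round_floats({
                "probe_radius_A": sasa_params["probe_radius"],
                "n_points": sasa_params["n_points"],
                "total_asa_A2": sasa_table.total,
            })
        _stage(report, "sasa", sasa_stage)

        def cysteines():
            if sasa_table is None:
                raise RuntimeError("SASA stage did not run")
            rep = cysteine_report(
                s, sasa_table,
                bond_cutoff=float(cfg.param("redox", "bond_cutoff", 2.3)),
                direct_exchange_cutoff=float(
                    cfg.param("redox", "direct_exchange_cutoff", 5.0)),
                rearrangement_cutoff=float(
                    cfg.param("redox", "rearrangement_cutoff", 11.0)),
                sg_exposure_threshold=float(
                    cfg.param("redox", "sg_exposure_threshold", 0.05)))
            out = rep.to_dict()
            titr = cfg.get("titration")
            if titr:
                res = dtnb_stoichiometry(
                    A412=float(titr["A412"]),
                    path_length=float(titr.get("path_length", 1.0)),
                    protein_conc=float(titr["protein_conc"]),
                    epsilon=float(titr.get("epsilon", 14.15)))
                out["titration"] = {
                    "thiols_per_monomer": res.thiols_per_monomer,
                    **reconcile_titration(
                        rep, res.thiols_per_monomer,
                        float(titr.get("sd", 0.0)),
                        chain=titr.get("chain")),
                }
            return _round_floats(out)
        _stage(report, "cysteines", cysteines)

        def interfaces():
            if s.n_chains < 2:
                return {"skipped": "fewer than two chains"}
            graph = detect_assemblies(
                s, threshold=float(cfg.param("assembly", "threshold", 500.0)),
                **sasa_params)
            pairs = {}
            for a, b, w in graph.edges:
                rep = buried_area(s, a, b, **sasa_params)
                pairs[f"{a}-{b}"] = rep.to_dict()
            return _round_floats({"assemblies": graph.to_dict(),
                                  "interfaces": pairs})
        _stage(report, "interfaces", interfaces)

    # ---- pocket mapping
    if structure is not None and cfg.get("holo") and cfg.get("ligand"):
        def pocket():
            holo = parse_structure(cfg._path(cfg.get("holo")).read_text())
            target_chain = cfg.param("pocket", "target_chain",
                                     next(iter(structure.chains)))
            holo_chain = cfg.param("pocket", "holo_chain",
                                   next(iter(holo.chains)))
            pm = map_pocket_from_holo(
                structure, target_chain, holo, holo_chain, cfg.get("ligand"),
                cutoff=float(cfg.param("pocket", "cutoff", 4.0)))
            out = pm.to_dict()
            groups = cfg.param("pocket", "site_groups")
            ref = cfg.param("pocket", "reference_atom")
            if groups and ref:
                out["site_distances"] = site_distances(
                    structure, ref, groups, chain=target_chain).to_dict()
            return _round_floats(out)
        _stage(report, "pocket", pocket)
    else:
        report["stages"]["pocket"] = {"skipped": "no holo/ligand input"}

    # ---- SEC
    if cfg.get("chromatogram"):
        def sec():
            chrom = parse_chromatogram(
                cfg._path(cfg.get("chromatogram")).read_text(),
                v0=cfg.param("sec", "v0"), vc=cfg.param("sec", "vc"))
            out: dict = {"n_points": len(chrom.volume)}
            curve = None
            std = cfg.get("standards")
            if std is not None:
                if isinstance(std, str):
                    rows = [ln.split(",") for ln in
                            cfg._path(std).read_text().strip().splitlines()
                            if ln and not ln[0].isalpha()]
                    std = [(float(a), float(b)) for a, b in rows]
                curve = sec_calibrate(std, v0=cfg.param("sec", "v0"),
                                      vc=cfg.param("sec", "vc"))
                out["calibration"] = {
                    "slope": curve.slope, "intercept": curve.intercept,
                    "r_squared": curve.r_squared, "warning": curve.warning,
                }
            centers = cfg.param("sec", "init_centers")
            if centers:
                model = deconvolve(chrom, len(centers), centers)
                out["peaks"] = [
                    {"center_mL": p.center, "width_mL": p.width,
                     "area": p.area,
                     **({"apparent_mass_kDa": apparent_mass(curve, p.center)}
                        if curve else {})}
                    for p in model.peaks]
                out["baseline"] = model.baseline
                out["converged"] = model.converged
                out["residual_norm"] = model.residual_norm
                labels = cfg.param("sec", "labels")
                if labels:
                    rep = repartition(model, labels)
                    out["repartition_pct"] = rep.to_dict()
            return _round_floats(out)
        _stage(report, "sec", sec)
    else:
        report["stages"]["sec"] = {"skipped": "no chromatogram input"}

    # ---- trajectory analytics
    if cfg.get("trajectory"):
        def traj_stage():
            duration = cfg.param("trajectory", "total_duration")
            t = parse_trajectory(cfg._path(cfg.get("trajectory")).read_text(),
                                 total_duration=duration)
            chain = cfg.param("trajectory", "chain",
                              next(iter(t.topology.chains)))
            motif = cfg.param("trajectory", "motif", [112, 131])
            residues = [(chain, n) for n in range(int(motif[0]),
                                                  int(motif[1]) + 1)]
            core = cfg.param("trajectory", "core", "auto")
            core_sel = (traj_mod.default_core_selection(t.topology)
                        if core == "auto" else
                        [(chain, int(n)) for n in core])
            aligned = traj_mod.core_superpose(t, core_sel)
            series = traj_mod.residue_rmsd_series(aligned, residues)
            cps = traj_mod.detect_transitions(
                series,
                min_jump=float(cfg.param("trajectory", "min_jump", 1.0)),
                min_segment=int(cfg.param("trajectory", "min_segment", 5)),
                concert_window=float(
                    cfg.param("trajectory", "concert_window", 0.5)),
                concert_fraction=float(
                    cfg.param("trajectory", "concert_fraction", 0.75)))
            span = float(t.times[-1] - t.times[0])
            window = cfg.param("trajectory", "block_window") or \
                [float(t.times[0] + 0.85 * span), float(t.times[-1])]
            block = traj_mod.block_representative(aligned, tuple(window))
            fl = traj_mod.rmsf(aligned, residues)
            out = {
                "n_frames": t.n_frames,
                "core_rmsd_max_A": float(np.max(
                    aligned.metadata["core_rmsd"])),
                "events": [{"time_us": e.time, "fraction": e.fraction,
                            "concerted": e.concerted,
                            "mean_jump_A": e.mean_jump}
                           for e in cps.events],
                "block": {"window_us": list(block.window),
                          "medoid_frame": block.medoid_frame,
                          "medoid_time_us": block.medoid_time,
                          "mean_intra_block_rmsd_A":
                              block.mean_intra_block_rmsd},
                "rmsf_A": {f"{c}:{n}": v for (c, n), v in fl.items()},
            }
            pair = cfg.param("trajectory", "pair")
            if pair:
                d = traj_mod.pair_distance_series(aligned, pair[0], pair[1])
                out["pair_distance"] = {
                    "atoms": list(pair), "final_A": float(d[-1]),
                    "max_A": float(np.max(d)), "mean_A": float(np.mean(d)),
                }
            return _round_floats(out)
        _stage(report, "trajectory", traj_stage)
    else:
        report["stages"]["trajectory"] = {"skipped": "no trajectory input"}

    # ---- scalar assays
    if cfg.get("activity"):
        def activity():
            a = cfg.get("activity")
            res = specific_activity(
                dA340_per_min=float(a["dA340_per_min"]),
                epsilon_NADPH=float(a.get("epsilon", 6.22)),
                path_length=float(a.get("path_length", 1.0)),
                assay_volume=float(a.get("assay_volume", 1.0)),
                enzyme_mass=float(a["enzyme_mass"]))
            return _round_floats({
                "specific_activity_umol_min_mg": res.specific_activity})
        _stage(report, "activity", activity)
    else:
        report["stages"]["activity"] = {"skipped": "no assay input"}

    if cfg.get("sequence"):
        def sequence():
            seq = cfg.get("sequence")
            if not set(seq.upper()) <= set("ACDEFGHIKLMNPQRSTVWY") or \
                    Path(str(seq)).suffix in (".fa", ".fasta", ".txt"):
                p = cfg._path(seq)
                if p.exists():
                    lines = [ln.strip() for ln in p.read_text().splitlines()
                             if ln and not ln.startswith(">")]
                    seq = "".join(lines)
            return _round_floats(mass_extinction(seq))
        _stage(report, "sequence", sequence)
    else:
        report["stages"]["sequence"] = {"skipped": "no sequence input"}

    validate_report(report)
    if outdir:
        _write_bundle(report, Path(outdir))
    return report


# ---------------------------------------------------------------------------
# rendering and schema

def _render_text(obj, indent: int = 0) -> list[str]:
    pad = "  " * indent
    lines = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                lines.extend(_render_text(v, indent + 1))
            else:
                lines.append(f"{pad}{k}: {v}")
    elif isinstance(obj, list):
        for v in obj:
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}-")
                lines.extend(_render_text(v, indent + 1))
            else:
                lines.append(f"{pad}- {v}")
    else:
        lines.append(f"{pad}{obj}")
    return lines


def _write_bundle(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    # the text report is rendered from the JSON itself, so every number in
    # the text is guaranteed to appear in the JSON
    (outdir / "report.txt").write_text("\n".join(_render_text(report)) + "\n")
    log.info("report written to %s", outdir)


def load_schema() -> dict:
    path = Path(__file__).parent / "schemas" / "report.schema.json"
    return json.loads(path.read_text())


def _check(value, spec, where: str):
    kind = spec.get("type")
    types = {"object": dict, "array": list, "string": str, "integer": int,
             "number": (int, float), "boolean": bool}
    if kind and not isinstance(value, types[kind]):
        raise ValueError(f"report schema violation at {where}: "
                         f"expected {kind}, got {type(value).__name__}")
    if kind == "object":
        for req in spec.get("required", []):
            if req not in value:
                raise ValueError(f"report schema violation at {where}: "
                                 f"missing required key {req!r}")
        for key, sub in spec.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{where}.{key}")


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (raises on violation)."""
    _check(report, load_schema(), "report")
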