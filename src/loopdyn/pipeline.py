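"""Configuration-driven orchestration of the analysis stages.

A pipeline run reads one plain-text (YAML) config, executes the requested
stages in dependency order (I/O → superposition → analyses), writes every
table as CSV into the output directory and records a manifest (parameters,
package version, seed, per-stage status and outputs).  Any stage failure
aborts the run with the failing stage named; partial outputs are kept and
the manifest carries a FAILED marker for that stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlations import build_network, dccm, lmi, loop_pair_average
from .dihedrals import box_occupancy, phi_psi
from .ensembles import (Ensemble, EnsembleError, SelectionMask, read_ensemble,
                        read_structure, resolve_loops, superpose)
from .fluctuations import bfactor_from_rmsf, rmsf
from .hbonds import occupancy_map
from .orderparams import direct_order_parameters, extract_vectors, ired_order_parameters
from .surface import fit_rmsf_model, relative_sasa, sasa

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineConfig", "run_pipeline"]

KNOWN_STAGES = ("superpose", "rmsf", "orderparams", "dccm", "lmi",
                "communities", "phipsi", "hbonds", "sasa", "regress")

DEFAULT_PARAMETERS = {
    "n_excluded": 5,
    "lmi_min": 0.4,
    "distance_range": [8.0, 10.0],
    "distance_step": 0.5,
    "hbond_floor": 10.0,
    "probe_radius": 1.4,
    "points_per_atom": 240,
    "running_window": 1,
    "phipsi_residue": None,
    "phipsi_reference": None,
    "hbond_groups": None,
}


class PipelineError(RuntimeError):
    """A stage failed or the configuration did not validate."""


class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULT_PARAMETERS`` for knobs)."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.stages: list[str] = list(raw.get("stages", KNOWN_STAGES))
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise PipelineError(f"unknown stage name(s): {unknown}; "
                                f"known stages: {list(KNOWN_STAGES)}")
        # keep dependency order regardless of listing order
        self.stages = [s for s in KNOWN_STAGES if s in self.stages]
        self.ensemble_path = raw.get("ensemble")
        if self.ensemble_path is None:
            raise PipelineError("config needs an 'ensemble' path")
        self.crystal_path = raw.get("crystal")
        self.hbond_path = raw.get("hbond_ensemble")
        for key in ("ensemble_path", "crystal_path", "hbond_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file does not exist: {p}")
        self.loops = {
            name: (chain, seq)
            for name, (chain, seq) in (raw.get("loops") or {}).items()
        }
        self.seed = int(raw.get("seed", 0))
        self.frame_interval_ps = raw.get("frame_interval_ps")
        self.parameters = dict(DEFAULT_PARAMETERS)
        self.parameters.update(raw.get("parameters") or {})
        p = self.parameters
        if not 0 < p["probe_radius"] <= 3.0:
            raise PipelineError("probe_radius out of range (0, 3] Å")
        if p["points_per_atom"] < 10:
            raise PipelineError("points_per_atom must be at least 10")
        if p["n_excluded"] < 0:
            raise PipelineError("n_excluded must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _convention_header(config: PipelineConfig) -> str:
    p = config.parameters
    return ("# conventions: angles wrapped to (-180,180] deg; "
            f"occupancy floor {p['hbond_floor']}%; "
            f"iRED n_excluded {p['n_excluded']}; LMI in nats (ln)\n")


def _write_csv(path: Path, df: pd.DataFrame, config: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_convention_header(config))
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig | dict | str | Path,
                 out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "loopdyn",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.parameters,
        "stages": {},
    }
    p = config.parameters

    ensemble = read_ensemble(config.ensemble_path, config.frame_interval_ps)
    crystal = (read_structure(config.crystal_path)
               if config.crystal_path else None)
    loops = (resolve_loops(ensemble.topology, config.loops)
             if config.loops else [])
    ca_mask = SelectionMask.alpha_carbons(ensemble.topology)
    state: dict = {}

    def finish(stage: str, outputs: list[str]) -> None:
        manifest["stages"][stage] = {"status": "OK", "outputs": outputs}

    for stage in config.stages:
        try:
            if stage == "superpose":
                ref = (crystal.atoms.coord if crystal is not None
                       and crystal.n_atoms == ensemble.n_atoms else 0)
                ensemble = superpose(ensemble, ca_mask, ref)
                finish(stage, [])
            elif stage == "rmsf":
                profile = bfactor_from_rmsf(rmsf(ensemble, ca_mask))
                path = out / "rmsf.csv"
                _write_csv(path, profile.to_frame(), config)
                state["rmsf"] = profile
                finish(stage, [str(path)])
            elif stage == "orderparams":
                residues = [(c, r) for c, r, _ in ca_mask.references]
                vt = extract_vectors(ensemble, residues)
                frames = [
                    ired_order_parameters(vt, p["n_excluded"]).to_frame(),
                    direct_order_parameters(vt).to_frame(),
                ]
                path = out / "orderparams.csv"
                _write_csv(path, pd.concat(frames, ignore_index=True), config)
                finish(stage, [str(path)])
            elif stage == "dccm":
                mat = dccm(ensemble, ca_mask)
                path = out / "dccm.csv"
                _write_csv(path, mat.to_frame(), config, index=True)
                outputs = [str(path)]
                if loops:
                    pair_path = out / "loop_correlations.csv"
                    _write_csv(pair_path, loop_pair_average(mat, loops),
                               config, index=True)
                    outputs.append(str(pair_path))
                finish(stage, outputs)
            elif stage == "lmi":
                state["lmi"] = lmi(ensemble, ca_mask)
                path = out / "lmi.csv"
                _write_csv(path, state["lmi"].to_frame(), config, index=True)
                finish(stage, [str(path)])
            elif stage == "communities":
                if "lmi" not in state:
                    state["lmi"] = lmi(ensemble, ca_mask)
                lo, hi = p["distance_range"]
                graph, part = build_network(
                    state["lmi"], p["lmi_min"], (lo, hi), p["distance_step"]
                )
                df = pd.DataFrame(
                    [{"chain": c, "res_id": r, "community": k}
                     for (c, r), k in sorted(part.assignment.items())]
                )
                path = out / "communities.csv"
                _write_csv(path, df, config)
                edge_path = out / "community_edges.csv"
                _write_csv(edge_path, pd.DataFrame(
                    [{"community_a": a, "community_b": b, "weight": w}
                     for (a, b), w in sorted(part.edge_weights.items())]
                ), config)
                manifest["selected_distance_cutoff_A"] = part.selected_cutoff
                manifest["n_communities"] = part.n_communities
                finish(stage, [str(path), str(edge_path)])
            elif stage == "phipsi":
                if not p["phipsi_residue"]:
                    raise PipelineError("phipsi stage needs 'phipsi_residue'")
                chain, res_id = p["phipsi_residue"]
                series = phi_psi(ensemble, (chain, int(res_id)))
                path = out / "phipsi.csv"
                _write_csv(path, series.to_frame(), config)
                outputs = [str(path)]
                if p["phipsi_reference"]:
                    occ = box_occupancy(series, tuple(p["phipsi_reference"]))
                    occ_path = out / "box_occupancy.json"
                    occ_path.write_text(json.dumps({
                        "reference_deg": list(occ.reference),
                        "half_width_deg": occ.half_width,
                        "occupancy_pct": occ.percent_rounded,
                    }, indent=2))
                    outputs.append(str(occ_path))
                finish(stage, outputs)
            elif stage == "hbonds":
                hb_source = (read_ensemble(config.hbond_path)
                             if config.hbond_path else ensemble)
                groups = p["hbond_groups"] or [[hb_source.topology.chain_ids[0]],
                                               [hb_source.topology.chain_ids[-1]]]
                def chain_group(chains, topo):
                    return [
                        (c, int(r))
                        for c in chains
                        for r in topo.chain_residues(c)[0]
                    ]
                omap = occupancy_map(
                    hb_source,
                    chain_group(groups[0], hb_source.topology),
                    chain_group(groups[1], hb_source.topology),
                    crystal=None, floor=p["hbond_floor"],
                )
                path = out / "hbond_occupancy.csv"
                _write_csv(path, omap.table, config)
                manifest["hbond_count"] = omap.n_bonds
                finish(stage, [str(path)])
            elif stage == "sasa":
                target = crystal if crystal is not None else ensemble.frame(0)
                profile = relative_sasa(
                    sasa(target, p["probe_radius"], p["points_per_atom"])
                )
                path = out / "sasa.csv"
                _write_csv(path, profile.to_frame(), config)
                state["sasa"] = profile
                finish(stage, [str(path)])
            elif stage == "regress":
                if "rmsf" not in state or "sasa" not in state or crystal is None:
                    raise PipelineError(
                        "regress stage needs rmsf and sasa stages plus a crystal"
                    )
                sasa_by_res = {
                    (c, r): v for (c, r, _), v in
                    zip(state["sasa"].residues, state["sasa"].relative)
                }
                bfac, rel, obs = [], [], []
                for (c, r, _), value in zip(state["rmsf"].references,
                                            state["rmsf"].rmsf):
                    idx = crystal.atom_index(c, r, "CA")
                    bfac.append(float(crystal.atoms.b_factor[idx]))
                    rel.append(sasa_by_res[(c, r)])
                    obs.append(float(value))
                model = fit_rmsf_model(np.array(obs), np.array(bfac),
                                       np.array(rel))
                path = out / "regression.json"
                path.write_text(json.dumps({
                    "a_sasa_A": model.a, "b_bfactor_A_per_A2": model.b,
                    "c_intercept_A": model.c, "pearson_r": model.r,
                    "n": model.n,
                }, indent=2))
                finish(stage, [str(path)])
        except Exception as exc:
            manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
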