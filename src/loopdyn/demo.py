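"""A TCR-like synthetic demonstration dataset.

Builds a two-chain (α/β-like) toy receptor whose chain sequences embed the
six CDR loop sequences of either the A6 or the DMF5 T cell receptor, realises
a planted dynamic contrast on it — a highly mobile, uncorrelated CDR3β-like
loop against a rigid, mutually correlated CDR1α/CDR2α pair — and writes the
ensemble, a synthetic "crystal" reference with matching B-factors, and a loop
configuration file.  Every analysis stage of the package can run end-to-end
on this dataset with known ground truth.

The per-chain backbone is an ideal α-helical curve with full N/CA/C/O (+CB,
or Hα for glycine) atoms, so dihedral and hydrogen-bond machinery has real
atoms to work with.  Tryptophan linkers separate the loops; none of the CDR
sequences can recur across a linker boundary, so motif resolution is unique.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.sequence import ProteinSequence

from .ensembles import Ensemble, StructureModel, write_ensemble
from .fluctuations import B_FROM_MSF
from .geometry import build_backbone, place_atom
from .synthetic import GaussianEnsembleSpec, HBondScriptSpec, gaussian_ensemble, hbond_script

__all__ = ["CDR_SEQUENCES", "demo_loop_specs", "build_toy_receptor",
           "generate_demo_data"]

# CDR loop sequences of the A6 and DMF5 T cell receptors (α chain loops on
# chain A, β chain loops on chain B); CDR1α/CDR2α are germline-identical
CDR_SEQUENCES: dict[str, dict[str, tuple[str, str]]] = {
    "A6": {
        "CDR1a": ("A", "DRGSQS"),
        "CDR2a": ("A", "IYSNGD"),
        "CDR3a": ("A", "AVTTDSWGKLQ"),
        "CDR1b": ("B", "MNHEY"),
        "CDR2b": ("B", "SVGAGI"),
        "CDR3b": ("B", "ASRPGLAGGRPEQY"),
    },
    "DMF5": {
        "CDR1a": ("A", "DRGSQS"),
        "CDR2a": ("A", "IYSNGD"),
        "CDR3a": ("A", "AVNFGGGKLI"),
        "CDR1b": ("B", "MRHNA"),
        "CDR2b": ("B", "SNTAGT"),
        "CDR3b": ("B", "ASSLSFGTEAF"),
    },
}

LINKER = "WWWW"


def demo_loop_specs(receptor: str = "A6") -> dict[str, tuple[str, str]]:
    """Loop name → (chain, one-letter sequence) for the chosen receptor."""
    try:
        return dict(CDR_SEQUENCES[receptor])
    except KeyError:
        raise ValueError(f"unknown receptor {receptor!r}; "
                         f"choose from {sorted(CDR_SEQUENCES)}") from None


def _chain_sequence(loops: dict[str, tuple[str, str]], chain: str) -> str:
    parts = [seq for _, (c, seq) in sorted(loops.items()) if c == chain]
    return LINKER + LINKER.join(parts) + LINKER


def _build_chain(sequence: str, chain_id: str, origin: np.ndarray) -> list:
    n_res = len(sequence)
    bb = build_backbone(n_res, phi=-57.0, psi=-47.0)
    atoms = []
    for i, letter in enumerate(sequence):
        res_name = ProteinSequence.convert_letter_1to3(letter).upper()
        for name in ("N", "CA", "C", "O"):
            atoms.append(struc.Atom(bb[name][i] + origin, chain_id=chain_id,
                                    res_id=i + 1, res_name=res_name,
                                    atom_name=name, element=name[0]))
        side_name, elem, bond = (
            ("HA", "H", 1.09) if res_name == "GLY" else ("CB", "C", 1.53)
        )
        side = place_atom(bb["C"][i], bb["N"][i], bb["CA"][i],
                          bond, 110.5, 122.5)
        atoms.append(struc.Atom(side + origin, chain_id=chain_id,
                                res_id=i + 1, res_name=res_name,
                                atom_name=side_name, element=elem))
    return atoms


def build_toy_receptor(receptor: str = "A6") -> tuple[StructureModel, dict]:
    """Two-chain toy receptor embedding the receptor's CDR sequences."""
    loops = demo_loop_specs(receptor)
    seq_a = _chain_sequence(loops, "A")
    seq_b = _chain_sequence(loops, "B")
    atoms = _build_chain(seq_a, "A", np.zeros(3))
    atoms += _build_chain(seq_b, "B", np.array([40.0, 0.0, 0.0]))
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr), loops


def _planted_sigma_rho(model: StructureModel, receptor: str,
                       mobile_sigma: float = 1.2,
                       rigid_sigma: float = 0.25,
                       base_sigma: float = 0.4,
                       rigid_rho: float = 0.8) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-residue amplitudes and correlations realising the planted contrast."""
    from .ensembles import resolve_loops

    loops = resolve_loops(model, demo_loop_specs(receptor))
    arr = model.atoms
    starts = struc.get_residue_starts(arr)
    res_keys = [(str(arr.chain_id[s]), int(arr.res_id[s])) for s in starts]
    n = len(res_keys)
    index = {key: k for k, key in enumerate(res_keys)}
    sigma = np.full(n, base_sigma)
    rho = np.eye(n)
    loop_idx = {
        l.name: [index[(l.chain_id, int(r))] for r in l.res_ids] for l in loops
    }
    for i in loop_idx["CDR3b"]:
        sigma[i] = mobile_sigma
    rigid = loop_idx["CDR1a"] + loop_idx["CDR2a"]
    for i in rigid:
        sigma[i] = rigid_sigma
    for i in rigid:
        for j in rigid:
            if i != j:
                rho[i, j] = rigid_rho
    planted = {
        "mobile_loop": "CDR3b", "mobile_sigma_A": mobile_sigma,
        "rigid_loops": ["CDR1a", "CDR2a"], "rigid_sigma_A": rigid_sigma,
        "rigid_rho": rigid_rho, "base_sigma_A": base_sigma,
    }
    return sigma, rho, planted


def generate_demo_data(seed: int, out_dir: str | Path,
                       receptor: str = "A6",
                       n_frames: int = 2000) -> dict[str, str]:
    """Write the demonstration dataset; identical seed → identical files.

    Produces a multi-model PDB ensemble with the planted dynamic contrast, a
    single-frame "crystal" whose B-factor column encodes the planted
    amplitudes (B = 8π²σ², the isotropic equivalent of per-axis σ), a
    scripted hydrogen-bond ensemble with 60 % occupancy, and a YAML config
    for the pipeline.  Returns the mapping of artefact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, loop_specs = build_toy_receptor(receptor)
    sigma, rho, planted = _planted_sigma_rho(model, receptor)
    n_res = len(sigma)
    spec = GaussianEnsembleSpec(
        n_residues=n_res, sigma=sigma, rho=rho, n_frames=n_frames,
        seed=seed, template=model,
    )
    ensemble = gaussian_ensemble(spec)

    # crystal reference: template coordinates, B from the planted amplitudes
    crystal = StructureModel(model.atoms.copy())
    starts = struc.get_residue_starts(crystal.atoms, add_exclusive_stop=True)
    bfac = np.empty(crystal.n_atoms)
    for k, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        bfac[s:e] = B_FROM_MSF * 3.0 * sigma[k] ** 2
    crystal.atoms.b_factor = bfac

    rng = np.random.default_rng(seed + 1)
    flags = rng.random(200) < 0.6
    hb_ensemble, _ = hbond_script(HBondScriptSpec(flags))

    paths = {
        "ensemble": out / "demo_ensemble.pdb",
        "crystal": out / "demo_crystal.pdb",
        "hbond_ensemble": out / "demo_hbonds.pdb",
        "config": out / "demo_config.yaml",
        "planted": out / "planted_truth.json",
    }
    write_ensemble(paths["ensemble"], ensemble)
    write_ensemble(paths["crystal"],
                   Ensemble(crystal, crystal.atoms.coord[None, :, :]))
    write_ensemble(paths["hbond_ensemble"], hb_ensemble)
    config = {
        "ensemble": str(paths["ensemble"]),
        "crystal": str(paths["crystal"]),
        "hbond_ensemble": str(paths["hbond_ensemble"]),
        "frame_interval_ps": 1.0,
        "receptor": receptor,
        "loops": {k: list(v) for k, v in loop_specs.items()},
        "seed": seed,
        "stages": ["superpose", "rmsf", "orderparams", "dccm", "lmi",
                   "communities", "phipsi", "hbonds", "sasa", "regress"],
        "parameters": {
            "n_excluded": 5,
            "lmi_min": 0.4,
            "distance_range": [8.0, 10.0],
            "distance_step": 0.5,
            "hbond_floor": 10.0,
            "probe_radius": 1.4,
            "points_per_atom": 240,
            "running_window": 5,
            "phipsi_residue": ["A", 10],
            "phipsi_reference": [-57.0, -47.0],
            "hbond_groups": [["A"], ["B"]],
        },
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(paths["planted"], "w") as fh:
        json.dump(planted, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
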