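"""Structure/ensemble I/O, loop resolution and superposition."""

import numpy as np
import pytest
import biotite.structure as struc

from loopdyn.demo import build_toy_receptor, demo_loop_specs
from loopdyn.ensembles import (Ensemble, EnsembleError, SelectionMask,
                               StructureModel, read_ensemble, read_structure,
                               resolve_loops, superpose, write_ensemble)
from loopdyn.synthetic import GaussianEnsembleSpec, gaussian_ensemble

from conftest import make_model

PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 26.32           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      5  CA  GLY A   2       4.023   2.812   0.000  1.00 11.50           C
ATOM      6  C   GLY A   2       5.531   2.605   0.000  1.00 10.00           C
ATOM      7  N   SER A   3       6.244   3.730   0.000  1.00 10.00           N
ATOM      8  CA  SER A   3       7.700   3.700   0.000  1.00 12.00           C
ATOM      9  C   SER A   3       8.251   5.120   0.000  1.00 10.00           C
END
"""


def write_two_model_pdb(path, drop_atom_in_model=None):
    lines = [l for l in PDB_THREE_RESIDUES.splitlines() if l != "END"]
    out = []
    for m in (1, 2):
        out.append(f"MODEL     {m:4d}")
        body = list(lines)
        if drop_atom_in_model == m:
            body = body[:-1]
        out.extend(body)
        out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


class TestReadStructure:
    def test_bfactor_round_trips_from_file(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(PDB_THREE_RESIDUES)
        model = read_structure(p)
        idx = model.atom_index("A", 1, "CA")
        assert model.atoms.b_factor[idx] == pytest.approx(26.32)

    def test_two_models_topology_from_first(self, tmp_path):
        p = tmp_path / "two.pdb"
        write_two_model_pdb(p)
        model = read_structure(p)
        assert model.n_atoms == 9
        ens = read_ensemble(p)
        assert ens.n_frames == 2

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(EnsembleError):
            read_structure(p)

    def test_duplicate_atom_in_residue_rejected(self):
        atoms = [
            struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                       atom_name="CA", element="C"),
            struc.Atom([1, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                       atom_name="CA", element="C"),
        ]
        with pytest.raises(EnsembleError, match="duplicate"):
            make_model(atoms)


class TestReadEnsemble:
    def test_model_count(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_THREE_RESIDUES)
        assert read_ensemble(p).n_frames == 1

    def test_atom_count_mismatch_names_model(self, tmp_path):
        p = tmp_path / "bad.pdb"
        write_two_model_pdb(p, drop_atom_in_model=2)
        with pytest.raises(EnsembleError, match="2"):
            read_ensemble(p)

    def test_write_read_round_trip_to_pdb_precision(self, tmp_path):
        ens = gaussian_ensemble(
            GaussianEnsembleSpec(5, np.full(5, 0.4), n_frames=4, seed=3)
        )
        path = tmp_path / "ens.pdb"
        write_ensemble(path, ens)
        back = read_ensemble(path)
        assert back.n_frames == 4
        assert np.abs(back.coords - ens.coords).max() < 1.5e-3


class TestResolveLoops:
    def test_a6_and_dmf5_hypervariable_loop_lengths(self):
        for receptor, cdr3a, cdr3b in (("A6", 11, 14), ("DMF5", 10, 11)):
            model, _ = build_toy_receptor(receptor)
            loops = {l.name: l for l in
                     resolve_loops(model, demo_loop_specs(receptor))}
            assert len(loops["CDR3a"]) == cdr3a
            assert len(loops["CDR3b"]) == cdr3b

    def test_loop_sequence_matches_topology(self):
        model, _ = build_toy_receptor("A6")
        (loop,) = resolve_loops(model, {"CDR3b": ("B", "ASRPGLAGGRPEQY")})
        assert model.chain_sequence("B")[
            np.searchsorted(model.chain_residues("B")[0], loop.res_ids[0]):
        ].startswith(loop.sequence)

    def test_absent_sequence_is_error(self):
        model, _ = build_toy_receptor("A6")
        with pytest.raises(EnsembleError, match="0 times"):
            resolve_loops(model, {"missing": ("A", "KKKKKK")})

    def test_multiple_matches_is_error(self):
        model, _ = build_toy_receptor("A6")
        with pytest.raises(EnsembleError, match="times"):
            resolve_loops(model, {"linker": ("A", "WW")})

    def test_independent_of_spec_order(self):
        model, _ = build_toy_receptor("A6")
        specs = demo_loop_specs("A6")
        forward = resolve_loops(model, specs)
        backward = resolve_loops(
            model, dict(reversed(list(specs.items())))
        )
        assert [(l.name, list(l.res_ids)) for l in forward] == \
               [(l.name, list(l.res_ids)) for l in backward]


def random_rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.standard_normal(3) * 5


class TestSuperpose:
    def make_ensemble(self, rng, n_frames=1):
        ens = gaussian_ensemble(
            GaussianEnsembleSpec(8, np.full(8, 0.0), n_frames=n_frames,
                                 seed=int(rng.integers(1 << 30)))
        )
        return ens

    def test_exact_rigid_motion_is_removed(self, rng):
        ens = self.make_ensemble(rng)
        rot, trans = random_rigid(rng)
        moved = Ensemble(ens.topology,
                         np.stack([ens.coords[0], ens.coords[0] @ rot.T + trans]))
        mask = SelectionMask.alpha_carbons(ens.topology)
        fitted = superpose(moved, mask, 0)
        rmsd = np.sqrt(((fitted.coords[1] - fitted.coords[0]) ** 2)
                       .sum(axis=1).mean())
        assert rmsd < 1e-8

    def test_identity_frame_unchanged(self, rng):
        ens = self.make_ensemble(rng)
        mask = SelectionMask.alpha_carbons(ens.topology)
        fitted = superpose(ens, mask, 0)
        assert np.allclose(fitted.coords, ens.coords, atol=1e-10)

    def test_collinear_mask_is_error(self):
        atoms = [
            struc.Atom([i * 1.5, 0, 0], chain_id="A", res_id=i + 1,
                       res_name="ALA", atom_name="CA", element="C")
            for i in range(3)
        ]
        model = make_model(atoms)
        ens = Ensemble(model, model.atoms.coord[None, :, :])
        with pytest.raises(EnsembleError, match="collinear"):
            superpose(ens, SelectionMask.alpha_carbons(model), 0)

    def test_fit_beats_random_rigid_placements(self, rng):
        """The Kabsch fit is optimal among rigid motions (spot-checked)."""
        ens = gaussian_ensemble(
            GaussianEnsembleSpec(6, np.full(6, 0.8), n_frames=2, seed=11)
        )
        mask = SelectionMask.alpha_carbons(ens.topology)
        fitted = superpose(ens, mask, 0)
        ref = ens.coords[0][mask.indices]
        best = np.sqrt(((fitted.coords[1][mask.indices] - ref) ** 2)
                       .sum(axis=1).mean())
        frame = ens.coords[1][mask.indices]
        for _ in range(50):
            rot, trans = random_rigid(rng)
            rival = np.sqrt(((frame @ rot.T + trans - ref) ** 2)
                            .sum(axis=1).mean())
            assert best <= rival + 1e-9
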