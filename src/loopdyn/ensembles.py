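"""Structure and ensemble I/O, residue selections, loop resolution and superposition.

The central containers are :class:`StructureModel` (one topology: atoms,
residues, chains, B-factors) and :class:`Ensemble` (one topology plus an
ordered stack of coordinate frames, in Å).  Multi-model PDB is the on-disk
interchange format; parsing and writing are delegated to biotite.

Residue identity follows PDB author numbering plus insertion code throughout —
no renumbering is ever applied, so residue references like ``S127`` on a chain
mean exactly what the depositing authors wrote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleError",
    "StructureModel",
    "Ensemble",
    "SelectionMask",
    "LoopDefinition",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "resolve_loops",
    "superpose",
    "kabsch",
]


class EnsembleError(ValueError):
    """Raised for malformed structures, ensembles or unresolvable selections."""


@dataclass
class StructureModel:
    """One topology: an atom table with chain/residue organisation.

    Wraps a biotite ``AtomArray`` carrying at least ``chain_id``, ``res_id``,
    ``ins_code``, ``res_name``, ``atom_name``, ``element``, and (when the
    source file provides them) ``b_factor`` and ``occupancy`` annotations.
    """

    atoms: struc.AtomArray

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        arr = self.atoms
        if arr.array_length() == 0:
            raise EnsembleError("structure contains no atoms")
        starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
        for s, e in zip(starts[:-1], starts[1:]):
            names = arr.atom_name[s:e]
            if len(set(names)) != len(names):
                dup = sorted({n for n in names if list(names).count(n) > 1})
                raise EnsembleError(
                    f"duplicate atom name(s) {dup} in residue "
                    f"{arr.res_name[s]} {arr.chain_id[s]}{arr.res_id[s]}{arr.ins_code[s]}".strip()
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def chain_residues(self, chain_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(res_ids, ins_codes, res_names) of a chain, in file order."""
        sub = self.atoms[self.atoms.chain_id == chain_id]
        if sub.array_length() == 0:
            raise EnsembleError(f"chain {chain_id!r} not present")
        starts = struc.get_residue_starts(sub)
        return sub.res_id[starts], sub.ins_code[starts], sub.res_name[starts]

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter amino-acid sequence of a chain ('X' for non-standard)."""
        _, _, res_names = self.chain_residues(chain_id)
        letters = []
        for name in res_names:
            try:
                letters.append(ProteinSequence.convert_letter_3to1(str(name)))
            except KeyError:
                letters.append("X")
        return "".join(letters)

    def atom_index(self, chain_id: str, res_id: int, atom_name: str,
                   ins_code: str = "") -> int:
        arr = self.atoms
        hit = np.where(
            (arr.chain_id == chain_id)
            & (arr.res_id == res_id)
            & (arr.ins_code == ins_code)
            & (arr.atom_name == atom_name)
        )[0]
        if len(hit) != 1:
            raise EnsembleError(
                f"atom reference ({chain_id}, {res_id}{ins_code}, {atom_name}) "
                f"resolved to {len(hit)} atoms (need exactly 1)"
            )
        return int(hit[0])


@dataclass
class Ensemble:
    """An ordered stack of coordinate frames sharing one topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å.  ``frame_interval_ps``
    is metadata only (e.g. 1.0 for coordinates saved every picosecond); no
    analysis in this package is time-correlated, so it is used purely to
    translate time-based strides into frame strides.
    """

    topology: StructureModel
    coords: np.ndarray
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EnsembleError("an ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise EnsembleError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureModel:
        """A single frame as a standalone structure."""
        arr = self.topology.atoms.copy()
        arr.coord = np.array(self.coords[i])
        return StructureModel(arr)


@dataclass
class SelectionMask:
    """An ordered, fully resolved atom selection against one topology."""

    references: list[tuple[str, int, str]]
    indices: np.ndarray

    @classmethod
    def from_references(cls, model: StructureModel,
                        references: list[tuple[str, int, str]]) -> "SelectionMask":
        idx = np.array(
            [model.atom_index(c, r, a) for c, r, a in references], dtype=int
        )
        return cls(list(references), idx)

    @classmethod
    def alpha_carbons(cls, model: StructureModel,
                      chain_id: str | None = None,
                      res_ids: np.ndarray | list[int] | None = None) -> "SelectionMask":
        """All Cα atoms, optionally restricted to one chain and residue set."""
        arr = model.atoms
        sel = arr.atom_name == "CA"
        if chain_id is not None:
            sel &= arr.chain_id == chain_id
        if res_ids is not None:
            sel &= np.isin(arr.res_id, np.asarray(res_ids))
        idx = np.where(sel)[0]
        if len(idx) == 0:
            raise EnsembleError("selection matched no Cα atoms")
        refs = [
            (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.atom_name[i]))
            for i in idx
        ]
        return cls(refs, idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class LoopDefinition:
    """A named contiguous residue stretch on one chain (e.g. a CDR loop)."""

    name: str
    chain_id: str
    res_ids: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if len(self.res_ids) != len(self.sequence):
            raise EnsembleError(
                f"loop {self.name}: {len(self.res_ids)} residues but "
                f"sequence of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.res_ids)

    def mask(self, model: StructureModel, atom_name: str = "CA") -> SelectionMask:
        refs = [(self.chain_id, int(r), atom_name) for r in self.res_ids]
        return SelectionMask.from_references(model, refs)


# -- file I/O ------------------------------------------------------------------


def _load_pdb(path: str | Path) -> PDBFile:
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise EnsembleError(f"cannot parse PDB file {path}: {exc}") from exc
    if pdb.get_model_count() == 0:
        raise EnsembleError(f"{path}: no coordinate records found")
    return pdb


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file, returning the first model as a :class:`StructureModel`.

    B-factors and occupancies are preserved.  Alternate locations are reduced
    to the highest-occupancy conformer (ties broken by altloc letter order).
    """
    pdb = _load_pdb(path)
    arr = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    return StructureModel(arr)


def read_ensemble(path: str | Path, frame_interval_ps: float | None = None) -> Ensemble:
    """Read a multi-model PDB as an :class:`Ensemble`, frames in MODEL order."""
    pdb = _load_pdb(path)
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(
            altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:
        # locate the offending model for a useful message
        counts = []
        for m in range(1, n_models + 1):
            try:
                counts.append(
                    pdb.get_structure(model=m, altloc="occupancy").array_length()
                )
            except Exception:
                counts.append(-1)
        bad = [
            m + 1
            for m, c in enumerate(counts)
            if c != counts[0] or c < 0
        ]
        raise EnsembleError(
            f"{path}: models do not share one topology "
            f"(model(s) {bad or '?'} differ in atom count): {exc}"
        ) from exc
    template = stack[0]
    model = StructureModel(template)
    return Ensemble(model, np.array(stack.coord, dtype=float), frame_interval_ps)


def write_ensemble(path: str | Path, ensemble: Ensemble) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    stack = struc.from_template(
        ensemble.topology.atoms, np.asarray(ensemble.coords, dtype=np.float32)
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# -- loop resolution -----------------------------------------------------------


def resolve_loops(model: StructureModel,
                  loop_specs: dict[str, tuple[str, str]]) -> list[LoopDefinition]:
    """Locate named loops by sequence motif.

    ``loop_specs`` maps a loop name (e.g. ``CDR3b``) to ``(chain_id,
    one_letter_sequence)``.  Each sequence must occur exactly once in the
    chain; zero or multiple matches raise :class:`EnsembleError`.  The result
    is sorted by (chain, first residue) and is independent of spec order.
    """
    loops = []
    for name, (chain_id, seq) in loop_specs.items():
        chain_seq = model.chain_sequence(chain_id)
        n_hits = chain_seq.count(seq)
        if n_hits != 1:
            raise EnsembleError(
                f"loop {name}: sequence {seq!r} found {n_hits} times in "
                f"chain {chain_id} (need exactly 1)"
            )
        start = chain_seq.index(seq)
        res_ids, ins_codes, _ = model.chain_residues(chain_id)
        if any(ins_codes[start:start + len(seq)] != ""):
            logger.warning("loop %s spans residues with insertion codes", name)
        loops.append(
            LoopDefinition(name, chain_id, res_ids[start:start + len(seq)], seq)
        )
    loops.sort(key=lambda l: (l.chain_id, int(l.res_ids[0])))
    return loops


# -- superposition -------------------------------------------------------------


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation ``R`` and translation ``t`` mapping mobile onto reference.

    Least-squares rigid fit with a determinant guard so reflections are never
    returned.  Returns ``(R, t)`` with ``fitted = mobile @ R.T + t``.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ref_c - r @ mob_c
    return r, t


def superpose(ensemble: Ensemble, mask: SelectionMask,
              reference: np.ndarray | int = 0) -> Ensemble:
    """Rigid-body least-squares fit of every frame onto a reference.

    Each frame is rotated/translated so that the RMSD of the mask atoms to
    the reference is minimal (Kabsch fit; no reflection).  ``reference`` is
    a frame index or an explicit ``(n_atoms, 3)`` coordinate array (e.g. the
    crystallographic coordinates).
    """
    if isinstance(reference, (int, np.integer)):
        ref_coords = ensemble.coords[int(reference)]
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (ensemble.n_atoms, 3):
            raise EnsembleError("reference coordinates do not match topology")
    ref_sub = ref_coords[mask.indices]
    if len(mask) < 3:
        raise EnsembleError("superposition mask needs at least 3 atoms")
    centered = ref_sub - ref_sub.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise EnsembleError("superposition mask atoms are collinear/degenerate")
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        r, t = kabsch(ensemble.coords[f][mask.indices], ref_sub)
        out[f] = ensemble.coords[f] @ r.T + t
    return Ensemble(ensemble.topology, out, ensemble.frame_interval_ps)
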