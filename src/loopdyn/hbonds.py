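"""Hydrogen-bond detection, ensemble occupancy maps and interloop bond counting.

A hydrogen bond is declared when the donor→acceptor heavy-atom distance is at
most 3.5 Å and the donor–hydrogen–acceptor angle is at least 120°.  Donor and
acceptor chemistry for the standard amino acids is packaged below; only the
geometric criterion itself is tunable.

Crystal structures usually lack hydrogens.  A clearly-labelled fallback mode
detects bonds from the heavy-atom distance plus an antecedent–donor–acceptor
angle proxy (≥ 90°); results from that mode are flagged, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import Ensemble, EnsembleError, StructureModel
from .geometry import angle

logger = logging.getLogger(__name__)

__all__ = [
    "HBond",
    "OccupancyMap",
    "DONOR_ATOMS",
    "ACCEPTOR_ATOMS",
    "detect_hbonds",
    "occupancy_map",
    "interloop_hbonds",
]

DISTANCE_CUTOFF = 3.5   # Å, donor→acceptor heavy atoms
ANGLE_MIN = 120.0       # degrees, donor–hydrogen–acceptor
PROXY_ANGLE_MIN = 90.0  # degrees, antecedent–donor–acceptor (no-hydrogen mode)
_EPS = 1e-4             # absorbs float32 coordinate rounding at the inclusive
                        # boundaries (1e-4 Å / 1e-3 deg, far below any physics)

# side-chain donor/acceptor heavy atoms per residue type; the backbone amide
# N donates and the carbonyl O (and OXT) accepts for every amino acid
DONOR_ATOMS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
ACCEPTOR_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (atom references are (chain, res_id, atom))."""

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    hydrogen: tuple[str, int, str] | None
    distance: float
    angle: float
    proxy: bool = False  # True when detected without an explicit hydrogen


@dataclass
class OccupancyMap:
    """Residue-pair hydrogen-bond occupancy across an ensemble.

    ``table`` has one row per residue pair with at least one detected bond:
    the occupancy (%) of the most persistent donor/acceptor combination, and
    whether that pair is bonded in the crystallographic reference.  The
    summary (bond count, mean occupancy) applies ``floor`` (%) as the minimum
    occupancy for a bond to be counted as present in the interface.
    """

    table: pd.DataFrame
    floor: float

    @property
    def n_bonds(self) -> int:
        return int((self.table["occupancy_pct"] >= self.floor).sum())

    @property
    def mean_occupancy(self) -> float:
        kept = self.table.loc[self.table["occupancy_pct"] >= self.floor,
                              "occupancy_pct"]
        return float(kept.mean()) if len(kept) else float("nan")


def _group_atom_indices(model: StructureModel,
                        group: list[tuple[str, int]]) -> np.ndarray:
    arr = model.atoms
    keys = {(str(c), int(r)) for c, r in group}
    sel = np.array(
        [(str(arr.chain_id[i]), int(arr.res_id[i])) in keys
         for i in range(model.n_atoms)]
    )
    return np.where(sel)[0]


def _donors_and_acceptors(model: StructureModel, atom_idx: np.ndarray):
    arr = model.atoms
    donors, acceptors = [], []
    for i in atom_idx:
        res, name = str(arr.res_name[i]), str(arr.atom_name[i])
        if name == "N" or name in DONOR_ATOMS.get(res, ()):
            donors.append(i)
        if name in ("O", "OXT") or name in ACCEPTOR_ATOMS.get(res, ()):
            acceptors.append(i)
    return np.asarray(donors, dtype=int), np.asarray(acceptors, dtype=int)


def _attached(model: StructureModel, coords: np.ndarray, donor: int,
              element: str, max_dist: float) -> list[int]:
    """Atoms of the given element class covalently near the donor, same residue."""
    arr = model.atoms
    sel = (
        (arr.chain_id == arr.chain_id[donor])
        & (arr.res_id == arr.res_id[donor])
        & (arr.ins_code == arr.ins_code[donor])
    )
    idx = np.where(sel)[0]
    out = []
    for i in idx:
        if i == donor:
            continue
        is_h = str(arr.element[i]).upper() == "H"
        if (element == "H") != is_h:
            continue
        if np.linalg.norm(coords[i] - coords[donor]) <= max_dist:
            out.append(int(i))
    return out


def _ref(model: StructureModel, i: int) -> tuple[str, int, str]:
    arr = model.atoms
    return (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.atom_name[i]))


def detect_hbonds(model: StructureModel,
                  group_a: list[tuple[str, int]],
                  group_b: list[tuple[str, int]],
                  coords: np.ndarray | None = None,
                  allow_missing_hydrogen: bool = False) -> list[HBond]:
    """Hydrogen bonds between two residue groups in a single frame.

    Both donor→acceptor directions are examined.  Donors with no attached
    hydrogen are skipped with a warning unless ``allow_missing_hydrogen`` is
    set, in which case the antecedent-angle proxy is applied and the bond is
    flagged ``proxy=True``.
    """
    coords = model.atoms.coord if coords is None else np.asarray(coords, float)
    ia = _group_atom_indices(model, group_a)
    ib = _group_atom_indices(model, group_b)
    bonds: list[HBond] = []
    for d_idx, a_idx in ((ia, ib), (ib, ia)):
        donors, _ = _donors_and_acceptors(model, d_idx)
        _, acceptors = _donors_and_acceptors(model, a_idx)
        for d in donors:
            hydrogens = _attached(model, coords, d, "H", 1.25)
            antecedents = _attached(model, coords, d, "heavy", 1.8)
            for a in acceptors:
                dist = float(np.linalg.norm(coords[a] - coords[d]))
                if dist > DISTANCE_CUTOFF + _EPS:
                    continue
                if hydrogens:
                    best = max(
                        (angle(coords[d], coords[h], coords[a]), h)
                        for h in hydrogens
                    )
                    if best[0] >= ANGLE_MIN - 1e-3:
                        bonds.append(HBond(_ref(model, d), _ref(model, a),
                                           _ref(model, best[1]), dist, best[0]))
                elif allow_missing_hydrogen and antecedents:
                    best = max(
                        (angle(coords[x], coords[d], coords[a]), x)
                        for x in antecedents
                    )
                    if best[0] >= PROXY_ANGLE_MIN:
                        bonds.append(HBond(_ref(model, d), _ref(model, a),
                                           None, dist, best[0], proxy=True))
                else:
                    logger.warning(
                        "donor %s has no attached hydrogen; skipped "
                        "(enable allow_missing_hydrogen for proxy detection)",
                        _ref(model, d),
                    )
                    break  # no point looping remaining acceptors
    return bonds


def occupancy_map(ensemble: Ensemble,
                  group_a: list[tuple[str, int]],
                  group_b: list[tuple[str, int]],
                  crystal: StructureModel | None = None,
                  floor: float = 10.0,
                  allow_missing_hydrogen: bool = False) -> OccupancyMap:
    """Percent duration of every donor/acceptor contact across an ensemble.

    Per residue pair, the most persistent donor/acceptor atom combination
    defines the pair's occupancy.  When a crystallographic reference is
    given, pairs also bonded there (proxy mode, since crystals typically
    lack hydrogens) are flagged.
    """
    counts: dict[tuple, dict[tuple, int]] = {}
    for f in range(ensemble.n_frames):
        for bond in detect_hbonds(ensemble.topology, group_a, group_b,
                                  ensemble.coords[f], allow_missing_hydrogen):
            pair = (bond.donor[:2], bond.acceptor[:2])
            combo = (bond.donor, bond.acceptor)
            counts.setdefault(pair, {})
            counts[pair][combo] = counts[pair].get(combo, 0) + 1
    crystal_pairs = set()
    if crystal is not None:
        for bond in detect_hbonds(crystal, group_a, group_b,
                                  allow_missing_hydrogen=True):
            crystal_pairs.add((bond.donor[:2], bond.acceptor[:2]))
    rows = []
    for (res_a, res_b), combos in sorted(counts.items()):
        (donor, acceptor), n_present = max(
            combos.items(), key=lambda kv: (kv[1], kv[0])
        )
        rows.append({
            "residue_a": f"{res_a[0]}{res_a[1]}",
            "residue_b": f"{res_b[0]}{res_b[1]}",
            "donor_atom": donor[2],
            "acceptor_atom": acceptor[2],
            "occupancy_pct": 100.0 * n_present / ensemble.n_frames,
            "in_crystal": (res_a, res_b) in crystal_pairs,
        })
    table = pd.DataFrame(
        rows, columns=["residue_a", "residue_b", "donor_atom",
                       "acceptor_atom", "occupancy_pct", "in_crystal"]
    )
    return OccupancyMap(table, floor)


def interloop_hbonds(model: StructureModel,
                     loops: list) -> tuple[int, list[tuple[str, str, HBond]]]:
    """Hydrogen bonds between residues of two *different* loops of one receptor.

    Runs on a single structure; the no-hydrogen proxy mode is enabled since
    crystallographic models rarely carry hydrogens.  Returns the bond count
    and a breakdown listing the two loop names for every bond.
    """
    results: list[tuple[str, str, HBond]] = []
    for i, la in enumerate(loops):
        for lb in loops[i + 1:]:
            ga = [(la.chain_id, int(r)) for r in la.res_ids]
            gb = [(lb.chain_id, int(r)) for r in lb.res_ids]
            for bond in detect_hbonds(model, ga, gb,
                                      allow_missing_hydrogen=True):
                results.append((la.name, lb.name, bond))
    return len(results), results
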