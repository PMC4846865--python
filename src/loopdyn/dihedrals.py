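"""Backbone φ/ψ time series and bound-state box-occupancy statistics.

The box-occupancy statistic asks: in what percentage of frames does a
residue's (φ, ψ) pair lie within ±h° (circular distance, both angles) of a
reference conformation — e.g. the bound-state crystallographic angles?  Low
occupancy of the bound-state box in a free-receptor ensemble indicates that
the bound conformation is not spontaneously sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import Ensemble, EnsembleError
from .geometry import angular_difference, wrap_degrees

__all__ = ["DihedralSeries", "BoxOccupancy", "phi_psi", "box_occupancy"]


@dataclass
class DihedralSeries:
    """Per-frame (φ, ψ) for one residue, degrees in (−180, 180], NaN if undefined."""

    residue: tuple[str, int]
    phi: np.ndarray
    psi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"phi_deg": self.phi, "psi_deg": self.psi})


@dataclass
class BoxOccupancy:
    """Fraction of frames inside a ±half-width circular box around (φ0, ψ0)."""

    reference: tuple[float, float]
    half_width: float
    percent: float

    @property
    def percent_rounded(self) -> float:
        """Occupancy to the 0.1 % granularity used in reporting."""
        return round(self.percent, 1)


def _dihedral_series(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion over frame-stacked points, IUPAC convention, degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b1 / np.linalg.norm(b1, axis=1,
                                                       keepdims=True)), axis=1)
    return np.degrees(np.arctan2(y, x))


def phi_psi(ensemble: Ensemble, residue: tuple[str, int]) -> DihedralSeries:
    """Backbone φ/ψ series for one residue.

    φ needs C of the preceding residue, ψ the N of the following one; at
    chain termini the absent angle is NaN for every frame.  A missing
    backbone atom on the residue itself is an error naming the atom.
    """
    chain_id, res_id = residue
    topo = ensemble.topology
    res_ids, ins_codes, _ = topo.chain_residues(chain_id)
    pos = np.where(res_ids == res_id)[0]
    if len(pos) != 1:
        raise EnsembleError(f"residue ({chain_id}, {res_id}) not uniquely found")
    pos = int(pos[0])

    def backbone(rid: int, name: str) -> np.ndarray:
        try:
            return ensemble.coords[:, topo.atom_index(chain_id, rid, name), :]
        except EnsembleError as exc:
            raise EnsembleError(
                f"missing backbone atom {name} in residue ({chain_id}, {rid})"
            ) from exc

    n = backbone(res_id, "N")
    ca = backbone(res_id, "CA")
    c = backbone(res_id, "C")
    nan = np.full(ensemble.n_frames, np.nan)
    if pos > 0:
        c_prev = backbone(int(res_ids[pos - 1]), "C")
        phi = wrap_degrees(_dihedral_series(c_prev, n, ca, c))
    else:
        phi = nan
    if pos < len(res_ids) - 1:
        n_next = backbone(int(res_ids[pos + 1]), "N")
        psi = wrap_degrees(_dihedral_series(n, ca, c, n_next))
    else:
        psi = nan
    return DihedralSeries(residue, np.asarray(phi, float), np.asarray(psi, float))


def box_occupancy(series: DihedralSeries | np.ndarray,
                  reference: tuple[float, float],
                  half_width: float = 30.0) -> BoxOccupancy:
    """Percent of frames with both wrapped |Δφ| and |Δψ| ≤ half_width (inclusive).

    Accepts a :class:`DihedralSeries` or a plain (n_frames, 2) array of
    (φ, ψ) in degrees.  Frames with an undefined angle never count as inside.
    """
    if isinstance(series, DihedralSeries):
        phi, psi = series.phi, series.psi
    else:
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise EnsembleError("angle array must have shape (n_frames, 2)")
        phi, psi = arr[:, 0], arr[:, 1]
    if half_width < 0:
        raise EnsembleError("half-width must be non-negative")
    inside = (
        (angular_difference(phi, reference[0]) <= half_width)
        & (angular_difference(psi, reference[1]) <= half_width)
    )
    percent = 100.0 * float(np.count_nonzero(inside)) / len(phi)
    return BoxOccupancy(tuple(reference), float(half_width), percent)
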