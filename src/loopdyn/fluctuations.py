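"""Per-residue fluctuation profiles, B-factor interconversion, distance monitors
and snapshot RMSD matrices.

RMSF is defined against the ensemble-mean position,
``RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)``, and converts to an equivalent isotropic
temperature factor through ``B = (8π²/3)·RMSF²``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import Ensemble, EnsembleError, SelectionMask, kabsch

logger = logging.getLogger(__name__)

__all__ = [
    "FluctuationProfile",
    "DistanceSeries",
    "SnapshotRMSDMatrix",
    "rmsf",
    "bfactor_from_rmsf",
    "rmsf_from_bfactor",
    "distance_series",
    "groove_width",
    "snapshot_rmsd_matrix",
]

B_FROM_MSF = 8.0 * np.pi**2 / 3.0


@dataclass
class FluctuationProfile:
    """Per-atom (typically per-residue Cα) RMSF in Å, optional B in Å²."""

    references: list[tuple[str, int, str]]
    rmsf: np.ndarray
    bfactor: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.references, columns=["chain", "res_id", "atom"])
        df["rmsf_A"] = self.rmsf
        if self.bfactor is not None:
            df["bfactor_A2"] = self.bfactor
        return df


@dataclass
class DistanceSeries:
    """Per-frame distance between one atom pair, with a running average."""

    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    distances: np.ndarray
    window: int
    smoothed: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances.mean())


@dataclass
class SnapshotRMSDMatrix:
    """Pairwise Cα RMSD between snapshots pooled from labelled ensembles."""

    labels: list[str]             # per-snapshot source label
    matrix: np.ndarray            # symmetric, Å
    block_means: pd.DataFrame     # average RMSD per (source, source) pair


def rmsf(ensemble: Ensemble, mask: SelectionMask) -> FluctuationProfile:
    """Root-mean-square fluctuation of each mask atom about its mean position.

    The ensemble is expected to be superposed already; RMSF of a rigid
    ensemble is zero.
    """
    if len(mask) == 0:
        raise EnsembleError("RMSF needs a non-empty selection")
    if ensemble.n_frames == 1:
        logger.warning("single-frame ensemble: RMSF is identically zero")
    sub = ensemble.coords[:, mask.indices, :]
    dev = sub - sub.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return FluctuationProfile(list(mask.references), values)


def bfactor_from_rmsf(profile: FluctuationProfile) -> FluctuationProfile:
    """Fill the equivalent isotropic B-factor, B = (8π²/3)·RMSF² (Å²)."""
    return FluctuationProfile(
        profile.references, profile.rmsf, B_FROM_MSF * profile.rmsf**2
    )


def rmsf_from_bfactor(bfactor: np.ndarray) -> np.ndarray:
    """Inverse conversion, RMSF = sqrt(3·B/(8π²)); exact round-trip partner."""
    b = np.asarray(bfactor, dtype=float)
    if np.any(b < 0):
        raise EnsembleError("B-factors must be non-negative")
    return np.sqrt(b / B_FROM_MSF)


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean, truncated at the edges (output length = input)."""
    n = len(x)
    if window < 1:
        raise EnsembleError("window must be >= 1")
    if window > n:
        logger.warning("running-average window %d exceeds series length %d; "
                       "using the global mean", window, n)
        return np.full(n, x.mean())
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def distance_series(ensemble: Ensemble,
                    atom_a: tuple[str, int, str],
                    atom_b: tuple[str, int, str],
                    window: int = 1) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms plus a centered running mean."""
    ia = ensemble.topology.atom_index(*atom_a)
    ib = ensemble.topology.atom_index(*atom_b)
    d = np.linalg.norm(ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1)
    return DistanceSeries(atom_a, atom_b, d, window, running_mean(d, window))


def groove_width(ensemble: Ensemble,
                 res_a: tuple[str, int], res_b: tuple[str, int],
                 atom_name: str = "CA",
                 window: int = 1) -> DistanceSeries:
    """Distance series between two marker residues (Cα–Cα by default).

    Used e.g. to monitor the width of an MHC peptide-binding groove between
    a residue on the α1 helix and one on the α2 helix.
    """
    return distance_series(
        ensemble, (*res_a, atom_name), (*res_b, atom_name), window
    )


def _pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets after optimal rigid fit."""
    r, t = kabsch(b, a)
    fitted = b @ r.T + t
    return float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))


def snapshot_rmsd_matrix(ensembles: list[tuple[str, Ensemble]],
                         mask: SelectionMask,
                         stride: int = 1) -> SnapshotRMSDMatrix:
    """All-pairs Cα RMSD between snapshots taken every ``stride`` frames.

    Each snapshot pair is optimally superposed on the mask before the RMSD is
    taken, so rigid-body differences between ensembles do not contribute.
    Block means are unweighted averages of all cross-snapshot RMSDs per
    (source, source) pair; diagonal blocks use within-source off-diagonal
    pairs only.
    """
    if stride < 1:
        raise EnsembleError("stride must be >= 1")
    snaps, labels = [], []
    for label, ens in ensembles:
        for f in range(0, ens.n_frames, stride):
            snaps.append(ens.coords[f][mask.indices])
            labels.append(label)
    n = len(snaps)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pairwise_rmsd(snaps[i], snaps[j])
    uniq = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    rows = []
    for la in uniq:
        for lb in uniq:
            ia, ib = np.where(lab == la)[0], np.where(lab == lb)[0]
            block = mat[np.ix_(ia, ib)]
            if la == lb:
                vals = block[np.triu_indices_from(block, k=1)]
            else:
                vals = block.ravel()
            rows.append({"source_a": la, "source_b": lb,
                         "mean_rmsd_A": float(vals.mean()) if len(vals) else np.nan})
    return SnapshotRMSDMatrix(labels, mat, pd.DataFrame(rows))
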