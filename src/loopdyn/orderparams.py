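"""Generalized order parameters S² for bond vectors.

Two estimators are provided:

* :func:`ired_order_parameters` — isotropic reorientational eigenmode
  dynamics (iRED).  The M×M matrix ``A_ij = ⟨P2(μ̂_i·μ̂_j)⟩`` is
  eigendecomposed and ``S²_i = 1 − Σ_m λ_m e_{m,i}²`` where the sum runs over
  the internal modes, i.e. all but the ``n_excluded`` largest-eigenvalue
  (reorientational) modes.
* :func:`direct_order_parameters` — the closed-form second-rank estimator
  ``S²_i = (3·Σ_{ab} ⟨μ_a μ_b⟩² − 1)/2`` over the Cartesian components,
  independent of the eigenmode machinery; it serves as the cross-check.

Note that iRED carries a finite-size bias for small vector counts: excluding
``n_excluded`` of M modes removes at least a fraction ``n_excluded/M`` of
purely internal variance when the motions have no collective component, so
estimates converge to the direct values only for M ≫ n_excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import Ensemble, EnsembleError

__all__ = [
    "VectorTrajectory",
    "OrderParameterSet",
    "extract_vectors",
    "ired_order_parameters",
    "direct_order_parameters",
]


@dataclass
class VectorTrajectory:
    """Unit bond vectors per residue per frame, shape (n_frames, n_residues, 3)."""

    residues: list[tuple[str, int]]  # (chain_id, res_id)
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise EnsembleError("vectors must have shape (n_frames, n_residues, 3)")
        norms = np.linalg.norm(self.vectors, axis=2)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise EnsembleError("bond vectors must be unit-norm to 1e-6")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[1]


@dataclass
class OrderParameterSet:
    """Per-residue S² plus (for iRED) the eigenmode spectrum."""

    residues: list[tuple[str, int]]
    s2: np.ndarray
    method: str
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    n_excluded: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.residues, columns=["chain", "res_id"])
        df["s2"] = self.s2
        df["method"] = self.method
        df["n_excluded"] = self.n_excluded if self.n_excluded is not None else 0
        return df


def extract_vectors(ensemble: Ensemble,
                    residues: list[tuple[str, int]]) -> VectorTrajectory:
    """Normalised Cα→Cβ vectors per residue per frame (Cα→Hα for glycine).

    A glycine without an Hα/HA atom is an error, never a silent skip.
    """
    topo = ensemble.topology
    idx_pairs = []
    for chain_id, res_id in residues:
        sel = (topo.atoms.chain_id == chain_id) & (topo.atoms.res_id == res_id)
        if not sel.any():
            raise EnsembleError(f"residue ({chain_id}, {res_id}) not found")
        res_name = str(topo.atoms.res_name[np.where(sel)[0][0]])
        ca = topo.atom_index(chain_id, res_id, "CA")
        if res_name == "GLY":
            names = set(topo.atoms.atom_name[sel])
            hname = next((n for n in ("HA", "HA2", "HA1") if n in names), None)
            if hname is None:
                raise EnsembleError(
                    f"glycine ({chain_id}, {res_id}) lacks an Hα atom; "
                    "cannot build its bond vector"
                )
            other = topo.atom_index(chain_id, res_id, hname)
        else:
            other = topo.atom_index(chain_id, res_id, "CB")
        idx_pairs.append((ca, other))
    pairs = np.asarray(idx_pairs)
    vec = ensemble.coords[:, pairs[:, 1], :] - ensemble.coords[:, pairs[:, 0], :]
    vec /= np.linalg.norm(vec, axis=2, keepdims=True)
    return VectorTrajectory(list(residues), vec)


def _p2(x: np.ndarray) -> np.ndarray:
    return 1.5 * x * x - 0.5


def ired_covariance(vt: VectorTrajectory) -> np.ndarray:
    """The M×M iRED matrix ⟨P2(μ̂_i·μ̂_j)⟩ averaged over frames."""
    v = vt.vectors
    # Σ_f P2(v_fi · v_fj) accumulated through Gram matrices per frame batch
    n_f = v.shape[0]
    acc = np.zeros((v.shape[1], v.shape[1]))
    batch = max(1, int(2e7 // (v.shape[1] ** 2 or 1)))
    for s in range(0, n_f, batch):
        dots = np.einsum("fia,fja->fij", v[s:s + batch], v[s:s + batch])
        acc += _p2(dots).sum(axis=0)
    return acc / n_f


def ired_order_parameters(vt: VectorTrajectory,
                          n_excluded: int = 5) -> OrderParameterSet:
    """iRED order parameters with the ``n_excluded`` largest modes removed.

    Eigenvalues are returned in descending order; degenerate eigenvectors are
    made deterministic by forcing the first non-negligible component of each
    to be positive.  Tiny negative S² (> −1e−6) are clamped to 0.
    """
    m = vt.n_residues
    if m < 2 or vt.n_frames < 2:
        raise EnsembleError("iRED needs at least 2 residues and 2 frames")
    if n_excluded >= m:
        raise EnsembleError(
            f"cannot exclude {n_excluded} modes from a {m}-vector system"
        )
    mat = ired_covariance(vt)
    w, u = np.linalg.eigh(mat)      # ascending
    order = np.argsort(w)[::-1]     # descending, stable for ties by position
    w, u = w[order], u[:, order]
    for k in range(u.shape[1]):     # deterministic sign convention
        nz = np.where(np.abs(u[:, k]) > 1e-12)[0]
        if len(nz) and u[nz[0], k] < 0:
            u[:, k] = -u[:, k]
    internal = slice(n_excluded, m)  # the M − n_excluded smallest-λ modes
    s2 = 1.0 - np.einsum("m,im->i", w[internal], u[:, internal] ** 2)
    if np.any(s2 < -1e-6):
        raise EnsembleError("order parameter below numerical tolerance")
    s2 = np.clip(s2, 0.0, None)
    return OrderParameterSet(vt.residues, s2, "ired", w, u, n_excluded)


def direct_order_parameters(vt: VectorTrajectory) -> OrderParameterSet:
    """Second-rank tensor estimator: S² = (3·Σ_ab ⟨μ_a μ_b⟩² − 1)/2."""
    v = vt.vectors
    second = np.einsum("fia,fib->iab", v, v) / vt.n_frames  # ⟨μ_a μ_b⟩
    s2 = 0.5 * (3.0 * np.einsum("iab,iab->i", second, second) - 1.0)
    s2 = np.clip(s2, 0.0, 1.0 + 1e-9)
    return OrderParameterSet(vt.residues, s2, "direct")
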