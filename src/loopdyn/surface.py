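"""Solvent-accessible surface area and the surface/B-factor mobility regression.

SASA uses the Shrake–Rupley method with a deterministic Fibonacci-spiral
sphere point set (240 points per atom by default) and a 1.4 Å probe.  Per-
residue areas are normalised to the same residue type's area in an extended
Ala-X-Ala tripeptide, giving a relative accessibility in [0, ~1+] that is
comparable across residue types.

The mobility model is ordinary least squares on
``RMSF = a·(relative SASA) + b·(B-factor) + c``
with the Pearson correlation between fitted and observed RMSF as the summary
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr as _scipy_pearsonr
import statsmodels.api as sm

import biotite.structure as struc
from biotite.structure.info import residue as ccd_residue

from .ensembles import EnsembleError, StructureModel, kabsch
from .geometry import build_backbone

logger = logging.getLogger(__name__)

__all__ = [
    "SASAProfile",
    "RegressionModel",
    "VDW_RADII",
    "fibonacci_sphere",
    "sasa",
    "relative_sasa",
    "load_axa_reference",
    "build_axa_tripeptide",
    "build_axa_reference",
    "fit_rmsf_model",
    "pearson_r",
]

PROBE_RADIUS = 1.4
POINTS_PER_ATOM = 240

# Bondi van der Waals radii (Å); the single radii set used package-wide
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class SASAProfile:
    """Per-residue solvent-accessible surface area (Å²), optionally relative."""

    residues: list[tuple[str, int, str]]  # (chain, res_id, res_name)
    absolute: np.ndarray
    relative: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.residues, columns=["chain", "res_id", "res_name"])
        df["sasa_A2"] = self.absolute
        if self.relative is not None:
            df["relative_sasa"] = self.relative
        return df


@dataclass
class RegressionModel:
    """OLS fit of RMSF (Å) on relative SASA and B-factor (Å²).

    ``a`` is Å per unit of relative SASA (a fraction, not a percent), ``b``
    is Å per Å² of B-factor, ``c`` the intercept in Å.
    """

    a: float
    b: float
    c: float
    r: float
    n: int
    stderr_a: float
    stderr_b: float
    stderr_c: float

    def predict(self, relative_sasa: np.ndarray, bfactor: np.ndarray) -> np.ndarray:
        return (self.a * np.asarray(relative_sasa, float)
                + self.b * np.asarray(bfactor, float) + self.c)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _radii(model: StructureModel) -> np.ndarray:
    radii = np.empty(model.n_atoms)
    for i, elem in enumerate(model.atoms.element):
        key = str(elem).upper()
        if key not in VDW_RADII:
            ref = (str(model.atoms.chain_id[i]), int(model.atoms.res_id[i]),
                   str(model.atoms.atom_name[i]))
            raise EnsembleError(f"no van der Waals radius for element "
                                f"{key!r} (atom {ref})")
        radii[i] = VDW_RADII[key]
    return radii


def sasa(model: StructureModel,
         probe_radius: float = PROBE_RADIUS,
         points_per_atom: int = POINTS_PER_ATOM,
         include_hydrogens: bool = False) -> SASAProfile:
    """Shrake–Rupley accessible surface per atom, summed into residues.

    Test points on each atom's solvent-expanded sphere are counted as
    accessible when they fall outside every neighbouring expanded sphere.
    Hydrogens are excluded by default (crystal structures rarely have them;
    heavy-atom SASA keeps structures with and without H comparable).
    """
    arr = model.atoms
    keep = np.ones(model.n_atoms, dtype=bool)
    if not include_hydrogens:
        keep = np.array([str(e).upper() != "H" for e in arr.element])
    sub = arr[keep]
    sub_model = StructureModel(sub)
    coords = sub.coord.astype(float)
    radii = _radii(sub_model) + probe_radius
    sphere = fibonacci_sphere(points_per_atom)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
    residues, areas = [], []
    for s, e in zip(starts[:-1], starts[1:]):
        residues.append((str(sub.chain_id[s]), int(sub.res_id[s]),
                         str(sub.res_name[s])))
        areas.append(per_atom[s:e].sum())
    return SASAProfile(residues, np.asarray(areas))


# -- Ala-X-Ala normalisation ---------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def build_axa_tripeptide(res_name: str) -> StructureModel:
    """An extended (φ=−120°, ψ=120°) Ala-X-Ala tripeptide, heavy atoms only.

    The backbone is built from ideal internal coordinates; side chains are
    grafted from ideal residue conformers by superposing their N/CA/C onto
    each backbone residue frame.
    """
    bb = build_backbone(3, phi=-120.0, psi=120.0)
    names = ["ALA", res_name, "ALA"]
    atoms = []
    for i, name in enumerate(names):
        conf = ccd_residue(name)
        heavy = conf[np.array([str(e).upper() != "H" for e in conf.element])]
        anchor_local = np.stack([
            heavy.coord[heavy.atom_name == a][0] for a in ("N", "CA", "C")
        ])
        anchor_target = np.stack([bb[a][i] for a in ("N", "CA", "C")])
        rot, trans = kabsch(anchor_local, anchor_target)
        for bb_name in ("N", "CA", "C", "O"):
            atoms.append(struc.Atom(bb[bb_name][i], chain_id="A", res_id=i + 1,
                                    res_name=name, atom_name=bb_name,
                                    element=bb_name[0]))
        for k in range(heavy.array_length()):
            a_name = str(heavy.atom_name[k])
            if a_name in _BACKBONE:
                continue
            pos = heavy.coord[k] @ rot.T + trans
            atoms.append(struc.Atom(pos, chain_id="A", res_id=i + 1,
                                    res_name=name, atom_name=a_name,
                                    element=str(heavy.element[k])))
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr)


def build_axa_reference(probe_radius: float = PROBE_RADIUS,
                        points_per_atom: int = POINTS_PER_ATOM) -> pd.DataFrame:
    """Reference SASA of every residue type X in an extended Ala-X-Ala tripeptide."""
    rows = []
    for name in AMINO_ACIDS:
        profile = sasa(build_axa_tripeptide(name), probe_radius, points_per_atom)
        rows.append({"res_name": name, "reference_sasa_A2": profile.absolute[1]})
    return pd.DataFrame(rows)


def load_axa_reference() -> dict[str, float]:
    """The packaged Ala-X-Ala reference table as res_name → Å²."""
    with resources.files("loopdyn.data").joinpath("axa_reference.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["res_name"], df["reference_sasa_A2"]))


def relative_sasa(profile: SASAProfile,
                  reference: dict[str, float] | None = None) -> SASAProfile:
    """Fill relative accessibility, absolute / reference(residue type)."""
    ref = load_axa_reference() if reference is None else reference
    rel = np.empty(len(profile.absolute))
    for k, (_, _, res_name) in enumerate(profile.residues):
        if res_name not in ref:
            raise EnsembleError(
                f"no Ala-X-Ala reference area for residue type {res_name!r}"
            )
        rel[k] = profile.absolute[k] / ref[res_name]
    return SASAProfile(profile.residues, profile.absolute, rel)


# -- mobility regression -------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN (with warning) on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance input: Pearson correlation undefined")
        return float("nan")
    return float(_scipy_pearsonr(x, y).statistic)


def fit_rmsf_model(observed_rmsf: np.ndarray,
                   bfactors: np.ndarray,
                   rel_sasa: np.ndarray) -> RegressionModel:
    """OLS fit of RMSF = a·(relative SASA) + b·(B-factor) + c.

    Raises on collinear predictors (condition number of the design matrix
    above 1e10).  ``r`` is the Pearson correlation between fitted and
    observed RMSF (NaN when the observations have zero variance).
    """
    y = np.asarray(observed_rmsf, float)
    b_vec = np.asarray(bfactors, float)
    s_vec = np.asarray(rel_sasa, float)
    if not (len(y) == len(b_vec) == len(s_vec)):
        raise EnsembleError("regression inputs must be aligned")
    if len(y) < 4:
        raise EnsembleError("regression needs at least 4 residues")
    design = sm.add_constant(np.column_stack([s_vec, b_vec]))
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise EnsembleError(
            f"collinear predictors (design condition number {cond:.3g})"
        )
    fit = sm.OLS(y, design).fit()
    c, a, b = fit.params
    se_c, se_a, se_b = fit.bse
    r = pearson_r(fit.fittedvalues, y)
    return RegressionModel(float(a), float(b), float(c), r, len(y),
                           float(se_a), float(se_b), float(se_c))
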