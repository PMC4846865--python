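"""Synthetic ensembles with analytically known statistics.

Every analysis stage in this package is validated against data whose ground
truth is known in closed form:

* :func:`gaussian_ensemble` — multivariate-Gaussian positional fluctuations
  around a rigid template with prescribed per-residue amplitudes ``σ_i`` (per
  Cartesian axis) and an inter-residue correlation matrix ``ρ``.  Expected
  RMSF is ``σ√3``; expected DCCM is ``ρ``; expected linear mutual information
  between two residues with per-axis correlation r is ``−(3/2)·ln(1−r²)``.
* :func:`cone_vectors` — bond vectors uniform on a spherical cap of
  half-angle θ0, for which the generalized order parameter is
  ``S² = [cosθ0·(1+cosθ0)/2]²`` (diffusion in a cone).
* :func:`dihedral_switch` — two-state circular (φ, ψ) switching with known
  state occupancies, the oracle for box-occupancy statistics.
* :func:`hbond_script` — donor–H–acceptor geometries scripted frame by frame
  so hydrogen-bond occupancy is known by construction.

Displacements are independent across frames: all statistics in scope are
ensemble averages, so autocorrelation would add nothing but cost.  Each spec
carries a mandatory seed and generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .ensembles import Ensemble, EnsembleError, StructureModel

__all__ = [
    "GaussianEnsembleSpec",
    "ConeSpec",
    "DihedralSwitchSpec",
    "HBondScriptSpec",
    "make_template",
    "gaussian_ensemble",
    "cone_vectors",
    "cone_order_parameter",
    "dihedral_switch",
    "hbond_script",
]


# -- templates -----------------------------------------------------------------

def make_template(n_residues: int,
                  glycine_positions: tuple[int, ...] = (),
                  chain_id: str = "A",
                  res_names: list[str] | None = None,
                  ca_coords: np.ndarray | None = None,
                  first_res_id: int = 1) -> StructureModel:
    """An ideal pseudo-protein template with Cα and Cβ (Hα for glycine) sites.

    Cα positions follow an α-helix-like curve (non-collinear by construction)
    unless explicit ``ca_coords`` are given; Cβ sits at ideal distance 1.53 Å
    from Cα pointing radially outward, glycine carries an Hα at 1.09 Å instead.
    """
    if ca_coords is None:
        i = np.arange(n_residues)
        turn = np.radians(100.0) * i
        ca_coords = np.stack(
            [2.3 * np.cos(turn), 2.3 * np.sin(turn), 1.5 * i], axis=1
        )
    else:
        ca_coords = np.asarray(ca_coords, dtype=float)
        if ca_coords.shape != (n_residues, 3):
            raise EnsembleError("ca_coords must have shape (n_residues, 3)")
    if res_names is None:
        res_names = [
            "GLY" if i in set(glycine_positions) else "ALA"
            for i in range(n_residues)
        ]
    atoms = []
    for i in range(n_residues):
        ca = ca_coords[i]
        outward = np.array([ca[0], ca[1], 0.0])
        nrm = np.linalg.norm(outward)
        outward = outward / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        res_id = first_res_id + i
        is_gly = res_names[i] == "GLY"
        side_name, side_elem, side_len = (
            ("HA", "H", 1.09) if is_gly else ("CB", "C", 1.53)
        )
        atoms.append(struc.Atom(ca, chain_id=chain_id, res_id=res_id,
                                res_name=res_names[i], atom_name="CA",
                                element="C"))
        atoms.append(struc.Atom(ca + side_len * outward, chain_id=chain_id,
                                res_id=res_id, res_name=res_names[i],
                                atom_name=side_name, element=side_elem))
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr)


# -- Gaussian positional ensembles ---------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Prescription for a Gaussian-fluctuation ensemble.

    ``sigma`` is the per-residue displacement standard deviation per Cartesian
    axis (Å); ``rho`` the inter-residue correlation matrix (identity if None).
    Each residue moves rigidly (Cα and its Cβ/Hα share one displacement), so
    bond-vector orientations are untouched by this generator.
    """

    n_residues: int
    sigma: np.ndarray
    n_frames: int
    seed: int
    rho: np.ndarray | None = None
    glycine_positions: tuple[int, ...] = ()
    template: StructureModel | None = None
    ca_coords: np.ndarray | None = None
    frame_interval_ps: float = 1.0

    def covariance(self) -> np.ndarray:
        """Per-axis residue covariance Σ_ij = ρ_ij σ_i σ_j."""
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (self.n_residues,):
            raise EnsembleError("sigma must have one entry per residue")
        if np.any(sigma < 0):
            raise EnsembleError("sigma must be non-negative")
        rho = np.eye(self.n_residues) if self.rho is None else np.asarray(self.rho, float)
        if rho.shape != (self.n_residues,) * 2 or not np.allclose(rho, rho.T, atol=1e-10):
            raise EnsembleError("rho must be a symmetric n×n matrix")
        cov = rho * np.outer(sigma, sigma)
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise EnsembleError(
                f"implied covariance is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        return cov


def gaussian_ensemble(spec: GaussianEnsembleSpec) -> Ensemble:
    """Sample an ensemble of template + correlated Gaussian displacements.

    Displacements are i.i.d. across frames and across the three Cartesian
    axes; the residue-residue covariance per axis is ``ρ_ij σ_i σ_j``.
    """
    cov = spec.covariance()
    template = spec.template or make_template(
        spec.n_residues, spec.glycine_positions, ca_coords=spec.ca_coords
    )
    n_res = spec.n_residues
    # map each atom row to its residue index, in residue order
    starts = struc.get_residue_starts(template.atoms, add_exclusive_stop=True)
    if len(starts) - 1 != n_res:
        raise EnsembleError(
            f"template has {len(starts) - 1} residues, spec says {n_res}"
        )
    res_of_atom = np.empty(template.n_atoms, dtype=int)
    for k, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        res_of_atom[s:e] = k
    w, u = np.linalg.eigh(cov)
    factor = u * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, n_res, 3))
    disp = np.einsum("ij,fja->fia", factor, z)  # (F, n_res, 3)
    coords = template.atoms.coord[None, :, :] + disp[:, res_of_atom, :]
    return Ensemble(template, coords, spec.frame_interval_ps)


# -- cone vectors --------------------------------------------------------------

@dataclass
class ConeSpec:
    """Unit vectors uniform on a spherical cap of half-angle θ0 (degrees)."""

    theta0: float
    n_frames: int
    seed: int
    n_residues: int = 1
    axes: str = "z"  # "z": all cones about +z; "random": one random axis each

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta0 <= 180.0:
            raise EnsembleError("cone half-angle must lie in [0°, 180°]")


def cone_order_parameter(theta0: float) -> float:
    """Analytic S² for uniform diffusion in a cone of half-angle θ0 (degrees)."""
    c = np.cos(np.radians(theta0))
    return float((c * (1.0 + c) / 2.0) ** 2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def cone_vectors(spec: ConeSpec) -> np.ndarray:
    """Sample unit vectors uniform on the cap; shape (n_frames, n_residues, 3).

    Frames are independent.  With ``axes="random"`` each residue's cone is
    tilted by its own fixed random rotation, which removes the artificial
    collective alignment of identical cone axes.
    """
    rng = np.random.default_rng(spec.seed)
    cos0 = np.cos(np.radians(spec.theta0))
    cos_t = rng.uniform(cos0, 1.0, size=(spec.n_frames, spec.n_residues))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_frames, spec.n_residues))
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    vec = np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=2
    )
    if spec.axes == "random":
        for j in range(spec.n_residues):
            vec[:, j, :] = vec[:, j, :] @ _random_rotation(rng).T
    elif spec.axes != "z":
        raise EnsembleError(f"unknown axes mode {spec.axes!r}")
    return vec


# -- two-state dihedral switching ----------------------------------------------

@dataclass
class DihedralSwitchSpec:
    """Bernoulli switching between two (φ, ψ) centers with wrapped-normal jitter."""

    center_a: tuple[float, float]
    center_b: tuple[float, float]
    jitter: float  # degrees, std of wrapped-normal noise on each angle
    p_state_a: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_state_a <= 1.0:
            raise EnsembleError("state-A probability must lie in [0, 1]")
        if self.jitter < 0:
            raise EnsembleError("jitter must be non-negative")


def dihedral_switch(spec: DihedralSwitchSpec) -> np.ndarray:
    """(φ, ψ) series of shape (n_frames, 2), degrees wrapped to (−180, 180]."""
    from .geometry import wrap_degrees

    rng = np.random.default_rng(spec.seed)
    in_a = rng.random(spec.n_frames) < spec.p_state_a
    centers = np.where(
        in_a[:, None],
        np.asarray(spec.center_a, float)[None, :],
        np.asarray(spec.center_b, float)[None, :],
    )
    noise = rng.normal(0.0, spec.jitter, size=(spec.n_frames, 2)) if spec.jitter else 0.0
    return np.asarray(wrap_degrees(centers + noise), dtype=float)


# -- scripted hydrogen-bond geometries -----------------------------------------

@dataclass
class HBondScriptSpec:
    """Per-frame scripted donor–H–acceptor geometry.

    ``flags[f]`` is True where frame f must satisfy the hydrogen-bond
    criterion (donor–acceptor ≤ 3.5 Å and donor–H–acceptor angle ≥ 120°).
    Non-bonded frames violate exactly one criterion, alternating between a
    long distance (3.6 Å at 160°) and a bent angle (2.9 Å at 100°) unless
    overridden.
    """

    flags: np.ndarray
    bonded_distance: float = 2.9
    bonded_angle: float = 160.0
    broken_distance: tuple[float, float] = (3.6, 160.0)   # distance violation
    broken_angle: tuple[float, float] = (2.9, 100.0)      # angle violation

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)


def _acceptor_position(distance: float, dha_angle: float) -> np.ndarray:
    """Acceptor position for donor at origin, H at (1, 0, 0), given |D−A| and ∠D–H–A."""
    theta = np.radians(dha_angle)
    # A = H + r·(−cosθ, sinθ, 0); solve |A| = distance for r ≥ 0
    c = np.cos(theta)
    r = c + np.sqrt(max(c * c - 1.0 + distance * distance, 0.0))
    return np.array([1.0 - r * c, r * np.sin(theta), 0.0])


def hbond_script(spec: HBondScriptSpec) -> tuple[Ensemble, np.ndarray]:
    """Build a two-chain ensemble realising the scripted geometry.

    Chain B holds the donor (backbone N with its amide H); chain A holds the
    acceptor (carbonyl O with its antecedent C).  Returns the ensemble and a
    copy of the per-frame bonded flags.
    """
    atoms = [
        # chain A: acceptor side (C=O plus a CA to anchor the residue)
        struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                   atom_name="C", element="C"),
        struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                   atom_name="O", element="O"),
        struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                   atom_name="CA", element="C"),
        # chain B: donor side
        struc.Atom([0, 0, 0], chain_id="B", res_id=1, res_name="ALA",
                   atom_name="N", element="N"),
        struc.Atom([1.0, 0, 0], chain_id="B", res_id=1, res_name="ALA",
                   atom_name="H", element="H"),
        struc.Atom([-0.9, -1.2, 0], chain_id="B", res_id=1, res_name="ALA",
                   atom_name="CA", element="C"),
    ]
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    topology = StructureModel(arr)

    n_frames = len(spec.flags)
    coords = np.repeat(arr.coord[None, :, :], n_frames, axis=0).astype(float)
    n_breaks = 0
    for f in range(n_frames):
        if spec.flags[f]:
            d, a = spec.bonded_distance, spec.bonded_angle
        else:
            d, a = spec.broken_distance if n_breaks % 2 == 0 else spec.broken_angle
            n_breaks += 1
        acceptor = _acceptor_position(d, a)
        coords[f, 1] = acceptor                       # O
        coords[f, 0] = acceptor + [0.0, 1.231, 0.0]    # antecedent C
        coords[f, 2] = acceptor + [1.3, 2.0, 0.0]      # CA, out of the way
    return Ensemble(topology, coords, 1.0), spec.flags.copy()
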