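"""Small geometry toolkit: internal-coordinate atom placement, dihedrals, wrapping.

Used to build ideal peptide backbones (for reference tripeptides and for
constructed test geometries) and to measure torsion angles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_degrees",
    "angular_difference",
    "dihedral",
    "angle",
    "place_atom",
    "build_backbone",
]

# ideal backbone internal coordinates (Engh & Huber style averages), Å / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def wrap_degrees(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (−180°, 180°]."""
    w = np.mod(x, 360.0)
    return np.where(w > 180.0, w - 360.0, w) if np.ndim(w) else (w - 360.0 if w > 180.0 else w)


def angular_difference(a, b):
    """Smallest absolute circular difference |a − b| in degrees, in [0, 180]."""
    return np.abs(wrap_degrees(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0–p1–p2–p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a–b–c.

    ``bond`` = |c−d|, ``bond_angle`` = angle b–c–d (degrees), ``torsion`` =
    dihedral a–b–c–d (degrees).  Standard NeRF construction.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_residues: int, phi: float, psi: float,
                   omega: float = 180.0) -> dict[str, np.ndarray]:
    """Ideal-geometry peptide backbone with uniform (φ, ψ, ω).

    Returns arrays ``N``, ``CA``, ``C``, ``O`` of shape (n_residues, 3).
    The first residue is seeded in a canonical pose; the φ of residue 1 and
    ψ/ω of the last residue are realised through the same placement rules so
    measured interior torsions equal the requested values exactly.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    n = np.zeros((n_residues, 3))
    ca = np.zeros((n_residues, 3))
    c = np.zeros((n_residues, 3))
    o = np.zeros((n_residues, 3))

    n[0] = [0.0, 0.0, 0.0]
    ca[0] = [BOND_N_CA, 0.0, 0.0]
    # place C of residue 1 so that the chain has somewhere to go; the torsion
    # used here is φ once residue 0 has a preceding C, which it does not —
    # seed with an arbitrary virtual predecessor consistent with φ
    virtual_c = place_atom(ca[0] + [0, 0, 1.0], ca[0], n[0],
                           BOND_C_N, ANGLE_C_N_CA, 0.0)
    c[0] = place_atom(virtual_c, n[0], ca[0], BOND_CA_C, ANGLE_N_CA_C, phi)

    for i in range(1, n_residues):
        n[i] = place_atom(n[i - 1], ca[i - 1], c[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi)
        ca[i] = place_atom(ca[i - 1], c[i - 1], n[i],
                           BOND_N_CA, ANGLE_C_N_CA, omega)
        c[i] = place_atom(c[i - 1], n[i], ca[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi)
    for i in range(n_residues):
        if i + 1 < n_residues:
            # carbonyl O opposite the next amide N
            o[i] = place_atom(n[i], ca[i], c[i],
                              BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        else:
            o[i] = place_atom(n[i], ca[i], c[i],
                              BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return {"N": n, "CA": ca, "C": c, "O": o}
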