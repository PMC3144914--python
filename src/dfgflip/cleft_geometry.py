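"""Active-site cleft width and rigid N-lobe rotation.

The width of the cleft between the kinase N- and C-lobes is summarized by a
single number D: the sum of the four pairwise distances from the catalytic
Lys and the alphaC Glu to the DFG Asp and Phe (K-D, K-F, E-D, E-F). In
DFG-out structures the N-lobe swings outward, widening the cleft; starting
from a DFG-in structure, the amount of outward rotation to apply before
activation-loop remodeling follows a three-tier rule on D:

* D > 32 A   -> no rotation (cleft already wide enough)
* 30 <= D <= 32 -> 5 degrees
* D < 30 A   -> 15 degrees

The rotation axis is the normal of the plane through the catalytic-domain
centroid and the CA atoms of the alphaC start and end residues, placed at
the CA of the middle hinge residue. The sense of rotation is resolved per
structure by trial: the direction that widens the cleft (increases D) is the
outward one. The rotation itself is rigid (Rodrigues construction) and is
applied only to N-lobe atoms (res_seq <= nlobe_last).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from dfgflip.structure_io import KinaseStructure

__all__ = [
    "CleftMetrics", "RotationSpec", "residue_representative",
    "cleft_distance_sum", "rotation_category", "rotation_axis",
    "rotate_nlobe", "CONVENTIONS", "rodrigues_matrix",
]

#: atom used per residue type under the "functional" convention
_FUNCTIONAL_ATOM = {"LYS": "NZ", "GLU": "CD", "ASP": "CG", "PHE": "CZ"}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

CONVENTIONS = ("CA", "sidechain_centroid", "functional")


@dataclass(frozen=True)
class CleftMetrics:
    """The four conserved-residue distances and their sum D (Angstrom)."""

    d_kd: float
    d_kf: float
    d_ed: float
    d_ef: float
    convention: str = "sidechain_centroid"

    @property
    def distance_sum(self) -> float:
        return self.d_kd + self.d_kf + self.d_ed + self.d_ef


@dataclass
class RotationSpec:
    """Axis, angle and sense of an outward N-lobe rotation."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    angle_deg: float = 0.0
    sense: int = 1

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("axis_dir must be nonzero")
        self.axis_dir = d / n
        if self.sense not in (1, -1):
            raise ValueError("sense must be +1 or -1")


def _require_annotation(s: KinaseStructure):
    if s.annotation is None:
        raise ValueError("structure is not annotated")
    return s.annotation


def residue_representative(
    s: KinaseStructure, res_seq: int, convention: str = "sidechain_centroid"
) -> np.ndarray:
    """Representative point of a residue for cleft-distance purposes.

    * ``"CA"`` — the CA coordinate.
    * ``"sidechain_centroid"`` — mean of side-chain heavy atoms (CB outward);
      glycine, having no side chain, falls back to CA.
    * ``"functional"`` — the chemically functional tip atom
      (Lys NZ, Glu CD, Asp CG, Phe CZ).
    """
    atoms = s.residue_atoms(res_seq)
    if not atoms:
        raise KeyError(f"residue {res_seq} not found")
    if convention == "CA":
        return s.atom_coord(res_seq, "CA")
    if convention == "sidechain_centroid":
        side = [a for a in atoms
                if a.name not in _BACKBONE and not a.is_hydrogen]
        if not side:  # Gly or stripped side chain
            return s.atom_coord(res_seq, "CA")
        return np.mean([a.coord for a in side], axis=0)
    if convention == "functional":
        res_name = atoms[0].res_name
        name = _FUNCTIONAL_ATOM.get(res_name)
        if name is None:
            raise ValueError(
                f"no functional atom defined for residue type {res_name}"
            )
        return s.atom_coord(res_seq, name)
    raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")


def cleft_distance_sum(
    s: KinaseStructure, convention: str = "sidechain_centroid"
) -> CleftMetrics:
    """Four pairwise distances K-D, K-F, E-D, E-F and their sum."""
    ann = _require_annotation(s)
    k = residue_representative(s, ann.catalytic_lys, convention)
    e = residue_representative(s, ann.alphaC_glu, convention)
    d = residue_representative(s, ann.dfg_asp, convention)
    f = residue_representative(s, ann.dfg_phe, convention)
    dist = lambda a, b: float(np.linalg.norm(a - b))
    return CleftMetrics(
        d_kd=dist(k, d), d_kf=dist(k, f), d_ed=dist(e, d), d_ef=dist(e, f),
        convention=convention,
    )


def rotation_category(distance_sum: float) -> int:
    """Outward-rotation angle (degrees) from the cleft distance sum.

    D > 32 -> 0; 30 <= D <= 32 -> 5; D < 30 -> 15.
    """
    d = float(distance_sum)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"distance sum must be finite and >= 0, got {distance_sum}")
    if d > 32.0:
        return 0
    if d >= 30.0:
        return 5
    return 15


def rodrigues_matrix(axis_dir: np.ndarray, angle_deg: float) -> np.ndarray:
    """Orthonormal rotation matrix about a unit axis (Rodrigues formula)."""
    k = np.asarray(axis_dir, dtype=float)
    k = k / np.linalg.norm(k)
    theta = math.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)


def rotation_axis(
    s: KinaseStructure, convention: str = "sidechain_centroid",
    trial_angle_deg: float = 1.0,
) -> RotationSpec:
    """Construct the N-lobe rotation axis of an annotated structure.

    The axis is the unit normal of the plane through the CA centroid of the
    catalytic domain and the CA atoms of the alphaC start and end residues; it
    passes through the CA of the middle hinge residue. The sense is chosen by
    trial rotations of ``trial_angle_deg`` so that the cleft widens
    (D increases). The returned spec has ``angle_deg`` 0; combine with
    :func:`rotation_category` to set it.
    """
    ann = _require_annotation(s)
    all_ca = s.ca_coords()
    if len(all_ca) < 3:
        raise ValueError("need at least 3 CA atoms for the domain centroid")
    center = all_ca.mean(axis=0)
    p1 = s.atom_coord(ann.alphaC_start, "CA")
    p2 = s.atom_coord(ann.alphaC_end, "CA")
    normal = np.cross(p1 - center, p2 - center)
    nrm = np.linalg.norm(normal)
    scale = max(np.linalg.norm(p1 - center), np.linalg.norm(p2 - center), 1.0)
    if nrm < 1e-6 * scale**2:
        raise ValueError("plane points are collinear; rotation axis undefined")
    axis_dir = normal / nrm
    axis_point = s.atom_coord(ann.hinge_middle, "CA")
    spec = RotationSpec(axis_point=axis_point, axis_dir=axis_dir, angle_deg=0.0)

    d0 = cleft_distance_sum(s, convention).distance_sum
    gains = {}
    for sense in (1, -1):
        trial = replace_spec(spec, angle_deg=trial_angle_deg, sense=sense)
        gains[sense] = (
            cleft_distance_sum(rotate_nlobe(s, trial), convention).distance_sum - d0
        )
    best = max(gains, key=lambda k: gains[k])
    if gains[best] <= 0:
        raise ValueError("neither rotation sense widens the cleft")
    spec.sense = best
    return spec


def replace_spec(spec: RotationSpec, **kw) -> RotationSpec:
    params = dict(axis_point=spec.axis_point, axis_dir=spec.axis_dir,
                  angle_deg=spec.angle_deg, sense=spec.sense)
    params.update(kw)
    return RotationSpec(**params)


def rotate_nlobe(s: KinaseStructure, spec: RotationSpec) -> KinaseStructure:
    """Rigidly rotate the N-lobe (res_seq <= nlobe_last) about the axis.

    All other atoms are returned bit-identical.
    """
    ann = _require_annotation(s)
    if spec.angle_deg == 0.0:
        return s.with_atoms(list(s.atoms))
    R = rodrigues_matrix(spec.axis_dir, spec.angle_deg * spec.sense)
    p0 = spec.axis_point
    moved = []
    for a in s.atoms:
        if a.res_seq <= ann.nlobe_last:
            x = np.asarray(a.coord)
            moved.append(a.moved_to(R @ (x - p0) + p0))
        else:
            moved.append(a)
    return s.with_atoms(moved)
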