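"""Vector-based DFG-in / DFG-out classification.

Before and after the DFG flip the Asp and Phe side chains sit on opposite
sides of the activation-loop backbone. The classifier exploits this: after
rigid superposition of a model onto a DFG-in reference (over CA atoms outside
the remodeled activation-loop segment), each of the two DFG side chains is
assigned a normal vector

    n = (CA_Asp -> CA_Phe) x (CA -> CG)

computed in both the reference and the model. If a side chain crossed to the
other side of the backbone, its model normal is anti-parallel to the
reference normal and the dot product is negative. Both dots negative ->
DFG-out; both positive -> DFG-in; anything else (one flipped, or a degenerate
zero) -> intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from dfgflip.structure_io import KinaseStructure

__all__ = [
    "DFG_IN", "DFG_OUT", "INTERMEDIATE",
    "SidednessVectors", "SidednessResult",
    "superpose", "align_to_reference", "sidedness_vectors", "classify_dfg",
]

DFG_IN = "DFG_IN"
DFG_OUT = "DFG_OUT"
INTERMEDIATE = "INTERMEDIATE"

_ZERO_TOL = 1e-12  # |dot| below this counts as neither side


@dataclass(frozen=True)
class SidednessVectors:
    """The four DFG anchor atoms of each structure and the derived normals."""

    ref_atoms: np.ndarray     # (4,3): Asp CG, Asp CA, Phe CA, Phe CG
    model_atoms: np.ndarray   # same order, aligned frame
    normal_ref_asp: np.ndarray
    normal_ref_phe: np.ndarray
    normal_model_asp: np.ndarray
    normal_model_phe: np.ndarray


@dataclass(frozen=True)
class SidednessResult:
    dot_asp: float
    dot_phe: float
    label: str


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of one point set onto another.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1) such
    that ``R @ x + t`` best fits the target in the least-squares (Kabsch)
    sense.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(np.vstack([P0, Q0])) < 2:
        raise ValueError("degenerate (collinear) point sets")
    rot, rssd = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - R @ pc
    rmsd = float(rssd) / np.sqrt(n)
    return R, t, rmsd


def _alignment_selection(model: KinaseStructure, reference: KinaseStructure):
    """Common CA atoms outside the remodeled loop segment (DFG-2 .. loop end)."""
    ann = reference.annotation or model.annotation
    if ann is None:
        raise ValueError("structures must be annotated")
    loop = set(range(ann.dfg_asp - 2, ann.activation_loop_end + 1))
    ca_m = model.ca_map()
    ca_r = reference.ca_map()
    keys = [k for k in ca_r if k in ca_m and k[0] not in loop]
    keys.sort()
    if len(keys) < 3:
        raise ValueError("fewer than 3 common non-loop CA atoms")
    P = np.array([ca_m[k] for k in keys])
    Q = np.array([ca_r[k] for k in keys])
    return P, Q


def align_to_reference(
    model: KinaseStructure, reference: KinaseStructure
) -> tuple[KinaseStructure, float]:
    """Superpose a model onto the reference over non-loop CA atoms."""
    P, Q = _alignment_selection(model, reference)
    R, t, rmsd = superpose(P, Q)
    return model.transformed(R, t), rmsd


def _dfg_anchors(s: KinaseStructure) -> np.ndarray:
    ann = s.annotation
    if ann is None:
        raise ValueError("structure is not annotated")
    try:
        pts = np.array([
            s.atom_coord(ann.dfg_asp, "CG"),
            s.atom_coord(ann.dfg_asp, "CA"),
            s.atom_coord(ann.dfg_phe, "CA"),
            s.atom_coord(ann.dfg_phe, "CG"),
        ])
    except KeyError as exc:
        raise ValueError(f"DFG anchor atom missing: {exc}") from exc
    return pts


def _normals(anchors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue side-chain normals from the 4 anchor points."""
    cg_asp, ca_asp, ca_phe, cg_phe = anchors
    backbone = ca_phe - ca_asp
    side_asp = cg_asp - ca_asp
    side_phe = cg_phe - ca_phe
    n_asp = np.cross(backbone, side_asp)
    n_phe = np.cross(backbone, side_phe)
    for vec, label in ((n_asp, "Asp"), (n_phe, "Phe")):
        if np.linalg.norm(vec) < 1e-9:
            raise ValueError(
                f"degenerate {label} side-chain vector (CG on the CA-CA axis)"
            )
    return n_asp, n_phe


def sidedness_vectors(
    model: KinaseStructure, reference: KinaseStructure, prealigned: bool = False
) -> SidednessVectors:
    """Extract DFG anchor atoms of both structures and build the 4 normals.

    Unless ``prealigned``, the model is first superposed onto the reference
    over CA atoms outside the activation-loop segment so that rigid motion of
    the whole model cannot affect the sign test.
    """
    if not prealigned:
        model, _ = align_to_reference(model, reference)
    ref_atoms = _dfg_anchors(reference)
    model_atoms = _dfg_anchors(model)
    n_ref_asp, n_ref_phe = _normals(ref_atoms)
    n_mod_asp, n_mod_phe = _normals(model_atoms)
    return SidednessVectors(
        ref_atoms=ref_atoms, model_atoms=model_atoms,
        normal_ref_asp=n_ref_asp, normal_ref_phe=n_ref_phe,
        normal_model_asp=n_mod_asp, normal_model_phe=n_mod_phe,
    )


def classify_dfg(
    model: KinaseStructure, reference: KinaseStructure, prealigned: bool = False
) -> SidednessResult:
    """Label a model DFG_IN, DFG_OUT or INTERMEDIATE against a DFG-in reference.

    Both dots negative -> DFG_OUT (both side chains crossed the backbone);
    both positive -> DFG_IN; mixed signs or an exact zero -> INTERMEDIATE.
    """
    v = sidedness_vectors(model, reference, prealigned=prealigned)
    dot_asp = float(np.dot(v.normal_model_asp, v.normal_ref_asp))
    dot_phe = float(np.dot(v.normal_model_phe, v.normal_ref_phe))
    if dot_asp < -_ZERO_TOL and dot_phe < -_ZERO_TOL:
        label = DFG_OUT
    elif dot_asp > _ZERO_TOL and dot_phe > _ZERO_TOL:
        label = DFG_IN
    else:
        label = INTERMEDIATE
    return SidednessResult(dot_asp=dot_asp, dot_phe=dot_phe, label=label)
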