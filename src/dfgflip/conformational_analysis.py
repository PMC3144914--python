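"""Activation-loop clustering and ensemble comparison metrics.

The activation loop of an ensemble of predicted DFG-out models is compared
through a 16-residue segment that starts two residues before the DFG motif.
Loop conformations are clustered by nearest-neighbour (single-linkage)
clustering of the segment CA RMSD matrix at a 4 A threshold. RMSDs are
computed in the fixed non-loop frame (each model is superposed onto the other
over CA atoms outside the segment first), so clusters reflect where the loop
sits in the cleft rather than internal loop shape alone.

Model-vs-crystal similarity is measured two ways: locally by the heavy-atom
RMSD over the three DFG residues, and globally by a fixed-correspondence
TM-score with the standard length normalization d0 = 1.24 (L-15)^(1/3) - 1.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from dfgflip.dfg_classifier import superpose
from dfgflip.structure_io import KinaseAnnotation, KinaseStructure

__all__ = [
    "LoopSegment", "ClusterResult",
    "segment_rmsd", "nn_cluster", "dfg_motif_rmsd", "tm_score",
]

CLUSTER_SEGMENT_LENGTH = 16


@dataclass(frozen=True)
class LoopSegment:
    """Residue range of the activation-loop segment (inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    @classmethod
    def for_clustering(cls, ann: KinaseAnnotation) -> "LoopSegment":
        """16 residues beginning two before the DFG Asp."""
        start = ann.dfg_asp - 2
        return cls(start=start, end=start + CLUSTER_SEGMENT_LENGTH - 1)


@dataclass
class ClusterResult:
    assignments: dict[str, int]       # model_id -> cluster index
    populations: list[int]            # descending
    representatives: list[str]        # one model_id per cluster, same order
    threshold: float


def _frame_and_segment_cas(
    a: KinaseStructure, b: KinaseStructure, seg: LoopSegment
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    seg_set = set(seg.residues)
    ca_a, ca_b = a.ca_map(), b.ca_map()
    common = sorted(k for k in ca_a if k in ca_b)
    missing = [r for r in seg.residues if (r, " ") not in ca_a or (r, " ") not in ca_b]
    if missing:
        raise ValueError(f"segment residues missing CA atoms: {missing}")
    frame_keys = [k for k in common if k[0] not in seg_set]
    seg_keys = [(r, " ") for r in seg.residues]
    A_frame = np.array([ca_a[k] for k in frame_keys])
    B_frame = np.array([ca_b[k] for k in frame_keys])
    A_seg = np.array([ca_a[k] for k in seg_keys])
    B_seg = np.array([ca_b[k] for k in seg_keys])
    return A_frame, B_frame, A_seg, B_seg


def segment_rmsd(a: KinaseStructure, b: KinaseStructure, seg: LoopSegment) -> float:
    """Loop-segment CA RMSD in the shared non-loop frame.

    ``a`` is superposed onto ``b`` over CA atoms outside the segment, then the
    RMSD is taken over the segment CA atoms. Symmetric to numerical precision.
    """
    A_frame, B_frame, A_seg, B_seg = _frame_and_segment_cas(a, b, seg)
    R, t, _ = superpose(A_frame, B_frame)
    moved = A_seg @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - B_seg) ** 2, axis=1))))


def nn_cluster(
    models: list[KinaseStructure], seg: LoopSegment, threshold: float = 4.0
) -> ClusterResult:
    """Nearest-neighbour clustering of loop conformations.

    Single-linkage clusters cut at the RMSD threshold, i.e. connected
    components of the graph joining pairs with segment RMSD <= threshold.
    Cluster indices are ordered by descending population (ties by the lowest
    member index); the representative of a cluster is the member minimizing
    the summed RMSD to its cluster mates (ties -> lower model index).
    """
    if not models:
        raise ValueError("need at least one model")
    n = len(models)
    ids = [m.source_id or f"model{i}" for i, m in enumerate(models)]
    if len(set(ids)) != n:
        raise ValueError("model source_ids must be unique")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = segment_rmsd(models[i], models[j], seg)
    edges = np.argwhere((D <= threshold) & ~np.eye(n, dtype=bool))
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                     shape=(n, n))
    _, comp = connected_components(adj, directed=False)

    # order clusters by (descending size, lowest member index)
    members: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        members.setdefault(int(c), []).append(i)
    order = sorted(members, key=lambda c: (-len(members[c]), min(members[c])))

    assignments: dict[str, int] = {}
    populations: list[int] = []
    representatives: list[str] = []
    for rank, c in enumerate(order):
        idxs = members[c]
        for i in idxs:
            assignments[ids[i]] = rank
        populations.append(len(idxs))
        rep = min(idxs, key=lambda i: (D[i, idxs].sum(), i))
        representatives.append(ids[rep])
    return ClusterResult(assignments=assignments, populations=populations,
                         representatives=representatives, threshold=threshold)


def dfg_motif_rmsd(model: KinaseStructure, crystal: KinaseStructure) -> float:
    """Heavy-atom RMSD over the three DFG residues after global superposition.

    The superposition frame is the non-loop CA set (the activation-loop
    segment from DFG-2 to the loop end is excluded), matching how the loop
    segment RMSD is framed.
    """
    ann = model.annotation or crystal.annotation
    if ann is None:
        raise ValueError("structures must be annotated")
    loop = set(range(ann.dfg_asp - 2, ann.activation_loop_end + 1))
    ca_m, ca_c = model.ca_map(), crystal.ca_map()
    frame_keys = sorted(k for k in ca_m if k in ca_c and k[0] not in loop)
    if len(frame_keys) < 3:
        raise ValueError("fewer than 3 common non-loop CA atoms")
    R, t, _ = superpose(np.array([ca_m[k] for k in frame_keys]),
                        np.array([ca_c[k] for k in frame_keys]))

    motif = (ann.dfg_asp, ann.dfg_phe, ann.dfg_gly)
    pairs_m, pairs_c, missing = [], [], []
    for res in motif:
        atoms_m = {a.name: a for a in model.residue_atoms(res) if not a.is_hydrogen}
        atoms_c = {a.name: a for a in crystal.residue_atoms(res) if not a.is_hydrogen}
        names = sorted(set(atoms_m) & set(atoms_c))
        missing += [f"{res}:{n}" for n in sorted(set(atoms_c) ^ set(atoms_m))]
        for name in names:
            pairs_m.append(atoms_m[name].coord)
            pairs_c.append(atoms_c[name].coord)
    if not pairs_m:
        raise ValueError(f"no common DFG heavy atoms; mismatches: {missing}")
    P = np.asarray(pairs_m) @ R.T + t
    Q = np.asarray(pairs_c)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def tm_score(model: KinaseStructure, reference: KinaseStructure) -> float:
    """Fixed-correspondence TM-score of a model against a reference.

    Residues are paired by (res_seq, i_code); no alignment search is done.
    The score max over superpositions is approximated by the standard
    iterative refinement: seed superpositions on sliding windows of several
    lengths, then alternate between scoring all residues and re-superposing
    on the subset within the inclusion cutoff, keeping the best final score.
    Normalization d0 = 1.24 (L-15)^(1/3) - 1.8 with L the number of paired
    residues; requires L > 15.
    """
    ca_m, ca_r = model.ca_map(), reference.ca_map()
    keys = sorted(k for k in ca_m if k in ca_r)
    L = len(keys)
    if L <= 15:
        raise ValueError(f"TM-score needs more than 15 paired residues, got {L}")
    P = np.array([ca_m[k] for k in keys])
    Q = np.array([ca_r[k] for k in keys])
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    d0 = max(d0, 0.5)

    def score_from(subset: np.ndarray) -> float:
        """Iteratively refine a superposition seeded on `subset` indices."""
        best = 0.0
        sel = subset
        for _ in range(20):
            if len(sel) < 3:
                break
            try:
                R, t, _ = superpose(P[sel], Q[sel])
            except ValueError:  # collinear seed window
                break
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            s = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
            best = max(best, s)
            cutoff = max(d0, 4.5)
            new_sel = np.flatnonzero(d < cutoff)
            if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                break
            sel = new_sel
        return best

    best = 0.0
    for win in {L, max(L // 2, 7), 7}:
        step = max(win // 2, 1)
        for start in range(0, L - win + 1, step):
            best = max(best, score_from(np.arange(start, start + win)))
    return best
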