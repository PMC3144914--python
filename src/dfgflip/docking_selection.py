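"""Conformational selection on ensemble-docking output.

Docking a ligand against every model of a DFG-out ensemble yields many poses;
the selection protocol is: (1) discard poses outside the active-site cleft —
a pose is in-cleft iff any heavy atom lies strictly within 3 A of binding
site B2 or B3 of its receptor model; (2) rank the surviving poses of each
ligand by docking energy; (3) the lowest-energy pose is the ligand's
representative and its receptor model the representative DFG-out
conformation. For virtual screening, ligands are re-ranked by representative
energy into a hit list, and performance against active/decoy labels is
summarized by the ROC AUC (Mann-Whitney statistic, ties counted 1/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from dfgflip.pocket_analysis import BindingSites

__all__ = [
    "DockedPose", "HitList", "ROCResult", "NO_IN_CLEFT_POSE",
    "parse_poses", "write_poses_tsv", "filter_in_cleft", "representative_pose",
    "ligand_rmsd", "build_hitlist", "roc_auc", "top_fraction_rank",
]

IN_CLEFT_CUTOFF = 3.0  # A, strict

#: sentinel energy for ligands whose every pose fell outside the cleft
NO_IN_CLEFT_POSE = float("inf")

_HYDROGEN_TYPES = {"H", "HD", "HS"}  # AutoDock hydrogen atom types


@dataclass(frozen=True)
class DockedPose:
    ligand_id: str
    model_id: str
    run_index: int
    energy: float
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n,3) heavy atoms

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite")
        if len(self.atom_names) == 0:
            raise ValueError("pose must have at least one heavy atom")

    def min_distance_to(self, points: np.ndarray) -> float:
        pts = np.atleast_2d(points)
        d = np.linalg.norm(self.coords[:, None, :] - pts[None], axis=2)
        return float(d.min())


@dataclass
class HitList:
    """Ligands ranked by representative docking energy (ascending)."""

    entries: list[tuple[str, float, str]]  # (ligand_id, energy, model_id)
    labels: dict[str, str]                 # ligand_id -> "active" | "decoy"

    def rank(self, ligand_id: str) -> int:
        for i, (lig, _, _) in enumerate(self.entries, start=1):
            if lig == ligand_id:
                return i
        raise KeyError(f"ligand {ligand_id} not in hit list")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    curve: np.ndarray  # (n,2): FPR, TPR
    n_active: int
    n_decoy: int


# ---------------------------------------------------------------------------
# Pose parsing
# ---------------------------------------------------------------------------


def _parse_model_blocks(
    lines: list[str], ligand_id: str, model_id: str, dialect: str
) -> list[DockedPose]:
    poses: list[DockedPose] = []
    block: list[str] | None = None
    run = 0
    for raw in lines:
        line = raw[8:] if dialect == "dlg" and raw.startswith("DOCKED: ") else raw
        if dialect == "dlg" and not raw.startswith("DOCKED:"):
            continue
        rec = line[:6].strip()
        if rec == "MODEL":
            block = [line]
        elif block is not None:
            block.append(line)
            if rec == "ENDMDL":
                run += 1
                poses.append(_pose_from_block(block, ligand_id, model_id, run))
                block = None
    return poses


def _pose_from_block(
    block: list[str], ligand_id: str, model_id: str, run: int
) -> DockedPose:
    energy = None
    names, coords = [], []
    for line in block:
        if "Estimated Free Energy of Binding" in line or "Binding energy" in line:
            tail = line.split("=", 1)[1] if "=" in line else line.split(":", 1)[1]
            energy = float(tail.split()[0])
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            name = line[12:16].strip()
            atype = line[77:79].strip() or name[0]
            if atype.upper() in _HYDROGEN_TYPES:
                continue
            names.append(name)
            coords.append((float(line[30:38]), float(line[38:46]),
                           float(line[46:54])))
    if energy is None:
        raise ValueError(f"pose {run} of {ligand_id} has no energy record")
    return DockedPose(ligand_id=ligand_id, model_id=model_id, run_index=run,
                      energy=energy, atom_names=tuple(names),
                      coords=np.asarray(coords, dtype=float))


def _parse_tsv_pdb(path: Path) -> list[DockedPose]:
    """Documented plain-text test dialect: a pose table with PDB blocks.

    Layout::

        POSE <ligand_id> <model_id> <run_index> <energy>
        ATOM ... (PDB fixed columns, heavy atoms)
        ENDPOSE
    """
    poses = []
    header: tuple[str, str, int, float] | None = None
    names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("POSE"):
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: bad POSE header")
            header = (parts[1], parts[2], int(parts[3]), float(parts[4]))
            names, coords = [], []
        elif line.startswith("ENDPOSE"):
            if header is None:
                raise ValueError(f"{path}:{lineno}: ENDPOSE without POSE")
            lig, mod, run, energy = header
            poses.append(DockedPose(
                ligand_id=lig, model_id=mod, run_index=run, energy=energy,
                atom_names=tuple(names),
                coords=np.asarray(coords, dtype=float)))
            header = None
        elif line[:6].strip() in ("ATOM", "HETATM"):
            el = line[76:78].strip()
            if el.upper() in ("H", "D"):
                continue
            names.append(line[12:16].strip())
            coords.append((float(line[30:38]), float(line[38:46]),
                           float(line[46:54])))
    return poses


def parse_poses(
    path: str | Path, dialect: str, ligand_id: str = "", model_id: str = ""
) -> list[DockedPose]:
    """Parse docked poses from a file.

    Dialects: ``dlg`` (AutoDock docking log, DOCKED: records), ``pdbqt_multi``
    (multi-MODEL PDBQT with energy REMARK/USER lines) and ``tsv_pdb`` (the
    package's plain-text exchange dialect, see :func:`write_poses_tsv`).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lig = ligand_id or path.stem
    mod = model_id or "receptor"
    if dialect == "dlg":
        return _parse_model_blocks(lines, lig, mod, "dlg")
    if dialect == "pdbqt_multi":
        return _parse_model_blocks(lines, lig, mod, "pdbqt")
    if dialect == "tsv_pdb":
        return _parse_tsv_pdb(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_poses_tsv(poses: list[DockedPose], path: str | Path) -> Path:
    """Write poses in the tsv_pdb exchange dialect (round-trips parse_poses)."""
    path = Path(path)
    out = []
    for p in poses:
        out.append(f"POSE {p.ligand_id} {p.model_id} {p.run_index} {p.energy:g}")
        for i, (name, xyz) in enumerate(zip(p.atom_names, p.coords), start=1):
            el = "".join(c for c in name if c.isalpha())[:1] or "C"
            out.append(
                "HETATM{serial:>5d} {name:<4s} LIG A   1    "
                "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}".format(
                    serial=i, name=name[:4], x=xyz[0], y=xyz[1], z=xyz[2],
                    el=el.upper())
            )
        out.append("ENDPOSE")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Selection protocol
# ---------------------------------------------------------------------------


def filter_in_cleft(
    poses: list[DockedPose],
    sites_by_model: dict[str, BindingSites] | BindingSites,
    cutoff: float = IN_CLEFT_CUTOFF,
) -> list[DockedPose]:
    """Keep poses with at least one heavy atom strictly within `cutoff` of B2 or B3.

    ``sites_by_model`` maps receptor model_id to its labeled sites (a single
    BindingSites applies to every pose).
    """
    kept = []
    for p in poses:
        if isinstance(sites_by_model, BindingSites):
            sites = sites_by_model
        else:
            if p.model_id not in sites_by_model:
                raise KeyError(f"no binding sites for receptor model {p.model_id}")
            sites = sites_by_model[p.model_id]
        anchors = np.vstack([sites.center("B2"), sites.center("B3")])
        if p.min_distance_to(anchors) < cutoff:
            kept.append(p)
    return kept


def representative_pose(poses: list[DockedPose]) -> DockedPose | None:
    """Lowest-energy retained pose of one ligand across the ensemble.

    Ties resolve to the lexicographically smallest (model_id, run_index).
    Returns None when no pose survived the cleft filter ("no in-cleft pose").
    """
    if not poses:
        return None
    lig_ids = {p.ligand_id for p in poses}
    if len(lig_ids) > 1:
        raise ValueError(f"poses of multiple ligands passed: {sorted(lig_ids)}")
    return min(poses, key=lambda p: (p.energy, p.model_id, p.run_index))


def ligand_rmsd(
    pose: DockedPose,
    crystal_pose: DockedPose,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> float:
    """Heavy-atom RMSD of a docked pose against the crystal pose.

    The receptor-frame transform (from superposing the docked receptor model
    onto the crystal receptor) is applied to the pose first. Atoms pair by
    name (1:1); no symmetry correction is applied, so RMSDs of symmetric
    ligands are pessimistic.
    """
    a = dict(zip(pose.atom_names, pose.coords))
    b = dict(zip(crystal_pose.atom_names, crystal_pose.coords))
    if len(a) != len(pose.atom_names) or len(b) != len(crystal_pose.atom_names):
        raise ValueError("duplicate atom names in pose")
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise ValueError(
            f"atom-set mismatch: pose-only {only_a}, crystal-only {only_b}"
        )
    names = sorted(a)
    P = np.array([a[n] for n in names])
    Q = np.array([b[n] for n in names])
    if rotation is not None:
        P = P @ np.asarray(rotation).T
    if translation is not None:
        P = P + np.asarray(translation)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def build_hitlist(
    representatives: dict[str, DockedPose | None],
    labels: dict[str, str],
) -> HitList:
    """Rank ligands by representative energy; no-pose ligands rank last.

    ``representatives`` maps ligand_id to its representative pose (or None
    for "no in-cleft pose"). Ties order by ligand_id.
    """
    ids = list(representatives)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ligand ids")
    entries = []
    for lig, pose in representatives.items():
        if pose is None:
            entries.append((lig, NO_IN_CLEFT_POSE, ""))
        else:
            entries.append((lig, pose.energy, pose.model_id))
    entries.sort(key=lambda e: (e[1], e[0]))
    return HitList(entries=entries, labels=dict(labels))


def roc_auc(h: HitList) -> ROCResult:
    """Screening AUC of a hit list (Mann-Whitney; ties count 1/2).

    The ROC curve itself is computed from the rank thresholds; the AUC equals
    its trapezoidal area to numerical precision.
    """
    y, scores = [], []
    for lig, energy, _ in h.entries:
        if lig not in h.labels:
            raise KeyError(f"no activity label for ligand {lig}")
        y.append(1 if h.labels[lig] == "active" else 0)
        scores.append(-energy)  # lower energy = better = higher score
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    # map the no-pose sentinel (-inf score) to one below the worst real score
    if np.any(np.isinf(scores)):
        finite = scores[np.isfinite(scores)]
        floor = (finite.min() - 1.0) if len(finite) else 0.0
        scores[np.isinf(scores)] = floor
    n_act = int(y.sum())
    n_dec = int(len(y) - n_act)
    if n_act == 0 or n_dec == 0:
        raise ValueError("need at least one active and one decoy")
    ranks = rankdata(scores)  # average ranks: ties count 1/2 in the statistic
    auc = (ranks[y == 1].sum() - n_act * (n_act + 1) / 2.0) / (n_act * n_dec)
    fpr, tpr, _ = roc_curve(y, scores)
    return ROCResult(auc=float(auc), curve=np.column_stack([fpr, tpr]),
                     n_active=n_act, n_decoy=n_dec)


def top_fraction_rank(h: HitList, ligand_id: str) -> float:
    """Fractional rank of a ligand in the hit list (rank 1 -> 1/len)."""
    return h.rank(ligand_id) / len(h.entries)


def write_summary(result: ROCResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(
        {"auc": result.auc, "n_active": result.n_active,
         "n_decoy": result.n_decoy}, indent=2) + "\n")
    return path
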