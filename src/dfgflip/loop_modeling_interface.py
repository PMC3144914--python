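"""Job specifications for external loop remodeling and ensemble docking.

Activation-loop remodeling and docking themselves are run by external
programs (Rosetta's loop rebuilding, AutoDock's Lamarckian GA); this module
only encodes the segment and cut-point rules, writes the corresponding input
files, and reads externally produced models back in.

The remodeled segment starts two residues before the DFG Asp and ends at the
last activation-loop residue. The chain-closure cut point is the most
hydrophilic residue (lowest Kyte-Doolittle hydropathy) in the middle third of
the segment, ties resolved toward the segment midpoint and then N-terminally.
Docking jobs default to the ensemble-docking protocol: a 60 A cubic grid box
centered on binding site B2, 20 LGA runs with population 150, 27,000
generations and 1.5 million energy evaluations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from dfgflip.conformational_analysis import LoopSegment
from dfgflip.pocket_analysis import BindingSites
from dfgflip.structure_io import (
    KinaseAnnotation,
    KinaseStructure,
    THREE_TO_ONE,
    annotate,
    read_pdb,
)

__all__ = [
    "RemodelJob", "DockingJobSpec", "KYTE_DOOLITTLE",
    "remodel_segment", "cut_point", "emit_loops_file", "parse_loops_file",
    "emit_docking_spec", "ingest_models",
]

#: Kyte-Doolittle hydropathy (positive = hydrophobic)
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class RemodelJob:
    """One loop-remodeling job: segment, cut point, number of models."""

    segment: LoopSegment
    cut_point: int
    n_models: int = 200

    def __post_init__(self) -> None:
        if not (self.segment.start < self.cut_point < self.segment.end):
            raise ValueError("cut point must lie strictly inside the segment")


@dataclass(frozen=True)
class DockingJobSpec:
    """Grid box and Lamarckian-GA parameters for one receptor model."""

    box_center: tuple[float, float, float]
    box_edge: float = 60.0
    n_runs: int = 20
    ga_pop: int = 150
    ga_generations: int = 27000
    ga_evals: int = 1500000

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")


def remodel_segment(ann: KinaseAnnotation) -> LoopSegment:
    """Remodeling segment: DFG Asp - 2 through the activation-loop end."""
    start = ann.dfg_asp - 2
    end = ann.activation_loop_end
    if end <= start:
        raise ValueError(
            f"activation_loop_end ({end}) must exceed segment start ({start})"
        )
    return LoopSegment(start=start, end=end)


def middle_third_indices(length: int) -> range:
    """Middle third of 0..length-1, rounded outward (never empty for length>=3)."""
    lo = math.floor(length / 3)
    hi = math.ceil(2 * length / 3) - 1
    return range(lo, hi + 1)


def cut_point(segment_sequence: str, seg: LoopSegment) -> int:
    """Cut-point residue: most hydrophilic residue of the segment's middle third.

    ``segment_sequence`` is the one-letter sequence of the whole segment.
    Ties go to the residue nearest the segment midpoint, then N-terminal.
    """
    seq = segment_sequence.upper()
    if len(seq) != seg.length:
        raise ValueError(
            f"sequence length {len(seq)} != segment length {seg.length}"
        )
    if seg.length < 3:
        raise ValueError("segment must have at least 3 residues")
    unknown = sorted({c for c in seq if c not in KYTE_DOOLITTLE})
    if unknown:
        raise ValueError(f"unknown residue codes: {unknown}")
    mid = (seg.length - 1) / 2.0
    candidates = middle_third_indices(seg.length)
    best = min(
        candidates,
        key=lambda i: (KYTE_DOOLITTLE[seq[i]], abs(i - mid), i),
    )
    return seg.start + best


def segment_sequence(s: KinaseStructure, seg: LoopSegment) -> str:
    """One-letter sequence of a segment read off a structure."""
    out = []
    for res in seg.residues:
        name = s.residue_name(res)
        if name not in THREE_TO_ONE:
            raise ValueError(f"non-standard residue {name} at {res}")
        out.append(THREE_TO_ONE[name])
    return "".join(out)


def emit_loops_file(jobs: RemodelJob | list[RemodelJob], path: str | Path) -> Path:
    """Write Rosetta-style loop definition lines: ``LOOP <start> <end> <cut> 0 1``."""
    if isinstance(jobs, RemodelJob):
        jobs = [jobs]
    path = Path(path)
    path.write_text(
        "".join(
            f"LOOP {j.segment.start} {j.segment.end} {j.cut_point} 0 1\n"
            for j in jobs
        )
    )
    return path


def parse_loops_file(path: str | Path) -> list[RemodelJob]:
    jobs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] != "LOOP" or len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: not a LOOP line: {raw!r}")
        start, end, cut = int(parts[1]), int(parts[2]), int(parts[3])
        jobs.append(RemodelJob(segment=LoopSegment(start=start, end=end),
                               cut_point=cut))
    return jobs


def emit_docking_spec(
    sites: BindingSites, out_dir: str | Path, **overrides
) -> DockingJobSpec:
    """Write grid (gpf) and docking (dpf) parameter stubs centered on site B2."""
    center = sites.center("B2")  # raises KeyError if unlabeled
    spec = DockingJobSpec(box_center=tuple(float(v) for v in center), **overrides)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    npts = int(round(spec.box_edge))  # 1 A grid spacing
    (out_dir / "grid.gpf").write_text(
        f"npts {npts} {npts} {npts}\n"
        f"spacing 1.0\n"
        f"gridcenter {spec.box_center[0]:.3f} {spec.box_center[1]:.3f} "
        f"{spec.box_center[2]:.3f}\n"
    )
    (out_dir / "dock.dpf").write_text(
        f"ga_pop_size {spec.ga_pop}\n"
        f"ga_num_generations {spec.ga_generations}\n"
        f"ga_num_evals {spec.ga_evals}\n"
        f"ga_run {spec.n_runs}\n"
    )
    return spec


def ingest_models(
    directory: str | Path, ann: KinaseAnnotation, chain: str = "A",
    score_table: str = "scores.tsv",
) -> list[tuple[KinaseStructure, float | None]]:
    """Read a directory of model PDBs, annotate, and sort by energy.

    Energies come from an optional sidecar TSV (``model_id<TAB>score``); when
    absent, models are returned in filename order with ``None`` energies.
    Unreadable models are skipped with a warning.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.pdb"))
    if not paths:
        raise ValueError(f"no PDB models in {directory}")
    scores: dict[str, float] = {}
    score_path = directory / score_table
    if score_path.exists():
        for raw in score_path.read_text().splitlines():
            if not raw.strip() or raw.startswith("#"):
                continue
            name, value = raw.split("\t")
            scores[name] = float(value)
    out = []
    for p in paths:
        try:
            s = annotate(read_pdb(p, chain), ann)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"skipping unreadable model {p.name}: {exc}")
            continue
        out.append((s, scores.get(p.stem)))
    if not out:
        raise ValueError(f"no readable models in {directory}")
    if scores:
        out.sort(key=lambda pair: (pair[1] is None, pair[1] or 0.0))
    return out
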