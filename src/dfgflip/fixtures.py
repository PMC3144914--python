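"""Synthetic structures with known ground truth.

Everything in the package is testable offline through three generators:

* :func:`make_toy_kinase` — a CA-trace two-lobe kinase scaffold with full
  DFG side-chain stubs. The CA atoms of the four conserved cleft residues
  (Lys, Glu, Asp, Phe) are placed on a rectangle scaled so that the cleft
  distance sum equals a requested target exactly under the "CA" convention,
  and the DFG side chains are oriented to realize a requested DFG state
  (in / out / intermediate) relative to the structure's DFG-in twin.
* :func:`make_toy_cavity` — closed atom shells enclosing cube, sphere or
  three-chamber cavities of known analytic volume, for the pocket pipeline.
* :func:`make_screening_set` — per-ligand representative docking energies
  drawn from two normal distributions, for which the expected screening AUC
  has the closed form Phi((mu_decoy - mu_active) / (sigma * sqrt(2))).

The fixtures are geometric, not physical: no sterics or energetics beyond
what the tested operations measure. All randomness is seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from dfgflip.docking_selection import DockedPose
from dfgflip.structure_io import AtomRecord, KinaseAnnotation, KinaseStructure, annotate

__all__ = [
    "ToyKinaseSpec", "ToyCavity", "TOY_ANNOTATION",
    "make_toy_kinase", "make_toy_cavity", "make_screening_set",
    "expected_screening_auc",
]

#: residue numbering of the toy kinase scaffold
TOY_ANNOTATION = KinaseAnnotation(
    dfg_asp=50, dfg_phe=51, dfg_gly=52,
    catalytic_lys=10, alphaC_glu=21,
    alphaC_start=18, alphaC_end=24,
    hinge_start=31, hinge_end=33,
    activation_loop_end=60,
    nlobe_last=30,
)

#: fraction of the distance sum carried by each rectangle side; the K/E pair
#: sits 0.75c from the D/F pair laterally so that D = 2c + 2*sqrt(a^2+c^2)
#: = 4.5c with a = 0.75c (3-4-5 triangle).
_RECT_RATIO = 0.75

_MIN_DISTANCE_SUM = 13.5  # 4.5 * 3.0 A minimal steric spacing of the rectangle


@dataclass(frozen=True)
class ToyKinaseSpec:
    """Construction parameters of the toy kinase."""

    target_distance_sum: float = 31.0
    dfg_state: str = "in"          # "in" | "out" | "intermediate"
    n_lobe_size: int = 30          # residues 1..n_lobe_size
    c_lobe_size: int = 37          # residues after the hinge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_distance_sum <= 0:
            raise ValueError("target distance sum must be positive")
        if self.dfg_state not in ("in", "out", "intermediate"):
            raise ValueError(f"unknown dfg_state {self.dfg_state!r}")


@dataclass(frozen=True)
class ToyCavity:
    """A cavity fixture: enclosing shell plus its analytic ground truth."""

    structure: KinaseStructure
    kind: str
    analytic_volume: float            # A^3 of the designed cavity interior
    chamber_centers: np.ndarray       # (k,3) designed cavity centers


def _residue(atoms: list[AtomRecord], serial: int, res_name: str, res_seq: int,
             positions: dict[str, np.ndarray]) -> int:
    elements = {"CA": "C", "CB": "C", "CG": "C", "CZ": "C"}
    for name, xyz in positions.items():
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=name, element=elements.get(name, "C"),
            res_name=res_name, chain_id="A", res_seq=res_seq, i_code=" ",
            coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
        ))
    return serial


def make_toy_kinase(
    spec: ToyKinaseSpec | None = None, **kw
) -> tuple[KinaseStructure, KinaseAnnotation]:
    """Build the annotated toy kinase for a construction spec.

    Contracts (asserted by the test suite): the cleft distance sum under the
    "CA" convention equals ``target_distance_sum`` to 1e-6; classifying the
    structure against its ``dfg_state="in"`` twin returns the requested
    state; the alphaC/hinge/Lys/Glu anchors are geometrically sensible
    (non-collinear rotation-axis plane, N-lobe above the cleft).
    """
    if spec is None:
        spec = ToyKinaseSpec(**kw)
    elif kw:
        raise TypeError("pass either a spec or keyword arguments, not both")
    D = spec.target_distance_sum
    if D < _MIN_DISTANCE_SUM:
        raise ValueError(
            f"target distance sum {D} below minimal steric spacing "
            f"({_MIN_DISTANCE_SUM} A)"
        )
    ann = TOY_ANNOTATION
    c = D / 4.5                      # vertical K/E vs D/F separation
    a = _RECT_RATIO * c              # lateral Asp-Phe separation
    rng = np.random.default_rng(spec.seed)

    # conserved rectangle (exact): Asp, Phe CA on the cleft floor; Lys, Glu above
    ca_asp = np.array([0.0, 0.0, 0.0])
    ca_phe = np.array([a, 0.0, 0.0])
    ca_lys = np.array([0.0, c, 0.0])
    ca_glu = np.array([a, c, 0.0])

    atoms: list[AtomRecord] = []
    serial = 0
    placed: set[int] = set()

    def put(res_seq: int, res_name: str, positions: dict[str, np.ndarray]) -> None:
        nonlocal serial
        serial = _residue(atoms, serial, res_name, res_seq, positions)
        placed.add(res_seq)

    # alphaC helix 18..24 as a straight segment through the Glu CA
    for res in range(ann.alphaC_start, ann.alphaC_end + 1):
        k = res - ann.alphaC_glu
        pos = ca_glu + k * np.array([1.5, 0.5, 1.2])
        if res == ann.alphaC_glu:
            put(res, "GLU", {"CA": ca_glu})
        else:
            put(res, "LEU", {"CA": pos})
    put(ann.catalytic_lys, "LYS", {"CA": ca_lys})

    # remaining N-lobe: jittered cloud above the cleft
    nlobe_center = np.array([a / 2.0, c + 6.0, 0.0])
    for res in range(1, spec.n_lobe_size + 1):
        if res in placed:
            continue
        put(res, "ALA", {"CA": nlobe_center + rng.uniform(-3.0, 3.0, 3)})

    # hinge 31..33 at the cleft mouth
    hinge_anchor = np.array([a + 8.0, c / 2.0, 0.0])
    for res, dy in zip(range(ann.hinge_start, ann.hinge_end + 1), (1.0, 0.0, -1.0)):
        put(res, "GLY", {"CA": hinge_anchor + np.array([0.0, dy, 0.3 * dy])})

    # DFG motif with side-chain stubs; side vectors perpendicular to the
    # Asp->Phe backbone axis (+x), Asp up / Phe down in the DFG-in state
    s_asp = np.array([0.0, 1.4, 0.5])
    s_phe = np.array([0.0, -1.4, 0.5])
    if spec.dfg_state in ("out",):
        s_asp, s_phe = -s_asp, -s_phe      # both side chains cross the axis
    elif spec.dfg_state == "intermediate":
        s_asp = -s_asp                     # only Asp crosses
    put(ann.dfg_asp, "ASP", {"CA": ca_asp, "CB": ca_asp + 0.5 * s_asp,
                             "CG": ca_asp + s_asp})
    put(ann.dfg_phe, "PHE", {"CA": ca_phe, "CB": ca_phe + 0.5 * s_phe,
                             "CG": ca_phe + s_phe, "CZ": ca_phe + 1.8 * s_phe})
    put(ann.dfg_gly, "GLY", {"CA": ca_phe + np.array([1.5, -1.5, 0.0])})

    # activation loop 53..60 arcing under the cleft
    for res in range(ann.dfg_gly + 1, ann.activation_loop_end + 1):
        k = res - ann.dfg_gly
        put(res, "SER", {"CA": ca_phe + np.array([1.5 + k, -1.5 - 0.6 * k, 0.4 * k])})

    # remaining C-lobe: cloud below the cleft
    clobe_center = np.array([a / 2.0, -9.0, 0.0])
    last_res = ann.hinge_end + spec.c_lobe_size
    for res in range(ann.hinge_end + 1, last_res + 1):
        if res in placed:
            continue
        put(res, "VAL", {"CA": clobe_center + rng.uniform(-4.0, 4.0, 3)})

    atoms.sort(key=lambda at: (at.res_seq, at.name != "CA", at.name))
    atoms = [
        AtomRecord(serial=i, name=at.name, element=at.element,
                   res_name=at.res_name, chain_id=at.chain_id,
                   res_seq=at.res_seq, i_code=at.i_code, coord=at.coord)
        for i, at in enumerate(atoms, start=1)
    ]
    s = KinaseStructure(
        atoms=atoms, chain_filter="A",
        source_id=f"toy-{spec.dfg_state}-D{D:g}-s{spec.seed}",
    )
    return annotate(s, ann), ann


# ---------------------------------------------------------------------------
# Cavities
# ---------------------------------------------------------------------------

#: wall shells are placed so that the probe-inflated protein region
#: (vdW 1.70 + probe 1.4 = 3.10 A around each wall atom) ends at the
#: designed cavity boundary
_WALL_STANDOFF = 3.10 + 0.05


def _wall_lattice(half: float) -> np.ndarray:
    """Symmetric ~1 A lattice covering [-half, half]."""
    n = max(int(round(2 * half)) + 1, 2)
    return np.linspace(-half, half, n)


def _cube_shell(center: np.ndarray, inner_half: float) -> list[np.ndarray]:
    h = inner_half + _WALL_STANDOFF
    ticks = _wall_lattice(h)
    pts = []
    for axis in range(3):
        u, v = np.meshgrid(ticks, ticks, indexing="ij")
        for side in (-h, h):
            face = np.zeros((u.size, 3))
            face[:, axis] = side
            face[:, (axis + 1) % 3] = u.ravel()
            face[:, (axis + 2) % 3] = v.ravel()
            pts.append(face + center)
    return pts


def _partitioned_box(center: np.ndarray, inner_half: float,
                     n_chambers: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Closed box split into chambers along x by interior partition walls.

    Sharing walls (rather than placing separate boxes) leaves no partially
    enclosed exterior gaps between chambers that the pocket scan could score
    as spurious sites.
    """
    L = 2 * inner_half
    sep = L + 2 * _WALL_STANDOFF          # chamber center-to-center spacing
    x_half = ((n_chambers - 1) / 2.0) * sep + inner_half + _WALL_STANDOFF
    yz_half = inner_half + _WALL_STANDOFF
    xt = _wall_lattice(x_half)
    yt = _wall_lattice(yz_half)
    pts = []
    # outer shell
    for xs in (-x_half, x_half):          # x faces
        u, v = np.meshgrid(yt, yt, indexing="ij")
        pts.append(np.column_stack([np.full(u.size, xs), u.ravel(), v.ravel()]))
    for axis in (1, 2):                   # y and z faces
        u, v = np.meshgrid(xt, yt, indexing="ij")
        for side in (-yz_half, yz_half):
            face = np.zeros((u.size, 3))
            face[:, 0] = u.ravel()
            face[:, axis] = side
            face[:, 3 - axis] = v.ravel()
            pts.append(face)
    # interior partitions between adjacent chambers
    offsets = (np.arange(n_chambers) - (n_chambers - 1) / 2.0) * sep
    for xp in (offsets[:-1] + offsets[1:]) / 2.0:
        u, v = np.meshgrid(yt, yt, indexing="ij")
        pts.append(np.column_stack([np.full(u.size, xp), u.ravel(), v.ravel()]))
    centers = np.column_stack([offsets, np.zeros(n_chambers),
                               np.zeros(n_chambers)]) + center
    return [p + center for p in pts], centers


def _sphere_shell(center: np.ndarray, inner_radius: float) -> list[np.ndarray]:
    r = inner_radius + _WALL_STANDOFF
    n = max(int(math.ceil(4.0 * math.pi * r * r / 0.6)), 64)  # ~1 atom / 0.6 A^2
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i       # Fibonacci sphere
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z]) * r
    return [pts + center]


def make_toy_cavity(kind: str, size: float, seed: int = 0) -> ToyCavity:
    """Atom shell enclosing a cavity with known analytic volume.

    * ``cube``: closed box, interior side = ``size``; volume size^3.
    * ``sphere``: shell, interior diameter = ``size``; volume (pi/6) size^3.
    * ``three_chamber``: one closed box split by two interior partition
      walls into three disjoint chambers of side ``size`` along x (one
      binding site per chamber downstream).
    ``seed`` fixes the (sub-grid) placement offset of the shell.
    """
    if size < 6.0:
        raise ValueError("cavity size must be at least 6 A")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 1.0, 3)   # decouple walls from grid registration
    if kind == "cube":
        centers = np.array([offset])
        blocks = _cube_shell(centers[0], size / 2.0)
        volume = size ** 3
    elif kind == "sphere":
        centers = np.array([offset])
        blocks = _sphere_shell(centers[0], size / 2.0)
        volume = math.pi * size ** 3 / 6.0
    elif kind == "three_chamber":
        blocks, centers = _partitioned_box(offset, size / 2.0, n_chambers=3)
        volume = 3 * size ** 3
    else:
        raise ValueError(f"unknown cavity kind {kind!r}")

    pts = np.vstack(blocks)
    atoms = [
        AtomRecord(serial=i, name="C", element="C", res_name="UNK",
                   chain_id="A", res_seq=i, i_code=" ",
                   coord=(float(p[0]), float(p[1]), float(p[2])))
        for i, p in enumerate(pts, start=1)
    ]
    s = KinaseStructure(atoms=atoms, chain_filter="A",
                        source_id=f"cavity-{kind}-{size:g}-s{seed}")
    return ToyCavity(structure=s, kind=kind, analytic_volume=volume,
                     chamber_centers=centers)


# ---------------------------------------------------------------------------
# Screening sets
# ---------------------------------------------------------------------------


def expected_screening_auc(mu_active: float, mu_decoy: float, sigma: float) -> float:
    """Closed-form AUC for two equal-variance normal energy populations.

    With energies lower-is-better, AUC = Phi((mu_decoy - mu_active) /
    (sigma * sqrt(2))).
    """
    return float(norm.cdf((mu_decoy - mu_active) / (sigma * math.sqrt(2.0))))


def make_screening_set(
    n_active: int = 50,
    n_decoy: int = 500,
    mu_active: float = -10.0,
    mu_decoy: float = -7.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, DockedPose], dict[str, str]]:
    """Per-ligand representative poses with normal docking energies.

    Returns (representatives, labels) ready for
    :func:`dfgflip.docking_selection.build_hitlist`. Actives draw energies
    from N(mu_active, sigma^2), decoys from N(mu_decoy, sigma^2); the
    expected AUC is :func:`expected_screening_auc`.
    """
    if n_active < 1 or n_decoy < 1:
        raise ValueError("need at least one active and one decoy")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    reps: dict[str, DockedPose] = {}
    labels: dict[str, str] = {}
    origin = np.zeros((1, 3))
    for i in range(n_active):
        lig = f"act{i:04d}"
        reps[lig] = DockedPose(
            ligand_id=lig, model_id="m01", run_index=1,
            energy=float(rng.normal(mu_active, sigma)),
            atom_names=("C1",), coords=origin.copy())
        labels[lig] = "active"
    for i in range(n_decoy):
        lig = f"dec{i:04d}"
        reps[lig] = DockedPose(
            ligand_id=lig, model_id="m01", run_index=1,
            energy=float(rng.normal(mu_decoy, sigma)),
            atom_names=("C1",), coords=origin.copy())
        labels[lig] = "decoy"
    return reps, labels
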