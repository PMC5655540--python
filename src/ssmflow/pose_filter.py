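"""Design-pose selection, the multi-threshold filter cascade, and dSASA.

Implements top-k pose selection per scaffold, the conjunction of design
filters (shape complementarity, interface energy, buried ligand surface,
restraint, pocket rotamer RMSD, ddG, and electrostatic field signs) with
per-filter attrition logging, and a Shrake-Rupley solvent-accessible
surface area routine for the buried-fraction (dSASA) metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np
import pandas as pd

__all__ = [
    "PoseScoreRecord",
    "FilterThresholds",
    "FilterReport",
    "AtomSet",
    "select_top_poses",
    "apply_design_filters",
    "shrake_rupley_sasa",
    "compute_dsasa",
    "BONDI_RADII",
]

FIELD_SIGNS = ("negative", "nonnegative", "missing")


@dataclass(frozen=True)
class PoseScoreRecord:
    """Filter metrics for one designed pose. ``None`` marks missing data."""

    pose_id: str
    scaffold_id: str = ""
    dock_score: float | None = None
    sc: float | None = None  # shape complementarity, unitless
    ife: float | None = None  # interface energy, REU
    dsasa: float | None = None  # buried fraction of ligand surface, [0, 1]
    restraint: float | None = None
    pocket_rmsd: float | None = None  # Å
    ddg: float | None = None  # REU
    field_H_sign: str = "missing"
    field_O_sign: str = "missing"

    def __post_init__(self) -> None:
        if self.dsasa is not None and not (0.0 <= self.dsasa <= 1.0):
            raise ValueError(f"{self.pose_id}: dsasa {self.dsasa} outside [0, 1]")
        for sign in (self.field_H_sign, self.field_O_sign):
            if sign not in FIELD_SIGNS:
                raise ValueError(f"{self.pose_id}: bad field sign {sign!r}")


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults follow the published cascade, inequality strictness included:
    sc > 0.5, ife < -10, dsasa >= 0.8, restraint <= 5, pocket_rmsd < 1,
    ddg < -10, both field signs negative."""

    sc_min: float = 0.5  # strict >
    ife_max: float = -10.0  # strict <
    dsasa_min: float = 0.8  # non-strict >=
    restraint_max: float = 5.0  # non-strict <=
    pocket_rmsd_max: float = 1.0  # strict <
    ddg_max: float = -10.0  # strict <


# (name, attribute, predicate) applied in declared order
def _filter_chain(t: FilterThresholds):
    return [
        ("sc", "sc", lambda v: v > t.sc_min),
        ("ife", "ife", lambda v: v < t.ife_max),
        ("dsasa", "dsasa", lambda v: v >= t.dsasa_min),
        ("restraint", "restraint", lambda v: v <= t.restraint_max),
        ("pocket_rmsd", "pocket_rmsd", lambda v: v < t.pocket_rmsd_max),
        ("ddg", "ddg", lambda v: v < t.ddg_max),
        ("field_H", "field_H_sign", lambda v: v == "negative"),
        ("field_O", "field_O_sign", lambda v: v == "negative"),
    ]


@dataclass
class FilterReport:
    survivors: list[str]
    attrition: dict[str, int]  # per-filter failure counts, declared order
    thresholds: FilterThresholds
    n_input: int = 0
    failures: dict[str, str] = field(default_factory=dict)  # pose_id -> first failed filter


def select_top_poses(
    dock_scores: list[tuple[str, str, float]], k: int
) -> dict[str, list[tuple[str, float]]]:
    """Per scaffold, the k best-scoring poses (higher score is better).

    ``dock_scores`` holds (scaffold_id, pose_id, score). Ties break on
    pose_id lexicographic order, so selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_scaffold: dict[str, list[tuple[str, float]]] = {}
    for scaffold_id, pose_id, score in dock_scores:
        by_scaffold.setdefault(scaffold_id, []).append((pose_id, float(score)))
    return {
        scaffold: sorted(poses, key=lambda p: (-p[1], p[0]))[:k]
        for scaffold, poses in by_scaffold.items()
    }


def apply_design_filters(
    records: list[PoseScoreRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterReport:
    """Run the filter cascade; a pose survives iff it passes every filter.

    Attrition is attributed to the first failing filter in declared order.
    A missing metric fails that record with reason ``missing_data`` — it
    never silently passes.
    """
    chain = _filter_chain(thresholds)
    attrition = {name: 0 for name, _, _ in chain}
    attrition["missing_data"] = 0
    survivors: list[str] = []
    failures: dict[str, str] = {}
    for record in records:
        failed = None
        for name, attr, predicate in chain:
            value = getattr(record, attr)
            if value is None or value == "missing":
                failed = "missing_data"
                break
            if not predicate(value):
                failed = name
                break
        if failed is None:
            survivors.append(record.pose_id)
        else:
            attrition[failed] += 1
            failures[record.pose_id] = failed
    return FilterReport(
        survivors=survivors,
        attrition=attrition,
        thresholds=thresholds,
        n_input=len(records),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA

#: Bondi van der Waals radii (Å) for elements common in ligands/proteins.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass
class AtomSet:
    """Atoms with coordinates and radii for SASA computations."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    role: str = "ligand"  # ligand | environment

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")

    @classmethod
    def from_arrays(cls, elements, coords, role="ligand") -> "AtomSet":
        radii = np.array(
            [BONDI_RADII.get(e.upper(), DEFAULT_RADIUS) for e in elements]
        )
        return cls(elements=list(elements), coords=coords, radii=radii, role=role)

    @classmethod
    def from_pdb(cls, path, role="ligand", include_hydrogens=False) -> "AtomSet":
        """Read heavy atoms (optionally hydrogens) from a PDB file."""
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("s", str(path))
        elements, coords = [], []
        for atom in structure.get_atoms():
            element = atom.element.strip() or atom.get_name()[0]
            if element.upper() == "H" and not include_hydrogens:
                continue
            elements.append(element)
            coords.append(atom.get_coord())
        if not elements:
            raise ValueError(f"no atoms read from {path}")
        return cls.from_arrays(elements, np.array(coords), role=role)

    def __len__(self) -> int:
        return len(self.radii)


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=np.float64) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    atoms: AtomSet,
    context: AtomSet | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2) of ``atoms``.

    Each atom's sphere of radius (r + probe) is sampled at ``n_points``
    quasi-uniform points; a point is accessible when outside every other
    expanded sphere of ``atoms`` and, when given, of ``context``.
    """
    unit = _sphere_points(n_points)
    coords = atoms.coords
    radii = atoms.radii + probe
    if context is not None:
        occ_coords = np.vstack([coords, context.coords])
        occ_radii = np.concatenate([radii, context.radii + probe])
    else:
        occ_coords = coords
        occ_radii = radii

    sasa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        points = coords[i] + radii[i] * unit
        dist = np.linalg.norm(occ_coords - coords[i], axis=1)
        near = np.nonzero(dist < radii[i] + occ_radii)[0]
        near = near[near != i]  # atoms precede context rows, so i is itself
        accessible = np.ones(n_points, dtype=bool)
        for j in near:
            d2 = np.sum((points - occ_coords[j]) ** 2, axis=1)
            accessible &= d2 > occ_radii[j] ** 2
            if not accessible.any():
                break
        sasa[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return sasa


def compute_dsasa(
    ligand: AtomSet,
    environment: AtomSet,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Fraction of the ligand's accessible surface buried by the environment.

    dsasa = 1 - SASA(ligand in complex) / SASA(ligand alone), both sides by
    Shrake-Rupley on the same point set.
    """
    if len(ligand) == 0:
        raise ValueError("empty ligand")
    alone = shrake_rupley_sasa(ligand, probe=probe, n_points=n_points).sum()
    if alone <= 0:
        raise ValueError("ligand has zero accessible surface alone")
    in_complex = shrake_rupley_sasa(
        ligand, context=environment, probe=probe, n_points=n_points
    ).sum()
    return 1.0 - in_complex / alone


# ---------------------------------------------------------------------------
# Tabular I/O

_RECORD_COLUMNS = [f.name for f in dataclass_fields(PoseScoreRecord)]


def read_pose_table(path) -> list[PoseScoreRecord]:
    """Read PoseScoreRecords from TSV; empty cells become missing values."""
    frame = pd.read_csv(path, sep="\t", dtype={"pose_id": str, "scaffold_id": str})
    records = []
    for row in frame.to_dict("records"):
        kwargs = {}
        for col in _RECORD_COLUMNS:
            if col not in row:
                continue
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                value = None if not col.endswith("_sign") else "missing"
            kwargs[col] = value
        kwargs.setdefault("scaffold_id", "")
        records.append(PoseScoreRecord(**kwargs))
    return records


def write_filter_report(report: FilterReport, path) -> None:
    rows = [
        {"pose_id": pid, "outcome": "pass", "failed_filter": ""}
        for pid in report.survivors
    ] + [
        {"pose_id": pid, "outcome": "fail", "failed_filter": reason}
        for pid, reason in report.failures.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
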