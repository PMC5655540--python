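"""Hydrated-ligand preparation and rotatable-bond counting.

Places explicit water oxygens at idealized geometry around a ligand's
tertiary amine (3.0 Å N-O, 109° C-N-O, fourth tetrahedral vertex) and
carbonyl oxygen (3.0 Å O-O, 120° C-O-O, in the sp2 plane), and counts
rotatable bonds as acyclic single bonds between non-terminal heavy atoms,
excluding amide C-N bonds. All geometry runs on heavy atoms; hydrogens are
ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conformer",
    "HydrationSite",
    "HydratedConformer",
    "find_tertiary_amine",
    "find_carbonyls",
    "place_amine_water",
    "place_carbonyl_water",
    "rotatable_bond_count",
    "hydrate",
]

AMINE_WATER_DISTANCE = 3.0  # Å
AMINE_WATER_ANGLE = 109.0  # degrees (C-N-O)
CARBONYL_WATER_DISTANCE = 3.0  # Å
CARBONYL_WATER_ANGLE = 120.0  # degrees (C-O-O)


@dataclass
class Conformer:
    """Heavy-atom molecular graph with 3D coordinates.

    ``atoms`` holds (element, x, y, z); ``bonds`` holds (i, j, order) with
    order 1/2/3 (aromatic bonds carry order 1 plus membership in
    ``aromatic_atoms``/``aromatic_bonds``). Coordinates may be all-zero for
    graph-only operations such as rotatable-bond counting.
    """

    atoms: list[tuple[str, float, float, float]]
    bonds: list[tuple[int, int, int]]
    formal_charges: list[int] = field(default_factory=list)
    aromatic_atoms: frozenset[int] = frozenset()
    aromatic_bonds: frozenset[frozenset[int]] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.formal_charges:
            self.formal_charges = [0] * n
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
        coords = self.coords()
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=np.float64)

    def element(self, i: int) -> str:
        return self.atoms[i][0]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def bond_order(self, i: int, j: int) -> int | None:
        for a, b, order in self.bonds:
            if {a, b} == {i, j}:
                return order
        return None

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol) -> "Conformer":
        """Build from an RDKit Mol (heavy atoms only; 3D coords if present)."""
        from rdkit import Chem

        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms, charges = [], []
        for atom in mol.GetAtoms():
            if conf is not None:
                p = conf.GetAtomPosition(atom.GetIdx())
                xyz = (p.x, p.y, p.z)
            else:
                xyz = (0.0, 0.0, 0.0)
            atoms.append((atom.GetSymbol(), *xyz))
            charges.append(atom.GetFormalCharge())
        bonds, arom_bonds = [], set()
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if bond.GetIsAromatic():
                order = 1
                arom_bonds.add(frozenset((i, j)))
            else:
                order = int(bond.GetBondTypeAsDouble())
            bonds.append((i, j, order))
        aromatic = frozenset(
            a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()
        )
        return cls(
            atoms=atoms,
            bonds=bonds,
            formal_charges=charges,
            aromatic_atoms=aromatic,
            aromatic_bonds=frozenset(arom_bonds),
        )

    @classmethod
    def from_smiles(cls, smiles: str) -> "Conformer":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls.from_rdkit(mol)

    @classmethod
    def from_sdf(cls, path) -> "Conformer":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mol = next(iter(supplier))
        if mol is None:
            raise ValueError(f"unparseable SDF: {path}")
        return cls.from_rdkit(mol)


@dataclass(frozen=True)
class HydrationSite:
    """A placed water oxygen with its geometric provenance."""

    anchor_atom: int
    water_O: tuple[float, float, float]
    target_distance: float
    target_angle: float
    site_kind: str  # amine | carbonyl
    mean_angle_deg: float = float("nan")
    flagged: bool = False


@dataclass
class HydratedConformer:
    """A conformer plus water pseudo-atoms (outside the covalent graph)."""

    base: Conformer
    sites: list[HydrationSite]


def _is_carbonyl_carbon(c: Conformer, i: int) -> bool:
    return c.element(i) == "C" and any(
        c.element(j) == "O" and c.bond_order(i, j) == 2 for j in c.neighbors(i)
    )


def find_tertiary_amine(c: Conformer) -> list[int]:
    """Indices of tertiary amine nitrogens.

    A candidate nitrogen has exactly three heavy neighbors, all carbon, none
    of them a carbonyl carbon (excluding amide nitrogens), and is not part
    of an aromatic ring.
    """
    hits = []
    for i, (element, *_xyz) in enumerate(c.atoms):
        if element != "N" or i in c.aromatic_atoms:
            continue
        nbrs = c.neighbors(i)
        if len(nbrs) != 3:
            continue
        if all(c.element(j) == "C" for j in nbrs) and not any(
            _is_carbonyl_carbon(c, j) for j in nbrs
        ):
            hits.append(i)
    if not hits:
        raise ValueError("no_amine: no tertiary amine nitrogen found")
    return hits


def find_carbonyls(c: Conformer) -> list[tuple[int, int]]:
    """(carbon, oxygen) index pairs for every C=O double bond."""
    return [
        (i, j) if c.element(i) == "C" else (j, i)
        for i, j, order in c.bonds
        if order == 2 and {c.element(i), c.element(j)} == {"C", "O"}
    ]


def _angle_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - apex, b - apex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def place_amine_water(c: Conformer, n_idx: int) -> HydrationSite:
    """Water oxygen at the fourth tetrahedral vertex of a tertiary amine.

    The oxygen sits on the ray opposite the normalized sum of the three
    N->C unit vectors, at exactly 3.0 Å from the nitrogen; for an ideal
    tetrahedral amine every C-N-O angle is 109.47°.
    """
    coords = c.coords()
    nbrs = c.neighbors(n_idx)
    if len(nbrs) != 3:
        raise ValueError(f"atom {n_idx} is not three-coordinate")
    n_pos = coords[n_idx]
    direction = np.zeros(3)
    for j in nbrs:
        v = coords[j] - n_pos
        direction += v / np.linalg.norm(v)
    norm = np.linalg.norm(direction)
    if norm < 1e-8:
        raise ValueError("degenerate amine geometry: substituent vectors cancel")
    water = n_pos - AMINE_WATER_DISTANCE * direction / norm
    mean_angle = float(
        np.mean([_angle_deg(coords[j], n_pos, water) for j in nbrs])
    )
    return HydrationSite(
        anchor_atom=n_idx,
        water_O=tuple(water),
        target_distance=AMINE_WATER_DISTANCE,
        target_angle=AMINE_WATER_ANGLE,
        site_kind="amine",
        mean_angle_deg=mean_angle,
    )


def place_carbonyl_water(c: Conformer, c_idx: int, o_idx: int) -> HydrationSite:
    """Water oxygen in the carbonyl sp2 plane at 3.0 Å / 120° from the oxygen.

    Of the two in-plane candidates, the one with the larger minimum distance
    to all other ligand heavy atoms is kept (ties resolve to the first
    candidate). A carbonyl carbon without two heavy substituents cannot
    define a plane; an arbitrary perpendicular is used and the site is
    flagged.
    """
    if c.bond_order(c_idx, o_idx) != 2 or {c.element(c_idx), c.element(o_idx)} != {
        "C",
        "O",
    }:
        raise ValueError(f"({c_idx}, {o_idx}) is not a C=O double bond")
    coords = c.coords()
    c_pos, o_pos = coords[c_idx], coords[o_idx]
    u = c_pos - o_pos
    u /= np.linalg.norm(u)

    substituents = [j for j in c.neighbors(c_idx) if j != o_idx]
    flagged = False
    if len(substituents) >= 2:
        v1 = coords[substituents[0]] - c_pos
        v2 = coords[substituents[1]] - c_pos
        normal = np.cross(v1, v2)
    elif len(substituents) == 1:
        normal = np.cross(coords[substituents[0]] - c_pos, u)
        flagged = len(substituents) < 1  # single substituent still fixes the plane
    else:
        flagged = True
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, u)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        normal = np.cross(trial, u)
    norm = np.linalg.norm(normal)
    if norm < 1e-8:
        raise ValueError("degenerate carbonyl geometry: no plane")
    in_plane = np.cross(normal / norm, u)
    in_plane /= np.linalg.norm(in_plane)

    theta = math.radians(CARBONYL_WATER_ANGLE)
    candidates = [
        o_pos + CARBONYL_WATER_DISTANCE * (math.cos(theta) * u + s * math.sin(theta) * in_plane)
        for s in (+1.0, -1.0)
    ]
    others = np.delete(coords, [c_idx, o_idx], axis=0)
    if len(others):
        clearances = [
            np.min(np.linalg.norm(others - cand, axis=1)) for cand in candidates
        ]
        # near-ties resolve to the first candidate so the choice is stable
        # under rigid motion of a symmetric fragment
        if clearances[1] - clearances[0] > 1e-9:
            water = candidates[1]
        else:
            water = candidates[0]
    else:
        water = candidates[0]
    return HydrationSite(
        anchor_atom=o_idx,
        water_O=tuple(water),
        target_distance=CARBONYL_WATER_DISTANCE,
        target_angle=CARBONYL_WATER_ANGLE,
        site_kind="carbonyl",
        mean_angle_deg=_angle_deg(c_pos, o_pos, water),
        flagged=flagged,
    )


def hydrate(c: Conformer, amine_idx: int | None = None) -> HydratedConformer:
    """Place waters at the (first) tertiary amine and every carbonyl."""
    sites = []
    amines = [amine_idx] if amine_idx is not None else find_tertiary_amine(c)
    sites.append(place_amine_water(c, amines[0]))
    for c_idx, o_idx in find_carbonyls(c):
        sites.append(place_carbonyl_water(c, c_idx, o_idx))
    return HydratedConformer(base=c, sites=sites)


# ---------------------------------------------------------------------------
# Rotatable bonds

def bridge_bonds(n_atoms: int, bonds: list[tuple[int, int, int]]) -> set[frozenset[int]]:
    """Bridges (acyclic edges) of the heavy-atom graph.

    An edge is a bridge iff removing it disconnects its endpoints; checked
    directly by BFS per edge, which is plenty fast for molecule-sized
    graphs and immune to the classic low-link bookkeeping pitfalls.
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)

    def connected_without(i: int, j: int) -> bool:
        seen = {i}
        queue = [i]
        while queue:
            node = queue.pop()
            for nbr in adj[node]:
                if node == i and nbr == j:
                    continue  # the removed edge
                if nbr == j:
                    return True
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        return False

    return {
        frozenset((i, j))
        for i, j, _ in bonds
        if not connected_without(i, j)
    }


def rotatable_bond_count(c: Conformer) -> int:
    """Count rotatable bonds.

    A bond rotates iff it is a single bond, acyclic (a bridge of the
    molecular graph), joins two non-terminal heavy atoms, and is not an
    amide C-N bond (carbonyl carbon to nitrogen).
    """
    bridges = bridge_bonds(len(c.atoms), c.bonds)
    count = 0
    for i, j, order in c.bonds:
        if order != 1 or frozenset((i, j)) in c.aromatic_bonds:
            continue
        if frozenset((i, j)) not in bridges:
            continue
        if c.degree(i) < 2 or c.degree(j) < 2:
            continue
        elements = {c.element(i), c.element(j)}
        if elements == {"C", "N"}:
            carbon = i if c.element(i) == "C" else j
            if _is_carbonyl_carbon(c, carbon):
                continue
        count += 1
    return count


# ---------------------------------------------------------------------------
# Output

def write_hydrated_sdf(h: HydratedConformer, sdf_path, json_path=None, name="ligand") -> None:
    """Write the ligand plus water-oxygen pseudo-atoms as an SDF (V2000).

    Waters are appended as unbonded O atoms; a JSON sidecar records each
    hydration site's geometry.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf_coords = list(h.base.atoms) + [
        ("O", *site.water_O) for site in h.sites
    ]
    for element, *_ in conf_coords:
        mol.AddAtom(Chem.Atom(element))
    for idx, charge in enumerate(h.base.formal_charges):
        mol.GetAtomWithIdx(idx).SetFormalCharge(charge)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, order in h.base.bonds:
        mol.AddBond(i, j, order_map[order])
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, (_, x, y, z) in enumerate(conf_coords):
        conf.SetAtomPosition(idx, Point3D(x, y, z))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.SetProp("_Name", name)
    Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    with Chem.SDWriter(str(sdf_path)) as writer:
        writer.write(out)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                [
                    {
                        "anchor_atom": s.anchor_atom,
                        "water_O": list(s.water_O),
                        "target_distance": s.target_distance,
                        "target_angle": s.target_angle,
                        "site_kind": s.site_kind,
                        "mean_angle_deg": s.mean_angle_deg,
                        "flagged": s.flagged,
                    }
                    for s in h.sites
                ],
                fh,
                indent=2,
            )
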