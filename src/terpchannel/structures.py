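"""Ligand pose geometry: minimal readers, torsions, RMSD, core restraints.

The conformer of the 6,6-bicyclic cation I1 determines which reaction
channel it can feed: the signed torsion Φ(C16–C17–C18–H18) is positive for
the A-channel conformer and negative for the B/C-channel conformers, so a
single dihedral classifies a docked pose. Pose-vs-reference agreement is
quantified by RMSD, either in the shared receptor frame (``in_place``) or
after optimal rigid superposition (``kabsch``), and a core restraint passes
a pose whose core atoms stay within a tolerance (default 1.0 Å in-place
RMSD) of a reference placement.

File readers cover the minimal subsets of TRIPOS MOL2 (MOLECULE/ATOM/BOND),
SDF V2000 (counts + atom block) and PDB (ATOM/HETATM); partial charges are
read when the format carries them (mol2 column 9) and zero otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Pose",
    "read_pose",
    "write_mol2",
    "dihedral",
    "classify_conformer",
    "rmsd",
    "check_core_restraint",
    "read_correspondence",
    "PoseFormatError",
    "GeometryError",
]


class PoseFormatError(ValueError):
    """Malformed pose file (message carries the line number)."""


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points)."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    charge: float = 0.0


@dataclass
class Pose:
    """Named atoms with coordinates (Å) and partial charges (e)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    frame_note: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError("atom names must be unique within a pose")
        coords = np.asarray([a.xyz for a in self.atoms], dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def coords(self) -> np.ndarray:
        return np.asarray([a.xyz for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.asarray([a.charge for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom named {name!r}")

    def transformed(self, rotation: Rotation, translation: np.ndarray) -> "Pose":
        """Rigidly transformed copy (rotate about the origin, then translate)."""
        xyz = rotation.apply(self.coords()) + np.asarray(translation, dtype=float)
        atoms = [
            Atom(a.name, a.element, tuple(p), a.charge)
            for a, p in zip(self.atoms, xyz)
        ]
        return Pose(atoms=atoms, bonds=list(self.bonds), frame_note=self.frame_note)


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    alpha = "".join(c for c in name if c.isalpha())
    if len(alpha) >= 2 and alpha[:2].capitalize() in ("Cl", "Br"):
        return alpha[:2].capitalize()
    return alpha[:1].upper() if alpha else "X"


def _read_mol2(lines: list[str], path: str) -> Pose:
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    section = None
    n_atoms = n_bonds = None
    mol_count_line = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            mol_count_line = lineno + 2 if section == "MOLECULE" else None
            continue
        if not line or line.startswith("#"):
            continue
        if section == "MOLECULE" and lineno == mol_count_line:
            counts = line.split()
            try:
                n_atoms = int(counts[0])
                n_bonds = int(counts[1]) if len(counts) > 1 else 0
            except (ValueError, IndexError):
                raise PoseFormatError(
                    f"{path}:{lineno}: malformed MOLECULE counts line {line!r}"
                ) from None
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise PoseFormatError(
                    f"{path}:{lineno}: ATOM record needs >= 6 fields"
                )
            try:
                xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
                charge = float(parts[8]) if len(parts) >= 9 else 0.0
            except ValueError:
                raise PoseFormatError(
                    f"{path}:{lineno}: unparsable ATOM record {line!r}"
                ) from None
            element = parts[5].split(".")[0]
            atoms.append(Atom(parts[1], element, xyz, charge))
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 3:
                raise PoseFormatError(
                    f"{path}:{lineno}: BOND record needs >= 3 fields"
                )
            try:
                bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
            except ValueError:
                raise PoseFormatError(
                    f"{path}:{lineno}: unparsable BOND record {line!r}"
                ) from None
    if n_atoms is not None and len(atoms) != n_atoms:
        raise PoseFormatError(
            f"{path}: MOLECULE declares {n_atoms} atoms, found {len(atoms)}"
        )
    if n_bonds is not None and bonds and len(bonds) != n_bonds:
        raise PoseFormatError(
            f"{path}: MOLECULE declares {n_bonds} bonds, found {len(bonds)}"
        )
    return Pose(atoms=atoms, bonds=bonds)


def _read_sdf(lines: list[str], path: str) -> Pose:
    if len(lines) < 4:
        raise PoseFormatError(f"{path}:1: SDF needs a 3-line header + counts line")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise PoseFormatError(
            f"{path}:4: malformed V2000 counts line {counts.rstrip()!r}"
        ) from None
    atoms: list[Atom] = []
    elem_counts: dict[str, int] = {}
    for i in range(n_atoms):
        lineno = 5 + i
        if lineno - 1 >= len(lines):
            raise PoseFormatError(f"{path}:{lineno}: truncated atom block")
        line = lines[lineno - 1]
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (ValueError, IndexError):
            raise PoseFormatError(
                f"{path}:{lineno}: unparsable atom record {line.rstrip()!r}"
            ) from None
        elem_counts[element] = elem_counts.get(element, 0) + 1
        atoms.append(Atom(f"{element}{elem_counts[element]}", element, (x, y, z)))
    bonds: list[tuple[int, int]] = []
    for i in range(n_bonds):
        lineno = 5 + n_atoms + i
        if lineno - 1 >= len(lines):
            raise PoseFormatError(f"{path}:{lineno}: truncated bond block")
        line = lines[lineno - 1]
        try:
            bonds.append((int(line[0:3]) - 1, int(line[3:6]) - 1))
        except (ValueError, IndexError):
            raise PoseFormatError(
                f"{path}:{lineno}: unparsable bond record {line.rstrip()!r}"
            ) from None
    return Pose(atoms=atoms, bonds=bonds)


def _read_pdb(lines: list[str], path: str) -> Pose:
    atoms: list[Atom] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        try:
            name = line[12:16].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError):
            raise PoseFormatError(
                f"{path}:{lineno}: unparsable coordinate record {line.rstrip()!r}"
            ) from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(name)
        if name in seen:
            seen[name] += 1
            name = f"{name}_{seen[name]}"
        else:
            seen[name] = 1
        atoms.append(Atom(name, element, (x, y, z)))
    return Pose(atoms=atoms)


def read_pose(path: str | Path, fmt: str | None = None) -> Pose:
    """Read a ligand pose from mol2, SDF (V2000) or PDB.

    ``fmt`` defaults to the file suffix. Malformed records raise
    :class:`PoseFormatError` carrying the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
        if fmt == "mol":
            fmt = "sdf"
    lines = path.read_text().splitlines()
    if fmt == "mol2":
        return _read_mol2(lines, str(path))
    if fmt == "sdf":
        return _read_sdf(lines, str(path))
    if fmt == "pdb":
        return _read_pdb(lines, str(path))
    raise ValueError(f"unknown pose format {fmt!r}")


def write_mol2(pose: Pose, path: str | Path, name: str = "LIG") -> None:
    """Write a pose as TRIPOS MOL2 (charges in column 9, round-trippable)."""
    lines = ["@<TRIPOS>MOLECULE", name, f"{len(pose.atoms)} {len(pose.bonds)} 0 0 0",
             "SMALL", "USER_CHARGES", "@<TRIPOS>ATOM"]
    for i, a in enumerate(pose.atoms, start=1):
        x, y, z = a.xyz
        lines.append(
            f"{i:>7} {a.name:<8} {x:>12.6f} {y:>12.6f} {z:>12.6f} "
            f"{a.element:<5} 1 LIG {a.charge:>10.6f}"
        )
    if pose.bonds:
        lines.append("@<TRIPOS>BOND")
        for i, (a, b) in enumerate(pose.bonds, start=1):
            lines.append(f"{i:>6} {a + 1:>5} {b + 1:>5} 1")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (−180, 180].

    Positive when, sighting down p2→p3, the far bond p3→p4 is rotated
    clockwise from the near bond p2→p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise GeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear triple: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    angle = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if angle == -180.0 else angle


#: |Φ| below this (or within it of 180°) refuses conformer classification.
CLASSIFY_TOLERANCE_DEG = 1.0


class AmbiguousConformerError(ValueError):
    """Torsion too close to 0° or ±180° for a meaningful sign."""


def classify_conformer(
    pose: Pose, atom_map: Mapping[str, str]
) -> str:
    """Classify an I1 pose as ``'A_like'`` (Φ > 0) or ``'BC_like'`` (Φ < 0).

    ``atom_map`` maps the roles ``C16, C17, C18, H18`` to atom names in the
    pose. Torsions within :data:`CLASSIFY_TOLERANCE_DEG` of 0° or ±180° are
    refused: inside coordinate noise the sign is meaningless.
    """
    pts = [np.asarray(pose.atom(atom_map[k]).xyz) for k in ("C16", "C17", "C18", "H18")]
    phi = dihedral(*pts)
    if abs(phi) < CLASSIFY_TOLERANCE_DEG or abs(abs(phi) - 180.0) < CLASSIFY_TOLERANCE_DEG:
        raise AmbiguousConformerError(
            f"torsion {phi:.3f} deg is within {CLASSIFY_TOLERANCE_DEG} deg of a "
            "sign boundary; classification refused"
        )
    return "A_like" if phi > 0 else "BC_like"


def _paired_coords(
    pose_a: Pose, pose_b: Pose, correspondence: Sequence[tuple[str, str]] | None
) -> tuple[np.ndarray, np.ndarray]:
    if correspondence is None:
        names = [a.name for a in pose_a.atoms]
        correspondence = [(n, n) for n in names]
    if len(correspondence) == 0:
        raise ValueError("empty correspondence")
    xa = np.asarray([pose_a.atom(na).xyz for na, _ in correspondence], dtype=float)
    xb = np.asarray([pose_b.atom(nb).xyz for _, nb in correspondence], dtype=float)
    return xa, xb


def rmsd(
    pose_a: Pose,
    pose_b: Pose,
    correspondence: Sequence[tuple[str, str]] | None = None,
    fit: str = "in_place",
) -> float:
    """RMSD in Å over corresponding atoms.

    ``in_place`` compares coordinates in the shared (receptor) frame;
    ``kabsch`` first applies the optimal rigid superposition, so its value
    never exceeds the in-place one. ``correspondence`` is a list of
    (name_in_a, name_in_b) pairs; by default atoms are matched by name.
    """
    xa, xb = _paired_coords(pose_a, pose_b, correspondence)
    if fit == "in_place":
        return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    if fit == "kabsch":
        if len(xa) < 3:
            raise ValueError("kabsch fit needs >= 3 atom pairs")
        ca, cb = xa.mean(axis=0), xb.mean(axis=0)
        rot, rssd = Rotation.align_vectors(xa - ca, xb - cb)
        return float(rssd / np.sqrt(len(xa)))
    raise ValueError(f"unknown fit mode {fit!r}")


def check_core_restraint(
    pose: Pose,
    reference_core: Mapping[str, Sequence[float]],
    tolerance: float = 1.0,
) -> bool:
    """True iff the in-place RMSD over the core atoms is ≤ tolerance (Å).

    ``reference_core`` maps atom names (present in the pose) to reference
    coordinates. The boundary is inclusive: exactly at tolerance passes.
    """
    names = list(reference_core)
    if not names:
        raise ValueError("empty core definition")
    xa = np.asarray([pose.atom(n).xyz for n in names], dtype=float)
    xr = np.asarray([reference_core[n] for n in names], dtype=float)
    value = float(np.sqrt(np.mean(np.sum((xa - xr) ** 2, axis=1))))
    return value <= tolerance


def read_correspondence(path: str | Path) -> list[tuple[str, str]]:
    """Two-column atom-name pairs, '#' comments, blank lines ignored."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected two atom names, got {len(parts)} fields"
            )
        pairs.append((parts[0], parts[1]))
    return pairs
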