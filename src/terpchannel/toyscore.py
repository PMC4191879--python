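"""Desk-scale rigid docking of carbocation ligands into toy pockets.

A stand-in for the induced-fit docking / MM-GBSA rescoring stage, small
enough to run exhaustively in tests while preserving the protocol's
structure: an anionic *anchor* site plays the catalytic aspartate (the
ligand's cationic center must stay within hydrogen-bond range of it), a core
restraint keeps poses in a consistent orientation, and the interaction
energy is a Lennard-Jones 12-6 term plus Coulomb electrostatics with a
distance-dependent dielectric ε(r) = 4r. Receptor flexibility is emulated,
as in the reduced-van-der-Waals stage of the real protocol, by scaling the
contact radii (``vdw_scale``).

A pose is accepted only if it satisfies the geometric constraints *and* is
net non-repulsive (score ≤ ``max_score``, default 0 kcal/mol); a cationic
ligand facing a +1 anchor is therefore abolished (NO_POSE) by electrostatic
repulsion alone, reproducing the behavior of charge-reversal mutants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structures import Pose

__all__ = [
    "Site",
    "ToyReceptor",
    "DockConstraints",
    "DockResult",
    "score_pose",
    "dock",
    "read_receptor",
    "write_receptor",
    "ClashError",
]

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0636
#: Pair distances below this raise a clash error (Å).
CLASH_DISTANCE = 0.05

#: Lennard-Jones radii (Å) and well depths (kcal/mol) for ligand atoms.
ATOM_RADII = {"C": 1.9, "H": 1.2, "O": 1.66, "N": 1.8}
ATOM_EPS = 0.1
DEFAULT_RADIUS = 1.8


class ClashError(ValueError):
    """Two centers closer than the clash distance."""


@dataclass(frozen=True)
class Site:
    """One receptor interaction site."""

    position: tuple[float, float, float]
    charge: float = 0.0
    radius: float = 1.9
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


@dataclass(frozen=True)
class ToyReceptor:
    """A pocket of LJ/charge sites with one catalytic-anion anchor."""

    sites: tuple[Site, ...]
    anchor_site: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.anchor_site < len(self.sites)):
            raise ValueError(
                f"anchor_site {self.anchor_site} out of range for "
                f"{len(self.sites)} sites"
            )

    def positions(self) -> np.ndarray:
        return np.asarray([s.position for s in self.sites], dtype=float)

    def anchor_position(self) -> np.ndarray:
        return np.asarray(self.sites[self.anchor_site].position, dtype=float)


@dataclass
class DockConstraints:
    """Pose-acceptance constraints used during the search."""

    anchor_max_dist: float = 2.5  # Å, cation-to-anchor
    core_reference: Mapping[str, Sequence[float]] | None = None
    core_tolerance: float = 1.0  # Å, in-place RMSD over core atoms
    max_score: float = 0.0  # kcal/mol; poses above this are rejected


@dataclass
class DockResult:
    best_pose: Pose | None
    score: float | None
    n_sampled: int
    n_passed_constraints: int
    seed: int

    @property
    def is_no_pose(self) -> bool:
        return self.best_pose is None


def _ligand_params(ligand: Pose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    radii = np.asarray(
        [ATOM_RADII.get(a.element, DEFAULT_RADIUS) for a in ligand.atoms]
    )
    eps = np.full(len(ligand.atoms), ATOM_EPS)
    return ligand.charges(), radii, eps


def _score_coords(
    site_pos: np.ndarray,
    site_q: np.ndarray,
    site_r: np.ndarray,
    site_eps: np.ndarray,
    lig_xyz: np.ndarray,
    lig_q: np.ndarray,
    lig_r: np.ndarray,
    lig_eps: np.ndarray,
    vdw_scale: float,
) -> float:
    diff = site_pos[:, None, :] - lig_xyz[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r < CLASH_DISTANCE):
        return float("inf")
    rm = vdw_scale * (site_r[:, None] + lig_r[None, :])
    eps = np.sqrt(site_eps[:, None] * lig_eps[None, :])
    ratio6 = (rm / r) ** 6
    lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    # distance-dependent dielectric eps(r) = 4 r  =>  E = k q1 q2 / (4 r^2)
    coul = COULOMB_K * site_q[:, None] * lig_q[None, :] / (4.0 * r * r)
    return float(np.sum(lj + coul))


def score_pose(receptor: ToyReceptor, ligand: Pose, vdw_scale: float = 1.0) -> float:
    """Interaction energy of a rigid pose, kcal/mol (lower = better).

    Sum over all site-atom pairs of a 12-6 Lennard-Jones term (minimum at
    ``vdw_scale * (site radius + atom radius)``) and screened Coulomb
    electrostatics. Raises :class:`ClashError` for overlapping centers.
    """
    site_q = np.asarray([s.charge for s in receptor.sites])
    site_r = np.asarray([s.radius for s in receptor.sites])
    site_eps = np.asarray([s.epsilon for s in receptor.sites])
    lig_q, lig_r, lig_eps = _ligand_params(ligand)
    value = _score_coords(
        receptor.positions(), site_q, site_r, site_eps,
        ligand.coords(), lig_q, lig_r, lig_eps, vdw_scale,
    )
    if value == float("inf"):
        raise ClashError("receptor site and ligand atom closer than clash distance")
    return value


def _anchor_atom_index(ligand: Pose, anchor_atom: str | None) -> int:
    if anchor_atom is not None:
        for i, a in enumerate(ligand.atoms):
            if a.name == anchor_atom:
                return i
        raise KeyError(f"no ligand atom named {anchor_atom!r}")
    return int(np.argmax(ligand.charges()))


def dock(
    receptor: ToyReceptor,
    ligand: Pose,
    constraints: DockConstraints | None = None,
    n_samples: int = 2000,
    seed: int = 0,
    vdw_scale: float = 1.0,
    anchor_atom: str | None = None,
    refine: bool = True,
    n_refine: int = 5,
) -> DockResult:
    """Constrained rigid-pose search: seeded random placements, then local
    minimization of the best survivors.

    Uniform random rotations (quaternions) and translations in a bounding
    box around the anchor are sampled; placements violating the anchor
    distance, the core restraint or the energy cutoff are discarded. The
    ``n_refine`` best survivors are polished by derivative-free rigid-body
    minimization (the analogue of the protocol's pose-minimization stage).
    Deterministic given (inputs, seed); returns NO_POSE when nothing passes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    constraints = constraints or DockConstraints()
    rng = np.random.default_rng(seed)

    site_q = np.asarray([s.charge for s in receptor.sites])
    site_r = np.asarray([s.radius for s in receptor.sites])
    site_eps = np.asarray([s.epsilon for s in receptor.sites])
    site_pos = receptor.positions()
    lig_q, lig_r, lig_eps = _ligand_params(ligand)
    base = ligand.coords()
    centroid = base.mean(axis=0)
    centered = base - centroid
    anchor_idx = _anchor_atom_index(ligand, anchor_atom)
    anchor_pos = receptor.anchor_position()
    extent = float(np.max(np.linalg.norm(centered, axis=1)))
    box = constraints.anchor_max_dist + extent

    core_idx = core_ref = None
    if constraints.core_reference is not None:
        names = [a.name for a in ligand.atoms]
        core_idx = np.asarray([names.index(n) for n in constraints.core_reference])
        core_ref = np.asarray(
            [constraints.core_reference[n] for n in constraints.core_reference],
            dtype=float,
        )

    def passes_and_score(xyz: np.ndarray) -> tuple[bool, float]:
        if np.linalg.norm(xyz[anchor_idx] - anchor_pos) > constraints.anchor_max_dist:
            return False, float("inf")
        if core_idx is not None:
            core_rmsd = np.sqrt(
                np.mean(np.sum((xyz[core_idx] - core_ref) ** 2, axis=1))
            )
            if core_rmsd > constraints.core_tolerance:
                return False, float("inf")
        s = _score_coords(
            site_pos, site_q, site_r, site_eps, xyz, lig_q, lig_r, lig_eps, vdw_scale
        )
        if not (s <= constraints.max_score):
            return False, s
        return True, s

    core_ref_centroid = core_ref.mean(axis=0) if core_ref is not None else None
    core_base_rot = None
    if core_ref is not None and len(core_idx) >= 3:
        # orientation implied by the core restraint (restrained docking seeds
        # placements from the reference core, as the real protocol does)
        core_base_rot, _ = Rotation.align_vectors(
            core_ref - core_ref_centroid,
            centered[core_idx] - centered[core_idx].mean(axis=0),
        )

    survivors: list[tuple[float, np.ndarray, np.ndarray]] = []  # (score, rotvec, trans)
    n_passed = 0
    for k in range(n_samples):
        quat = rng.normal(size=4)
        quat /= np.linalg.norm(quat)
        rot = Rotation.from_quat(quat)
        if core_base_rot is not None and k % 2 == 0:
            # half the samples perturb the core-implied orientation
            rot = Rotation.from_rotvec(rng.normal(0.0, 0.3, size=3)) * core_base_rot
        if core_ref_centroid is not None:
            # core-restrained placement: align the rotated core centroid to
            # the reference, then jitter within the tolerance
            rotated = rot.apply(centered)
            trans = (
                core_ref_centroid
                - rotated[core_idx].mean(axis=0)
                + rng.uniform(-constraints.core_tolerance,
                              constraints.core_tolerance, size=3)
            )
        else:
            trans = anchor_pos + rng.uniform(-box, box, size=3)
        xyz = rot.apply(centered) + trans
        ok, s = passes_and_score(xyz)
        if ok:
            n_passed += 1
            survivors.append((s, rot.as_rotvec(), trans))

    survivors.sort(key=lambda t: t[0])
    best = survivors[0] if survivors else None

    if refine and survivors:
        for s0, rotvec, trans in survivors[:n_refine]:
            def objective(params: np.ndarray) -> float:
                d_rot = Rotation.from_rotvec(params[:3])
                xyz = (
                    d_rot.apply(Rotation.from_rotvec(rotvec).apply(centered))
                    + trans
                    + params[3:]
                )
                ok, s = passes_and_score(xyz)
                return s if ok else 1e6 + min(s, 1e6)

            res = minimize(
                objective,
                np.zeros(6),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600},
            )
            if res.fun < best[0]:
                d_rot = Rotation.from_rotvec(res.x[:3])
                combined = d_rot * Rotation.from_rotvec(rotvec)
                best = (float(res.fun), combined.as_rotvec(), trans + res.x[3:])

    if best is None:
        return DockResult(None, None, n_samples, n_passed, seed)
    s, rotvec, trans = best
    rot = Rotation.from_rotvec(rotvec)
    best_pose = Pose(
        atoms=[
            type(a)(a.name, a.element, tuple(p), a.charge)
            for a, p in zip(ligand.atoms, rot.apply(centered) + trans)
        ],
        bonds=list(ligand.bonds),
        frame_note="docked",
    )
    return DockResult(best_pose, float(s), n_samples, n_passed, seed)


# ---------------------------------------------------------------------------
# Receptor file format: 'site x y z charge radius epsilon', 'anchor <index>'
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path) -> ToyReceptor:
    sites: list[Site] = []
    anchor = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "anchor":
            anchor = int(parts[1])
        elif parts[0] == "site":
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: site record needs 6 numbers, got "
                    f"{len(parts) - 1}"
                )
            x, y, z, q, r, eps = (float(v) for v in parts[1:])
            sites.append(Site((x, y, z), q, r, eps))
        else:
            raise ValueError(f"{path}:{lineno}: unknown record {parts[0]!r}")
    return ToyReceptor(sites=tuple(sites), anchor_site=anchor)


def write_receptor(receptor: ToyReceptor, path: str | Path) -> None:
    lines = ["# toy receptor: site x y z charge radius epsilon"]
    lines.append(f"anchor {receptor.anchor_site}")
    for s in receptor.sites:
        x, y, z = s.position
        lines.append(
            f"site {x:.6f} {y:.6f} {z:.6f} {s.charge:.4f} {s.radius:.4f} "
            f"{s.epsilon:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
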