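"""Synthetic fixtures: planted score profiles, sequence families, toy complexes.

Every stage of the pipeline is testable without external downloads:

* :func:`gen_profiles` emits docking-score tables whose planted channel's
  representatives are a controlled gap better than the competitors', with
  the characteristic along-channel shape observed for lanosterol-synthase-
  like enzymes — a highly favorable I1, a penalized I2, gradual improvement
  to a minimum at the product-precursor cation, and failed dockings at
  chosen downstream positions.
* :func:`gen_sequences` emits protein families with controlled within- and
  between-family percent identity (uniform substitutions, no indels, so the
  identity targeting is exact in expectation).
* :func:`gen_toy_complex` emits a toy pocket + cationic ligand whose planted
  pose satisfies the anchor and core constraints and sits at a local score
  minimum.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .channels import ChannelLibrary, default_library
from .scores import NO_POSE, ScoreStatus, ScoreTable
from .structures import Atom, Pose
from .toyscore import DockConstraints, Site, ToyReceptor, score_pose

__all__ = [
    "ProfileSpec",
    "gen_profiles",
    "gen_sequences",
    "ToyComplex",
    "gen_toy_complex",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProfileSpec:
    """Study conditions for planted score-profile generation.

    ``representative_gap`` (g, kcal/mol) is how much better the planted
    channel's I1/I2 score than the other channels'; ``noise`` (σ, kcal/mol)
    is i.i.d. Gaussian noise on every numeric score. The planted channel's
    profile descends to a minimum at ``precursor_index`` and rises after it;
    ``downstream_nonbinder_indices`` become failed dockings.
    """

    planted_channel: str = "C"
    representative_gap: float = 3.0
    noise: float = 1.0
    precursor_index: int = 6
    downstream_nonbinder_indices: tuple[int, ...] = (8,)
    n_enzymes: int = 100
    seed: int = 0
    # profile shape anchors (kcal/mol)
    i1_score: float = -60.0
    i2_penalty: float = 15.0
    precursor_depth: float = 10.0  # precursor minimum below the I2 level
    rise_step: float = 5.0  # per-index worsening past the precursor

    def __post_init__(self) -> None:
        if self.representative_gap <= 0:
            raise ValueError("representative_gap must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def gen_profiles(
    spec: ProfileSpec, lib: ChannelLibrary | None = None
) -> tuple[ScoreTable, dict[str, dict[str, str]]]:
    """Generate a planted-truth score table.

    Returns ``(table, truth)`` with ``truth[enzyme] = {'channel': ...,
    'precursor': ...}``. The planted channel gets a full profile; competitor
    channels get their two representative intermediates (all that channel
    ranking consumes).
    """
    lib = lib or default_library()
    planted = lib.channel(spec.planted_channel)
    if not (2 <= spec.precursor_index <= len(planted)):
        raise ValueError(
            f"precursor_index {spec.precursor_index} outside channel "
            f"{planted.id} (length {len(planted)})"
        )
    for idx in spec.downstream_nonbinder_indices:
        if not (1 <= idx <= len(planted)):
            raise ValueError(f"non-binder index {idx} outside channel {planted.id}")
    rng = np.random.default_rng(spec.seed)
    table = ScoreTable(metadata={"mode": "absolute", "source": "synthetic"})
    truth: dict[str, dict[str, str]] = {}
    i2_level = spec.i1_score + spec.i2_penalty
    precursor_level = i2_level - spec.precursor_depth
    width = len(str(spec.n_enzymes))

    def noisy(mean: float) -> ScoreStatus:
        return ScoreStatus(mean + float(rng.normal(0.0, spec.noise)))

    for k in range(spec.n_enzymes):
        enzyme = f"synth-{k + 1:0{width}d}"
        truth[enzyme] = {
            "channel": planted.id,
            "precursor": planted.intermediates[spec.precursor_index - 1].id,
        }
        for inter in planted.intermediates:
            i = inter.index
            if i in spec.downstream_nonbinder_indices:
                table.add(enzyme, inter.id, NO_POSE)
                continue
            if i == 1:
                mean = spec.i1_score
            elif i <= spec.precursor_index:
                frac = (i - 2) / max(spec.precursor_index - 2, 1)
                mean = i2_level + frac * (precursor_level - i2_level)
            else:
                mean = precursor_level + spec.rise_step * (i - spec.precursor_index)
            table.add(enzyme, inter.id, noisy(mean))
        for chan in lib.enabled_channels():
            if chan.id == planted.id:
                continue
            g = spec.representative_gap
            table.add(enzyme, chan.representative(1).id, noisy(spec.i1_score + g))
            table.add(enzyme, chan.representative(2).id, noisy(i2_level + g))
    return table, truth


# ---------------------------------------------------------------------------
# Sequence families
# ---------------------------------------------------------------------------

def _member_mutation_rate(target_identity: float) -> float:
    """Per-member mutation fraction m so two members share ``target_identity``.

    Two members independently mutate a fraction m of positions (uniform over
    the 19 alternatives), so expected pairwise identity is
    (1−m)² + m²/19; solved for m.
    """
    t = target_identity / 100.0
    a = 1.0 + 1.0 / 19.0
    disc = 4.0 - 4.0 * a * (1.0 - t)
    if disc < 0:
        raise ValueError(f"within-family identity {target_identity}% infeasible")
    return (2.0 - math.sqrt(disc)) / (2.0 * a)


def _ancestor_keep_fraction(target_identity: float) -> float:
    """Fraction of master positions an ancestor keeps so two ancestors share
    ``target_identity`` (random-match floor 1/20 accounted for)."""
    t = target_identity / 100.0
    floor = 1.0 / 20.0
    if t < floor:
        raise ValueError(
            f"between-family identity {target_identity}% below the random "
            f"floor of {floor * 100:.0f}%"
        )
    return math.sqrt((t - floor) / (1.0 - floor))


def gen_sequences(
    n_families: int,
    members: int,
    within_identity: float = 90.0,
    between_identity: float = 25.0,
    length: int = 300,
    seed: int = 0,
    channels: tuple[str, ...] = ("A", "B", "C", "D"),
) -> tuple[dict[str, str], dict[str, dict[str, str]]]:
    """Sequence families with controlled divergence.

    Returns ``(seqs, annotations)``; annotations cycle family labels through
    ``channels``. Members are generated from a family ancestor by point
    substitution at a rate targeting the within-family pairwise identity;
    ancestors derive from a shared master sequence targeting the
    between-family identity. No indels, so identities are exact per-position
    comparisons in expectation (±2% sampling noise at typical lengths).
    """
    if within_identity <= between_identity:
        raise ValueError("within_identity must exceed between_identity")
    if not (0 < within_identity <= 100):
        raise ValueError("within_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    m = _member_mutation_rate(within_identity)
    k = _ancestor_keep_fraction(between_identity)
    aas = np.array(list(AMINO_ACIDS))
    master = rng.choice(len(aas), size=length)
    seqs: dict[str, str] = {}
    annotations: dict[str, dict[str, str]] = {}

    def mutate(base: np.ndarray, fraction: float) -> np.ndarray:
        n_mut = int(round(fraction * length))
        pos = rng.choice(length, size=n_mut, replace=False)
        out = base.copy()
        # substitute with a uniformly chosen *different* residue
        shift = rng.integers(1, len(aas), size=n_mut)
        out[pos] = (out[pos] + shift) % len(aas)
        return out

    for fam in range(n_families):
        ancestor = mutate(master, 1.0 - k)
        channel = channels[fam % len(channels)]
        for mem in range(members):
            seq = mutate(ancestor, m)
            sid = f"fam{fam + 1:02d}_m{mem + 1:02d}"
            seqs[sid] = "".join(aas[seq])
            annotations[sid] = {"channel": channel, "ec": ""}
    return seqs, annotations


# ---------------------------------------------------------------------------
# Toy receptor–ligand complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    """A generated pocket, its ligand in the planted pose, and constraints."""

    receptor: ToyReceptor
    ligand: Pose  # in the planted pose
    planted_pose: Pose
    constraints: DockConstraints = field(default_factory=DockConstraints)


def _refine_planted(receptor: ToyReceptor, pose: Pose) -> Pose:
    """Slide the constructed pose to the nearest local score minimum."""
    coords = pose.coords()
    centroid = coords.mean(axis=0)
    centered = coords - centroid

    def objective(params: np.ndarray) -> float:
        rot = Rotation.from_rotvec(params[:3])
        xyz = rot.apply(centered) + centroid + params[3:]
        moved = Pose(
            atoms=[
                Atom(a.name, a.element, tuple(p), a.charge)
                for a, p in zip(pose.atoms, xyz)
            ]
        )
        try:
            return score_pose(receptor, moved)
        except Exception:
            return 1e6

    starts = [np.zeros(6)]
    rng = np.random.default_rng(1)
    starts += [
        np.concatenate([rng.normal(0, 0.1, 3), rng.normal(0, 0.2, 3)])
        for _ in range(4)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 800},
        )
        if best is None or res.fun < best.fun:
            best = res
    rot = Rotation.from_rotvec(best.x[:3])
    xyz = rot.apply(centered) + centroid + best.x[3:]
    return Pose(
        atoms=[
            Atom(a.name, a.element, tuple(p), a.charge)
            for a, p in zip(pose.atoms, xyz)
        ],
        frame_note="planted",
    )


def gen_toy_complex(seed: int = 0, n_pocket_sites: int = 14) -> ToyComplex:
    """Generate a pocket of LJ sites with one anionic anchor plus a cationic
    four-bead ligand whose planted pose satisfies all docking constraints.

    The pocket sites are placed at near-optimal contact distances around the
    ligand, the anchor anion within hydrogen-bond range (≤ 2.5 Å) of the
    cationic head bead, and the planted pose is relaxed to the local score
    minimum of the finished receptor.
    """
    if not (10 <= n_pocket_sites + 1 <= 30):
        raise ValueError("total site count must lie in [10, 30]")
    rng = np.random.default_rng(seed)
    # graded charges break the orientational symmetry of the bead cluster
    atoms = [
        Atom("C1", "C", (0.0, 0.0, 0.0), 0.7),
        Atom("C2", "C", (1.5, 0.0, 0.0), 0.25),
        Atom("C3", "C", (0.75, 1.3, 0.0), 0.1),
        Atom("C4", "C", (0.75, 0.43, 1.2), -0.05),
    ]
    ligand = Pose(atoms=atoms, frame_note="planted")
    coords = ligand.coords()

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def away_from_cluster(atom_idx: int) -> np.ndarray:
        # direction pointing outward so the site clears the other beads
        for _ in range(200):
            d = random_unit()
            if all(
                np.dot(d, coords[j] - coords[atom_idx]) < 0.3
                for j in range(len(atoms))
                if j != atom_idx
            ):
                return d
        return random_unit()

    # anchor anion ~2.2 Å from the cationic head; small radius so the
    # hydrogen-bond-like contact is not sterically strained
    anchor = Site(tuple(coords[0] + 2.2 * away_from_cluster(0)), charge=-1.0,
                  radius=0.5, epsilon=0.15)
    # orientation-selective charged contacts near specific beads
    sel1 = Site(tuple(coords[1] + 3.4 * away_from_cluster(1)), charge=-0.6,
                radius=1.5, epsilon=0.2)
    sel2 = Site(tuple(coords[3] + 3.4 * away_from_cluster(3)), charge=+0.4,
                radius=1.5, epsilon=0.2)
    sites = [anchor, sel1, sel2]
    attempts = 0
    while len(sites) < n_pocket_sites + 1 and attempts < 10000:
        attempts += 1
        atom_idx = int(rng.integers(len(atoms)))
        direction = random_unit()
        radius = 1.9
        rm = radius + 1.9  # carbon contact optimum
        pos = coords[atom_idx] + rm * direction
        dists = np.linalg.norm(coords - pos, axis=1)
        site_dists = [np.linalg.norm(np.asarray(s.position) - pos) for s in sites]
        if np.min(dists) < 0.95 * rm or (site_dists and min(site_dists) < 2.0):
            continue
        sites.append(Site(tuple(pos), charge=0.0, radius=radius, epsilon=0.1))
    receptor = ToyReceptor(sites=tuple(sites), anchor_site=0)

    planted = _refine_planted(receptor, ligand)
    # the planted optimum is the *global* constrained optimum: a thorough
    # search around the constructed pose may find a deeper basin inside the
    # core-restraint region, and that basin is the pose later runs must find
    from .toyscore import dock, score_pose

    probe_constraints = DockConstraints(
        anchor_max_dist=2.5,
        core_reference={a.name: a.xyz for a in planted.atoms},
        core_tolerance=1.0,
        max_score=0.0,
    )
    probe = dock(
        receptor, planted, probe_constraints, n_samples=4000,
        seed=int(np.random.default_rng(seed).integers(2**31)), n_refine=10,
    )
    if probe.best_pose is not None and probe.score < score_pose(receptor, planted):
        planted = Pose(atoms=list(probe.best_pose.atoms), frame_note="planted")
    constraints = DockConstraints(
        anchor_max_dist=2.5,
        core_reference={a.name: a.xyz for a in planted.atoms},
        core_tolerance=1.0,
        max_score=0.0,
    )
    return ToyComplex(
        receptor=receptor,
        ligand=planted,
        planted_pose=planted,
        constraints=constraints,
    )
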