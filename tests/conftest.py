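"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from terpchannel.channels import default_library
from terpchannel.scores import NO_POSE, ScoreStatus, ScoreTable


@pytest.fixture(scope="session")
def lib():
    return default_library()


def random_score_table(rng: np.random.Generator, lib, p_no_pose: float = 0.15,
                       enzyme: str = "E") -> ScoreTable:
    """Random representative scores for every enabled channel."""
    table = ScoreTable()
    for chan in lib.enabled_channels():
        for rank in (1, 2):
            inter = chan.representative(rank)
            if rng.random() < p_no_pose:
                table.add(enzyme, inter.id, NO_POSE)
            else:
                value = float(np.round(rng.normal(-50.0, 8.0), 1))
                table.add(enzyme, inter.id, ScoreStatus(value))
    return table


def brute_force_channel_ranking(table: ScoreTable, enzyme: str, lib,
                                tie_threshold: float = 1.0):
    """Independent one-shot lexicographic oracle for the two-round rule.

    Channels in the round-1 tie bucket of the best channel sort by
    (round-2 score, round-1 score, rep sum, id); the rest sort after by
    (round-1 score, id). Scores compare as (is-no-pose, value).
    """

    def key(status):
        return (1, 0.0) if status.is_no_pose else (0, status.value)

    chans = [c.id for c in lib.enabled_channels()]
    r1 = {c: table.require(enzyme, lib.channel(c).representative(1).id) for c in chans}
    r2 = {c: table.require(enzyme, lib.channel(c).representative(2).id) for c in chans}
    best_c = min(chans, key=lambda c: (key(r1[c]), c))
    best = r1[best_c]

    def tied(c):
        s = r1[c]
        if best.is_no_pose:
            return s.is_no_pose
        return not s.is_no_pose and abs(s.value - best.value) < tie_threshold

    def sum_key(c):
        if r1[c].is_no_pose or r2[c].is_no_pose:
            return (1, 0.0)
        return (0, r1[c].value + r2[c].value)

    bucket = sorted(
        (c for c in chans if tied(c)),
        key=lambda c: (key(r2[c]), key(r1[c]), sum_key(c), c),
    )
    rest = sorted((c for c in chans if not tied(c)), key=lambda c: (key(r1[c]), c))
    return bucket + rest


def enumerate_local_alignment_score(
    a: str, b: str, sub, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Exhaustive local-alignment oracle for tiny sequences.

    Every local alignment is a strictly increasing matching of positions of
    *a* to positions of *b*; unmatched stretches between consecutive matched
    columns are charged as affine gap runs (open + length * extend per run).
    Terminal overhangs are free (local). The optimum over all matchings,
    floored at 0 (the empty alignment), equals the Smith-Waterman score.
    """
    best = 0.0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for ia in itertools.combinations(range(la), k):
            for ib in itertools.combinations(range(lb), k):
                score = 0.0
                for t in range(k):
                    score += sub[a[ia[t]], b[ib[t]]]
                    if t:
                        ga = ia[t] - ia[t - 1] - 1
                        gb = ib[t] - ib[t - 1] - 1
                        if ga:
                            score -= gap_open + ga * gap_extend
                        if gb:
                            score -= gap_open + gb * gap_extend
                best = max(best, score)
    return best


def praxeolitic_dihedral(p1, p2, p3, p4) -> float:
    """Independent projection-based torsion formula (degrees)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def horn_quaternion_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigen-method."""
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    m = xb.T @ xa
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = np.sum(xa**2) + np.sum(xb**2)
    msd = max((e0 - 2.0 * lam) / len(xa), 0.0)
    return float(np.sqrt(msd))


class UnionFind:
    """Tiny union-find oracle for component counting."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted(groups.values(), key=lambda c: (-len(c), min(c)))
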