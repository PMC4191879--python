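"""Hierarchical ranking of reaction channels and intermediates.

The central decision rules of mechanism-based carbocation docking:

* **Channel prediction** (two-round hierarchical ranking): channels are first
  ordered by the docking score of their rank-1 representative intermediate
  (the 6,6-bicyclic I1; more negative = better). Channels whose round-1
  scores lie within a tie threshold (default 1 kcal/mol) of the best form a
  tie group, which is then re-ordered by the rank-2 representative (the
  6,6,6,5-tetracyclic I2). After the second representatives the best channel
  is selected.
* **Intermediate ranking**: all intermediates along the chosen channel are
  ranked by score, without considering further branching points.
* **Endpoint prediction**: the inability of a binding site to stabilize a
  downstream cation (a failed docking, or a score above a binder threshold)
  terminates the channel there and rules out all downstream products.
* **Mutant comparison**: per-intermediate mutant − wild-type score
  differences classify each cation as unaffected, destabilized, or abolished
  (no pose at all).

A failed docking (NO_POSE) is always ordered strictly worse than any numeric
score and never enters arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .channels import ChannelLibrary, Intermediate
from .scores import NO_POSE, ScoreStatus, ScoreTable, score_sort_key

__all__ = [
    "ChannelPrediction",
    "EndpointPrediction",
    "MutantComparison",
    "rank_channels",
    "predict_channel",
    "rank_intermediates",
    "predict_endpoint",
    "compare_mutant",
    "evaluate_predictions",
    "DEFAULT_TIE_THRESHOLD",
    "DEFAULT_BINDER_THRESHOLD",
    "DEFAULT_DESTABILIZATION_THRESHOLD",
]

#: Round-1 tie threshold, kcal/mol ("similar binding affinity").
DEFAULT_TIE_THRESHOLD = 1.0
#: Scores above this are treated as non-binders in endpoint analysis, kcal/mol.
DEFAULT_BINDER_THRESHOLD = 0.0
#: Mutant − wild-type shift classifying an intermediate as destabilized, kcal/mol.
DEFAULT_DESTABILIZATION_THRESHOLD = 5.0


@dataclass
class ChannelPrediction:
    """Outcome of hierarchical channel ranking for one enzyme."""

    enzyme: str
    ranked_channels: list[str]
    best_channel: str | None
    tie_group: list[str]
    round_trace: dict = field(default_factory=dict)
    ambiguous: bool = False


@dataclass
class EndpointPrediction:
    """Channel-termination analysis for one enzyme along one channel."""

    enzyme: str
    channel: str
    best_intermediate: str | None
    terminate_after: int
    ruled_out_products: list[str]
    rise_check_passed: bool


@dataclass
class MutantComparison:
    """Mutant vs wild-type score shift for a single intermediate.

    ``delta`` is the shift in kcal/mol, or ``None`` when the mutant (or, in
    absolute mode, either side) has no pose, in which case no numeric
    difference exists.
    """

    intermediate: str
    delta: float | None
    classification: str  # 'unaffected' | 'destabilized' | 'abolished'


def _representative_scores(
    table: ScoreTable, enzyme: str, lib: ChannelLibrary, rank: int
) -> dict[str, ScoreStatus]:
    out = {}
    for chan in lib.enabled_channels():
        rep = chan.representative(rank)
        out[chan.id] = table.require(enzyme, rep.id)
    return out


def rank_channels(
    table: ScoreTable,
    enzyme: str,
    lib: ChannelLibrary,
    tie_threshold: float = DEFAULT_TIE_THRESHOLD,
) -> ChannelPrediction:
    """Two-round hierarchical channel ranking.

    Round 1 orders the enabled channels by the rank-1 representative score;
    channels within ``tie_threshold`` of the round-1 best form a tie group.
    Round 2 re-orders the tie group by the rank-2 representative score; the
    remaining channels keep their round-1 order. Persisting exact ties are
    broken deterministically (better round-1 score, then summed
    representative scores, then channel label) and flagged ``ambiguous``.
    """
    if table.mode != "absolute":
        raise ValueError("channel ranking requires an absolute-mode score table")
    r1 = _representative_scores(table, enzyme, lib, rank=1)
    r2 = _representative_scores(table, enzyme, lib, rank=2)
    if not r1:
        raise ValueError("no enabled channels in library")

    def sum_key(cid: str) -> tuple[int, float]:
        s1, s2 = r1[cid], r2[cid]
        if s1.is_no_pose or s2.is_no_pose:
            return (1, 0.0)
        return (0, s1.value + s2.value)

    order1 = sorted(r1, key=lambda c: (score_sort_key(r1[c]), c))
    best1 = r1[order1[0]]

    def in_tie_group(cid: str) -> bool:
        s = r1[cid]
        if best1.is_no_pose:
            return s.is_no_pose
        return (not s.is_no_pose) and abs(s.value - best1.value) < tie_threshold

    tie_group_members = [c for c in order1 if in_tie_group(c)]
    rest = [c for c in order1 if c not in tie_group_members]

    tie_sorted = sorted(
        tie_group_members,
        key=lambda c: (score_sort_key(r2[c]), score_sort_key(r1[c]), sum_key(c), c),
    )
    ranked = tie_sorted + rest

    ambiguous = False
    if len(tie_sorted) >= 2:
        a, b = tie_sorted[0], tie_sorted[1]
        if score_sort_key(r2[a]) == score_sort_key(r2[b]):
            ambiguous = True

    all_no_pose = all(s.is_no_pose for s in r1.values()) and all(
        s.is_no_pose for s in r2.values()
    )
    best = None if all_no_pose else ranked[0]
    if all_no_pose:
        ambiguous = True

    trace = {
        "round1": {c: r1[c] for c in order1},
        "tie_group": list(tie_sorted),
        "round2": {c: r2[c] for c in tie_sorted},
        "tie_threshold": tie_threshold,
    }
    return ChannelPrediction(
        enzyme=enzyme,
        ranked_channels=ranked,
        best_channel=best,
        tie_group=tie_sorted,
        round_trace=trace,
        ambiguous=ambiguous,
    )


def predict_channel(
    table: ScoreTable,
    enzyme: str,
    lib: ChannelLibrary,
    tie_threshold: float = DEFAULT_TIE_THRESHOLD,
) -> str | None:
    """Best reaction channel for *enzyme* (None when fully undecidable)."""
    return rank_channels(table, enzyme, lib, tie_threshold).best_channel


def rank_intermediates(
    table: ScoreTable,
    enzyme: str,
    channel: str,
    lib: ChannelLibrary,
) -> list[Intermediate]:
    """Intermediates of *channel* sorted best-first (NO_POSE last, ties in
    library order)."""
    chan = lib.channel(channel)
    table.require(enzyme, chan.intermediates[0].id)  # at least I1 scored
    scored = [i for i in chan.intermediates if table.get(enzyme, i.id) is not None]
    return sorted(
        scored, key=lambda i: (score_sort_key(table.require(enzyme, i.id)), i.index)
    )


def predict_endpoint(
    table: ScoreTable,
    enzyme: str,
    channel: str,
    lib: ChannelLibrary,
    binder_threshold: float = DEFAULT_BINDER_THRESHOLD,
) -> EndpointPrediction:
    """Termination analysis: where along *channel* does the reaction stop?

    The putative product precursor is the best binder among intermediates at
    index ≥ 2. Scanning downstream of it, the first *non-binder* (NO_POSE or
    score above ``binder_threshold``) terminates the channel just before
    itself; products of all intermediates beyond the termination point are
    ruled out. ``rise_check_passed`` records whether any intermediate after
    the putative precursor is strictly worse than it — profiles that keep
    improving to the channel end carry no endpoint signal.
    """
    chan = lib.channel(channel)
    if len(chan) < 2:
        raise ValueError(f"channel {channel} has fewer than 2 intermediates")
    statuses: dict[int, ScoreStatus] = {}
    for inter in chan.intermediates:
        statuses[inter.index] = table.require(enzyme, inter.id)
    if len(statuses) < 2:
        raise ValueError(f"fewer than 2 intermediates scored for {enzyme}")

    candidates = [
        (statuses[i].value, i)
        for i in statuses
        if i >= 2 and not statuses[i].is_no_pose
    ]
    n = len(chan)
    if not candidates:
        best_idx = None
        terminate_after = 1
        rise = False
    else:
        best_val, best_idx = min(candidates)
        terminate_after = n
        for j in range(best_idx + 1, n + 1):
            s = statuses[j]
            if s.is_no_pose or s.value > binder_threshold:
                terminate_after = j - 1
                break
        rise = any(
            statuses[j].is_no_pose or statuses[j].value > best_val
            for j in range(best_idx + 1, n + 1)
        )

    ruled_out = [
        name
        for inter in chan.intermediates
        if inter.index > terminate_after
        for name, _ec in inter.products
    ]
    best_id = chan.intermediates[best_idx - 1].id if best_idx is not None else None
    return EndpointPrediction(
        enzyme=enzyme,
        channel=channel,
        best_intermediate=best_id,
        terminate_after=terminate_after,
        ruled_out_products=ruled_out,
        rise_check_passed=rise,
    )


def compare_mutant(
    wt: ScoreTable,
    mut: ScoreTable,
    wt_enzyme: str,
    mut_enzyme: str,
    channel: str,
    lib: ChannelLibrary,
    destabilization_threshold: float = DEFAULT_DESTABILIZATION_THRESHOLD,
) -> list[MutantComparison]:
    """Classify each intermediate of *channel* as unaffected / destabilized /
    abolished in the mutant.

    Either both tables are absolute (delta = mutant − wild-type) or the
    mutant table is relative-to-wild-type (its values *are* the deltas).
    An intermediate is *abolished* iff the mutant has no pose, *destabilized*
    iff its delta is at least ``destabilization_threshold`` kcal/mol.
    """
    if wt.mode == "relative":
        raise ValueError("wild-type table must be absolute-mode")
    relative = mut.mode == "relative"
    chan = lib.channel(channel)
    out: list[MutantComparison] = []
    for inter in chan.intermediates:
        m = mut.get(mut_enzyme, inter.id)
        w = wt.get(wt_enzyme, inter.id)
        if not relative and (m is None) != (w is None):
            raise ValueError(
                f"intermediate {inter.id} present in only one score table"
            )
        if m is None:
            continue
        if m.is_no_pose:
            out.append(MutantComparison(inter.id, None, "abolished"))
            continue
        if relative:
            delta: float | None = m.value
        elif w.is_no_pose:
            # pose gained relative to wild type: no numeric delta exists
            delta = None
        else:
            delta = m.value - w.value
        if delta is not None and delta >= destabilization_threshold:
            cls = "destabilized"
        else:
            cls = "unaffected"
        out.append(MutantComparison(inter.id, delta, cls))
    return out


def evaluate_predictions(
    predictions: Mapping[str, str | None],
    truth: Mapping[str, str],
    clusters: Mapping[str, str],
    endpoint_best: Mapping[str, str] | None = None,
    precursor_sets: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Per-cluster and total channel-prediction statistics.

    ``predictions`` maps enzyme → predicted channel; every enzyme must carry
    a truth channel and a cluster label (e.g. which template/cluster its
    model derives from). Optionally, ``endpoint_best`` (enzyme → best
    downstream intermediate) is scored against per-enzyme acceptable
    ``precursor_sets``, yielding product-precursor statistics.
    """
    per_cluster: dict[str, dict] = {}
    total = {"n": 0, "correct": 0}
    for enzyme, predicted in predictions.items():
        if enzyme not in truth:
            raise KeyError(f"enzyme {enzyme!r} has no truth label")
        if enzyme not in clusters:
            raise KeyError(f"enzyme {enzyme!r} has no cluster label")
        cluster = clusters[enzyme]
        stats = per_cluster.setdefault(cluster, {"n": 0, "correct": 0})
        stats["n"] += 1
        total["n"] += 1
        if predicted == truth[enzyme]:
            stats["correct"] += 1
            total["correct"] += 1
    for stats in [*per_cluster.values(), total]:
        stats["success_rate"] = stats["correct"] / stats["n"] if stats["n"] else 0.0
    report = {"clusters": per_cluster, "total": total}

    if endpoint_best is not None and precursor_sets is not None:
        hits = 0
        n = 0
        for enzyme, best in endpoint_best.items():
            if enzyme not in precursor_sets:
                raise KeyError(f"enzyme {enzyme!r} has no precursor set")
            n += 1
            if best in set(precursor_sets[enzyme]):
                hits += 1
        report["precursor"] = {
            "n": n,
            "hits": hits,
            "rate": hits / n if n else 0.0,
        }
    return report
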