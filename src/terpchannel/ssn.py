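"""Protein sequence similarity networks for triterpenoid synthases.

All-vs-all pairwise local alignment (Smith–Waterman, affine gaps, BLOSUM62)
with Karlin–Altschul E-values; sequences become nodes and pairs with E-value
at or below a cutoff become edges. Scanning the cutoff from permissive to
strict progressively breaks the network into clusters, and mapping reaction
channels (or EC numbers) onto nodes shows at which stringency the functional
classes segregate. Uncharacterized sequences carry the label ``unknown`` and
are excluded from purity statistics.

E-values here come from an exact Smith–Waterman score converted with the
published ungapped BLOSUM62 Karlin–Altschul parameters and the raw search
space m·n; they differ numerically from BLAST's (which uses gapped
parameters and length corrections), so cutoffs are comparable within this
implementation but not transferable from BLAST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "PairScore",
    "SimilarityNetwork",
    "align_pair",
    "all_pairs",
    "build_network",
    "components",
    "quartile_table",
    "segregation_purity",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_edge_list",
    "write_xgmml",
]

#: Karlin–Altschul parameters for ungapped BLOSUM62 (published values).
KA_LAMBDA = 0.3176
KA_K = 0.134

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PairScore:
    """One pairwise local alignment summary."""

    id_a: str
    id_b: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float  # percent over aligned columns
    alignment_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    mat = substitution_matrices.load(matrix).copy()
    if "X" in mat.alphabet:
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    aligner.substitution_matrix = mat
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float) -> float:
    """Karlin–Altschul bit conversion: (λ·S − ln K) / ln 2."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    """E = m·n·2^(−bit score), raw sequence lengths, no length correction."""
    log2_e = math.log2(m) + math.log2(n) - bit_score(raw_score)
    return 2.0 ** log2_e


def align_pair(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairScore:
    """Optimal local alignment of two protein sequences.

    Affine gaps (a gap of length k costs ``gap_open + k * gap_extend``),
    BLOSUM62 by default, ``X`` scored 0 against everything. Identity is
    matches over aligned columns (gap columns included) of one optimal
    alignment.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    score = float(aligner.score(a, b))
    try:
        best = alignments[0]
        counts = best.counts()
        matches = counts.identities
        length = counts.identities + counts.mismatches + counts.gaps
    except (IndexError, ValueError):
        matches, length = 0, 0
    identity = 100.0 * matches / length if length else 0.0
    return PairScore(
        id_a=id_a,
        id_b=id_b,
        raw_score=score,
        bit_score=bit_score(score),
        evalue=evalue(score, len(a), len(b)),
        identity=identity,
        alignment_length=length,
    )


def all_pairs(
    seqs: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[PairScore]:
    """All unordered pairs, deterministic (sorted id) order."""
    ids = sorted(seqs)
    out = []
    for i, ida in enumerate(ids):
        for idb in ids[i + 1:]:
            out.append(
                align_pair(seqs[ida], seqs[idb], ida, idb, matrix, gap_open, gap_extend)
            )
    return out


@dataclass
class SimilarityNetwork:
    """Sequences as nodes; edges where the pair E-value passes the cutoff."""

    graph: nx.Graph
    threshold: float
    pair_scores: list[PairScore]

    def at_threshold(self, threshold: float) -> "SimilarityNetwork":
        """Re-threshold without re-aligning."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes(data=True))
        for ps in self.pair_scores:
            if ps.evalue <= threshold:
                g.add_edge(ps.id_a, ps.id_b, pair=ps)
        return SimilarityNetwork(graph=g, threshold=threshold,
                                 pair_scores=self.pair_scores)


def build_network(
    seqs: Mapping[str, str],
    annotations: Mapping[str, Mapping[str, str]] | None = None,
    threshold: float = 1e-10,
    pair_scores: list[PairScore] | None = None,
) -> SimilarityNetwork:
    """Build the E-value-thresholded similarity network.

    ``annotations`` maps sequence id → {'channel': ..., 'ec': ...}; missing
    ids get channel ``unknown``. Precomputed ``pair_scores`` may be supplied
    to avoid re-aligning.
    """
    ids = list(seqs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    if pair_scores is None:
        pair_scores = all_pairs(seqs)
    g = nx.Graph()
    annotations = annotations or {}
    for sid in sorted(ids):
        ann = annotations.get(sid, {})
        g.add_node(sid, channel=ann.get("channel", "unknown"), ec=ann.get("ec", ""))
    for ps in pair_scores:
        if ps.id_a == ps.id_b:
            continue
        if ps.evalue <= threshold:
            g.add_edge(ps.id_a, ps.id_b, pair=ps)
    return SimilarityNetwork(graph=g, threshold=threshold, pair_scores=pair_scores)


def components(net: SimilarityNetwork) -> list[set[str]]:
    """Connected components, largest first; ties by smallest member id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def quartile_table(
    pair_scores: Sequence[PairScore], evalue_grid: Sequence[float]
) -> pd.DataFrame:
    """Identity / alignment-length quartiles and edge counts per E cutoff.

    For each cutoff, summaries run over the pairs with E ≤ cutoff; cutoffs
    retaining no pairs yield NaN quartiles and edge count 0.
    """
    if not pair_scores:
        raise ValueError("empty pair set")
    rows = []
    for cutoff in evalue_grid:
        kept = [p for p in pair_scores if p.evalue <= cutoff]
        ident = np.asarray([p.identity for p in kept])
        alen = np.asarray([p.alignment_length for p in kept])
        row = {"evalue_cutoff": cutoff, "n_edges": len(kept)}
        for label, arr in (("identity", ident), ("alignment_length", alen)):
            for q, name in ((25, "q1"), (50, "median"), (75, "q3")):
                row[f"{label}_{name}"] = (
                    float(np.percentile(arr, q)) if len(arr) else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)


def segregation_purity(net: SimilarityNetwork, label: str = "channel") -> dict:
    """Majority-label fraction per component and globally.

    Nodes labeled ``unknown`` (uncharacterized, the grey nodes) are excluded.
    Global purity is the labeled-node-weighted mean of per-component majority
    fractions; components with no labeled node are skipped.
    """
    per_component = []
    weighted = 0.0
    labeled_total = 0
    for comp in components(net):
        labels = [
            net.graph.nodes[n].get(label, "unknown")
            for n in comp
            if net.graph.nodes[n].get(label, "unknown") != "unknown"
        ]
        if not labels:
            per_component.append(
                {"nodes": len(comp), "labeled": 0, "majority_label": None,
                 "purity": None}
            )
            continue
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        majority = max(sorted(counts), key=lambda k: counts[k])
        purity = counts[majority] / len(labels)
        per_component.append(
            {"nodes": len(comp), "labeled": len(labels),
             "majority_label": majority, "purity": purity}
        )
        weighted += purity * len(labels)
        labeled_total += len(labels)
    return {
        "components": per_component,
        "global_purity": weighted / labeled_total if labeled_total else None,
        "labeled_nodes": labeled_total,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines fine) → id → sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    lines = []
    for sid in seqs:
        lines.append(f">{sid}")
        s = seqs[sid]
        lines.extend(s[i:i + width] for i in range(0, len(s), width))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """Annotation TSV: id, channel, EC list (semicolon-separated, optional)."""
    out: dict[str, dict[str, str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(
                f"{path}:{lineno}: expected at least 'id<TAB>channel'"
            )
        out[parts[0]] = {
            "channel": parts[1],
            "ec": parts[2] if len(parts) > 2 else "",
        }
    return out


def write_edge_list(net: SimilarityNetwork, path: str | Path) -> None:
    """Simple TSV edge list: id_a, id_b, E-value, percent identity."""
    lines = ["#id_a\tid_b\tevalue\tidentity"]
    for a, b, data in sorted(net.graph.edges(data=True)):
        ps: PairScore = data["pair"]
        lines.append(f"{a}\t{b}\t{ps.evalue:.6e}\t{ps.identity:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xgmml(net: SimilarityNetwork, path: str | Path, name: str = "ssn") -> None:
    """XGMML-style XML readable by standard graph viewers."""
    from xml.sax.saxutils import quoteattr

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<graph label={quoteattr(name)} directed="0" '
        'xmlns="http://www.cs.rpi.edu/XGMML">',
    ]
    ids = {n: i for i, n in enumerate(sorted(net.graph.nodes))}
    for n in sorted(net.graph.nodes):
        attrs = net.graph.nodes[n]
        lines.append(f'  <node id="{ids[n]}" label={quoteattr(n)}>')
        lines.append(
            f'    <att name="channel" type="string" '
            f'value={quoteattr(attrs.get("channel", "unknown"))}/>'
        )
        lines.append("  </node>")
    for a, b, data in sorted(net.graph.edges(data=True)):
        ps: PairScore = data["pair"]
        lines.append(
            f'  <edge source="{ids[a]}" target="{ids[b]}" '
            f'label={quoteattr(f"{a}-{b}")}>'
        )
        lines.append(
            f'    <att name="evalue" type="real" value="{ps.evalue:.6e}"/>'
        )
        lines.append("  </edge>")
    lines.append("</graph>")
    Path(path).write_text("\n".join(lines) + "\n")
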