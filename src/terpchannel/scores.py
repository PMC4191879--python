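"""Docking-score tables: ingestion, validation and the failed-docking state.

Scores are MM/GBSA-style binding-energy estimates in kcal/mol; more negative
means a better-stabilized carbocation. An intermediate for which no docking
pose satisfying the constraints exists is recorded as the distinct state
``NO_POSE`` — never as a numeric sentinel. Sentinel numbers (+100 or −10
kcal/mol) exist only as *display* conventions for plotting and never enter
ranking arithmetic.

Tables are either *absolute* (raw scores) or *relative* (mutant − wild-type
differences); the mode is carried in the table metadata and mixing modes in
one comparison is an error.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .channels import ChannelLibrary

__all__ = [
    "NO_POSE",
    "ScoreStatus",
    "ScoreTable",
    "read_scores_csv",
    "write_scores_csv",
    "display_score",
    "score_sort_key",
]

logger = logging.getLogger(__name__)

#: Token used for failed dockings in the CSV dialect.
NP_TOKEN = "NP"


@dataclass(frozen=True)
class ScoreStatus:
    """Either a finite energy in kcal/mol or the failed-docking state."""

    value: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError(f"score must be finite, got {self.value}")

    @property
    def is_no_pose(self) -> bool:
        return self.value is None

    def __repr__(self) -> str:
        return "NO_POSE" if self.is_no_pose else f"ScoreStatus({self.value})"


#: The failed-docking singleton state.
NO_POSE = ScoreStatus(None)


def score_sort_key(status: ScoreStatus) -> tuple[int, float]:
    """Sort key ordering numeric scores ascending with NO_POSE strictly last.

    NO_POSE is ordered strictly worse than any numeric score; no sentinel
    number ever enters a comparison.
    """
    if status.is_no_pose:
        return (1, 0.0)
    return (0, status.value)


def display_score(status: ScoreStatus, convention: str = "plus100") -> float:
    """Numeric value for plotting; NO_POSE maps to the chosen sentinel.

    ``plus100`` places failed dockings at +100 kcal/mol (score-profile plots
    where up is unfavorable); ``minus10`` places them at −10 kcal/mol
    (profiles where the numeric scores are all far below −10). Display only —
    ranking never consumes these numbers.
    """
    if not status.is_no_pose:
        return float(status.value)
    if convention == "plus100":
        return 100.0
    if convention == "minus10":
        return -10.0
    raise ValueError(f"unknown display convention {convention!r}")


@dataclass
class ScoreTable:
    """(enzyme, intermediate) → ScoreStatus with provenance metadata.

    ``metadata['mode']`` is ``'absolute'`` or ``'relative'`` (relative to a
    wild-type reference, as in mutant comparisons).
    """

    enzymes: list[str] = field(default_factory=list)
    entries: dict[tuple[str, str], ScoreStatus] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("mode", "absolute")
        self.metadata.setdefault("units", "kcal/mol")

    @property
    def mode(self) -> str:
        return self.metadata["mode"]

    def add(self, enzyme: str, intermediate: str, status: ScoreStatus) -> None:
        key = (enzyme, intermediate)
        if key in self.entries:
            raise ValueError(f"duplicate entry for {key}")
        if enzyme not in self.enzymes:
            self.enzymes.append(enzyme)
        self.entries[key] = status

    def get(self, enzyme: str, intermediate: str) -> ScoreStatus | None:
        return self.entries.get((enzyme, intermediate))

    def require(self, enzyme: str, intermediate: str) -> ScoreStatus:
        status = self.get(enzyme, intermediate)
        if status is None:
            raise KeyError(
                f"no score entry for enzyme {enzyme!r}, intermediate "
                f"{intermediate!r}"
            )
        return status

    def intermediates_for(self, enzyme: str) -> list[str]:
        return [i for (e, i) in self.entries if e == enzyme]

    def __len__(self) -> int:
        return len(self.entries)


def read_scores_csv(
    path: str | Path,
    library: ChannelLibrary,
    mode: str = "absolute",
) -> ScoreTable:
    """Read a scores CSV (header ``enzyme,intermediate,score``).

    ``score`` is a number in kcal/mol or the token ``NP`` for a failed
    docking. Unknown intermediate ids and unparsable scores are hard errors
    reported with their row number.
    """
    path = Path(path)
    known = library.intermediate_ids()
    table = ScoreTable(metadata={"mode": mode, "source": str(path)})
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            logger.warning("scores file %s is empty", path)
            return table
        if [h.strip().lower() for h in header[:3]] != ["enzyme", "intermediate", "score"]:
            raise ValueError(
                f"{path}:1: expected header 'enzyme,intermediate,score', "
                f"got {','.join(header)!r}"
            )
        nrows = 0
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{rownum}: expected 3 columns, got {len(row)}")
            enzyme, inter, score = (c.strip() for c in row[:3])
            if inter not in known:
                raise ValueError(
                    f"{path}:{rownum}: unknown intermediate id {inter!r}"
                )
            if score.upper() == NP_TOKEN:
                status = NO_POSE
            else:
                try:
                    status = ScoreStatus(float(score))
                except ValueError:
                    raise ValueError(
                        f"{path}:{rownum}: score {score!r} is neither numeric "
                        f"nor '{NP_TOKEN}'"
                    ) from None
            table.add(enzyme, inter, status)
            nrows += 1
        if nrows == 0:
            logger.warning("scores file %s contains no data rows", path)
    return table


def write_scores_csv(table: ScoreTable, path: str | Path) -> None:
    """Write the same CSV dialect read by :func:`read_scores_csv` (bit-exact)."""
    lines = ["enzyme,intermediate,score"]
    for (enzyme, inter), status in table.entries.items():
        # str() is the shortest representation that round-trips exactly
        token = NP_TOKEN if status.is_no_pose else str(status.value)
        lines.append(f"{enzyme},{inter},{token}")
    Path(path).write_text("\n".join(lines) + "\n")


def table_from_entries(
    entries: Iterable[tuple[str, str, ScoreStatus | float | None]],
    mode: str = "absolute",
    metadata: Mapping[str, str] | None = None,
) -> ScoreTable:
    """Build a table from (enzyme, intermediate, score) triples.

    Floats are wrapped; ``None`` means NO_POSE.
    """
    meta = {"mode": mode}
    if metadata:
        meta.update(metadata)
    table = ScoreTable(metadata=meta)
    for enzyme, inter, score in entries:
        if isinstance(score, ScoreStatus):
            status = score
        elif score is None:
            status = NO_POSE
        else:
            status = ScoreStatus(float(score))
        table.add(enzyme, inter, status)
    return table
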