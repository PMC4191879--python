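"""Reaction-channel model for triterpenoid synthases.

A *reaction channel* is an ordered series of carbocationic intermediates
leading from the cyclization substrate (squalene or 2,3-oxidosqualene) to a
family of products sharing a carbon skeleton:

* Channel A — the hopene channel (squalene, all-chair fold; four
  intermediates, terminating in the hopanyl cation A-I4);
* Channel B — the lupeol/dammarenyl channel (chair-boat fold; I1/I2 are
  mandatory, further intermediates may be added via the channel file);
* Channel C — the lanosterol/protosteryl channel (oxidosqualene,
  chair-boat-chair fold; nine intermediates, C-I6 through C-I9 being the
  precursors of lanosterol, parkeol, cycloartenol and cucurbitadienol);
* Channel D — a sesquarterpenoid (C35) channel, represented but excluded
  from ranking by default.

Each intermediate may quench (by deprotonation or hydration) to one or more
products; the library maintains a product index mapping each product name to
its unique precursor cation and EC number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Intermediate",
    "ReactionChannel",
    "ChannelLibrary",
    "default_library",
    "downstream",
    "read_channel_file",
    "write_channel_file",
]


class ChannelError(ValueError):
    """Raised for malformed channel definitions or unknown lookups."""


@dataclass(frozen=True)
class Intermediate:
    """One carbocationic intermediate along a reaction channel.

    Parameters
    ----------
    id : str
        Label of the form ``"<channel>-I<index>"``, e.g. ``"C-I6"``.
    channel : str
        Channel label (``A``–``D``).
    index : int
        1-based position along the channel.
    representative : int
        Rank used in hierarchical channel ranking: 1 for the first
        representative (the 6,6-bicyclic I1), 2 for the second (the
        6,6,6,5-tetracyclic I2), 0 otherwise.
    products : tuple of (name, ec)
        Products this cation can quench to; ``ec`` may be empty.
    conformer_note : str
        Free-text conformational annotation (e.g. "chair-boat-chair").
    chemical_id : str
        Chemical identity shared across channels: A-I1 and B-I1 are the same
        cation in different conformations and share a chemical id.
    """

    id: str
    channel: str
    index: int
    representative: int = 0
    products: tuple[tuple[str, str], ...] = ()
    conformer_note: str = ""
    chemical_id: str = ""

    def __post_init__(self) -> None:
        expected = f"{self.channel}-I{self.index}"
        if self.id != expected:
            raise ChannelError(
                f"intermediate id {self.id!r} does not parse as {expected!r}"
            )
        if self.index < 1:
            raise ChannelError(f"index must be >= 1, got {self.index}")
        if self.representative not in (0, 1, 2):
            raise ChannelError(
                f"representative rank must be 0, 1 or 2, got {self.representative}"
            )


@dataclass(frozen=True)
class ReactionChannel:
    """An ordered reaction channel with its intermediates."""

    id: str
    intermediates: tuple[Intermediate, ...]
    enabled: bool = True

    def __post_init__(self) -> None:
        indices = [i.index for i in self.intermediates]
        if indices != list(range(1, len(indices) + 1)):
            raise ChannelError(
                f"channel {self.id}: intermediates must be strictly ordered "
                f"1..n with no gaps, got indices {indices}"
            )
        for inter in self.intermediates:
            if inter.channel != self.id:
                raise ChannelError(
                    f"intermediate {inter.id} filed under channel {self.id}"
                )
        for rank in (1, 2):
            n = sum(1 for i in self.intermediates if i.representative == rank)
            if n != 1:
                raise ChannelError(
                    f"channel {self.id}: representative rank {rank} occurs "
                    f"{n} times (expected exactly once)"
                )

    def representative(self, rank: int) -> Intermediate:
        """Return the rank-1 or rank-2 representative intermediate."""
        for inter in self.intermediates:
            if inter.representative == rank:
                return inter
        raise ChannelError(f"channel {self.id} has no rank-{rank} representative")

    def __len__(self) -> int:
        return len(self.intermediates)


@dataclass(frozen=True)
class ChannelLibrary:
    """A collection of reaction channels with a total product index."""

    channels: Mapping[str, ReactionChannel]
    product_index: Mapping[str, tuple[str, str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        index: dict[str, tuple[str, str, str]] = {}
        for chan in self.channels.values():
            for inter in chan.intermediates:
                for name, ec in inter.products:
                    if name in index:
                        raise ChannelError(
                            f"product {name!r} listed under both "
                            f"{index[name][1]} and {inter.id}"
                        )
                    index[name] = (chan.id, inter.id, ec)
        object.__setattr__(self, "product_index", index)

    def channel(self, channel_id: str) -> ReactionChannel:
        try:
            return self.channels[channel_id]
        except KeyError:
            raise ChannelError(f"unknown channel id {channel_id!r}") from None

    def intermediate(self, inter_id: str) -> Intermediate:
        chan_id = inter_id.split("-", 1)[0]
        chan = self.channel(chan_id)
        for inter in chan.intermediates:
            if inter.id == inter_id:
                return inter
        raise ChannelError(f"unknown intermediate id {inter_id!r}")

    def enabled_channels(self) -> list[ReactionChannel]:
        """Channels participating in ranking, in library (alphabetical) order."""
        return [c for _, c in sorted(self.channels.items()) if c.enabled]

    def intermediate_ids(self) -> set[str]:
        return {i.id for c in self.channels.values() for i in c.intermediates}

    def with_channel_enabled(self, channel_id: str, enabled: bool = True) -> "ChannelLibrary":
        """Return a copy with one channel's enabled flag changed."""
        chan = self.channel(channel_id)
        channels = dict(self.channels)
        channels[channel_id] = replace(chan, enabled=enabled)
        return ChannelLibrary(channels=channels)


def downstream(lib: ChannelLibrary, inter: Intermediate | str) -> list[Intermediate]:
    """Intermediates of the same channel strictly after *inter*, in order."""
    if isinstance(inter, str):
        inter = lib.intermediate(inter)
    else:
        lib.intermediate(inter.id)  # totality check
    chan = lib.channel(inter.channel)
    return [i for i in chan.intermediates if i.index > inter.index]


# ---------------------------------------------------------------------------
# Channel definition file (plain TSV; see data/channels.tsv for the format)
# ---------------------------------------------------------------------------

_COLUMNS = ("id", "channel", "index", "rep", "chemical_id", "conformer_note", "products")


def _parse_products(token: str) -> tuple[tuple[str, str], ...]:
    if token == "-" or not token:
        return ()
    out = []
    for entry in token.split(";"):
        if "|" not in entry:
            raise ChannelError(f"product entry {entry!r} must be 'name|EC'")
        name, ec = entry.split("|", 1)
        out.append((name, ec))
    return tuple(out)


def _format_products(products: Iterable[tuple[str, str]]) -> str:
    entries = [f"{name}|{ec}" for name, ec in products]
    return ";".join(entries) if entries else "-"


def read_channel_file(path: str | Path) -> ChannelLibrary:
    """Read a channel definition file (tab-separated, '#' comments)."""
    disabled: set[str] = set()
    by_channel: dict[str, list[Intermediate]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("!channel"):
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("disabled", "enabled"):
                raise ChannelError(
                    f"{path}:{lineno}: malformed channel directive {line!r}"
                )
            if parts[2] == "disabled":
                disabled.add(parts[1])
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ChannelError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} tab-separated "
                f"fields, got {len(parts)}"
            )
        rec = dict(zip(_COLUMNS, parts))
        try:
            inter = Intermediate(
                id=rec["id"],
                channel=rec["channel"],
                index=int(rec["index"]),
                representative=int(rec["rep"]),
                chemical_id=rec["chemical_id"],
                conformer_note=rec["conformer_note"],
                products=_parse_products(rec["products"]),
            )
        except (ValueError, ChannelError) as exc:
            raise ChannelError(f"{path}:{lineno}: {exc}") from None
        by_channel.setdefault(rec["channel"], []).append(inter)
    channels = {
        cid: ReactionChannel(
            id=cid,
            intermediates=tuple(sorted(inters, key=lambda i: i.index)),
            enabled=cid not in disabled,
        )
        for cid, inters in by_channel.items()
    }
    return ChannelLibrary(channels=channels)


def write_channel_file(lib: ChannelLibrary, path: str | Path) -> None:
    """Write a library back to the channel definition format (round-trips)."""
    lines = ["# terpchannel reaction-channel library"]
    lines.append("# columns: " + "\t".join(_COLUMNS))
    for cid in sorted(lib.channels):
        if not lib.channels[cid].enabled:
            lines.append(f"!channel\t{cid}\tdisabled")
    for cid in sorted(lib.channels):
        for inter in lib.channels[cid].intermediates:
            lines.append(
                "\t".join(
                    [
                        inter.id,
                        inter.channel,
                        str(inter.index),
                        str(inter.representative),
                        inter.chemical_id,
                        inter.conformer_note,
                        _format_products(inter.products),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def default_library() -> ChannelLibrary:
    """The default A/B/C/D triterpenoid channel library.

    Channels A (I1–I4, hopene), B (I1–I2, lupeol/dammarenyl), C (I1–I9,
    lanosterol/protosteryl) are enabled; the sesquarterpenoid channel D is
    present but disabled.
    """
    with resources.as_file(
        resources.files("terpchannel.data").joinpath("channels.tsv")
    ) as p:
        return read_channel_file(p)
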