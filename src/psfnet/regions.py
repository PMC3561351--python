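"""Anatomical region label table (116-region AAL parcellation).

The bundled table lists the 90 cerebral and 26 cerebellar/vermal regions
used to extract regional time series. Divisions are assigned from the
region name: ``Cerebelum*`` -> cerebellum, ``Vermis*`` -> vermis,
everything else -> cerebrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = ["Region", "RegionTable", "load_region_table", "region_lookup"]

_DIVISIONS = ("cerebrum", "cerebellum", "vermis")
_N_REGIONS = 116
_N_CEREBRUM = 90


@dataclass(frozen=True)
class Region:
    """One row of the anatomical label table."""

    index: int
    name: str
    abbreviation: str
    division: str


class RegionTable:
    """Ordered, validated collection of the 116 anatomical regions."""

    def __init__(self, entries: list[Region]):
        self.entries = list(entries)
        self._validate()
        self._by_index = {e.index: e for e in self.entries}
        self._by_abbrev: dict[str, list[Region]] = {}
        for e in self.entries:
            self._by_abbrev.setdefault(e.abbreviation, []).append(e)

    def _validate(self) -> None:
        n = len(self.entries)
        if n != _N_REGIONS:
            raise ValueError(f"expected {_N_REGIONS} regions, got {n}")
        indices = [e.index for e in self.entries]
        if sorted(indices) != list(range(1, _N_REGIONS + 1)):
            raise ValueError("region indices must be exactly 1..116, each once")
        for e in self.entries:
            if e.division not in _DIVISIONS:
                raise ValueError(f"region {e.index}: bad division {e.division!r}")
            if not e.abbreviation:
                raise ValueError(f"region {e.index}: empty abbreviation")
        n_cerebrum = sum(e.division == "cerebrum" for e in self.entries)
        if n_cerebrum != _N_CEREBRUM:
            raise ValueError(
                f"expected {_N_CEREBRUM} cerebral regions, got {n_cerebrum}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionTable) and self.entries == other.entries

    def lookup(self, key: int | str) -> list[Region]:
        """All entries matching an integer index or an abbreviation string."""
        if isinstance(key, int):
            e = self._by_index.get(key)
            return [e] if e is not None else []
        return list(self._by_abbrev.get(key, []))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("index\tname\tabbreviation\tdivision\n")
            for e in self.entries:
                fh.write(f"{e.index}\t{e.name}\t{e.abbreviation}\t{e.division}\n")


def _parse_tsv(lines: list[str], source: str) -> RegionTable:
    if not lines:
        raise ValueError(f"{source}: empty region table")
    header = lines[0].rstrip("\n").split("\t")
    if header != ["index", "name", "abbreviation", "division"]:
        raise ValueError(f"{source}: row 1: unexpected header {header!r}")
    entries = []
    for row_no, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{source}: row {row_no}: expected 4 fields, got {len(fields)}")
        try:
            index = int(fields[0])
        except ValueError as exc:
            raise ValueError(f"{source}: row {row_no}: bad index {fields[0]!r}") from exc
        entries.append(Region(index, fields[1], fields[2], fields[3]))
    return RegionTable(entries)


def load_region_table(path: str | Path | None = None) -> RegionTable:
    """Load the region table; defaults to the bundled 116-region file."""
    if path is None:
        ref = resources.files("psfnet.data").joinpath("aal116.tsv")
        text = ref.read_text(encoding="utf-8")
        return _parse_tsv(text.splitlines(), "bundled aal116.tsv")
    with open(path, encoding="utf-8") as fh:
        return _parse_tsv(fh.read().splitlines(), str(path))


def region_lookup(table: RegionTable, key: int | str) -> list[Region]:
    """Entries of ``table`` matching ``key``; empty list when nothing matches."""
    return table.lookup(key)
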