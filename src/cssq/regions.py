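"""Genomic region containers and BED input.

Regions define the rows of every downstream matrix; their order is fixed at
load time and preserved bytewise through counting, transformation and testing.
Coordinates are BED-style: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence


class BedParseError(ValueError):
    """A BED line could not be parsed; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """One genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based inclusive start, exclusive end; ``end > start``.
    name : str or None
        Optional region identifier (BED column 4).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        """Name if present, else ``chrom:start-end``."""
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RegionSet:
    """Ordered collection of regions; order is stable across all matrices."""

    regions: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions if r.name is not None]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique when present")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, key: int | str) -> GenomicRegion:
        if isinstance(key, str):
            for r in self.regions:
                if r.name == key:
                    return r
            raise KeyError(key)
        return self.regions[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]


def read_bed(path: str) -> RegionSet:
    """Read a BED (>=3 column, tab-separated) file into a :class:`RegionSet`.

    File order is preserved; coordinates are kept 0-based half-open as in the
    file. Track/browser/comment lines are skipped.

    Raises
    ------
    BedParseError
        On a malformed line (too few columns, non-integer coordinates or
        ``end <= start``), naming the 1-based line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields: Sequence[str] = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            try:
                regions.append(GenomicRegion(chrom, start, end, name))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return RegionSet(regions)
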