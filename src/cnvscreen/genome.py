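"""Reference genome model: chromosome inventory and fixed-width bin tiling.

Coordinates are 0-based, half-open throughout.  A :class:`BinGrid` tiles each
chromosome of a :class:`GenomeIndex` into consecutive ``bin_size`` windows;
the final window of each chromosome is truncated to the chromosome end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATEGORY_RULES",
    "ChromRecord",
    "GenomeIndex",
    "Bin",
    "BinGrid",
    "classify_chrom_name",
    "load_genome_index",
    "make_bins",
]

CATEGORIES = ("autosome", "X", "Y", "other")

#: Default name-classification rules: ordered (category, regex) pairs; the
#: first matching regex wins, anything unmatched is an autosome.
DEFAULT_CATEGORY_RULES: tuple[tuple[str, str], ...] = (
    ("X", r"(?i)^(chr)?x$"),
    ("Y", r"(?i)^(chr)?y([._\-].*)?$"),
)


def classify_chrom_name(
    name: str, rules: Sequence[tuple[str, str]] = DEFAULT_CATEGORY_RULES
) -> str:
    """Assign a chromosome category from its name via the first matching rule."""
    for category, pattern in rules:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        if re.match(pattern, name.strip()):
            return category
    return "autosome"


@dataclass(frozen=True)
class ChromRecord:
    """One reference sequence: name, length in bp, and allosome category."""

    name: str
    length: int
    category: str = "autosome"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be nonempty")
        if not isinstance(self.length, (int, np.integer)) or self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be a positive integer")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"chromosome {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )


class GenomeIndex:
    """Ordered chromosome inventory; order defines the global bin ordering."""

    def __init__(self, chroms: Iterable[ChromRecord]) -> None:
        self.chroms: list[ChromRecord] = list(chroms)
        seen: dict[str, int] = {}
        for rec in self.chroms:
            if rec.name in seen:
                raise ValueError(f"duplicate chromosome {rec.name!r}")
            seen[rec.name] = 1
        self._by_name = {rec.name: rec for rec in self.chroms}

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[ChromRecord]:
        return iter(self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ChromRecord:
        return self._by_name[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return self.chroms == other.chroms

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.chroms]

    @property
    def total_length(self) -> int:
        return sum(rec.length for rec in self.chroms)

    def by_category(self, category: str) -> list[ChromRecord]:
        return [rec for rec in self.chroms if rec.category == category]

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self.chroms)} chromosomes, {self.total_length:,} bp)"


def load_genome_index(
    path: str | Path,
    category_rules: Sequence[tuple[str, str]] = DEFAULT_CATEGORY_RULES,
) -> GenomeIndex:
    """Load chromosome names and lengths from a ``.fai`` or chrom-sizes file.

    Both formats are tab/whitespace separated with the sequence name in
    column 1 and its length in column 2 (a ``.fai`` simply carries extra
    columns, which are ignored).  Categories are assigned by
    ``category_rules`` (see :func:`classify_chrom_name`).
    """
    path = Path(path)
    records: list[ChromRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}")
            name = fields[0].strip()
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: length {fields[1]!r} is not an integer") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: length must be > 0, got {length}")
            records.append(ChromRecord(name, length, classify_chrom_name(name, category_rules)))
    if not records:
        raise ValueError(f"{path}: no chromosome records found")
    return GenomeIndex(records)


@dataclass(frozen=True)
class Bin:
    """A fixed-width genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    global_index: int

    @property
    def width(self) -> int:
        return self.end - self.start


class BinGrid:
    """Tiling of every chromosome of a genome into fixed-width bins.

    Within each chromosome the bins cover ``[0, length)`` without gaps or
    overlaps; every bin except possibly the last has width ``bin_size``.
    Bin metadata is held in parallel numpy arrays for fast vectorised use.
    """

    def __init__(self, index: GenomeIndex, bin_size: int) -> None:
        if bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {bin_size}")
        self.index = index
        self.bin_size = int(bin_size)

        chrom_ids: list[int] = []
        starts: list[int] = []
        ends: list[int] = []
        offsets: dict[str, tuple[int, int]] = {}  # name -> (first global index, n bins)
        g = 0
        for ci, rec in enumerate(index):
            n = -(-rec.length // bin_size)  # ceil division
            offsets[rec.name] = (g, n)
            for b in range(n):
                s = b * bin_size
                chrom_ids.append(ci)
                starts.append(s)
                ends.append(min(s + bin_size, rec.length))
            g += n
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int64)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self._offsets = offsets
        cat = {"autosome": 0, "X": 1, "Y": 2, "other": 3}
        self.category_codes = np.asarray(
            [cat[index.chroms[ci].category] for ci in chrom_ids], dtype=np.int8
        )

    # -- basic properties ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_bins

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def is_autosomal(self) -> np.ndarray:
        return self.category_codes == 0

    @property
    def is_x(self) -> np.ndarray:
        return self.category_codes == 1

    @property
    def is_y(self) -> np.ndarray:
        return self.category_codes == 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return self.bin_size == other.bin_size and self.index == other.index

    def __repr__(self) -> str:
        return f"BinGrid({self.n_bins} bins of {self.bin_size:,} bp over {len(self.index)} chromosomes)"

    # -- lookup -------------------------------------------------------------

    def bin(self, global_index: int) -> Bin:
        ci = int(self.chrom_ids[global_index])
        return Bin(
            chrom=self.index.chroms[ci].name,
            start=int(self.starts[global_index]),
            end=int(self.ends[global_index]),
            global_index=int(global_index),
        )

    def __iter__(self) -> Iterator[Bin]:
        for g in range(self.n_bins):
            yield self.bin(g)

    def chrom_offset(self, name: str) -> tuple[int, int]:
        """Return (first global bin index, number of bins) for a chromosome."""
        return self._offsets[name]

    def chrom_slice(self, name: str) -> slice:
        first, n = self._offsets[name]
        return slice(first, first + n)

    def bin_index(self, chrom: str, pos0: int) -> int:
        """Global index of the bin containing 0-based position ``pos0``."""
        if chrom not in self._offsets:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        length = self.index[chrom].length
        if not 0 <= pos0 < length:
            raise ValueError(f"position {pos0} out of range [0, {length}) on {chrom!r}")
        first, _ = self._offsets[chrom]
        return first + pos0 // self.bin_size

    # -- masking ------------------------------------------------------------

    def default_mask(self, mask_y: bool = True, min_width_frac: float = 0.25) -> np.ndarray:
        """Boolean mask (True = excluded) for bins unsuitable for copy-number work.

        Masks Y-category bins (fragmented, repeat-rich scaffolds violate the
        uniform-depth model) and truncated terminal bins narrower than
        ``min_width_frac`` of the bin size, whose counts are disproportionately
        noisy.
        """
        mask = self.widths < min_width_frac * self.bin_size
        if mask_y:
            mask = mask | self.is_y
        return mask

    def to_dataframe(self):
        import pandas as pd

        names = np.asarray(self.index.names, dtype=object)
        return pd.DataFrame(
            {
                "chrom": names[self.chrom_ids],
                "start": self.starts,
                "end": self.ends,
            }
        )


def make_bins(index: GenomeIndex, bin_size: int = 1_000_000) -> BinGrid:
    """Tile every chromosome into consecutive ``bin_size`` windows."""
    return BinGrid(index, bin_size)
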