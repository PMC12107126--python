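"""Per-bin read counting from SAM/BAM alignments.

Alignments are filtered with the SAM flag mask 2308 (unmapped 0x4,
secondary 0x100, supplementary 0x800), keeping one primary record per
mapped read, and each surviving record is assigned to the single bin
containing its 0-based leftmost mapped position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .genome import BinGrid

__all__ = ["FLAG_MASK", "BinCounts", "passes_filter", "assign_bin", "count_reads", "UNKNOWN_CHROM"]

logger = logging.getLogger(__name__)

#: samtools ``-F 2308``: unmapped (4) + secondary (256) + supplementary (2048).
FLAG_MASK = 2308

#: Sentinel returned by :func:`assign_bin` for reads on chromosomes absent
#: from the grid.
UNKNOWN_CHROM = "unknown-chromosome"

_META_KEYS = (
    "records_seen",
    "records_counted",
    "filtered_by_flag",
    "filtered_by_mapq",
    "skipped_unknown_chrom",
)


@dataclass
class BinCounts:
    """Per-bin primary-alignment counts for one sample, plus filter tallies."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match grid ({self.grid.n_bins} bins)"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def validate_meta(self) -> None:
        """Check the conservation invariants of the filter tallies."""
        m = self.meta
        if int(self.counts.sum()) != m["records_counted"]:
            raise ValueError("sum of counts does not equal records_counted")
        accounted = (
            m["records_counted"]
            + m["filtered_by_flag"]
            + m["filtered_by_mapq"]
            + m["skipped_unknown_chrom"]
        )
        if m["records_seen"] != accounted:
            raise ValueError("records_seen does not equal counted + filtered + skipped")


def passes_filter(flag: int, mapq: int, min_mapq: int = 0) -> bool:
    """True iff a record is a mapped primary alignment with sufficient MAPQ.

    Equivalent to ``samtools view -F 2308 -q min_mapq``; duplicate-marked
    reads (flag 1024) pass because 1024 is not in the mask.
    """
    if flag < 0:
        raise ValueError(f"SAM flag must be >= 0, got {flag}")
    return (flag & FLAG_MASK) == 0 and mapq >= min_mapq


def assign_bin(chrom: str, pos0: int, grid: BinGrid) -> int | str:
    """Global bin index for a filtered read, by leftmost mapped position.

    Returns the :data:`UNKNOWN_CHROM` sentinel when the reference sequence
    is not part of the grid.  A position at or beyond the chromosome end is
    a malformed alignment and raises.
    """
    try:
        return grid.bin_index(chrom, pos0)
    except KeyError:
        return UNKNOWN_CHROM


def _check_header(header: pysam.AlignmentHeader, grid: BinGrid) -> None:
    for sq in header.get("SQ", []):
        name = sq["SN"]
        if name in grid.index and int(sq["LN"]) != grid.index[name].length:
            raise ValueError(
                f"header length for {name!r} ({sq['LN']}) does not match grid "
                f"({grid.index[name].length})"
            )


def count_reads(
    alignments: str | Path,
    grid: BinGrid,
    min_mapq: int = 0,
    sample_id: str | None = None,
) -> BinCounts:
    """Count primary alignments per bin from a SAM (or BAM) file.

    Records failing the flag mask or MAPQ cutoff are tallied separately;
    records mapped to reference sequences absent from the grid are skipped
    with a warning.  Header sequence lengths must agree with the grid.
    """
    path = Path(alignments)
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    meta = dict.fromkeys(_META_KEYS, 0)

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        _check_header(af.header.to_dict(), grid)
        for rec in af.fetch(until_eof=True):
            meta["records_seen"] += 1
            flag = rec.flag
            if flag & FLAG_MASK:
                meta["filtered_by_flag"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                meta["filtered_by_mapq"] += 1
                continue
            chrom = rec.reference_name
            if chrom is None or chrom not in grid.index:
                meta["skipped_unknown_chrom"] += 1
                continue
            pos0 = rec.reference_start
            length = grid.index[chrom].length
            if pos0 >= length:
                raise ValueError(
                    f"{path}: read {rec.query_name!r} at {chrom}:{pos0} beyond "
                    f"chromosome end ({length}); malformed alignment"
                )
            counts[grid.bin_index(chrom, pos0)] += 1
            meta["records_counted"] += 1

    if meta["records_seen"] == 0:
        logger.warning("%s: alignment stream contained no records", path)
    if meta["skipped_unknown_chrom"]:
        logger.warning(
            "%s: %d records on chromosomes absent from the grid were skipped",
            path,
            meta["skipped_unknown_chrom"],
        )
    result = BinCounts(sample_id or path.stem, grid, counts, meta)
    result.validate_meta()
    return result
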