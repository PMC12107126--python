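"""Plain-text serialization of pipeline artifacts.

Counts and segments travel as TSV, copy-ratio tracks as bedGraph
(0-based half-open, masked bins omitted), calls as TSV plus BED4.  The
counts TSV enumerates every bin, so the bin grid can be reconstructed
from it without a separate chrom-sizes file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall, CallSet
from .counting import BinCounts
from .genome import BinGrid, ChromRecord, GenomeIndex, classify_chrom_name
from .ratio import CopyRatioTrack
from .segment import Segment, SegmentationResult

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_bedgraph",
    "read_bedgraph",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_calls_bed",
    "write_chrom_sizes",
]


def write_chrom_sizes(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in index:
            fh.write(f"{rec.name}\t{rec.length}\n")


def write_counts_tsv(counts: BinCounts, path: str | Path) -> None:
    """Write per-bin counts as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = counts.grid.to_dataframe()
    df["count"] = counts.counts
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "sample_id": counts.sample_id,
        "bin_size": counts.grid.bin_size,
        "meta": {k: int(v) for k, v in counts.meta.items()},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def _grid_from_bins(df: pd.DataFrame, bin_size: int) -> BinGrid:
    lengths = df.groupby("chrom", sort=False)["end"].max()
    index = GenomeIndex(
        ChromRecord(str(name), int(length), classify_chrom_name(str(name)))
        for name, length in lengths.items()
    )
    return BinGrid(index, bin_size)


def read_counts_tsv(path: str | Path) -> BinCounts:
    """Rebuild a BinCounts (grid included) from a counts TSV and its sidecar."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        bin_size = int(sidecar["bin_size"])
        sample_id = sidecar["sample_id"]
        meta = sidecar.get("meta", {})
    else:
        bin_size = int((df["end"] - df["start"]).max())
        sample_id = path.stem
        meta = {}
    grid = _grid_from_bins(df, bin_size)
    counts = df["count"].to_numpy(dtype=np.int64)
    expected = grid.to_dataframe()
    if not (
        expected["start"].to_numpy() == df["start"].to_numpy()
    ).all() or not (expected["chrom"].to_numpy() == df["chrom"].to_numpy()).all():
        raise ValueError(f"{path}: rows do not enumerate a complete bin tiling")
    return BinCounts(sample_id, grid, counts, meta)


def write_bedgraph(track: CopyRatioTrack, path: str | Path, precision: int = 6) -> None:
    """Write unmasked bins of a copy-ratio track as bedGraph."""
    grid = track.grid
    names = np.asarray(grid.index.names, dtype=object)
    with open(path, "w") as fh:
        for g in np.flatnonzero(track.unmasked):
            fh.write(
                f"{names[grid.chrom_ids[g]]}\t{grid.starts[g]}\t{grid.ends[g]}\t"
                f"{track.values[g]:.{precision}f}\n"
            )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


_SEG_COLS = ["chrom", "start", "end", "first_bin", "last_bin", "n_bins", "mean_log2", "split_pvalue"]


def segments_to_dataframe(result: SegmentationResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.first_bin, s.last_bin, s.n_bins, s.mean_value, s.split_pvalue)
            for s in result.segments
        ],
        columns=_SEG_COLS,
    )


def write_segments_tsv(result: SegmentationResult, path: str | Path) -> None:
    segments_to_dataframe(result).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_segments_tsv(path: str | Path, grid: BinGrid) -> SegmentationResult:
    df = pd.read_csv(path, sep="\t")
    result = SegmentationResult(grid)
    for row in df.itertuples(index=False):
        result.segments.append(
            Segment(
                chrom=str(row.chrom),
                first_bin=int(row.first_bin),
                last_bin=int(row.last_bin),
                n_bins=int(row.n_bins),
                start=int(row.start),
                end=int(row.end),
                mean_value=float(row.mean_log2),
                split_pvalue=float(row.split_pvalue),
            )
        )
    return result


def calls_to_dataframe(callset: CallSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.segment.chrom,
                c.segment.start,
                c.segment.end,
                c.segment.n_bins,
                c.segment.mean_value,
                c.state,
                c.whole_chromosome,
                callset.sample_id,
            )
            for c in callset.calls
        ],
        columns=["chrom", "start", "end", "n_bins", "mean_log2", "state", "whole_chromosome", "sample"],
    )


def write_calls_tsv(callsets: Sequence[CallSet], path: str | Path) -> None:
    pd.concat([calls_to_dataframe(cs) for cs in callsets], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_calls_tsv(path: str | Path, grid: BinGrid) -> dict[str, CallSet]:
    """Rebuild per-sample call sets from a calls TSV on a known grid."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CallSet] = {}
    for row in df.itertuples(index=False):
        first = grid.bin_index(str(row.chrom), int(row.start))
        last = grid.bin_index(str(row.chrom), int(row.end) - 1)
        seg = Segment(
            chrom=str(row.chrom),
            first_bin=first,
            last_bin=last,
            n_bins=last - first + 1,
            start=int(row.start),
            end=int(row.end),
            mean_value=float(row.mean_log2),
            split_pvalue=float("nan"),
        )
        cs = out.setdefault(str(row.sample), CallSet(grid, str(row.sample)))
        cs.calls.append(CnvCall(seg, str(row.state), bool(row.whole_chromosome)))
    return out


def write_calls_bed(calls: Sequence[CnvCall], path: str | Path, track_name: str = "cnv_calls") -> None:
    """BED4 of non-neutral calls; neutral segments are never written."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for c in calls:
            if c.state == "neutral":
                continue
            label = c.state + ("_whole_chrom" if c.whole_chromosome else "")
            fh.write(f"{c.segment.chrom}\t{c.segment.start}\t{c.segment.end}\t{label}\n")
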