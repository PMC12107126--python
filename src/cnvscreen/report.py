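"""Report rendering: tables, BED/bedGraph tracks, a mirrored ideogram
figure, and a plain-text summary of test-specific aberrations."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calls import CallSet, ComparisonReport, XPloidyReport
from .io import write_bedgraph, write_calls_bed, write_calls_tsv
from .ratio import CopyRatioTrack

__all__ = ["render_ideogram", "render_report", "write_summary"]


def render_ideogram(
    control: CopyRatioTrack,
    test: CopyRatioTrack,
    path: str | Path,
    control_label: str = "control",
    test_label: str = "test",
    vmin: float = -1.5,
    vmax: float = 1.5,
    cmap: str = "RdBu_r",
) -> None:
    """Mirrored per-chromosome ideogram: each chromosome is a vertical bar
    with the control track colour-coded on the left half and the test track
    on the right, on a shared log2 colour scale."""
    if control.grid != test.grid:
        raise ValueError("tracks are on different bin grids")
    grid = control.grid
    chroms = [rec for rec in grid.index if rec.category != "Y"]
    max_len = max(rec.length for rec in chroms)
    fig, ax = plt.subplots(figsize=(max(8, 0.45 * len(chroms)), 6))
    norm = plt.Normalize(vmin=vmin, vmax=vmax)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.85")
    for xi, rec in enumerate(chroms):
        sl = grid.chrom_slice(rec.name)
        col = np.column_stack(
            [np.ma.masked_invalid(control.values[sl]), np.ma.masked_invalid(test.values[sl])]
        )
        ax.imshow(
            col,
            extent=(xi - 0.35, xi + 0.35, rec.length / 1e6, 0),
            aspect="auto",
            cmap=cm,
            norm=norm,
            interpolation="nearest",
        )
    ax.set_xlim(-0.6, len(chroms) - 0.4)
    ax.set_ylim(max_len / 1e6 * 1.02, -2)
    ax.set_xticks(range(len(chroms)))
    ax.set_xticklabels([r.name.removeprefix("chr") for r in chroms], fontsize=7)
    ax.set_ylabel("position (Mb)")
    ax.set_xlabel("chromosome")
    ax.set_title(f"{control_label} (left half) vs {test_label} (right half)")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cm), ax=ax, label="log2 copy ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_summary(
    comparison: ComparisonReport,
    path: str | Path,
    x_ploidy: XPloidyReport | None = None,
) -> None:
    """Plain-text summary of test-specific aberrations.

    The X copy state is reported separately and never listed as an
    aberration: expected hemizygosity in a male sample is not an event.
    """
    lines = ["# Genomic integrity summary", ""]
    if x_ploidy is not None:
        lines.append(
            f"X ploidy: {x_ploidy.inferred_state} "
            f"(median X log2 = {x_ploidy.median_x_log2:.3f})"
        )
        lines.append("")
    if not comparison.test_specific_calls:
        lines.append("No aberrations detected: zero test-specific CNV calls.")
    else:
        lines.append(f"Test-specific aberrations ({len(comparison.test_specific_calls)}):")
        for c in comparison.test_specific_calls:
            s = c.segment
            scope = "whole-chromosome " if c.whole_chromosome else ""
            lines.append(
                f"  {scope}{c.state}\t{s.chrom}:{s.start}-{s.end}"
                f"\t{(s.end - s.start) / 1e6:.1f} Mb\tmean log2 {s.mean_value:+.3f}"
            )
    lines.append("")
    lines.append(
        f"Shared events: {len(comparison.shared_calls)}; "
        f"control-specific events: {len(comparison.control_specific_calls)} "
        f"(reciprocal overlap >= {comparison.overlap_rule})"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def render_report(
    tracks: dict[str, CopyRatioTrack],
    calls: dict[str, CallSet],
    comparison: ComparisonReport,
    out_dir: str | Path,
    control: str = "control",
    test: str = "test",
    x_ploidy: XPloidyReport | None = None,
    vmin: float = -1.5,
    vmax: float = 1.5,
) -> dict[str, Path]:
    """Write the full report bundle for a control/test pair.

    Produces a calls TSV, a BED of non-neutral calls, one bedGraph per
    sample, the mirrored ideogram figure, and a text summary; returns the
    paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["calls_tsv"] = out_dir / "calls.tsv"
    write_calls_tsv([calls[control], calls[test]], paths["calls_tsv"])

    paths["calls_bed"] = out_dir / "calls.bed"
    non_neutral = calls[control].non_neutral() + calls[test].non_neutral()
    write_calls_bed(non_neutral, paths["calls_bed"])

    for name, track in tracks.items():
        p = out_dir / f"{name}.bedgraph"
        write_bedgraph(track, p)
        paths[f"bedgraph_{name}"] = p

    paths["ideogram"] = out_dir / "ideogram.png"
    render_ideogram(
        tracks[control], tracks[test], paths["ideogram"],
        control_label=control, test_label=test, vmin=vmin, vmax=vmax,
    )

    paths["summary"] = out_dir / "summary.txt"
    write_summary(comparison, paths["summary"], x_ploidy=x_ploidy)
    return paths
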