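"""Log2 copy-ratio tracks from binned read counts.

Two modes: within-sample normalisation (each bin against the sample's
median autosomal bin count, so autosomes of a normal diploid sit at log2 0
and a single-copy X at about -1) and test-vs-control (the ratio of the two
within-sample normalised counts, so only differences between the samples
remain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counting import BinCounts
from .genome import BinGrid

__all__ = ["CopyRatioTrack", "normalize_counts", "relative_track"]


@dataclass
class CopyRatioTrack:
    """Per-bin log2 copy ratios; masked bins carry NaN."""

    grid: BinGrid
    values: np.ndarray
    norm_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values length does not match grid")

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.masked


def _resolve_mask(grid: BinGrid, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return grid.default_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.n_bins,):
        raise ValueError("mask length does not match grid")
    return mask


def _reference_median(counts: BinCounts, mask: np.ndarray) -> float:
    """Median count over unmasked autosomal bins (allosomes excluded so a
    male sample's X reads out near log2 -1 rather than shifting the baseline)."""
    sel = counts.grid.is_autosomal & ~mask
    if not sel.any() or not (counts.counts[sel] > 0).any():
        raise ValueError(f"sample {counts.sample_id!r} has no usable coverage")
    return float(np.median(counts.counts[sel]))


def normalize_counts(
    c: BinCounts,
    pseudocount: float = 0.5,
    mask: np.ndarray | None = None,
) -> CopyRatioTrack:
    """Within-sample log2 copy ratios: log2((count + p) / (R + p)).

    R is the median count over unmasked autosomal bins; the pseudocount
    keeps zero-count bins finite.  Masked bins (grid default: Y scaffolds
    and narrow terminal bins) carry no value.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mask = _resolve_mask(c.grid, mask)
    ref = _reference_median(c, mask)
    with np.errstate(divide="ignore"):
        values = np.log2((c.counts + pseudocount) / (ref + pseudocount))
    values[mask] = np.nan
    meta = {
        "mode": "within-sample",
        "sample_id": c.sample_id,
        "reference_statistic": ref,
        "pseudocount": pseudocount,
        "masked_bin_indices": np.flatnonzero(mask),
    }
    return CopyRatioTrack(c.grid, values, meta)


def relative_track(
    test: BinCounts,
    control: BinCounts,
    pseudocount: float = 0.5,
    mask: np.ndarray | None = None,
) -> CopyRatioTrack:
    """Test-vs-control log2 ratio of within-sample normalised counts.

    Shared copy-number structure (for instance the haploid X of a male
    line) cancels; only events private to one sample remain.  Bins masked
    in either input are masked in the output.
    """
    if test.grid != control.grid:
        raise ValueError("test and control counts are on different bin grids")
    t = normalize_counts(test, pseudocount=pseudocount, mask=mask)
    c = normalize_counts(control, pseudocount=pseudocount, mask=mask)
    values = t.values - c.values  # log2(t_norm / c_norm)
    meta = {
        "mode": "vs-control",
        "sample_id": f"{test.sample_id}_vs_{control.sample_id}",
        "reference_statistic": (
            t.norm_meta["reference_statistic"],
            c.norm_meta["reference_statistic"],
        ),
        "pseudocount": pseudocount,
        "masked_bin_indices": np.flatnonzero(np.isnan(values)),
    }
    return CopyRatioTrack(test.grid, values, meta)
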