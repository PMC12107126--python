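"""Gain/loss calling, X-ploidy inference, and test-vs-control comparison.

Segments are classified purely by their mean log2 copy ratio against
fixed thresholds sitting between the diploid level (0) and the one-copy
expectations (-1 for a hemizygous loss, +0.585 for a single-copy gain).
A male sample's haploid X is expected hemizygosity, not an aberration,
so X losses can be exempted when a single X has been inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid
from .ratio import CopyRatioTrack
from .segment import Segment, SegmentationResult

__all__ = [
    "CallThresholds",
    "CnvCall",
    "CallSet",
    "XPloidyReport",
    "ComparisonReport",
    "call_segments",
    "infer_x_ploidy",
    "compare_samples",
]

#: Fraction of a chromosome's unmasked bins a segment must span to count as
#: a whole-chromosome event (aneuploidy rather than a focal CNV).
WHOLE_CHROM_FRACTION = 0.9


@dataclass(frozen=True)
class CallThresholds:
    """Mean-log2 cutoffs for loss and gain calls.

    Defaults -0.4 / +0.32 sit between 0 and the one-copy expectations
    (-1 and +0.585) with margin for noise on both sides.
    """

    loss_log2: float = -0.4
    gain_log2: float = 0.32

    def __post_init__(self) -> None:
        if not self.loss_log2 < 0 < self.gain_log2:
            raise ValueError("need loss_log2 < 0 < gain_log2")

    def state_of(self, mean_value: float) -> str:
        if mean_value <= self.loss_log2:
            return "loss"
        if mean_value >= self.gain_log2:
            return "gain"
        return "neutral"


@dataclass(frozen=True)
class CnvCall:
    """A segment with its copy state and whole-chromosome flag."""

    segment: Segment
    state: str
    whole_chromosome: bool


@dataclass
class CallSet:
    """All calls for one sample on one grid."""

    grid: BinGrid
    sample_id: str
    calls: list[CnvCall] = field(default_factory=list)

    def non_neutral(self) -> list[CnvCall]:
        return [c for c in self.calls if c.state != "neutral"]


@dataclass(frozen=True)
class XPloidyReport:
    """X copy state inferred from the median X-bin log2 ratio.

    single_X when the median is at or below ``single_x_max`` (one X against
    a diploid autosomal baseline reads out near -1); double_X at or above
    ``double_x_min``; indeterminate in between.
    """

    median_x_log2: float
    inferred_state: str
    single_x_max: float = -0.5
    double_x_min: float = -0.25


@dataclass
class ComparisonReport:
    """Non-neutral calls split into test-specific / control-specific / shared."""

    test_specific_calls: list[CnvCall]
    control_specific_calls: list[CnvCall]
    shared_calls: list[tuple[CnvCall, CnvCall]]
    overlap_rule: float


def call_segments(
    result: SegmentationResult,
    thresholds: CallThresholds | None = None,
    single_x: bool = False,
    sample_id: str = "sample",
) -> CallSet:
    """Classify every segment as loss / gain / neutral.

    ``whole_chromosome`` is set when a segment spans at least 90% of its
    chromosome's unmasked (segmented) bins.  With ``single_x=True``, loss
    calls on the X are downgraded to neutral: in a male sample the haploid
    X is the expected state.
    """
    thresholds = thresholds or CallThresholds()
    chrom_bins: dict[str, int] = {}
    for seg in result.segments:
        chrom_bins[seg.chrom] = chrom_bins.get(seg.chrom, 0) + seg.n_bins
    calls = []
    for seg in result.segments:
        state = thresholds.state_of(seg.mean_value)
        if single_x and state == "loss" and result.grid.index[seg.chrom].category == "X":
            state = "neutral"
        whole = seg.n_bins >= WHOLE_CHROM_FRACTION * chrom_bins[seg.chrom]
        calls.append(CnvCall(seg, state, whole))
    return CallSet(result.grid, sample_id, calls)


def infer_x_ploidy(
    track: CopyRatioTrack,
    single_x_max: float = -0.5,
    double_x_min: float = -0.25,
) -> XPloidyReport:
    """Infer the X copy state from the median log2 ratio of unmasked X bins."""
    sel = track.grid.is_x & track.unmasked
    if not track.grid.is_x.any():
        raise ValueError("no X chromosome in index")
    if not sel.any():
        raise ValueError("no unmasked X bins with values")
    med = float(np.median(track.values[sel]))
    if med <= single_x_max:
        state = "single_X"
    elif med >= double_x_min:
        state = "double_X"
    else:
        state = "indeterminate"
    return XPloidyReport(med, state, single_x_max, double_x_min)


def _overlap(a: Segment, b: Segment) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _reciprocal_match(a: CnvCall, b: CnvCall, rule: float) -> bool:
    if a.segment.chrom != b.segment.chrom or a.state != b.state:
        return False
    ov = _overlap(a.segment, b.segment)
    return ov >= rule * a.segment.length and ov >= rule * b.segment.length


def compare_samples(
    test_calls: CallSet,
    control_calls: CallSet,
    overlap_rule: float = 0.5,
) -> ComparisonReport:
    """Match non-neutral calls between a test and a control sample.

    Two calls are the same event when they share chromosome and state and
    overlap reciprocally by at least ``overlap_rule`` of each length.
    Matched calls are shared; unmatched ones are sample-specific — the
    culture-acquired candidates.  Neutral segments are never reported.
    """
    if test_calls.grid != control_calls.grid:
        raise ValueError("test and control call sets are on different bin grids")
    if not 0 < overlap_rule <= 1:
        raise ValueError("overlap_rule must be in (0, 1]")
    t_nn = test_calls.non_neutral()
    c_nn = control_calls.non_neutral()
    shared: list[tuple[CnvCall, CnvCall]] = []
    t_matched: set[int] = set()
    c_matched: set[int] = set()
    for ti, t in enumerate(t_nn):
        for ci, c in enumerate(c_nn):
            if _reciprocal_match(t, c, overlap_rule):
                shared.append((t, c))
                t_matched.add(ti)
                c_matched.add(ci)
    return ComparisonReport(
        test_specific_calls=[t for ti, t in enumerate(t_nn) if ti not in t_matched],
        control_specific_calls=[c for ci, c in enumerate(c_nn) if ci not in c_matched],
        shared_calls=shared,
        overlap_rule=overlap_rule,
    )
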