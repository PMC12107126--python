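"""One-call convenience wrapper for the control/test screening workflow."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import (
    CallSet,
    CallThresholds,
    ComparisonReport,
    XPloidyReport,
    call_segments,
    compare_samples,
    infer_x_ploidy,
)
from .counting import BinCounts
from .ratio import CopyRatioTrack, normalize_counts
from .segment import SegmentationParams, SegmentationResult, segment_genome

__all__ = ["ScreenResult", "screen_pair"]


@dataclass
class ScreenResult:
    """Everything the screen produced, keyed per sample where applicable."""

    tracks: dict[str, CopyRatioTrack]
    segmentations: dict[str, SegmentationResult]
    calls: dict[str, CallSet]
    comparison: ComparisonReport
    x_ploidy: dict[str, XPloidyReport]


def screen_pair(
    test: BinCounts,
    control: BinCounts,
    params: SegmentationParams,
    thresholds: CallThresholds | None = None,
    pseudocount: float = 0.5,
    mask: np.ndarray | None = None,
    overlap_rule: float = 0.5,
) -> ScreenResult:
    """Run normalize -> segment -> call -> compare for a control/test pair.

    Each sample is normalised within-sample and segmented independently;
    the two call sets are then matched by reciprocal overlap so that only
    events private to one sample surface as candidates.  When a sample's
    X reads out as single_X, its X loss calls are exempted (expected male
    hemizygosity).
    """
    if test.grid != control.grid:
        raise ValueError("test and control counts are on different bin grids")
    thresholds = thresholds or CallThresholds()
    tracks: dict[str, CopyRatioTrack] = {}
    segs: dict[str, SegmentationResult] = {}
    callsets: dict[str, CallSet] = {}
    xrep: dict[str, XPloidyReport] = {}
    for name, counts in (("control", control), ("test", test)):
        track = normalize_counts(counts, pseudocount=pseudocount, mask=mask)
        tracks[name] = track
        segs[name] = segment_genome(track, params)
        if track.grid.is_x.any():
            xrep[name] = infer_x_ploidy(track)
            single_x = xrep[name].inferred_state == "single_X"
        else:
            single_x = False
        callsets[name] = call_segments(
            segs[name], thresholds, single_x=single_x, sample_id=counts.sample_id
        )
    comparison = compare_samples(callsets["test"], callsets["control"], overlap_rule=overlap_rule)
    return ScreenResult(tracks, segs, callsets, comparison, xrep)
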