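"""Circular binary segmentation (CBS) of log2 copy-ratio tracks.

A data stretch is conceptually joined into a circle and every arc is
tested for a mean shift against its complement with a two-sample
t-like statistic; the most extreme arc is assessed by a permutation
test and, if significant, the stretch is split at the arc boundaries
and each piece re-examined recursively.  The result is a partition of
each chromosome into mean-constant segments.

Permutations are seeded per data stretch (derived from the global seed
and the stretch's bin range), so results are reproducible and the
segmentation at a stricter significance level is always a coarsening of
the one at a looser level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import BinGrid
from .ratio import CopyRatioTrack

__all__ = [
    "SegmentationParams",
    "Segment",
    "SegmentationResult",
    "arc_statistic",
    "max_arc_statistic",
    "permutation_pvalue",
    "segment_values",
    "segment_genome",
]

# Relative slack when comparing permuted maxima with the observed statistic,
# so exact ties survive floating-point reordering.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the recursive CBS procedure.

    alpha: split significance level; n_perm: permutations per test;
    min_bins: smallest piece a split may create; seed: mandatory RNG seed.
    The variance in the arc statistic is the sample variance of the data
    stretch currently under test.
    """

    seed: int
    alpha: float = 0.01
    n_perm: int = 10_000
    min_bins: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")


@dataclass(frozen=True)
class Segment:
    """A maximal stretch of bins judged to share one underlying copy level.

    ``first_bin``/``last_bin`` are inclusive global bin indices;
    ``split_pvalue`` is the permutation p of the test that failed to split
    the segment further (NaN when no test was run: stretch too small,
    zero-variance, or blocked by ``min_bins``).
    """

    chrom: str
    first_bin: int
    last_bin: int
    n_bins: int
    start: int
    end: int
    mean_value: float
    split_pvalue: float

    def __post_init__(self) -> None:
        if self.n_bins != self.last_bin - self.first_bin + 1 or self.n_bins < 1:
            raise ValueError("inconsistent segment bin range")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Ordered segments partitioning each chromosome's unmasked bins."""

    grid: BinGrid
    segments: list[Segment] = field(default_factory=list)

    def for_chrom(self, name: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == name]

    def __len__(self) -> int:
        return len(self.segments)


def arc_statistic(x: Sequence[float], i: int, j: int, sigma2: float) -> float:
    """Two-sample arc statistic comparing x[i:j] with its complement.

    T = (mean(arc) - mean(complement)) / sqrt(sigma2 * (1/k + 1/(n-k)))
    with k = j - i; by convention T = 0 when sigma2 = 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = j - i
    if not (0 <= i < j <= n) or k <= 0 or k >= n:
        raise ValueError(f"arc ({i}, {j}) leaves an empty arc or complement for n={n}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return 0.0
    arc_mean = x[i:j].mean()
    comp_mean = (x.sum() - x[i:j].sum()) / (n - k)
    return float((arc_mean - comp_mean) / np.sqrt(sigma2 * (1.0 / k + 1.0 / (n - k))))


def _pairwise_abs_t(x: np.ndarray) -> np.ndarray:
    """|T| for every admissible arc (i, j); inadmissible entries are -inf.

    Because sigma2 > 0 is a common positive factor it is dropped: the
    argmax of |T| does not depend on it.
    """
    n = len(x)
    c = np.concatenate(([0.0], np.cumsum(x)))
    total = c[-1]
    arc_sum = c[None, :] - c[:, None]  # [i, j] -> sum of x[i:j]
    k = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
    valid = (k > 0) & (k < n)
    kf = np.where(valid, k, 1).astype(float)
    comp = np.where(valid, n - k, 1).astype(float)
    with np.errstate(invalid="ignore"):
        t = (arc_sum / kf - (total - arc_sum) / comp) / np.sqrt(1.0 / kf + 1.0 / comp)
    t = np.abs(t)
    t[~valid] = -np.inf
    return t


def max_arc_statistic(x: Sequence[float]) -> tuple[int, int, float]:
    """Arc (i*, j*) maximising |T| over all arcs, ties to smallest i then j.

    Returns (i*, j*, |T*|) with the variance term being the sample
    variance of x (|T*| = 0 for a constant stretch).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values to search for an arc")
    sigma2 = float(x.var(ddof=1))
    t = _pairwise_abs_t(x)
    m = float(t.max())
    # Exact ties are structural (an arc and its complement share |T|); pick
    # the first candidate in row-major order — smallest i, then smallest j —
    # with a relative tolerance so float noise cannot flip the choice.
    flat = int(np.argmax(t >= m - _TIE_EPS * max(1.0, abs(m))))
    i, j = divmod(flat, n + 1)
    if sigma2 == 0:
        return i, j, 0.0
    return i, j, float(t[i, j] / np.sqrt(sigma2))


def _perm_max_abs_t(
    x: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 128
) -> "np.ndarray":
    """Max |T| (without the sigma2 factor) for ``n_perm`` row permutations."""
    n = len(x)
    ks = np.arange(1, n)
    denom = np.sqrt(1.0 / ks + 1.0 / (n - ks))
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (m, n)), axis=1)
        c = np.concatenate([np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1)
        total = c[:, -1:]
        best = np.zeros(m)
        for k in ks:
            s = c[:, k:] - c[:, : n + 1 - k]
            t = np.abs(s / k - (total - s) / (n - k)) / denom[k - 1]
            best = np.maximum(best, t.max(axis=1))
        out[done : done + m] = best
        done += m
    return out


def permutation_pvalue(
    x: Sequence[float],
    t_obs: float,
    n_perm: int,
    seed: int | np.random.Generator | np.random.SeedSequence,
) -> float:
    """Permutation p-value of an observed max-|T| statistic.

    p = (1 + #{permutations whose max |T| >= t_obs}) / (1 + n_perm), never
    zero; deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    sigma2 = float(x.var(ddof=1)) if len(x) > 1 else 0.0
    if sigma2 == 0.0:
        # All permutations tie at T = 0.
        exceed = n_perm if t_obs <= 0 else 0
        return (1 + exceed) / (1 + n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = _perm_max_abs_t(x, n_perm, rng) / np.sqrt(sigma2)
    exceed = int(np.count_nonzero(maxima >= t_obs - _TIE_EPS * max(1.0, abs(t_obs))))
    return (1 + exceed) / (1 + n_perm)


def _node_rng(seed: int, lo: int, hi: int, salt: int) -> np.random.Generator:
    # Keyed by the bin range so the same stretch always sees the same
    # permutations, independent of what happened elsewhere in the recursion.
    return np.random.default_rng([seed & 0x7FFFFFFF, salt, lo, hi])


def _split_decision(
    x: np.ndarray, t_obs: float, params: SegmentationParams, rng: np.random.Generator
) -> tuple[bool, float]:
    """Permutation test with early stopping.

    Draws permutations in chunks and stops as soon as the exceedance count
    guarantees p >= alpha (the count can only grow), which leaves the
    split/no-split decision identical to the full-n_perm test.  When the
    test stops early the returned p is the running estimate at that point
    (always >= alpha); when the stretch is split the p is exact.
    """
    sigma2 = float(x.var(ddof=1))
    threshold = int(np.ceil(params.alpha * (1 + params.n_perm)))  # count => p >= alpha
    t_cut = (t_obs - _TIE_EPS * max(1.0, abs(t_obs))) * np.sqrt(sigma2)
    exceed = 0
    drawn = 0
    chunk = 128
    while drawn < params.n_perm:
        m = min(chunk, params.n_perm - drawn)
        maxima = _perm_max_abs_t(x, m, rng, chunk=m)
        exceed += int(np.count_nonzero(maxima >= t_cut))
        drawn += m
        if 1 + exceed >= threshold:
            return False, (1 + exceed) / (1 + drawn)
    p = (1 + exceed) / (1 + params.n_perm)
    return p < params.alpha, p


def segment_values(
    x: Sequence[float], params: SegmentationParams
) -> list[tuple[int, int, float, float]]:
    """Recursive CBS over one data stretch.

    Returns ordered (start, end, mean, split_pvalue) tuples, half-open in
    local indices, that partition [0, len(x)).  A stretch is split at its
    most extreme arc when the permutation test is significant and every
    resulting piece has at least ``min_bins`` bins; an interior arc yields
    three pieces, an end-abutting arc two.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 1:
        raise ValueError("cannot segment an empty stretch")
    out: list[tuple[int, int, float, float]] = []

    def emit(lo: int, hi: int, p: float) -> None:
        out.append((lo, hi, float(x[lo:hi].mean()), p))

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 or m < 2 * params.min_bins:
            emit(lo, hi, np.nan)
            return
        xs = x[lo:hi]
        if float(xs.var(ddof=1)) == 0.0:
            emit(lo, hi, np.nan)  # zero-variance stretches are unsplittable
            return
        i, j, t_obs = max_arc_statistic(xs)
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        pieces = [(a, b) for a, b in pieces if b > a]
        if any(b - a < params.min_bins for a, b in pieces):
            emit(lo, hi, np.nan)
            return
        split, p = _split_decision(xs, t_obs, params, _node_rng(params.seed, lo, hi, n))
        if split:
            for a, b in pieces:
                recurse(a, b)
        else:
            emit(lo, hi, p)

    recurse(0, n)
    return out


def segment_genome(track: CopyRatioTrack, params: SegmentationParams) -> SegmentationResult:
    """Segment each chromosome of a copy-ratio track independently.

    Masked bins are never members of any segment; within a chromosome each
    contiguous run of unmasked bins is segmented on its own, and the
    segments partition the chromosome's unmasked bins exactly.
    """
    grid = track.grid
    if not track.unmasked.any():
        raise ValueError("track has no unmasked bins")
    result = SegmentationResult(grid)
    for rec in grid.index:
        first, n = grid.chrom_offset(rec.name)
        unmasked = track.unmasked[first : first + n]
        if not unmasked.any():
            continue
        # contiguous runs of unmasked bins within this chromosome
        idx = np.flatnonzero(unmasked)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks + 1, [len(idx)]))
        for rs, re_ in zip(run_starts, run_ends):
            g0 = first + int(idx[rs])  # global index of run start
            values = track.values[g0 : first + int(idx[re_ - 1]) + 1]
            for lo, hi, mean, p in segment_values(values, params):
                result.segments.append(
                    Segment(
                        chrom=rec.name,
                        first_bin=g0 + lo,
                        last_bin=g0 + hi - 1,
                        n_bins=hi - lo,
                        start=int(grid.starts[g0 + lo]),
                        end=int(grid.ends[g0 + hi - 1]),
                        mean_value=mean,
                        split_pvalue=p,
                    )
                )
    return result
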