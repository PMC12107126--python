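"""Seeded synthetic inputs: genomes, binned counts, and toy SAM files.

The generator emulates the screening scenario the package is built for: a
male rhinoceros-like karyotype of 40 acrocentric autosomes plus an X (and
optionally a fragmented Y), long-read coverage averaging 75 reads per 1-Mb
bin, and planted copy-number events — hemizygous losses (multiplier 0.5),
single-copy gains (1.5), or whole-chromosome amplifications — so every
pipeline stage can be exercised end to end without any sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .counting import BinCounts
from .genome import BinGrid, ChromRecord, GenomeIndex

__all__ = [
    "CnvSpec",
    "SimulationConfig",
    "make_rhino_like_index",
    "simulate_bin_counts",
    "expected_bin_means",
    "simulate_alignment_file",
    "load_simulation_config",
]


@dataclass(frozen=True)
class CnvSpec:
    """A planted copy-number event: mean depth over [start, end) is scaled
    by ``multiplier`` (0.5 hemizygous loss, 1.5 single-copy gain, 0
    homozygous loss)."""

    chrom: str
    start: int
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"CNV on {self.chrom!r}: need 0 <= start < end")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass
class SimulationConfig:
    """Generative description of one synthetic sample.

    ``mean_depth`` is the expected read count per full-width autosomal bin;
    X and Y bins get half of it when ``sex == "XY"``.  Noise is Poisson by
    default or negative binomial with the given dispersion (variance
    mu + mu^2 / dispersion).
    """

    index: GenomeIndex
    seed: int
    mean_depth: float = 75.0
    noise: str = "poisson"
    dispersion: float | None = None
    sex: str = "XY"
    cnvs: Sequence[CnvSpec] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.noise not in ("poisson", "negative-binomial"):
            raise ValueError("noise must be 'poisson' or 'negative-binomial'")
        if self.noise == "negative-binomial" and (self.dispersion is None or self.dispersion <= 0):
            raise ValueError("negative-binomial noise needs a positive dispersion")
        if self.sex not in ("XY", "XX"):
            raise ValueError("sex must be 'XY' or 'XX'")
        by_chrom: dict[str, list[CnvSpec]] = {}
        for cnv in self.cnvs:
            if cnv.chrom not in self.index:
                raise ValueError(f"CNV references unknown chromosome {cnv.chrom!r}")
            if cnv.end > self.index[cnv.chrom].length:
                raise ValueError(f"CNV on {cnv.chrom!r} extends past chromosome end")
            by_chrom.setdefault(cnv.chrom, []).append(cnv)
        for chrom, specs in by_chrom.items():
            specs = sorted(specs, key=lambda s: s.start)
            for a, b in zip(specs, specs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping CNV specs on {chrom!r}")


def make_rhino_like_index(
    n_autosomes: int = 40,
    include_y: bool = False,
    seed: int = 0,
    n_y_scaffolds: int = 155,
    x_length: int = 130_600_000,
) -> GenomeIndex:
    """A synthetic karyotype shaped like the white rhinoceros genome.

    Autosome lengths fall smoothly from ~230 Mb to ~20 Mb (total ~2.4 Gb,
    many small acrocentric chromosomes), the X is ~130 Mb, and the optional
    Y is a pile of sub-megabase scaffolds.  Lengths carry a small seeded
    jitter; the result is deterministic for a fixed seed.  The lengths are
    synthetic approximations — only their ordering and scale matter.
    """
    if n_autosomes < 1:
        raise ValueError("n_autosomes must be >= 1")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x9E3779B9])
    # 20 Mb floor + power-law decay from 230 Mb; exponent 4.25 puts the
    # 40-autosome total near 2.4 Gb.
    u = (n_autosomes - 1 - np.arange(n_autosomes)) / max(n_autosomes - 1, 1)
    lengths = 20e6 + 210e6 * u**4.25
    lengths = np.sort(lengths * rng.uniform(0.98, 1.02, size=n_autosomes))[::-1]
    records = [
        ChromRecord(f"chr{i + 1}", int(round(L)), "autosome") for i, L in enumerate(lengths)
    ]
    records.append(ChromRecord("chrX", int(x_length * rng.uniform(0.99, 1.01)), "X"))
    if include_y:
        y_lengths = rng.uniform(50_000, 950_000, size=n_y_scaffolds)
        records.extend(
            ChromRecord(f"chrY_scaffold_{i + 1}", int(round(L)), "Y")
            for i, L in enumerate(y_lengths)
        )
    return GenomeIndex(records)


def expected_bin_means(config: SimulationConfig, grid: BinGrid) -> np.ndarray:
    """Expected count per bin before noise.

    mean_depth x (bin width / bin size) x CNV multiplier x allosome factor,
    where the multiplier is the length-weighted average of CNV specs
    overlapping the bin (1 where none) and the allosome factor is 0.5 for
    X and Y bins of an XY sample.
    """
    if grid.index != config.index:
        raise ValueError("grid was not built from the config's genome index")
    mult = np.ones(grid.n_bins)
    for cnv in config.cnvs:
        sl = grid.chrom_slice(cnv.chrom)
        starts = grid.starts[sl]
        ends = grid.ends[sl]
        ov = np.clip(np.minimum(ends, cnv.end) - np.maximum(starts, cnv.start), 0, None)
        frac = ov / (ends - starts)
        mult[sl] += frac * (cnv.multiplier - 1.0)
    allosome = np.ones(grid.n_bins)
    if config.sex == "XY":
        allosome[grid.is_x | grid.is_y] = 0.5
    return config.mean_depth * (grid.widths / grid.bin_size) * mult * allosome


def simulate_bin_counts(config: SimulationConfig, grid: BinGrid) -> BinCounts:
    """Draw per-bin counts from the configured noise model, deterministically."""
    mu = expected_bin_means(config, grid)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x5EED])
    if config.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        d = float(config.dispersion)  # variance mu + mu^2/d
        p = d / (d + mu)
        counts = rng.negative_binomial(d, p)
    meta = {
        "records_seen": int(counts.sum()),
        "records_counted": int(counts.sum()),
        "filtered_by_flag": 0,
        "filtered_by_mapq": 0,
        "skipped_unknown_chrom": 0,
    }
    return BinCounts(f"sim_seed{config.seed}", grid, counts.astype(np.int64), meta)


def _sam_header_lines(index: GenomeIndex) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{rec.name}\tLN:{rec.length}" for rec in index]
    return lines


def simulate_alignment_file(
    grid: BinGrid,
    reads_per_bin: Sequence[int] | np.ndarray,
    contamination: Mapping[str, int] | None = None,
    seed: int = 0,
    out: str | Path | None = None,
) -> tuple[str, np.ndarray]:
    """Emit a toy SAM file realising a per-bin primary-read ledger.

    Writes the requested number of primary records into each bin (leftmost
    position uniform within the bin) plus contaminating records that the
    flag filter must reject: ``n_secondary`` (flag 256), ``n_supplementary``
    (2048), and ``n_unmapped`` (4).  Sequences and qualities are
    placeholders; records carry a 1M CIGAR so any position inside a bin is
    valid.  Returns (SAM text, ledger) for round-trip testing; the text is
    also written to ``out`` when given.
    """
    ledger = np.asarray(reads_per_bin, dtype=np.int64)
    if ledger.shape != (grid.n_bins,):
        raise ValueError("ledger length does not match grid")
    if (ledger < 0).any():
        raise ValueError("ledger counts must be nonnegative")
    contamination = dict(contamination or {})
    n_sec = int(contamination.pop("n_secondary", 0))
    n_sup = int(contamination.pop("n_supplementary", 0))
    n_unm = int(contamination.pop("n_unmapped", 0))
    if contamination:
        raise ValueError(f"unknown contamination keys: {sorted(contamination)}")

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5A11])
    names = grid.index.names
    lines = _sam_header_lines(grid.index)
    rid = 0

    def record(flag: int, chrom: str, pos0: int) -> str:
        nonlocal rid
        rid += 1
        if flag & 4:
            return f"read{rid}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t*\t*"
        return f"read{rid}\t{flag}\t{chrom}\t{pos0 + 1}\t60\t1M\t*\t0\t0\t*\t*"

    for g in np.flatnonzero(ledger):
        chrom = names[grid.chrom_ids[g]]
        lo, hi = int(grid.starts[g]), int(grid.ends[g])
        for pos0 in rng.integers(lo, hi, size=int(ledger[g])):
            lines.append(record(0, chrom, int(pos0)))
    for flag, n in ((256, n_sec), (2048, n_sup), (4, n_unm)):
        for _ in range(n):
            if flag & 4:
                lines.append(record(flag, "*", 0))
            else:
                g = int(rng.integers(0, grid.n_bins))
                chrom = names[grid.chrom_ids[g]]
                pos0 = int(rng.integers(grid.starts[g], grid.ends[g]))
                lines.append(record(flag, chrom, pos0))

    text = "\n".join(lines) + "\n"
    if out is not None:
        Path(out).write_text(text)
    return text, ledger


def load_simulation_config(path: str | Path) -> tuple[SimulationConfig, int]:
    """Build a SimulationConfig (and bin size) from a YAML file.

    The genome comes either from ``chrom_sizes: <path>`` or from a
    ``rhino_like:`` block passed to :func:`make_rhino_like_index`.
    Remaining keys mirror SimulationConfig; ``bin_size`` (default 1 Mb)
    is returned alongside for grid construction.
    """
    import yaml

    from .genome import load_genome_index

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    if "chrom_sizes" in raw:
        index = load_genome_index(raw["chrom_sizes"])
    else:
        rl = raw.get("rhino_like", {}) or {}
        index = make_rhino_like_index(
            n_autosomes=int(rl.get("n_autosomes", 40)),
            include_y=bool(rl.get("include_y", False)),
            seed=int(rl.get("seed", seed)),
        )
    cnvs = tuple(
        CnvSpec(str(c["chrom"]), int(c["start"]), int(c["end"]), float(c["multiplier"]))
        for c in raw.get("cnvs", []) or []
    )
    config = SimulationConfig(
        index=index,
        seed=seed,
        mean_depth=float(raw.get("mean_depth", 75.0)),
        noise=str(raw.get("noise", "poisson")),
        dispersion=raw.get("dispersion"),
        sex=str(raw.get("sex", "XY")),
        cnvs=cnvs,
    )
    return config, int(raw.get("bin_size", 1_000_000))
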