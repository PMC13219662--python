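"""Runs of homozygosity: F_ROH, length-class fractions, ROH ages, recent Ne.

An ROH is a homozygous tract inherited identical-by-descent from a common
ancestor of the two parental lineages. The expected time back to that
ancestor for a tract of length L megabases under recombination rate r
(cM/Mb) is

    g = 100 / (2 r L)   generations,

and the fraction of the genome expected to have coalesced within t
generations in a population of constant effective size Ne is

    F_ROH,t = 1 - (1 - 1/(2 Ne))^t.

Inverting the second relation on the genome fraction observed in each ROH
length class, at the age implied by the first, yields an epoch-wise recent
Ne trajectory. Intervals may come from an external probabilistic caller
(BED-like TSV with a posterior column) or from the built-in fixed-window
caller, a deliberately simple stand-in that labels windows with at most a
given number of heterozygous sites as ROH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("loadscape")

MB = 1_000_000


@dataclass
class ROHInterval:
    """A homozygous tract; coordinates are 0-based half-open."""

    sample: str
    chrom: str
    start: int
    end: int
    p_roh: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"ROH interval end {self.end} <= start {self.start}")
        if not 0.0 <= self.p_roh <= 1.0:
            raise ValueError("p_roh must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ROHDemographyConfig:
    """Parameters of the F_ROH and recent-Ne computations.

    ``recombination_rate`` is in cM/Mb (chicken-map default 2.8, the closest
    available estimate for reptiles), ``generation_time`` in years,
    ``length_bins`` in Mb as [low, high) pairs, ``genome_length`` the
    callable autosomal length in bp.
    """

    genome_length: int
    min_roh_length: int = 1 * MB
    p_threshold: float = 0.9
    recombination_rate: float = 2.8
    generation_time: float = 2.0
    length_bins: tuple[tuple[float, float], ...] = ((1.0, 4.0), (4.0, 16.0), (16.0, 64.0))
    chrom_lengths: dict[str, int] | None = None
    bin_representative: str = "geometric"  # or "midpoint"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.recombination_rate <= 0:
            raise ValueError("recombination_rate must be positive")
        last = -np.inf
        for low, high in self.length_bins:
            if not (low < high) or low < last:
                raise ValueError("length_bins must be increasing and non-overlapping")
            last = high
        if self.bin_representative not in ("geometric", "midpoint"):
            raise ValueError("bin_representative must be 'geometric' or 'midpoint'")


def merge_roh_intervals(intervals: Iterable[ROHInterval]) -> list[ROHInterval]:
    """Merge overlapping/adjacent intervals per (sample, chromosome).

    The merged interval takes the maximum posterior of its members.
    """
    by_key: dict[tuple[str, str], list[ROHInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.sample, iv.chrom), []).append(iv)
    merged: list[ROHInterval] = []
    for (sample, chrom), ivs in sorted(by_key.items()):
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur = None
        for iv in ivs:
            if cur is None or iv.start > cur.end:
                if cur is not None:
                    merged.append(cur)
                cur = ROHInterval(sample, chrom, iv.start, iv.end, iv.p_roh)
            else:
                cur.end = max(cur.end, iv.end)
                cur.p_roh = max(cur.p_roh, iv.p_roh)
        if cur is not None:
            merged.append(cur)
    return merged


def call_roh_windows(
    het_positions: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    window_bp: int,
    max_het_per_window: int = 0,
    sample: str = "sample",
) -> list[ROHInterval]:
    """Fixed-window ROH delineation from per-chromosome het-site positions.

    Each chromosome is tiled into ``window_bp`` windows; windows whose het
    count is at most ``max_het_per_window`` are ROH (posterior set to 1.0)
    and adjacent ROH windows are merged. A simple stand-in for probabilistic
    HMM callers; positions are 0-based.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out: list[ROHInterval] = []
    for chrom, length in chrom_lengths.items():
        n_windows = int(np.ceil(length / window_bp))
        pos = np.asarray(het_positions.get(chrom, []), dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"het position outside chromosome {chrom}")
        counts = np.bincount(pos // window_bp, minlength=n_windows)
        is_roh = counts <= max_het_per_window
        # merge runs of consecutive ROH windows
        edges = np.flatnonzero(np.diff(np.concatenate(([0], is_roh.view(np.int8), [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            out.append(
                ROHInterval(
                    sample=sample,
                    chrom=chrom,
                    start=int(run_start * window_bp),
                    end=int(min(run_end * window_bp, length)),
                    p_roh=1.0,
                )
            )
    return out


def _confident(intervals: Iterable[ROHInterval], config: ROHDemographyConfig) -> list[ROHInterval]:
    kept = [iv for iv in intervals if iv.p_roh > config.p_threshold]
    if config.chrom_lengths is not None:
        for iv in kept:
            limit = config.chrom_lengths.get(iv.chrom)
            if limit is not None and iv.end > limit:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome length {limit}"
                )
    return merge_roh_intervals(kept)


def froh(intervals: Sequence[ROHInterval], config: ROHDemographyConfig) -> float:
    """Genomic inbreeding coefficient: fraction of the genome in long ROH.

    Intervals (one sample) with posterior above ``p_threshold`` are merged;
    those at least ``min_roh_length`` long contribute their length, divided
    by ``genome_length``.
    """
    samples = {iv.sample for iv in intervals}
    if len(samples) > 1:
        raise ValueError(f"froh expects intervals of one sample, got {sorted(samples)}")
    merged = _confident(intervals, config)
    total = sum(iv.length for iv in merged if iv.length >= config.min_roh_length)
    if total > config.genome_length:
        raise ValueError("total ROH length exceeds genome length (coordinate mismatch?)")
    return total / config.genome_length


def roh_age(length_mb: float, recombination_rate: float) -> float:
    """Expected generations back to the tract's parental common ancestor: 100/(2 r L)."""
    if length_mb <= 0 or recombination_rate <= 0:
        raise ValueError("length and recombination rate must be positive")
    return 100.0 / (2.0 * recombination_rate * length_mb)


def froh_expected(ne: float, t: float) -> float:
    """Forward model: expected genome fraction coalesced within t generations."""
    if ne <= 0 or t <= 0:
        raise ValueError("ne and t must be positive")
    return -np.expm1(t * np.log1p(-1.0 / (2.0 * ne)))


def froh_survival(ne: float, t: float) -> float:
    """Complement of :func:`froh_expected`: (1 - 1/(2 Ne))^t.

    For very small Ne or deep t the coalesced fraction is within a few ulp of
    one and double precision cannot represent it usefully; the survival form
    keeps full precision, mirroring the cdf/sf convention of distribution
    libraries.
    """
    if ne <= 0 or t <= 0:
        raise ValueError("ne and t must be positive")
    return float(np.exp(t * np.log1p(-1.0 / (2.0 * ne))))


def ne_from_froh(f: float, t: float) -> float:
    """Invert F = 1 - (1 - 1/(2 Ne))^t for Ne; requires 0 < F < 1 and t > 0."""
    if t <= 0:
        raise ValueError("t must be positive")
    if not 0.0 < f < 1.0:
        raise ValueError(
            f"F must be in (0, 1); got {f} (F=0 implies infinite Ne, F=1 the Ne=0.5 limit)"
        )
    return ne_from_froh_survival(1.0 - f, t)


def ne_from_froh_survival(s: float, t: float) -> float:
    """Invert the survival form: Ne = 1 / (2 (1 - s^(1/t)))."""
    if t <= 0:
        raise ValueError("t must be positive")
    if not 0.0 < s < 1.0:
        raise ValueError("survival fraction must be in (0, 1)")
    return float(1.0 / (2.0 * -np.expm1(np.log(s) / t)))


def ne_trajectory(
    intervals_by_sample: Mapping[str, Sequence[ROHInterval]],
    config: ROHDemographyConfig,
) -> pd.DataFrame:
    """Epoch-wise recent Ne from ROH length classes.

    For each length bin [L_low, L_high) (Mb): the genome fraction F_bin in
    ROH of that length (averaged over samples), the representative length
    (geometric mean of the bounds by default), its age g = 100/(2 r L) in
    generations and years, and Ne from inverting the coalescent-fraction
    formula. Bins with F_bin = 0 (or >= 1) are reported with Ne = NaN
    (undetermined).
    """
    if not config.length_bins:
        raise ValueError("length_bins must be nonempty")
    if not intervals_by_sample:
        raise ValueError("no samples provided")

    fractions = np.zeros((len(intervals_by_sample), len(config.length_bins)))
    counts = np.zeros(len(config.length_bins), dtype=int)
    for i, (sample, intervals) in enumerate(sorted(intervals_by_sample.items())):
        merged = _confident(intervals, config)
        lengths = np.array([iv.length for iv in merged], dtype=float)
        for j, (low, high) in enumerate(config.length_bins):
            in_bin = (lengths >= low * MB) & (lengths < high * MB)
            counts[j] += int(in_bin.sum())
            fractions[i, j] = lengths[in_bin].sum() / config.genome_length

    rows = []
    for j, (low, high) in enumerate(config.length_bins):
        if config.bin_representative == "geometric":
            l_rep = float(np.sqrt(low * high))
        else:
            l_rep = (low + high) / 2.0
        g = roh_age(l_rep, config.recombination_rate)
        f_bin = float(fractions[:, j].mean())
        if 0.0 < f_bin < 1.0:
            ne = ne_from_froh(f_bin, g)
        else:
            logger.warning("bin [%g, %g) Mb has F=%g; Ne undetermined", low, high, f_bin)
            ne = float("nan")
        rows.append(
            {
                "bin_low_mb": low,
                "bin_high_mb": high,
                "length_rep_mb": l_rep,
                "age_generations": g,
                "age_years": g * config.generation_time,
                "f_bin": f_bin,
                "n_tracts": int(counts[j]),
                "ne": ne,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interval I/O
# ---------------------------------------------------------------------------

def read_roh_tsv(path) -> list[ROHInterval]:
    """BED-like TSV: sample, chrom, start, end[, p_roh], 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "p_roh" not in df.columns:
        df["p_roh"] = 1.0
    return [
        ROHInterval(str(r.sample), str(r.chrom), int(r.start), int(r.end), float(r.p_roh))
        for r in df.itertuples()
    ]


def write_roh_tsv(intervals: Sequence[ROHInterval], path) -> None:
    pd.DataFrame(
        [
            {"sample": iv.sample, "chrom": iv.chrom, "start": iv.start, "end": iv.end, "p_roh": iv.p_roh}
            for iv in intervals
        ]
    ).to_csv(path, sep="\t", index=False)


def group_by_sample(intervals: Iterable[ROHInterval]) -> dict[str, list[ROHInterval]]:
    out: dict[str, list[ROHInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.sample, []).append(iv)
    return out
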