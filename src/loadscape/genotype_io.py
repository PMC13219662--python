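"""Reading, validation, hard-filtering and subsetting of multi-sample genotype data.

Genotypes are held as a sites x individuals matrix of small integer codes
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) together with per-site
records carrying the VCF QUAL/INFO annotations needed by the hard filters
(QD, FS, MQ, MQRankSum, ReadPosRankSum, DP) and per-genotype depth and
quality (DP, GQ for variant sites, RGQ for invariant blocks).

The site-level filters mirror the GATK-style hard-filter recipe commonly
used on non-model organisms: QUAL < 60, QD < 2, FS > 60, MQ < 40,
MQRankSum < -20, ReadPosRankSum < -8, per-genotype depth outside
(mean/3, mean*2), GQ < 10 (variants) or RGQ < 10 (invariant sites),
removal of SNPs within 5 bp of a high-quality indel, region masks, and a
25% site missingness cap applied after genotype-level masking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("loadscape")

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: site-removal rules in report-attribution order. A removed site is charged to
#: the first rule in this list that flags it; the surviving set itself does not
#: depend on the order because every rule is evaluated on the unfiltered input.
RULE_ORDER = (
    "qual",
    "qd",
    "fs",
    "mq",
    "mqranksum",
    "readposranksum",
    "indel_proximity",
    "excluded_chromosome",
    "region_mask",
    "missingness",
)

_SITE_INFO_RULES = {
    # rule -> (INFO key, threshold attribute, direction); "lt" fails when value < threshold
    "qd": ("QD", "min_qd", "lt"),
    "fs": ("FS", "max_fs", "gt"),
    "mq": ("MQ", "min_mq", "lt"),
    "mqranksum": ("MQRankSum", "min_mqranksum", "lt"),
    "readposranksum": ("ReadPosRankSum", "min_readposranksum", "lt"),
}


@dataclass
class SiteRecord:
    """One VCF record: a biallelic SNP, an invariant site, or an indel.

    Positions are 1-based as in VCF. Indel records are retained only so the
    indel-proximity mask can be computed; they are never genotyped downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str | None
    site_type: str  # "snp" | "invariant" | "indel"
    qual: float
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.site_type == "snp" and self.alt == self.ref:
            raise ValueError(f"{self.chrom}:{self.pos}: snp with ref == alt")


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotype calls plus quality annotations.

    ``genotypes`` uses the codes 0/1/2 for hom-ref/het/hom-alt and -1 for
    missing. ``depth`` and ``gt_qual`` are aligned arrays (-1 where absent);
    ``gt_qual`` holds GQ at variant sites and RGQ at invariant sites.
    """

    sites: list[SiteRecord]
    individuals: list[str]
    genotypes: np.ndarray
    depth: np.ndarray
    gt_qual: np.ndarray
    populations: dict[str, str]

    def __post_init__(self) -> None:
        n_sites, n_ind = self.genotypes.shape
        if n_sites != len(self.sites) or n_ind != len(self.individuals):
            raise ValueError("genotype matrix shape does not match sites/individuals")
        for name in self.individuals:
            if name not in self.populations:
                raise ValueError(f"sample {name!r} has no population label")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def site_types(self) -> np.ndarray:
        return np.array([s.site_type for s in self.sites])

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.individuals)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def population_samples(self, population: str) -> list[str]:
        return [s for s in self.individuals if self.populations[s] == population]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in index],
            individuals=list(self.individuals),
            genotypes=self.genotypes[index],
            depth=self.depth[index],
            gt_qual=self.gt_qual[index],
            populations=dict(self.populations),
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        cols = self.sample_indices(names)
        return GenotypeMatrix(
            sites=list(self.sites),
            individuals=list(names),
            genotypes=self.genotypes[:, cols],
            depth=self.depth[:, cols],
            gt_qual=self.gt_qual[:, cols],
            populations={n: self.populations[n] for n in names},
        )

    def mean_depths(self) -> dict[str, float]:
        """Per-sample mean depth over genotypes with a recorded DP."""
        out = {}
        for j, name in enumerate(self.individuals):
            dp = self.depth[:, j]
            dp = dp[dp >= 0]
            out[name] = float(dp.mean()) if dp.size else float("nan")
        return out


@dataclass
class FilterConfig:
    """Thresholds of the site- and genotype-level hard filters."""

    min_qual: float = 60.0
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_mqranksum: float = -20.0
    min_readposranksum: float = -8.0
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0
    min_gq: int = 10
    min_rgq: int = 10
    max_missing_fraction: float = 0.25
    indel_window_bp: int = 5
    # name -> list of (chrom, start, end) 1-based inclusive intervals
    excluded_region_sets: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    excluded_chromosomes: tuple[str, ...] = ()
    # "sample": per-genotype DP tested against that sample's mean depth;
    # "cohort": tested against the mean of all sample means.
    depth_scope: str = "sample"
    # the missingness cap is applied after GQ/RGQ/DP genotype masking by
    # default; set True to evaluate it on the raw genotypes instead.
    missingness_before_masking: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.indel_window_bp < 0:
            raise ValueError("indel_window_bp must be >= 0")
        if self.depth_scope not in ("sample", "cohort"):
            raise ValueError("depth_scope must be 'sample' or 'cohort'")


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass.

    Invariant: ``sites_in == sites_surviving + sum(sites_removed.values())``;
    each removed site is attributed to the first rule in RULE_ORDER that
    flagged it.
    """

    sites_in: int = 0
    sites_surviving: int = 0
    sites_removed: dict[str, int] = field(default_factory=dict)
    genotypes_masked: dict[str, int] = field(default_factory=dict)
    indels_in: int = 0
    indels_low_quality: int = 0
    missing_info_events: dict[str, int] = field(default_factory=dict)

    def check_identity(self) -> None:
        total = self.sites_surviving + sum(self.sites_removed.values())
        if total != self.sites_in:
            raise AssertionError(
                f"filter report identity violated: {self.sites_in} != {total}"
            )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"sites in:        {self.sites_in}",
            f"sites surviving: {self.sites_surviving}",
            f"indels in / low-quality: {self.indels_in} / {self.indels_low_quality}",
            "sites removed per rule:",
        ]
        for rule in RULE_ORDER:
            lines.append(f"  {rule:20s} {self.sites_removed.get(rule, 0)}")
        lines.append("genotypes set to missing per rule:")
        for rule, n in sorted(self.genotypes_masked.items()):
            lines.append(f"  {rule:20s} {n}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_populations(path) -> dict[str, str]:
    """Two-column TSV (sample, population), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_bed_regions(path, name: str | None = None) -> list[tuple[str, int, int]]:
    """Read a BED file into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, start0 + 1, end))
    return out


def read_genotypes(vcf_path, populations_path) -> GenotypeMatrix:
    """Read a multi-sample VCF (variant + invariant records) into a matrix.

    Invariant records (no ALT) are preserved with ``site_type='invariant'``;
    indel records are kept for the proximity mask only. Multi-allelic or
    otherwise unsupported records are excluded with a logged count. Every VCF
    sample must appear in the populations table.
    """
    from cyvcf2 import VCF

    populations = read_populations(populations_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in populations:
            raise ValueError(f"sample {s!r} in VCF is absent from populations table")

    sites: list[SiteRecord] = []
    geno_rows, dp_rows, q_rows = [], [], []
    n_multi = 0
    n_other = 0
    n = len(samples)
    for v in vcf:
        alts = [a for a in (v.ALT or []) if a != "."]
        if len(alts) > 1:
            n_multi += 1
            continue
        if len(alts) == 0 or alts[0] == v.REF:
            site_type, alt = "invariant", None
        elif len(v.REF) == 1 and len(alts[0]) == 1 and alts[0] in "ACGT":
            site_type, alt = "snp", alts[0]
        elif set(v.REF) <= set("ACGTN") and set(alts[0]) <= set("ACGTN"):
            site_type, alt = "indel", alts[0]
        else:
            n_other += 1
            continue

        info = {}
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP"):
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        sites.append(
            SiteRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                site_type=site_type,
                qual=float(v.QUAL) if v.QUAL is not None else float("nan"),
                info=info,
            )
        )

        # gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(v.gt_types, dtype=np.int8).copy()
        g[g == 3] = MISSING
        geno_rows.append(g)

        dp_rows.append(_format_column(_safe_format(v, "DP"), n))
        key = "RGQ" if site_type == "invariant" else "GQ"
        q = _safe_format(v, key)
        if q is None and site_type == "invariant":
            q = _safe_format(v, "GQ")
        q_rows.append(_format_column(q, n))

    if n_multi:
        logger.info("excluded %d multi-allelic records", n_multi)
    if n_other:
        logger.info("excluded %d unsupported records", n_other)

    matrix = GenotypeMatrix(
        sites=sites,
        individuals=samples,
        genotypes=np.array(geno_rows, dtype=np.int8) if geno_rows else np.empty((0, n), np.int8),
        depth=np.array(dp_rows, dtype=np.int32) if dp_rows else np.empty((0, n), np.int32),
        gt_qual=np.array(q_rows, dtype=np.int32) if q_rows else np.empty((0, n), np.int32),
        populations={s: populations[s] for s in samples},
    )
    order = np.lexsort((matrix.positions, matrix.chroms))
    return matrix.take_sites(order)


def _safe_format(variant, key: str):
    try:
        return variant.format(key)
    except KeyError:
        return None


def _format_column(arr, n: int) -> np.ndarray:
    if arr is None:
        return np.full(n, MISSING, dtype=np.int32)
    out = np.asarray(arr, dtype=np.int64).reshape(n, -1)[:, 0].astype(np.int32)
    out[out < 0] = MISSING
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_site_filters(
    matrix: GenotypeMatrix,
    config: FilterConfig,
    mean_depths: Mapping[str, float],
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the hard filters; returns the surviving matrix and a report.

    Indels below ``min_qual`` are discarded; SNPs within ``indel_window_bp``
    of a surviving indel are removed. SNP sites failing any site-level
    threshold are removed. Genotypes failing GQ (variants), RGQ (invariant
    sites) or the per-sample depth bounds (mean/3, mean*2), both exclusive,
    are set to missing; sites whose missing fraction then exceeds the cap are
    removed, as are sites on excluded chromosomes or inside region masks.

    A site-level rule whose INFO key is absent fails that site (the event is
    counted in the report, not raised).
    """
    for name in matrix.individuals:
        if name not in mean_depths:
            raise ValueError(f"mean_depths has no entry for sample {name!r}")

    report = FilterReport()

    site_types = matrix.site_types
    is_indel = site_types == "indel"
    is_snp = site_types == "snp"
    is_invariant = site_types == "invariant"
    report.indels_in = int(is_indel.sum())
    report.sites_in = int((~is_indel).sum())

    chroms = matrix.chroms
    positions = matrix.positions
    quals = np.array([s.qual for s in matrix.sites], dtype=float)

    # indel proximity mask built from high-quality indels
    indel_ok = is_indel & (quals >= config.min_qual)
    report.indels_low_quality = int(is_indel.sum() - indel_ok.sum())
    indel_spans: dict[str, list[tuple[int, int]]] = {}
    for i in np.flatnonzero(indel_ok):
        s = matrix.sites[i]
        indel_spans.setdefault(s.chrom, []).append((s.pos, s.pos + len(s.ref) - 1))

    fails: dict[str, np.ndarray] = {}
    nan_qual = np.isnan(quals)
    if nan_qual.any():
        report.missing_info_events["QUAL"] = int((nan_qual & is_snp).sum())
    fails["qual"] = is_snp & (nan_qual | (quals < config.min_qual))

    for rule, (key, attr, direction) in _SITE_INFO_RULES.items():
        threshold = getattr(config, attr)
        values = np.array(
            [s.info.get(key, np.nan) for s in matrix.sites], dtype=float
        )
        absent = np.isnan(values) & is_snp
        if absent.any():
            report.missing_info_events[key] = int(absent.sum())
        with np.errstate(invalid="ignore"):
            bad = values < threshold if direction == "lt" else values > threshold
        fails[rule] = is_snp & (bad | np.isnan(values))

    fails["indel_proximity"] = is_snp & _near_spans(
        chroms, positions, indel_spans, config.indel_window_bp
    )
    fails["excluded_chromosome"] = ~is_indel & np.isin(
        chroms, list(config.excluded_chromosomes)
    )
    region_fail = np.zeros(matrix.n_sites, dtype=bool)
    for intervals in config.excluded_region_sets.values():
        spans: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            spans.setdefault(chrom, []).append((start, end))
        region_fail |= _near_spans(chroms, positions, spans, 0)
    fails["region_mask"] = ~is_indel & region_fail

    # genotype-level masking (evaluated on all non-indel sites)
    genotypes = matrix.genotypes.copy()
    called_before = genotypes != MISSING

    gq_bad = (matrix.gt_qual >= 0) & (matrix.gt_qual < config.min_gq) & is_snp[:, None]
    rgq_bad = (
        (matrix.gt_qual >= 0) & (matrix.gt_qual < config.min_rgq) & is_invariant[:, None]
    )
    if config.depth_scope == "sample":
        means = np.array([mean_depths[s] for s in matrix.individuals], dtype=float)[None, :]
    else:
        means = np.full(
            (1, matrix.n_individuals), float(np.mean(list(mean_depths.values())))
        )
    dp = matrix.depth
    dp_known = dp >= 0
    dp_bad = dp_known & (
        (dp < means * config.depth_low_factor) | (dp > means * config.depth_high_factor)
    ) & (~is_indel)[:, None]

    report.genotypes_masked["gq"] = int((gq_bad & called_before).sum())
    report.genotypes_masked["rgq"] = int((rgq_bad & called_before).sum())
    report.genotypes_masked["depth"] = int(
        (dp_bad & called_before & ~gq_bad & ~rgq_bad).sum()
    )
    masked = gq_bad | rgq_bad | dp_bad
    genotypes[masked] = MISSING

    miss_src = matrix.genotypes if config.missingness_before_masking else genotypes
    n_ind = matrix.n_individuals
    missing_fraction = (miss_src == MISSING).sum(axis=1) / n_ind
    fails["missingness"] = ~is_indel & (missing_fraction > config.max_missing_fraction)

    # attribute each removed site to the first rule that flagged it
    removed_any = np.zeros(matrix.n_sites, dtype=bool)
    attributed = np.zeros(matrix.n_sites, dtype=bool)
    for rule in RULE_ORDER:
        flag = fails.get(rule)
        if flag is None:
            continue
        removed_any |= flag
        new = flag & ~attributed
        count = int(new.sum())
        if count:
            report.sites_removed[rule] = report.sites_removed.get(rule, 0) + count
        attributed |= flag

    keep = ~is_indel & ~removed_any
    report.sites_surviving = int(keep.sum())
    report.check_identity()

    out = GenotypeMatrix(
        sites=[matrix.sites[i] for i in np.flatnonzero(keep)],
        individuals=list(matrix.individuals),
        genotypes=genotypes[keep],
        depth=matrix.depth[keep],
        gt_qual=matrix.gt_qual[keep],
        populations=dict(matrix.populations),
    )
    return out, report


def _near_spans(
    chroms: np.ndarray,
    positions: np.ndarray,
    spans: dict[str, list[tuple[int, int]]],
    window: int,
) -> np.ndarray:
    """True where a position lies within ``window`` bp of any span (inclusive)."""
    hit = np.zeros(len(positions), dtype=bool)
    if not spans:
        return hit
    for chrom, intervals in spans.items():
        idx = np.flatnonzero(chroms == chrom)
        if idx.size == 0:
            continue
        merged = _merge_intervals(
            [(start - window, end + window) for start, end in intervals]
        )
        starts = [a for a, _ in merged]
        pos = positions[idx]
        where = np.searchsorted(starts, pos, side="right") - 1
        ok = where >= 0
        ends = np.array([merged[w][1] if w >= 0 else -1 for w in where])
        hit[idx] = ok & (pos <= ends)
    return hit


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def subset_region(matrix: GenotypeMatrix, chromosome: str, start: int, end: int) -> GenotypeMatrix:
    """Sites with ``start <= position <= end`` on a chromosome (1-based inclusive)."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    chroms = matrix.chroms
    if chromosome not in chroms:
        logger.warning("chromosome %r not present; returning empty matrix", chromosome)
    positions = matrix.positions
    keep = (chroms == chromosome) & (positions >= start) & (positions <= end)
    return matrix.take_sites(keep)
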