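"""Synthetic datasets with known truth for every stage of the pipeline.

The generator emulates the study design the pipeline targets: three ingroup
populations of strongly contrasting diversity (an almost-clonal islet
population, a larger islet population, and an abundant mainland sister
species, per-site heterozygosity in the ratio 1 : 40 : 1400), two outgroup
species fixed for the ancestral allele except at a known fraction of
outgroup-branch mutation sites, effect-class annotations with
class-dependent GERP score distributions (synonymous mean -0.87, missense
1.9, nonsense 2.3), and planted ROH tracts of known total genome fraction.

Sites are independent: per-population derived-allele frequencies are drawn
from a symmetric Beta tuned so the expected Hardy-Weinberg heterozygosity
hits the target theta, genotypes are drawn under Hardy-Weinberg outside the
planted ROH tracts and forced homozygous inside them. No linkage is
simulated (ROH structure is planted explicitly, the only LD-dependent
quantity in scope).

A separate forward Wright-Fisher simulator with recessive multiplicative
selection provides the purging oracle (small focal population against a
large reference), and a tract-based constant-Ne coalescent generator
provides ROH sets for validating the recent-Ne reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_io import GenotypeMatrix, SiteRecord, MISSING
from .roh_demography import ROHInterval, MB

_NONSENSE_TERMS = (
    "stop_gained",
    "start_gained",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
)
_OTHER_TERMS = ("intron_variant", "intergenic_region", "3_prime_UTR_variant")
_CLASS_FIRST_TERM = {
    "synonymous": ("synonymous_variant",),
    "missense": ("missense_variant",),
    "nonsense": _NONSENSE_TERMS,
    "other": _OTHER_TERMS,
}


@dataclass
class ROHSpec:
    """Planted-tract geometry: lognormal lengths, minimum inter-tract gap."""

    median_length_bp: int = 5 * MB
    sigma_log: float = 0.5
    min_gap_bp: int = 500_000


@dataclass
class PopulationSpec:
    """One ingroup population: sample count, diversity, planted inbreeding.

    ``roh`` sets the planted-tract geometry for this population (falls back
    to the config-level spec); near-clonal populations need long tracts for
    high F_ROH targets to be placeable.
    """

    name: str
    n_samples: int
    theta: float  # target per-site Hardy-Weinberg het probability outside ROH
    target_froh: float = 0.0
    roh: ROHSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 0.5:
            raise ValueError("theta must be in (0, 0.5)")
        if not 0.0 <= self.target_froh < 1.0:
            raise ValueError("target_froh must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic dataset.

    The three default populations mirror the 1 : 40 : 1400 diversity regime
    (theta 3.4e-6 / 1.36e-4 / 4.76e-3) with planted F_ROH 0.98 / 0.48 / 0,
    ten samples each; outgroup A has four individuals (support threshold 3)
    and outgroup B two.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 50 * MB
    n_sites: int = 200_000
    n_invariant_sites: int = 2_000
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("LC", 10, 3.4e-6, 0.98, ROHSpec(median_length_bp=40 * MB)),
        PopulationSpec("ST", 10, 1.36e-4, 0.48, ROHSpec(median_length_bp=1_500_000)),
        PopulationSpec("SI", 10, 4.76e-3, 0.0),
    )
    n_outgroup_a: int = 4
    n_outgroup_b: int = 2
    outgroup_a_name: str = "outgroupA"
    outgroup_b_name: str = "outgroupB"
    outgroup_mutation_prob: float = 0.01  # per site per outgroup individual
    effect_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": 0.30,
            "missense": 0.50,
            "nonsense": 0.05,
            "other": 0.15,
        }
    )
    gerp_means: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": -0.87,
            "missense": 1.9,
            "nonsense": 2.3,
            "other": 0.0,
        }
    )
    gerp_sd: float = 2.0
    mean_depth: float = 15.0
    missing_rate: float = 0.05
    secondary_effect_prob: float = 0.2
    roh: ROHSpec = field(default_factory=ROHSpec)

    def __post_init__(self) -> None:
        total = sum(self.effect_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("effect proportions must sum to 1")


@dataclass
class TruthTable:
    """Planted ground truth, consistent with the emitted files by construction."""

    sites: pd.DataFrame  # chrom, pos, ref, alt, ancestral, ancestral_is_ref,
    #                      effect_class, gerp_score, outgroup_mutated, freq_<pop>...
    roh: list[ROHInterval]
    target_froh: dict[str, float]
    theta: dict[str, float]

    def derived_totals(self, population: str) -> pd.Series:
        """Expected per-class derived totals implied by the planted frequencies
        are not recorded; this returns the realized truth allele frequencies."""
        return self.sites[f"freq_{population}"]


@dataclass
class SimulatedDataset:
    """In-memory dataset plus writers for the standard file formats."""

    matrix: GenotypeMatrix
    annotations: pd.DataFrame  # chrom, pos, effects (comma-separated terms)
    gerp: pd.DataFrame  # chrom, pos, gerp_score
    truth: TruthTable
    config: SimulationConfig

    def annotation_frame(self) -> pd.DataFrame:
        """Resolved annotations (chrom, pos, effect_class, impact, gerp_score)."""
        from .load_metrics import classify_effects

        resolved = [classify_effects(str(e).split(",")) for e in self.annotations["effects"]]
        out = pd.DataFrame(
            {
                "chrom": self.annotations["chrom"],
                "pos": self.annotations["pos"],
                "effect_class": [a.effect_class for a in resolved],
                "impact": [a.impact for a in resolved],
            }
        )
        return out.merge(self.gerp, on=["chrom", "pos"], how="left")

    def write(self, outdir) -> dict[str, Path]:
        """Emit VCF, populations/annotations/GERP TSVs, ROH truth BED, truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "dataset.vcf",
            "populations": outdir / "populations.tsv",
            "annotations": outdir / "annotations.tsv",
            "gerp": outdir / "gerp.tsv",
            "roh_truth": outdir / "roh_truth.bed",
            "truth_sites": outdir / "truth_sites.tsv",
        }
        _write_vcf(self.matrix, self.config, paths["vcf"])
        with open(paths["populations"], "w") as fh:
            for sample in self.matrix.individuals:
                fh.write(f"{sample}\t{self.matrix.populations[sample]}\n")
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.gerp.to_csv(paths["gerp"], sep="\t", index=False, header=False)
        with open(paths["roh_truth"], "w") as fh:
            for iv in self.truth.roh:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.sample}\n")
        self.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def symmetric_beta_frequencies(theta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw allele frequencies from Beta(a, a) with E[2p(1-p)] = theta.

    Solves a/(2a+1) = theta, i.e. a = theta/(1-2 theta). For the tiny shape
    parameters that low-diversity populations require, Gamma samples
    underflow to zero, so the draw uses the log-scale boosting identity
    Gamma(a) = Gamma(a+1) * U^(1/a) and maps the log-ratio through a
    logistic; extreme sites collapse to exactly 0 or 1, whose contribution
    to the expected heterozygosity is below double precision.
    """
    a = theta / (1.0 - 2.0 * theta)
    log_x = np.log(rng.gamma(a + 1.0, size=size)) + np.log(rng.uniform(size=size)) / a
    log_y = np.log(rng.gamma(a + 1.0, size=size)) + np.log(rng.uniform(size=size)) / a
    return expit(log_x - log_y)


def plant_roh_tracts(
    length: int,
    target_fraction: float,
    spec: ROHSpec,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Non-overlapping tracts totalling ``target_fraction`` of a chromosome.

    Tract lengths are lognormal (median ``median_length_bp``); the last tract
    is truncated so the total matches the target exactly (up to integer
    rounding). Tracts are separated by at least ``min_gap_bp``. Raises if
    the target cannot be met with the required gaps.
    """
    target = int(round(target_fraction * length))
    if target <= 0:
        return []
    lengths: list[int] = []
    total = 0
    while total < target:
        l = int(rng.lognormal(np.log(spec.median_length_bp), spec.sigma_log))
        l = max(l, 1)
        if total + l > target:
            l = target - total
        lengths.append(l)
        total += l
    k = len(lengths)
    free = length - target
    if free < spec.min_gap_bp * (k - 1):
        raise ValueError(
            f"cannot place {k} tracts totalling {target} bp in {length} bp "
            f"with {spec.min_gap_bp} bp gaps; lower target_froh or use longer tracts"
        )
    extra = free - spec.min_gap_bp * (k - 1)
    cuts = np.sort(rng.uniform(0.0, 1.0, size=k))
    parts = np.diff(np.concatenate(([0.0], cuts, [1.0]))) * extra
    tracts = []
    pos = float(parts[0])
    for idx, l in enumerate(lengths):
        start = int(round(pos))
        tracts.append((start, start + l))
        pos += l
        if idx < k - 1:
            pos += spec.min_gap_bp + float(parts[idx + 1])
    return tracts


def _chrom_names(n: int) -> list[str]:
    return [f"chr{c + 1:02d}" for c in range(n)]


# ---------------------------------------------------------------------------
# main dataset generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full labeled dataset under the study-condition defaults.

    Sites are placed uniformly over the chromosomes; the ancestral allele is
    ref or alt with equal probability and both outgroups are homozygous
    ancestral except at outgroup-branch mutation sites; ingroup genotypes
    are Hardy-Weinberg draws from per-population Beta frequencies, forced
    homozygous inside each sample's planted ROH tracts. Identical config and
    seed give identical output, including emitted bytes.
    """
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config.n_chromosomes)
    genome = {c: config.chromosome_length for c in chroms}

    # --- site placement (variant + invariant), sorted, unique positions
    n_total = config.n_sites + config.n_invariant_sites
    chrom_idx = rng.integers(0, config.n_chromosomes, size=int(n_total * 1.02) + 10)
    pos = rng.integers(1, config.chromosome_length + 1, size=chrom_idx.size)
    keys = np.unique(chrom_idx.astype(np.int64) * (config.chromosome_length + 1) + pos)
    if keys.size > n_total:
        keys = rng.choice(keys, size=n_total, replace=False)
        keys.sort()
    chrom_of = (keys // (config.chromosome_length + 1)).astype(int)
    pos_of = (keys % (config.chromosome_length + 1)).astype(np.int64)
    n_total = keys.size
    is_variant = np.zeros(n_total, dtype=bool)
    is_variant[rng.choice(n_total, size=min(config.n_sites, n_total), replace=False)] = True

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_total)]
    alt_shift = rng.integers(1, 4, size=n_total)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]

    ancestral_is_ref = rng.random(n_total) < 0.5
    ancestral_is_ref[~is_variant] = True  # invariant sites are hom-ref everywhere

    var = np.flatnonzero(is_variant)
    n_var = var.size

    # --- per-population frequencies and genotypes (derived-allele dosage)
    pops = config.populations
    sample_names: list[str] = []
    populations: dict[str, str] = {}
    for p in pops:
        for i in range(p.n_samples):
            name = f"{p.name}{i + 1:02d}"
            sample_names.append(name)
            populations[name] = p.name
    out_a = [f"OGA{i + 1}" for i in range(config.n_outgroup_a)]
    out_b = [f"OGB{i + 1}" for i in range(config.n_outgroup_b)]
    for name in out_a:
        populations[name] = config.outgroup_a_name
    for name in out_b:
        populations[name] = config.outgroup_b_name
    all_samples = sample_names + out_a + out_b
    n_ind = len(all_samples)

    freq = {p.name: symmetric_beta_frequencies(p.theta, n_var, rng) for p in pops}

    dosage = np.zeros((n_total, n_ind), dtype=np.int8)  # derived-allele count
    col = 0
    roh_truth: list[ROHInterval] = []
    for p in pops:
        f = freq[p.name]
        G = rng.binomial(2, f[:, None], size=(n_var, p.n_samples)).astype(np.int8)
        # planted ROH: force homozygosity (derived with probability f)
        roh_spec = p.roh or config.roh
        for s in range(p.n_samples):
            sample = f"{p.name}{s + 1:02d}"
            if p.target_froh > 0.0:
                for chrom_i, chrom in enumerate(chroms):
                    tracts = plant_roh_tracts(
                        genome[chrom], p.target_froh, roh_spec, rng
                    )
                    for start, end in tracts:
                        roh_truth.append(ROHInterval(sample, chrom, start, end, 1.0))
                        in_tract = (
                            (chrom_of[var] == chrom_i)
                            & (pos_of[var] > start)
                            & (pos_of[var] <= end)
                        )
                        idx = np.flatnonzero(in_tract)
                        G[idx, s] = 2 * (rng.random(idx.size) < f[idx]).astype(np.int8)
        dosage[var, col : col + p.n_samples] = G
        col += p.n_samples

    # --- outgroups: homozygous ancestral, with rare branch mutations
    og_cols = np.arange(col, n_ind)
    out_mut = np.zeros(n_total, dtype=bool)
    for j in og_cols:
        mutated = np.flatnonzero(
            (rng.random(n_var) < config.outgroup_mutation_prob)
        )
        out_mut[var[mutated]] = True
        kind = rng.random(mutated.size) < 0.5  # True -> het, False -> hom-derived
        dosage[var[mutated], j] = np.where(kind, 1, 2).astype(np.int8)

    # --- missingness, depth, genotype quality
    genotypes = np.where(
        ancestral_is_ref[:, None], dosage, 2 - dosage
    ).astype(np.int8)
    genotypes[~is_variant] = 0
    if config.missing_rate > 0:
        miss = rng.random((n_total, n_ind)) < config.missing_rate
        genotypes[miss] = MISSING
    depth = rng.poisson(config.mean_depth, size=(n_total, n_ind)).astype(np.int32)
    depth[genotypes == MISSING] = MISSING
    gt_qual = np.full((n_total, n_ind), 99, dtype=np.int32)
    gt_qual[genotypes == MISSING] = MISSING

    # --- effect classes and GERP scores (variant sites only)
    class_names = list(config.effect_proportions)
    class_probs = np.array([config.effect_proportions[c] for c in class_names])
    class_of_var = rng.choice(len(class_names), size=n_var, p=class_probs)
    means = np.array([config.gerp_means[c] for c in class_names])
    gerp_scores = rng.normal(means[class_of_var], config.gerp_sd)
    all_terms = sorted({t for terms in _CLASS_FIRST_TERM.values() for t in terms})
    first_terms = np.empty(n_var, dtype=object)
    for c, name in enumerate(class_names):
        idx = np.flatnonzero(class_of_var == c)
        choices = np.array(_CLASS_FIRST_TERM[name], dtype=object)
        first_terms[idx] = choices[rng.integers(0, len(choices), size=idx.size)]
    secondary = rng.random(n_var) < config.secondary_effect_prob
    second_terms = np.array(all_terms, dtype=object)[
        rng.integers(0, len(all_terms), size=n_var)
    ]
    effects = [
        f"{first},{second}" if extra else str(first)
        for first, second, extra in zip(first_terms, second_terms, secondary)
    ]

    # --- assemble matrix and tables
    sites = []
    for i in range(n_total):
        chrom = chroms[chrom_of[i]]
        if is_variant[i]:
            sites.append(
                SiteRecord(
                    chrom=chrom,
                    pos=int(pos_of[i]),
                    ref=str(ref[i]),
                    alt=str(alt[i]),
                    site_type="snp",
                    qual=100.0,
                    info={
                        "QD": 25.0,
                        "FS": 0.5,
                        "MQ": 60.0,
                        "MQRankSum": 0.1,
                        "ReadPosRankSum": 0.2,
                        "DP": float(depth[i][depth[i] >= 0].sum()),
                    },
                )
            )
        else:
            sites.append(
                SiteRecord(
                    chrom=chrom,
                    pos=int(pos_of[i]),
                    ref=str(ref[i]),
                    alt=None,
                    site_type="invariant",
                    qual=100.0,
                    info={"DP": float(depth[i][depth[i] >= 0].sum())},
                )
            )
    matrix = GenotypeMatrix(
        sites=sites,
        individuals=all_samples,
        genotypes=genotypes,
        depth=depth,
        gt_qual=gt_qual,
        populations=populations,
    )

    chrom_names_var = [chroms[c] for c in chrom_of[var]]
    annotations = pd.DataFrame(
        {"chrom": chrom_names_var, "pos": pos_of[var], "effects": effects}
    )
    gerp = pd.DataFrame(
        {"chrom": chrom_names_var, "pos": pos_of[var], "gerp_score": gerp_scores}
    )

    truth_sites = pd.DataFrame(
        {
            "chrom": [chroms[c] for c in chrom_of],
            "pos": pos_of,
            "ref": ref,
            "alt": np.where(is_variant, alt, "."),
            "is_variant": is_variant,
            "ancestral_is_ref": ancestral_is_ref,
            "ancestral": np.where(ancestral_is_ref, ref, alt),
            "outgroup_mutated": out_mut,
        }
    )
    eff_full = np.full(n_total, "", dtype=object)
    eff_full[var] = [class_names[c] for c in class_of_var]
    truth_sites["effect_class"] = eff_full
    gerp_full = np.full(n_total, np.nan)
    gerp_full[var] = gerp_scores
    truth_sites["gerp_score"] = gerp_full
    for p in pops:
        f_full = np.zeros(n_total)
        f_full[var] = freq[p.name]
        truth_sites[f"freq_{p.name}"] = f_full

    truth = TruthTable(
        sites=truth_sites,
        roh=roh_truth,
        target_froh={p.name: p.target_froh for p in pops},
        theta={p.name: p.theta for p in pops},
    )
    return SimulatedDataset(
        matrix=matrix, annotations=annotations, gerp=gerp, truth=truth, config=config
    )


def _write_vcf(matrix: GenotypeMatrix, config: SimulationConfig, path: Path) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = sorted({s.chrom for s in matrix.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom},length={config.chromosome_length}>\n")
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            '##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="Reference genotype quality">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.individuals) + "\n")
        for i, site in enumerate(matrix.sites):
            if site.site_type == "snp":
                alt = site.alt
                info = (
                    f"QD={site.info['QD']:g};FS={site.info['FS']:g};MQ={site.info['MQ']:g};"
                    f"MQRankSum={site.info['MQRankSum']:g};"
                    f"ReadPosRankSum={site.info['ReadPosRankSum']:g};DP={int(site.info['DP'])}"
                )
                fmt = "GT:DP:GQ"
            else:
                alt = "."
                info = f"DP={int(site.info['DP'])}"
                fmt = "GT:DP:RGQ"
            cells = []
            for j in range(matrix.n_individuals):
                g = int(matrix.genotypes[i, j])
                dp = int(matrix.depth[i, j])
                q = int(matrix.gt_qual[i, j])
                cells.append(
                    f"{gt_str[g]}:{dp if dp >= 0 else '.'}:{q if q >= 0 else '.'}"
                )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t{site.qual:g}\tPASS\t"
                f"{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# ROH generators
# ---------------------------------------------------------------------------

@dataclass
class FrohGenome:
    """Planted-F genome summarized as het positions plus truth tracts."""

    het_positions: dict[str, np.ndarray]
    tracts: list[ROHInterval]
    chrom_lengths: dict[str, int]
    target_froh: float


def simulate_froh_genome(
    target_froh: float,
    genome_length: int,
    het_rate: float,
    rng: np.random.Generator,
    roh: ROHSpec | None = None,
    chrom: str = "chr01",
    sample: str = "S1",
) -> FrohGenome:
    """One chromosome with planted ROH tracts and Poisson het sites outside.

    Het sites occur at ``het_rate`` per bp outside the tracts and never
    inside, the idealized signal a window-based ROH caller consumes.
    """
    roh = roh or ROHSpec()
    tract_bounds = plant_roh_tracts(genome_length, target_froh, roh, rng)
    n_het = rng.poisson(het_rate * genome_length)
    positions = np.sort(rng.integers(0, genome_length, size=n_het))
    inside = np.zeros(n_het, dtype=bool)
    for start, end in tract_bounds:
        inside |= (positions >= start) & (positions < end)
    return FrohGenome(
        het_positions={chrom: positions[~inside]},
        tracts=[ROHInterval(sample, chrom, s, e, 1.0) for s, e in tract_bounds],
        chrom_lengths={chrom: genome_length},
        target_froh=target_froh,
    )


def simulate_constant_ne_roh(
    ne: float,
    n_samples: int,
    genome_length: int,
    rng: np.random.Generator,
    recombination_rate: float = 2.8,
    chrom: str = "chr01",
    min_length_bp: int = 100_000,
    length_model: str = "deterministic",
) -> dict[str, list[ROHInterval]]:
    """ROH tract sets under a constant-Ne coalescent model of IBD segments.

    Each genome is a mosaic of segments whose parental-lineage coalescence
    time t is geometric with rate 1/(2 Ne) at the locus level; tract
    coalescent times are sampled with probability proportional to
    t x Geom(t) so that the length-weighted (locus-level) time distribution
    is geometric. Under the default ``length_model="deterministic"`` a
    segment of age t has the expected length 100/(2 r t) Mb — the exact
    length-age correspondence the bin-based Ne estimator assumes, so
    recovery tests the implementation rather than the approximation;
    ``"exponential"`` draws lengths from the classical exponential IBD
    segment-length distribution with that mean, which blurs length classes
    and shows the method's intrinsic bias.

    Old segments are short and fall below ROH length classes naturally; only
    segments of at least ``min_length_bp`` are emitted (shorter ones act as
    the inter-ROH spacers a caller would leave), and a single-base spacer
    marks the recombination breakpoint where two emitted segments abut, so
    interval merging downstream preserves segment identity.
    """
    if ne <= 0 or n_samples <= 0 or genome_length <= 0:
        raise ValueError("ne, n_samples and genome_length must be positive")
    if length_model not in ("deterministic", "exponential"):
        raise ValueError("length_model must be 'deterministic' or 'exponential'")
    p = 1.0 / (2.0 * ne)
    t_max = int(np.ceil(2.0 * ne * 16.0))
    t = np.arange(1, t_max + 1, dtype=float)
    geom = p * (1.0 - p) ** (t - 1.0)
    weights = geom * t
    weights /= weights.sum()
    mean_bp = 100.0 * MB / (2.0 * recombination_rate * t)
    overall_mean = float((weights * mean_bp).sum())

    out: dict[str, list[ROHInterval]] = {}
    for s in range(n_samples):
        sample = f"S{s + 1}"
        lengths_parts = []
        total = 0.0
        while total < genome_length:
            n_draw = max(int((genome_length - total) / overall_mean * 1.3), 64)
            ts = rng.choice(t, size=n_draw, p=weights)
            means = 100.0 * MB / (2.0 * recombination_rate * ts)
            drawn = rng.exponential(means) if length_model == "exponential" else means
            lengths_parts.append(drawn)
            total += float(drawn.sum())
        lengths = np.concatenate(lengths_parts)
        ends = np.cumsum(lengths)
        last = int(np.searchsorted(ends, genome_length))
        ends = np.minimum(ends[: last + 1], genome_length).astype(np.int64)
        starts = np.concatenate(([0], ends[:-1]))
        keep = (ends - starts) >= min_length_bp
        out[sample] = [
            ROHInterval(sample, chrom, int(a), int(b) - 1, 1.0)
            for a, b in zip(starts[keep], ends[keep])
            if b - 1 > a
        ]
    return out


# ---------------------------------------------------------------------------
# purging oracle: forward Wright-Fisher with recessive selection
# ---------------------------------------------------------------------------

@dataclass
class PurgingSimConfig:
    """Two-population forward simulation with class-dependent selection.

    Selection is multiplicative and recessive (genotype fitness 1, 1, 1-s);
    the focal population is small, the reference large, both seeded from the
    same standing variation and evolved independently.
    """

    seed: int = 0
    n_sites_per_class: int = 2_000
    ne_reference: int = 200
    ne_focal: int = 20
    generations: int = 100
    selection: dict[str, float] = field(
        default_factory=lambda: {"synonymous": 0.0, "missense": 0.08, "nonsense": 0.2}
    )
    initial_freq: float = 0.1
    n_samples: int = 10
    reference_name: str = "REF"
    focal_name: str = "FOC"

    def __post_init__(self) -> None:
        if self.ne_reference <= 0 or self.ne_focal <= 0 or self.generations <= 0:
            raise ValueError("population sizes and generations must be positive")


def recessive_selection_freq(p, s):
    """Post-selection derived frequency under recessive selection.

    p' = p (1 - s p) / (1 - s p^2); a lethal homozygote (s = 1, p = 1)
    contributes nothing to the next generation, so the limit is 0.
    """
    p = np.asarray(p, dtype=float)
    denom = 1.0 - s * p * p
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0.0, p * (1.0 - s * p) / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.shape else float(out)


@dataclass
class PurgingPairResult:
    """Final state of the two-population purging simulation."""

    config: PurgingSimConfig
    classes: list[str]
    freqs: dict[str, dict[str, np.ndarray]]  # population -> class -> final freq
    sampled_dosage: dict[str, dict[str, np.ndarray]]  # pop -> class -> (sites, n) dosage
    totals: dict[str, dict[str, int]]  # population -> class -> sampled derived total

    def percent_reductions(self) -> dict[str, float | None]:
        from .purging import percent_reduction

        return percent_reduction(
            self.totals, self.config.reference_name, self.config.focal_name
        )

    def write(self, outdir) -> dict[str, Path]:
        """Emit a minimal VCF + annotations + populations file set."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        rows = []
        ann_rows = []
        samples = [f"{cfg.reference_name}{i+1:02d}" for i in range(cfg.n_samples)] + [
            f"{cfg.focal_name}{i+1:02d}" for i in range(cfg.n_samples)
        ]
        vcf_path = outdir / "purging.vcf"
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=chr01,length=1000000000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
            pos = 0
            for cls in self.classes:
                ref_d = self.sampled_dosage[cfg.reference_name][cls]
                foc_d = self.sampled_dosage[cfg.focal_name][cls]
                for k in range(ref_d.shape[0]):
                    pos += 100
                    ann_rows.append(
                        {"chrom": "chr01", "pos": pos, "effects": _CLASS_FIRST_TERM[cls][0]}
                    )
                    cells = [gt_str[int(d)] for d in ref_d[k]] + [
                        gt_str[int(d)] for d in foc_d[k]
                    ]
                    fh.write(
                        f"chr01\t{pos}\t.\tA\tG\t100\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
                    )
        pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        with open(outdir / "populations.tsv", "w") as fh:
            for s in samples:
                pop = cfg.reference_name if s.startswith(cfg.reference_name) else cfg.focal_name
                fh.write(f"{s}\t{pop}\n")
        return {
            "vcf": vcf_path,
            "annotations": outdir / "annotations.tsv",
            "populations": outdir / "populations.tsv",
        }


def simulate_purging_pair(config: PurgingSimConfig) -> PurgingPairResult:
    """Evolve the reference and focal populations and sample final genotypes.

    Per site and generation: deterministic recessive selection on the derived
    frequency followed by binomial drift over 2N gametes. At the end,
    ``n_samples`` diploids per population are drawn under Hardy-Weinberg at
    the final frequencies and per-class derived-allele totals are tallied.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.selection)
    sizes = {config.reference_name: config.ne_reference, config.focal_name: config.ne_focal}
    freqs: dict[str, dict[str, np.ndarray]] = {}
    init = {
        cls: np.full(config.n_sites_per_class, config.initial_freq) for cls in classes
    }
    for pop, n in sizes.items():
        state = {cls: init[cls].copy() for cls in classes}
        for _ in range(config.generations):
            for cls in classes:
                p = recessive_selection_freq(state[cls], config.selection[cls])
                state[cls] = rng.binomial(2 * n, p) / (2.0 * n)
        freqs[pop] = state

    sampled: dict[str, dict[str, np.ndarray]] = {}
    totals: dict[str, dict[str, int]] = {}
    for pop in sizes:
        sampled[pop] = {}
        totals[pop] = {}
        for cls in classes:
            d = rng.binomial(
                2, freqs[pop][cls][:, None], size=(config.n_sites_per_class, config.n_samples)
            )
            sampled[pop][cls] = d.astype(np.int8)
            totals[pop][cls] = int(d.sum())
    return PurgingPairResult(
        config=config, classes=classes, freqs=freqs, sampled_dosage=sampled, totals=totals
    )
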