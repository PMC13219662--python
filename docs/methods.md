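# Methods

`loadscape` re-implements a conservation-genomics workflow for comparing
genetic variation and genetic load across populations of very different
effective size: hard filtering of jointly called genotypes, ancestral-allele
polarization from two outgroup species, partitioning of the genetic load
into masked and realized components per deleteriousness class, purging
contrasts with their statistics, ROH-based inbreeding and recent-Ne
reconstruction, and diversity summaries with an individual-level
neighbor-joining phylogeny. A synthetic-data generator provides fully
labeled inputs with the statistical structure the analysis assumes, so
every stage is testable at desk scale.

## Variant filtering

Filtering operates on already-called multi-sample VCF records (SNPs,
invariant blocks, and indels; variant calling itself is out of scope).
Site-level hard filters for SNPs follow the GATK-style recipe: QUAL < 60,
QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −20.0, ReadPosRankSum < −8.0.
Indels with QUAL ≥ 60 define a proximity mask: SNPs within 5 bp of an
indel's reference span are removed; indels themselves are never genotyped
downstream. Genotype-level masking sets calls to missing when GQ < 10
(variants), RGQ < 10 (invariant sites), or the genotype depth falls outside
the exclusive bounds (mean/3, mean·2). Depth bounds are evaluated against
the *per-sample* genome-wide mean depth by default, because DP is a
per-genotype FORMAT field in the joint-calling toolchain this mirrors; a
cohort-mean alternative is available via `FilterConfig.depth_scope`.
After masking, sites with more than 25% missing genotypes are removed
(`missingness_before_masking` switches this to the raw genotypes). Region
masks (e.g. repeats, high-heterozygosity regions) and an
excluded-chromosome list (e.g. sex chromosomes) remove whole sites.

Every rule is evaluated on the unfiltered input and a removed site is
charged to the first flagging rule in a fixed order (QUAL → QD → FS → MQ →
MQRankSum → ReadPosRankSum → indel proximity → excluded chromosome → region
mask → missingness). The order only affects report attribution, never the
surviving set, and the bookkeeping identity `sites_in = surviving +
Σ removed` is asserted on every run. A site-level rule whose INFO key is
absent fails that site and the event is counted rather than raised, since
rank-sum annotations are routinely absent for records without heterozygous
calls.

## Ancestral-allele polarization

Two outgroup species polarize each biallelic SNP: a distant outgroup A
(four individuals) and a nearer outgroup B (two individuals). Any
heterozygous outgroup genotype discards the site. Otherwise an allele is
the ancestral candidate if it is carried homozygously by at least three
outgroup-A individuals (an absolute count, not a fraction of those called)
and by every non-missing outgroup-B individual, with at least one B
called. If no unique allele qualifies the site is discarded as
non-consensus. A site is *polarized* (analyzable) when, additionally, the
pooled ingroup carries at least one derived allele and the pooled derived
frequency is below one; "pooled" spans all ingroup populations, so an
allele fixed in one population but absent in another remains analyzable.
Statuses partition all SNP sites, and the vectorized dataset path is
checked in tests against a per-site scalar evaluator and against exhaustive
enumeration of all 4^6 outgroup genotype configurations.

No probabilistic ancestral reconstruction is attempted; with two close
outgroups and the heterozygote-discard rule, parsimony misassignment
requires the same derived allele to be homozygous across effectively all
outgroup individuals, which the generator reproduces as a small,
traceable error mode.

## Mutation classes and load partitioning

Effect annotations resolve through a first-term rule: annotators order
effects by putative impact and canonical transcript first, so only the
first term is consulted. The mapping is synonymous → LOW, missense →
MODERATE, and the nonsense set {stop-gained, start-gained, start-lost,
splice-acceptor, splice-donor} → HIGH; anything else is "other".
Evolutionary-constraint classes use GERP scores (supplied as input, not
computed): a site is putatively deleterious when GERP > 4, strictly.
Classes are deliberately not mutually exclusive (high-GERP overlaps
missense and nonsense; combined classes are provided).

Assuming recessivity, each individual's **masked load** in a class is its
count of heterozygous genotypes at polarized class sites and its
**realized load** the count of genotypes homozygous for the derived
allele; missing genotypes contribute to neither. The counting identity
`derived-allele total = masked + 2 × realized` is asserted for every
individual and class on every run. Population-level load is the number of
class sites whose within-population derived frequency exceeds 0.9
(strict), computed over non-missing alleles only; populations with no
called alleles at a site skip it. Total derived-allele counts at
synonymous sites serve as the neutral baseline for cross-population
comparisons. Per-individual counts use each individual's non-missing
genotypes; a normalization by callable class sites is available downstream
of the tidy output if required.

## Purging contrasts

Three contrasts quantify purging of a small focal population against a
large reference:

1. **Percent reduction** per class: `100 × (total_ref − total_focal) /
   total_ref`, with the synonymous baseline alongside. The identity
   `total_ref × (1 − pr/100) = total_focal` is the invariant form (the
   percentage is not antisymmetric under swapping the roles).
2. **GERP profile** per population: mean score and strict proportion > 4
   over the set of derived alleles present (a site counts once if any
   derived copy is present; a frequency-weighted variant is behind a
   flag, since "average deleteriousness of segregating alleles" admits
   both readings).
3. **Statistics**: two-tailed Wilcoxon rank-sum on per-individual masked
   and realized counts for every population pair and class;
   Kruskal–Wallis and pairwise two-sample Kolmogorov–Smirnov on the GERP
   score sets; chi-square without continuity correction on the counts
   above/below the GERP threshold (df = groups − 1). No multiple-testing
   correction is applied, matching the workflow's small test count and
   extreme p-values. Rank tests on groups with fewer than two individuals
   are skipped with a warning. All tests delegate to scipy.stats.

## ROH, F_ROH, and recent Ne

ROH intervals are 0-based half-open with a posterior `p_roh`; external
probabilistic-caller output is read from a BED-like TSV. The built-in
window caller is an explicit stand-in for HMM callers: fixed windows
(default 100 kb) with at most `max_het_per_window` heterozygous sites
(default 0) are ROH, adjacent ROH windows merge, and `p_roh` is set to 1.
Its boundary error is at most one window per tract edge, which drives the
planted-F recovery error budget below. At very sparse site density the
caller saturates (few sites per window means few observable heterozygotes),
so accurate F recovery requires a dense het track — the pipeline inherits
this limitation from the window approximation, not from F_ROH itself.

`F_ROH` is the merged length of confident intervals (`p_roh` > 0.9) at
least 1 Mb long, divided by the callable autosomal genome length — the
genomic inbreeding coefficient.

Recent Ne uses two closed forms: the expected coalescent age of a tract of
length L Mb under recombination rate r cM/Mb, `g = 100/(2 r L)`, and the
expected genome fraction coalesced within t generations at constant Ne,
`F_ROH,t = 1 − (1 − 1/(2 Ne))^t`. Defaults are r = 2.8 cM/Mb (the chicken
map, the nearest available proxy for reptiles) and a generation time of
2 years for reporting ages in years. For each ROH length bin (defaults
[1, 4), [4, 16), [16, 64) Mb — the bin layout is a configuration choice),
the genome fraction in the bin is averaged over individuals, the
representative length is the geometric mean of the bin bounds (arithmetic
midpoint behind a flag), and Ne follows by inverting the second formula at
the age of the first; `ne_trajectory` is exactly this composition, with no
hidden transforms, unit-tested by composing the two public functions. Bins
with zero fraction are reported undetermined.

Numerical note: the coalesced fraction approaches 1 within a few ulp for
small Ne at deep t, so the forward/inverse pair is also exposed in
survival form (`froh_survival`, `ne_from_froh_survival`), following the
cdf/sf convention of distribution libraries; the survival-form round trip
is exact to 10⁻⁹ relative error across Ne ∈ [2, 10⁴], t ∈ [1, 100], while
the F-form is limited near F → 1 by double-precision representability.

## Diversity and phylogeny

Per-individual heterozygosity is the het-genotype count over all
non-missing called sites, variant plus invariant — the denominator
requires the invariant sites to be retained through filtering. SNP counts
per population require both alleles observed within the population's
non-missing calls. Site thinning is greedy left-to-right with a minimum
spacing (default 50 kb) for approximately independent markers. The
pairwise distance is the allele-sharing distance d = 1 − IBS over jointly
genotyped SNP sites (identical genotypes share 2 alleles, het vs
homozygote 1, opposite homozygotes 0); a per-site Hamming alternative was
considered and rejected as the less standard reading of toolkit-style
individual-pair distances. Neighbor joining uses the Studier–Keppler Q
criterion with ties broken by the lowest current index pair (deterministic
output), negative branch lengths clamped to zero with the deficit moved to
the sister branch, and the final three-way join serialized as the Newick
trifurcation. On additive matrices the generating topology and branch
lengths are recovered exactly; tests cross-check the topology against
scikit-bio's NJ.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets: three
ingroup populations whose per-site diversity spans the 1 : 40 : 1400
regime (θ = 3.4×10⁻⁶, 1.36×10⁻⁴, 4.76×10⁻³ for the near-clonal islet
population LC, the larger islet population ST, and the abundant mainland
relative SI; ten samples each), planted F_ROH targets of 0.98 / 0.48 / 0
with population-specific tract scales (median 40 Mb for LC, 1.5 Mb for
ST, matching the contrast between an essentially clonal genome and
moderately inbred one), four outgroup-A and two outgroup-B individuals
homozygous ancestral except at outgroup-branch mutation sites (default
probability 0.01 per site per individual, half heterozygous and half
homozygous-derived), effect classes in proportions 0.30 / 0.50 / 0.05 /
0.15 (synonymous / missense / nonsense / other), and class-dependent
Gaussian GERP scores with means −0.87 / 1.9 / 2.3 / 0 (sd 2.0),
reproducing the observed ordering of constraint across effect classes.
Genotype quality fields are emitted at passing values with Poisson(15)
depths and a 5% missing-genotype rate, so the filter stage runs as it
would on real data.

Sites are independent. Per-population derived-allele frequencies come from
a symmetric Beta(a, a) with a = θ/(1 − 2θ), which makes the expected
Hardy–Weinberg heterozygosity equal θ exactly; for the tiny shapes that
low diversity requires, the draw uses the log-scale Gamma boosting
identity and a logistic map, so extreme sites collapse to exactly 0 or 1
with a heterozygosity contribution below double precision. θ is the
Hardy–Weinberg het probability *outside* ROH; planted tracts force
homozygosity (derived with probability equal to the site frequency), so
observed heterozygosity is reduced by roughly the factor (1 − F), as in
real inbred genomes. A deliberate consequence of the shared symmetric
frequency model is that the expected realized load per site is nearly
equal across populations (E[p²] ≈ 1/2 for all small shapes) while masked
load scales with θ — the generator constructs the
diversity-versus-realized-load decoupling the analysis is designed to
detect, so the regime tests verify the measurement machinery, not a
biological discovery. Because the per-site heterozygosity h = 2p(1−p) is
extremely heavy-tailed under this model, recovery tests condition on the
planted frequencies (binomial genotype noise only) rather than on θ.

What the generator does not emulate: linkage disequilibrium (ROH structure
is planted explicitly; no other LD-dependent statistic is in scope),
sequencing reads and mapping artifacts, site-frequency-spectrum shape
beyond the symmetric Beta family, gene structure (annotations are
i.i.d. site labels), and correlated missingness. Passing tests therefore
demonstrate correctness of the estimators on data satisfying their
assumptions, not robustness to real-data pathologies.

Planted ROH tracts have lognormal lengths (configured median, σ_log 0.5)
placed without overlap with a minimum inter-tract gap (default 0.5 Mb,
which guarantees the window caller at default settings sees at least one
fully heterozygous-bearing window between tracts); the last tract is
truncated so the planted fraction is met exactly, and an infeasible
target/geometry combination is a hard error.

The purging oracle is a per-site forward Wright–Fisher model with
deterministic recessive selection (genotype fitnesses 1, 1, 1 − s)
followed by binomial drift over 2N gametes, run independently in a large
reference (Ne 200) and a small focal population (Ne 20) from shared
standing variation (initial derived frequency 0.1, 2000 sites per class)
for 100 generations, with s = 0 / 0.08 / 0.2 for synonymous / missense /
nonsense. These defaults were set so the model exhibits the graded purging
contrast it exists to produce: at desk scale, s = 0.01 for missense is
statistically indistinguishable from neutral, and runs much longer than
~100 generations let drift in the small population fix mildly deleterious
alleles faster than it purges them, reversing the contrast. Ten diploids
per population are sampled under Hardy–Weinberg at the final frequencies
for the load tables.

The constant-Ne ROH generator tiles a genome with IBD segments whose
locus-level coalescent-time distribution is geometric with rate 1/(2Ne)
(tract times are drawn with probability ∝ t × Geom(t) so that the
length-weighted distribution is geometric). Segment lengths default to the
deterministic expectation L = 100/(2 r t) Mb — precisely the length–age
correspondence the bin-based estimator assumes — so recovery tests isolate
the implementation; with this matched model the estimator's residual bias
is a factor ≈ 1.3–1.5, from binning and the cumulative-form inversion
applied to per-bin fractions. Drawing lengths from the classical
exponential IBD distribution instead (`length_model="exponential"`)
inflates the bias to ≈ 2.5–3, which is the method's intrinsic blur rather
than an implementation defect. Segments below 100 kb are not emitted
(they act as the spacers a real caller would leave), and a single-base
spacer separates abutting emitted segments so interval merging preserves
segment identity.

## Pipeline and reproducibility

Stages hand off through plain files (VCF/TSV/BED), so any stage can run
standalone on external tool outputs. A run serializes its configuration,
writes a manifest with SHA-256 input checksums, per-stage tables, and a
consolidated JSON summary; identical config and inputs reproduce identical
bytes. All randomness in the generators flows from a single integer seed
through `numpy.random.default_rng`. Stage failures abort with the stage
name, leaving partial outputs and a `FAILED` marker.

Problem sizes in the test and acceptance runs (200,000 variant sites over
two 50-Mb chromosomes for the regime replicates, 200-Mb genomes for
planted-F recovery, 2-Gb genomes for Ne recovery, 200 purging replicates)
are the package's chosen desk-scale study conditions; they keep every
stochastic check's sampling error well inside its tolerance.

## Known limitations

- The window ROH caller is a stand-in; it has no posterior model and
  saturates on sparse site tracks (see above).
- Polarization implements the two-outgroup parsimony rule only; sites are
  biallelic SNPs, and more elaborate substitution models are out of scope.
- Load proxies are genotype counts; no dominance- or
  selection-coefficient-weighted load, and no fitness prediction.
- The Ne trajectory inherits the bias of inverting a cumulative
  coalescent-fraction formula on per-bin genome fractions; estimates are
  order-of-magnitude tools, as the factor-2 recovery band reflects.
- Sex chromosomes are handled only as an exclusion list; no hemizygous
  genotype logic.
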