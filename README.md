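# loadscape

Genetic-load partitioning, purging statistics, ROH-based inbreeding and
recent-Ne reconstruction for small-population conservation genomics.

Tiny, long-isolated populations can persist with almost no genomic
variation — provided their burden of deleterious mutations stays within
tolerable bounds. Telling those two quantities apart requires separating
the **masked load** (deleterious alleles hidden in heterozygotes, affecting
future generations) from the **realized load** (expressed in
homozygous-derived genotypes, reducing fitness now), and reading inbreeding
and recent demography directly from runs of homozygosity. `loadscape`
implements that workflow for whole-genome diploid data: it is aimed at
population and conservation geneticists comparing populations of strongly
contrasting effective size from a joint multi-sample VCF.

## What it computes

- **Hard filtering** of called variants: QUAL < 60, QD < 2.0, FS > 60.0,
  MQ < 40.0, MQRankSum < −20.0, ReadPosRankSum < −8.0; genotypes masked at
  GQ/RGQ < 10 or depth outside (mean/3, mean·2); SNPs within 5 bp of a
  high-quality indel, masked regions, and sites with > 25% missingness
  removed — with per-rule accounting.
- **Polarization** of each biallelic SNP into ancestral/derived states from
  two outgroup species (≥ 3 of 4 distant-outgroup individuals plus all
  called near-outgroup individuals homozygous for the ancestral allele;
  heterozygous outgroups discard the site), keeping sites whose derived
  allele segregates but is not fixed in the pooled ingroup.
- **Load partitioning** per deleteriousness class — missense, nonsense,
  GERP > 4, and their combinations, with synonymous as the neutral
  baseline: per individual, masked = het count and realized =
  homozygous-derived count (so derived total = masked + 2·realized); per
  population, the number of class sites at derived frequency > 0.9.
- **Purging contrasts**: class-wise percent reduction of derived-allele
  totals relative to a large reference population; mean GERP and the
  proportion of scores > 4 among derived alleles present; Wilcoxon
  rank-sum, Kruskal–Wallis, Kolmogorov–Smirnov and chi-square comparisons.
- **ROH and demography**: F_ROH = genome fraction in ROH ≥ 1 Mb with
  P(ROH) > 0.9; tract age g = 100/(2rL) generations (r in cM/Mb, L in Mb);
  epoch-wise Ne from length-binned genome fractions via
  F_ROH,t = 1 − (1 − 1/(2Ne))^t. External HMM-caller intervals are
  accepted; a simple window caller is built in as a stand-in.
- **Diversity**: per-individual heterozygosity over callable sites, SNP
  counts per population, 50-kb site thinning, allele-sharing distances
  (d = 1 − IBS), and a deterministic neighbor-joining tree.
- **Synthetic data**: a generator that emulates the full study design
  (three diversity regimes spanning 1 : 40 : 1400, planted ROH, two
  outgroups, class-dependent GERP scores, a forward Wright–Fisher purging
  scenario) with every planted truth recorded, so the whole pipeline is
  testable without sequencing data.

## Worked example

Generate a labeled dataset at the default study conditions (50,000 variant
sites here), polarize it, and partition the load:

```python
import loadscape as ls
from loadscape.load_metrics import align_annotations

ds = ls.simulate_dataset(ls.SimulationConfig(seed=42, n_sites=50_000))
outgroups = ls.OutgroupSpec(("OGA1", "OGA2", "OGA3", "OGA4"), ("OGB1", "OGB2"))
polarized = ls.polarize_dataset(ds.matrix, outgroups, ["LC", "ST", "SI"])
print(polarized.status_counts())

annotations = align_annotations(polarized, ds.annotation_frame())
ingroup = [s for s in ds.matrix.individuals
           if ds.matrix.populations[s] in ("LC", "ST", "SI")]
report = ls.build_load_report(polarized, annotations, ds.matrix,
                              class_specs=("missense",), individuals=ingroup)
ind = report.individual
print(ind.groupby("population")[["masked", "realized"]].mean().round(1))
```

prints

```
{'discarded_fixed_derived': 5700, 'discarded_het_outgroup': 1451,
 'discarded_no_consensus': 1438, 'discarded_no_derived': 5876,
 'polarized': 35535}
            masked  realized
population
LC             0.0    8292.3
SI           109.5    8489.0
ST             2.7    8500.1
```

The masked load tracks diversity across three orders of magnitude
(LC 0.0 → ST 2.7 → SI 109.5 mean het genotypes at missense sites), while
the realized load is level across the three populations (≈ 8,300–8,500
homozygous-derived genotypes each) — the decoupling between genomic
variation and expressed load that motivates the analysis. Mean genome-wide
heterozygosity in the same run is 0, 7.3 × 10⁻⁵ and 4.6 × 10⁻³ for LC, ST
and SI.

The ROH closed forms compose the same way on real intervals:

```python
from loadscape.roh_demography import roh_age, ne_from_froh
g = roh_age(1.5, 2.8)          # 11.905 generations for a 1.5-Mb tract
ne_from_froh(0.3, g)           # Ne ≈ 16.9 if 30% of the genome is in such tracts
```

A shell interface wraps the same stages (`loadscape simulate`, `filter`,
`polarize`, `load`, `purging`, `roh`, `netraj`, `diversity`, `tree`, and
`loadscape run --config run.yaml` for the full pipeline with manifest and
consolidated summary).

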