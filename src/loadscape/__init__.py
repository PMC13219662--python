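"""loadscape: genetic-load partitioning and purging analyses for small populations.

Reimplements a conservation-genomics workflow for whole-genome diploid data:
hard filtering of called variants, ancestral-allele polarization from two
outgroup species, masked/realized genetic-load partitioning by mutation
class (annotation impact and GERP constraint), purging contrasts and their
statistics, ROH-based inbreeding (F_ROH) and recent-Ne reconstruction, and
diversity summaries with a neighbor-joining phylogeny — together with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes, so every stage is testable without sequencing data.
"""

from .genotype_io import (
    FilterConfig,
    FilterReport,
    GenotypeMatrix,
    SiteRecord,
    apply_site_filters,
    read_genotypes,
    subset_region,
)
from .polarization import (
    OutgroupSpec,
    PolarizationResult,
    PolarizedSite,
    assign_ancestral,
    polarize_dataset,
)
from .load_metrics import (
    BUILTIN_CLASSES,
    LoadReport,
    MutationClassSpec,
    SiteAnnotation,
    build_load_report,
    classify_effects,
    derived_allele_totals,
    individual_load,
    population_load,
    read_annotations,
)
from .purging import (
    GerpProfile,
    PurgingSummary,
    compare_groups,
    gerp_profile,
    percent_reduction,
)
from .roh_demography import (
    ROHDemographyConfig,
    ROHInterval,
    call_roh_windows,
    froh,
    froh_expected,
    froh_survival,
    merge_roh_intervals,
    ne_from_froh,
    ne_from_froh_survival,
    ne_trajectory,
    roh_age,
)
from .diversity import (
    DistanceMatrix,
    distance_matrix,
    heterozygosity,
    nj_tree,
    snp_count,
    thin_sites,
)
from .simulate import (
    PopulationSpec,
    PurgingSimConfig,
    ROHSpec,
    SimulationConfig,
    SimulatedDataset,
    TruthTable,
    plant_roh_tracts,
    recessive_selection_freq,
    simulate_constant_ne_roh,
    simulate_dataset,
    simulate_froh_genome,
    simulate_purging_pair,
)
from .pipeline import RunConfig, run_pipeline

__version__ = "0.1.0"
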