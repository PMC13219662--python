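"""End-to-end orchestration: filter -> polarize -> load -> purging -> ROH -> diversity.

Stages hand off through plain files (VCF/TSV/BED), so any stage can also be
run standalone on external tool outputs (for instance ROH intervals from a
probabilistic HMM caller). A run writes per-stage tables, a consolidated
JSON summary, the serialized configuration, and a manifest with input
checksums; re-running with identical config and inputs reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import load_metrics as lm
from . import purging as pg
from . import roh_demography as rd
from .genotype_io import FilterConfig, apply_site_filters, read_genotypes
from .polarization import OutgroupSpec, polarize_dataset

logger = logging.getLogger("loadscape")

DEFAULT_CLASSES = ("synonymous", "missense", "nonsense", "high_gerp")


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    vcf: str
    populations: str
    annotations: str
    outdir: str
    gerp: str | None = None
    roh: str | None = None  # external ROH intervals (TSV); else window caller
    outgroup_a_population: str = "outgroupA"
    outgroup_b_population: str = "outgroupB"
    reference_population: str | None = None  # default: last ingroup population
    mutation_classes: tuple[str, ...] = DEFAULT_CLASSES
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_support_a: int = 3
    freq_threshold: float = 0.9
    genome_length: int | None = None  # default: sum of spanned positions
    roh_window_bp: int = 100_000
    roh_max_het_per_window: int = 0
    recombination_rate: float = 2.8
    generation_time: float = 2.0
    thin_bp: int = 50_000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if "mutation_classes" in raw:
            raw["mutation_classes"] = tuple(raw["mutation_classes"])
        return cls(**raw)

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["mutation_classes"] = list(self.mutation_classes)
        payload["filter"]["excluded_chromosomes"] = list(
            self.filter.excluded_chromosomes
        )
        return yaml.safe_dump(payload, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the consolidated summary dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "setup"
    try:
        (outdir / "run_config.yaml").write_text(config.to_yaml())
        manifest = {}
        for key in ("vcf", "populations", "annotations", "gerp", "roh"):
            path = getattr(config, key)
            if path is not None:
                manifest[key] = {"path": str(path), "sha256": _sha256(path)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

        stage = "read"
        matrix = read_genotypes(config.vcf, config.populations)

        stage = "filter"
        mean_depths = matrix.mean_depths()
        filtered, report = apply_site_filters(matrix, config.filter, mean_depths)
        (outdir / "filter_report.json").write_text(report.to_json())
        (outdir / "filter_report.txt").write_text(report.to_text())

        stage = "polarize"
        all_pops = list(dict.fromkeys(filtered.populations.values()))
        ingroup = [
            p
            for p in all_pops
            if p not in (config.outgroup_a_population, config.outgroup_b_population)
        ]
        spec = OutgroupSpec(
            outgroup_a_samples=tuple(
                filtered.population_samples(config.outgroup_a_population)
            ),
            outgroup_b_samples=tuple(
                filtered.population_samples(config.outgroup_b_population)
            ),
            min_support_a=config.min_support_a,
        )
        polarized = polarize_dataset(filtered, spec, ingroup)
        polarized.to_frame().to_csv(outdir / "polarized_sites.tsv", sep="\t", index=False)

        stage = "load"
        annotations = lm.read_annotations(config.annotations, config.gerp)
        aligned = lm.align_annotations(polarized, annotations)
        ingroup_samples = [
            s for s in filtered.individuals if filtered.populations[s] in ingroup
        ]
        load_report = lm.build_load_report(
            polarized,
            aligned,
            filtered,
            class_specs=config.mutation_classes,
            freq_threshold=config.freq_threshold,
            individuals=ingroup_samples,
        )
        load_report.individual.to_csv(outdir / "individual_load.tsv", sep="\t", index=False)
        load_report.population.to_csv(outdir / "population_load.tsv", sep="\t", index=False)

        stage = "purging"
        reference = config.reference_population or ingroup[-1]
        totals = {
            pop: dict(
                zip(
                    load_report.population[
                        load_report.population["population"] == pop
                    ]["mutation_class"],
                    load_report.population[
                        load_report.population["population"] == pop
                    ]["total_derived"],
                )
            )
            for pop in ingroup
        }
        reductions = {
            pop: pg.percent_reduction(totals, reference, pop)
            for pop in ingroup
            if pop != reference
        }
        profiles = [
            pg.gerp_profile(polarized, aligned["gerp_score"], pop) for pop in ingroup
        ]
        summary_tests = pg.compare_groups(load_report, profiles)
        summary_tests.percent_reduction = reductions
        (outdir / "purging_summary.json").write_text(summary_tests.to_json())
        if summary_tests.tests:
            summary_tests.tests_frame().to_csv(
                outdir / "purging_tests.tsv", sep="\t", index=False
            )

        stage = "roh"
        chroms = filtered.chroms
        positions = filtered.positions
        chrom_lengths = {
            str(c): int(positions[chroms == c].max()) for c in np.unique(chroms)
        }
        genome_length = config.genome_length or sum(chrom_lengths.values())
        roh_config = rd.ROHDemographyConfig(
            genome_length=genome_length,
            recombination_rate=config.recombination_rate,
            generation_time=config.generation_time,
        )
        if config.roh is not None:
            intervals = rd.read_roh_tsv(config.roh)
            by_sample = rd.group_by_sample(intervals)
        else:
            by_sample = {}
            het = filtered.genotypes == 1
            for sample in ingroup_samples:
                j = filtered.individuals.index(sample)
                het_pos = {
                    str(c): positions[(chroms == c) & het[:, j]] - 1
                    for c in np.unique(chroms)
                }
                by_sample[sample] = rd.call_roh_windows(
                    het_pos,
                    chrom_lengths,
                    config.roh_window_bp,
                    config.roh_max_het_per_window,
                    sample=sample,
                )
            rd.write_roh_tsv(
                [iv for ivs in by_sample.values() for iv in ivs],
                outdir / "roh_intervals.tsv",
            )
        froh_table = pd.DataFrame(
            {
                "individual": list(by_sample),
                "population": [
                    filtered.populations.get(s, "unknown") for s in by_sample
                ],
                "froh": [rd.froh(ivs, roh_config) for ivs in by_sample.values()],
            }
        )
        froh_table.to_csv(outdir / "froh.tsv", sep="\t", index=False)
        trajectories = {}
        for pop in ingroup:
            pop_intervals = {
                s: ivs
                for s, ivs in by_sample.items()
                if filtered.populations.get(s) == pop
            }
            if pop_intervals:
                traj = rd.ne_trajectory(pop_intervals, roh_config)
                traj.insert(0, "population", pop)
                trajectories[pop] = traj
        if trajectories:
            pd.concat(trajectories.values(), ignore_index=True).to_csv(
                outdir / "ne_trajectory.tsv", sep="\t", index=False
            )

        stage = "diversity"
        het_rates = dv.heterozygosity(filtered)
        het_rates.loc[ingroup_samples].to_csv(outdir / "heterozygosity.tsv", sep="\t")
        snp_counts = {pop: dv.snp_count(filtered, pop) for pop in ingroup}
        thinned = dv.thin_sites(filtered, config.thin_bp)
        newick = ""
        if thinned.n_individuals >= 3 and (thinned.site_types == "snp").sum() > 0:
            dm = dv.distance_matrix(thinned)
            dm.to_frame().to_csv(outdir / "distance_matrix.tsv", sep="\t")
            newick = dv.nj_tree(dm)
            (outdir / "tree.nwk").write_text(newick + "\n")

        stage = "summary"
        summary = {
            "filter": {
                "sites_in": report.sites_in,
                "sites_surviving": report.sites_surviving,
            },
            "polarization_status_counts": polarized.status_counts(),
            "individual_load": load_report.individual.to_dict(orient="records"),
            "population_load": load_report.population.to_dict(orient="records"),
            "percent_reduction": reductions,
            "gerp_mean": summary_tests.gerp_mean,
            "froh": dict(zip(froh_table["individual"], froh_table["froh"])),
            "snp_counts": snp_counts,
            "heterozygosity": het_rates.loc[ingroup_samples].to_dict(),
            "tree_newick": newick,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float)
        )
        return summary
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
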