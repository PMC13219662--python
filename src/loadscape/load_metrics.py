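"""Mutation-class definitions and masked/realized genetic-load counts.

Deleteriousness is assessed two ways: (i) from annotation impact classes
(synonymous -> LOW, missense -> MODERATE, nonsense-type terms -> HIGH) and
(ii) from evolutionary constraint (GERP score strictly above 4). Assuming
recessivity, each individual's masked load is its count of heterozygous
genotypes at derived deleterious sites, and its realized load the count of
genotypes homozygous for the derived allele. Population-level load is the
number of class sites whose derived allele segregates above frequency 0.9,
with total derived-allele counts at synonymous sites as the neutral
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING, HET, HOM_REF, HOM_ALT
from .polarization import PolarizationResult, STATUS_POLARIZED

logger = logging.getLogger("loadscape")

#: first-term lookup of annotator effect terms; anything else maps to "other".
EFFECT_TABLE: dict[str, tuple[str, str]] = {
    "synonymous_variant": ("synonymous", "LOW"),
    "missense_variant": ("missense", "MODERATE"),
    "stop_gained": ("nonsense", "HIGH"),
    "start_gained": ("nonsense", "HIGH"),
    "start_lost": ("nonsense", "HIGH"),
    "splice_acceptor_variant": ("nonsense", "HIGH"),
    "splice_donor_variant": ("nonsense", "HIGH"),
}

GERP_THRESHOLD = 4.0  # strictly greater-than


@dataclass
class SiteAnnotation:
    """Resolved effect class, impact category, and optional GERP score."""

    effect_class: str = "other"
    impact: str = "other"
    gerp_score: float | None = None


def classify_effects(raw_annotations: Sequence[str]) -> SiteAnnotation:
    """Resolve a site's (ordered) effect-term list to a single annotation.

    Annotators list effects highest-impact and canonical-transcript first, so
    only the first term is consulted; unrecognized or empty lists map to
    "other".
    """
    if not raw_annotations:
        return SiteAnnotation()
    term = str(raw_annotations[0]).strip().lower().replace("-", "_")
    effect_class, impact = EFFECT_TABLE.get(term, ("other", "other"))
    return SiteAnnotation(effect_class=effect_class, impact=impact)


@dataclass(frozen=True)
class MutationClassSpec:
    """A named deterministic predicate over site annotations.

    ``mask`` maps an annotation frame (columns ``effect_class``, ``impact``,
    ``gerp_score``) to a boolean membership vector. Classes need not be
    mutually exclusive (the high-GERP class overlaps missense/nonsense).
    """

    name: str
    mask: Callable[[pd.DataFrame], np.ndarray]

    def __call__(self, annotations: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.mask(annotations), dtype=bool)


def _gerp_gt(df: pd.DataFrame) -> np.ndarray:
    g = pd.to_numeric(df["gerp_score"], errors="coerce")
    return (g > GERP_THRESHOLD).to_numpy()


BUILTIN_CLASSES: dict[str, MutationClassSpec] = {
    "synonymous": MutationClassSpec(
        "synonymous", lambda df: (df["effect_class"] == "synonymous").to_numpy()
    ),
    "missense": MutationClassSpec(
        "missense", lambda df: (df["effect_class"] == "missense").to_numpy()
    ),
    "nonsense": MutationClassSpec(
        "nonsense", lambda df: (df["effect_class"] == "nonsense").to_numpy()
    ),
    "high_gerp": MutationClassSpec("high_gerp", _gerp_gt),
    "high_gerp_missense": MutationClassSpec(
        "high_gerp_missense",
        lambda df: (df["effect_class"] == "missense").to_numpy() & _gerp_gt(df),
    ),
    "high_gerp_nonsense": MutationClassSpec(
        "high_gerp_nonsense",
        lambda df: (df["effect_class"] == "nonsense").to_numpy() & _gerp_gt(df),
    ),
}


def read_annotations(annotations_path, gerp_path=None) -> pd.DataFrame:
    """Load per-site effect terms (TSV: chrom, pos, effects) and GERP scores.

    ``effects`` is a comma-separated ordered term list; the resolved frame has
    one row per site with columns chrom, pos, effect_class, impact,
    gerp_score (NaN where unscored).
    """
    ann = pd.read_csv(
        annotations_path, sep="\t", dtype={"chrom": str, "pos": np.int64, "effects": str}
    )
    resolved = [classify_effects(str(e).split(",") if pd.notna(e) else []) for e in ann["effects"]]
    out = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "pos": ann["pos"],
            "effect_class": [a.effect_class for a in resolved],
            "impact": [a.impact for a in resolved],
            "gerp_score": np.nan,
        }
    )
    if gerp_path is not None:
        gerp = pd.read_csv(
            gerp_path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "gerp_score"],
            dtype={"chrom": str, "pos": np.int64, "gerp_score": float},
            comment="#",
        )
        out = out.drop(columns="gerp_score").merge(gerp, on=["chrom", "pos"], how="left")
    return out


def align_annotations(polarized: PolarizationResult, annotations: pd.DataFrame) -> pd.DataFrame:
    """One annotation row per polarized-result site, in site order.

    Sites without an annotation entry get effect_class/impact "other" and a
    missing GERP score.
    """
    sites = [polarized.matrix.sites[i] for i in polarized.site_index]
    key = pd.DataFrame(
        {
            "chrom": pd.Series([s.chrom for s in sites], dtype=str),
            "pos": pd.Series([s.pos for s in sites], dtype=np.int64),
        }
    )
    merged = key.merge(annotations, on=["chrom", "pos"], how="left")
    merged["effect_class"] = merged["effect_class"].fillna("other")
    merged["impact"] = merged["impact"].fillna("other")
    if "gerp_score" not in merged:
        merged["gerp_score"] = np.nan
    return merged


def _resolve_class(class_spec) -> MutationClassSpec:
    if isinstance(class_spec, str):
        return BUILTIN_CLASSES[class_spec]
    return class_spec


def _class_site_selection(
    polarized: PolarizationResult, annotations: pd.DataFrame, class_spec
) -> np.ndarray:
    """Row mask (over the polarization result) of polarized sites in a class."""
    spec = _resolve_class(class_spec)
    mask = polarized.is_polarized & spec(annotations)
    if not mask.any():
        logger.warning("mutation class %r selects zero polarized sites", spec.name)
    return mask


def individual_load(
    polarized: PolarizationResult,
    annotations: pd.DataFrame,
    matrix: GenotypeMatrix,
    class_spec,
    individuals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-individual masked (het) and realized (hom-derived) counts.

    Restricted to polarized sites of the class; missing genotypes contribute
    to neither component. The returned frame also carries the derived-allele
    total, which equals masked + 2 x realized by the counting identity.
    """
    mask = _class_site_selection(polarized, annotations, class_spec)
    rows = polarized.site_index[mask]
    derived_is_alt = polarized.derived_is_alt[mask]
    if individuals is None:
        individuals = list(matrix.individuals)
    cols = matrix.sample_indices(individuals)
    G = matrix.genotypes[np.ix_(rows, cols)]
    masked = (G == HET).sum(axis=0)
    hom_derived_code = np.where(derived_is_alt, HOM_ALT, HOM_REF)[:, None]
    realized = (G == hom_derived_code).sum(axis=0)
    return pd.DataFrame(
        {
            "individual": list(individuals),
            "population": [matrix.populations[s] for s in individuals],
            "mutation_class": _resolve_class(class_spec).name,
            "masked": masked.astype(int),
            "realized": realized.astype(int),
            "derived_total": (masked + 2 * realized).astype(int),
        }
    )


def population_load(
    polarized: PolarizationResult,
    annotations: pd.DataFrame,
    class_spec,
    freq_threshold: float = 0.9,
) -> dict[str, int]:
    """Count of class sites at high derived frequency (> threshold) per population.

    Frequencies use non-missing alleles only; a population with zero called
    alleles at a site skips that site.
    """
    mask = _class_site_selection(polarized, annotations, class_spec)
    out = {}
    for pop in polarized.populations:
        derived = polarized.derived_count[pop][mask]
        called = polarized.called_count[pop][mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called > 0, derived / np.maximum(called, 1), np.nan)
        out[pop] = int(np.nansum(freq > freq_threshold))
    return out


def derived_allele_totals(
    polarized: PolarizationResult, annotations: pd.DataFrame, class_spec
) -> dict[str, int]:
    """Total derived-allele count per population over the class sites."""
    mask = _class_site_selection(polarized, annotations, class_spec)
    return {
        pop: int(polarized.derived_count[pop][mask].sum())
        for pop in polarized.populations
    }


@dataclass
class LoadReport:
    """Individual- and population-level load tables across mutation classes."""

    individual: pd.DataFrame  # individual, population, mutation_class, masked, realized, derived_total
    population: pd.DataFrame  # population, mutation_class, high_freq_count, total_derived

    def check_conservation(self) -> None:
        """derived_total == masked + 2 * realized for every row."""
        lhs = self.individual["derived_total"]
        rhs = self.individual["masked"] + 2 * self.individual["realized"]
        if not (lhs == rhs).all():
            raise AssertionError("masked/realized conservation identity violated")


def build_load_report(
    polarized: PolarizationResult,
    annotations: pd.DataFrame,
    matrix: GenotypeMatrix,
    class_specs: Sequence = ("synonymous", "missense", "nonsense", "high_gerp"),
    freq_threshold: float = 0.9,
    individuals: Sequence[str] | None = None,
) -> LoadReport:
    ind_tables = []
    pop_rows = []
    for spec in class_specs:
        ind_tables.append(individual_load(polarized, annotations, matrix, spec, individuals))
        high = population_load(polarized, annotations, spec, freq_threshold)
        totals = derived_allele_totals(polarized, annotations, spec)
        for pop in polarized.populations:
            pop_rows.append(
                {
                    "population": pop,
                    "mutation_class": _resolve_class(spec).name,
                    "high_freq_count": high[pop],
                    "total_derived": totals[pop],
                }
            )
    report = LoadReport(
        individual=pd.concat(ind_tables, ignore_index=True),
        population=pd.DataFrame(pop_rows),
    )
    report.check_conservation()
    return report
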