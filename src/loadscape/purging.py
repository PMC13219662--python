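"""Purging contrasts and group-comparison statistics.

Three lines of evidence for purging in small populations are computed:
(1) the percentage reduction in per-population derived-allele totals of each
deleteriousness class relative to a large reference population (with the
synonymous class as the neutral baseline); (2) the mean GERP score and the
proportion of GERP scores strictly above 4 among the derived alleles
present in each population; and (3) nonparametric group comparisons:
two-tailed Wilcoxon rank-sum tests on per-individual load counts,
Kruskal-Wallis and pairwise two-sample Kolmogorov-Smirnov tests on GERP
score distributions, and a chi-square test (no continuity correction) on
counts above/below the GERP threshold. No multiple-testing correction is
applied.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .load_metrics import GERP_THRESHOLD, LoadReport
from .polarization import PolarizationResult

logger = logging.getLogger("loadscape")


@dataclass
class GerpProfile:
    """GERP summary of the derived alleles present in one population."""

    population: str
    mean_score: float
    proportion_above_threshold: float
    scores: np.ndarray
    frequency_weighted: bool = False


@dataclass
class TestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    pvalue: float
    df: int | None = None
    detail: str = ""


@dataclass
class PurgingSummary:
    """Percent reductions, per-population GERP profiles, and test results."""

    percent_reduction: dict[str, dict[str, float | None]] = field(default_factory=dict)
    gerp_mean: dict[str, float] = field(default_factory=dict)
    gerp_proportion_above: dict[str, float] = field(default_factory=dict)
    tests: list[TestResult] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "percent_reduction": self.percent_reduction,
            "gerp_mean": self.gerp_mean,
            "gerp_proportion_above": self.gerp_proportion_above,
            "tests": [asdict(t) for t in self.tests],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.tests])


def percent_reduction(
    totals: Mapping[str, Mapping[str, float]],
    reference_pop: str,
    focal_pop: str,
) -> dict[str, float | None]:
    """Per-class 100 x (total_ref - total_focal) / total_ref.

    ``totals`` maps population -> mutation class -> derived-allele total.
    Classes with a zero reference total are reported as None (undefined).
    The identity total_ref x (1 - pr/100) == total_focal holds whenever the
    value is defined.
    """
    ref = totals[reference_pop]
    focal = totals[focal_pop]
    out: dict[str, float | None] = {}
    for cls in ref:
        r = float(ref[cls])
        if r <= 0:
            logger.warning("zero reference total for class %r; reduction undefined", cls)
            out[cls] = None
        else:
            out[cls] = 100.0 * (r - float(focal[cls])) / r
    return out


def gerp_profile(
    polarized: PolarizationResult,
    gerp_scores: Sequence[float] | pd.Series | np.ndarray,
    population: str,
    frequency_weighted: bool = False,
) -> GerpProfile:
    """GERP score set of the derived alleles present in a population.

    ``gerp_scores`` is aligned to the polarization result rows (NaN where
    unscored). A site contributes once if any derived copy is present in the
    population; with ``frequency_weighted`` each site contributes with
    multiplicity equal to its derived-allele count.
    """
    scores = np.asarray(pd.to_numeric(pd.Series(gerp_scores), errors="coerce"), dtype=float)
    if scores.shape[0] != len(polarized):
        raise ValueError("gerp_scores must align with the polarization result")
    derived = polarized.derived_count[population]
    present = polarized.is_polarized & (derived > 0) & np.isfinite(scores)
    values = scores[present]
    if frequency_weighted:
        values = np.repeat(values, derived[present])
    if values.size == 0:
        logger.warning("population %r has no scored derived alleles", population)
        return GerpProfile(population, float("nan"), float("nan"), values, frequency_weighted)
    return GerpProfile(
        population=population,
        mean_score=float(values.mean()),
        proportion_above_threshold=float((values > GERP_THRESHOLD).mean()),
        scores=values,
        frequency_weighted=frequency_weighted,
    )


def compare_groups(
    load_report: LoadReport | None,
    gerp_profiles: Sequence[GerpProfile],
    classes: Sequence[str] | None = None,
) -> PurgingSummary:
    """Run the purging comparison battery across populations.

    Wilcoxon rank-sum (two-sided) on per-individual masked and realized
    counts for every population pair and mutation class; Kruskal-Wallis and
    pairwise KS on the GERP score sets; chi-square (df = n_groups - 1,
    no continuity correction) on the counts above/below the GERP threshold.
    Rank tests on groups with fewer than two individuals are skipped with a
    warning.
    """
    summary = PurgingSummary()
    for prof in gerp_profiles:
        summary.gerp_mean[prof.population] = prof.mean_score
        summary.gerp_proportion_above[prof.population] = prof.proportion_above_threshold

    if load_report is not None:
        ind = load_report.individual
        if classes is None:
            classes = list(dict.fromkeys(ind["mutation_class"]))
        pops = list(dict.fromkeys(ind["population"]))
        for cls in classes:
            sub = ind[ind["mutation_class"] == cls]
            for p1, p2 in itertools.combinations(pops, 2):
                for component in ("masked", "realized"):
                    x = sub.loc[sub["population"] == p1, component].to_numpy()
                    y = sub.loc[sub["population"] == p2, component].to_numpy()
                    if len(x) < 2 or len(y) < 2:
                        logger.warning(
                            "skipping Wilcoxon %s/%s (%s): group with < 2 individuals",
                            p1, p2, cls,
                        )
                        continue
                    stat, p = stats.ranksums(x, y)
                    summary.tests.append(
                        TestResult(
                            test="wilcoxon_rank_sum",
                            groups=(p1, p2),
                            statistic=float(stat),
                            pvalue=float(p),
                            detail=f"{component} load, class {cls}",
                        )
                    )

    score_sets = {p.population: p.scores for p in gerp_profiles if p.scores.size > 0}
    if len(score_sets) >= 2:
        names = list(score_sets)
        stat, p = stats.kruskal(*score_sets.values())
        summary.tests.append(
            TestResult(
                test="kruskal_wallis",
                groups=tuple(names),
                statistic=float(stat),
                pvalue=float(p),
                df=len(names) - 1,
                detail="GERP score distributions",
            )
        )
        for p1, p2 in itertools.combinations(names, 2):
            res = stats.ks_2samp(score_sets[p1], score_sets[p2])
            summary.tests.append(
                TestResult(
                    test="kolmogorov_smirnov",
                    groups=(p1, p2),
                    statistic=float(res.statistic),
                    pvalue=float(res.pvalue),
                    detail="GERP score distributions",
                )
            )
        table = np.array(
            [
                [
                    int((score_sets[name] > GERP_THRESHOLD).sum()),
                    int((score_sets[name] <= GERP_THRESHOLD).sum()),
                ]
                for name in names
            ]
        )
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
            summary.tests.append(
                TestResult(
                    test="chi_square",
                    groups=tuple(names),
                    statistic=float(chi2),
                    pvalue=float(p),
                    df=int(dof),
                    detail=f"proportion of GERP scores > {GERP_THRESHOLD:g}",
                )
            )
    return summary
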