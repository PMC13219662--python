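"""Effect classification and masked/realized load counting."""

import numpy as np
import pandas as pd
import pytest

import loadscape as ls
from loadscape.genotype_io import MISSING
from loadscape.load_metrics import (
    BUILTIN_CLASSES,
    EFFECT_TABLE,
    classify_effects,
    derived_allele_totals,
    individual_load,
    population_load,
)

from conftest import make_matrix


class TestClassifyEffects:
    @pytest.mark.parametrize(
        "terms, expected_class, expected_impact",
        [
            (["missense_variant", "synonymous_variant"], "missense", "MODERATE"),
            (["stop_gained"], "nonsense", "HIGH"),
            (["synonymous_variant"], "synonymous", "LOW"),
            (["splice_donor_variant", "intron_variant"], "nonsense", "HIGH"),
            (["intergenic_region"], "other", "other"),
            ([], "other", "other"),
            (["Stop-Gained"], "nonsense", "HIGH"),  # case / hyphen normalization
        ],
    )
    def test_first_term_rule(self, terms, expected_class, expected_impact):
        ann = classify_effects(terms)
        assert (ann.effect_class, ann.impact) == (expected_class, expected_impact)

    def test_random_lists_match_table_lookup(self):
        rng = np.random.default_rng(2)
        vocab = list(EFFECT_TABLE) + ["intron_variant", "upstream_gene_variant"]
        for _ in range(1000):
            terms = [vocab[k] for k in rng.integers(0, len(vocab), rng.integers(1, 4))]
            got = classify_effects(terms)
            expected = EFFECT_TABLE.get(terms[0], ("other", "other"))
            assert (got.effect_class, got.impact) == expected


def _tiny_polarized(codes, effect_classes, gerp=None, populations=None):
    """Polarize a small matrix with unanimous hom-ref outgroups (ancestral=ref)."""
    n = codes.shape[0]
    n_in = codes.shape[1]
    full = np.hstack([codes, np.zeros((n, 6), dtype=np.int8)])
    pops = populations or {f"S{i+1}": "P" for i in range(n_in)}
    pops = dict(pops)
    pops.update({f"S{n_in+i+1}": "A" for i in range(4)})
    pops.update({f"S{n_in+5}": "B", f"S{n_in+6}": "B"})
    m = make_matrix(full, populations=pops)
    spec = ls.OutgroupSpec(
        tuple(f"S{n_in+i+1}" for i in range(4)), (f"S{n_in+5}", f"S{n_in+6}")
    )
    ingroups = sorted({pops[f"S{i+1}"] for i in range(n_in)})
    result = ls.polarize_dataset(m, spec, ingroups)
    ann = pd.DataFrame(
        {
            "chrom": [s.chrom for s in m.sites],
            "pos": [s.pos for s in m.sites],
            "effect_class": effect_classes,
            "impact": "x",
            "gerp_score": gerp if gerp is not None else np.nan,
        }
    )
    return m, result, ann


class TestIndividualLoad:
    def test_single_site_genotype_cases(self):
        m, pol, ann = _tiny_polarized(
            np.array([[1, 2, 0]], dtype=np.int8), ["missense"]
        )
        table = individual_load(pol, ann, m, "missense", individuals=["S1", "S2", "S3"])
        assert table["masked"].tolist() == [1, 0, 0]
        assert table["realized"].tolist() == [0, 1, 0]

    def test_counts_and_conservation_identity(self):
        codes = np.array([[1, 0], [1, 0], [2, 0]], dtype=np.int8)
        m, pol, ann = _tiny_polarized(codes, ["missense"] * 3)
        table = individual_load(pol, ann, m, "missense", individuals=["S1"])
        assert (table["masked"][0], table["realized"][0]) == (2, 1)
        assert table["derived_total"][0] == 4 == 2 + 2 * 1

    def test_missing_genotypes_count_for_neither(self):
        codes = np.array([[MISSING, 1]], dtype=np.int8)
        m, pol, ann = _tiny_polarized(codes, ["missense"])
        table = individual_load(pol, ann, m, "missense", individuals=["S1", "S2"])
        assert table["masked"].tolist() == [0, 1]
        assert table["realized"].tolist() == [0, 0]

    def test_matches_bruteforce_recount(self, small_dataset, small_polarized, small_annotations):
        """Vectorized counts equal a direct per-genotype Python tally."""
        m = small_dataset.matrix
        individuals = ["LC01", "ST03", "SI05"]
        table = individual_load(
            small_polarized, small_annotations, m, "missense", individuals=individuals
        )
        mask = small_polarized.is_polarized & (
            small_annotations["effect_class"] == "missense"
        ).to_numpy()
        rows = small_polarized.site_index[mask]
        der_alt = small_polarized.derived_is_alt[mask]
        for k, name in enumerate(individuals):
            j = m.individuals.index(name)
            masked = realized = 0
            for r, da in zip(rows, der_alt):
                g = m.genotypes[r, j]
                if g == 1:
                    masked += 1
                elif (g == 2 and da) or (g == 0 and not da):
                    realized += 1
            assert table["masked"][k] == masked
            assert table["realized"][k] == realized

    def test_empty_class_gives_zeros(self):
        m, pol, ann = _tiny_polarized(np.array([[1, 0]], dtype=np.int8), ["missense"])
        table = individual_load(pol, ann, m, "nonsense", individuals=["S1", "S2"])
        assert table["masked"].tolist() == [0, 0]
        assert table["realized"].tolist() == [0, 0]


class TestPopulationLoad:
    def test_strict_frequency_boundary(self):
        # 10 diploids: derived count 19/20 (> 0.9, counted) vs 18/20 (not)
        site_095 = [2] * 9 + [1]  # 19 derived of 20
        site_090 = [2] * 8 + [1, 1]  # 18 of 20
        codes = np.array([site_095, site_090], dtype=np.int8)
        m, pol, ann = _tiny_polarized(codes, ["missense"] * 2)
        counts = population_load(pol, ann, "missense", freq_threshold=0.9)
        assert counts["P"] == 1

    def test_monotone_in_threshold_and_scan_oracle(self):
        rng = np.random.default_rng(9)
        codes = rng.choice([0, 1, 2, MISSING], size=(200, 8), p=[0.2, 0.2, 0.5, 0.1])
        m, pol, ann = _tiny_polarized(codes, ["missense"] * 200)
        previous = None
        for thr in (0.5, 0.7, 0.9, 0.99):
            counts = population_load(pol, ann, "missense", freq_threshold=thr)
            # brute-force scan over the tidy frame
            frame = pol.to_frame()
            polarized = frame[frame.status == "polarized"]
            expected = int(
                (
                    polarized["derived_P"][polarized["called_P"] > 0]
                    / polarized["called_P"][polarized["called_P"] > 0]
                    > thr
                ).sum()
            )
            assert counts["P"] == expected
            if previous is not None:
                assert counts["P"] <= previous
            previous = counts["P"]


class TestDerivedTotals:
    def test_single_site_total(self):
        codes = np.array([[2, 2, 2, 1, 0]], dtype=np.int8)  # 7 derived alleles
        m, pol, ann = _tiny_polarized(codes, ["missense"])
        assert derived_allele_totals(pol, ann, "missense")["P"] == 7

    def test_additivity_over_disjoint_classes(self, small_polarized, small_annotations):
        syn = derived_allele_totals(small_polarized, small_annotations, "synonymous")
        mis = derived_allele_totals(small_polarized, small_annotations, "missense")
        union_spec = ls.MutationClassSpec(
            "syn_or_mis",
            lambda df: (df["effect_class"].isin(["synonymous", "missense"])).to_numpy(),
        )
        union = derived_allele_totals(small_polarized, small_annotations, union_spec)
        for pop in union:
            assert union[pop] == syn[pop] + mis[pop]

    def test_matches_generator_truth(self, small_dataset, small_polarized, small_annotations):
        """Totals at correctly-polarized sites equal a direct tally of derived
        genotype dosages from the planted truth."""
        m = small_dataset.matrix
        truth = small_dataset.truth.sites
        frame = small_polarized.to_frame().merge(
            truth.loc[truth.is_variant, ["chrom", "pos", "ancestral", "effect_class"]],
            on=["chrom", "pos"],
            suffixes=("", "_truth"),
        )
        class_mask = small_polarized.is_polarized & (
            small_annotations["effect_class"] == "nonsense"
        ).to_numpy()
        correct = (frame.ancestral == frame.ancestral_truth).to_numpy()
        # restrict comparison to correctly polarized sites on both sides
        lhs = int(small_polarized.derived_count["SI"][class_mask & correct].sum())
        cols = m.sample_indices(m.population_samples("SI"))
        rows = small_polarized.site_index[class_mask & correct]
        der_alt = small_polarized.derived_is_alt[class_mask & correct]
        G = m.genotypes[np.ix_(rows, cols)]
        dosage = np.where(der_alt[:, None], G, 2 - G)
        dosage[G == MISSING] = 0
        assert lhs == int(dosage.sum())


class TestConservation:
    def test_identity_holds_for_every_individual_and_class(
        self, small_dataset, small_polarized, small_annotations
    ):
        ingroup = [
            s
            for s in small_dataset.matrix.individuals
            if small_dataset.matrix.populations[s] in ("LC", "ST", "SI")
        ]
        report = ls.build_load_report(
            small_polarized,
            small_annotations,
            small_dataset.matrix,
            class_specs=tuple(BUILTIN_CLASSES),
            individuals=ingroup,
        )
        report.check_conservation()
        lhs = report.individual["derived_total"]
        rhs = report.individual["masked"] + 2 * report.individual["realized"]
        assert (lhs == rhs).all()
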