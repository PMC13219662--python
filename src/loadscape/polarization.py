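"""Ancestral/derived allele assignment from two outgroup species.

The ancestral allele at a biallelic site is the allele carried homozygously
by at least ``min_support_a`` of the distant-outgroup individuals (default 3
of 4) and by every non-missing near-outgroup individual (at least one
called). Any heterozygous outgroup genotype discards the site outright. A
site is analyzable ("polarized") when, in addition, at least one derived
allele is present in the pooled ingroup but the derived allele is not fixed
there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SiteRecord, MISSING, HET, HOM_REF, HOM_ALT

STATUS_POLARIZED = "polarized"
STATUS_HET_OUTGROUP = "discarded_het_outgroup"
STATUS_NO_CONSENSUS = "discarded_no_consensus"
STATUS_FIXED_DERIVED = "discarded_fixed_derived"
STATUS_NO_DERIVED = "discarded_no_derived"

ALL_STATUSES = (
    STATUS_POLARIZED,
    STATUS_HET_OUTGROUP,
    STATUS_NO_CONSENSUS,
    STATUS_FIXED_DERIVED,
    STATUS_NO_DERIVED,
)


@dataclass
class OutgroupSpec:
    """Samples and support thresholds for the two outgroup species.

    ``outgroup_a_samples`` are the distant-outgroup individuals (support
    threshold ``min_support_a`` is absolute, regardless of missingness);
    ``outgroup_b_samples`` are the near-outgroup individuals, all of whose
    non-missing genotypes must agree (``require_all_b``), with at least
    ``min_called_b`` of them called.
    """

    outgroup_a_samples: tuple[str, ...]
    outgroup_b_samples: tuple[str, ...]
    min_support_a: int = 3
    require_all_b: bool = True
    min_called_b: int = 1

    def __post_init__(self) -> None:
        if set(self.outgroup_a_samples) & set(self.outgroup_b_samples):
            raise ValueError("outgroup A and B sample lists overlap")
        if self.min_support_a > len(self.outgroup_a_samples):
            raise ValueError("min_support_a exceeds number of outgroup-A samples")


@dataclass
class PolarizedSite:
    """A site with its polarization outcome and per-population derived counts."""

    site: SiteRecord
    status: str
    ancestral_allele: str | None = None
    derived_allele: str | None = None
    derived_is_alt: bool | None = None
    derived_count: dict[str, int] = field(default_factory=dict)
    called_count: dict[str, int] = field(default_factory=dict)


def assign_ancestral(
    codes_a: Sequence[int],
    codes_b: Sequence[int],
    spec: OutgroupSpec,
) -> tuple[str | None, str]:
    """Ancestral call at one site from outgroup genotype codes.

    Returns ``("ref" | "alt", "assigned")`` or ``(None, <discard status>)``.
    Codes follow the matrix convention (0 hom-ref, 1 het, 2 hom-alt,
    -1 missing).
    """
    a = np.asarray(codes_a, dtype=int)
    b = np.asarray(codes_b, dtype=int)
    if (a == HET).any() or (b == HET).any():
        return None, STATUS_HET_OUTGROUP

    candidates = []
    b_called = b != MISSING
    for code, allele in ((HOM_REF, "ref"), (HOM_ALT, "alt")):
        support_a = int((a == code).sum())
        if support_a < spec.min_support_a:
            continue
        if int(b_called.sum()) < spec.min_called_b:
            continue
        if spec.require_all_b:
            if not (b[b_called] == code).all():
                continue
        else:
            if int((b == code).sum()) < spec.min_called_b:
                continue
        candidates.append(allele)
    if len(candidates) == 1:
        return candidates[0], "assigned"
    return None, STATUS_NO_CONSENSUS


class PolarizationResult:
    """Vectorized polarization outcome over the biallelic SNP sites.

    Behaves as a sequence of :class:`PolarizedSite`; array views are exposed
    for the load computations (``site_index`` into the source matrix,
    ``status``, ``derived_is_alt``, and per-population ``derived_count`` /
    ``called_count`` arrays).
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        site_index: np.ndarray,
        status: np.ndarray,
        derived_is_alt: np.ndarray,
        derived_count: dict[str, np.ndarray],
        called_count: dict[str, np.ndarray],
    ):
        self.matrix = matrix
        self.site_index = site_index
        self.status = status
        self.derived_is_alt = derived_is_alt
        self.derived_count = derived_count
        self.called_count = called_count

    def __len__(self) -> int:
        return len(self.site_index)

    def __getitem__(self, i: int) -> PolarizedSite:
        site = self.matrix.sites[self.site_index[i]]
        status = str(self.status[i])
        if status in (STATUS_HET_OUTGROUP, STATUS_NO_CONSENSUS):
            return PolarizedSite(site=site, status=status)
        der_alt = bool(self.derived_is_alt[i])
        return PolarizedSite(
            site=site,
            status=status,
            ancestral_allele=site.ref if der_alt else site.alt,
            derived_allele=site.alt if der_alt else site.ref,
            derived_is_alt=der_alt,
            derived_count={p: int(c[i]) for p, c in self.derived_count.items()},
            called_count={p: int(c[i]) for p, c in self.called_count.items()},
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def populations(self) -> list[str]:
        return list(self.derived_count)

    def status_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.status, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    @property
    def is_polarized(self) -> np.ndarray:
        return self.status == STATUS_POLARIZED

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: chrom, position, alleles, status, per-population counts."""
        sites = [self.matrix.sites[i] for i in self.site_index]
        anc = np.where(self.derived_is_alt, [s.ref for s in sites], [s.alt for s in sites])
        der = np.where(self.derived_is_alt, [s.alt for s in sites], [s.ref for s in sites])
        informative = ~np.isin(self.status, [STATUS_HET_OUTGROUP, STATUS_NO_CONSENSUS])
        data = {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "status": self.status,
            "ancestral": np.where(informative, anc, "."),
            "derived": np.where(informative, der, "."),
        }
        for pop in self.populations:
            data[f"derived_{pop}"] = self.derived_count[pop]
            data[f"called_{pop}"] = self.called_count[pop]
        return pd.DataFrame(data)


def polarize_dataset(
    matrix: GenotypeMatrix,
    spec: OutgroupSpec,
    ingroup_populations: Sequence[str],
) -> PolarizationResult:
    """Polarize every biallelic SNP site of the matrix.

    Sites without an ancestral call keep their discard status; sites with a
    call are classified as polarized only when the pooled ingroup carries at
    least one derived allele and the pooled derived frequency is below 1.
    """
    if not ingroup_populations:
        raise ValueError("ingroup_populations must be nonempty")
    pop_cols: dict[str, np.ndarray] = {}
    for pop in ingroup_populations:
        samples = matrix.population_samples(pop)
        if not samples:
            raise ValueError(f"ingroup population {pop!r} has zero samples")
        pop_cols[pop] = matrix.sample_indices(samples)

    a_cols = matrix.sample_indices(spec.outgroup_a_samples)
    b_cols = matrix.sample_indices(spec.outgroup_b_samples)

    snp_idx = np.flatnonzero(matrix.site_types == "snp")
    G = matrix.genotypes[snp_idx]
    A = G[:, a_cols]
    B = G[:, b_cols]
    n = len(snp_idx)

    status = np.full(n, STATUS_NO_CONSENSUS, dtype=object)
    het_out = (A == HET).any(axis=1) | (B == HET).any(axis=1)
    status[het_out] = STATUS_HET_OUTGROUP

    b_called = B != MISSING
    n_called_b = b_called.sum(axis=1)
    ok = {}
    for code, allele in ((HOM_REF, "ref"), (HOM_ALT, "alt")):
        support_a = (A == code).sum(axis=1)
        cond = (support_a >= spec.min_support_a) & (n_called_b >= spec.min_called_b)
        if spec.require_all_b:
            agree = ((B == code) | ~b_called).all(axis=1)
            cond &= agree
        else:
            cond &= (B == code).sum(axis=1) >= spec.min_called_b
        ok[allele] = cond
    assigned = ~het_out & (ok["ref"] ^ ok["alt"])
    ancestral_is_ref = ok["ref"] & assigned
    derived_is_alt = np.where(assigned, ancestral_is_ref, False)

    derived_count: dict[str, np.ndarray] = {}
    called_count: dict[str, np.ndarray] = {}
    total_derived = np.zeros(n, dtype=np.int64)
    total_called = np.zeros(n, dtype=np.int64)
    for pop, cols in pop_cols.items():
        P = G[:, cols]
        called = 2 * (P != MISSING).sum(axis=1)
        hets = (P == HET).sum(axis=1)
        hom_alt = (P == HOM_ALT).sum(axis=1)
        hom_ref = (P == HOM_REF).sum(axis=1)
        derived = np.where(derived_is_alt, 2 * hom_alt + hets, 2 * hom_ref + hets)
        derived = np.where(assigned, derived, 0)
        derived_count[pop] = derived.astype(np.int64)
        called_count[pop] = called.astype(np.int64)
        total_derived += derived
        total_called += np.where(assigned, called, 0)

    status[assigned] = STATUS_POLARIZED
    no_derived = assigned & (total_derived == 0)
    status[no_derived] = STATUS_NO_DERIVED
    fixed = assigned & (total_called > 0) & (total_derived == total_called)
    status[fixed] = STATUS_FIXED_DERIVED

    return PolarizationResult(
        matrix=matrix,
        site_index=snp_idx,
        status=status.astype(str),
        derived_is_alt=derived_is_alt,
        derived_count=derived_count,
        called_count=called_count,
    )
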