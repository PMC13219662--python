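"""Diversity summaries and the individual-level distance phylogeny.

Per-individual heterozygosity is the het-genotype count over all callable
(non-missing, variant plus invariant) sites. Per-population SNP counts tally
sites actually polymorphic within the population. Sites can be thinned to a
minimum spacing for approximately independent markers. Pairwise distances
are allele-sharing distances d = 1 - IBS, with IBS the proportion of alleles
shared identical-by-state over jointly genotyped sites, and the tree is a
canonical neighbor-joining agglomeration with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING, HET


def heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Per-individual het rate over callable sites (variant + invariant)."""
    keep = matrix.site_types != "indel"
    G = matrix.genotypes[keep]
    called = (G != MISSING).sum(axis=0)
    hets = (G == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(called > 0, hets / np.maximum(called, 1), np.nan)
    return pd.Series(rate, index=matrix.individuals, name="heterozygosity")


def snp_count(matrix: GenotypeMatrix, population: str) -> int:
    """Sites biallelic-polymorphic within the population's non-missing calls."""
    samples = matrix.population_samples(population)
    if not samples:
        return 0
    cols = matrix.sample_indices(samples)
    keep = matrix.site_types == "snp"
    G = matrix.genotypes[keep][:, cols]
    has_het = (G == HET).any(axis=1)
    has_ref = (G == 0).any(axis=1)
    has_alt = (G == 2).any(axis=1)
    return int((has_het | (has_ref & has_alt)).sum())


def thin_sites(matrix: GenotypeMatrix, min_distance_bp: int = 50_000) -> GenotypeMatrix:
    """Greedy left-to-right thinning to a minimum inter-site spacing.

    A site is kept iff it lies at least ``min_distance_bp`` from the last
    kept site on the same chromosome (the first site of each chromosome is
    always kept).
    """
    chroms = matrix.chroms
    positions = matrix.positions
    keep = np.zeros(matrix.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for i in range(matrix.n_sites):
        chrom, pos = chroms[i], positions[i]
        if chrom not in last or pos - last[chrom] >= min_distance_bp:
            keep[i] = True
            last[chrom] = pos
    return matrix.take_sites(keep)


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distance matrix with per-pair site counts."""

    labels: list[str]
    values: np.ndarray
    sites_used: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise d(i,j) = 1 - IBS over jointly non-missing SNP sites.

    IBS counts shared alleles per site (2 for identical genotypes, 1 for a
    het against a homozygote, 0 for opposite homozygotes) over twice the
    number of jointly genotyped sites. A pair with zero shared sites is an
    error.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least 2 samples")
    keep = matrix.site_types == "snp"
    G = matrix.genotypes[keep].astype(np.int16)
    n = matrix.n_individuals
    values = np.zeros((n, n))
    sites_used = np.zeros((n, n), dtype=np.int64)
    called = G != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {matrix.individuals[i]!r} and {matrix.individuals[j]!r} "
                    "share no genotyped sites"
                )
            shared = (2 - np.abs(G[both, i] - G[both, j])).sum()
            d = 1.0 - shared / (2.0 * m)
            values[i, j] = values[j, i] = d
            sites_used[i, j] = sites_used[j, i] = m
    return DistanceMatrix(list(matrix.individuals), values, sites_used)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, serialized as Newick.

    Canonical Saitou-Nei agglomeration with the Studier-Keppler Q criterion.
    Ties on Q are broken by the lowest current index pair, so output is
    deterministic. Negative branch lengths are clamped to zero with the
    deficit transferred to the sister branch. On additive matrices the
    generating tree (topology and branch lengths) is recovered exactly. The
    tree is unrooted; Newick serialization uses the final three-way join as
    the trifurcating root.
    """
    D = np.array(dm.values, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite")
    n = D.shape[0]
    labels = [_quote(l) for l in dm.labels]
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        h = D[0, 1] / 2.0
        return f"({labels[0]}:{_fmt(h)},{labels[1]}:{_fmt(h)});"

    nodes = list(labels)
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin gives the lexicographically lowest (i, j), i < j
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new_node = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[: m - 2, m - 2] = D2[m - 2, : m - 2] = d_new[keep]
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new_node]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    l0, l1, l2 = (max(x, 0.0) for x in _spread_deficit([l0, l1, l2]))
    return (
        f"({nodes[0]}:{_fmt(l0)},{nodes[1]}:{_fmt(l1)},{nodes[2]}:{_fmt(l2)});"
    )


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _spread_deficit(lengths: list[float]) -> list[float]:
    """Move any negative three-point length onto its sisters, preserving the sum."""
    out = list(lengths)
    for _ in range(2):
        deficit = sum(min(x, 0.0) for x in out)
        if deficit >= 0.0:
            break
        positives = [k for k, x in enumerate(out) if x > 0.0]
        out = [max(x, 0.0) for x in out]
        if positives:
            share = deficit / len(positives)
            for k in positives:
                out[k] = max(out[k] + share, 0.0)
    return out


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label
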