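"""Per-locus diversity statistics for codominant genotype tables.

For a locus with allele frequencies p_i estimated over the gene copies of the
complete-case individuals (missing or partial calls are dropped per locus):

* A  — observed number of alleles
* Ne — effective number of alleles, 1 / sum(p_i^2)
* He — Nei's gene diversity (expected heterozygosity), 1 - sum(p_i^2)
* Ho — observed heterozygosity, the fraction of complete-case individuals
       whose call contains at least two distinct alleles
* H  — Shannon's information index, -sum(p_i * ln p_i) (natural log by
       default, base configurable)

He carries no small-sample correction by default; an unbiased variant with
the 2n/(2n-1) factor is available.  He and Ne are algebraically linked,
He = 1 - 1/Ne, and H >= ln(Ne) with equality iff frequencies are uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import NoDataError
from .seqio import GenotypeTable


@dataclass(frozen=True)
class AlleleFrequencies:
    locus: str
    freqs: dict
    n_individuals: int
    n_gene_copies: int

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError("all frequencies must be positive")


@dataclass(frozen=True)
class LocusStats:
    """Diversity parameters for one locus (values kept at full precision;
    rendering rounds to 4 decimals)."""

    locus: str
    n: int
    A: int
    Ne: float
    Ho: float
    He: float
    H: float

    def rounded(self) -> "LocusStats":
        return LocusStats(
            self.locus,
            self.n,
            self.A,
            round(self.Ne, 4),
            round(self.Ho, 4),
            round(self.He, 4),
            round(self.H, 4),
        )


def allele_frequencies(table: GenotypeTable, locus: str) -> AlleleFrequencies:
    """Allele frequencies over all gene copies of complete-case individuals."""
    if locus not in table.loci:
        raise KeyError(f"unknown locus {locus!r}")
    counts: dict = {}
    n_ind = 0
    for ind in table.individuals:
        call = table.call(ind, locus)
        if call is None:
            continue
        n_ind += 1
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
    if n_ind == 0:
        raise NoDataError(f"locus {locus!r}: all calls missing")
    copies = n_ind * table.ploidy
    return AlleleFrequencies(
        locus=locus,
        freqs={a: c / copies for a, c in sorted(counts.items(), key=lambda kv: str(kv[0]))},
        n_individuals=n_ind,
        n_gene_copies=copies,
    )


def stats_from_frequencies(
    freqs, locus: str = "", n: int = 0, ho: float = float("nan"),
    log_base: float = math.e, unbiased: bool = False, n_gene_copies: int = 0,
) -> LocusStats:
    """Closed-form A / Ne / He / H from a frequency vector (Ho supplied)."""
    p = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    sum_p2 = sum(x * x for x in p)
    he = 1.0 - sum_p2
    if unbiased and n_gene_copies > 1:
        he *= n_gene_copies / (n_gene_copies - 1)
    h = -sum(x * math.log(x) for x in p) / math.log(log_base)
    return LocusStats(locus=locus, n=n, A=len(p), Ne=1.0 / sum_p2, Ho=ho, He=he, H=h)


def locus_stats(
    table: GenotypeTable,
    locus: str,
    log_base: float = math.e,
    unbiased: bool = False,
) -> LocusStats:
    """A, Ne, Ho, He and Shannon's H for one locus (complete cases only)."""
    af = allele_frequencies(table, locus)
    het = 0
    for ind in table.individuals:
        call = table.call(ind, locus)
        if call is not None and len(set(call)) >= 2:
            het += 1
    ho = het / af.n_individuals
    return stats_from_frequencies(
        af.freqs,
        locus=locus,
        n=af.n_individuals,
        ho=ho,
        log_base=log_base,
        unbiased=unbiased,
        n_gene_copies=af.n_gene_copies,
    )


@dataclass(frozen=True)
class LocusSummary:
    """Across-locus means and ranges of the diversity parameters."""

    n_loci: int
    mean_A: float
    mean_A_printed: int  # nearest integer, as printed alongside
    mean_Ne: float
    mean_Ho: float
    mean_He: float
    mean_H: float
    range_A: tuple
    range_Ho: tuple
    range_He: tuple
    range_H: tuple


def summarize_loci(stats) -> LocusSummary:
    """Arithmetic means (4 decimals) and (min, max) ranges over loci."""
    stats = list(stats)
    if not stats:
        raise NoDataError("no loci to summarize")
    k = len(stats)

    def mean(attr):
        return round(sum(getattr(s, attr) for s in stats) / k, 4)

    def rng(attr):
        vals = [getattr(s, attr) for s in stats]
        return (min(vals), max(vals))

    mean_a = sum(s.A for s in stats) / k
    return LocusSummary(
        n_loci=k,
        mean_A=round(mean_a, 4),
        mean_A_printed=round(mean_a),
        mean_Ne=mean("Ne"),
        mean_Ho=mean("Ho"),
        mean_He=mean("He"),
        mean_H=mean("H"),
        range_A=rng("A"),
        range_Ho=rng("Ho"),
        range_He=rng("He"),
        range_H=rng("H"),
    )
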