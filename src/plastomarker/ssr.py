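"""Perfect microsatellite (SSR) detection and motif-class summaries.

The scanner reports every maximal perfect tandem repeat whose copy number
meets a per-unit-length threshold, in the style of the MISA definition file:
the stock thresholds are 10 copies for mononucleotide motifs, 6 for
dinucleotide and 5 for tri- through hexanucleotide motifs, all configurable.

A run that is reportable at several unit sizes (a homopolymer is also a
tandem of a dinucleotide) is reported only at the smallest unit size whose
threshold it meets.  Runs are broken at N.  Motifs are grouped into canonical
classes under cyclic rotation and reverse complementation, the usual
convention by which e.g. TC, CT and GA all belong to class AG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidMotifError
from .seqio import SequenceRecord, revcomp

#: stock MISA-style definition: unit length -> minimum tandem copy count
DEFAULT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SsrThresholds:
    """Minimum tandem copy count per motif unit length (1..6)."""

    min_copies: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.min_copies:
            raise ValueError("thresholds empty")
        for unit, copies in self.min_copies.items():
            if unit not in range(1, 7):
                raise ValueError(f"unit length {unit} outside 1..6")
            if copies < 2:
                raise ValueError(f"minimum copies for unit {unit} must be >= 2")

    @classmethod
    def misa_default(cls) -> "SsrThresholds":
        return cls(dict(DEFAULT_MIN_COPIES))

    @classmethod
    def without_mono(cls) -> "SsrThresholds":
        return cls({u: c for u, c in DEFAULT_MIN_COPIES.items() if u != 1})

    @classmethod
    def parse(cls, text: str) -> "SsrThresholds":
        """Parse "1=10,2=6,..." as used by the command line."""
        pairs = {}
        for item in text.split(","):
            unit, _, copies = item.partition("=")
            pairs[int(unit)] = int(copies)
        return cls(pairs)

    def __contains__(self, unit: int) -> bool:
        return unit in self.min_copies

    def __getitem__(self, unit: int) -> int:
        return self.min_copies[unit]


@dataclass(frozen=True)
class SsrLocus:
    """One maximal perfect tandem repeat.

    ``motif`` is the repeat unit as written on the scanned strand;
    ``canonical`` is its rotation/reverse-complement class.  Coordinates are
    1-based inclusive and satisfy ``end - start + 1 == unit * copies``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical: str
    unit: int
    copies: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit * self.copies:
            raise ValueError(
                f"locus {self.seq_id}:{self.start}-{self.end}: span does not "
                f"equal unit*copies"
            )


def primitive_period(motif: str) -> int:
    """Smallest p such that motif is a tandem tiling of its first p bases."""
    n = len(motif)
    for p in range(1, n + 1):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n  # unreachable


def canonical_motif(motif: str) -> str:
    """Canonical class: lexicographic minimum over all cyclic rotations of the
    motif and of its reverse complement (so TC, CT, GA and AG are all AG)."""
    if not motif or len(motif) > 6 or set(motif) - set("ACGT"):
        raise InvalidMotifError(f"bad motif {motif!r}")
    if primitive_period(motif) != len(motif):
        raise InvalidMotifError(
            f"motif {motif!r} is a repetition of a shorter unit"
        )
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _bool_runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of the maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2] - 1))


def find_ssrs(record: SequenceRecord, thresholds: SsrThresholds | None = None):
    """All maximal perfect tandem repeats of ``record`` meeting ``thresholds``.

    Returns loci sorted by (start, unit).  Soft-masked input should be
    uppercased by the caller (SequenceRecord already enforces uppercase).
    """
    th = thresholds or SsrThresholds.misa_default()
    seq = record.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    not_n = arr != b"N"
    loci = []
    for p in range(1, 7):
        if n < 2 * p:
            continue
        eq = (arr[p:] == arr[:-p]) & not_n[p:] & not_n[:-p]
        for r0, r1 in _bool_runs(eq):
            run_len = int(r1 - r0 + 1) + p  # bases in the tandem run
            if run_len < 2 * p:
                continue
            start0 = int(r0)
            motif = seq[start0 : start0 + p]
            if primitive_period(motif) != p:
                continue  # captured at the smaller period
            locus = _emit(record.id, seq, start0, run_len, p, th)
            if locus is not None:
                loci.append(locus)
    loci.sort(key=lambda l: (l.start, l.unit))
    return loci


def _emit(seq_id, seq, start0, run_len, p, th):
    """Report a primitive-period run at the smallest qualifying unit size."""
    for unit in range(p, 7, p):
        if unit in th and run_len // unit >= th[unit]:
            copies = int(run_len // unit)
            return SsrLocus(
                seq_id=seq_id,
                start=start0 + 1,
                end=start0 + unit * copies,
                motif=seq[start0 : start0 + unit],
                canonical=canonical_motif(seq[start0 : start0 + p]),
                unit=unit,
                copies=copies,
            )
    return None


def merge_compound(loci, max_gap: int):
    """Optional MISA-style compound post-pass: group loci whose gaps are
    ``<= max_gap`` bp into compound tuples.  Off by default; simple loci are
    returned untouched as singleton groups."""
    groups = []
    for locus in sorted(loci, key=lambda l: l.start):
        if groups and locus.start - groups[-1][-1].end - 1 <= max_gap:
            groups[-1].append(locus)
        else:
            groups.append([locus])
    return [tuple(g) for g in groups]


@dataclass
class SsrSummary:
    """Genome-level tally of SSR loci by unit length and canonical class."""

    total: int
    by_unit: dict
    unit_percentages: dict
    by_motif: Counter
    density_kb_per_ssr: float | None
    scanned_length_bp: int

    @property
    def density_undefined(self) -> bool:
        return self.density_kb_per_ssr is None

    def top_classes(self, k: int = 10):
        """Top-k canonical classes by count, ties broken alphabetically."""
        ranked = sorted(self.by_motif.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


def summarize_ssrs(loci, scanned_length_bp: int) -> SsrSummary:
    """Counts and percentages per unit length plus kb-per-SSR density.

    Percentages are ``count / total * 100`` rounded to 2 decimals; the density
    of an empty locus list is flagged undefined rather than raising.
    """
    if scanned_length_bp <= 0:
        raise ValueError("scanned_length_bp must be positive")
    loci = list(loci)
    total = len(loci)
    by_unit = dict(Counter(l.unit for l in loci))
    pct = {
        u: round(c / total * 100, 2) for u, c in sorted(by_unit.items())
    } if total else {}
    by_motif = Counter(l.canonical for l in loci)
    density = scanned_length_bp / 1000 / total if total else None
    return SsrSummary(
        total=total,
        by_unit=dict(sorted(by_unit.items())),
        unit_percentages=pct,
        by_motif=by_motif,
        density_kb_per_ssr=density,
        scanned_length_bp=scanned_length_bp,
    )
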