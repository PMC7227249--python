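"""Quadripartite plastome structure, GC content and positional annotation.

Angiosperm chloroplast genomes are circular with two exact (or near-exact)
reverse-complement copies of a large inverted repeat (IRa/IRb) separating a
large and a small single-copy region (LSC/SSC).  ``detect_quadripartite``
locates the longest disjoint pair of exact reverse-complement intervals on
the circle and labels the two gaps LSC (longer) and SSC (shorter).

``classify_position`` assigns exon / intron / spacer labels against a gene
annotation, resolving nested genes (a gene inside another gene's intron) to
the innermost feature, and names spacers by their flanking genes in genome
coordinate order.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .errors import StructureNotFoundError
from .seqio import GeneFeature, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / IRa / SSC / IRb intervals on a circular genome.

    Intervals are 1-based inclusive and may wrap the origin (start > end).
    ``sequence(irb) == revcomp(sequence(ira))`` and ``|lsc| > |ssc|``.
    """

    lsc: tuple
    ira: tuple
    ssc: tuple
    irb: tuple
    genome_length: int

    def _length(self, interval) -> int:
        s, e = interval
        return e - s + 1 if s <= e else self.genome_length - s + 1 + e

    @property
    def lengths(self) -> dict:
        return {
            "LSC": self._length(self.lsc),
            "IRa": self._length(self.ira),
            "SSC": self._length(self.ssc),
            "IRb": self._length(self.irb),
        }

    def interval(self, region: str) -> tuple:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}[
            region
        ]

    def _contains(self, interval, coord: int) -> bool:
        s, e = interval
        if s <= e:
            return s <= coord <= e
        return coord >= s or coord <= e

    def region_of(self, coord: int) -> str:
        if not 1 <= coord <= self.genome_length:
            raise ValueError(f"coordinate {coord} outside genome")
        for name in ("LSC", "IRa", "SSC", "IRb"):
            if self._contains(self.interval(name), coord):
                return name
        raise AssertionError("partition does not cover the genome")


@dataclass(frozen=True)
class PositionLabel:
    """exon/intron/spacer call for one genome coordinate."""

    location: str  # exon | intron | spacer
    name: str  # gene name, or "geneA-geneB" for spacers
    region: str  # LSC | SSC | IRa | IRb | NA


# ---------------------------------------------------------------------------
# inverted-repeat detection
# ---------------------------------------------------------------------------


def _maximal_inverted_matches(seq: str, min_len: int):
    """Seed-and-extend search for maximal exact inverted repeats on a circle.

    A match is a pair of equal-length intervals A, B with
    seq[A] == revcomp(seq[B]).  All base pairings of one match share the
    anti-diagonal c = x + y (x on the A side, y on the B side), so seeds are
    grouped per diagonal, merged, and extended once.
    """
    n = len(seq)
    k = max(8, min(21, min_len))
    doubled = seq + seq[:k]
    index = defaultdict(list)
    for i in range(n):
        index[doubled[i : i + k]].append(i)
    diagonals = defaultdict(list)
    for j in range(n):
        for i in index.get(revcomp(doubled[j : j + k]), ()):
            diagonals[i + j + k - 1].append(i)

    matches = set()
    for c, starts in diagonals.items():
        starts = sorted(set(starts))
        segments = []
        for x in starts:
            if segments and x <= segments[-1][1] + 1:
                segments[-1][1] = max(segments[-1][1], x + k - 1)
            else:
                segments.append([x, x + k - 1])
        for xa, xb in segments:
            # extend left of A (pairs with right of B) and right of A
            while (xb - xa + 1) < n and seq[(xa - 1) % n] == _COMP[seq[(c - xa + 1) % n]]:
                xa -= 1
            while (xb - xa + 1) < n and seq[(xb + 1) % n] == _COMP[seq[(c - xb - 1) % n]]:
                xb += 1
            length = xb - xa + 1
            a = (xa % n, (xa + length - 1) % n)
            b = ((c - xb) % n, (c - xa) % n)
            matches.add((length, tuple(sorted((a, b)))))
    return sorted(matches, key=lambda m: (-m[0], m[1]))


def _circ_contains(interval, coord, n):
    s, e = interval
    if s <= e:
        return s <= coord <= e
    return coord >= s or coord <= e


def detect_quadripartite(
    record: SequenceRecord, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Locate IRa/IRb as the longest disjoint exact reverse-complement interval
    pair (each >= ``min_ir_len``) and partition the circle.

    The IR that immediately follows the LSC in genome order is labelled IRa.
    Raises :class:`StructureNotFoundError` when no such pair exists.
    """
    n = len(record)
    if n <= 4 * min_ir_len:
        raise ValueError(
            f"genome of {n} bp too short for min_ir_len={min_ir_len}"
        )
    seq = record.sequence
    for length, (a, b) in _maximal_inverted_matches(seq, min_ir_len):
        if length < min_ir_len:
            break
        if _circ_contains(a, b[0], n) or _circ_contains(b, a[0], n):
            continue  # palindromic self-overlap, not an IR pair
        gap_ab = (b[0] - a[1] - 1) % n  # arc from end(A) to start(B)
        gap_ba = (a[0] - b[1] - 1) % n
        if gap_ab == 0 or gap_ba == 0:
            continue
        if gap_ab >= gap_ba:
            lsc = ((a[1] + 1) % n, (b[0] - 1) % n)
            ssc = ((b[1] + 1) % n, (a[0] - 1) % n)
            ira, irb = b, a
        else:
            lsc = ((b[1] + 1) % n, (a[0] - 1) % n)
            ssc = ((a[1] + 1) % n, (b[0] - 1) % n)
            ira, irb = a, b
        part = QuadripartitePartition(
            lsc=(lsc[0] + 1, lsc[1] + 1),
            ira=(ira[0] + 1, ira[1] + 1),
            ssc=(ssc[0] + 1, ssc[1] + 1),
            irb=(irb[0] + 1, irb[1] + 1),
            genome_length=n,
        )
        residue = n - sum(part.lengths.values())
        if residue:
            logger.warning("partition leaves %d bp unassigned", residue)
        return part
    raise StructureNotFoundError(
        f"no inverted-repeat pair of >= {min_ir_len} bp in {record.id!r}"
    )


def normalize_rotation(record: SequenceRecord, partition: QuadripartitePartition):
    """Rotate a circular genome so the LSC starts at coordinate 1 (the
    conventional plastome origin), returning the rotated record+partition."""
    n = len(record)
    shift = partition.lsc[0] - 1

    def rot(iv):
        s = (iv[0] - 1 - shift) % n + 1
        e = (iv[1] - 1 - shift) % n + 1
        return (s, e)

    seq = record.sequence[shift:] + record.sequence[:shift]
    rotated = SequenceRecord(record.id, seq, record.circular)
    return rotated, QuadripartitePartition(
        lsc=rot(partition.lsc),
        ira=rot(partition.ira),
        ssc=rot(partition.ssc),
        irb=rot(partition.irb),
        genome_length=n,
    )


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def gc_content(source, interval: tuple | None = None) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N is excluded from both numerator and
    denominator.  Returns NaN for an interval with no unambiguous base."""
    if isinstance(source, SequenceRecord):
        seq = source.subseq(*interval) if interval else source.sequence
    else:
        seq = source
        if interval:
            seq = seq[interval[0] - 1 : interval[1]]
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return float("nan")
    return gc / denom


# ---------------------------------------------------------------------------
# positional classification
# ---------------------------------------------------------------------------


def classify_position(
    coord: int,
    features,
    partition: QuadripartitePartition | None = None,
    genome_length: int | None = None,
) -> PositionLabel:
    """exon / intron / spacer label for one 1-based coordinate.

    Nested genes resolve to the innermost (shortest-span) containing feature.
    A spacer is named "A-B" after the nearest flanking genes in coordinate
    order, wrapping circularly at the genome ends.
    """
    region = partition.region_of(coord) if partition else "NA"
    if not features:
        logger.warning("classify_position called with no features")
        return PositionLabel("spacer", "NA-NA", region)
    containing = [f for f in features if f.span[0] <= coord <= f.span[1]]
    if containing:
        inner = min(containing, key=lambda f: f.span[1] - f.span[0])
        for s, e in inner.exons:
            if s <= coord <= e:
                return PositionLabel("exon", inner.name, region)
        return PositionLabel("intron", inner.name, region)
    before = [f for f in features if f.span[1] < coord]
    after = [f for f in features if f.span[0] > coord]
    left = max(before, key=lambda f: f.span[1]) if before else max(
        features, key=lambda f: f.span[1]
    )
    right = min(after, key=lambda f: f.span[0]) if after else min(
        features, key=lambda f: f.span[0]
    )
    return PositionLabel("spacer", f"{left.name}-{right.name}", region)
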