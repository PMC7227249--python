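"""Comparative polymorphism calling over a conspecific plastome alignment.

Given a gapped multiple alignment of chloroplast genomes and a designated
reference genotype, this module calls four marker classes:

* **SNPs** — gap-free, N-free columns with exactly two observed bases;
  columns with three or more bases are reported separately as multi-allelic.
* **Indels** — maximal runs of consecutive columns in which every genotype is
  either fully gapped or fully present (and both classes occur); presence is
  reported as the *Insertion* state, absence as *Deletion*, with no ancestral
  inference.  Runs with ragged gap patterns are reported as complex events.
* **SSR copy-number polymorphisms** — perfect-repeat loci found per genotype,
  clustered across genotypes by overlapping homologous alignment intervals,
  and emitted when copy numbers differ.
* **Small inversions** — maximal mismatch runs whose segment equals the
  reverse complement of the reference segment and which are flanked by a pair
  of exact inverted repeats on the reference.  Even-length perfectly
  palindromic segments are invisible to this test (the flip is the identity);
  the detector documents rather than guesses around this blind spot.

All reference coordinates are 1-based positions in the reference genotype's
ungapped sequence.  Columns containing N are excluded from SNP calling and
break indel runs.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import PlastomarkerError
from .regions import QuadripartitePartition, classify_position
from .seqio import Alignment, SequenceRecord, revcomp
from .ssr import SsrThresholds, find_ssrs

logger = logging.getLogger(__name__)

GAP = b"-"
NBYTE = b"N"


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """A biallelic substitution column.  ``type`` is the unordered base pair
    "X/Y" with X < Y alphabetically; ``states`` maps genotype -> base."""

    ref_coord: int | None
    column: int | None
    type: str
    states: dict
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class MultiAllelicRecord:
    """A gap-free column with three or more observed bases (not a SNP)."""

    ref_coord: int | None
    column: int | None
    type: str
    states: dict
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class IndelRecord:
    """A length polymorphism: ``states`` maps genotype to Insertion (segment
    present) or Deletion (segment absent).  ``ref_coord`` is the reference
    base immediately left of the event (0 if at the start)."""

    ref_coord: int
    length: int
    states: dict
    columns: tuple = (0, 0)
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class ComplexRecord:
    """A gap region whose column-wise gap pattern is not constant."""

    ref_coord: int
    columns: tuple
    patterns: int
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class SsrPolymorphismRecord:
    """An SSR tract whose tandem copy number differs between genotypes."""

    locus_id: str
    motif: str
    canonical: str
    copies: dict
    ref_interval: tuple
    columns: tuple
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class InversionRecord:
    """A small inversion flanked by a reference inverted-repeat pair.

    ``orientation`` maps genotype to "Yes" (inverted relative to the
    reference) or "No"; "NA" marks a genotype whose segment is neither
    orientation (gap or extra substitutions)."""

    ref_interval: tuple
    inv_length: int
    flank_length: int
    orientation: dict
    columns: tuple = (0, 0)
    location: str = "NA"
    region: str = "NA"
    name: str = "NA"


@dataclass
class ColumnAccounting:
    """Column-by-column accounting: every alignment column falls in exactly
    one category, so the counts sum to the alignment length."""

    invariant: int = 0
    snp: int = 0
    multiallelic: int = 0
    indel: int = 0
    complex: int = 0
    masked: int = 0  # columns containing N
    inversion: int = 0  # substitution-like columns inside called inversions

    @property
    def total(self) -> int:
        return (
            self.invariant
            + self.snp
            + self.multiallelic
            + self.indel
            + self.complex
            + self.masked
            + self.inversion
        )


@dataclass
class MarkerSet:
    snps: list
    multiallelic: list
    indels: list
    complex_events: list
    ssr_polymorphisms: list
    inversions: list
    accounting: ColumnAccounting
    excluded_ssr_indels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------


def ref_coord_array(alignment: Alignment, ref_id: str) -> np.ndarray:
    """For each 0-based column, the count of reference bases in columns up to
    and including it (== the 1-based reference coordinate at non-gap columns,
    and the coordinate of the last reference base at gap columns)."""
    row = alignment.matrix[alignment.index(ref_id)]
    return np.cumsum(row != GAP)


def column_to_ref_coord(alignment: Alignment, ref_id: str, column: int):
    """Map a 1-based alignment column to the 1-based reference coordinate, or
    None if the reference is gapped at that column."""
    if not 1 <= column <= alignment.length:
        raise ValueError(f"column {column} outside 1..{alignment.length}")
    row = alignment.matrix[alignment.index(ref_id)]
    if row[column - 1] == GAP:
        return None
    return int((row[:column] != GAP).sum())


# ---------------------------------------------------------------------------
# column scan (SNPs, indels, complex, accounting)
# ---------------------------------------------------------------------------


def _runs_of(mask: np.ndarray):
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2] - 1))


def _scan(alignment: Alignment, ref_id: str):
    M = alignment.matrix
    coords = ref_coord_array(alignment, ref_id)
    gaps = M == GAP
    ns = M == NBYTE
    any_gap = gaps.any(axis=0)
    any_n = ns.any(axis=0)
    masked = any_n
    gapcol = any_gap & ~any_n

    acc = ColumnAccounting(masked=int(masked.sum()))

    # substitution columns: no gap, no N
    clean = ~any_gap & ~any_n
    differs = (M != M[0]).any(axis=0) & clean
    snps, multis = [], []
    for col in np.flatnonzero(differs):
        bases = [chr(b[0]) for b in M[:, col]]
        uniq = sorted(set(bases))
        states = dict(zip(alignment.ids, bases))
        rec_cls = SnpRecord if len(uniq) == 2 else MultiAllelicRecord
        rec = rec_cls(
            ref_coord=int(coords[col]),
            column=int(col) + 1,
            type="/".join(uniq),
            states=states,
        )
        (snps if len(uniq) == 2 else multis).append(rec)
    acc.snp = len(snps)
    acc.multiallelic = len(multis)

    # gap runs: constant pattern -> indel, ragged -> complex
    pattern = (gaps.astype(np.int64) << np.arange(M.shape[0])[:, None]).sum(axis=0)
    indels, complexes = [], []
    for r0, r1 in _runs_of(gapcol):
        pats = pattern[r0 : r1 + 1]
        boundaries = np.flatnonzero(np.diff(pats)) + r0
        if boundaries.size == 0:
            states = {
                name: "Deletion" if gaps[i, r0] else "Insertion"
                for i, name in enumerate(alignment.ids)
            }
            indels.append(
                IndelRecord(
                    ref_coord=int(coords[r0]) - int(M[alignment.index(ref_id), r0] != GAP),
                    length=int(r1 - r0 + 1),
                    states=states,
                    columns=(int(r0) + 1, int(r1) + 1),
                )
            )
            acc.indel += int(r1 - r0 + 1)
        else:
            complexes.append(
                ComplexRecord(
                    ref_coord=max(0, int(coords[r0]) - 1),
                    columns=(int(r0) + 1, int(r1) + 1),
                    patterns=len(set(pats.tolist())),
                )
            )
            acc.complex += int(r1 - r0 + 1)

    acc.invariant = alignment.length - acc.total
    return snps, multis, indels, complexes, acc


def call_snps(alignment: Alignment, ref_id: str, return_multiallelic: bool = False):
    """Biallelic SNPs sorted by reference coordinate.  Columns with gaps or N
    are excluded; columns with >= 3 bases go to the multi-allelic list."""
    snps, multis, *_ = _scan(alignment, ref_id)
    snps.sort(key=lambda r: r.ref_coord)
    if return_multiallelic:
        return snps, multis
    return snps


BASE_PAIRS = ("A/C", "A/G", "A/T", "C/G", "C/T", "G/T")


def snp_spectrum(records) -> dict:
    """Counts over the six unordered base pairs; always sums to len(records)."""
    spectrum = {bp: 0 for bp in BASE_PAIRS}
    for rec in records:
        pair = "/".join(sorted(rec.type.split("/")))
        if pair not in spectrum:
            raise PlastomarkerError(f"not a biallelic SNP type: {rec.type!r}")
        spectrum[pair] += 1
    return spectrum


def call_indels(alignment: Alignment, ref_id: str):
    """Column-consistent gap runs as IndelRecords (complex runs excluded)."""
    *_, indels, _complex, _acc = _scan(alignment, ref_id)
    return indels


def call_indel_events(alignment: Alignment, ref_id: str):
    """(indels, complex_events) from one scan."""
    *_, indels, complexes, _acc = _scan(alignment, ref_id)
    return indels, complexes


# ---------------------------------------------------------------------------
# SSR copy-number polymorphisms
# ---------------------------------------------------------------------------


def _max_tandem_copies(segment: str, motif: str) -> int:
    best = 0
    for m in re.finditer(f"(?:{re.escape(motif)})+", segment):
        best = max(best, (m.end() - m.start()) // len(motif))
    return best


def call_ssr_polymorphisms(
    alignment: Alignment,
    thresholds: SsrThresholds | None = None,
    ref_id: str | None = None,
):
    """SSR loci found per ungapped genotype, clustered across genotypes by
    canonical class and overlapping alignment intervals; a cluster is emitted
    iff tandem copy numbers differ.  A genotype with no qualifying locus
    contributes the copy count actually present in its homologous window
    (0 when the tract is absent)."""
    th = thresholds or SsrThresholds.misa_default()
    ref_id = ref_id or alignment.ids[0]
    coords = ref_coord_array(alignment, ref_id)

    placed = []  # (col_start0, col_end0, genotype, locus)
    for name in alignment.ids:
        row = alignment.row(name)
        pos2col = np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != GAP)
        ung = row.replace("-", "")
        if not ung:
            continue
        for locus in find_ssrs(SequenceRecord(name, ung), th):
            placed.append(
                (int(pos2col[locus.start - 1]), int(pos2col[locus.end - 1]), name, locus)
            )

    clusters = defaultdict(list)  # canonical -> merged interval clusters
    for canon in {p[3].canonical for p in placed}:
        items = sorted((p for p in placed if p[3].canonical == canon))
        merged = []
        for item in items:
            if merged and item[0] <= merged[-1][0][1]:
                merged[-1][0][1] = max(merged[-1][0][1], item[1])
                merged[-1][1].append(item)
            else:
                merged.append([[item[0], item[1]], [item]])
        clusters[canon] = merged

    records = []
    for canon, merged in clusters.items():
        for (c0, c1), items in merged:
            copies = {}
            best = {}
            for _s, _e, name, locus in items:
                if name not in best or locus.copies > best[name].copies:
                    best[name] = locus
            exemplar = max(best.values(), key=lambda l: l.copies)
            for name in alignment.ids:
                if name in best:
                    copies[name] = best[name].copies
                else:
                    window = alignment.row(name)[c0 : c1 + 1].replace("-", "")
                    copies[name] = _max_tandem_copies(window, exemplar.motif)
            if min(copies.values()) != max(copies.values()):
                ref_lo = int(coords[c0])
                ref_hi = int(coords[c1])
                records.append(
                    SsrPolymorphismRecord(
                        locus_id="",
                        motif=exemplar.motif,
                        canonical=canon,
                        copies=copies,
                        ref_interval=(max(ref_lo, 1), ref_hi),
                        columns=(c0 + 1, c1 + 1),
                    )
                )
    records.sort(key=lambda r: r.columns)
    for i, rec in enumerate(records, start=1):
        rec.locus_id = f"cpSSR{i:03d}"
    return records


# ---------------------------------------------------------------------------
# small inversions
# ---------------------------------------------------------------------------


def _largest_flank(ref_ung: str, a: int, b: int, min_flank: int, max_flank: int):
    """Largest f in [min_flank, max_flank] with the f bases left of a equal to
    the reverse complement of the f bases right of b (1-based a..b)."""
    best = None
    for f in range(min_flank, max_flank + 1):
        if a - f < 1 or b + f > len(ref_ung):
            break
        if ref_ung[a - 1 - f : a - 1] == revcomp(ref_ung[b : b + f]):
            best = f
    return best


def detect_inversions(
    alignment: Alignment,
    ref_id: str | None = None,
    min_len: int = 3,
    max_len: int = 30,
    min_flank: int = 10,
    max_flank: int = 40,
):
    """Small inversions relative to the reference genotype.

    For each maximal mismatch run (consecutive columns, no gaps or N) of width
    within [min_len, max_len] between a genotype and the reference, a record
    is emitted iff the genotype segment equals the reverse complement of the
    reference segment AND the reference carries a pair of exact inverted
    repeats of length in [min_flank, max_flank] immediately flanking the run;
    the reported flank length is the largest such f.  Candidates from
    different genotypes sharing the identical interval are merged with
    per-genotype orientations; partially overlapping candidates are reported
    separately with a warning.
    """
    ref_id = ref_id or alignment.ids[0]
    M = alignment.matrix
    ref_idx = alignment.index(ref_id)
    R = M[ref_idx]
    coords = ref_coord_array(alignment, ref_id)
    ref_ung = alignment.ungapped(ref_id)

    candidates = {}
    for name in alignment.ids:
        if name == ref_id:
            continue
        G = M[alignment.index(name)]
        ok = (R != GAP) & (G != GAP) & (R != NBYTE) & (G != NBYTE)
        mm = ok & (R != G)
        for c0, c1 in _runs_of(mm):
            w = int(c1 - c0 + 1)
            if not min_len <= w <= max_len:
                continue
            ref_seg = R[c0 : c1 + 1].tobytes().decode()
            g_seg = G[c0 : c1 + 1].tobytes().decode()
            if g_seg != revcomp(ref_seg):
                continue
            a, b = int(coords[c0]), int(coords[c1])
            flank = _largest_flank(ref_ung, a, b, min_flank, max_flank)
            if flank is None:
                continue
            candidates.setdefault((a, b), (int(c0), int(c1), ref_seg, flank))

    records = []
    intervals = sorted(candidates)
    for i, (a, b) in enumerate(intervals):
        c0, c1, ref_seg, flank = candidates[(a, b)]
        if i and intervals[i - 1][1] >= a and intervals[i - 1] != (a, b):
            logger.warning(
                "partially overlapping inversion candidates at %s and %s",
                intervals[i - 1],
                (a, b),
            )
        orientation = {}
        for name in alignment.ids:
            seg = M[alignment.index(name), c0 : c1 + 1].tobytes().decode()
            if seg == ref_seg:
                orientation[name] = "No"
            elif seg == revcomp(ref_seg):
                orientation[name] = "Yes"
            else:
                orientation[name] = "NA"
        records.append(
            InversionRecord(
                ref_interval=(a, b),
                inv_length=b - a + 1,
                flank_length=flank,
                orientation=orientation,
                columns=(c0 + 1, c1 + 1),
            )
        )
    return records


# ---------------------------------------------------------------------------
# orchestration and annotation
# ---------------------------------------------------------------------------


def call_markers(
    alignment: Alignment,
    ref_id: str | None = None,
    thresholds: SsrThresholds | None = None,
    min_len: int = 3,
    max_len: int = 30,
    min_flank: int = 10,
    max_flank: int = 40,
    exclude_ssr_indels: bool = True,
) -> MarkerSet:
    """Run every caller and reconcile the marker classes.

    An indel whose gap run lies wholly inside an SSR polymorphism cluster is
    a copy-number variant already reported there and is removed from the
    indel list; substitution columns inside a called inversion belong to that
    inversion, not to the SNP list (they move to the accounting's inversion
    category)."""
    ref_id = ref_id or alignment.ids[0]
    snps, multis, indels, complexes, acc = _scan(alignment, ref_id)
    snps.sort(key=lambda r: r.ref_coord)
    ssr_polys = call_ssr_polymorphisms(alignment, thresholds, ref_id)
    inversions = detect_inversions(
        alignment, ref_id, min_len, max_len, min_flank, max_flank
    )
    if inversions:
        inv_cols = set()
        for inv in inversions:
            inv_cols.update(range(inv.columns[0], inv.columns[1] + 1))
        kept_snps = [s for s in snps if s.column not in inv_cols]
        kept_multis = [m for m in multis if m.column not in inv_cols]
        acc.inversion = (len(snps) - len(kept_snps)) + (len(multis) - len(kept_multis))
        acc.snp -= len(snps) - len(kept_snps)
        acc.multiallelic -= len(multis) - len(kept_multis)
        snps, multis = kept_snps, kept_multis
    excluded = []
    if exclude_ssr_indels and ssr_polys:
        spans = [rec.columns for rec in ssr_polys]
        kept = []
        for indel in indels:
            inside = any(
                s0 <= indel.columns[0] and indel.columns[1] <= s1 for s0, s1 in spans
            )
            (excluded if inside else kept).append(indel)
        indels = kept
    return MarkerSet(
        snps=snps,
        multiallelic=multis,
        indels=indels,
        complex_events=complexes,
        ssr_polymorphisms=ssr_polys,
        inversions=inversions,
        accounting=acc,
        excluded_ssr_indels=excluded,
    )


def annotate_markers(
    markers: MarkerSet,
    features=(),
    partition: QuadripartitePartition | None = None,
) -> MarkerSet:
    """Fill location / region / name labels from a gene annotation and a
    quadripartite partition of the reference genome (both optional)."""

    def label(rec, coord):
        if coord < 1:
            coord = 1
        if features or partition:
            pl = classify_position(coord, list(features), partition)
            if features:
                rec.location = pl.location
                rec.name = pl.name
            rec.region = pl.region if partition else "NA"

    for rec in markers.snps + markers.multiallelic:
        label(rec, rec.ref_coord)
    for rec in markers.indels + markers.excluded_ssr_indels:
        label(rec, max(rec.ref_coord, 1))
    for rec in markers.complex_events:
        label(rec, max(rec.ref_coord, 1))
    for rec in markers.ssr_polymorphisms:
        label(rec, rec.ref_interval[0])
    for rec in markers.inversions:
        label(rec, rec.ref_interval[0])
    return markers
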