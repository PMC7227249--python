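"""Readers, writers and shared coordinate conventions.

Every coordinate exposed by this package is 1-based and inclusive, matching
GenBank convention.  Sequences are uppercase DNA over the five-letter alphabet
``{A, C, G, T, N}``; other IUPAC ambiguity codes are rejected rather than
silently converted, because the downstream SSR and SNP logic assumes the
five-letter alphabet.  Alignments additionally allow the gap character ``-``.

Parsing of the standard formats is delegated to Biopython (FASTA, GenBank) and
gffutils (GFF3); this module only enforces the contracts stated above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

SEQ_ALPHABET = frozenset("ACGTN")
ALN_ALPHABET = frozenset("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A single ungapped DNA sequence (a genome, contig or template)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, start=1) if c in bad
            )
            raise FormatError(
                f"record {self.id!r}: illegal character {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.sequence), self.circular)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps around the origin iff circular."""
        n = len(self.sequence)
        if start < 1 or end < 1 or (not self.circular and end > n):
            raise ValueError(f"interval {start}..{end} outside sequence of length {n}")
        if start <= end and end <= n:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError(f"wrapped interval {start}..{end} on a linear sequence")
        # wrapped interval on the circle
        return self.sequence[start - 1 :] + self.sequence[: end % n]


class Alignment:
    """A gapped multiple alignment of conspecific sequences.

    Rows are equal-length strings over ``{A,C,G,T,N,-}``; row order follows the
    source file.  Column indices are 1-based at the interface.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]) -> None:
        ids = list(ids)
        rows = [r.upper() for r in rows]
        if len(ids) != len(rows):
            raise FormatError("alignment ids and rows differ in count")
        if len(rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sequence ids in alignment")
        length = len(rows[0])
        for name, row in zip(ids, rows):
            if len(row) != length:
                raise FormatError(
                    f"ragged alignment: row {name!r} has length {len(row)}, "
                    f"expected {length}"
                )
            bad = set(row) - ALN_ALPHABET
            if bad:
                raise FormatError(f"row {name!r}: illegal characters {sorted(bad)}")
        if length == 0:
            raise FormatError("alignment has zero columns")
        self.ids = ids
        self.rows = rows
        self._index = {name: i for i, name in enumerate(ids)}
        self._matrix: np.ndarray | None = None
        gap_cols = np.flatnonzero((self.matrix == b"-").all(axis=0))
        if gap_cols.size:
            raise FormatError(f"column {int(gap_cols[0]) + 1} is all gaps")

    @property
    def matrix(self) -> np.ndarray:
        """(n_rows, length) byte matrix; lazily built, shared by callers."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self.rows).encode(), dtype="S1"
            ).reshape(len(self.rows), -1)
        return self._matrix

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return self.length

    def index(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def row(self, seq_id: str) -> str:
        return self.rows[self.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )


@dataclass(frozen=True)
class GeneFeature:
    """A gene / tRNA / rRNA with its exon structure.

    ``exons`` are 1-based inclusive intervals in genome coordinate order; the
    gap between consecutive exons is the implied intron.
    """

    name: str
    kind: str  # gene | tRNA | rRNA
    strand: str  # + | -
    exons: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "tRNA", "rRNA"):
            raise FormatError(f"feature {self.name!r}: bad kind {self.kind!r}")
        if self.strand not in "+-":
            raise FormatError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"feature {self.name!r} has no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise FormatError(
                    f"feature {self.name!r}: exons unordered or overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass
class GenotypeTable:
    """Codominant multilocus genotypes.

    ``calls[(individual, locus)]`` is a sorted tuple of ``ploidy`` allele
    labels, or ``None`` for missing.  Partial calls are treated as missing.
    """

    individuals: list
    loci: list
    calls: dict
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise FormatError("ploidy must be >= 2")

    def call(self, individual: str, locus: str):
        return self.calls.get((individual, locus))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _clean_sequence(seq_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - SEQ_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
        raise FormatError(
            f"record {seq_id!r}: illegal character {seq[pos - 1]!r} at position {pos}"
        )
    return seq


def read_fasta(path) -> list:
    """Read a plain FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and U mapped to T; characters outside
    ``{A,C,G,T,N}`` are rejected with their position.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file ("-" gaps) preserving row order."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - ALN_ALPHABET
        if bad:
            raise FormatError(f"row {rec.id!r}: illegal characters {sorted(bad)}")
        rows.append(seq)
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(ids, rows)


def write_alignment(alignment: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank / GFF3 annotations
# ---------------------------------------------------------------------------

_KIND_BY_TYPE = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank_features(path):
    """Read a GenBank flat file into ``(SequenceRecord, [GeneFeature])``.

    ``join()`` locations become multi-exon features; tRNA/rRNA typed features
    take precedence over the plain ``gene`` feature of the same name.
    """
    try:
        gb = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        seq = str(gb.seq)
    except Exception as exc:  # Bio.Seq.UndefinedSequenceError
        raise FormatError(f"{path}: missing ORIGIN sequence") from exc
    if not seq:
        raise FormatError(f"{path}: missing ORIGIN sequence")
    circular = gb.annotations.get("topology", "") == "circular"
    record = SequenceRecord(gb.id or gb.name, _clean_sequence(gb.id, seq), circular)

    by_name: dict = {}
    order: list = []
    for feat in gb.features:
        kind = _KIND_BY_TYPE.get(feat.type)
        if kind is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        exons = sorted(
            (int(part.start) + 1, int(part.end)) for part in feat.location.parts
        )
        if exons[-1][1] > len(record):
            raise FormatError(
                f"feature {name!r} extends to {exons[-1][1]}, beyond sequence "
                f"end {len(record)}"
            )
        strand = "-" if feat.location.strand == -1 else "+"
        gf = GeneFeature(name, kind, strand, tuple(exons))
        if name not in by_name:
            order.append(name)
            by_name[name] = gf
        elif kind != "gene":  # tRNA/rRNA refines a prior plain gene entry
            by_name[name] = gf
    return record, [by_name[n] for n in order]


def read_gff3_features(path) -> list:
    """Read gene/tRNA/rRNA features from GFF3 under the GeneFeature contract.

    exon/CDS sub-features of one gene are merged into its exon list; a gene
    with no sub-features contributes a single exon spanning the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features = []
    for ftype, kind in (("gene", "gene"), ("tRNA", "tRNA"), ("rRNA", "rRNA")):
        for gene in db.features_of_type(ftype, order_by="start"):
            name = (
                gene.attributes.get("Name", [None])[0]
                or gene.attributes.get("gene", [None])[0]
                or gene.id
            )
            intervals = set()
            for child in db.children(gene, featuretype=("exon", "CDS")):
                intervals.add((child.start, child.end))
            if not intervals:
                intervals = {(gene.start, gene.end)}
            merged = _merge_intervals(sorted(intervals))
            strand = gene.strand if gene.strand in "+-" else "+"
            features.append(GeneFeature(name, kind, strand, tuple(merged)))
    features.sort(key=lambda f: f.span)
    return features


def _merge_intervals(intervals):
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# genotype CSV
# ---------------------------------------------------------------------------


def _parse_call(cell: str, ploidy: int, where: str):
    if cell is None:
        return None
    cell = cell.strip()
    if cell in ("", "NA", "na", "NaN"):
        return None
    alleles = cell.split("/")
    if len(alleles) != ploidy:
        raise FormatError(
            f"cell {where}: expected {ploidy} alleles, got {len(alleles)} ({cell!r})"
        )
    out = []
    for a in alleles:
        a = a.strip()
        out.append(int(a) if re.fullmatch(r"\d+", a) else a)
    return tuple(sorted(out, key=str))


def read_genotype_table(path, ploidy: int = 2) -> GenotypeTable:
    """Read a genotype CSV: header of locus names, first column sample id,
    cells of ``ploidy`` allele labels joined by "/", "NA" or empty = missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a sample-id column plus >=1 locus")
    id_col = df.columns[0]
    loci = list(df.columns[1:])
    individuals = list(df[id_col])
    if len(set(individuals)) != len(individuals):
        raise FormatError(f"{path}: duplicate sample ids")
    calls = {}
    for row_i, ind in enumerate(individuals):
        for locus in loci:
            cell = df.at[row_i, locus]
            call = _parse_call(cell, ploidy, where=f"({ind!r}, {locus!r})")
            if call is not None:
                calls[(ind, locus)] = call
    return GenotypeTable(individuals, loci, calls, ploidy)


def write_genotype_table(table: GenotypeTable, path) -> None:
    rows = []
    for ind in table.individuals:
        row = {"id": ind}
        for locus in table.loci:
            call = table.call(ind, locus)
            row[locus] = "NA" if call is None else "/".join(str(a) for a in call)
        rows.append(row)
    pd.DataFrame(rows, columns=["id"] + list(table.loci)).to_csv(path, index=False)
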