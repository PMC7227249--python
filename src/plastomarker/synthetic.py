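"""Synthetic genomes, alignments and genotype tables with planted truth.

Every generator is deterministic in (seed, specification) and records what it
planted in a machine-readable :class:`PlantedTruth`, so the detection modules
can be tested for exact recovery without any external data.  Alignments are
emitted directly as ground truth — genotype rows differ from the base genome
only at planted events, and gap placement is exactly the planted one — which
isolates caller correctness from aligner behaviour.

The default four-genotype scenario mirrors a typical intraspecific plastome
comparison: a ~159 kb quadripartite circular genome and, in its single-copy
regions, 45 substitutions, 17 deletions of 2–458 bp, 5 small inversions of
3–23 bp flanked by 17–29 bp inverted repeats, and 49 mononucleotide SSR
tracts with genotype-specific copy numbers (plus invariant tracts that must
not be called).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import PlacementError
from .seqio import Alignment, GenotypeTable, SequenceRecord, revcomp
from .regions import QuadripartitePartition

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# event specifications and planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SsrPlant:
    offset: int  # 1-based start of the tract
    motif: str
    copies: int


@dataclass(frozen=True)
class SnpPlant:
    pos: int  # 1-based base-genome coordinate
    alt: str
    carriers: tuple  # genotypes carrying the alternate base


@dataclass(frozen=True)
class IndelPlant:
    pos: int  # 1-based start of the deleted segment
    length: int
    carriers: tuple  # genotypes lacking the segment (Deletion state)


@dataclass(frozen=True)
class InversionPlant:
    start: int  # 1-based start of the invertible segment
    length: int
    flank: int  # length of the flanking inverted repeat written into the base
    carriers: tuple  # genotypes carrying the inverted orientation

    @property
    def footprint(self) -> tuple:
        return (self.start - self.flank, self.start + self.length - 1 + self.flank)


@dataclass(frozen=True)
class SsrVariantPlant:
    offset: int
    motif: str
    copies: int  # copies in the base genome / non-carriers
    alt_copies: int  # copies in carriers (alt < copies; tail is gapped)
    carriers: tuple


@dataclass
class MutationSpec:
    snps: list = field(default_factory=list)
    indels: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    ssr_variants: list = field(default_factory=list)


@dataclass
class PlantedTruth:
    """Machine-readable record of everything a generator planted."""

    ssrs: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    indels: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    ssr_variants: list = field(default_factory=list)
    allele_freqs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(obj):
            return asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj

        return json.dumps(
            {
                "ssrs": [enc(x) for x in self.ssrs],
                "snps": [enc(x) for x in self.snps],
                "indels": [enc(x) for x in self.indels],
                "inversions": [enc(x) for x in self.inversions],
                "ssr_variants": [enc(x) for x in self.ssr_variants],
                "allele_freqs": self.allele_freqs,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        raw = json.loads(text)

        def tup(d):
            return {
                k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
            }

        return cls(
            ssrs=[SsrPlant(**tup(d)) for d in raw["ssrs"]],
            snps=[SnpPlant(**tup(d)) for d in raw["snps"]],
            indels=[IndelPlant(**tup(d)) for d in raw["indels"]],
            inversions=[InversionPlant(**tup(d)) for d in raw["inversions"]],
            ssr_variants=[SsrVariantPlant(**tup(d)) for d in raw["ssr_variants"]],
            allele_freqs=raw["allele_freqs"],
        )


# ---------------------------------------------------------------------------
# genome generators
# ---------------------------------------------------------------------------


def make_genome(seed: int, length: int, gc: float = 0.39, seq_id: str = "synthetic") -> SequenceRecord:
    """Reproducible random genome with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceRecord(seq_id, seq)


def make_quadripartite_genome(
    seed: int,
    lsc_len: int,
    ir_len: int,
    ssc_len: int,
    gc: float = 0.39,
    seq_id: str = "synthetic_plastome",
):
    """Circular genome LSC·IRa·SSC·IRb with IRb = revcomp(IRa); returns
    (record, partition) in the frame where the LSC starts at coordinate 1."""
    for name, val in (("lsc_len", lsc_len), ("ir_len", ir_len), ("ssc_len", ssc_len)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    def rand(n):
        return "".join(rng.choice(_BASES, size=n, p=p))

    lsc, ira, ssc = rand(lsc_len), rand(ir_len), rand(ssc_len)
    # pin the junction bases so the IR pair cannot extend into the
    # single-copy regions by chance and the lengths are exactly as requested
    if lsc_len > 1 and lsc[-1] == _COMP[lsc[0]]:
        lsc = lsc[:-1] + _other_base(_COMP[lsc[0]])
    if ssc_len > 1 and ssc[-1] == _COMP[ssc[0]]:
        ssc = ssc[:-1] + _other_base(_COMP[ssc[0]])
    seq = lsc + ira + ssc + revcomp(ira)
    record = SequenceRecord(seq_id, seq, circular=True)
    n = len(seq)
    partition = QuadripartitePartition(
        lsc=(1, lsc_len),
        ira=(lsc_len + 1, lsc_len + ir_len),
        ssc=(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len + 1, n),
        genome_length=n,
    )
    return record, partition


# ---------------------------------------------------------------------------
# SSR planting
# ---------------------------------------------------------------------------


def _other_base(*avoid) -> str:
    for b in "ACGT":
        if b not in avoid:
            return b
    raise AssertionError


def _write_tract(seq: bytearray, plant: SsrPlant) -> None:
    """Write a tract and adjust the two flanking bases so it is maximal."""
    motif, start0 = plant.motif, plant.offset - 1
    tract = motif * plant.copies
    end0 = start0 + len(tract) - 1
    if start0 < 1 or end0 >= len(seq) - 1:
        raise PlacementError(f"tract at {plant.offset} does not fit with flanks")
    seq[start0 : end0 + 1] = tract.encode()
    # left neighbour must not continue the period; avoid homopolymer joins too
    left = _other_base(motif[-1], chr(seq[start0 - 2]) if start0 >= 2 else "")
    seq[start0 - 1] = ord(left)
    right = _other_base(motif[0], chr(seq[end0 + 2]) if end0 + 2 < len(seq) else "")
    seq[end0 + 1] = ord(right)


def plant_ssrs(record: SequenceRecord, specs, min_gap: int = 20):
    """Plant maximal perfect tracts; events must be separated by >= min_gap."""
    specs = sorted(specs, key=lambda s: s.offset)
    prev_end = -min_gap
    for s in specs:
        if s.offset <= prev_end + min_gap:
            raise PlacementError(f"tract at {s.offset} closer than min_gap")
        prev_end = s.offset + len(s.motif) * s.copies - 1
        if prev_end > len(record):
            raise PlacementError(f"tract at {s.offset} runs past the genome end")
    seq = bytearray(record.sequence.encode())
    for s in specs:
        _write_tract(seq, s)
    truth = PlantedTruth(ssrs=list(specs))
    return SequenceRecord(record.id, seq.decode(), record.circular), truth


# ---------------------------------------------------------------------------
# alignment generator
# ---------------------------------------------------------------------------


def _prepare_inversion_site(seq: bytearray, inv: InversionPlant) -> None:
    """Write flank · segment · revcomp(flank) into the base genome and make
    the segment free of self-complementary mirrored positions, so the
    genotype-vs-reference mismatch run covers the whole segment."""
    f0 = inv.start - 1 - inv.flank
    if f0 < 1 or inv.footprint[1] >= len(seq):
        raise PlacementError(f"inversion at {inv.start} does not fit its flanks")
    flank = bytes(seq[f0 : f0 + inv.flank]).decode()
    seq[inv.start - 1 + inv.length : inv.start - 1 + inv.length + inv.flank] = revcomp(
        flank
    ).encode()
    seg = bytearray(seq[inv.start - 1 : inv.start - 1 + inv.length])
    for t in range(len(seg) // 2 + 1):
        u = len(seg) - 1 - t
        if t > u:
            break
        if chr(seg[t]) == _COMP[chr(seg[u])]:
            seg[t] = ord(_other_base(_COMP[chr(seg[u])]))
    seq[inv.start - 1 : inv.start - 1 + inv.length] = seg
    # the flanking inverted repeat must not extend by chance
    outer_left = f0 - 1
    outer_right = inv.footprint[1]  # 0-based index just right of the footprint
    if chr(seq[outer_left]) == _COMP[chr(seq[outer_right])]:
        seq[outer_left] = ord(_other_base(_COMP[chr(seq[outer_right])]))


def mutate_genomes(
    base: SequenceRecord,
    genotype_names,
    spec: MutationSpec,
    min_gap: int = 20,
):
    """Emit a true gapped alignment of ``genotype_names`` differing from the
    (possibly adjusted) base genome exactly at the planted events.

    The first genotype is the reference and carries no planted event, so
    reference coordinates coincide with base-genome coordinates.  Events,
    including inversion flanks, must be pairwise separated by ``min_gap``.
    """
    names = list(genotype_names)
    if len(names) < 2:
        raise ValueError("need at least two genotypes")
    ref = names[0]
    footprints = []
    for s in spec.snps:
        footprints.append((s.pos, s.pos, s.carriers))
    for d in spec.indels:
        footprints.append((d.pos, d.pos + d.length - 1, d.carriers))
    for inv in spec.inversions:
        footprints.append((*inv.footprint, inv.carriers))
    for v in spec.ssr_variants:
        footprints.append(
            (v.offset, v.offset + len(v.motif) * v.copies - 1, v.carriers)
        )
    footprints.sort()
    for (s1, e1, c1), (s2, e2, c2) in zip(footprints, footprints[1:]):
        if s2 <= e1 + min_gap:
            raise PlacementError(f"events at {s1} and {s2} overlap or abut")
    for _s, _e, carriers in footprints:
        bad = set(carriers) - set(names[1:])
        if bad:
            raise PlacementError(
                f"carriers {sorted(bad)} unknown or reference (reference "
                f"cannot carry planted events)"
            )

    seq = bytearray(base.sequence.encode())
    for v in spec.ssr_variants:
        _write_tract(seq, SsrPlant(v.offset, v.motif, v.copies))
    for inv in spec.inversions:
        _prepare_inversion_site(seq, inv)
    adjusted = seq.decode()

    rows = {}
    for name in names:
        row = bytearray(adjusted.encode())
        if name != ref:
            for s in spec.snps:
                if name in s.carriers:
                    if s.alt == adjusted[s.pos - 1]:
                        raise PlacementError(f"SNP at {s.pos}: alt equals base")
                    row[s.pos - 1] = ord(s.alt)
            for d in spec.indels:
                if name in d.carriers:
                    row[d.pos - 1 : d.pos - 1 + d.length] = b"-" * d.length
            for inv in spec.inversions:
                if name in inv.carriers:
                    seg = adjusted[inv.start - 1 : inv.start - 1 + inv.length]
                    row[inv.start - 1 : inv.start - 1 + inv.length] = revcomp(
                        seg
                    ).encode()
            for v in spec.ssr_variants:
                if name in v.carriers:
                    unit = len(v.motif)
                    drop = (v.copies - v.alt_copies) * unit
                    tract_end = v.offset - 1 + unit * v.copies
                    row[tract_end - drop : tract_end] = b"-" * drop
        rows[name] = row.decode()

    alignment = Alignment(names, [rows[n] for n in names])
    truth = PlantedTruth(
        snps=list(spec.snps),
        indels=list(spec.indels),
        inversions=list(spec.inversions),
        ssr_variants=list(spec.ssr_variants),
    )
    return alignment, truth, SequenceRecord(base.id, adjusted, base.circular)


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


def simulate_genotypes(
    allele_freqs: dict,
    n_individuals: int,
    ploidy: int = 2,
    seed: int = 0,
) -> GenotypeTable:
    """Draw gene copies independently from per-locus allele frequencies."""
    rng = np.random.default_rng(seed)
    loci = list(allele_freqs)
    individuals = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    calls = {}
    for locus in loci:
        freqs = allele_freqs[locus]
        alleles = list(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {locus!r}: frequencies sum to {p.sum()}")
        draws = rng.choice(len(alleles), size=(n_individuals, ploidy), p=p)
        for i, ind in enumerate(individuals):
            calls[(ind, locus)] = tuple(
                sorted((alleles[j] for j in draws[i]), key=str)
            )
    return GenotypeTable(individuals, loci, calls, ploidy)


# ---------------------------------------------------------------------------
# the default four-genotype scenario
# ---------------------------------------------------------------------------

GENOTYPE_NAMES = ("GZST", "JXLS", "GZLP", "HNSN")

#: deletion lengths of the default scenario (2–458 bp)
DEFAULT_INDEL_LENGTHS = (9, 15, 2, 24, 9, 153, 5, 30, 126, 458, 3, 15, 8, 9, 22, 6, 9)
#: (inversion length, flank length) pairs of the default scenario
DEFAULT_INVERSIONS = ((8, 21), (10, 17), (12, 29), (3, 22), (23, 17))


@dataclass
class Scenario:
    alignment: Alignment
    truth: PlantedTruth
    base: SequenceRecord
    partition: QuadripartitePartition
    names: tuple


def default_scenario(
    seed: int = 0,
    lsc_len: int = 87766,
    ir_len: int = 26333,
    ssc_len: int = 18997,
    n_snps: int = 45,
    indel_lengths=DEFAULT_INDEL_LENGTHS,
    inversions=DEFAULT_INVERSIONS,
    n_variable_ssrs: int = 49,
    n_invariant_ssrs: int = 8,
    gc: float = 0.39,
) -> Scenario:
    """Four-genotype plastome comparison with all events planted in the
    single-copy regions (so the IR pair stays exact and detectable)."""
    rng = np.random.default_rng(seed)
    base, partition = make_quadripartite_genome(
        int(rng.integers(2**31)), lsc_len, ir_len, ssc_len, gc
    )
    non_ref = GENOTYPE_NAMES[1:]

    def carriers():
        k = int(rng.integers(1, len(non_ref) + 1))
        picked = rng.choice(len(non_ref), size=k, replace=False)
        return tuple(non_ref[i] for i in sorted(picked))

    # interleave the events along the single-copy regions with random gaps
    events = []
    for length in indel_lengths:
        events.append(("indel", length))
    for inv_len, flank in inversions:
        events.append(("inversion", (inv_len, flank)))
    for i in range(n_variable_ssrs):
        events.append(("ssr_var", None))
    for i in range(n_invariant_ssrs):
        events.append(("ssr_fix", None))
    for i in range(n_snps):
        events.append(("snp", None))
    order = rng.permutation(len(events))
    events = [events[i] for i in order]

    spec = MutationSpec()
    fixed_ssrs = []
    # place the first 3/4 of events in the LSC, the rest in the SSC
    split = (3 * len(events)) // 4
    cursors = [(200, partition.lsc[1] - 200), (partition.ssc[0] + 200, partition.ssc[1] - 200)]
    cursor = cursors[0][0]
    limit = cursors[0][1]
    for i, (kind, payload) in enumerate(events):
        if i == split:
            cursor, limit = cursors[1]
        cursor += int(rng.integers(40, 200))
        if kind == "snp":
            pos = cursor
            ref_base = base.sequence[pos - 1]
            alt = _other_base(ref_base)
            spec.snps.append(SnpPlant(pos, alt, carriers()))
            cursor = pos
        elif kind == "indel":
            spec.indels.append(IndelPlant(cursor, payload, carriers()))
            cursor = cursor + payload - 1
        elif kind == "inversion":
            inv_len, flank = payload
            start = cursor + flank
            spec.inversions.append(InversionPlant(start, inv_len, flank, carriers()))
            cursor = start + inv_len - 1 + flank
        else:
            copies = int(rng.integers(12, 17))
            if kind == "ssr_var":
                alt_copies = int(rng.integers(10, copies))
                spec.ssr_variants.append(
                    SsrVariantPlant(cursor, "A", copies, alt_copies, carriers())
                )
            else:
                fixed_ssrs.append(SsrPlant(cursor, "A", copies))
            cursor = cursor + copies - 1
        if cursor > limit:
            raise PlacementError("scenario does not fit in the single-copy regions")

    base_with_fixed, _ = plant_ssrs(base, fixed_ssrs) if fixed_ssrs else (base, None)
    alignment, truth, adjusted = mutate_genomes(
        base_with_fixed, GENOTYPE_NAMES, spec
    )
    truth.ssrs = fixed_ssrs
    return Scenario(
        alignment=alignment,
        truth=truth,
        base=adjusted,
        partition=partition,
        names=GENOTYPE_NAMES,
    )
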