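"""Constraint-based PCR primer selection around marker loci.

Candidate oligos are enumerated in the flanks of a target tract (an SSR or
other marker) under simple, configurable constraints: length 18–22 nt with an
optimum of 20, annealing temperature >= 60 °C, GC fraction 0.30–0.70, a G/C
3' clamp, a homopolymer cap, and a minimum product size of 100 bp.  Melting
temperature uses the basic GC closed form

    Tm = 64.9 + 41 * (G + C - 16.4) / length        (length >= 14 nt)

(the Wallace rule ``2(A+T) + 4(G+C)`` for shorter oligos, flagged), not
nearest-neighbour thermodynamics.  Pair selection is deterministic: the
candidate cross-product is scored by a penalty combining length deviation
from the optimum, forward/reverse Tm mismatch and product-size shortfall,
with ties broken by smaller product and then leftmost forward primer.

A universal M13 tail (5'-TGTAAAACGACGGCCAGT-3') can be prepended to forward
primers so one fluorescent universal primer labels all PCR products.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import DesignError
from .seqio import revcomp

M13_TAIL = "TGTAAAACGACGGCCAGT"


@dataclass(frozen=True)
class PrimerConstraints:
    size_min: int = 18
    size_opt: int = 20
    size_max: int = 22
    tm_min: float = 60.0
    product_min: int = 100
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 4
    gc_clamp: bool = True

    def __post_init__(self) -> None:
        if not self.size_min <= self.size_opt <= self.size_max:
            raise ValueError("need size_min <= size_opt <= size_max")
        if self.product_min <= 2 * self.size_min:
            raise ValueError("product_min must exceed 2*size_min")


@dataclass(frozen=True)
class PrimerSpec:
    """One oligo written 5'->3'.  ``start`` is the 1-based template coordinate
    of the 5' end; a minus-strand oligo is the reverse complement of the
    template at its coordinates."""

    sequence: str
    start: int
    strand: str  # + | -
    tm: float
    gc: float
    tm_flagged: bool = False  # Wallace-rule fallback used

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerSpec
    reverse: PrimerSpec
    product_size: int
    penalty: float


def tm_basic(oligo: str) -> float:
    """Basic GC-content melting temperature, reported to 2 decimals."""
    tm, _ = _tm(oligo)
    return tm


def _tm(oligo: str):
    if set(oligo) - set("ACGT"):
        raise ValueError("oligo must be over ACGT")
    gc = oligo.count("G") + oligo.count("C")
    n = len(oligo)
    if n < 14:
        return round(2 * (n - gc) + 4 * gc, 2), True  # Wallace rule, flagged
    return round(64.9 + 41 * (gc - 16.4) / n, 2), False


def _homopolymer(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


def _window_ok(oligo: str, constraints: PrimerConstraints) -> bool:
    gc = (oligo.count("G") + oligo.count("C")) / len(oligo)
    if not constraints.gc_min <= gc <= constraints.gc_max:
        return False
    if constraints.gc_clamp and oligo[-1] not in "GC":
        return False
    if _homopolymer(oligo) > constraints.max_homopolymer:
        return False
    tm, _ = _tm(oligo)
    return tm >= constraints.tm_min


def enumerate_candidates(
    template: str,
    target_interval: tuple,
    constraints: PrimerConstraints | None = None,
    strand: str = "+",
):
    """All constraint-passing windows wholly left (+) or right (-) of the
    target (1-based inclusive ``target_interval``); never overlapping it."""
    c = constraints or PrimerConstraints()
    t0, t1 = target_interval
    n = len(template)
    if not 1 <= t0 <= t1 <= n:
        raise ValueError(f"target {target_interval} outside template")
    left_flank = t0 - 1
    right_flank = n - t1
    flank = left_flank if strand == "+" else right_flank
    if flank < c.size_max:
        raise DesignError(
            f"flank of {flank} bp on strand {strand} shorter than size_max"
        )
    out = []
    for length in range(c.size_min, c.size_max + 1):
        if strand == "+":
            for a in range(1, t0 - length + 1):  # window [a, a+length-1] < t0
                oligo = template[a - 1 : a - 1 + length]
                if set(oligo) - set("ACGT"):
                    continue
                if _window_ok(oligo, c):
                    tm, flagged = _tm(oligo)
                    out.append(
                        PrimerSpec(
                            oligo,
                            start=a,
                            strand="+",
                            tm=tm,
                            gc=(oligo.count("G") + oligo.count("C")) / length,
                            tm_flagged=flagged,
                        )
                    )
        else:
            for b in range(t1 + 1, n - length + 2):  # window [b, b+length-1] > t1
                window = template[b - 1 : b - 1 + length]
                if set(window) - set("ACGT"):
                    continue
                oligo = revcomp(window)
                if _window_ok(oligo, c):
                    tm, flagged = _tm(oligo)
                    out.append(
                        PrimerSpec(
                            oligo,
                            start=b + length - 1,  # 5' end on the template
                            strand="-",
                            tm=tm,
                            gc=(oligo.count("G") + oligo.count("C")) / length,
                            tm_flagged=flagged,
                        )
                    )
    return out


def longest_complement_run(a: str, b: str) -> int:
    """Longest perfect complementary stretch between two oligos (both read
    5'->3'), the simple dimer screen used instead of thermodynamic dG."""
    rb = revcomp(b)
    best = 0
    for i in range(len(a)):
        for j in range(len(rb)):
            k = 0
            while i + k < len(a) and j + k < len(rb) and a[i + k] == rb[j + k]:
                k += 1
            best = max(best, k)
    return best


def pick_primer_pair(
    template: str,
    target_interval: tuple,
    constraints: PrimerConstraints | None = None,
    screen_dimers: bool = False,
    dimer_max_run: int = 8,
):
    """Deterministic penalty-minimal pair over the candidate cross-product,
    or None (with the reason logged in the exception-free return) when no
    feasible pair exists.

    penalty = |len_f - size_opt| + |len_r - size_opt| + |tm_f - tm_r|
              + max(0, product_min - product) * 10
    Pairs whose product would fall below ``product_min`` are infeasible.
    Ties break by smaller product, then leftmost forward primer.
    """
    c = constraints or PrimerConstraints()
    forwards = enumerate_candidates(template, target_interval, c, "+")
    reverses = enumerate_candidates(template, target_interval, c, "-")
    if not forwards or not reverses:
        return None
    best = None
    for f in forwards:
        for r in reverses:
            product = r.start - f.start + 1
            if product < c.product_min:
                continue
            if screen_dimers and (
                longest_complement_run(f.sequence, r.sequence) >= dimer_max_run
                or longest_complement_run(f.sequence, f.sequence) >= dimer_max_run
                or longest_complement_run(r.sequence, r.sequence) >= dimer_max_run
            ):
                continue
            penalty = (
                abs(len(f) - c.size_opt)
                + abs(len(r) - c.size_opt)
                + abs(f.tm - r.tm)
                + max(0, c.product_min - product) * 10
            )
            key = (penalty, product, f.start)
            if best is None or key < best[0]:
                best = (key, PrimerPair(f, r, product, round(penalty, 2)))
    return best[1] if best else None


def add_tail(primer: PrimerSpec | str, tail: str = M13_TAIL) -> str:
    """Concatenate a universal tail 5' of the primer sequence."""
    if set(tail) - set("ACGT"):
        raise ValueError("tail must be over ACGT")
    seq = primer if isinstance(primer, str) else primer.sequence
    return tail + seq
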