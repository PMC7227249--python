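import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastomarker import data as refdata
from plastomarker.compare import (
    call_indel_events,
    call_indels,
    call_markers,
    call_snps,
    call_ssr_polymorphisms,
    column_to_ref_coord,
    detect_inversions,
    snp_spectrum,
)
from plastomarker.seqio import Alignment, revcomp
from plastomarker.ssr import SsrThresholds
from plastomarker.synthetic import (
    IndelPlant,
    InversionPlant,
    MutationSpec,
    SnpPlant,
    SsrVariantPlant,
    default_scenario,
    make_genome,
    mutate_genomes,
)

from conftest import carrier_set


# ---------------------------------------------------------------------------
# column -> reference coordinate mapping
# ---------------------------------------------------------------------------


def test_column_to_ref_coord_basics():
    aln = Alignment(["r", "o"], ["A-CG", "AACG"])
    assert column_to_ref_coord(aln, "r", 1) == 1
    assert column_to_ref_coord(aln, "r", 2) is None
    assert column_to_ref_coord(aln, "r", 3) == 2
    assert column_to_ref_coord(aln, "r", 4) == 3
    with pytest.raises(KeyError):
        column_to_ref_coord(aln, "zz", 1)
    with pytest.raises(ValueError):
        column_to_ref_coord(aln, "r", 0)


@given(st.lists(st.sampled_from(["A", "C", "G", "T", "-"]), min_size=2, max_size=60))
def test_ref_coord_mapping_monotone_surjective(chars):
    if all(c == "-" for c in chars):
        return
    row = "".join(chars)
    other = "A" * len(row)
    aln = Alignment(["r", "o"], [row, other])
    coords = [
        column_to_ref_coord(aln, "r", c) for c in range(1, aln.length + 1)
    ]
    seen = [c for c in coords if c is not None]
    assert seen == sorted(seen)  # monotone
    assert seen == list(range(1, len(aln.ungapped("r")) + 1))  # surjective


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------


def test_call_snps_minimal_column():
    aln = Alignment(["a", "b", "c", "d"], ["ATTA", "ATTA", "AGTA", "ATTA"])
    (snp,) = call_snps(aln, "a")
    assert snp.type == "G/T" and snp.ref_coord == 2
    assert snp.states == {"a": "T", "b": "T", "c": "G", "d": "T"}


def test_gap_and_n_columns_excluded():
    aln = Alignment(["a", "b", "c", "d"], ["ATA", "A-A", "ATA", "ATA"])
    assert call_snps(aln, "a") == []
    aln2 = Alignment(["a", "b", "c", "d"], ["ATA", "ANA", "AGA", "ATA"])
    assert call_snps(aln2, "a") == []


def test_multiallelic_reported_separately():
    aln = Alignment(["a", "b", "c", "d"], ["AAT", "ACT", "AGT", "AAT"])
    snps, multis = call_snps(aln, "a", return_multiallelic=True)
    assert snps == []
    assert len(multis) == 1 and multis[0].type == "A/C/G"


def test_planted_substitutions_recovered_exactly():
    base = make_genome(5, 4000, 0.4, "base")
    rng = np.random.default_rng(8)
    names = ["g1", "g2", "g3", "g4"]
    spec = MutationSpec()
    positions = sorted(rng.choice(np.arange(100, 3900), size=30, replace=False))
    positions = [int(p) for p in positions]
    # enforce spacing
    spaced = [positions[0]]
    for p in positions[1:]:
        if p - spaced[-1] > 25:
            spaced.append(p)
    for p in spaced:
        ref = base.sequence[p - 1]
        alt = next(b for b in "ACGT" if b != ref)
        k = int(rng.integers(1, 4))
        carriers = tuple(np.random.default_rng(p).permutation(names[1:])[:k])
        spec.snps.append(SnpPlant(p, alt, carriers))
    aln, truth, _ = mutate_genomes(base, names, spec)
    snps = call_snps(aln, "g1")
    truth_set = {(s.pos, s.alt, frozenset(s.carriers)) for s in truth.snps}
    found = set()
    for r in snps:
        ref = r.states["g1"]
        alt = next(b for b in r.states.values() if b != ref)
        found.add((r.ref_coord, alt, carrier_set(r.states, alt)))
    assert found == truth_set  # precision = recall = 1


def test_snp_spectrum_sums_and_symmetry():
    assert sum(snp_spectrum([]).values()) == 0
    records = refdata.chloroplast_snps()
    spectrum = snp_spectrum(records)
    assert sum(spectrum.values()) == 45
    # lowest-frequency types in the published set are C/G and A/T
    assert spectrum["C/G"] == min(spectrum.values())
    # spectrum depends only on the type column, not genotype order
    for rec in records:
        rec.states = dict(reversed(list(rec.states.items())))
    assert snp_spectrum(records) == spectrum


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------


def test_simple_deletion_run():
    aln = Alignment(
        ["a", "b", "c", "d"],
        ["AACGTGTCC", "AA-----CC", "AACGTGTCC", "AACGTGTCC"],
    )
    (indel,) = call_indels(aln, "a")
    assert indel.length == 5 and indel.ref_coord == 2
    assert indel.states == {
        "a": "Insertion", "b": "Deletion", "c": "Insertion", "d": "Insertion"
    }


def test_indel_when_reference_is_gapped():
    # reference carries the deletion; anchor is the last reference base before
    aln = Alignment(
        ["ref", "b", "c", "d"],
        ["AAC---TCC", "AACGGGTCC", "AACGGGTCC", "AACGGGTCC"],
    )
    (indel,) = call_indels(aln, "ref")
    assert indel.ref_coord == 3 and indel.length == 3
    assert indel.states["ref"] == "Deletion"


def test_ragged_gap_run_is_complex():
    aln = Alignment(
        ["a", "b", "c", "d"],
        ["ACGTGTA", "A--TGTA", "A---GTA", "ACGTGTA"],
    )
    indels, complexes = call_indel_events(aln, "a")
    assert indels == []
    assert len(complexes) == 1 and complexes[0].patterns == 2


def test_planted_indel_lengths_recovered(small_scenario):
    markers = call_markers(small_scenario.alignment, "GZST")
    truth = small_scenario.truth
    truth_set = {
        (d.pos - 1, d.length, frozenset(d.carriers)) for d in truth.indels
    }
    found = {
        (r.ref_coord, r.length, carrier_set(r.states, "Deletion"))
        for r in markers.indels
    }
    assert found == truth_set
    assert {r.length for r in markers.indels} == set(
        d.length for d in truth.indels
    )


# ---------------------------------------------------------------------------
# SSR copy-number polymorphisms
# ---------------------------------------------------------------------------


def _tract_alignment(copies_by_row):
    rows, names = [], []
    longest = max(copies_by_row.values())
    for name, copies in copies_by_row.items():
        names.append(name)
        rows.append(
            "GCTTGC" + "A" * copies + "-" * (longest - copies) + "GCTTGC"
        )
    return Alignment(names, rows)


def test_variable_tract_emitted_with_copy_numbers():
    aln = _tract_alignment({"a": 12, "b": 10, "c": 12, "d": 12})
    (rec,) = call_ssr_polymorphisms(aln, SsrThresholds.misa_default(), "a")
    assert rec.copies == {"a": 12, "b": 10, "c": 12, "d": 12}
    assert rec.canonical == "A"


def test_invariant_tract_not_emitted():
    aln = _tract_alignment({"a": 12, "b": 12, "c": 12, "d": 12})
    assert call_ssr_polymorphisms(aln, SsrThresholds.misa_default(), "a") == []


def test_planted_variable_tracts_exactly(small_scenario):
    markers = call_markers(small_scenario.alignment, "GZST")
    truth = small_scenario.truth
    assert len(markers.ssr_polymorphisms) == len(truth.ssr_variants)
    truth_set = {
        (v.offset, v.copies, v.alt_copies, frozenset(v.carriers))
        for v in truth.ssr_variants
    }
    found = set()
    for r in markers.ssr_polymorphisms:
        hi, lo = max(r.copies.values()), min(r.copies.values())
        found.add((r.ref_interval[0], hi, lo, frozenset(
            g for g, c in r.copies.items() if c == lo)))
    assert found == truth_set


def test_ssr_length_variants_not_double_reported_as_indels(small_scenario):
    markers = call_markers(small_scenario.alignment, "GZST")
    assert len(markers.excluded_ssr_indels) == len(
        small_scenario.truth.ssr_variants
    )
    spans = [r.columns for r in markers.ssr_polymorphisms]
    for indel in markers.excluded_ssr_indels:
        assert any(s0 <= indel.columns[0] and indel.columns[1] <= s1
                   for s0, s1 in spans)


# ---------------------------------------------------------------------------
# small inversions
# ---------------------------------------------------------------------------


def _inversion_alignment(flank_len=17, seg_len=9, seed=3):
    rng = np.random.default_rng(seed)
    x = "".join(rng.choice(list("ACGT"), size=60))
    y = "".join(rng.choice(list("ACGT"), size=60))
    u = "".join(rng.choice(list("ACGT"), size=flank_len))
    s = list(rng.choice(list("ACGT"), size=seg_len))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for t in range(seg_len):  # make every mirrored position mismatch
        if s[t] == comp[s[seg_len - 1 - t]]:
            s[t] = next(b for b in "ACGT" if b != comp[s[seg_len - 1 - t]])
    s = "".join(s)
    ref = x + u + s + revcomp(u) + y
    alt = x + u + revcomp(s) + revcomp(u) + y
    names = ["ref", "g2", "g3", "g4"]
    aln = Alignment(names, [ref, alt, ref, ref])
    return aln, (len(x) + flank_len + 1, len(x) + flank_len + seg_len)


def test_constructed_inversion_detected():
    aln, interval = _inversion_alignment()
    (rec,) = detect_inversions(aln, "ref")
    assert rec.ref_interval == interval
    assert rec.inv_length == 9 and rec.flank_length == 17
    assert rec.orientation == {"ref": "No", "g2": "Yes", "g3": "No", "g4": "No"}


def test_identical_genotypes_no_inversions():
    row = "ACGTTGCA" * 10
    aln = Alignment(["a", "b", "c"], [row, row, row])
    assert detect_inversions(aln, "a") == []


def test_substitution_cluster_is_not_an_inversion():
    ref = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    alt = ref[:16] + "GGG" + ref[19:]
    if alt == ref:
        alt = ref[:16] + "CCC" + ref[19:]
    aln = Alignment(["r", "x"], [ref, alt])
    assert detect_inversions(aln, "r") == []


def test_inversion_involution_consistency():
    aln, interval = _inversion_alignment()
    fwd = detect_inversions(aln, "ref")[0]
    # re-reference on the inverted genotype: orientations flip, lengths stay
    back = detect_inversions(aln, "g2")[0]
    assert back.inv_length == fwd.inv_length
    assert back.flank_length == fwd.flank_length
    assert back.orientation["ref"] == "Yes" and back.orientation["g2"] == "No"


def test_planted_inversions_recovered(small_scenario):
    markers = call_markers(small_scenario.alignment, "GZST")
    truth_set = {
        (v.start, v.start + v.length - 1, v.flank, frozenset(v.carriers))
        for v in small_scenario.truth.inversions
    }
    found = {
        (r.ref_interval[0], r.ref_interval[1], r.flank_length,
         carrier_set(r.orientation, "Yes"))
        for r in markers.inversions
    }
    assert found == truth_set


# ---------------------------------------------------------------------------
# column accounting
# ---------------------------------------------------------------------------


def test_column_accounting_partitions_alignment(small_scenario):
    markers = call_markers(small_scenario.alignment, "GZST")
    acc = markers.accounting
    assert acc.total == small_scenario.alignment.length
    assert acc.snp == len(markers.snps)
    assert acc.complex == 0
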