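"""Bundled reference marker tables for *Liriodendron chinense*.

These are the published characterization tables for the four-genotype
chloroplast comparison (genotypes GZST, JXLS, GZLP, HNSN; plastome GenBank
accessions MK887904–MK887907) and the 13-locus nuclear SSR panel genotyped
on 109 individuals.  They serve as worked-example inputs: the raw genotypes
and contigs behind them are unpublished, so per-locus values are fixtures,
while column arithmetic (class percentages, location breakdowns, panel
means) is recomputed by the package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..compare import IndelRecord, InversionRecord, SnpRecord
from ..popgen import LocusStats

GENOTYPES = ("GZST", "JXLS", "GZLP", "HNSN")

#: nuclear SSR counts per motif unit length from the genome-wide scan
NUCLEAR_SSR_UNIT_COUNTS = {2: 6417, 3: 2115, 4: 312, 5: 219, 6: 92}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def chloroplast_snp_table() -> pd.DataFrame:
    return _read("lchinense_cp_snps.tsv")


def chloroplast_snps() -> list:
    """The 45 chloroplast SNPs as SnpRecords (type normalized X<Y)."""
    out = []
    for _, row in chloroplast_snp_table().iterrows():
        out.append(
            SnpRecord(
                ref_coord=None,
                column=None,
                type="/".join(sorted(row["type"].split("/"))),
                states={g: row[g] for g in GENOTYPES},
                location=row["location"],
                region=row["region"],
                name=row["position"],
            )
        )
    return out


def chloroplast_indel_table() -> pd.DataFrame:
    return _read("lchinense_cp_indels.tsv")


def chloroplast_indels() -> list:
    out = []
    for _, row in chloroplast_indel_table().iterrows():
        out.append(
            IndelRecord(
                ref_coord=0,
                length=int(row["length"]),
                states={g: row[g] for g in GENOTYPES},
                location=row["location"],
                region=row["region"],
                name=row["position"],
            )
        )
    return out


def chloroplast_inversion_table() -> pd.DataFrame:
    return _read("lchinense_cp_inversions.tsv")


def chloroplast_inversions() -> list:
    out = []
    for _, row in chloroplast_inversion_table().iterrows():
        out.append(
            InversionRecord(
                ref_interval=(0, 0),
                inv_length=int(row["inv_length"]),
                flank_length=int(row["flank_length"]),
                orientation={g: row[g] for g in GENOTYPES},
                region=row["region"],
                name=row["position"],
            )
        )
    return out


def nuclear_ssr_panel() -> pd.DataFrame:
    return _read("lchinense_nuclear_ssr_panel.tsv")


def nuclear_locus_stats() -> list:
    """The 13-locus panel as LocusStats (Ne unavailable -> NaN; n = 109)."""
    out = []
    for _, row in nuclear_ssr_panel().iterrows():
        out.append(
            LocusStats(
                locus=row["locus"],
                n=109,
                A=int(row["A"]),
                Ne=float("nan"),
                Ho=float(row["Ho"]),
                He=float(row["He"]),
                H=float(row["H"]),
            )
        )
    return out
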