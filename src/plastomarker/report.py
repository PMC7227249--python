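"""Marker tables and the end-to-end pipeline.

``run_pipeline`` reads an alignment (plus optional annotation and reference
genome), calls every marker class, annotates locations/regions, and writes
one TSV per marker class plus a run log that echoes every parameter and the
column accounting (SNP + multi-allelic + indel + complex + inversion +
masked + invariant columns = alignment length).  Re-running with the same
configuration is byte-identical.

``render_table`` formats records of one kind in the conventional published
table layouts (position / location / region / type plus one column per
genotype; diversity tables end with a Mean row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import (
    ComplexRecord,
    IndelRecord,
    InversionRecord,
    MarkerSet,
    MultiAllelicRecord,
    SnpRecord,
    SsrPolymorphismRecord,
    annotate_markers,
    call_markers,
)
from .errors import PlastomarkerError
from .popgen import LocusStats, summarize_loci
from .regions import detect_quadripartite
from .seqio import (
    Alignment,
    SequenceRecord,
    read_alignment,
    read_fasta,
    read_genbank_features,
    read_gff3_features,
)
from .ssr import SsrThresholds

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alignment_path: str
    ref_id: str
    outdir: str
    annotation_path: str | None = None
    thresholds: SsrThresholds | None = None
    min_ir_len: int = 1000
    detect_partition: bool = True
    inv_min_len: int = 3
    inv_max_len: int = 30
    inv_min_flank: int = 10
    inv_max_flank: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.alignment_path).exists():
            raise PlastomarkerError(f"alignment {self.alignment_path} not found")
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise PlastomarkerError(f"annotation {self.annotation_path} not found")


# ---------------------------------------------------------------------------
# frames for each marker class (fixed, documented column orders)
# ---------------------------------------------------------------------------


def snp_frame(records, genotypes) -> pd.DataFrame:
    cols = ["position", "location", "region", "type", "ref_coord"] + list(genotypes)
    rows = [
        {
            "position": r.name,
            "location": r.location,
            "region": r.region,
            "type": r.type,
            "ref_coord": r.ref_coord,
            **r.states,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def indel_frame(records, genotypes) -> pd.DataFrame:
    cols = ["position", "location", "region", "length", "ref_coord"] + list(genotypes)
    rows = [
        {
            "position": r.name,
            "location": r.location,
            "region": r.region,
            "length": r.length,
            "ref_coord": r.ref_coord,
            **r.states,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def inversion_frame(records, genotypes) -> pd.DataFrame:
    cols = [
        "position",
        "location",
        "region",
        "inv_length",
        "flank_length",
        "ref_start",
        "ref_end",
    ] + list(genotypes)
    rows = [
        {
            "position": r.name,
            "location": r.location,
            "region": r.region,
            "inv_length": r.inv_length,
            "flank_length": r.flank_length,
            "ref_start": r.ref_interval[0],
            "ref_end": r.ref_interval[1],
            **r.orientation,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def ssr_poly_frame(records, genotypes) -> pd.DataFrame:
    cols = [
        "locus_id",
        "motif",
        "canonical",
        "location",
        "region",
        "ref_start",
        "ref_end",
    ] + list(genotypes)
    rows = [
        {
            "locus_id": r.locus_id,
            "motif": r.motif,
            "canonical": r.canonical,
            "location": r.location,
            "region": r.region,
            "ref_start": r.ref_interval[0],
            "ref_end": r.ref_interval[1],
            **r.copies,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def complex_frame(records) -> pd.DataFrame:
    cols = ["position", "location", "region", "col_start", "col_end", "patterns"]
    rows = [
        {
            "position": r.name,
            "location": r.location,
            "region": r.region,
            "col_start": r.columns[0],
            "col_end": r.columns[1],
            "patterns": r.patterns,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def locus_stats_frame(stats) -> pd.DataFrame:
    """Diversity table ending with a Mean row."""
    stats = [s.rounded() for s in stats]
    rows = [
        {
            "locus": s.locus,
            "n": s.n,
            "A": s.A,
            "Ne": s.Ne,
            "Ho": s.Ho,
            "He": s.He,
            "H": s.H,
        }
        for s in stats
    ]
    summary = summarize_loci(stats)
    rows.append(
        {
            "locus": "Mean",
            "n": "",
            "A": summary.mean_A_printed,
            "Ne": summary.mean_Ne,
            "Ho": summary.mean_Ho,
            "He": summary.mean_He,
            "H": summary.mean_H,
        }
    )
    return pd.DataFrame(rows, columns=["locus", "n", "A", "Ne", "Ho", "He", "H"])


_STYLES = {
    "snp": (SnpRecord, snp_frame),
    "multiallelic": (MultiAllelicRecord, snp_frame),
    "indel": (IndelRecord, indel_frame),
    "inversion": (InversionRecord, inversion_frame),
    "ssr_polymorphism": (SsrPolymorphismRecord, ssr_poly_frame),
    "locus_stats": (LocusStats, None),
}


def render_table(records, style: str) -> str:
    """Plain-text table of one record kind in its published layout."""
    if style not in _STYLES:
        raise PlastomarkerError(f"unknown table style {style!r}")
    cls, framer = _STYLES[style]
    records = list(records)
    if any(not isinstance(r, cls) for r in records):
        raise PlastomarkerError(f"mixed record kinds in a {style!r} table")
    if style == "locus_stats":
        df = locus_stats_frame(records) if records else pd.DataFrame(
            columns=["locus", "n", "A", "Ne", "Ho", "He", "H"]
        )
    else:
        genotypes = []
        if records:
            first = records[0]
            states = getattr(first, "states", None) or getattr(
                first, "orientation", None
            ) or getattr(first, "copies", None)
            genotypes = list(states)
        df = framer(records, genotypes)
    if df.empty:
        return "  ".join(df.columns)
    return df.to_string(index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _load_annotation(path: str):
    if path.endswith((".gb", ".gbk", ".genbank")):
        record, features = read_genbank_features(path)
        return record, features
    return None, read_gff3_features(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Scan -> compare -> annotate -> report.  Returns a manifest mapping
    artifact names to paths plus row counts; aborts on the first stage error
    with the stage named."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read-alignment"
    try:
        alignment = read_alignment(config.alignment_path)
        if config.ref_id not in alignment.ids:
            raise PlastomarkerError(
                f"reference id {config.ref_id!r} not in alignment "
                f"({', '.join(alignment.ids)})"
            )

        features: list = []
        partition = None
        if config.annotation_path:
            stage = "read-annotation"
            _rec, features = _load_annotation(config.annotation_path)
        if config.detect_partition:
            stage = "detect-partition"
            ref_record = SequenceRecord(
                config.ref_id, alignment.ungapped(config.ref_id), circular=True
            )
            try:
                partition = detect_quadripartite(ref_record, config.min_ir_len)
            except (PlastomarkerError, ValueError) as exc:
                logger.warning("no quadripartite structure: %s", exc)

        stage = "call-markers"
        markers = call_markers(
            alignment,
            config.ref_id,
            config.thresholds,
            config.inv_min_len,
            config.inv_max_len,
            config.inv_min_flank,
            config.inv_max_flank,
        )
        annotate_markers(markers, features, partition)

        stage = "write-tables"
        genotypes = alignment.ids
        artifacts = {
            "snps.tsv": snp_frame(markers.snps, genotypes),
            "multiallelic.tsv": snp_frame(markers.multiallelic, genotypes),
            "indels.tsv": indel_frame(markers.indels, genotypes),
            "complex.tsv": complex_frame(markers.complex_events),
            "ssr_poly.tsv": ssr_poly_frame(markers.ssr_polymorphisms, genotypes),
            "inversions.tsv": inversion_frame(markers.inversions, genotypes),
        }
        manifest = {}
        for name, df in artifacts.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            manifest[name] = {"path": str(path), "rows": len(df)}

        stage = "write-log"
        acc = markers.accounting
        log_lines = [
            f"plastomarker {__version__}",
            f"alignment: {config.alignment_path} "
            f"({len(genotypes)} genotypes x {alignment.length} columns)",
            f"reference: {config.ref_id}",
            f"annotation: {config.annotation_path or 'none'}",
            f"thresholds: {(config.thresholds or SsrThresholds.misa_default()).min_copies}",
            f"inversion-params: len {config.inv_min_len}..{config.inv_max_len}, "
            f"flank {config.inv_min_flank}..{config.inv_max_flank}",
            f"min_ir_len: {config.min_ir_len}",
            f"seed: {config.seed}",
            "column-accounting: "
            f"invariant={acc.invariant} snp={acc.snp} "
            f"multiallelic={acc.multiallelic} indel={acc.indel} "
            f"complex={acc.complex} inversion={acc.inversion} "
            f"masked={acc.masked} total={acc.total} "
            f"alignment_length={alignment.length}",
            f"ssr-indel-exclusions: {len(markers.excluded_ssr_indels)}",
        ]
        if acc.total != alignment.length:
            raise PlastomarkerError("column accounting does not close")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        manifest["run.log"] = {"path": str(outdir / "run.log"), "rows": len(log_lines)}
        return manifest
    except PlastomarkerError:
        raise
    except Exception as exc:
        raise PlastomarkerError(f"stage {stage!r} failed: {exc}") from exc
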