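"""Readers and writers for the standard formats mutation catalogs travel in.

FASTA is read through pyfaidx, VCF through pysam; BED (0-based half-open) is
converted to the internal 1-based inclusive convention on load.
Rearrangements use an 8-column tab-delimited dialect
(sample, chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b, class);
BEDPE is also accepted.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pyfaidx
import pysam

from .catalog import (
    CpGIslandSet,
    ExpressionTable,
    FormatError,
    Gene,
    GeneAnnotation,
    IndelRecord,
    RearrangementRecord,
    ReferenceGenome,
    SubstitutionRecord,
)


# ---------------------------------------------------------------- FASTA

def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA reference; lowercase is folded to uppercase and the
    trinucleotide table is built lazily with N windows excluded."""
    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    try:
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()
    return ReferenceGenome(seqs)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- VCF

def _vcf_header(contigs: dict[str, int] | None) -> str:
    lines = ["##fileformat=VCFv4.2", '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample ID">']
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def read_substitutions(
    path: str | os.PathLike,
    format: str = "vcf",
    sample_id: str | None = None,
    genome: ReferenceGenome | None = None,
) -> list[SubstitutionRecord]:
    """Read single-nucleotide substitutions from VCF or TSV.

    VCF rows must be SNVs (len(REF) == len(ALT) == 1); multi-allelic rows are
    split into one record per ALT.  The sample is taken from the
    ``SAMPLE`` INFO key, falling back to ``sample_id``.  TSV columns:
    sample, chrom, pos, ref, alt.
    """
    records: list[SubstitutionRecord] = []
    if format == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            for row in vf:
                if len(row.ref) != 1:
                    continue
                sid = row.info.get("SAMPLE", sample_id)
                if sid is None:
                    raise FormatError("VCF row lacks SAMPLE info and no sample_id given")
                for alt in row.alts or ():
                    if len(alt) != 1 or alt == "*":
                        continue
                    records.append(
                        SubstitutionRecord(str(sid), row.chrom, row.pos, row.ref, alt)
                    )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
        for col in ("sample", "chrom", "pos", "ref", "alt"):
            if col not in df.columns:
                raise FormatError(f"TSV missing column {col!r}")
        records = [
            SubstitutionRecord(r.sample, r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown format {format!r}")
    if genome is not None:
        bad = [r for r in records if genome.base(r.chrom, r.pos) != r.ref]
        if bad:
            lines = ", ".join(f"{r.chrom}:{r.pos}" for r in bad[:10])
            raise FormatError(f"{len(bad)} rows mismatch the reference: {lines}")
    return records


def write_substitutions_vcf(
    records: Sequence[SubstitutionRecord],
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs))
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\tSAMPLE={r.sample_id}\n")


def read_indels(
    path: str | os.PathLike,
    genome: ReferenceGenome,
    sample_id: str | None = None,
) -> list[IndelRecord]:
    """Read indels from a left-anchored VCF (REF/ALT share their first base).

    The anchor base becomes ``pos`` (the base immediately 5' of the event).
    """
    records: list[IndelRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for row in vf:
            sid = str(row.info.get("SAMPLE", sample_id))
            for alt in row.alts or ():
                if len(row.ref) == len(alt):
                    continue
                if row.ref[0] != alt[0]:
                    raise FormatError(f"indel at {row.chrom}:{row.pos} is not left-anchored")
                if len(row.ref) > len(alt):
                    seq = row.ref[len(alt):]
                    kind = "deletion"
                else:
                    seq = alt[len(row.ref):]
                    kind = "insertion"
                records.append(
                    IndelRecord(sid, row.chrom, row.pos, kind, seq, len(seq))
                )
    return records


def write_indels_vcf(
    records: Sequence[IndelRecord],
    path: str | os.PathLike,
    genome: ReferenceGenome,
    contigs: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs or genome.chrom_lengths))
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            anchor = genome.base(r.chrom, r.pos)
            if r.kind == "deletion":
                ref, alt = anchor + r.seq, anchor
            elif r.kind == "insertion":
                ref, alt = anchor, anchor + r.seq
            else:
                continue  # complex events are not representable as a single indel row
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{ref}\t{alt}\t.\t.\tSAMPLE={r.sample_id}\n")


# ---------------------------------------------------------------- BED

def read_islands(path: str | os.PathLike) -> CpGIslandSet:
    """BED (0-based half-open) -> merged 1-based inclusive island set."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"BED start >= end: {line.strip()!r}")
            out.append((chrom, start + 1, end))
    return CpGIslandSet(out)


def read_genes(path: str | os.PathLike) -> GeneAnnotation:
    """BED6 (chrom, start, end, name, score, strand) -> GeneAnnotation."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError("gene BED requires 6 columns incl. strand")
            chrom, start, end, name, _score, strand = parts[:6]
            if int(start) >= int(end):
                raise FormatError(f"BED start >= end: {line.strip()!r}")
            genes.append(Gene(name, chrom, strand, int(start) + 1, int(end)))
    return GeneAnnotation(genes)


def write_islands(islands: CpGIslandSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in islands.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def write_genes(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(f"{g.chrom}\t{g.tx_start - 1}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------- tables

def read_expression(
    path: str | os.PathLike, annotation: GeneAnnotation | None = None
) -> ExpressionTable:
    """TSV columns: gene_id, sample_id, log2_expression."""
    df = pd.read_csv(path, sep="\t")
    values = {
        (str(r.gene_id), str(r.sample_id)): float(r.log2_expression)
        for r in df.itertuples()
    }
    return ExpressionTable(values, annotation)


def write_expression(table: ExpressionTable, path: str | os.PathLike) -> None:
    rows = [
        {"gene_id": g, "sample_id": s, "log2_expression": v}
        for (g, s), v in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_REARR_COLS = ["sample", "chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b", "class"]


def read_rearrangements(path: str | os.PathLike) -> list[RearrangementRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    if set(_REARR_COLS) <= set(df.columns):
        return [
            RearrangementRecord(
                str(r.sample), r.chrom_a, int(r.pos_a), r.chrom_b, int(r.pos_b),
                f"{r.strand_a}{r.strand_b}",
            )
            for r in df.itertuples()
        ]
    # BEDPE fallback: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 3: str})
    return [
        RearrangementRecord(
            str(row[6]) if len(row) > 6 else "NA",
            row[0], int(row[1]) + 1, row[3], int(row[4]) + 1,
            f"{row[8]}{row[9]}" if len(row) > 9 else "+-",
        )
        for _, row in df.iterrows()
    ]


def write_rearrangements(records: Iterable[RearrangementRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        s_a, s_b = (r.orientation + "+-")[:2]
        rows.append(
            {
                "sample": r.sample_id, "chrom_a": r.chrom_a, "pos_a": r.pos_a,
                "strand_a": s_a, "chrom_b": r.chrom_b, "pos_b": r.pos_b,
                "strand_b": s_b, "class": "NA",
            }
        )
    pd.DataFrame(rows, columns=_REARR_COLS).to_csv(path, sep="\t", index=False)
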