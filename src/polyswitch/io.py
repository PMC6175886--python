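"""File input/output: FASTA genomes, GFF3 gene models, VCF variant tables.

Readers lean on the established parsers (Biopython, gffutils, pysam); writers
emit the small, plain-text subsets of each format that the pipeline produces.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, VariantRecord, VariantTable


class VariantParseError(ValueError):
    """A variant file could not be parsed; the message locates the failure."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            common = f"{g.contig}\tpolyswitch\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(
                f"{common}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n"
                f"{common}mRNA\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(f"{common}exon\t{s}\t{e}{tail}.\tParent={g.gene_id}.t1\n")
            # phase of each CDS piece follows from the bases already consumed 5'->3'
            pieces = list(g.cds) if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phases = {}
            for s, e in pieces:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for s, e in g.cds:
                fh.write(f"{common}CDS\t{s}\t{e}{tail}{phases[(s, e)]}\tParent={g.gene_id}.t1\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS; first transcript per gene)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted((f.start, f.end) for f in db.children(parent, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
        if not exons:
            exons = cds
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF / TSV variant tables

_TSV_COLUMNS = ["contig", "position", "ref", "alt", "quality", "depth", "strain"]


def write_vcf(
    table: VariantTable,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write an SNV table as minimal VCF v4.2 (QUAL column, DP in INFO)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table.records:
            vr = out.new_record(
                contig=rec.contig,
                start=rec.position - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.quality,
            )
            vr.info["DP"] = int(rec.depth)
            out.write(vr)


def _load_vcf(path: Path, strain: str) -> VariantTable:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VariantParseError(f"{path}: malformed VCF header or file: {exc}") from exc
    records: list[VariantRecord] = []
    skipped = 0
    with vf:
        for i, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1  # multi-allelic or indel line: not an SNV
                continue
            if rec.ref not in "ACGT" or alts[0] not in "ACGT":
                skipped += 1
                continue
            try:
                records.append(
                    VariantRecord(
                        contig=rec.chrom,
                        position=rec.pos,
                        ref=rec.ref,
                        alt=alts[0],
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=int(rec.info.get("DP", 0)),
                        strain=strain,
                    )
                )
            except ValueError as exc:
                raise VariantParseError(f"{path}: record {i}: {exc}") from exc
    return VariantTable(records=tuple(records), n_skipped=skipped)


def _load_tsv(path: Path, strain: str) -> VariantTable:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # pandas raises several parser error types
        raise VariantParseError(f"{path}: malformed variant TSV: {exc}") from exc
    missing = [c for c in _TSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise VariantParseError(f"{path}: line 1: missing columns {missing}")
    records: list[VariantRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            skipped += 1
            continue
        try:
            records.append(
                VariantRecord(
                    contig=str(row.contig),
                    position=int(row.position),
                    ref=ref,
                    alt=alt,
                    quality=float(row.quality),
                    depth=int(float(row.depth)),
                    strain=str(getattr(row, "strain", strain) or strain),
                )
            )
        except ValueError as exc:
            raise VariantParseError(f"{path}: line {i}: {exc}") from exc
    return VariantTable(records=tuple(records), n_skipped=skipped)


def load_variants(path: str | os.PathLike, strain: str | None = None) -> VariantTable:
    """Load an SNV table from VCF v4.2 or the tab-separated dialect.

    Non-SNV lines (indels, multi-allelic sites) are skipped and counted in
    ``VariantTable.n_skipped``.  The strain defaults to the file stem.
    """
    path = Path(path)
    strain = strain if strain is not None else path.stem
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or first.startswith("##"):
        return _load_vcf(path, strain)
    return _load_tsv(path, strain)


def write_variants_tsv(table: VariantTable, path: str | os.PathLike) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)
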