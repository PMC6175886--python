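"""Core records shared across the pipeline: variants, gene models, genomes.

Coordinate conventions (used consistently everywhere):

* all genomic positions are 1-based;
* intervals are inclusive on both ends (GFF3-style);
* a genome is a plain ``dict`` mapping contig name to an upper-case sequence
  string, so ``genome[contig][pos - 1]`` is the base at ``pos``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

from Bio.Seq import Seq

Genome = Mapping[str, str]

_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single called SNV in one strain."""

    contig: str
    position: int
    ref: str
    alt: str
    quality: float = 0.0
    depth: int = 0
    strain: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.contig}:{self.position}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-strain matching; strain is deliberately excluded."""
        return (self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class VariantTable:
    """An ordered collection of SNVs, typically one strain's call set."""

    records: tuple[VariantRecord, ...] = ()
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records}

    def with_records(self, records: Iterable[VariantRecord]) -> "VariantTable":
        return replace(self, records=tuple(records))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "contig": r.contig,
                    "position": r.position,
                    "ref": r.ref,
                    "alt": r.alt,
                    "quality": r.quality,
                    "depth": r.depth,
                    "strain": r.strain,
                }
                for r in self.records
            ],
            columns=["contig", "position", "ref", "alt", "quality", "depth", "strain"],
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: exon and CDS intervals on one contig.

    ``exons`` and ``cds`` are tuples of 1-based inclusive ``(start, end)``
    intervals sorted by genomic start and non-overlapping.  ``cds`` must be
    contained in ``exons`` and its total length must be a codon multiple.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivs:
                if not (1 <= s <= e):
                    raise ValueError(f"{self.gene_id}: bad {name} interval ({s}, {e})")
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: {name} intervals unsorted or overlapping")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not a codon multiple")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_by_ordinal(self, ordinal: int) -> tuple[int, int]:
        """Exon interval by transcript-order ordinal (1-based, 5' to 3')."""
        if not 1 <= ordinal <= self.n_exons:
            raise ValueError(f"{self.gene_id}: no exon ordinal {ordinal} (gene has {self.n_exons})")
        idx = ordinal - 1 if self.strand == "+" else self.n_exons - ordinal
        return self.exons[idx]

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced CDS in transcript orientation (starts ATG for generated genes)."""
        seq = "".join(genome[self.contig][s - 1 : e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, position: int) -> int | None:
        """0-based offset of a genomic position within the plus-strand spliced CDS.

        Returns None when the position does not fall in the CDS.  For minus-strand
        genes use :meth:`transcript_offset` to get the transcript coordinate.
        """
        off = 0
        for s, e in self.cds:
            if s <= position <= e:
                return off + (position - s)
            off += e - s + 1
        return None

    def transcript_offset(self, position: int) -> int | None:
        """0-based offset of a genomic position within the oriented CDS."""
        off = self.cds_offset(position)
        if off is None:
            return None
        return off if self.strand == "+" else self.cds_length - 1 - off

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))


class GenomeAnnotation:
    """Indexed gene models with per-gene CDS caching for impact classification."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: tuple[GeneModel, ...] = tuple(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")
        self._index: dict[str, tuple[list[int], list[GeneModel]]] = {}
        self._max_span: dict[str, int] = {}
        for g in sorted(self.genes, key=lambda g: (g.contig, g.start)):
            starts, models = self._index.setdefault(g.contig, ([], []))
            starts.append(g.start)
            models.append(g)
            span = g.end - g.start + 1
            if span > self._max_span.get(g.contig, 0):
                self._max_span[g.contig] = span
        self._cds_cache: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_at(self, contig: str, position: int) -> list[GeneModel]:
        """Gene models whose span covers the position (usually 0 or 1)."""
        if contig not in self._index:
            return []
        starts, models = self._index[contig]
        i = bisect.bisect_right(starts, position)
        max_span = self._max_span.get(contig, 0)
        hits = []
        # genes are near-disjoint; scan back over the few spans that can still cover
        for j in range(i - 1, -1, -1):
            g = models[j]
            if g.end >= position:
                hits.append(g)
            if position - g.start >= max_span:
                break
        hits.reverse()
        return hits

    def cds_sequence(self, gene: GeneModel, genome: Genome) -> str:
        seq = self._cds_cache.get(gene.gene_id)
        if seq is None:
            seq = gene.cds_sequence(genome)
            self._cds_cache[gene.gene_id] = seq
        return seq


def translate(seq: str) -> str:
    """Standard-code translation of an in-frame nucleotide string."""
    return str(Seq(seq).translate())
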