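"""Two-allele suppressor-mapping cascade.

Starting from per-strain SNV call sets, the cascade (i) filters on call
quality, (ii) subtracts variants shared with background strains (the
mutagenised parental line and any marker strains used during backcrossing),
(iii) classifies the coding impact of each remaining variant against the
genome and gene models, (iv) keeps the potentially harmful classes
(nonsense, missense, splice-site), and (v) intersects harmful gene hits
across two independently derived mutant alleles.  A gene qualifies as a
candidate when both alleles carry at least one harmful variant in it and the
two alleles' harmful variants are not the identical set — two independent
EMS alleles of the same gene are expected to carry distinct lesions, whereas
an inherited (shared-background) lesion appears identically in both.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import (
    Genome,
    GenomeAnnotation,
    VariantRecord,
    VariantTable,
    revcomp,
    translate,
)

log = logging.getLogger(__name__)

#: bases into the intron, at each exon/intron boundary, treated as splice site
#: (covers the near-invariant GT donor / AG acceptor dinucleotides)
SPLICE_WINDOW = 2

#: impact classes kept by :func:`harmful_subset`
HARMFUL_CLASSES = frozenset({"nonsense", "missense", "splice_site"})

#: default automated stand-ins for manual curation of artefactual calls
DEFAULT_MIN_QUALITY = 20.0
DEFAULT_MIN_DEPTH = 5


class ReferenceMismatchError(ValueError):
    """A variant's REF base disagrees with the genome sequence."""


@dataclass(frozen=True, slots=True)
class ImpactCall:
    """Predicted consequence of a single SNV."""

    variant: VariantRecord
    gene_id: str | None
    impact: str  # nonsense | missense | synonymous | splice_site | noncoding
    codon_index: int | None = None  # 1-based codon ordinal within the CDS
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def aa_change(self) -> str | None:
        if self.ref_aa is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class GeneCandidate:
    gene_id: str
    calls_a: tuple[ImpactCall, ...]
    calls_b: tuple[ImpactCall, ...]

    @property
    def qualifying(self) -> bool:
        if not self.calls_a or not self.calls_b:
            return False
        keys_a = {c.variant.key for c in self.calls_a}
        keys_b = {c.variant.key for c in self.calls_b}
        return keys_a != keys_b

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted({c.variant.position for c in self.calls_a + self.calls_b}))


@dataclass(frozen=True)
class CandidateReport:
    """Per-gene harmful variants from each allele and the qualifying verdict."""

    candidates: tuple[GeneCandidate, ...]

    @property
    def qualifying_genes(self) -> tuple[str, ...]:
        return tuple(c.gene_id for c in self.candidates if c.qualifying)

    def __getitem__(self, gene_id: str) -> GeneCandidate:
        for c in self.candidates:
            if c.gene_id == gene_id:
                return c
        raise KeyError(gene_id)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for c in self.candidates:
            for label, calls in (("A", c.calls_a), ("B", c.calls_b)):
                for call in calls:
                    rows.append(
                        {
                            "gene": c.gene_id,
                            "allele": label,
                            "contig": call.variant.contig,
                            "position": call.variant.position,
                            "ref": call.variant.ref,
                            "alt": call.variant.alt,
                            "impact": call.impact,
                            "aa_change": call.aa_change,
                            "qualifying": c.qualifying,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "gene",
                "allele",
                "contig",
                "position",
                "ref",
                "alt",
                "impact",
                "aa_change",
                "qualifying",
            ],
        )

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "qualifying_genes": list(self.qualifying_genes),
            "genes": {
                c.gene_id: {
                    "qualifying": c.qualifying,
                    "allele_a": [
                        {"contig": v.variant.contig, "position": v.variant.position,
                         "ref": v.variant.ref, "alt": v.variant.alt,
                         "impact": v.impact, "aa_change": v.aa_change}
                        for v in c.calls_a
                    ],
                    "allele_b": [
                        {"contig": v.variant.contig, "position": v.variant.position,
                         "ref": v.variant.ref, "alt": v.variant.alt,
                         "impact": v.impact, "aa_change": v.aa_change}
                        for v in c.calls_b
                    ],
                }
                for c in self.candidates
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# cascade stages


def quality_filter(
    table: VariantTable,
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> VariantTable:
    """Keep calls with quality >= min_quality and depth >= min_depth."""
    if min_quality < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    return table.with_records(
        r for r in table.records if r.quality >= min_quality and r.depth >= min_depth
    )


def subtract_shared(target: VariantTable, backgrounds: Iterable[VariantTable]) -> VariantTable:
    """Remove variants present in any background strain.

    Matching is on (contig, position, ref, alt); the strain field is ignored.
    """
    shared: set[tuple[str, int, str, str]] = set()
    for bg in backgrounds:
        shared |= bg.keys()
    return target.with_records(r for r in target.records if r.key not in shared)


def classify_impact(
    variant: VariantRecord,
    annotation: GenomeAnnotation | Sequence,
    genome: Genome,
) -> ImpactCall:
    """Classify one SNV by translating its mutated codon.

    Coding SNVs are classified through the standard genetic code, with
    minus-strand genes handled by working in transcript orientation.
    Variants within ``SPLICE_WINDOW`` bases of the intron side of an
    exon/intron boundary are splice-site; everything else is noncoding.
    """
    if not isinstance(annotation, GenomeAnnotation):
        annotation = GenomeAnnotation(annotation)
    if variant.contig not in genome:
        raise ReferenceMismatchError(f"contig {variant.contig!r} not in genome")
    ref_base = genome[variant.contig][variant.position - 1]
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.contig}:{variant.position}: variant REF {variant.ref!r} "
            f"!= genome base {ref_base!r}"
        )

    splice_hit: ImpactCall | None = None
    for gene in annotation.genes_at(variant.contig, variant.position):
        off = gene.transcript_offset(variant.position)
        if off is not None:
            cds = annotation.cds_sequence(gene, genome)
            alt_t = variant.alt if gene.strand == "+" else revcomp(variant.alt)
            codon_i = off // 3
            within = off % 3
            ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
            alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
            ref_aa = translate(ref_codon)
            alt_aa = translate(alt_codon)
            if alt_aa == ref_aa:
                impact = "synonymous"
            elif alt_aa == "*":
                impact = "nonsense"
            else:
                impact = "missense"  # includes stop-loss in the terminal codon
            return ImpactCall(
                variant=variant,
                gene_id=gene.gene_id,
                impact=impact,
                codon_index=codon_i + 1,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        if splice_hit is None:
            for intron_start, intron_end in gene.introns():
                near_donor = intron_start <= variant.position < intron_start + SPLICE_WINDOW
                near_acceptor = intron_end - SPLICE_WINDOW < variant.position <= intron_end
                if near_donor or near_acceptor:
                    splice_hit = ImpactCall(
                        variant=variant, gene_id=gene.gene_id, impact="splice_site"
                    )
                    break
    if splice_hit is not None:
        return splice_hit
    return ImpactCall(variant=variant, gene_id=None, impact="noncoding")


def classify_table(
    table: VariantTable, annotation: GenomeAnnotation, genome: Genome
) -> list[ImpactCall]:
    return [classify_impact(v, annotation, genome) for v in table.records]


def harmful_subset(calls: Iterable[ImpactCall]) -> list[ImpactCall]:
    """Keep the potentially harmful classes: nonsense, missense, splice-site."""
    return [c for c in calls if c.impact in HARMFUL_CLASSES]


def intersect_candidates(
    harmful_a: Iterable[ImpactCall], harmful_b: Iterable[ImpactCall]
) -> CandidateReport:
    """Genes hit by non-identical harmful variants in both mutant alleles."""
    by_gene: dict[str, tuple[list[ImpactCall], list[ImpactCall]]] = {}
    for idx, calls in enumerate((harmful_a, harmful_b)):
        for call in calls:
            if call.gene_id is None:
                continue
            by_gene.setdefault(call.gene_id, ([], []))[idx].append(call)
    candidates = tuple(
        GeneCandidate(gene_id=g, calls_a=tuple(a), calls_b=tuple(b))
        for g, (a, b) in sorted(by_gene.items())
        if a and b
    )
    return CandidateReport(candidates=candidates)


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class MappingInputs:
    """Everything the cascade needs, already in memory."""

    mutant_a: VariantTable
    mutant_b: VariantTable
    backgrounds: Sequence[VariantTable]
    annotation: GenomeAnnotation
    genome: Genome
    min_quality: float = DEFAULT_MIN_QUALITY
    min_depth: int = DEFAULT_MIN_DEPTH


@dataclass
class MappingResult:
    report: CandidateReport
    stage_counts: list[tuple[str, str, int]] = field(default_factory=list)


def run_mapping(inputs: MappingInputs) -> MappingResult:
    """Run quality filter -> background subtraction -> impact -> intersection.

    ``stage_counts`` records (stage, allele label, variant count) after every
    stage, mirroring the provenance one would log in a mapping notebook.
    """
    counts: list[tuple[str, str, int]] = []
    harmful: dict[str, list[ImpactCall]] = {}
    for label, table in (("A", inputs.mutant_a), ("B", inputs.mutant_b)):
        counts.append(("loaded", label, len(table)))
        table = quality_filter(table, inputs.min_quality, inputs.min_depth)
        counts.append(("quality_filter", label, len(table)))
        table = subtract_shared(table, inputs.backgrounds)
        counts.append(("subtract_shared", label, len(table)))
        calls = classify_table(table, inputs.annotation, inputs.genome)
        kept = harmful_subset(calls)
        counts.append(("harmful_subset", label, len(kept)))
        harmful[label] = kept
    report = intersect_candidates(harmful["A"], harmful["B"])
    counts.append(("qualifying_genes", "AB", len(report.qualifying_genes)))
    for stage, label, n in counts:
        log.debug("mapping stage %-16s allele %s: %d", stage, label, n)
    return MappingResult(report=report, stage_counts=counts)
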