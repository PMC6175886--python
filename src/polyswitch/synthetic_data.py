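"""Generators for every input the pipeline consumes, with known ground truth.

The screen fixture emulates a two-allele EMS suppressor screen: a desk-scale
genome (by default 2 contigs x 50 protein-coding genes, ~4 Mb in total), a
shared mutagenised-parental background present in both mutant call sets, a
handful of strain-private EMS background SNVs (G:C->A:T biased), and one
causal gene carrying a distinct planted nonsense lesion per mutant allele in
two different exons.  Variant loads represent strains after several rounds of
backcrossing, which is when mapping-by-intersection is actually attempted.

Morph counts are drawn from a dosage-dependent binomial decision: with E
functional copies of the Eu-promoting X-linked gene and S functional copies
of the St-promoting autosomal gene, the Eu probability is
logistic(a + b*log2(E/S)), with hard boundaries all-Eu at S=0 and all-St at
E=0, and rare intermediates drawn independently.  Ct tables follow the
doubling arithmetic of qPCR (one cycle per twofold template change) with a
shared biological-replicate effect; codon pairs evolve by planting exact
numbers of synonymous and nonsynonymous single-site substitutions.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, GenomeAnnotation, VariantRecord, VariantTable, revcomp
from .molevol_dnds import (
    CodonAlignment,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
)
from .morph_stats import MorphCount

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """The requested fixture cannot be generated (e.g., no room for a lesion)."""


def _rng(seed_or_rng: int | np.random.Generator | Sequence[int]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASE_LUT[rng.integers(0, 4, size=length)].tobytes().decode()


def random_cds(rng: int | np.random.Generator, n_codons: int, with_stop: bool = True) -> str:
    """A random in-frame CDS: ATG, random sense codons, optional terminal stop."""
    rng = _rng(rng)
    if n_codons < 2:
        raise ValueError("a CDS needs at least a start and one more codon")
    n_body = n_codons - 2 if with_stop else n_codons - 1
    body = "".join(rng.choice(SENSE_CODONS, size=n_body)) if n_body else ""
    stop = rng.choice(sorted(STOP_CODONS)) if with_stop else ""
    return "ATG" + body + stop


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class MorphDecisionParams:
    """Logistic dosage-to-morph decision: P(Eu) = expit(a + b*log2(E/S))."""

    intercept: float = math.log(9.0)  # logit(0.9): the reference strain is ~90% Eu
    slope: float = 2.0  # log-odds per unit log2 dosage ratio
    intermediate_rate: float = 0.005  # upper bound of the observed "rare" intermediates

    def __post_init__(self) -> None:
        if not 0.0 <= self.intermediate_rate <= 1.0:
            raise ValueError("intermediate_rate must be a probability")

    def eu_probability(self, E: int, S: int) -> float:
        if E < 0 or S < 0:
            raise ValueError("copy numbers must be non-negative")
        if E == 0 and S == 0:
            raise ValueError("genotype with no copies of either gene is undefined")
        if S == 0:
            return 1.0
        if E == 0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-(self.intercept + self.slope * math.log2(E / S))))


@dataclass(frozen=True)
class ScreenFixtureParams:
    """Knobs of the synthetic suppressor-screen fixture (defaults = study conditions)."""

    n_contigs: int = 2
    genes_per_contig: int = 50
    gene_length_mean: int = 900  # mean CDS length, bp
    n_background_variants: float = 8.0  # Poisson mean of private EMS SNVs per mutant
    shared_parental_variants: int = 30  # background shared with parental/marker strains
    causal_gene_index: int = 42  # index into the flattened gene list
    lesion_exons: tuple[int, int] = (8, 1)  # transcript-order exon ordinal per allele
    ems_transition_bias: float = 0.85  # P(mutation is a G:C->A:T transition)
    causal_n_exons: int = 10
    min_exons: int = 2
    max_exons: int = 10
    intron_length: tuple[int, int] = (40, 200)
    intergenic_mean: int = 38_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_contigs,
            self.genes_per_contig,
            self.gene_length_mean,
            self.shared_parental_variants,
        )
        if min(counts) < 0 or self.n_background_variants < 0:
            raise ValueError("all counts must be non-negative")
        if not 0.0 <= self.ems_transition_bias <= 1.0:
            raise ValueError("ems_transition_bias must be in [0, 1]")
        n_genes = self.n_contigs * self.genes_per_contig
        if n_genes and not 0 <= self.causal_gene_index < n_genes:
            raise ValueError("causal_gene_index out of range")
        for ordinal in self.lesion_exons:
            if not 1 <= ordinal <= self.causal_n_exons:
                raise ValueError(
                    f"lesion exon ordinal {ordinal} outside the causal gene's "
                    f"{self.causal_n_exons} exons"
                )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth planted by the generator, for end-to-end verification."""

    causal_gene: str
    lesions: dict[str, VariantRecord]  # mutant strain -> planted lesion
    lesion_exons: dict[str, int]  # mutant strain -> transcript exon ordinal
    morph_params: MorphDecisionParams
    complementation: dict[str, tuple[str, ...]]  # group name -> mutant ids

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "causal_gene": self.causal_gene,
            "lesions": {
                strain: {
                    "contig": v.contig,
                    "position": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "exon_ordinal": self.lesion_exons[strain],
                }
                for strain, v in self.lesions.items()
            },
            "morph_params": {
                "intercept": self.morph_params.intercept,
                "slope": self.morph_params.slope,
                "intermediate_rate": self.morph_params.intermediate_rate,
            },
            "complementation": {g: list(ms) for g, ms in self.complementation.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


#: the seven-mutant complementation truth used by the screen fixture: three
#: groups, with the two causal-gene alleles forming the two-member group
DEFAULT_COMPLEMENTATION: dict[str, tuple[str, ...]] = {
    "seud-1": ("iub7", "iub8"),
    "sup-A": ("iub1", "iub2", "iub3"),
    "sup-B": ("iub4", "iub5"),
}


# ---------------------------------------------------------------------------
# reference genome + annotation


def _split_lengths(
    rng: np.random.Generator, total: int, n_parts: int, minimum: int
) -> np.ndarray:
    """Random composition of ``total`` into ``n_parts`` parts, each >= minimum."""
    if total < n_parts * minimum:
        raise GenerationError(
            f"cannot split {total} bp into {n_parts} exons of >= {minimum} bp"
        )
    weights = rng.dirichlet(np.full(n_parts, 5.0))
    lengths = minimum + np.floor(weights * (total - n_parts * minimum)).astype(int)
    lengths[-1] += total - lengths.sum()
    return lengths


def gen_reference(
    params: ScreenFixtureParams,
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Generate the reference genome and gene models.

    Every CDS starts with ATG, ends with a stop codon, contains no internal
    stop, and has a codon-multiple length; roughly half the genes are on the
    minus strand.  Exon and CDS intervals coincide (no UTRs are modelled).
    """
    rng = np.random.default_rng(params.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    min_exon = 18
    gene_counter = 0
    causal_idx = params.causal_gene_index

    for ci in range(params.n_contigs):
        contig = f"Contig{ci + 1}"
        pieces: list[str] = []
        cursor = 0  # 0-based length assembled so far
        for _ in range(params.genes_per_contig):
            gap = int(rng.integers(params.intergenic_mean // 2, params.intergenic_mean * 3 // 2))
            pieces.append(_random_seq(rng, gap))
            cursor += gap

            is_causal = gene_counter == causal_idx
            if is_causal:
                n_exons = params.causal_n_exons
            else:
                n_exons = int(rng.integers(params.min_exons, params.max_exons + 1))
            n_codons = max(
                n_exons * (min_exon // 3 + 2) + 2,
                int(round(rng.normal(params.gene_length_mean / 3.0, params.gene_length_mean / 15.0))),
            )
            cds = random_cds(rng, n_codons)
            exon_lengths = _split_lengths(rng, len(cds), n_exons, min_exon)

            lo, hi = params.intron_length
            intron_lengths = rng.integers(lo, hi + 1, size=n_exons - 1)
            exon_local: list[tuple[int, int]] = []  # 0-based [start, end) in gene layout
            gene_parts: list[str] = []
            off = 0
            cds_pos = 0
            for k, ex_len in enumerate(exon_lengths):
                exon_local.append((off, off + int(ex_len)))
                gene_parts.append(cds[cds_pos : cds_pos + int(ex_len)])
                cds_pos += int(ex_len)
                off += int(ex_len)
                if k < n_exons - 1:
                    il = int(intron_lengths[k])
                    gene_parts.append("GT" + _random_seq(rng, il - 4) + "AG")
                    off += il
            gene_seq = "".join(gene_parts)
            gene_len = len(gene_seq)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                gene_seq = revcomp(gene_seq)
                exon_local = sorted(
                    (gene_len - e, gene_len - s) for s, e in exon_local
                )
            pieces.append(gene_seq)
            gene_start_1 = cursor + 1  # 1-based contig coordinate of the gene's first base
            intervals = tuple(
                (gene_start_1 + s, gene_start_1 + e - 1) for s, e in exon_local
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_counter:04d}",
                    contig=contig,
                    strand=strand,
                    exons=intervals,
                    cds=intervals,
                )
            )
            cursor += gene_len
            gene_counter += 1
        pieces.append(_random_seq(rng, int(rng.integers(200, 800))))
        genome[contig] = "".join(pieces)
    return genome, GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# screen variant sets


@dataclass
class ScreenDataset:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    tables: dict[str, VariantTable]  # mutant_a, mutant_b, parental, marker
    truth: TruthRecord


def _gc_index(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for contig, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        out[contig] = np.flatnonzero((arr == ord("G")) | (arr == ord("C")))
    return out


_NON_EMS_ALTS = {"G": "CT", "C": "AG", "A": "CGT", "T": "ACG"}


def _draw_ems_snvs(
    rng: np.random.Generator,
    genome: Mapping[str, str],
    gc_index: Mapping[str, np.ndarray],
    n: int,
    bias: float,
    taken: set[tuple[str, int]],
) -> list[tuple[str, int, str, str]]:
    """Draw n EMS-spectrum SNV sites: (contig, 1-based position, ref, alt)."""
    contigs = list(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    out: list[tuple[str, int, str, str]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * (n + 10):
            raise GenerationError("could not place the requested number of SNVs")
        contig = contigs[int(rng.choice(len(contigs), p=weights))]
        if rng.random() < bias:
            idx = gc_index[contig]
            if idx.size == 0:
                continue
            pos0 = int(idx[int(rng.integers(idx.size))])
            ref = genome[contig][pos0]
            alt = "A" if ref == "G" else "T"
        else:
            pos0 = int(rng.integers(len(genome[contig])))
            ref = genome[contig][pos0]
            alts = _NON_EMS_ALTS[ref]
            alt = alts[int(rng.integers(len(alts)))]
        key = (contig, pos0 + 1)
        if key in taken:
            continue
        taken.add(key)
        out.append((contig, pos0 + 1, ref, alt))
    return out


def _plant_nonsense(
    rng: np.random.Generator,
    gene: GeneModel,
    genome: Mapping[str, str],
    exon_ordinal: int,
    strain: str,
) -> VariantRecord:
    """Plant a single-base nonsense change in the given transcript exon."""
    cds = gene.cds_sequence(genome)
    n_codons = len(cds) // 3
    s, e = gene.exon_by_ordinal(exon_ordinal)
    candidates: list[tuple[int, str, bool]] = []  # (genomic pos, genomic alt, is_ems)
    for pos in range(s, e + 1):
        t_off = gene.transcript_offset(pos)
        if t_off is None:
            continue
        codon_i = t_off // 3
        if codon_i >= n_codons - 1 or codon_i == 0:
            continue  # leave the start and terminal stop codons alone
        within = t_off % 3
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        for alt_t in "ACGT":
            if alt_t == ref_codon[within]:
                continue
            alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
            if alt_codon in STOP_CODONS:
                ref_t = ref_codon[within]
                is_ems = (ref_t, alt_t) in (("G", "A"), ("C", "T"))
                alt_g = alt_t if gene.strand == "+" else revcomp(alt_t)
                candidates.append((pos, alt_g, is_ems))
    if not candidates:
        raise GenerationError(
            f"{gene.gene_id}: exon {exon_ordinal} has no room for a nonsense change"
        )
    ems = [c for c in candidates if c[2]]
    pool = ems if ems else candidates
    pos, alt_g, _ = pool[int(rng.integers(len(pool)))]
    return VariantRecord(
        contig=gene.contig,
        position=pos,
        ref=genome[gene.contig][pos - 1],
        alt=alt_g,
        quality=60.0,
        depth=30,
        strain=strain,
    )


def gen_screen_dataset(
    reference: tuple[dict[str, str], GenomeAnnotation],
    params: ScreenFixtureParams,
) -> ScreenDataset:
    """Generate the four per-strain variant tables and the truth record.

    ``mutant_a``/``mutant_b`` each carry: the shared parental/marker
    background, a Poisson number of private EMS SNVs, and one planted
    nonsense lesion in the causal gene (allele A in ``lesion_exons[0]``,
    allele B in ``lesion_exons[1]``).  ``parental`` and ``marker`` hold the
    respective shared backgrounds.
    """
    genome, annotation = reference
    rng = np.random.default_rng([params.seed, 2_718_281])
    if len(annotation) == 0:
        raise GenerationError("reference contains no genes")
    causal = annotation.genes[params.causal_gene_index]
    gc_idx = _gc_index(genome)
    taken: set[tuple[str, int]] = set()

    lesion_a = _plant_nonsense(rng, causal, genome, params.lesion_exons[0], "mutant_a")
    lesion_b = _plant_nonsense(rng, causal, genome, params.lesion_exons[1], "mutant_b")
    if lesion_a.key == lesion_b.key:
        raise GenerationError("the two planted lesions coincide; widen lesion_exons")
    taken.add((lesion_a.contig, lesion_a.position))
    taken.add((lesion_b.contig, lesion_b.position))

    n_parental = int(math.ceil(params.shared_parental_variants * 0.7))
    shared = _draw_ems_snvs(
        rng, genome, gc_idx, params.shared_parental_variants,
        params.ems_transition_bias, taken,
    )
    shared_parental, shared_marker = shared[:n_parental], shared[n_parental:]

    def _records(sites, strain) -> list[VariantRecord]:
        recs = []
        for contig, pos, ref, alt in sites:
            recs.append(
                VariantRecord(
                    contig=contig,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    quality=float(rng.uniform(5.0, 60.0)),
                    depth=int(rng.poisson(24)),
                    strain=strain,
                )
            )
        return recs

    tables: dict[str, VariantTable] = {}
    for strain, lesion in (("mutant_a", lesion_a), ("mutant_b", lesion_b)):
        n_bg = int(rng.poisson(params.n_background_variants))
        private = _draw_ems_snvs(
            rng, genome, gc_idx, n_bg, params.ems_transition_bias, taken
        )
        records = (
            [lesion]
            + _records(shared_parental + shared_marker, strain)
            + _records(private, strain)
        )
        records.sort(key=lambda r: (r.contig, r.position))
        tables[strain] = VariantTable(records=tuple(records))
    tables["parental"] = VariantTable(
        records=tuple(
            sorted(_records(shared_parental, "parental"), key=lambda r: (r.contig, r.position))
        )
    )
    tables["marker"] = VariantTable(
        records=tuple(
            sorted(_records(shared_marker, "marker"), key=lambda r: (r.contig, r.position))
        )
    )

    truth = TruthRecord(
        causal_gene=causal.gene_id,
        lesions={"mutant_a": lesion_a, "mutant_b": lesion_b},
        lesion_exons={
            "mutant_a": params.lesion_exons[0],
            "mutant_b": params.lesion_exons[1],
        },
        morph_params=MorphDecisionParams(),
        complementation=dict(DEFAULT_COMPLEMENTATION),
    )
    return ScreenDataset(genome=genome, annotation=annotation, tables=tables, truth=truth)


def gen_screen_fixture(params: ScreenFixtureParams | None = None) -> ScreenDataset:
    """Convenience: gen_reference + gen_screen_dataset with one parameter set."""
    params = params or ScreenFixtureParams()
    return gen_screen_dataset(gen_reference(params), params)


def gen_complementation_matrix(
    partition: Mapping[str, Sequence[str]] | None = None,
):
    """A consistent pairwise complementation matrix from a true partition."""
    from .cross_genetics import ComplementationMatrix

    partition = partition or DEFAULT_COMPLEMENTATION
    mutants = [m for group in partition.values() for m in group]
    pairs = [
        (a, b)
        for group in partition.values()
        for i, a in enumerate(group)
        for b in list(group)[i + 1 :]
    ]
    return ComplementationMatrix.from_pairs(mutants, pairs)


# ---------------------------------------------------------------------------
# morph counts


def simulate_morph_counts(
    E: int,
    S: int,
    n: int,
    params: MorphDecisionParams | None = None,
    rng: int | np.random.Generator = 0,
    line: str | None = None,
    replicate: str = "1",
) -> MorphCount:
    """Draw one clone's morph tally under the dosage decision model.

    Intermediates are drawn first at ``intermediate_rate``; the remaining
    individuals are Eu with probability logistic(a + b*log2(E/S)), with the
    hard boundaries all-Eu (S=0) and all-St (E=0).
    """
    params = params or MorphDecisionParams()
    rng = _rng(rng)
    if n < 0:
        raise ValueError("n must be non-negative")
    p_eu = params.eu_probability(E, S)  # validates E, S
    n_int = int(rng.binomial(n, params.intermediate_rate)) if n else 0
    remaining = n - n_int
    if p_eu == 1.0:
        n_eu = remaining
    elif p_eu == 0.0:
        n_eu = 0
    else:
        n_eu = int(rng.binomial(remaining, p_eu)) if remaining else 0
    return MorphCount(
        line=line if line is not None else f"E{E}S{S}",
        replicate=replicate,
        n_eu=n_eu,
        n_st=remaining - n_eu,
        n_intermediate=n_int,
    )


def simulate_dosage_panel(
    classes: Sequence[tuple[int, int]],
    n_per_class: int,
    params: MorphDecisionParams | None = None,
    rng: int | np.random.Generator = 0,
    n_replicates: int = 1,
) -> list[MorphCount]:
    """Morph counts across a panel of (E, S) dosage classes."""
    rng = _rng(rng)
    out = []
    for E, S in classes:
        for rep in range(1, n_replicates + 1):
            out.append(
                simulate_morph_counts(
                    E, S, n_per_class, params=params, rng=rng, replicate=str(rep)
                )
            )
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_ct_table(
    groups: Sequence[str],
    target_genes: Sequence[str],
    reference_genes: Sequence[str],
    log2fc: Mapping[tuple[str, str], float] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    noise_sd: float = 0.0,
    bio_sd: float = 0.4,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a Ct table: groups x genes x (bio x tech) replicates.

    ``log2fc[(group, gene)]`` is the true log2 expression change of a target
    gene in a group relative to baseline (unset entries are 0; reference
    genes are always unchanged).  Ct decreases by one cycle per doubling of
    template.  The biological-replicate effect (sd ``bio_sd``) acts on the
    whole sample, i.e., is shared by every gene and technical replicate of
    that biological replicate, so it cancels in ΔCt exactly; ``noise_sd`` is
    per-well technical noise.
    """
    rng = _rng(rng)
    log2fc = dict(log2fc or {})
    if not reference_genes:
        raise ValueError("design needs at least one reference gene per sample")
    base_ct = {g: float(rng.uniform(18.0, 26.0)) for g in [*target_genes, *reference_genes]}
    rows = []
    for group in groups:
        for bio in range(1, n_bio + 1):
            sample_effect = float(rng.normal(0.0, bio_sd)) if bio_sd > 0 else 0.0
            for gene in [*target_genes, *reference_genes]:
                fc = log2fc.get((group, gene), 0.0) if gene in target_genes else 0.0
                mean_ct = base_ct[gene] - fc + sample_effect
                for tech in range(1, n_tech + 1):
                    eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "strain": group,
                            "gene": gene,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": mean_ct + eps,
                        }
                    )
    return pd.DataFrame(rows, columns=["strain", "gene", "bio_rep", "tech_rep", "ct"])


def gen_titration(
    factor: float = 2.0,
    n_points: int = 5,
    intercept: float = 30.0,
    rng: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """A log-dilution series with Ct slope -1/log10(factor) per log10 input."""
    rng = _rng(rng)
    dilutions = -np.arange(n_points, dtype=float)  # 0, -1, ..., -(n-1) log10 units
    slope = -1.0 / math.log10(factor)
    ct = intercept + slope * dilutions
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"log10_dilution": dilutions, "ct": ct})


# ---------------------------------------------------------------------------
# codon-pair evolution


def evolve_codon_pair(
    cds: str,
    n_syn: int,
    n_nonsyn: int,
    rng: int | np.random.Generator = 0,
) -> CodonAlignment:
    """Derive a partner sequence by exactly ``n_syn`` synonymous and
    ``n_nonsyn`` nonsynonymous single-base substitutions in distinct codons.

    Substitutions never create stop codons.  Raises
    :class:`GenerationError` when the sequence has too few codons admitting
    the requested change types.
    """
    rng = _rng(rng)
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a codon multiple")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    editable = [
        i
        for i, c in enumerate(codons)
        if c not in STOP_CODONS or i < len(codons) - 1
    ]
    # never touch a terminal stop codon: invisible to (and invalid for) dN/dS
    if codons and codons[-1] in STOP_CODONS:
        editable = [i for i in editable if i != len(codons) - 1]

    def options(codon: str, synonymous: bool) -> list[str]:
        aa = GENETIC_CODE[codon]
        outs = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if (GENETIC_CODE[mutant] == aa) == synonymous:
                    outs.append(mutant)
        return outs

    order = list(rng.permutation(editable))
    mutated = list(codons)
    chosen_syn: list[int] = []
    chosen_nonsyn: list[int] = []
    for i in order:
        if len(chosen_syn) < n_syn and options(codons[i], True):
            chosen_syn.append(i)
        elif len(chosen_nonsyn) < n_nonsyn and options(codons[i], False):
            chosen_nonsyn.append(i)
        if len(chosen_syn) == n_syn and len(chosen_nonsyn) == n_nonsyn:
            break
    if len(chosen_syn) < n_syn or len(chosen_nonsyn) < n_nonsyn:
        raise GenerationError(
            f"CDS of {len(codons)} codons cannot host {n_syn} synonymous + "
            f"{n_nonsyn} nonsynonymous substitutions in distinct codons"
        )
    for i in chosen_syn:
        opts = options(codons[i], True)
        mutated[i] = opts[int(rng.integers(len(opts)))]
    for i in chosen_nonsyn:
        opts = options(codons[i], False)
        mutated[i] = opts[int(rng.integers(len(opts)))]
    return CodonAlignment(seq_a=cds, seq_b="".join(mutated))


# ---------------------------------------------------------------------------
# on-disk emission


def write_screen_dataset(dataset: ScreenDataset, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write genome.fa, genes.gff3, per-strain VCFs, and truth.json."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    pio.write_fasta(dataset.genome, paths["genome"])
    paths["gff"] = outdir / "genes.gff3"
    pio.write_gff3(dataset.annotation.genes, paths["gff"])
    contig_lengths = {c: len(s) for c, s in dataset.genome.items()}
    for strain, table in dataset.tables.items():
        p = outdir / f"{strain}.vcf"
        pio.write_vcf(table, p, contig_lengths)
        paths[strain] = p
    paths["truth"] = outdir / "truth.json"
    dataset.truth.to_json(paths["truth"])
    return paths
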