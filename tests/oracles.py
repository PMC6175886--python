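"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: the dN/dS oracle
re-derives sites and pathway-averaged differences by direct enumeration with
Biopython translation, and the impact oracle rebuilds and translates the
complete mutant CDS instead of mutating a single codon.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


@lru_cache(maxsize=None)
def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86 oracle


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in STOPS and aa_of(mut) == aa_of(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_codon_diffs(a: str, b: str) -> tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in permutations(positions):
        cur = a
        sd = nd = 0
        ok = True
        for step_idx, pos in enumerate(order):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS and step_idx < len(order) - 1:
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        sd = nd = 0
        for pos in positions:
            single = a[:pos] + b[pos] + a[pos + 1 :]
            if aa_of(single) == aa_of(a):
                sd += 1
            else:
                nd += 1
        return float(sd), float(nd)
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def oracle_ng86(seq_a: str, seq_b: str) -> dict[str, float | None]:
    import math

    codons = [
        (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
    ]
    if codons and (codons[-1][0] in STOPS or codons[-1][1] in STOPS):
        codons = codons[:-1]
    S = sum((oracle_codon_sites(a)[0] + oracle_codon_sites(b)[0]) / 2 for a, b in codons)
    N = 3 * len(codons) - S
    Sd = sum(oracle_codon_diffs(a, b)[0] for a, b in codons)
    Nd = sum(oracle_codon_diffs(a, b)[1] for a, b in codons)
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    dS, dN = jc(pS), jc(pN)
    return {
        "S": S, "N": N, "Sd": Sd, "Nd": Nd,
        "pS": pS, "pN": pN,
        "dS": dS, "dN": dN,
        "omega": None if dS in (None, 0) or dN is None else dN / dS,
    }


# ---------------------------------------------------------------------------
# full-CDS-rebuild impact oracle


def oracle_impact(variant, gene, genome) -> str:
    """Classify an SNV by rebuilding and translating the entire mutant CDS."""
    in_cds = any(s <= variant.position <= e for s, e in gene.cds)
    if not in_cds:
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            intron_start, intron_end = e1 + 1, s2 - 1
            if (
                intron_start <= variant.position <= intron_start + 1
                or intron_end - 1 <= variant.position <= intron_end
            ):
                return "splice_site"
        return "noncoding"
    contig = genome[variant.contig]
    mutant_contig = (
        contig[: variant.position - 1] + variant.alt + contig[variant.position :]
    )
    mutant_genome = dict(genome)
    mutant_genome[variant.contig] = mutant_contig
    wt_protein = aa_of(gene.cds_sequence(genome))
    mut_protein = aa_of(gene.cds_sequence(mutant_genome))
    if wt_protein == mut_protein:
        return "synonymous"
    diffs = [i for i, (w, m) in enumerate(zip(wt_protein, mut_protein)) if w != m]
    assert len(diffs) == 1, "an SNV must change at most one amino acid"
    return "nonsense" if mut_protein[diffs[0]] == "*" else "missense"
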