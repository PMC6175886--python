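"""Pairwise dN/dS by the Nei–Gojobori (1986) counting method.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the nine possible single-base changes that preserve the encoded amino
acid; *differences* between two codons are averaged over all minimal
substitution pathways, excluding pathways that pass through a stop codon.
Proportions of differences per site are corrected for multiple hits with
the Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3), and omega = dN/dS.

Conventions (unweighted NG86, universal code):

* a change *to* a stop codon counts as nonsynonymous in site counting;
* pathways through stop codons are dropped and the survivors re-weighted
  equally; in the (degenerate) case where every pathway is blocked, each
  differing position is classified independently against the first codon;
* omega is ``None`` (undefined), not infinity, when dS = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

_BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
#: codon -> amino acid, stops mapped to '*'
GENETIC_CODE = dict(_STANDARD.forward_table)
GENETIC_CODE.update({c: "*" for c in STOP_CODONS})
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))


class CodonAlignmentError(ValueError):
    """The input pair is not a valid gap-free codon alignment."""


class UndefinedDistanceError(ValueError):
    """Jukes–Cantor correction undefined (p >= 3/4)."""


def _check_coding(seq: str, label: str) -> None:
    if len(seq) % 3 != 0:
        raise CodonAlignmentError(f"{label}: length {len(seq)} not a multiple of 3")
    if set(seq) - set(_BASES):
        bad = sorted(set(seq) - set(_BASES))
        raise CodonAlignmentError(f"{label}: non-ACGT characters {bad} (strip gaps upstream)")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS:
            raise CodonAlignmentError(f"{label}: internal stop codon {codon} at codon {i + 1}")


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned, gap-free coding sequences of equal length."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise CodonAlignmentError(
                f"sequence lengths differ ({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        _check_coding(self.seq_a, "seq_a")
        _check_coding(self.seq_b, "seq_b")

    def codon_pairs(self, drop_terminal_stop: bool = True) -> list[tuple[str, str]]:
        pairs = [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]
        if drop_terminal_stop and pairs and (
            pairs[-1][0] in STOP_CODONS or pairs[-1][1] in STOP_CODONS
        ):
            pairs = pairs[:-1]
        return pairs


@dataclass(frozen=True)
class Ng86Result:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS = 0

    @property
    def omega_rounded(self) -> float | None:
        return None if self.omega is None else round(self.omega, 3)


def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    At each of the three positions, the synonymous fraction is the number of
    the three possible base changes that preserve the amino acid, divided by
    three; changes to stop codons count as nonsynonymous.  s + n = 3.
    """
    codon = codon.upper()
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Counts are averaged over all orderings of the differing positions,
    excluding orderings whose intermediate codons are stops.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    path_counts: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if not blocked:
            path_counts.append((sd, nd))

    if not path_counts:
        # every ordering passes through a stop: classify positions independently
        sd = nd = 0.0
        for pos in diff_positions:
            single = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
            if GENETIC_CODE[single] == GENETIC_CODE[codon_a]:
                sd += 1.0
            else:
                nd += 1.0
        return sd, nd

    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        raise UndefinedDistanceError(f"p = {p:.4f} >= 3/4; Jukes–Cantor correction undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: CodonAlignment) -> Ng86Result:
    """Nei–Gojobori dN/dS for one aligned coding-sequence pair.

    A terminal stop codon (present in either sequence) is excluded from the
    counts, as is standard for protein-coding distance estimation.
    """
    pairs = pair.codon_pairs(drop_terminal_stop=True)
    if not pairs:
        raise CodonAlignmentError("alignment contains no comparable codons")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        s_a += codon_sites(ca)[0]
        s_b += codon_sites(cb)[0]
        d = codon_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    n_codons = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = None if dS == 0.0 else dN / dS
    return Ng86Result(S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega)


def amino_acid_identity(pair: CodonAlignment) -> float:
    """Fraction of codon positions encoding the same amino acid."""
    pairs = pair.codon_pairs(drop_terminal_stop=True)
    same = sum(1 for a, b in pairs if GENETIC_CODE[a] == GENETIC_CODE[b])
    return same / len(pairs)
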