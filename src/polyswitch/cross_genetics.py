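"""Mendelian cross engine for functional gene dosage under XX/XO sex determination.

The system has two opposing switch loci: the X-linked sulfatase gene *eud-1*
(Eu-promoting) and the autosomal sulfotransferase gene *seud-1*
(St-promoting).  *P. exspectatus* carries a recent duplication of *seud-1*
(*seud-1.1* and *seud-1.2*, both functional), so interspecies hybrids can be
built with E:S functional-copy ratios unreachable within one species.  The
engine enumerates exact gamete and offspring distributions, computes the
(E, S) dosage of any genotype, and partitions mutants into complementation
groups.

Sexes are karyotypes: ``"XX"`` (hermaphrodite in *P. pacificus*, female in
*P. exspectatus* and hybrids) and ``"XO"`` (male).  An XO father transmits an
X-bearing and a nullo-X sperm class at 1/2 each, so male-sired broods are
half XX, half XO.  Hermaphrodite self-sperm are modelled as all X-bearing
(the rare nullo-X self-sperm that yield spontaneous males are ignored).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

XX = "XX"
XO = "XO"

FUNCTIONAL = "functional"
NULL = "null"


@dataclass(frozen=True, slots=True)
class Locus:
    name: str
    linkage: str  # "autosomal" | "X"

    def __post_init__(self) -> None:
        if self.linkage not in ("autosomal", "X"):
            raise ValueError(f"linkage must be 'autosomal' or 'X', got {self.linkage!r}")


#: the loci of the switch system; paralogs of seud-1 are separate autosomal loci
LOCI: dict[str, Locus] = {
    "eud-1": Locus("eud-1", "X"),
    "seud-1": Locus("seud-1", "autosomal"),
    "seud-1.1": Locus("seud-1.1", "autosomal"),
    "seud-1.2": Locus("seud-1.2", "autosomal"),
}

#: loci whose functional copies sum into the S dosage
SEUD_LOCI = ("seud-1", "seud-1.1", "seud-1.2")

#: loci carried by each species' haploid genome
SPECIES_LOCI: dict[str, tuple[str, ...]] = {
    "P. pacificus": ("eud-1", "seud-1"),
    "P. exspectatus": ("eud-1", "seud-1.1", "seud-1.2"),
}


def _freeze(alleles: Mapping[str, Sequence[str]]) -> tuple[tuple[str, tuple[str, ...]], ...]:
    return tuple(sorted((name, tuple(states)) for name, states in alleles.items()))


@dataclass(frozen=True)
class Genotype:
    """Sex (karyotype) plus per-locus allele states, one per chromosome copy."""

    sex: str
    alleles: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if self.sex not in (XX, XO):
            raise ValueError(f"sex must be '{XX}' or '{XO}', got {self.sex!r}")
        for name, states in self.alleles:
            locus = LOCI[name]
            for s in states:
                if s not in (FUNCTIONAL, NULL):
                    raise ValueError(f"{name}: allele state must be functional/null, got {s!r}")
            if locus.linkage == "X":
                expected = 2 if self.sex == XX else 1
                if len(states) != expected:
                    raise ValueError(
                        f"{name}: X-linked locus needs {expected} allele slot(s) "
                        f"in an {self.sex} individual, got {len(states)}"
                    )
            elif not 1 <= len(states) <= 2:
                raise ValueError(f"{name}: autosomal locus needs 1 or 2 slots")

    @property
    def allele_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.alleles)

    def states(self, locus: str) -> tuple[str, ...]:
        return self.allele_map.get(locus, ())


def genotype(sex: str, **alleles: Sequence[str] | str) -> Genotype:
    """Convenience constructor: ``genotype("XX", eud_1=("functional", "null"))``.

    Locus names may use underscores in place of hyphens/dots for keyword use.
    """
    canonical = {}
    for key, states in alleles.items():
        name = _canonical_locus(key)
        if isinstance(states, str):
            states = (states,)
        canonical[name] = tuple(states)
    return Genotype(sex=sex, alleles=_freeze(canonical))


def _canonical_locus(key: str) -> str:
    if key in LOCI:
        return key
    cleaned = key.replace("__", ".").replace("_", "-")
    for name in LOCI:
        if name.replace("-", "").replace(".", "") == key.replace("_", ""):
            return name
    if cleaned in LOCI:
        return cleaned
    raise KeyError(f"unknown locus {key!r}; known: {sorted(LOCI)}")


# ---------------------------------------------------------------------------
# reference genotypes


def wildtype(species: str, sex: str = XX) -> Genotype:
    """A wild-type individual of the given species."""
    alleles = {}
    for name in SPECIES_LOCI[species]:
        if LOCI[name].linkage == "X":
            alleles[name] = (FUNCTIONAL,) * (2 if sex == XX else 1)
        else:
            alleles[name] = (FUNCTIONAL, FUNCTIONAL)
    return Genotype(sex=sex, alleles=_freeze(alleles))


def pacificus_mutant(
    eud_1: Sequence[str] | None = None,
    seud_1: Sequence[str] | None = None,
    sex: str = XX,
) -> Genotype:
    """A *P. pacificus* genotype with explicit allele states (defaults wild type)."""
    x_slots = 2 if sex == XX else 1
    return genotype(
        sex,
        eud_1=tuple(eud_1) if eud_1 is not None else (FUNCTIONAL,) * x_slots,
        seud_1=tuple(seud_1) if seud_1 is not None else (FUNCTIONAL, FUNCTIONAL),
    )


# ---------------------------------------------------------------------------
# gametes and crosses


class Gamete(NamedTuple):
    """A haploid genome: carries an X (with its alleles) or not, plus autosomes."""

    has_x: bool
    alleles: tuple[tuple[str, str], ...]  # (locus, state) for loci present

    @property
    def allele_map(self) -> dict[str, str]:
        return dict(self.alleles)


def gametes(
    parent: Genotype,
    co_transmit: Sequence[Sequence[str]] = (),
) -> dict[Gamete, float]:
    """Exact gamete distribution of a parent.

    XX parents transmit one X per gamete; XO parents transmit their X to half
    of gametes and no X to the other half.  Autosomal loci assort
    independently unless grouped in ``co_transmit``, in which case the loci of
    a group travel on the same haplotype (slot index chosen together).
    """
    allele_map = parent.allele_map
    x_loci = [n for n in allele_map if LOCI[n].linkage == "X"]
    auto_loci = [n for n in allele_map if LOCI[n].linkage == "autosomal"]

    linked: dict[str, int] = {}
    groups: list[list[str]] = []
    for gi, group in enumerate(co_transmit):
        names = [_canonical_locus(n) for n in group]
        groups.append(names)
        for n in names:
            linked[n] = gi
    free = [n for n in auto_loci if n not in linked]
    group_present = [
        [n for n in names if n in allele_map] for names in groups
    ]

    # each independent unit contributes a list of (partial allele assignment, prob)
    units: list[list[tuple[dict[str, str], float]]] = []
    for name in free:
        states = allele_map[name]
        choices: dict[tuple[str, str], float] = {}
        for s in states:
            key = (name, s)
            choices[key] = choices.get(key, 0.0) + 1.0 / len(states)
        units.append([({name: s}, p) for (_, s), p in choices.items()])
    for names in group_present:
        if not names:
            continue
        n_slots = len(allele_map[names[0]])
        if any(len(allele_map[n]) != n_slots for n in names):
            raise ValueError("co-transmitted loci must have equal slot counts")
        units.append(
            [({n: allele_map[n][k] for n in names}, 1.0 / n_slots) for k in range(n_slots)]
        )

    # X transmission
    x_units: list[tuple[bool, dict[str, str], float]] = []
    if parent.sex == XX:
        per_copy: dict[tuple, float] = {}
        for k in range(2):
            key = tuple((n, allele_map[n][k]) for n in x_loci)
            per_copy[key] = per_copy.get(key, 0.0) + 0.5
        for key, p in per_copy.items():
            x_units.append((True, dict(key), p))
    else:
        x_units.append((True, {n: allele_map[n][0] for n in x_loci}, 0.5))
        x_units.append((False, {}, 0.5))

    out: dict[Gamete, float] = {}
    for has_x, x_assign, p_x in x_units:
        for combo in itertools.product(*units) if units else [()]:
            assign = dict(x_assign)
            p = p_x
            for partial, pp in combo:
                assign.update(partial)
                p *= pp
            g = Gamete(has_x=has_x, alleles=tuple(sorted(assign.items())))
            out[g] = out.get(g, 0.0) + p
    return out


def _combine(maternal: Gamete, paternal: Gamete) -> Genotype:
    if not maternal.has_x:
        raise ValueError("oocytes must carry an X")
    sex = XX if paternal.has_x else XO
    alleles: dict[str, list[str]] = {}
    for gam in (maternal, paternal):
        for name, state in gam.alleles:
            alleles.setdefault(name, []).append(state)
    return Genotype(sex=sex, alleles=_freeze(alleles))


def cross(
    mother: Genotype,
    father: Genotype,
    co_transmit: Sequence[Sequence[str]] = (),
) -> dict[Genotype, float]:
    """Exact offspring distribution (sexes included) of mother x father."""
    if father.sex != XO:
        raise ValueError("father must be XO (male)")
    out: dict[Genotype, float] = {}
    for gm, pm in gametes(mother, co_transmit).items():
        for gf, pf in gametes(father, co_transmit).items():
            child = _combine(gm, gf)
            out[child] = out.get(child, 0.0) + pm * pf
    return out


def self_cross(parent: Genotype) -> dict[Genotype, float]:
    """Hermaphrodite selfing with all-X self sperm (all offspring XX)."""
    if parent.sex != XX:
        raise ValueError("only XX hermaphrodites self-fertilise")
    out: dict[Genotype, float] = {}
    gs = gametes(parent)
    for gm, pm in gs.items():
        for gf, pf in gs.items():
            child = _combine(gm, gf)
            out[child] = out.get(child, 0.0) + pm * pf
    return out


def sample_cross(
    mother: Genotype,
    father: Genotype,
    n: int,
    rng: np.random.Generator,
) -> dict[Genotype, int]:
    """Monte-Carlo sample of offspring (for convergence checks against cross())."""
    dist = cross(mother, father)
    children = list(dist)
    probs = np.array([dist[c] for c in children])
    draws = rng.multinomial(n, probs / probs.sum())
    return {c: int(k) for c, k in zip(children, draws) if k}


# ---------------------------------------------------------------------------
# dosage


class DosageRatio(NamedTuple):
    E: int  # functional eud-1 copies
    S: int  # functional seud-1 copies, summed over paralogs


def functional_dosage(g: Genotype, locus: str) -> int:
    return sum(1 for s in g.states(_canonical_locus(locus)) if s == FUNCTIONAL)


def dosage_ratio(g: Genotype) -> DosageRatio:
    E = functional_dosage(g, "eud-1")
    S = sum(functional_dosage(g, name) for name in SEUD_LOCI)
    return DosageRatio(E, S)


def morph_regime(
    ratio: DosageRatio,
    intercept: float | None = None,
    slope: float | None = None,
) -> str:
    """Qualitative expectation for a dosage class under the default decision model.

    ``all-Eu``/``all-St`` are the hard boundaries (no functional seud-1 /
    no functional eud-1); ``almost all-Eu``/``almost all-St`` mark classes
    whose expected Eu fraction exceeds 0.95 or falls below 0.05; everything
    else is ``graded``.
    """
    from .synthetic_data import MorphDecisionParams

    defaults = MorphDecisionParams()
    a = defaults.intercept if intercept is None else intercept
    b = defaults.slope if slope is None else slope
    E, S = ratio
    if E == 0 and S == 0:
        raise ValueError("dosage undefined for a genotype with no switch-gene copies")
    if S == 0:
        return "all-Eu"
    if E == 0:
        return "all-St"
    p = 1.0 / (1.0 + np.exp(-(a + b * np.log2(E / S))))
    if p >= 0.95:
        return "almost all-Eu"
    if p <= 0.05:
        return "almost all-St"
    return "graded"


# ---------------------------------------------------------------------------
# cross panels


@dataclass(frozen=True)
class CrossDesign:
    name: str
    mother: Genotype
    father: Genotype


def hybrid_panel() -> list[CrossDesign]:
    """The four interspecies designs: *P. pacificus* mothers (wild-type and
    eud-1, seud-1, and double mutants) crossed to wild-type *P. exspectatus*
    fathers.  F1 females span the E:S classes 2:3, 1:3, 2:2 and 1:2."""
    pex_father = wildtype("P. exspectatus", sex=XO)
    ff = (FUNCTIONAL, FUNCTIONAL)
    nn = (NULL, NULL)
    return [
        CrossDesign("WTxWT", pacificus_mutant(eud_1=ff, seud_1=ff), pex_father),
        CrossDesign("eud-1xWT", pacificus_mutant(eud_1=nn, seud_1=ff), pex_father),
        CrossDesign("seud-1xWT", pacificus_mutant(eud_1=ff, seud_1=nn), pex_father),
        CrossDesign("doublexWT", pacificus_mutant(eud_1=nn, seud_1=nn), pex_father),
    ]


def intraspecific_panel() -> list[CrossDesign]:
    """Within-species designs mixing homozygous, heterozygous and hemizygous
    allele combinations of *eud-1* and *seud-1*."""
    ff = (FUNCTIONAL, FUNCTIONAL)
    fn = (FUNCTIONAL, NULL)
    nn = (NULL, NULL)
    wt_male = wildtype("P. pacificus", sex=XO)
    return [
        CrossDesign("WTxWT-male", pacificus_mutant(), wt_male),
        CrossDesign(
            "WTxseud-het-male",
            pacificus_mutant(),
            pacificus_mutant(eud_1=(FUNCTIONAL,), seud_1=fn, sex=XO),
        ),
        CrossDesign(
            "WTxseud-null-male",
            pacificus_mutant(),
            pacificus_mutant(eud_1=(FUNCTIONAL,), seud_1=nn, sex=XO),
        ),
        CrossDesign(
            "eud-hetxWT-male",
            pacificus_mutant(eud_1=fn),
            wt_male,
        ),
        CrossDesign(
            "doublexWT-male",
            pacificus_mutant(eud_1=nn, seud_1=nn),
            wt_male,
        ),
    ]


def enumerate_panel(
    designs: Iterable[CrossDesign],
    sexes: tuple[str, ...] = (XX,),
    co_transmit: Sequence[Sequence[str]] = (),
) -> pd.DataFrame:
    """Offspring dosage classes per design: one row per (design, sex, E, S).

    Phenotypes in the source experiments were scored on XX offspring only
    (hermaphrodites/females), so ``sexes`` defaults to XX.
    """
    rows = []
    for design in designs:
        dist = cross(design.mother, design.father, co_transmit=co_transmit)
        agg: dict[tuple[str, int, int], float] = {}
        for child, p in dist.items():
            if child.sex not in sexes:
                continue
            E, S = dosage_ratio(child)
            key = (child.sex, E, S)
            agg[key] = agg.get(key, 0.0) + p
        total = sum(agg.values())
        for (sex, E, S), p in sorted(agg.items()):
            rows.append(
                {
                    "design": design.name,
                    "sex": sex,
                    "E": E,
                    "S": S,
                    "probability": p / total if total else 0.0,
                    "regime": morph_regime(DosageRatio(E, S))
                    if (E, S) != (0, 0)
                    else "undefined",
                }
            )
    return pd.DataFrame(rows, columns=["design", "sex", "E", "S", "probability", "regime"])


# ---------------------------------------------------------------------------
# complementation


class TransitivityError(ValueError):
    """Fails-to-complement relation is not transitive; offending triples attached."""

    def __init__(self, triples: list[tuple[str, str, str]]):
        self.triples = triples
        shown = ", ".join(f"({a}, {b}, {c})" for a, b, c in triples[:5])
        super().__init__(
            f"complementation matrix is intransitive; offending triples: {shown}"
        )


@dataclass(frozen=True)
class ComplementationMatrix:
    """Symmetric pairwise complementation outcomes among recessive mutants."""

    mutants: tuple[str, ...]
    fails: frozenset[frozenset[str]]  # unordered pairs that fail to complement

    @classmethod
    def from_pairs(
        cls, mutants: Sequence[str], failing_pairs: Iterable[tuple[str, str]]
    ) -> "ComplementationMatrix":
        mutants = tuple(mutants)
        known = set(mutants)
        fails = set()
        for a, b in failing_pairs:
            if a not in known or b not in known:
                raise ValueError(f"unknown mutant in pair ({a}, {b})")
            if a != b:
                fails.add(frozenset((a, b)))
        return cls(mutants=mutants, fails=frozenset(fails))

    def fails_to_complement(self, a: str, b: str) -> bool:
        if a == b:
            return True  # a mutant never complements itself
        return frozenset((a, b)) in self.fails

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            b: [
                "fails_to_complement" if self.fails_to_complement(a, b) else "complements"
                for a in self.mutants
            ]
            for b in self.mutants
        }
        return pd.DataFrame(data, index=list(self.mutants))


def complementation_groups(matrix: ComplementationMatrix) -> list[tuple[str, ...]]:
    """Partition mutants into complementation groups.

    Groups are the connected components of the fails-to-complement graph;
    the relation must be transitive (each component a clique), otherwise a
    :class:`TransitivityError` lists the offending triples.
    """
    adj: dict[str, set[str]] = {m: set() for m in matrix.mutants}
    for pair in matrix.fails:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)

    seen: set[str] = set()
    components: list[tuple[str, ...]] = []
    for m in matrix.mutants:
        if m in seen:
            continue
        stack, comp = [m], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        components.append(tuple(sorted(comp)))

    bad: list[tuple[str, str, str]] = []
    for comp in components:
        for a, b in itertools.combinations(comp, 2):
            if not matrix.fails_to_complement(a, b):
                shared = sorted(adj[a] & adj[b])
                witness = shared[0] if shared else "?"
                bad.append((a, witness, b))
    if bad:
        raise TransitivityError(bad)
    return components
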