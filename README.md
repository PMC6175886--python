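# polyswitch

Toolkit for the genetics of a dosage-dependent mouth-form polyphenism
switch in *Pristionchus* nematodes.

*P. pacificus* develops into either a wide-mouthed predatory
(eurystomatous, Eu) or a narrow-mouthed microbivorous (stenostomatous, St)
adult.  The decision threshold is set by two enzymes of opposing effect:
the X-linked sulfatase gene *eud-1* (Eu-promoting) and the autosomal
sulfotransferase gene *seud-1* (St-promoting).  The morph ratio grades
with the ratio of functional copy numbers E:S — null *seud-1* strains are
all-Eu, null *eud-1* strains all-St, and intermediate dosages (including
interspecies hybrids exploiting a *seud-1* duplication in
*P. exspectatus*) fill the range in between.

`polyswitch` implements the computational chain used to identify and
characterise such a switch gene, for geneticists running suppressor
screens and dosage experiments in this or analogous systems:

* **`synthetic_data`** — generators for every pipeline input with known
  ground truth: a desk-scale genome + annotation, two-allele EMS screen
  variant sets with a planted causal gene, dosage-driven morph counts,
  qPCR Ct tables, and evolved codon pairs.
* **`mutant_mapping`** — the two-allele mapping cascade: quality filter →
  shared-background subtraction → coding-impact classification
  (nonsense/missense/synonymous/splice-site via the standard code) →
  harmful subset → intersection across alleles.  A gene qualifies when
  both alleles carry non-identical harmful lesions in it.
* **`cross_genetics`** — exact Mendelian enumeration under XX/XO sex
  determination: gametes, crosses, functional dosage (E, S) of any
  offspring class, the interspecies hybrid panel, and complementation-group
  partitioning (components of the fails-to-complement graph, validated for
  transitivity).
* **`morph_stats`** — Eu-fraction Clopper–Pearson intervals, pairwise
  χ²/Z tests (z² = X²), Benjamini–Hochberg adjustment, and a binomial
  GLM with logit link: logit P(Eu) = a + b·log2(E/S).
* **`expression_qpcr`** — ΔΔCt relative quantification with reference-gene
  normalisation, titration-based efficiency (F = 10^(−1/slope)),
  log2FC = −ΔΔCt·log2(F), and Tukey-HSD group comparisons.
* **`molevol_dnds`** — pairwise dN/dS by the Nei–Gojobori (1986) counting
  method: fractional synonymous/nonsynonymous sites, pathway-averaged
  differences with stop-avoiding path exclusion, Jukes–Cantor correction
  d = −(3/4)ln(1 − 4p/3), ω = dN/dS.

See `docs/methods.md` for models, defaults, and numerical conventions.

## Worked example

Simulate a suppressor screen and map the causal gene:

```bash
$ polyswitch simulate screen --seed 5 --out demo
$ polyswitch map --mutant-a demo/mutant_a.vcf --mutant-b demo/mutant_b.vcf \
    --background demo/parental.vcf --background demo/marker.vcf \
    --genome demo/genome.fa --gff demo/genes.gff3 --out demo/candidates
loaded          A  42
quality_filter  A  31
subtract_shared A  8
harmful_subset  A  1
...
qualifying genes (1): gene0042
```

Of mutant A's 42 called SNVs, 31 survive the quality filter, 8 remain
after subtracting the parental and marker backgrounds, and 1 is
potentially harmful; intersecting with mutant B leaves exactly one gene
carrying non-identical harmful lesions in both alleles — `gene0042`, which
is the gene the simulator planted (`demo/truth.json`).

Enumerate the interspecies hybrid panel:

```bash
$ polyswitch cross
design     sex  E  S  probability  regime
WTxWT      XX   2  3  1.0          graded
eud-1xWT   XX   1  3  1.0          graded
seud-1xWT  XX   2  2  1.0          graded
doublexWT  XX   1  2  1.0          graded
```

The four F1-female dosage classes 2:3, 1:3, 2:2 and 1:2 fall out of
first-principles gamete enumeration: e.g. a wild-type *P. pacificus*
mother contributes one X (*eud-1*) and one *seud-1* copy, a wild-type
*P. exspectatus* father one X and one copy each of *seud-1.1*/*seud-1.2*,
so wild-type hybrid females are E:S = 2:3.

Measure selection on an evolved codon pair:

```bash
$ polyswitch simulate codons --codons 300 --syn 20 --nonsyn 2 --seed 3 --out demo/pair.fa
$ polyswitch dnds --alignment demo/pair.fa
S       222.0000000000002
N       674.9999999999998
Sd      20.0
Nd      2.0
dS      0.0959774107225323
dN      0.0029688311898208083
omega   0.031
aa_identity     0.9933110367892977
omega = 0.031
```

With 20 synonymous and 2 nonsynonymous planted substitutions the counted
differences are recovered exactly (Sd = 20, Nd = 2), and ω ≈ 0.03 — the
strong-purifying-selection regime typical of functional duplicate pairs —
with >99% amino-acid identity.

`polyswitch morph-test` and `polyswitch ddct` provide the morph-ratio and
expression analyses on TSV inputs; `polyswitch complement` partitions a
pairwise complementation matrix.

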