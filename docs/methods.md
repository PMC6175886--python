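# Methods

`polyswitch` re-implements, as a tested pipeline, the computational chain
behind identifying and characterising a dosage-dependent polyphenism switch
gene in *Pristionchus* nematodes: a two-allele suppressor-screen mapping
cascade, complementation grouping, a Mendelian cross engine for functional
gene dosage under XX/XO sex determination, morph-ratio statistics, ΔΔCt
expression quantification, and pairwise dN/dS by the Nei–Gojobori counting
method.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data do and do
not establish.

## The biological model

The mouth-form polyphenism of *P. pacificus* produces either a wide-mouthed
predatory (eurystomatous, Eu) or narrow-mouthed microbivorous
(stenostomatous, St) adult from the same genotype.  Two opposing enzymes set
the decision threshold: the X-linked sulfatase gene *eud-1* promotes the Eu
morph, and the autosomal sulfotransferase gene *seud-1* promotes the St
morph.  Null mutants of *seud-1* are fully Eu regardless of *eud-1* copy
number; *eud-1* nulls with functional *seud-1* are fully St; between these
boundaries the morph ratio grades with the relative functional copy number
E:S.  The sister species *P. exspectatus* carries a recent duplication of
the sulfotransferase gene (*seud-1.1* and *seud-1.2*, both functional:
their pairwise dN/dS is far below 1 and their proteins are >99% identical),
so interspecies F1 females provide dosage classes (2:3, 1:3, 1:2)
unreachable within one species.

## Suppressor-screen mapping cascade (`mutant_mapping`)

Input is one SNV call set per strain (VCF v4.2 or an equivalent TSV).  The
cascade is: quality filter → shared-background subtraction → coding-impact
classification → harmful subset → two-allele intersection.

* **Quality filter.** Manual browser-level curation of artefactual calls is
  replaced by explicit thresholds, default QUAL ≥ 20 and DP ≥ 5, both
  configurable.
* **Background subtraction.** A variant is removed when any background
  strain (the mutagenised parental line, marker strains used in
  backcrossing) carries a call with the same (contig, position, ref, alt);
  the strain field never participates in matching.
* **Impact classification.** Coding SNVs are classified by mutating the
  affected codon of the spliced CDS (reverse-complemented for minus-strand
  genes) and translating with the standard code: nonsense (new stop),
  missense, or synonymous.  Variants within 2 bp of the intron side of an
  exon/intron boundary — the near-invariant GT/AG dinucleotides — are
  splice-site.  Everything else is noncoding.  A unit oracle verifies the
  single-codon logic against rebuilding and translating the entire mutant
  CDS.  Stop-loss in the terminal codon is reported as missense (it is
  "potentially harmful" either way).
* **Intersection.** A gene qualifies when both independently derived mutant
  alleles carry at least one harmful (nonsense/missense/splice-site)
  variant in it and the two harmful sets are not identical.  The
  non-identity clause discards inherited lesions that escaped background
  subtraction: a variant present identically in both alleles cannot be two
  independent mutagenesis events.
* Heterozygous versus homozygous call status is not modelled; all retained
  calls are treated equally.

All coordinates are 1-based with inclusive intervals (GFF3 convention);
VCF positions are used as-is.  Only SNVs are processed; indel and
multi-allelic lines are counted and skipped.

## Synthetic screen fixture (`synthetic_data`)

The generator produces a reference genome and annotation, four per-strain
variant tables (two mutants, the shared parental line, a marker strain),
and a truth record.  Defaults, fixed once:

| parameter | default | rationale |
|---|---|---|
| contigs × genes | 2 × 50 | desk-scale genome with enough genes for a genuine genome-wide search |
| mean CDS length | 900 bp | typical nematode coding length |
| causal gene | index 42, 10 exons | lesions planted in transcript exons 8 and 1 |
| intergenic mean | 38 kb | sets total genome size to ≈ 4 Mb (see collision analysis) |
| private EMS SNVs / mutant | Poisson(8) | residual load of a strain backcrossed 4–6×; the pre-mutagenesis density is not modelled |
| shared background SNVs | 30 (70% parental, 30% marker) | exercises multi-background subtraction |
| EMS G:C→A:T bias | 0.85 | EMS chemistry produces predominantly these transitions |

**Collision analysis (why 4 Mb and Poisson(8)).** The mapping cascade fails
only if some non-causal gene acquires harmful variants in *both* mutants.
With per-mutant background load B, per-gene CDS length c, genome length L,
harmful fraction h ≈ 0.78 of coding hits, and G genes, the expected number
of spurious qualifying genes per run is ≈ G·(B·h·c/L)².  The defaults give
≈ 1 × 10⁻⁴ per run, i.e. ≈ 0.01 expected failures across a 100-seed
acceptance sweep.  These values were fixed from this analysis before the
acceptance sweep was run.  A real 100-Mb genome with thousands of genes
achieves the same safety margin with a much higher variant load; the desk
fixture compensates for its small gene count with a low post-backcross
load.

Generated CDSs always start ATG, end with a stop, contain no internal stop,
and are split into exons by a Dirichlet composition with ≥ 18 bp per exon;
introns are GT…AG with lengths 40–200 bp; about half the genes are on the
minus strand.  Planted lesions are single-base nonsense changes (EMS-type
G:C→A:T preferred when available) at QUAL 60 / DP 30; background variants
get QUAL ~ U(5, 60) and DP ~ Poisson(24), so the quality filter has real
work to do.

**What the fixture does not emulate:** read-level errors, indels and
structural variants, linkage between background variants and the causal
locus (backcross linkage drag), heterozygous residual calls, annotation
errors, and the UTRs of real gene models.  Passing the truth-recovery sweep
therefore validates the cascade's logic and coordinate arithmetic, not its
robustness to call-set noise beyond the modelled quality/depth mixture.

## Cross engine (`cross_genetics`)

Genotypes are karyotype (XX/XO) plus per-locus allele states, one per
chromosome copy; X-linked loci have one slot in XO males.  Gamete
distributions are enumerated exactly: an XX parent transmits one X per
gamete; an XO father transmits X-bearing and nullo-X sperm at ½ each (so
male-sired broods are ½ XX : ½ XO — the standard XX/XO assumption);
autosomal loci assort independently.  The two *P. exspectatus* paralogs are
modelled as unlinked autosomal loci by default, both fully functional;
their physical linkage is unknown, so co-transmission is available as an
option (`co_transmit`) and changes nothing about F1 dosage classes, only
about F2 segregation.  Hermaphrodite selfing uses all-X self sperm; the
rare nullo-X self sperm that produce spontaneous males are ignored, and
phenotype scoring in the panels uses XX offspring only, matching how the
source experiments scored hybrids.

Functional dosage is E = functional *eud-1* copies and S = functional
copies summed over all *seud-1* paralogs.  `enumerate_panel` reduces any
cross list to (design, sex, E, S, probability) rows and attaches a
qualitative regime label derived from the decision model below (boundaries
`all-Eu`/`all-St`; `almost all-Eu`/`almost all-St` when the expected Eu
fraction passes 0.95/0.05).

One sentence in the source narrative ("no number of copies of the
sulfatase gene rescues the Eu morph without the sulfotransferase") is
inconsistent with the all-Eu phenotype of sulfotransferase nulls shown by
the same study's mutant data; the engine and the simulator follow the
mutant data (S = 0 ⇒ all-Eu).

Complementation groups are the connected components of the
fails-to-complement graph; the partition is only accepted if every
component is a clique, otherwise the offending intransitive triples are
reported in the error.

## Morph decision model (simulator)

P(Eu) = logistic(a + b·log2(E/S)) with hard boundaries at S = 0 (all Eu)
and E = 0 (all St), and E = S = 0 undefined.  Defaults a = logit(0.9),
b = 2: a reproduces the ~90% Eu of the wild-type reference strain at
E:S = 2:2, and b = 2 spreads the panel's ratio range (log2 ratios −1.585 …
+1) across nearly the full 0–1 Eu-fraction scale, giving the observed
all-St-to-all-Eu gradation.  This logistic form and its calibration are a
modelling invention of this package — the source data constrain the
monotone ordering and the boundary phenotypes, not a parametric curve.
Intermediate morphs are drawn independently at rate 0.005 (the upper bound
of "rare, < 0.5%") and are excluded from every analysis denominator.

## Morph-ratio statistics (`morph_stats`)

* Eu proportions carry exact Clopper–Pearson 95% intervals
  (scipy's inversion of the binomial tails); replicates are pooled within
  line for display, as in the source analysis.
* Pairwise tests are the uncorrected Pearson chi-square on the 2×2 table
  (no Yates correction — the uncorrected statistic satisfies z² = X² with
  the pooled two-proportion Z test, and its type-I error at n = 100 per
  group sits inside [0.04, 0.06]); a zero margin returns (0, 1) since the
  proportions are then trivially indistinguishable.
* Multiple comparisons use Benjamini–Hochberg (statsmodels step-up).
* The GLM is binomial with logit link on (n_Eu, n_St) responses, fitted by
  IRLS (statsmodels; deviance tolerance 1e-10, ≤ 100 iterations).
  Categorical covariates are dummy-coded against their first level.
  All-Eu or all-St groups separate the likelihood perfectly — unavoidable
  with boundary phenotypes — so fitted proportions are clamped to
  [1e-8, 1 − 1e-8] and the fit is flagged `separation=True` rather than
  rejected.  Likelihood-ratio tests compare nested fits by deviance
  difference.

## ΔΔCt quantification (`expression_qpcr`)

Technical replicates are averaged per biological replicate; ΔCt = target
mean Ct − arithmetic mean of the reference-gene Cts (the geometric mean of
the linear quantities; the combination rule is this package's choice, and
a single reference gene is supported); ΔΔCt subtracts the control group's
mean ΔCt, computed within each run when a `run` column is present (runs
with different primer sets are normalised independently, then combined).
log2FC = −ΔΔCt·log2(F) with amplification factor F = 2 by default or
estimated from a dilution titration as F = 10^(−1/slope), requiring ≥ 3
points spanning ≥ 2 logs.  Group comparison aggregates to
biological-replicate means and applies Tukey's HSD; for balanced designs
this equals the mixed model with a random biological-replicate intercept
that the source analysis used, which is why the repeated-measures model
was not re-implemented.  Zero-variance (noise-free) inputs short-circuit
to p = 1 for zero differences rather than dividing by a zero mean square.
Technical-replicate outliers are not removed.

## Pairwise dN/dS (`molevol_dnds`)

Unweighted Nei–Gojobori counting under the universal code, no
transition/transversion weighting.  Synonymous sites per codon are the
fraction of the nine single-base changes preserving the amino acid
(changes to stops count as nonsynonymous).  Differences per codon pair are
averaged over all orderings of the differing positions; orderings whose
intermediate codons are stops are excluded and the survivors reweighted
equally; in the degenerate case where every ordering is blocked, each
differing position is classified independently against the first codon.
pS = Sd/S and pN = Nd/N use sites averaged over the two sequences;
distances use Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), which is undefined at
p ≥ 3/4 (an explicit error — alignments that diverged are outside the
counting method's range) and ω = dN/dS is reported as undefined (`None`),
not infinity, when dS = 0.  A terminal stop codon is excluded from the
counts.  The whole computation is validated against a brute-force
enumeration oracle written independently in the test suite.

## Problem sizes and determinism

Every generator takes a seed and is fully deterministic given it.  The
sizes used by the test suite and the acceptance script — 100 screen seeds
at the default 4-Mb fixture, 10⁴ chi-square null simulations, 100 GLM
panel seeds at 500 individuals per class, 2 000 coverage simulations, 100
ΔΔCt noise seeds, 1 000 codon-pair oracle comparisons — were chosen as the
smallest runs at which the Monte-Carlo standard errors are comfortably
inside the asserted bands.

## Known limitations

* The variant loader reports record numbers, not raw file line numbers,
  for malformed VCF records (the TSV dialect reports true line numbers).
* ω for the real *P. exspectatus* duplicate pair requires the published
  coding sequences, which are an external download; the package computes ω
  for any supplied two-sequence FASTA (`polyswitch dnds`) and its counting
  core is validated by construction and by oracle instead.
* The GLM does not implement quasi-binomial dispersion or multivariate-t
  contrast machinery; the cross engine does not model recombination maps,
  hybrid incompatibility, or the asymmetric hybrid-male background effects
  noted in the source study (hybrids are scored on females only).
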