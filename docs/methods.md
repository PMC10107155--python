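# Methods

## The segregation model

A hybrid diploid carries 16 homolog pairs distinguishable by SNPs (one
homolog from parent A, one from parent B). Without recombination there are
no chiasmata, so MI segregation is modelled per chromosome, independently:

* with probability `x_N` the pair **disjoins** — each MI daughter receives
  one homolog, the parental assignment being a fair coin;
* otherwise both homologs move to the **same pole** (one daughter gets a
  heterodisomy precursor, the other nothing), the pole being a fair coin.

`x_N` is affine in chromosome length between `x_min` at the shortest
chromosome and `x_max` at the longest. This encodes the hypothesis that
residual chiasma-independent homolog pairing scales with length, making
long chromosomes disjoin more reliably. Both interpretations of the
interpolated probability are implemented: `disjunction` (default; `x` is
the opposite-pole probability) and `co_segregation` (`x` is the same-pole
probability). The disjunction reading is the default because it is the
direction under which raising `x_max` suppresses disomy of long
chromosomes and shifts the per-spore disomy mode from 5 into the 2–4 range,
which is the behaviour the biased model exists to produce; the flag keeps
the other direction available for comparison.

MII is equational: each spore receives one chromatid per homolog present
(a daughter carrying both homologs yields heterodisomic spores; there is no
way to produce a homozygous disomy, matching the observation that every
disomy carries one copy from each parent). Accidental MII loss fires once,
on the MII-entry state of each spore:

* `Pa` (default fit 0.017): a monosomic copy is lost — the spore then lacks
  that chromosome and dies;
* `Pb` (default fit 0.013): each copy of a disomy is lost independently.

**Pb semantics.** "Losing one of a disomic pair" could mean a per-pair or a
per-copy Bernoulli. We use per-copy: each copy is lost with probability
`Pb`, so a disomy survives intact with `(1−Pb)²`, becomes a monosomy of the
surviving parent with `2·Pb(1−Pb)`, and disappears with `Pb²`. Only this
convention reproduces the printed correspondence between the 76.9%
identical-pair fraction and `Pb = 1.3%`; the per-pair convention lands near
2.4–2.5% instead (verified against the closed-form oracle).

Losses are not chained: a monosomy created by a `Pb` event in MII is not
re-exposed to `Pa`. At the fitted values chained losses would be a
second-order (≈ 2 × 10⁻⁴) correction.

A spore is **viable** iff it has at least one copy of every chromosome.
Tetrads are classified by their viable spores: two viable with identical
per-chromosome states *including parental origin* → `copies`; two viable
differing anywhere → `altered_copies`; one → `single`; none → `mii_dead`
if an MI daughter had carried a full set, else `mi_dead`; three or more
viable (both MI daughters full, probability (1/2)¹⁶ unbiased) → `multi`,
reported but excluded from the four-category ratios.

## Conditioning and the analytic oracle

Unconditionally, ~99% of tetrads are `mi_dead` (the probability that a
daughter carries a full set is `Π(1 − c_N/2)`, = (3/4)¹⁶ ≈ 1.0% unbiased,
with `c_N` the same-pole probability). Fitting therefore simulates
conditionally on the first MI daughter being full; the conditioning
probability is recorded so unconditional rates can be reconstructed.
Conditional on a full daughter, chromosomes are independent with disomy
probability `p_N = (c_N/2)/(1 − c_N/2)` (= 1/3 unbiased), so every category
probability factorises into per-chromosome kernels; the
`analytic_oracle` module evaluates these exactly (in log space when kernel
entries get small) and anchors the simulator and both fits. The oracle
ignores the rare both-daughters-full tetrads; the resulting discrepancy
with the simulator is of order (2/3)¹⁶ ≈ 1.5 × 10⁻³ and is covered by the
3-standard-error tolerance of the agreement tests. Per-spore statistics
(the disomy histogram) are collected from the conditioned daughter only,
since the complementary daughter's spores are over-represented under the
conditioning.

The test suite additionally carries a brute-force enumeration oracle
(`tests/enumeration_oracle.py`) that enumerates *every* MI/MII/loss
outcome with its exact probability on 1–3-chromosome genomes; the product
formulas agree with it to 10⁻¹², and the unconditional simulator to 3 SE.

## Fitting

Grid searches mirror the study design: `Pb` on a 0.1-percentage-point grid
over 0–30% at `Pa = 0`, scored by the simulated fraction of `copies` among
all two-viable-spore asci against the observed 20/26 = 76.9%; then `Pa` on
0–4% at the fitted `Pb`, scored by the fraction of two-viable asci among
viable-set asci against the observed 71.0%. (The alternative reading of
71.0% as the `single` share of MI survivors is inconsistent with
`Pa ≈ 1.7%` under this model and is not implemented.) One million
conditional tetrads per grid point put the Monte-Carlo error of each
fraction near 4 × 10⁻⁴, far below the grid resolution. Ties resolve to the
smaller parameter.

## Synthetic sequencing data

The generator emulates hybrid-diploid spore resequencing at desk scale:

* **Genome**: by default a miniature genome — sacCer3 lengths × 0.15,
  rounded to whole kb (35–230 kb), preserving the length order; full-scale
  lengths are supported. Read-level stages use the miniature genome to keep
  tests fast; counts/Mbp statistics are always normalized with real
  chromosome lengths.
* **SNP map**: `round(density · L)` positions per chromosome without
  replacement, density 0.7% by default; two distinct parental bases per
  site.
* **Coverage**: per 1-kb bin, depth ~ Poisson(effective copies ×
  depth-per-copy). Default 30× per copy — the study does not state its
  per-spore depth; 30× is a routine resequencing depth and leaves the
  caller's error rate effectively zero, which is what the round-trip tests
  need. No overdispersion is modelled.
* **Allele depths**: at each SNP, total depth Poisson, parent-A count
  binomial with success `f_A(1−e) + (1−f_A)e`, symmetric error `e = 0.002`.
* **Mosaicism**: a disomy with mosaic fraction φ (fraction of cells that
  lost one copy) has effective copies `2 − φ`; the lost copy can be
  parent-specific or an even mixture.
* **Passage**: disomies drop to monosomy with a per-chromosome loss rate
  (retained parent uniform), monosomies duplicate with a gain rate
  (producing two same-parent copies, a state the meiotic simulator itself
  never emits); viability is preserved.

What this generator does **not** emulate: mappability and GC biases,
overdispersed coverage, alignment and variant-calling artefacts, indels and
point mutations, or selection during culture. Passing round-trip tests
therefore demonstrate internal consistency of model + caller at realistic
depths and SNP densities, not robustness to real-world artefacts.

## Karyotype calling

Two passes resolve the circularity between allele fractions and the
coverage baseline:

1. coverage-weighted mean parent-A fraction `f̄` per chromosome:
   `f̄ ≥ 1−δ` → provisional monoA, `f̄ ≤ δ` → monoB, `|f̄−0.5| ≤ δ` →
   biparental, with δ = 0.15;
2. monosome baseline = median mean depth over provisional monosomies
   (fallback, flagged: half the median biparental depth, else the global
   median); ratio `r` = chromosome depth / baseline. Bands sit midway
   between integer copy numbers: monosomy [0.75, 1.25], disomy
   [1.75, 2.25], the open interval (1.25, 1.75) → `partial_reduction` with
   mosaic estimate `φ̂ = 2 − r`; `r < 0.3` → absent. The exact thresholds
   used in the original analysis are not published; these bands are this
   package's choice and are config-exposed (`CallerConfig`). A biparental
   chromosome with `r ≤ 1.25` — outside the model's reachable states —
   is reported as `disomyAB` with its continuous copy estimate, leaving the
   anomaly visible in `r` rather than inventing a state.

**Stability.** Each generation's chromosome depths are normalized by that
generation's monosome baseline (median over chromosomes called monosomic
at g-0, median for robustness against the rare monosome that duplicated);
the verdict compares the g-110/g-0 ratio of normalized values to 0.5
(loss) and 1.5 (gain). The normalization makes the verdicts exactly
invariant to any uniform depth rescaling of either profile. The loss
comparison is inclusive (≤ 0.5): an ideal complete disomy-to-monosomy loss
sits exactly at 0.5, so a strict inequality would never classify the
canonical event on noise-free data; measured values scatter around the
boundary either way.

**Recombination.** The simplified detector works on per-SNP parental
genotypes of monosomic (phased-by-construction) chromosomes; disomic
chromosomes are skipped as unphased. Runs of identical parental origin are
simplified to a fixed point in priority order: isolated single-SNP flips
are absorbed as noise; an internal opposite-parent tract spanning at most
`max_gc_tract` = 10 kb is one gene conversion; remaining runs under
`min_block` = 20 SNPs are ambiguous and absorbed. Each boundary left
between two ≥ 20-SNP blocks is one crossover. Under 0.2% genotype noise the
only false positives are ≥ 2 adjacent flipped SNPs (probability ~n·p² per
chromosome), keeping per-chromosome specificity above 99%; false
crossovers would need 20 consecutive flips and effectively never occur.

## Cohort statistics

Disomy counts per chromosome (a `partial_reduction` counts as a disomy at
formation — the reduction happened after germination), normalized as
`count × 10⁶ / length`. The band subset keeps chromosomes with 10–25
counts/Mbp, reproducing the study's selection rule; length correlation is
Pearson's r of raw counts vs length over the subset (full-set r is also
reported, and whether the regression should use raw or normalized counts
is ambiguous in the source, so both are emitted). DSG impact is
`Σ 1/copy_limit` per chromosome; its association with counts is Pearson's
r of counts vs ln(impact) (zero-impact chromosomes excluded with a
warning; log-log available via flag — the exact transform used originally
is not stated). Parental bias counts one copy per monosomy and one of each
per heterodisomy, with Clopper–Pearson intervals. The study's empirical
correlations (r = .899 band-subset length correlation, r = −.437 DSG
association) require the real 66-spore cohort and are exercised here only
as generate-and-recover properties on synthetic cohorts.

The repository ships no external DSG dataset; `make_synthetic_dsg_table`
builds a synthetic stand-in (log-uniform copy limits 1–100, gene counts
scaling with length), and real data can be supplied as TSV
(gene, chrom, copy_limit).

## Problem sizes and numerical choices

Default problem sizes: 10⁶ conditional tetrads per fitted grid point
(Monte-Carlo SE ≈ 4 × 10⁻⁴ per fraction), 2 × 10⁵ per point in the demo
pipeline, 200-spore cohorts for recovery checks, miniature genome for
read-level work. Simulation uses a single seeded PCG64 stream per run;
every pipeline stage derives its stream from one top-level seed via
`SeedSequence.spawn`. MII outcomes are drawn as single-uniform categorical
draws in float32 (resolution 2⁻²⁴, six orders of magnitude below the
fitted loss probabilities); products over chromosomes are evaluated in log
space when kernels get small. Grid fits resolve ties toward the smaller
parameter; the 0.1-point grid matches the precision of the reported
estimates.

## Known limitations

* The diploid-euploid spore class (MI bypass, as in *spo13*-like dyads) is
  not modelled; such spores appear in the study but are outside the
  haploid-with-disomies model. They are simply absent from simulated
  cohorts.
* No recombination process exists in the model (the achiasmate mutant
  shows none), so the crossover/gene-conversion detector is validated on
  constructed haplotypes and noise, not on a wild-type-like positive
  control with known event positions.
* The length-bias direction rests on model behaviour (which direction
  reproduces the observed disomy-mode shift), not on an explicit statement;
  both directions are implemented.
* Chromosome lengths default to sacCer3; the strain pair's averaged
  lengths are not published, and the affine bias is insensitive to
  percent-level length differences.
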