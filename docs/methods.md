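# Methods

## Depth model and the copy-number scale

The analysis rests on the proportionality between a gene's copy number and
its sequencing depth. Per-gene raw depth is the **median** over every CDS
base of the gene, pooling all CDS exons into one vector (introns and
flanks are excluded; per-exon medians are never taken). The median, not
the mean, makes the statistic robust to mapping pile-ups at repeats.

Normalized depth is `raw / (0.5 × median over genes of raw)`, so the
genome-wide median of normalized depths is exactly 2.0 by construction and
the scale reads directly as copies: a 33× diploid genome shows modes near
1.0 (16.5×), 2.0 (33×) and 3.0 (49.5×). The transform is invariant under
rescaling of all raw depths, so samples sequenced to different total
depths are comparable. Genes on scaffolds absent from a depth track are
flagged `uncovered` and get normalized depth 0 but are excluded from the
genome median, so missing data is never conflated with deletion.

The genome-wide normalizer is the median of the per-gene medians (not a
per-base genome median); with ~75% of genes diploid the two coincide in
practice.

## Classification

With reference depth *r* and sample depth *d* (both normalized):

| class      | rule                  |
|------------|-----------------------|
| deleted    | d ≤ 0.05 and r > 0.95 |
| unresolved | d ≤ 0.05 and r ≤ 0.95 |
| haploid    | 0.05 < d < 1.3        |
| diploid    | 1.3 ≤ d < 2.7         |
| amplified  | d ≥ 2.7               |

The 1.3 and 2.7 cut points are the local density minima between the
coverage peaks of a mutagenized CHO genome at 33×. "Depth 0" is
interpreted as d ≤ `zero_tol` = 0.05 rather than bitwise zero: Poisson
noise makes an exact zero over a ~1.7 kb CDS effectively impossible for
any gene actually present, while a hemizygous-deleted gene's residual
mis-mapped reads stay well below 0.05. Exactly-boundary values are
assigned upward (half-open intervals); classification is therefore
monotone in depth. When no wild-type reference sample is available an
all-diploid pseudo-reference is assumed, which turns `unresolved` off.

`find_class_boundaries` estimates the two cut points from data with a
Gaussian KDE (absolute bandwidth 0.1, chosen to resolve integer-spaced
peaks at 33×) and takes the density minima between the three lowest
non-zero modes, falling back to (1.3, 2.7) with a warning when fewer than
three modes exist. Note that on the synthetic Poisson data the per-gene
medians are far tighter than real coverage, so the detected minima sit
near the midpoints (~1.5, ~2.5) rather than at the skewed positions real
data produce; classification therefore uses the fixed defaults unless a
user overrides them.

## Pairwise CNV calls

A gene is a copy-number variant between two genomes when its normalized
depths differ by **more than 0.95** — deliberately just under a full copy
at the haploid scale, and applied to the depths, not the class labels, so
a 2.9-vs-1.9 change counts even though both sides may classify diploid.
Strictness at the threshold is protected against binary floating-point
representation (comparisons use `> 0.95 + 1e-9`). Genes unresolved in
either profile are excluded from reduced/increased/unchanged sets, from
distance counts and from enrichment universes.

Because medians of Poisson counts are discrete (multiples of 0.5 raw),
a true one-copy loss at 33× produces depth differences with support
{0.91 … 1.09}; the 0.95 rule therefore misses ~1–2% of true single-copy
changes at this coverage. The planted-pair recovery test asserts counts
to within 2% for this reason; the effect shrinks with deeper coverage.

## SNP hard filters

Two call types with different depth demands (m = median CDS depth):

* homozygous — total depth ≥ 0.25 m and alternate fraction ≥ 0.90;
* heterozygous — total depth ≥ 0.75 m and both alleles ≥ 0.40.

The permissive homozygous depth bar exists because ~17% of CHO genes are
haploid and sit at half coverage; a diploid-pegged filter would discard
their variants wholesale. The two rules are mutually exclusive (alt ≥ 0.9
implies ref ≤ 0.1 < 0.4), asserted by a property test, so labeling
precedence never arises. Rejection reasons are resolved by the allele
fractions first: a call whose fractions fit one rule but whose depth does
not is logged `depth`; a call fitting neither fraction pattern is
`allele_fraction`.

The proximity filter removes every kept SNP with another call (SNP or
indel, kept or rejected) strictly within 5 bp (|Δpos| < 5); both members
of a close pair are removed — the conservative reading of "filtered away".
Calls at identical positions (multi-allelic splits) are not each other's
neighbors. Finally, calls whose (scaffold, pos, ref, alt) key appears in
the reference self-alignment blacklist are subtracted. The blacklist is an
input file: producing it requires the raw reference reads, which are out
of scope. The filter is idempotent and conserving (every input call lands
in exactly one of kept / rejection log).

## Mutational spectrum

Directed substitution counts are tallied on the reference strand; the
collapsed GC→AT class is G→A + C→T and AT→GC is A→G + T→C, i.e. the
complement-paired transitions that EMS drives. Whether the transversions
G→T/C→A belong in a "GC→AT" class is convention-dependent; they are kept
in a separate class by default with `include_transversions=True` to pool
them. The ratio GC→AT / AT→GC is reported per sample and flagged
undefined when the denominator is zero. Group comparisons use the classic
pooled-variance two-sample t-test with significance stars at 0.05 / 0.01 /
0.001.

## Coding effects

SNP effects come from standard-genetic-code translation of the affected
codon at the strand-aware CDS coordinate (scaffold position → coding
index, complementing alleles on minus-strand genes); indels are
frameshifting iff their net length change is not 0 mod 3. A CDS whose
length is not a codon multiple is an annotation error and is rejected
rather than guessed at.

## CNV phylogeny

The CNV count distance is a symmetric premetric (zero diagonal, symmetric,
integer ≥ 0); the triangle inequality is *not* guaranteed — two genomes
can each differ from a third in disjoint gene sets — and is not asserted.
Neighbor joining is the classic Saitou–Nei agglomeration with two
documented conventions where the algorithm is silent:

* Q-matrix ties break to the smallest (row, column) index pair after
  lexicographic label sort, making the output deterministic;
* negative branch lengths are clamped to zero with the deficit moved to
  the sibling branch.

On additive matrices NJ reproduces the generating tree exactly (tested up
to 8 taxa against tree-derived path lengths, and cross-checked against an
independent library implementation on random matrices). Bootstrap
resamples **genes** — the only exchangeable unit in the distance
definition — with replacement, recomputes all pairwise distances and
trees, and reports the majority-rule (>50%) consensus with support as the
percentage of replicates containing each bipartition. Genes at ~0 depth
in every sample carry no CNV information and are excluded by default
(`exclude_always_zero`).

## GO enrichment

One-sided hypergeometric upper-tail p-values, P(X ≥ overlap), per term,
sample and direction (reduced / amplified vs the reference by the 0.95
rule); the universe is the set of genes resolvable in both sample and
reference. The test is one-sided because the screen asks for terms
*enriched* among changed genes; a two-sided Fisher option exists behind a
flag. The inclusion rule is the raw p < 0.01 in at least one
sample/direction, with no multiple-testing correction — reproducing the
published procedure — while Benjamini–Hochberg q-values are attached as
clearly supplementary columns. The GO table is a flat gene→terms map; no
ontology-graph propagation is performed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions:

* 20,661 genes; CDS lengths gamma-distributed (shape 4) with mean 1,700 bp,
  floored at 300 bp and rounded to codon multiples; 8 genes per scaffold,
  scaffolds rotated through 11 chromosome labels (1–8, "9/10", X,
  unplaced); ~30% two-exon genes and both strands, so coordinate handling
  is exercised.
* Per-base depth ~ Poisson(copy_number × 16.5) over each gene's span
  (diploid median 33×), intergenic background diploid; copy number 0 gives
  exactly zero depth. A negative-binomial option
  (`overdispersion` > 0, var = μ + od·μ²) exists but defaults to 0: peak
  widths are not quantified in real data and Poisson is the standard
  null. No GC-content depth bias is simulated (GC is recorded, no bias
  model is fit); the annotation retains GC fractions as a hook.
* Copy-number presets reproduce the per-class counts of the nine
  sequenced cell lines plus the hamster reference. Preset maps are built
  hierarchically to mimic clonal history: 65% of the minimum class count
  is shared by all CHO lines, 75% of the remaining group minimum within
  each lineage group (K1 family / DXB11+F435 / CHO-S+C0101 / DG44), and
  private per-line events top each class up exactly. Amplified genes get
  CN = 3, the smallest value consistent with the ">2 copies" class.
  The sharing fractions were set once so that within-group CNV distances
  are clearly below between-group distances while marginals stay exact;
  the tree tests depend only on that ordering, not on the exact values.
* Variants: per-gene SNP counts binomial in CDS length (rate 6 × 10⁻⁴ per
  base, indels 10⁻⁵); positions ≥ 6 bp apart within a gene so the
  proximity filter does not erase intended calls (close pairs are tested
  with hand-built fixtures instead). Zygosity follows copy number:
  haploid-gene variants homozygous (alt fraction ~ Binomial(d, 0.98)),
  diploid-gene variants heterozygous with probability `het_fraction`
  (default 0.5, alt ~ Binomial(d, 0.5)). Substitution categories are drawn
  with weight `ems_bias` on G→A and C→T and 1 elsewhere;
  `expected_spectrum_ratio` enumerates the implied category probabilities
  so recovery tests have an independent closed form. A
  `blacklist_fraction` of artifact calls is emitted both into the sample
  VCF and a blacklist VCF to exercise the subtraction filter.

Everything is deterministic given the seed (per-stage child generators),
so pipeline reruns are byte-identical.

**What passing tests do and do not show.** The generator reproduces
marginal depth distributions, class compositions, lineage-correlated CNV
structure and spectrum biases — not mappability artifacts, GC-coverage
coupling, segmental duplications or reference errors. Recovery rates on
synthetic data (≥ 99% class labels at 33×) are therefore upper bounds on
real-data performance; at ~5× coverage class recovery degrades
substantially and is documented, not asserted.

## Problem sizes used

Worked-example and oracle tests run in milliseconds. Parameter-recovery
and phylogeny tests run at the full 20,661-gene universe with ~1.7 kb CDS
per gene, drawing gene depths directly (the `simulate_gene_depths` route,
statistically identical to full tracks but without materializing ~40 Mb
per-base vectors); the ten-sample bootstrap phylogeny uses 100 replicates.
The whole suite completes in a few minutes on one CPU.

## Known limitations

* No segment-level CNV segmentation: the gene is the unit throughout.
* Chromosome assignment consumes a precomputed similarity-hit table
  (best hit at E ≤ 0.05, ties to the lexicographically smallest
  chromosome and flagged); the similarity search itself is upstream.
* The spectrum's strand convention cannot distinguish which member of a
  complementary pair mutated; only base-pair-level classes are reported.
* Variant calling, read alignment, deduplication and realignment are out
  of scope — inputs are expected post-calling.
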