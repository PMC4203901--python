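# Methods

## The generative model

`pilecall` treats genotype calling at one genomic position as exact
inference in a small directed graphical model.  The variables are the
reference nucleotide `H`, the genotype `G`, and, for each of the `n` reads
covering the position, the sampled allele `S_i`, the read nucleotide `R_i`
and the sequencer signal summarised by the base's quality score.  The
joint distribution factorises as

```
P(H) · P(G|H) · Π_i  P(S_i|G) · P(R_i|S_i) · P(signal_i|R_i)
```

and the caller reports the genotype posterior `P(G | data, H)` obtained by
summing `S_i` and `R_i` out of the joint, together with the MAP genotype
and a Phred-scaled confidence `-10·log10(1 - P(G_MAP))`.

The factor distributions:

* **Reference prior `P(H)`** — flat (0.25 each) when the reference is
  ignored, a point mass on the reference base when it is used, or any
  user-supplied distribution.  In flat/custom mode `H` is marginalised
  into the genotype prior once per run rather than per position.
* **Genotype prior `P(G|H)`** — parameterised by an expected SNP rate
  `μ` (default 0.001).  Haploid: `1-μ` on the reference base, `μ/3` on
  each alternative.  Diploid, assuming Hardy-Weinberg equilibrium with
  per-draw alternative-allele probability `p`: mass `1-μ` on the
  homozygous-reference genotype, `p(1-p)` on each of the three
  single-alternative heterozygotes and `p²` on each of the six remaining
  genotypes, where `p` solves `3p(1-p) + 6p² = μ`, i.e. the positive root
  of `3p + 3p² = μ` (`p = 0.0333%` at the default rate).  The prior rows
  sum to one by construction.
* **Allele sampling `P(S|G)`** — identity for haploid genotypes; for
  diploid genotypes a point mass for homozygotes and ½/½ over the two
  alleles of a heterozygote.
* **Substitution matrix `P(R|S)`** — a 4×4 row-stochastic matrix.  The
  standard error matrix spreads a total error rate `τ` (default 0.2%)
  over the off-diagonal of each row in a 3:3:1 split, the rarest
  substitution being the one towards the Watson-Crick complement of the
  sampled base (an empirical pattern in mapped mismatch counts: the
  smallest off-diagonal probability is one third of the second largest).
  The ancient-DNA damage matrix additionally moves mass `δ` (default 3%)
  from C→C to C→T and from G→G to G→A, modelling post-mortem cytosine
  deamination.  `τ = δ = 0` yields the identity: quality scores are then
  trusted completely.
* **Base-call distribution** — a base called with effective quality `Q`
  has error probability `e = 10^(-Q/10)`, giving mass `1-e` on the called
  base and `e/3` on each alternative (uniform errors; equivalently the
  signal likelihood under a flat base prior).  The effective quality is
  `min(Q_base, Q_mapping)`, so a poorly mapped read is down-weighted no
  matter how clean its base calls are.

## Numerical choices

* All per-position arithmetic is in natural-log space; products over
  60-deep columns would underflow doubles otherwise.  Normalisation uses
  a max-shifted exponentiation (log-sum-exp).
* Per-read likelihood vectors depend only on (called base, effective
  quality), so the caller caches the per-genotype log contribution in a
  `4 × 94 × G` table; calling a column is then a table-gather and a sum.
  This is a computational layout only — the posterior is still exact,
  and the test suite checks it against brute-force enumeration of the
  full joint to 1e-12.
* The error probability of a base is capped at 0.75.  Phred 0 decodes to
  an error probability of 1, which would make a read *anti*-informative;
  the cap turns it into a flat, uninformative observation instead.  The
  cap also guarantees no read can assign zero likelihood to every
  genotype.
* MAP ties break to the lexicographically smallest genotype string
  (argmax over the fixed genotype order); determinism matters more than
  any particular convention.  The Phred confidence is capped at 9999 when
  the posterior rounds to 1 in double precision.
* Depth capping draws a uniform random subset without replacement using
  a generator seeded from the run seed, preserving read order; repeated
  runs with the same seed are byte-identical.
* Zero-depth columns return the prior as posterior; positions absent
  from the pileup are skipped entirely (the output has one record per
  covered position).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `snp_rate` (μ) | 0.001 | prior fraction of positions carrying a variant |
| `tau` (τ) | 0.002 | total substitution-error mass per matrix row |
| `delta` (δ) | 0.03 (damage mode) | deamination mass moved to C→T / G→A |
| `max_depth` | 60 | random downsampling cap on reads per position |
| `quality offset` | 33 | ASCII offset of quality characters (64 selectable) |
| `min_phred` | 30 (strict >) | QC threshold on the Phred posterior |
| `min_supporting_reads` | 10 | QC threshold on reads carrying the alt allele |

The QC filter's support rule counts reads whose called base equals the
called non-reference allele (the best-supported one for multi-allelic
genotypes).  For haploid screens of a known genome, quality-only QC
(`min_supporting_reads = 1`) is the appropriate setting; the 10-read rule
is aimed at diploid resequencing.

## The indel caller is a pragmatic extension

The generative model has no indel channel.  The indel caller reduces each
column to a two-allele problem — the most frequent indel allele against
the reference — with each read contributing a binary right/wrong
observation whose error probability comes from its effective quality, and
the {hom-ref, het, hom-indel} prior reusing the `(1-μ, p(1-p), p²)`
masses renormalised.  It is deliberately minimal and should be read as a
screening tool, not as a model of indel formation.

## What the simulator emulates (and what it does not)

The simulator generates an i.i.d. reference with configurable GC content,
plants SNPs at rate `snp_rate` (heterozygous with probability
`het_fraction`, default 5/9 so the planted hom:het ratio is 0.8, the
value expected in human resequencing), and samples single-end reads with
uniform starts and strands.  Per-read corruption happens in biological
order: deamination first — C→T with probability `d_max·exp(-λ·j)` at
distance `j` from the 5′ end and G→A mirrored from the 3′ end, applied to
the read-space sequence so the pattern is strand-consistent — then
sequencing error at the rate implied by a linear Phred profile
(default 40 at the 5′ end decaying to 30).  Emitted quality strings
encode the intended profile, never the realized errors: damage is
invisible to the sequencer, which is precisely the failure mode the
damage matrix corrects for.  The defaults `d_max = 0.3, λ = 0.3` give a
strong terminal C→T excess decaying within ~15 bp, qualitatively matching
published ancient-DNA damage profiles.

Not emulated: paired-end reads and overlapping mates, mapping error and
soft-clipping (the direct-pileup mode places reads perfectly and assigns
a constant mapping quality), indel variation, coverage biases (GC,
mappability), PCR duplicates, and base-quality miscalibration.  Passing
tests on simulated data therefore demonstrate correctness of the
inference and the direction of the damage-model effect, not end-to-end
accuracy on real libraries, where the mapper and its quality model sit
between the reads and the caller.

## Study-scale choices in the test suite

The whole-pipeline tests run desk-scale analogues of three study designs
on a 100 kb genome: a clean haploid screen (36 bp reads, 27×, reference
prior; zero high-quality SNPs expected at any depth cap), a damaged
low-depth run (5×, `d_max 0.3, λ 0.3`; the damage matrix must strictly
reduce false high-quality SNPs relative to the standard matrix), and a
diploid recovery run (100 bp reads, 30×, SNP rate 0.001; ≥99% genotype
concordance at planted sites and a QC hom:het ratio within 0.15 of the
planted ratio).  100 kb at ~30× keeps each analogue under a minute while
leaving expected event counts (planted SNPs ≈ 100, damaged sites in the
thousands) large enough for the assertions to be statistically stable.
In the diploid analogue, concordance is measured on the unfiltered
all-sites calls restricted to truth sites (uncalled truth sites count as
discordant), while the hom:het ratio is measured on the QC set: the
10-read support rule removes a binomially predictable ~5% of heterozygous
sites at 30× and would otherwise make the concordance figure a property
of the filter rather than of the genotyper.

## Known limitations

* Polyploid genotype spaces, multi-sample joint calling and
  haplotype-aware calling are out of scope.
* Overlapping mate pairs are not deduplicated (the pileup text carries no
  mate identity).
* The damage model is position-independent inside the caller (a single
  expected rate δ); position dependence exists only in the simulator.
  A position-aware damage likelihood would need per-read offsets, which
  the pileup format does not provide.
* Transition/transversion-specific error rates are not modelled.
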