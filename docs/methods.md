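# Methods

This note documents the models behind `csmkd`: what the synthetic-data
generator emulates, how each analysis stage is defined, the numerical choices
that matter, and the limitations of validating against simulation.

## The experiment being modelled

A Csm ribonucleoprotein loaded with a 32-nt-spacer crRNA is injected into
embryos; it cleaves the complementary mRNA (the protospacer region) in the
cytoplasm. Treated and mock-injected pools are sequenced with a stranded,
polyA-selected protocol at several timepoints, in replicate batches. Three
physical facts drive the analysis design:

* polyA selection retains full-length molecules and **3' cleavage fragments**
  (they keep the tail); 5' fragments are lost except for a small selection
  leak;
* a cleaved molecule may instead be degraded to completion by endogenous
  decay, in which case it contributes nothing;
* crRNA can contaminate libraries through nonspecific bead binding, appearing
  as short **antisense** reads confined to the protospacer window.

## Synthetic-data generator (`csmkd.simulate`)

The generator is first-class, tested code: its parameters are the study
conditions every downstream criterion is evaluated under.

**Transcriptome.** i.i.d. sequences at a target GC (default 0.5), lengths
uniform in [400, 2000] nt, abundances log-normal (log-mean 2.0, log-sd 1.2 —
a long-tailed expression distribution). One transcript is the designated
target; `target_weight` pins its share of total expression (default in the
demo: 0.12, reflecting a highly expressed maternal transcript). The default
simulation-study transcriptome is deliberately small (5 genes, target at 25%)
so that per-position profiles are deep at moderate total depth.

**Cleavage bookkeeping.** With cut probability *p*, full-degradation
probability *d* (default 0.9) and 5'-survival *f₅* (default 0.05), one
original target molecule yields on average

    E = (1 − p) + p(1 − d)(1 + f₅)

observable template molecules. Treated-sample target abundance is scaled by
*E*; templates are then drawn from the uncleaved / 3'-fragment / surviving
5'-fragment mixture in proportion. `expected_target_count_ratio` gives the
closed-form treated/mock count ratio (including the per-sample depth
renormalisation) and is used as an oracle in tests. Default *d* = 0.9 encodes
the observation that treated and mock coverage shapes stay broadly similar —
most cleaved molecules disappear entirely rather than persisting as
fragments.

**Fragmentation.** A template of length L is conceptually cut into
n ≈ round(L / mean fragment length) pieces (fragment lengths uniform in
[180, 320] nt; insert size is not documented for the emulated protocol, so it
is a parameter). A sampled fragment is the template-initial piece (start
exactly at the template 5' end) with probability 1/n, the terminal piece with
probability 1/n, otherwise an interior uniform window; templates shorter than
one fragment are sequenced whole. The initial-piece anchoring is what creates
the fragment-end pileup at a cleavage site — without terminal capture, cut
sites would be invisible in end space, which contradicts how such sites are
actually detected. A side effect is that end rates are strongly
position-dependent even without cleavage (steps at fragment-length
boundaries), which the peak caller must and does tolerate.

**Counts.** Per-sample, per-transcript fragment counts are gamma-Poisson
(NB) around the depth split by effective abundance, with dispersion 0.05 —
matching the abundance-test model class so parameter recovery is well-posed.
Batch effects are multiplicative factors on the **target's** abundance only
(the emulated experiments had target-specific batch variation from maternal
genotype); global batch factors would be absorbed by size factors anyway.
`simulate_counts` generates matrices directly at the count level for testing
the GLM machinery at scale.

**Contamination.** Per sample, round(rate × fragment total) antisense records
with lengths 16–32 nt placed inside the protospacer window. Deterministic
counts make the persistence ratio an exact plug-in of the rate ratio.

**FACS events.** A log-normal background (log-mean 2.0, log-sd 0.8) plus a
rare high population at `high_multiplier` × (defaults 0.002 and 2000).
Knockdown divides the high-population frequency. The defaults respect a real
constraint of mean-referenced gating: the high population's contribution to
the sample mean moves the 50× threshold, so its frequency must be small and
its separation large for the gate to cut cleanly between populations.

**What the generator does not emulate:** sequencing errors and quality,
alignment ambiguity, positional coverage biases (GC, priming), gene–gene
correlation, isoforms, and partial complementarity *cleavage* (off-target
transcripts are never actually cut — only planted count effects are). Tests
passing here show the statistics recover their own model's truth; they do not
certify behaviour under real-data artefacts outside this model class.

## Coverage and end profiles (`csmkd.profiles`)

* **Coverage fraction**: per-position depth from half-open intervals divided
  by its transcript sum (unit-sum invariant, 1e-9).
* **LFC coverage**: log2(mean treated fraction + ε) − log2(mean mock fraction
  + ε), computed as a difference of logs so swapping groups negates it
  exactly. ε defaults to 1e-6 (profiles are unit-sum, so this is 1e-6 of the
  total); no pseudocount is documented for the original analysis.
* **End profiles**: counts of fragment starts (5'), end−1 (3'), or both
  termini; normalised profiles sum to 1. Both-termini is the default; under
  polyA selection the cleavage signal concentrates in the 5' ends of 3'
  fragments, so a 5'-only mode is exposed as well.
* **Diff-ends**: mean(treated) − mean(mock) per position; 95% interval from a
  two-sample t construction over replicates (a bootstrap over replicates is
  available; the original figure does not state its CI construction).
  Normalised diff profiles sum to 0 by construction.
* **Peak calling**: argmax of the mean difference over interior positions.
  The score is standardised before the z test: dividing by
  sqrt(pooled end rate + floor) equalises the counting noise across positions
  (the floor is 5% of the uniform rate, preventing blow-ups at near-empty
  positions); the z is then (value − median)/1.4826·MAD over all other
  interior positions. The transcript's two terminal positions are excluded —
  every library piles fragment ends at molecule termini in both conditions,
  which is end-capture structure, not cleavage. Ties break to the lowest
  coordinate; calls require z ≥ `min_z` (default 4).
* **Stagger scan**: the same standardised score at anchor ± k·6 nt;
  "evidence" requires ≥ 2 non-zero offsets at z ≥ min_z, so one strong site
  never counts as a staggered pattern by itself.
* **Persistence**: antisense fragments overlapping the protospacer window ÷
  total sense fragments, per timepoint; the first/last ratio is flagged
  undefined when the last timepoint has no antisense signal.

## Abundance testing (`csmkd.abundance`)

Size factors are DESeq-style median-of-ratios against the geometric-mean
pseudo-reference over genes positive in all samples, normalised to geometric
mean 1, with a total-count fallback (warned) when no such gene exists.

Per-gene NB2 GLMs (log link, log-size-factor offsets) are fitted by IRLS at
fixed dispersion; dispersion is profiled by **Cox–Reid adjusted profile
likelihood** (the adjustment −½ log det(XᵀWX) corrects for estimated
coefficients). For matrix-wide testing the APL of every gene is evaluated on
a 120-point log grid; the trend is the summed-APL maximiser within abundance
bins, and each gene maximises its own APL plus `prior_df` (default 10)
residual-df-equivalents of its bin's average APL. This weighted-likelihood
shrinkage is essential at the 3 vs 3 scale: with 2 residual degrees of
freedom, raw per-gene estimates are noisy and median-biased low, which
inflates the LRT type-I error well beyond nominal; with shrinkage the
empirical type-I error at α = 0.05 sits inside [0.03, 0.07] (verified in the
acceptance suite). `per-gene` and `common` modes are exposed.

The knockdown test is the LRT of `batch + condition` against `batch`
(one χ²₁ degree of freedom; dispersion estimated once under the full model
and shared, statistic clipped at 0). A Wald alternative is provided since the
original per-gene test's form is not documented. A constant condition column
degenerates to statistic 0. Genes below a mean normalised count of 5 are
excluded before testing (independent filtering; stabilises dispersion
estimation) and BH adjustment runs over the tested genes.

QC: PCA and Pearson correlation on log2(normalised + 1); average-linkage
clustering on 1 − r; a depth floor check (default 10⁷ assigned counts, the
scale real libraries are held to — the demo simulation honestly fails it).

## Off-target analysis (`csmkd.offtarget`)

The scorer counts Watson–Crick pairs (G:U wobble behind a flag; the original
match-count definition does not specify wobble) between the spacer and every
ungapped register along the mRNA, including partial end overlaps, on raw
match counts. Ungapped only: mismatch counting against a fixed-length spacer
implies fixed registers. Only the sense strand is scanned — the complex
targets the transcript. The implementation is a vectorised sliding-window
comparison, checked exactly against a brute-force enumeration oracle.

Groups are cumulative (genes with ≥ k matches), so they are nested by
construction. Each group's member counts are **summed** into one pseudo-gene
(a per-gene-median alternative exists behind a flag) and tested with the same
full-vs-reduced LRT; the target is excluded so on-target signal cannot
masquerade as an off-target trend. The pseudo-gene's dispersion is derived
from the gene-wise trend: for independent NB genes,
α_G = Σ αᵢ mᵢ² / (Σ mᵢ)². This borrows the whole matrix's strength instead of
re-profiling six aggregated counts, whose 2 residual df would make a ±1.96·SE
interval behave like a t₂ interval (≈81% coverage instead of 95%). The
independence assumption is part of the generator's model class and a known
limitation for correlated real data.

Spectrum planting (for ground truth) splices a window that pairs at exactly
k positions into a transcript, verifies the transcript-wide maximum equals k
with the scorer, and resamples on violation; background transcripts are
resampled below the smallest planted k so the planted histogram is exact.
Spectrum keys should exceed the random background maximum (≈17–19 for
kb-scale transcripts) or generation will exhaust its retries.

## Spacer design (`csmkd.spacers`)

Transparent penalty components per 32-nt window: |GC − 0.5| (balanced GC),
the longest ungapped self-complementary stem with loop ≥ 3 as a secondary-
structure proxy (full RNA folding is out of scope), the derived spacer's
maximal complementarity to all other transcripts, and overlapping known
polymorphism positions. The composite is a weighted penalty sum (weights
exposed, defaults 1/1/2/5 with components normalised); ranking is
deterministic with coordinate tie-breaks. The scores of any historical
spacer-naming scheme are not reproduced — the ranking here is the package's
own, documented criterion set.

## FACS quantification (`csmkd.facs`)

Gating counts events strictly above fold × reference (mean by default,
matching the published wording; median and pooled-reference modes exposed
because "the mean" is ambiguous across samples). Gating is scale-equivariant
since the reference scales with the data. The fold change between two gated
samples is the ratio of high frequencies; conditional on the total number of
high events the control's share is binomial, and a Clopper–Pearson interval
on that share maps to an exact CI on the rate ratio (a one-sided bound when
the treated sample has zero high events). Side scatter is carried but not
gated on by default — it is confirmatory, not a selection criterion.

## Pipeline and reproducibility

All randomness flows from one mandatory root seed; stages derive
sub-generators deterministically, so identical configs give byte-identical
TSVs (tested). Stage failures abort with the stage named and a FAILED marker
next to the partial outputs. Problem sizes in the shipped demo (60 genes,
depth 3·10⁴, 12 samples) and in the acceptance studies (5-gene deep-coverage
transcriptomes at depth 10⁵ for profile work; 150–1000 genes for count work)
were chosen so each study completes in seconds to a couple of minutes on one
CPU while keeping per-position and per-gene noise at levels where the stated
tolerances are meaningful.

## Known limitations

* The generator's independence and NB assumptions are exactly the test
  model's; real libraries add positional bias, correlation and alignment
  artefacts that are out of scope here.
* The group-trend dispersion plug-in assumes independent member genes.
* The hairpin proxy is not a thermodynamic folding model.
* Partial-complementarity cleavage is not modelled; the off-target machinery
  quantifies abundance trends, not cut sites, for off-target candidates.
* p-values from the LRT are asymptotic (χ²₁) at n = 6; calibration is
  verified empirically under the generator, not guaranteed universally.
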