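# csmkd

RNA-seq on-target and off-target analysis for **Csm-mediated RNA knockdown**
(type III-A CRISPR-Cas effector complexes used as programmable mRNA
endoribonucleases), together with a synthetic-data generator that emulates the
stranded, polyA-selected RNA-seq design such experiments use — so every stage
of the pipeline is testable against known ground truth without any sequencing
download.

## Who this is for

Groups using Csm (or Cas13-style) ribonucleoproteins for transcript knockdown
in embryos or cell pools, who sequence treated vs mock samples and need to
answer, quantitatively:

1. **Where was the transcript cut?** Cleavage leaves a polyA-bearing 3'
   fragment whose 5' terminus sits at the cut site; polyA selection discards
   most 5' fragments. Coverage therefore drops 5' of the cut and the
   fragment-end distribution spikes at it.
2. **How strong is the knockdown?** Per-gene negative-binomial GLMs with batch
   factors, tested by likelihood ratio (full `batch + condition` vs reduced
   `batch`), with Benjamini–Hochberg correction across genes.
3. **Are there sequence-driven off-targets?** Every transcript is scored for
   its maximal base-pairing with the 32-nt crRNA spacer; transcripts are
   grouped cumulatively by minimal match count and each group's summed counts
   are tested for a condition effect. A real hybridization-driven off-target
   effect would make well-paired groups more downregulated.
4. Support analyses: crRNA contamination persistence across timepoints,
   high-fluorescence FACS gating (events above 50× mean) with fold-change
   CIs, spacer candidate ranking, and sample QC (size factors, PCA, Pearson
   correlation, hierarchical clustering, depth floors).

## The statistics at the core

For gene *g* with counts *y<sub>gj</sub>* in sample *j*, the model is NB2 with
log link:

    log E[y_gj] = log s_j + β_0 + Σ_b β_b 1[batch_j = b] + β_c 1[condition_j = treated]

with median-of-ratios size factors *s<sub>j</sub>*, and Var(y) = μ + αμ².
Dispersion α is profiled per gene by Cox–Reid adjusted profile likelihood and
shrunk toward an abundance-binned trend (small designs leave too few residual
degrees of freedom for stable per-gene estimates). The knockdown test is
LRT: 2(ℓ_full − ℓ_reduced) ~ χ²₁, with β_c/ln 2 reported as the log2 fold
change.

Cleavage-site localisation works on per-position **end profiles**: normalised
fragment-end fractions per replicate, differenced treated-minus-mock with a
95% t-interval, variance-stabilised by the local end rate, and peak-called
with a robust (median/MAD) z-score at `min_z = 4`. A stagger scan checks for
secondary cut sites at ±6·k nt around the called peak (type III complexes can
cut at 6-nt intervals in vitro).

## Worked example

```bash
csmkd run-all configs/demo.yaml --out runs/demo
```

simulates 60 transcripts (one 720-nt target at 12% of expression, cut at
position 300 with probability 0.9, 90% of cleaved molecules degraded to
completion), triplicate injected vs mock samples at two timepoints with
batch effects on the target, then runs all analysis stages. The
`summary.json` of that run contains (abridged, exact values for seed 11):

```
"peak":    {"position": 300, "z": 21.4, "within_protospacer": true}
"stagger_verdict": "no-evidence"
"persistence": {"ratio_first_to_last": 2.507}
"abundance": {"128cell": {"target_lfc": -2.48, "target_p": 3.5e-20}, ...}
"offtarget": {"fraction_groups_ci_contains_zero": 1.0}
"facs":    {"estimated_fold_change": 13.0, "ci": [6.6, 29.1]}
```

Read: the cleavage site is recovered exactly at the planted cut (robust z =
21) with no evidence for 6-nt-staggered secondary cuts; the target knockdown
is highly significant once batch is modelled (LFC ≈ −2.4, matching the
simulated observable-mass reduction); crRNA contamination decays ~2.5-fold
between timepoints; no complementarity group shows an off-target trend; and
the simulated 20× depletion of high-fluorescence cells is inside the gated
fold-change CI.

Each stage is also available as a subcommand (`simulate`, `profile`, `test`,
`offtarget`, `facs`, `design`) and produces the same numbers as the full run.
All outputs are plain TSV/JSON; coordinates are 0-based half-open.

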