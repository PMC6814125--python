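# Methods

This note documents the models and procedures implemented in rootmir,
the assumptions behind them, the defaults and why they were chosen,
and what the synthetic benchmark does and does not establish.

## Study design emulated

Three watering treatments of the maize seedling primary-root growth
zone — well-watered (Ψ_w ≈ −0.02 MPa), mild water deficit (−0.3 MPa)
and severe water deficit (−1.6 MPa) — with four biological replicates
per treatment entering the statistics. Small-RNA libraries yield
21–25-nt tags; degradome (PARE) libraries capture the uncapped 5′ ends
of cleavage products; counts per miRNA are analysed per library;
stem-loop RT-qPCR provides an orthogonal fold-change estimate for a
panel of miRNAs.

## Read cleaning

Adapter trimming truncates at the first exact occurrence of the 3′
adapter, or of an adapter prefix of ≥ 8 nt ending flush with the 3′
end of the read. Matching is exact: the tolerance of a fuzzy matcher
is unverifiable without knowing the sequencer's error profile, and the
synthetic benchmark plants exact adapters. The quality rule drops a
read when any Phred score strictly below 25 occurs among its first 25
bases (20 for degradome reads); a score of exactly 25 passes. Reads
shorter than the window are evaluated over their available bases
rather than auto-dropped — the ≥ 18-nt length rule already removes
short inserts, so auto-dropping would conflate two filters.

Degradome reads are reduced to their first 20 nucleotides, which are
*retained* as the tag: the 5′ end of a degradome read is the cleavage
signal, and a pipeline that discarded it would destroy the assay. A
`mode="literal"` alternative removes the first 20 nt and keeps the
remainder, for comparison with pipelines that read the rule that way.

## Tag assignment and isomiRs

Canonical assignment is exact string matching against the mature
sequences. Family members with identical mature sequences are
indistinguishable at the tag level, so they form one merged identifier
(`zma-miR399e,i,j-3p` style) counted once — merged groups, not
individual members, are the unit of the differential analysis.

A non-exact tag is interpreted against each canonical miRNA at every
feasible 5′ offset (|offset5| ≤ 2) with the 3′ offset implied by the
tag length (|offset3| ≤ 3). Bases outside the canonical interval are
extensions: templated if they continue the hairpin sequence,
untemplated otherwise. Mismatches inside the canonical interval are
internal substitutions (≤ 2). The winning interpretation minimises
(substitutions, untemplated bases, total end offset) lexicographically
— end variation is biologically cheap (imprecise DCL1/DCL2 cleavage),
untemplated tailing is rarer, internal polymorphism rarest — with ties
broken by canonical abundance when supplied, then id. Tags beyond all
bounds are `variant-novel`. Classes are mutually exclusive: any
internal substitution makes the call an internal variant; otherwise
the nonzero offsets decide 5′/3′/both; a zero-edit call is canonical.

IsomiR counts are reported separately and never added to canonical
counts, so the DE analysis operates on unambiguous canonical/merged
counts only.

Abundance is RPTM (reads per ten million): 10⁷ × count / library
total. The retention filter keeps a miRNA reaching ≥ 1 RPTM in at
least 3 of the 4 libraries of at least one treatment group —
abundance must be reproducible within a condition, not global.

## Differential abundance

Tests run on raw counts with normalisation carried as library scaling
factors, never on RPTM values, because scaling after the fact destroys
the mean–variance relationship the NB model needs.

**TMM.** Scaling factors follow the weighted trimmed mean of M-values:
reference library chosen by the 75th percentile of count fractions
closest to the mean; per-library M (log-ratio) and A (log-abundance)
over features positive in both libraries; 30% two-sided trim on M and
5% on A by ranks; weights are inverse asymptotic binomial variances;
factors re-centred to geometric mean 1. The implementation was checked
once against an independent Bioconductor implementation on a fixed
matrix and those factors are frozen in the test suite.

**Dispersion.** The NB dispersion φ (squared biological coefficient of
variation) is estimated by maximising the conditional log-likelihood
of counts given their group totals, which removes the group means from
the problem. Library sizes are first equalised by scaling counts to
the geometric-mean effective size and rounding ("pseudo-counts") — an
approximation to quantile adjustment that is accurate at the moderate
counts this assay produces. The common φ maximises the summed
conditional likelihood over a log-spaced grid (φ ∈ {0} ∪ [10⁻⁴, 5], 80
points); per-miRNA values maximise the feature's own likelihood plus
`prior_df / residual_df` times the across-feature average (prior_df =
10), which shrinks noisy per-feature estimates toward the common value
— essential at n = 4 per group.

**Test.** The two-group comparison is an exact NB test conditional on
the per-feature total of the equalised counts: the group sums are NB
with common mean and dispersion under the null, and the p-value
accumulates all splits of the total no more probable than the observed
one. This is a deliberate substitute for a quasi-likelihood F-test:
with 4 + 4 libraries and moderated dispersion the two agree closely,
and the exact test has no asymptotic approximation to fail at low
counts. Accuracy is therefore claimed through error-rate properties
(null uniformity, false-positive fraction, recall on planted effects),
not through numerical reproduction of any published test statistic —
published fold changes embed shrinkage constants that are not
recoverable from the publication.

**Fold changes.** log2FC uses TMM-normalised group means with a prior
count of 0.125 scaled by relative library size, the smallest value
that keeps fold changes finite and rank-stable when one group is all
zeros (a real case: a miRNA silenced by stress).

**Multiple testing.** Benjamini–Hochberg step-up; FDR < 0.05 declares
significance. The mild/severe contrast comparison partitions the
significant sets and counts shared miRNAs with discordant fold-change
signs.

**Replicate QC.** BCV = √(common φ) over the 100 highest-count miRNAs
on non-normalised counts; libraries are ordinated by classical scaling
of pairwise "leading log-fold-change" distances (root-mean-square of
the 500 largest |log2 ratios| per pair); a library is an outlier when
its median distance to its own group's members exceeds the median plus
3 robust MADs of those within-group distances. The MAD is floored at
10% of the median so that near-identical replicates do not produce a
degenerate threshold. The intended order of operations is QC → drop
outliers → retention filter → testing.

## Degradome target validation

Binding sites are transcript windows whose antiparallel Watson–Crick
pairing to the miRNA scores < 4 mismatches. G:U wobble counts as a
full mismatch by default — the strictest reading of a mismatch
criterion — with `match` and `half` policies available, since wobble
pairing is thermodynamically real. miRNA position i (1 = 5′ end) pairs
transcript base `site_end − i + 1`; transcript coordinates are 1-based
closed intervals throughout, matching degradome-viewer conventions.

A call is valid when ≥ 1 tag 5′ end lies on a base paired to miRNA
positions 9–11. AGO-catalysed slicing cuts between the bases opposite
positions 10–11, so the expected tag 5′ end is the base paired to
position 10; the 9–11 window absorbs ±1 register slop. The peak
category compares the best 9–11 position with the transcript-wide
modal 5′ position (dominant / co-dominant / minor). Multi-mapping tags
count at every locus and are flagged, with a unique-only switch;
dropping them silently would bias against recently duplicated targets.

## Target-mimic scan

A mimic locus pairs the miRNA perfectly-or-nearly except for a
transcript-side insertion bulge of 1–3 nt placed between miRNA
positions 10/11 (or 9/10), with ≤ 3 mismatches in the paired flanks.
The bulge at the slicing site is what converts a substrate into a
sponge. miRNA-side deletions are not searched: described plant mimics
(IPS1, *pilncr1*) are all transcript-side insertions. Windows
containing a perfectly complementary ungapped stretch are excluded as
cleavable sites; equal-scoring interpretations of one locus collapse
to the fewest-mismatch, shortest-bulge, 10/11-first description. With
the bulge disabled and exclusion off the scan provably degenerates to
the binding-site search, which the suite checks. Defaults recover
planted mimics in 100/100 seeds with a < 5% per-seed false hit rate on
random 2-kb transcripts.

## Coherence classes and cross-platform checks

Degradome-valid miRNA–transcript pairs are classified per pair: a
transcript significant in no contrast is *target-unchanged*; otherwise
the contrast of strongest transcript significance decides, by sign
agreement of the two fold changes, between *positively correlated*
(co-regulation) and *inversely correlated* (the signature expected if
the miRNA drives the transcript's abundance). Platform agreement uses
Spearman rank correlation with average ranks; the permutation p-value
is exhaustive for n ≤ 8, seeded Monte-Carlo (10⁵ draws) for n ≤ 10 and
the asymptotic t approximation beyond — exhaustive enumeration of 10!
arrangements buys no accuracy worth its cost.

## ddCt quantification

Technical replicates collapse by mean first; ΔCt subtracts the mean Ct
of the reference miRNAs (using two references is exactly equivalent to
averaging their Ct, a tested contract); ΔΔCt subtracts the calibrator
treatment; RQ = 2^(−ΔΔCt) with amplification efficiency fixed at 2, the
standard ddCt assumption. RQ is invariant to any machine-wide Ct
offset. Reference selection ranks candidates by the variance of their
treatment-mean Ct and accepts those below 0.5 cycles² — a stand-in
rule, since published reference choices rarely state their criterion;
its limitation is visible in the examples: a weak (2-fold, one
treatment) responder can slip under the threshold, so candidate panels
should exclude known responders.

## Synthetic data: what it emulates, what it does not

Every sub-generator draws from a named pseudorandom stream derived
from the single seed (`default_rng([seed, crc32(name)])`), so outputs
are bit-reproducible and adding a generator never perturbs another.

- **Reference.** Random mature sequences (21–24 nt by default) inside
  random-flank hairpins, invented high family numbers (miR9001+) so no
  fabricated sequence shadows a real annotation; one family carries
  identical mature sequences across members to exercise merged-ID
  counting.
- **Small-RNA reads.** Insert (canonical or isomiR) + adapter,
  truncated to 40 nt, Phred 30–40 baseline. IsomiRs appear at rate
  0.15 with one edit type each — 5′ offset, 3′ offset, both, or 1–2
  interior substitutions — extensions templated from the hairpin with
  probability 0.5, otherwise drawn from the three non-templated bases.
  1% of reads get one sub-25 quality score inside the first 25 bases
  and 1% a sub-18-nt insert, providing planted truth for the filters.
- **Degradome.** Per planted site, each of 50 tags falls on the base
  paired to miRNA position 10 with probability `peak_fraction` (0.8
  default), else uniformly; every transcript receives
  Poisson(noise_rate × 50) background tags.
- **Counts.** NB via the gamma–Poisson mixture, mean = depth ×
  relative abundance × group effect, φ = 0.2 (BCV ≈ 0.45, typical of
  biological replicates), abundances log-uniform over three decades,
  per-library depth jitter ±20%. A de_fraction = 0.2 subset receives
  2-, 4- or 8-fold effects with random sign, under severe only / both
  / mild only with probability 0.6/0.3/0.1, echoing the predominance
  of severe-stress responses; designated reference miRNAs always have
  zero effect. The `simulate_spike_benchmark` variant plants a fixed
  fold at a fixed mean for error-rate calibration (2000 features, 4v4,
  8-fold at mean 200 by default).
- **qPCR.** Ct = 35 − log2(10⁶ × abundance × effect) + biological
  (σ = 0.15) + technical (σ = 0.1) Gaussian noise.

Not emulated: genome-scale background small RNAs (tRNA/rRNA/repeat
fragments), position-dependent sequencing error, ligation bias,
multi-isoform transcripts, and annotation-driven attrition of read
counts. Consequently, passing benchmarks demonstrate the correctness
of the inference rules under the assumed statistical model, not
robustness to every artefact of real libraries; absolute recovery
counts from real data depend on external mapping stacks and databases
that are out of scope here.

## Problem sizes used by the test and acceptance runs

Read-level checks use 10⁵-read libraries (20k for classification
agreement); DE calibration uses 2000 features × 8 libraries over 20
null seeds and 3–5 spiked seeds; mimic rates use 100 seeds; ddCt
recovery uses 100 seeds. These sizes give Monte-Carlo error comfortably
inside the asserted margins while keeping a full run in minutes on one
CPU.
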