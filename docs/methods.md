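# Methods

## Measurement model

A probeset interrogates one gene with K = 11 perfect-match 25-mers. A
parent-specific feature (PSF) is a probe whose target carries a fixed
mutation separating the diploid parent's D-genome transcript from the
tetraploid parent's A/B-genome transcripts, so the probe binds one parental
pool at full efficiency and the other attenuated by `2^−δ` (δ in log2
units). A TC-specific probe cannot separate A- from B-genome expression;
it reads the combined AB pool.

Preprocessing follows the usual single-channel chain: optional per-sample
background shift (low-quantile baseline, floored at 1), quantile
normalization to the mean order-statistic distribution (average-of-ties
rule, deterministic), log2 transform, and — for probeset-level analyses —
Tukey median polish (row sweeps first, effect medians folded into the
overall term, tolerance 1e-6, 10 iterations) or probe means. The original
vendor background convolution is not reproduced; background handling is
`none` or `shift`, and the downstream statistics depend on it only weakly.
Bit-level agreement with any particular normalization of the real arrays is
therefore out of reach by design.

## PSF discovery

Per probeset, the additive model `Y_ijn = μ + p_i + g_j + ε` is fitted to
the two parental genotypes. Balanced designs use the closed form
(probe mean + genotype mean − grand mean), which equals the generic
least-squares solve; unbalanced designs fall back to the generic solve.
The residuals carry the probe-by-genotype interaction. Each probe's two
residual groups feed the SAM statistic

    d = (mean_TC − mean_AT) / (s + s0),

with `s` the pooled two-sample scale and `s0` a fudge factor, by default
the 5th percentile of the `s` distribution (the coefficient-of-variation
minimization search over `s` percentiles is available; both are
deterministic). Significance uses the classic SAM construction: d-statistics
under every balanced relabeling (all C(8,4) = 70 assignments at 4 vs 4
replicates; sampled with a fixed seed otherwise), expected d as rank-wise
means of the sorted permuted values, and cut points found by scanning
outward from the observed d nearest zero for the first
`observed − expected > Δ` (upper side; mirrored below). The permutation FDR
is `π0 ×` the median count of permuted d outside the cuts over the number
called, with `π0` estimated by the interquartile rule (or pinned to 1).
`Δ` is either fixed (0.2 reproduces the study setting) or the smallest
value on a 0.01 grid whose estimated FDR meets a target.

Retained probesets must carry no more PSFs than the neutral mutation
budget — rate 5.5e-9 /site/yr × 2.7 My divergence × 275 bp ≈ 4.08, floored
to 4 — and must not be all-PSF (a gene silenced in one parent makes every
probe look parent-specific). Both rules address cross-hybridization with
diverged paralogs rather than statistical error.

## Homoeolog expression ratios

For each PSF, `E_p/Ē_t = log2 E_p − log2 Ē_t`, with `Ē_t` the arithmetic
mean of the probeset's non-PSF probe intensities on the linear scale (a
log-scale mean is available for sensitivity analysis). The one-way genotype
model is fitted per PSF across AT, TC and SN (df = 12 − 3 = 9 at four
replicates); contrast standard errors use the pooled MSE,
`SE = sqrt(MSE Σ c_j²/n_j)`, with two-sided t p-values. Degenerate fits
(MSE = 0) flag p = 0 for a nonzero estimate and p = 1 otherwise. The two
mid-parent contrasts (1:1 and 1:2 dosage weights) are BH-controlled at
α = 0.05 separately per contrast family, giving four categories:
mid-parent (neither significant), non-additive (both), or consistent with
only one dosage model. Direction comes from the 1:1 contrast sign —
chosen because the 1:1 model is the standard best-fit reference for
allopolyploid expression — and is attributed to the D genome for
AT-specific probes and the combined AB genomes for TC-specific probes.
Concordance filtering removes whole probesets in which same-class PSFs call
opposite directions; an AT-specific "up" with a TC-specific "down" is
biologically consistent (the two genomes may move oppositely) and is kept.

The MIX arrays provide the method's experimental null: the 1:1 RNA mix
truly contains every gene at the mid-parent level, so significant
`MIX − (AT + TC)/2` contrasts are false positives by construction. The
module reports the MIX fraction, the corresponding SN fraction, and their
ratio, since more than one published summary of this comparison is in
circulation.

## Synthetic data generator

Defaults are the study conditions: 2,000 probesets × 11 probes, four
replicates of AT/TC/SN/MIX, log2 noise σ = 0.15, probe affinity offsets
N(0, 0.7²), baseline expression N(8, 1.5²) log2, half the genes divergent
between the parents with N(0, 1) log2 effects (a fixed-effect override
exists for calibration runs), PSF counts per probeset multinomial on 0..4
with probabilities (0.30, 0.30, 0.20, 0.12, 0.08) (mean ≈ 1.4 — of the
order of the filtered study set), AT/TC class balance 1/2, mismatch
penalties δ ~ U[0.5, 2] log2 (recovery analyses use U[1, 2], the regime in
which single-mismatch probes are reliably separable at this noise level),
a fifth of genes non-additive with a ±1 log2 shift of one genome's SN
contribution, and a 1:1 dosage mixture for additive genes. MIX is the
exact linear-scale mid-parent. All draws flow from one seeded generator;
same seed, same bits.

The generator emulates probe/probeset structure, divergent-mutation
hybridization penalties, parental expression divergence, additive vs
shifted genome contributions, and matched probe sequences/read pools. It
does not emulate non-specific background binding, intensity saturation,
sequence-dependent affinity beyond a random offset, read errors or indels,
or correlated replicate effects — so passing recovery tests demonstrate
the statistical machinery under the stated hybridization model, not
performance on real arrays.

Ground-truth labels: per-probe PSF status/class and, for PSF probes, the
noiseless `E_p/Ē_t` per genotype together with the noiseless 1:1 and 1:2
contrast values implied by the generative formula; per-gene regime
(additive vs non-additive with the shifted genome and direction). Scoring
reports PSF sensitivity, realized false-discovery proportion, class
accuracy, the category confusion matrix with binary accuracy, and
direction accuracy against the noiseless contrast sign.

## Known limitations

Two biases are intrinsic to the design and visible in the recovery
metrics; both follow exactly from the measurement model above.

1. **Induced interactions.** With k same-class PSFs in a probeset, the
   genotype main effect absorbs their mean penalty, leaving a genuine
   interaction of `(k/11)·mean(δ)` on every non-PSF sibling probe. These
   probes are honestly differential under permutation logic, so the
   permutation FDR cannot account for them and the realized per-probe
   false-discovery proportion against truth labels far exceeds the SAM
   estimate (≈ 0.59 vs 0.10 at the default conditions). The mutation-budget
   and all-PSF filters remove the worst probesets; the residual excess is a
   property of the residual-interaction design, not of the implementation.

2. **Mid-parent reference bias and ratio compression.** The SN ratio is the
   log of an arithmetic pool mixture while the in-silico mid-parent is a
   mean of log ratios including the pure cross-hybridization term −δ. For
   an additive gene the 1:1 contrast is therefore biased by up to ≈ 0.33
   log2 (δ = 2), while the cross-hybridization leak compresses a genuine
   2-fold shift of one genome to a measured ≈ 0.15–0.3 log2 change. At
   δ = 2 a 2-fold down-shift cancels the bias exactly and is undetectable,
   and a 2-fold TC-type up-shift under 1:1 dosage mimics the 1:2 dosage
   model. Consequently additive genes are classified mid-parent at ≈ 0.82
   rather than the nominal 1 − 2α, the binary category accuracy sits near
   0.79, and the MIX false-positive rate on genuinely divergent PSFs is
   ≈ 0.34 — the experimental signature of the same reference bias. The MIX
   null control (probes without true divergence) stays within its nominal
   α, confirming the inference machinery itself is calibrated.

Problem sizes in the test suite and the acceptance script (2,000 probesets
for recovery, 600 for the divergence analysis, 120 for read-pool
validation, ten seeds for the MIX null) keep seeded runs reproducible in
seconds while leaving the recovery metrics stable to the third decimal
across seeds.
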