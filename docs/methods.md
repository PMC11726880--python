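# Methods

## Model and procedure

`cashde` implements a two-condition differential-expression analysis in
which the test statistic is a difference of Shapley values rather than a
difference of group means.

**Discretization.** For each gene the control samples define a reference
mean m and sample standard deviation s (n−1 denominator, ≥2 controls
required). Every sample — case *and* control — is coded 1 in the
over-expression matrix when its value is ≥ m + s (boundary inclusive) and 1
in the under-expression matrix when its value is < m − s (strictly below).
Genes with s = 0 are non-informative: m ± 0 would flag vacuously, so their
rows are all-zero in both directions.

**Microarray game.** Within one group of m samples, sample j's *support*
sp(j) is the set of genes it flags; the coalitional game is
v(S) = |{j : sp(j) ≠ ∅, sp(j) ⊆ S}| / m — a coalition is worth the
fraction of samples whose abnormal profile it fully explains. v is monotone
with v(∅) = 0. The game decomposes into unanimity games, one per distinct
non-empty support, giving the exact closed-form Shapley value
Φ_g = (1/m) Σ_{j: k_j>0} b_gj / k_j with k_j = |sp(j)|: every sample
distributes one unit of credit equally over its flagged genes. Samples with
empty support still count in m (they dilute Φ; v is defined over all
samples of the group). The closed form satisfies efficiency
(Σ Φ = fraction of non-empty supports), symmetry, dummy and monotonicity,
and is verified in the suite against a brute-force oracle that evaluates
the permutation definition (predecessor-coalition weighting
|S|!(n−|S|−1)!/n!, exact; guarded to ≤10 genes).

**Inference.** For each direction the statistic is
d_g = Φ_g^case − Φ_g^control. The null is built by pooling the case and
control sample columns and redrawing, B times, a pseudo-case group of size
m_case and a pseudo-control group of size m_ctrl with replacement;
p_g = (1 + #{|d*| ≥ |d|}) / (B+1). Resampling is at the column level and
shared across genes, preserving gene–gene dependence; the +1 correction
keeps p > 0. The two directions are combined as
p_gene = min(1, 2·min(p_over, p_under)). Genes enter the analysis only if
their raw Welch p (configurable to the moderated-t p) is below the chosen
stringency (0.01 or 0.05); BH correction is applied across exactly that
preselected family. A fold-change filter |FC| > 2 (strict; signed
FC = 2^Δ for Δ ≥ 0, −2^(−Δ) otherwise, Δ = case−control mean log2
difference) can be required on top.

**Direction labels.** The reported direction combines the winning side with
the *sign* of its Shapley difference: over-game win with d_over > 0 → up;
under-game win with d_under > 0 → down; an under-game win with d_under < 0
means the cases are *less* under-expressed than the controls and is labeled
up (symmetrically for over/d < 0 → down). Labeling by winning side alone
demonstrably mislabels genes whose under-game significance is driven by the
controls. Remaining ties follow the sign of Δ, then default to up.

**Baselines.** Welch's t with Welch–Satterthwaite df is computed from the
closed formulas. The moderated t pools the two-group residual variance
(d = n1+n2−2 df), estimates the scaled-F prior (d0, s0²) by method of
moments on log s² (digamma/trigamma matching; trigamma inverted by Newton
iteration, tolerance 1e-8) and shrinks s̃² = (d0 s0² + d s²)/(d0 + d); the
statistic is referred to t on d0 + d df. When the excess spread of log s²
is ≤ 0 the prior df is infinite and every gene uses the common variance
with a normal reference (the Bioconductor implementation instead caps the
total df at the pooled residual df; the difference is a few 1e-4 in p and
only arises for homoscedastic data). BH is the classical step-up with
stable ties. p-values are floored at the smallest positive normal float so
BH never sees 0.

## Synthetic data

The generator emulates RMA-style normalized log2 microarray data: per-gene
baselines μ_g ~ N(7, 1.5²) (typical RMA intensity scale), i.i.d. Gaussian
noise N(0, 0.5²) for every sample, and for each planted DE gene an additive
shift of ±effect_size·noise_sd applied to a fixed-size random subset of
round(penetrance·n_case) case samples. The fixed-size subset (rather than
per-sample Bernoulli) makes the planted penetrance exact, which keeps power
comparisons free of binomial jitter. The default profile is 2000 genes, 12
cases vs 14 controls — the shape of a small autism peripheral-blood study —
with 2.5 % DE genes at 2× noise SD and full penetrance unless overridden.
The study regime used in the power checks lowers penetrance to 0.4.

What the generator does **not** emulate: probe-level structure, batch and
covariate effects, heavy-tailed or correlated noise, mean–variance trends.
Passing tests therefore demonstrate the statistical behaviour of the
methods under a clean heterogeneous-dysregulation model, not performance on
raw GEO data.

## Problem sizes and numerical choices

The suite and the acceptance script run everything at desk scale, chosen as
the smallest sizes at which the statistical statements are stable: oracle
equivalence on ≤6×6 games (1e-12 tolerance), axioms on 1000 random
matrices, calibration and power runs at 2000 genes × ~10v10–12v14 with
B = 200 and 10–20 seeds. The production default stays B = 1000. All
randomness flows through `numpy.random.default_rng` seeds; the CASh
pipeline derives one child stream per direction via `SeedSequence.spawn`,
and result TSVs are rendered at 6 significant digits so identical
(data, config, seed) runs are byte-identical.

## Known limitations

* **The bootstrap p is conservative for sparsely flagged genes.** With
  ~15 % flag rates and ~20 samples, most null genes carry only 1–3 flagged
  columns, so |d| lives on a few atoms; ties count as exceedances, and
  with-replacement redraws can duplicate a sparse gene's flagged columns so
  that |d*| stochastically dominates |d|. Measured type-I error on all-null
  data is ≈ 0.017 at nominal 0.05 and ≈ 0.003 at nominal 0.01 (a
  without-replacement variant is more conservative still, ≈ 0.007). The
  test is therefore valid — it never exceeds its nominal level, which is
  what the property suite asserts — but it is not exact, and no
  tie-respecting resampling p-value can be at these sample sizes. Power is
  correspondingly understated, yet the method still dominates Welch+BH in
  the partial-penetrance regime.
* Two-group designs only; no covariate or batch adjustment.
* The Bonferroni-2 direction combination is conservative when both
  directions carry signal.
* The preselection step conditions the BH family on a Welch screen; q
  values are interpretable within that family only.
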