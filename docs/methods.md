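# Methods

`mirmark` implements a network-topology model for nominating miRNA
biomarkers from paired miRNA/mRNA expression studies with three sample
groups — normal tissue, clinically localized primary tumour (`pPCa`) and
metastatic tumour (`mPCa`) — together with a reference catalogue of
miRNA→mRNA regulatory pairs.  This note records the model, its assumptions,
the numerical conventions, and the design choices that were genuinely open.

## Model and procedure

1. **Differential expression.**  For each contrast — *occurrence* (normal
   vs pooled tumour) and *progression* (pPCa vs mPCa) — every feature g gets
   a two-group fit: log fold change `b_g` (difference of group means, log2
   scale), pooled within-group variance `s²_g` on `d_g = n_a + n_b − 2`
   degrees of freedom, and the standard-error scale `v_g = 1/n_a + 1/n_b`.
   Empirical-Bayes moderation assumes `s²_g ~ s₀² · F(d_g, d₀)` and shrinks

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t̃_g  = b_g / √(s̃²_g · v_g)   on d₀ + d_g df.

   The prior `(d₀, s₀²)` is fit by the method of moments on
   `z_g = log s²_g`: the digamma/trigamma moment equations are inverted with
   Newton iteration on the trigamma function (tolerance 1e-8, ≤ 50 steps).
   When the spread of log-variances does not exceed the χ² sampling
   component, `d₀` is unbounded: all variances collapse to `s₀²` (estimated
   as the arithmetic mean of the sample variances in that branch) and p
   comes from the normal limit of the t.  Raw two-sided p-values are
   BH-adjusted per contrast; adjusted p < 0.05 defines the DE sets (the cut
   is strict; `alpha = 1` disables the filter entirely).  Multi-probe
   platforms are collapsed per gene to the probe with the smallest raw p
   (ties: larger |log FC|, then lexicographic probe id).  The implementation
   reproduces the Bioconductor limma two-group moderated-t to machine
   precision in the finite-`d₀` case (frozen cross-check in the test
   suite); the only deliberate divergence is the unbounded-`d₀` reference
   distribution, where limma caps the df at the pooled residual total while
   `mirmark` uses the normal limit.

2. **Condition-specific networks.**  Each contrast's DE-miRNA and DE-mRNA
   sets induce a subnetwork of the reference map: edges whose miRNA and
   mRNA are both DE, with zero-degree nodes dropped.  Extraction is
   monotone and idempotent; identifiers are matched case-sensitively and
   never normalized across miRBase versions (remapping is an
   input-preparation concern).

3. **Regulator topology.**  Per miRNA and per network:
   * `NTG` — number of targeted genes (out-degree), the hub property;
   * `NSR` — number of single-line regulations: targets with in-degree
     exactly 1, i.e. genes the miRNA controls with no redundancy.  These
     are the vulnerable points of the network, so a high NSR marks a miRNA
     whose dysregulation can destabilize the system;
   * `NSR/NTG` — the exclusively-controlled fraction, reported to 4
     decimals, defined 0 for an isolated miRNA.

4. **Prioritization.**  A miRNA is prioritized in a network when all three
   features are *significantly high* (conjunction, each p < 0.05, no
   correction across miRNAs — multiplicity is handled only at the DE
   stage).  The default test is a leave-one-out one-sample Wilcoxon
   signed-rank: for focal miRNA m and feature x, the differences
   `{x_i − x_m : i ≠ m}` are tested one-sided against a zero median
   (alternative: median below zero, i.e. m exceeds the network's typical
   value).  Zero differences are dropped; |d| is midranked under ties; the
   p-value is exact by sign-pattern enumeration (dynamic programme) for
   n ≤ 25 without ties, otherwise a normal approximation with tie and
   continuity correction.  An alternative *percentile* rule (flag
   `wilcoxon_variant="percentile"`) prioritizes miRNAs at or above the 95th
   empirical percentile of the remaining miRNAs on all three features.

5. **Intersection and shared regulations.**  Biomarker candidates are the
   miRNAs prioritized in *both* condition networks.  Their shared
   regulations are the incident edges present in both networks
   (`shared_mode="intersection"`, default) or in either (`"union"`).

6. **Evaluation.**  Per-candidate ROC/AUC for both contrasts, using the
   miRNA's expression directly as the classifier score: the AUC equals the
   Mann–Whitney probability (ties ½).  Down-regulated markers naturally
   score below 0.5, so both the directional AUC and the folded value
   `max(AUC, 1−AUC)` are reported.  Samples are clustered hierarchically
   (average linkage) on `1 − Pearson` distance over per-feature
   standardized candidate expression, with samples pre-sorted by id so the
   leaf order is invariant to input permutation; a 3-cut gives flat groups.
   The literature-precision index is `100·|predicted ∩ known|/|predicted|`
   for a user-supplied list of known biomarkers.  An external validation
   matrix can be scored against a fixed candidate list through the same
   code path.

7. **Over-representation.**  Shared-regulation target genes are tested per
   gene set with the one-sided hypergeometric upper tail
   `P(X ≥ k)` for overlap k, set size K, target-list size n and universe N;
   `mode="ease"` substitutes k−1 (floored at 0) for a conservative
   EASE-style score.  The default universe is every mRNA of the reference
   network — the natural background for targets drawn from that network —
   and is overridable.  BH is applied across the collection; the report
   keeps the ten smallest raw p below 0.05.  No curated GO/KEGG content is
   bundled: annotation databases are version-dependent and supplied by the
   user as GMT.

## The two prioritization variants are different questions

The signed-rank variant asks a *location* question — "is this miRNA's value
significantly above the typical network value?"  With many comparator
miRNAs it has high power, so under an unstructured (null) network it flags
every above-typical miRNA: measured per-metric rates are ~0.39 and the
three-feature conjunction ~0.18 at the default network scale.  It is the
variant that reliably recovers a planted biomarker *set*: all planted
miRNAs can exceed the typical value simultaneously.

The percentile variant asks a *selection* question — "is this miRNA in the
top 5%?"  It is calibrated by construction (measured per-metric null rate
≤ 0.047 over 20 seeds) but can never select more than ~5% of the network's
miRNAs, so it cannot recover a planted set that is a larger fraction of the
network.  Both variants are first-class and reported side by side; use the
signed-rank default to rank and collect candidates, and the percentile rule
when a nominal selection rate matters.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* setting of a three-group
prostate microarray study: log2-scale expression with Gaussian within-group
noise (`noise_sd`, default 1.0), group sizes 28/99/14 (miRNA arm) and
29/131/19 (mRNA arm), a fraction `de_fraction` (default 0.25) of features
DE per contrast with a ±`effect_size` shift (default 2.0 log2 units), and a
reference network with independent background edges at `edge_density`
(default 0.02, matching the edge density implied by condition networks of a
few thousand edges over ~10² miRNAs × ~2·10³ mRNAs).  Feature counts
default to 150 miRNAs × 1200 mRNAs — the study arrays' proportions at a
size where the full pipeline runs in well under a second.

Planted structure: `n_planted_biomarkers` (default 9) miRNAs are DE in both
contrasts and each receives `singleline_boost` (default 15) *exclusive*
targets — mRNAs regulated by that miRNA alone, themselves DE in both
contrasts so exclusivity survives condition-network extraction.  Occurrence
effects shift both tumour groups equally; progression effects shift mPCa
against pPCa with weights `(−n_m/(n_p+n_m), +n_p/(n_p+n_m))` so the pooled
tumour mean is unchanged — a progression-only feature is exactly null for
the pooled occurrence contrast, which keeps the per-contrast ground-truth
DE sets well-defined.  Effect signs are random and recorded.

Not emulated: probe-level artifacts (background correction, normalization,
batch), correlated noise between features, realistic degree distributions
(background edges are i.i.d. Bernoulli rather than scale-free), partial
overlap between miRNA and mRNA cohorts, and any biological annotation
content.  Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the generative model, not performance on real
microarray data.

## Numerical conventions and degenerate inputs

* Determinism: every random draw descends from one root seed
  (`numpy.random.SeedSequence` spawned per stage); identical configs give
  byte-identical artifacts.  Manifests carry no timestamps.
* Zero-variance features participate in shrinkage (`s̃² > 0` whenever
  `d₀ > 0`); if `d₀ = 0` they receive p = 0 for a nonzero effect and p = 1
  otherwise, with a logged warning.
* All-zero signed-rank differences are a degenerate input (error at the
  test level; the prioritizer maps "everyone identical" to p = 1, so a flat
  network prioritizes nothing).
* Constant features are dropped before clustering (warning); a sample with
  zero variance across candidates makes the correlation distance undefined
  and raises an error rather than guessing.
* AUC requires both classes; precision requires a nonempty predicted set.
* Edge lists are de-duplicated with a logged count; a line with other than
  two fields is a parse error naming the line number; an id appearing on
  both sides of the bipartition is an error, never silently fixed.

## Problem sizes used in the shipped checks

Unit and property tests run on hand fixtures and random networks up to
50 × 500 nodes; recovery and calibration checks use the default generator
conditions over 10–20 seeds (the full pipeline is ~0.1 s per seed at the
default scale).  The acceptance script recomputes the worked-example
regulator ratios and the precision index from their published inputs.

## Known limitations

* The signed-rank prioritization rate depends on network density: in very
  sparse networks most miRNAs have NSR/NTG ≈ 1 on one or two targets, the
  ratio feature saturates and loses discrimination (ties produce dropped
  zero differences and conservative tests).  The default synthetic scale
  avoids this regime; very small condition networks (< 10 miRNAs) are
  rejected outright.
* Only two-group contrasts are supported; no trend/robust variants of the
  variance moderation, no multi-factor designs.
* The reference interaction map is an input; the package neither builds one
  from target-prediction databases nor resolves miRNA identifier versions.
* No AUC confidence intervals and no biomarker-combination classifier.
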