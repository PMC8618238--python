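# Methods

## The analysis problem

Reduced insulin/IGF-1-like signaling (rIIS; a *daf-2* receptor mutant
background) extends *C. elegans* lifespan through the transcription factors
DAF-16/FOXO, SKN-1/Nrf and HSF-1. The experimental design knocks each factor
down by feeding RNAi in the rIIS background and sequences bulk mRNA from
seven conditions — Control (C), rIIS-Control, rIIS;*daf-16i*, rIIS;*skn-1i*,
and a heat-shock arm (C-HS, rIIS-C-HS, rIIS;*hsf-1i*-HS) used to engage
HSF-1 — with two biological replicates each. The analysis layer must answer:
which genes change under rIIS, which of those changes require each factor,
and, for genes targeted by several factors, whose direction wins.

## Differential expression

Comparisons are oriented, test group first; FC > 1 means higher in the test
group and such genes are "activated". Heat-shock and normal-temperature
groups are never mixed in one comparison (validation error).

**Fold change.** For gene *g*,

    FC(g) = (S_test / L_test) / (S_base / L_base)

where S is the group sum of counts and L the group sum of library sizes
(column totals of the count matrix). This is the maximum-likelihood mean
ratio of a two-group NB GLM with log link, library-size offsets and shared
dispersion. A pseudocount (default 0.5) is added to a group sum only when
that sum is zero: fold changes stay finite and positive without biasing
typical genes.

**Significance.** Per gene and group, replicate read proportions
p_i = y_i / n_i (n_i = library size) are combined by weighted least squares
with weights w_i = 1/(1/n_i + φ_g), weighted mean p̂ = Σw_i p_i / Σw_i and
variance V̂ = p̂(1−p̂)/Σw_i; the statistic is
z = (p̂_test − p̂_base) / √(V̂_test + V̂_base) with a two-sided normal tail.
The extra-binomial term is tied to a shared NB dispersion: under
Var(y) = μ + dμ², Var(p_i) ≈ p(1−p)(1/n_i + d·p), so φ_g = d̂·p̂_g with a
single d̂ per group estimated by the method of moments *pooled across
genes* (ratio of summed residual-variance excesses to summed p̂²(1−p̂)),
clamped at 0 and refined over two rounds (weighted means → pooled residual
variance → weights). Pooling is essential: a per-gene moment estimate from
two replicates has ~1 degree of freedom, making z effectively t₂-distributed
— measured type-I error 0.17 at α = 0.05 with a normal reference, while a t₂
reference restores calibration but halves sensitivity. With the pooled
estimator the measured null fraction at p ≤ 0.05 is 0.03–0.05 and power is
retained. When every gene's replicate proportions are equal within groups,
d̂ = 0 and the statistic reduces exactly to the classical pooled
two-proportion z-test. With a single replicate per group the test degrades
to that φ = 0 form with a warning. A t reference
(df = total replicates − 2) and Benjamini–Hochberg adjustment are available
behind flags; defaults are standard p-values, matching the calling rule
below.

**Calls.** Activated iff FC ≥ 1.5 and p ≤ 0.05; repressed iff FC ≤ 1/1.5
and p ≤ 0.05; boundaries included. Both thresholds are configurable.

## Overlap statistics

Detection defaults to "≥ 1 read in every replicate of the group"; an
RPKM-floor rule (mean RPKM ≥ 10) is available. Only genes detected in both
conditions of a comparison ("common genes") are carried into DE summaries;
exclusives are reported and discarded. Overlap significance is the
hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, m, n), evaluated in
log space: log-pmf terms from log-gamma, combined with log-sum-exp, reported
as log₁₀ p. This matters because published enrichment values reach
10⁻²⁷⁰⁰, far below double-precision underflow; the implementation agrees
with exact big-integer enumeration to < 10⁻⁹ in log₁₀ for all N ≤ 60 and to
~10⁻¹¹ at log₁₀ p ≈ −2721. The representation factor is RF = kN/(mn). The
background N defaults to the number of genes in the loaded matrix and is
configurable (published RF values back-solve to N ≈ 20,470). Percentages
are reported at one decimal, rounded half-up. The reported tail is the
over-representation direction; under-representation is behind a flag.

## Classification layer

* **Cross-tabulation**: rIIS-DE genes vs TF-regulated genes
  (rIIS-C vs rIIS;TFi), separately for activated and repressed, each overlap
  with RF and log₁₀ p; the combined dependence share is
  (k_act + k_rep)/(|rIIS_act| + |rIIS_rep|).
* **Reversal**: a rIIS-DE gene (restricted to mean RPKM ≥ 10 in control,
  rIIS and knockdown groups) counts as *reverted* when it is no longer DE
  between knockdown and control at the same thresholds. The alternative rule
  |log₂ FC(kd vs ctrl)| < log₂ 1.25 is provided; the default reuses the
  calibrated DE machinery rather than introducing a second threshold scale.
* **Quadrants**: common DE genes of two comparisons are assigned to the four
  sign pairs of their log₂ fold changes; exact zeros are excluded from
  percentages (measure-zero under the count model) and reported separately.
  Same-direction fraction = Q1 + Q3.
* **Dominance**: genes DE for ≥ 2 TFs and DE under rIIS contribute one sign
  pattern (call sign per TF plus rIIS direction); patterns are grouped and
  counted. A TF's concordance is the fraction of its own targets among these
  genes whose rIIS direction equals the TF's direction. The focus TF is
  flagged dominant when its concordance is maximal and ≥ 0.9 (margin
  configurable; an artifact parameter — the underlying biological claim is
  qualitative). All joins are by gene identifier, never row position.

## The synthetic regulome

Each gene carries: log₂ baseline expression at reference depth, signed log₂
effects for the three TFs (+ activator, − repressor, 0 non-target), an
optional TF-independent rIIS effect, an optional heat-shock effect (default
off), an NB dispersion and an exonic length. Per-sample activities a ∈ [0,1]
scale the effects:

    log₂ μ_gs = baseline_g + log₂(lib_s / ref) + r_s·riis_g + hs_s·hsdirect_g + Σ_TF a_TF,s·effect_TF,g

Counts are NB(μ, d) with Var = μ + dμ² (Poisson at d = 0), drawn in fixed
order from one seeded generator: identical (truth, design, rule, seed)
reproduce counts bit-identically.

Default design: DAF-16 and SKN-1 activity 1 under rIIS and 0 in controls;
HSF-1 basal 0.2 rising to 1.0 on heat shock; RNAi leaves residual activity
0.1; library scale 2×10⁷; 2 replicates/group. Default architecture: 16,000
genes; 15 % / 8 % / 4 % targeted by exactly one/two/three TFs; activator:
repressor 1:1 (deterministic alternation, exact to ±1); effect magnitudes
Uniform(log₂ 1.5, log₂ 8) so true targets straddle the call threshold;
baseline_log₂ ~ N(9, 2); dispersion 0.05; 5 % of unregulated genes receive a
TF-independent rIIS effect; lengths log-normal around 1.3 kb (lengths enter
RPKM only — the count model is per-gene, not per-kilobase).

**Mass conservation.** Balanced ± log₂ effects do *not* balance linear
expression: E[2^e + 2^−e]/2 > 1, so naive symmetric effects inflate rIIS
library totals ~1.4×, and under library-size-only normalization every null
gene then acquires a spurious fold change (measured null median log₂FC
−0.47, pushing the false-discovery proportion to ~0.5). Real analyses
assume total mRNA is roughly conserved; the generator builds that in.
Single-TF targets are mass-paired: each activated stress gene (baseline b,
effect +e) is matched by a repressed growth gene at baseline b + e with
effect −e, so induced mass exactly replaces switched-off mass at full
activity — biologically, rIIS induces lowly expressed stress genes while
shutting down highly expressed growth genes. Multi-TF genes are
mirror-paired (the partner negates the sign pattern at equal magnitudes,
baseline offset by the net effect) and sit 3 log₂ below the genome baseline,
a small lowly-expressed joint stress module. Residual composition drift is
~1–2 % of library mass.

**Dominance rule.** Under `daf16_dominant` (default), for DAF-16 targets the
summed SKN-1 + HSF-1 contribution is clipped to at most half the magnitude
of the DAF-16 contribution. Clipping at exactly the DAF-16 magnitude would
let equal-and-opposite input null the gene (and flip none), leaving the
intended invariant — every DAF-16 target's true rIIS direction equals
sign(effect_daf16) — unguaranteed; the factor-of-two cap (configurable)
makes it exact. `additive` disables the rule.

## What the simulation does and does not establish

Passing recovery tests shows the statistics are correct under their own
model: NB counts with shared dispersion, mass-conserving regulons,
independent genes, clean group labels. Real RNA-seq adds gene-specific
dispersion trends, GC/length biases, correlated modules, batch effects and
incomplete mRNA-mass conservation; none are modeled. Published
dataset-level counts (e.g. 14,933 common genes, the 78 %/50 % reversal
fractions) depend on the deposited experimental data and are not
reproduction targets of the simulation — the pipeline reproduces their
*arithmetic* from the published integer tables and their *qualitative
structure* (DAF-16 explains the largest share; DAF-16 dominates shared
targets) from the generative model.

## Numerical and reporting choices

* QC pipeline: log₂(CPM+1) → per-gene z-score (zero-variance genes dropped)
  → PCA over samples via SVD → complete-linkage clustering of Euclidean
  distances; explained-variance fractions sum to 1 within 10⁻⁹. Linkage and
  the pseudocount (1 for both log₂ CPM and log₁₀ RPKM displays) are
  configurable.
* ΔΔCt: 2^−[(Ct_target−Ct_ref)_test − (Ct_target−Ct_ref)_control].
* Seeds: one master seed per run; per-stage child seeds spawned via
  `numpy.random.SeedSequence` and logged in the run summary.
* Intermediates are persisted as TSV and the summary as sorted-key JSON, so
  re-running any stage from disk reproduces the end-to-end outputs and two
  runs of one config are byte-identical.
* Problem sizes used by the test-suite recovery checks: the study-scale
  16,000-gene matrix for calibration and recovery, 2,000–4,000 genes for
  structural checks — sizes at which every reported margin was stable
  across seeds.

## Known limitations

The weighted-proportions test shares one dispersion per group and
comparison; genes with genuinely atypical dispersion are mis-weighted.
Composition stability is a generator property, not an inference method —
the DE layer still normalizes by library size only (no TMM/median-ratio
step), faithful to the upstream workflow it mirrors. Reversal's default
rule inherits the DE thresholds, so its fractions move with fc/alpha. The
dominance margin (0.9) and the clipping cap (0.5) are artifact parameters;
conclusions drawn from them should be treated as orderings, not effect
sizes.
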