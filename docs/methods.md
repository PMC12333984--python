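# Methods

This note documents the statistical procedures implemented in `mirsig`, the
assumptions they make, every default that matters, and what the synthetic
validation does and does not establish.

## Data model

A cohort is a wide Ct table (samples × miRNA assays) with sample metadata
(cohort, timepoint, dose group) and a clinical table (CBC fields in 10⁹/L or
10¹²/L, CRP in ng/mL, TEWL difference in g/h/m², laser-Doppler perfusion
ratio IRR/NIR, ordinal injury score at D7/D14 only). Ct is the qPCR cycle
threshold: one cycle ≈ 2-fold abundance, lower = more. Missing cells,
`"Undetermined"` tokens, and Ct at or above the 40-cycle ceiling all parse to
missing — a 40-cycle run cannot produce an informative Ct at its ceiling.
Sample exclusion is always a metadata flag with a reason, never row deletion,
because per-figure n varies when animals are excluded for quality or
behavioral reasons.

## Quality control

* **Ct ceiling** — values strictly above 37 cycles are set missing
  (`ct_limit = 37`, the boundary value 37.0 is kept).
* **Hemolysis** — red blood cells are rich in miR-451a, so plasma
  contamination lowers its Ct relative to the universally expressed
  miR-23a-3p. The score is ΔCt = Ct(miR-23a-3p) − Ct(miR-451a); samples with
  ΔCt > 7 cycles are flagged (`hemolysis_threshold = 7`, the conventional
  cutoff for this two-assay method; config-surfaced because published
  variants use 5–8).
* **Spike-in** — cel-miR-39 is added before extraction; a sample whose
  spike-in Ct sits more than 2 cycles from the cohort median indicates an
  extraction-efficiency outlier. Median-relative by design, so global shifts
  never flag.
* **Detection filter** — assays detected in fewer than 75% of retained
  samples are removed (`min_detection_rate = 0.75`; this reproduces the
  typical ~750 → ~300 panel reduction and is reported because the signature
  content depends on it). Control assays are retained for QC but never enter
  the feature set.
* Flags do not auto-exclude; `run_sample_qc` excludes on (hemolysis OR
  spike-in) as an explicit, logged decision. The chain is idempotent.

## Adaptive normalization

ΔCt needs a reference. Fixed housekeeping genes are unreliable in plasma, so
the normalizer set is learned: assays with a complete Ct profile across
retained samples (a normalizer must exist in every sample) are clustered —
rows = assays, coordinates = per-sample Ct, Euclidean distance, Ward's
classical variance-minimizing linkage on squared distances. Walking merges
bottom-up, a candidate is recorded each time a cluster's size first reaches
k (= 3); such a candidate has at most 2(k−1) members, so the best size-k
subset (minimal sum of member-to-centroid distances, the centroid being the
subset's own) is found exhaustively. The global minimizer wins; dispersion
ties break lexicographically on assay names for determinism. The full
candidate list with dispersions is kept as an audit trail, making the
trimming rule inspectable. Normalization is per cohort/timepoint; no
cross-cohort pooling.

(−)ΔCt = −(Ct − mean normalizer Ct) increases with abundance and is exactly
invariant to any per-sample additive offset — the extraction-efficiency
artifact the spike-in monitors.

## Multiblock sparse PLS-DA

Blocks: `miR` ((−)ΔCt matrix) and `clinical` (numeric fields; the dose group
is the outcome, never a feature). Preprocessing centers and scales every
column to unit variance (zero-variance columns dropped with a log entry) and
expands the outcome to a centered one-column-per-group indicator matrix Y.
Missing values are imputed *before* preprocessing: missing (−)ΔCt at the
assay's observed minimum — truncation at the detection limit means the
target was below detection, i.e. at its lowest expression, so a minimum
carry-down distorts less than a central value — and missing clinical fields
at the within-cohort median.

The design matrix couples blocks weakly to each other (0.1 between miR and
clinical) and fully to the outcome (weight 1): components should first
discriminate dose, secondarily correlate across blocks. Both weights are
config-surfaced. Per component: block loadings initialize at the dominant
left singular vector of X_bᵀY (sign-fixed for determinism) and cycle through

    a_b ← normalize( soft_select( X_bᵀ(Σ_{k≠b} D_bk t_k + t_Y), keepX_b ) ),
    t_b = X_b a_b,

with the outcome block updated symmetrically (full connectivity, no
sparsity), until the largest loading change drops below 1e-6 or 100
iterations (non-convergence returns with a warning flag). `soft_select`
keeps the keepX largest-magnitude entries and shrinks them by the
(keepX+1)-th largest magnitude, preserving signs — the rank-constrained
equivalent of a Lasso penalty, matching "number of features per component"
tuning without housing an explicit λ. Blocks are deflated on their own
scores; the outcome block is deflated too by default (`deflate_outcome`,
both modes implemented). Successive scores within a block are orthogonal by
construction; the whole fit is deterministic given data and config.

**Prediction** projects a new sample through the training deflation,
averages the block score vectors with equal weights, and assigns the group
with the nearest training-centroid (Euclidean). Exact ties go to the
lexicographically first group and are flagged. Continuous per-group scores
(negative distances) feed the ROC.

**Tuning** is leave-one-out: for every (ncomp, keepX) grid point — defaults
ncomp ∈ {1,2,3}, keepX ∈ {3,5,7,10,15,20,30} applied to the miR block, the
clinical block unpenalized — refit on n−1, predict the held-out sample, and
score the balanced error rate (mean per-class error; chance = 0.75 for four
balanced groups). Ties prefer fewer components, then smaller total keepX,
then grid order. A held-out sample whose class has no other member makes its
fold's per-class error undefined; the fold is skipped with a warning.

**Stability** refits within each LOO fold at the chosen parameters;
stability(f, h) is the fraction of folds selecting feature f in component h.
The reported signature is the full-data support annotated with stability;
≥ 0.5 is deemed stably selected. `max_median_group` annotates each selected
miRNA with the dose group of maximal median expression (ties to the higher
dose, flagged). Cross-block similarity uses the standard correlation-circle
construction, s(x, y) = Σ_h corr(x, t_a,h)·corr(y, t_b,h), reported above a
0.5 cutoff plus as a full matrix.

## Evaluation

One-vs-rest ROC per dose group on the per-group continuous scores; AUC is the
tie-corrected Mann–Whitney U over n₁n₀, its p-value the two-sided
normal-approximated U test (the exact test choice behind published AUC
p-values is rarely stated; Mann–Whitney is the assumption-light default).
AUC is computed on LOO held-out scores by default — resubstitution AUCs are
optimistic — with a `--resubstitution` flag for comparison. AUC below 0.5 is
reported as-is, not flipped. The Kruskal–Wallis utility delegates to SciPy's
tie-corrected H with a chi-square reference; all-tied input returns H = 0,
p = 1.

## Bayesian cross-cohort bridge

Signature coordinates exist for cohort A animals, day-14 outcomes for cohort
B animals; no animal has both, defeating ordinary correlation. The bridge
uses the shared dose design: cohort A supplies group-wise mean μ_g and SD s_g
of a component's scores (plug-in constants by default; an optional
hyperprior mode draws μ_g ~ N(μ̂_g, ŝ_g/√n_g)). For B animal j in group
g(j):

    x_j ~ Normal(μ_g(j), s_g(j))        latent coordinate
    y_j ~ Normal(α + β x_j, σ_y)        outcome, standardized internally
    α, β ~ Normal(0, 10²),  σ_y ~ Half-Normal(5)

Each draw implies r = β·sd(x) / √(β²·var(x) + σ_y²), with var(x) the prior
mixture's variance under cohort B's dose composition — bounded in (−1, 1)
draw by draw and invariant to affine changes of y. Ordinal injury scores are
treated as continuous after standardization (an ordered-probit variant is out
of scope). The sampler is Metropolis-within-Gibbs: conjugate normal updates
for the x_j and (α, β), a random walk on log σ_y (scale 0.3) against the
Half-Normal prior. Defaults: 2 chains, 2,000 burn-in, 5,000 kept draws total;
split-R̂ and effective sample size (ArviZ) on every parameter, with R̂ > 1.05
flagging non-convergence. The two-sided tail probability is
2·min(P(r>0), P(r<0)); one bridge run per (component, outcome) pair.

## Synthetic cohorts

`simulate_cohort` draws Ct(s, i) = baseline_i + offset_s + effect_i(dose_s)
+ biological + technical noise, truncated to missing above the detection
limit. Defaults are the study conditions: 4 × 15 samples, 300 assays,
15 planted dose-responsive assays with |ΔCt| at 80 Gy between 0.75 and 1.5
cycles, linear in log2(dose+1) with random sign (dose effects of both signs
occur in real panels); a housekeeping cluster of 3 assays with near-identical
baselines and ≤ 0.05-cycle biological SD; technical SD 0.25, biological SD
0.5, sample-offset SD 0.3 cycles; 5% hemolysis events lowering miR-451a by
4–8 cycles; detection limit 37; baselines uniform on 22–36 so high-baseline
assays lose values to truncation. The clinical block plants a lymphocyte
decrease that is dominated by the 80 Gy arm (−1.5 × (dose/80)^1.5 × 10⁹/L)
and, at D7, a +0.4 perfusion-ratio elevation at 80 Gy; other fields carry no
dose effect. Day-14 outcomes derive from a latent severity that tracks dose
noisily (slope 2.4 at 80 Gy, SD 0.5) — dose and severity correlate without
strictly overlapping — discretized to a 0–5 injury score and an exponential
perfusion link. No published per-miRNA effect sizes exist for this setting;
these magnitudes were chosen once to be realistic for plasma qPCR panels and
to make recovery tests meaningful, and are not adjusted thereafter.

What the generator does **not** emulate: plate/batch structure, melting-curve
failures, assay cross-hybridization, non-monotone dose responses, or
correlated miRNA co-regulation modules. Passing recovery tests therefore
shows the pipeline finds additive, monotone dose effects of the planted size
under realistic noise — not that it is robust to batch confounding or
correlated feature sets.

## Validation design and expected values

* Normalizer selection is checked for exact agreement with exhaustive
  enumeration on ≥ 100 random small instances (≤ 10 assays).
* The dense single-block fit is checked against an independent classical
  NIPALS implementation (component-1 cosine ≥ 0.999) and cross-checked once
  against the reference R implementation (mixOmics::plsda).
* Full-pipeline recovery: median over 10 seeds of the fraction of planted
  assays at stability ≥ 0.5 must be ≥ 80%; measured ≈ 93%.
* Null calibration: on zero-effect cohorts the tuned model's
  **selection-free** LOO balanced error rate — chosen parameters evaluated by
  LOO on an independent null cohort — is compared to chance (0.75) within
  two single-run binomial Monte-Carlo SDs (≈ ±0.11 at 15 folds per class);
  measured median ≈ 0.68–0.76. The raw grid minimum is reported alongside
  but sits at ≈ 0.59–0.71 on pure noise: taking the minimum over a 21-point
  grid of noisy BER estimates is optimistically biased by construction, so
  that number is a property of min-over-grid tuning, not evidence of signal.
  Null bridge runs must cover 0 with their 95% credible interval in ≥ 90% of
  50 runs.
* Strong-signal limit: an outcome equal to the group coordinate means with
  tiny noise and tight priors must give posterior mean r > 0.95.

Problem sizes in the acceptance script (10 recovery seeds, 5 null seeds,
50 bridge runs at 2,000 kept draws) keep a full run around ten minutes on a
single CPU while leaving each check's Monte-Carlo error well below its
decision margin.

## Known limitations

* LOO tuning on 60 samples has high variance; the grid minimum is an
  optimistic estimate of generalization error (see above). Nested
  cross-validation would cost ~60× and is not implemented.
* The bridge treats cohort-A group summaries as known constants by default,
  understating uncertainty when group n is small; the hyperprior mode
  loosens this but still assumes normal within-group score distributions.
* The ΔCt minimum-imputation couples missingness to the detection limit; if
  values are missing for other reasons (failed wells), median imputation of
  the clinical block is the better model of the two.
* Signature content depends visibly on the detection-rate threshold and the
  hemolysis cutoff; both are config-surfaced and recorded in the run
  manifest rather than fixed silently.
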