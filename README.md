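# mirsig

Prognostic circulating-miRNA signature discovery from RT-qPCR Ct panels.

Localized radiation injuries (radiological burns) pass through a latency
phase with no clinical signs before symptoms erupt; triage after a
radiological event needs biomarkers that work *during* that silent window.
`mirsig` implements the full statistical pipeline for finding such biomarkers
in plasma miRNA qPCR panels from dose-stratified cohorts (0/20/40/80 Gy
hindlimb irradiation, ~15 animals per arm), and for asking whether the
discovered signature predicts clinical severity measured days later — on
*different* animals.

The pipeline, module by module:

1. **Quality control** (`mirsig.qc`) — discard Ct > 37 (late amplification is
   noise), score hemolysis as ΔCt = Ct(miR-23a-3p) − Ct(miR-451a) with a
   7-cycle flag, check the cel-miR-39 spike-in against the cohort median
   (±2 cycles), and drop assays detected in < 75% of samples. Flags never
   silently delete rows; exclusion is an explicit, logged decision.
2. **Adaptive normalization** (`mirsig.normalize`) — Ward-cluster assays on
   their raw Ct profiles (Euclidean distance), walk the merges bottom-up, and
   take as normalizers the k = 3 assays of the first-formed cluster with the
   smallest sum of distances to its centroid. Expression is then
   (−)ΔCt = −(Ct − mean normalizer Ct): a log2-scale abundance proxy,
   invariant to per-sample extraction-efficiency offsets.
3. **Multiblock sparse PLS-DA** (`mirsig.splsda`) — DIABLO-style supervised
   components coupling a miRNA block and a clinical block (CBC, CRP, TEWL,
   perfusion) against the dose groups. Per component h and block b the
   loading solves a rank-constrained Lasso update,

       a_b ← normalize( soft_select( X_bᵀ(Σ_{k≠b} D_{bk} t_k + t_Y), keepX ) ),

   keeping the `keepX` largest-magnitude entries shrunk by the next-largest
   magnitude. Components and `keepX` are tuned by leave-one-out
   cross-validated balanced error rate; **stability** of a miRNA is the
   fraction of LOO folds selecting it (≥ 0.5 = stably selected).
4. **Evaluation** (`mirsig.evaluate`) — one-vs-rest ROC per dose group with
   AUC = U/(n₁n₀) from the Mann–Whitney statistic (held-out LOO scores by
   default), plus a Kruskal–Wallis utility.
5. **Bayesian bridge** (`mirsig.bridge`) — signature scores live in cohort A,
   day-14 outcomes in cohort B, with only the dose label shared. Each B
   animal gets a latent coordinate x_j ~ N(μ_g, s_g) from cohort A's
   group-wise score distributions; the outcome regresses on x_j, and each
   posterior draw implies a correlation r = βσ_x/√(β²σ_x² + σ_y²) ∈ (−1, 1).
   Metropolis-within-Gibbs sampling, split-R̂/ESS diagnostics via ArviZ.
6. **Synthetic cohorts** (`mirsig.simulate`) — seeded generator planting
   dose-responsive assays, a housekeeping cluster, extraction offsets,
   hemolysis events, detection-limit truncation, and severity-driven day-14
   outcomes, with exported ground truth for recovery testing.

## Worked example

`examples/` holds one short script per capability. Discovery + bridging in a
few lines:

```python
from mirsig import (SimulationParams, simulate_cohort, simulate_d14_cohort,
                    run_sample_qc, normalize, build_block_dataset, fit_tuned,
                    attach_labels, summarize_coordinates, fit_bridge)

params = SimulationParams(seed=4)
ct, clinical, truth = simulate_cohort(params)      # 60 samples x ~300 assays
clean, report = run_sample_qc(ct)                  # hemolysis / spike-in / detection
expr = normalize(clean)                            # adaptive (−)ΔCt
dataset = build_block_dataset(expr, clinical)
model = fit_tuned(dataset, ncomp_grid=(1, 2), keepx_grid=(5, 10, 15))
print(model.signature)                             # component, miRNA, stability, loading
```

Running `python examples/04_signature_discovery.py` prints (seed 4):

```
tuned model: ncomp=2, keepX=[15, 15]
LOO balanced error rate at optimum: 0.299
planted assays recovered at stability >= 0.5: 14/15
one-vs-rest ROC on LOO held-out scores:
 group   auc  p_value
   0.0 0.980    0.000
  20.0 0.885    0.000
  40.0 0.744    0.007
  80.0 0.825    0.000
```

i.e. the tuned two-component signature recovers 14 of the 15 planted
dose-responsive miRNAs and separates every dose arm from the rest on
held-out scores. `examples/05_bridge_correlation.py` then links that
signature to day-14 injury scores from an independent cohort
(`mean r = +0.84, 95% CrI [+0.72, +0.91]`, R̂ ≤ 1.01).

The same flow is available from a shell:

```bash
mirsig --run-dir run1 --seed 4 simulate
mirsig --run-dir run1 qc
mirsig --run-dir run1 normalize
mirsig --run-dir run1 fit
mirsig --run-dir run1 evaluate
mirsig --run-dir run1 bridge --component 1 --outcome injury_score
```

Every run directory carries a `manifest.json` with the config snapshot, seed,
timings and SHA-256 digests of all artifacts; identical config + seed
reproduce identical digests for the deterministic stages.

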