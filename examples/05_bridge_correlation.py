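"""Cross-cohort Bayesian bridge: correlating a signature with D14 outcomes.

The signature scores come from one cohort (D1 animals) and the injury scores
from another (D14 animals); only the dose-group label is shared.  The bridge
treats each D14 animal's signature coordinate as a latent variable with a
group-specific prior estimated from the D1 fit, regresses the outcome on it,
and reports the implied correlation r with credible intervals.
"""

import warnings

from mirsig import (
    SimulationParams,
    attach_labels,
    build_block_dataset,
    fit_block_splsda,
    fit_bridge,
    normalize,
    run_sample_qc,
    simulate_cohort,
    simulate_d14_cohort,
    summarize_coordinates,
)

warnings.simplefilter("ignore")

params = SimulationParams(seed=6)
ct, clinical, _ = simulate_cohort(params)
clean, _ = run_sample_qc(ct)
dataset = build_block_dataset(normalize(clean), clinical)
model = fit_block_splsda(dataset, ncomp=2, keepX={"miR": 15})
attach_labels(model, dataset.outcome)

prior = summarize_coordinates(model, component=1)
print("component-1 score distribution by dose group (mean ± SD):")
for g in sorted(prior.mu):
    print(f"  {g:5.0f} Gy: {prior.mu[g]:+.2f} ± {prior.sd[g]:.2f}  (n={prior.n[g]})")

d14, _ = simulate_d14_cohort(params)   # independent animals, same dose design
result = fit_bridge(prior, d14, outcome="injury_score", seed=params.seed)

s = result.summaries["r"]
print(f"\nposterior correlation with D14 injury score:")
print(f"  mean r = {s['mean']:+.2f}, 95% CrI [{s['ci95'][0]:+.2f}, {s['ci95'][1]:+.2f}]")
print(f"  two-sided tail probability = {result.tail_probability:.3g}")
print(f"  convergence: R-hat max = {max(result.rhat.values()):.3f}, "
      f"min ESS = {min(result.ess.values()):.0f}")
print("-> |r| well away from 0 with a tiny tail probability says the latent"
      " signature coordinate tracks later injury severity; the sign follows"
      " the component's orientation.")
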