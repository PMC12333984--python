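"""Multiblock sPLS-DA signature discovery with LOO tuning and stability.

Couples the miRNA block with the clinical block against the dose groups,
tunes model size by leave-one-out balanced error rate, refits per fold for
stability scores, and evaluates the signature with one-vs-rest ROC on the
held-out LOO scores.  A reduced tuning grid keeps this demo under a minute.
"""

import warnings

from mirsig import (
    SimulationParams,
    build_block_dataset,
    fit_tuned,
    normalize,
    one_vs_rest_roc,
    roc_table,
    run_sample_qc,
    simulate_cohort,
)
from mirsig.splsda import loo_predictions

warnings.simplefilter("ignore")

ct, clinical, truth = simulate_cohort(SimulationParams(seed=4))
clean, _ = run_sample_qc(ct)
expr = normalize(clean)
dataset = build_block_dataset(expr, clinical)

model = fit_tuned(dataset, ncomp_grid=(1, 2), keepx_grid=(5, 10, 15))
print(f"tuned model: ncomp={model.ncomp}, keepX={model.keepX['miR']}")
print(f"LOO balanced error rate at optimum: {model.tuning_trace['ber'].min():.3f}")

sig = model.signature.sort_values(["component", "stability"], ascending=[True, False])
print("\nselected signature (component, miRNA, stability, loading):")
print(sig.head(12).to_string(index=False))
planted = set(truth.signature_assays)
stable = set(sig.loc[sig["stability"] >= 0.5, "miRNA"])
print(f"\nplanted assays recovered at stability >= 0.5: "
      f"{len(stable & planted)}/{len(planted)}")

preds, _ = loo_predictions(dataset, model.ncomp, model.keepX)
preds = preds.set_index("sample_id")
scores = preds[[f"score_{g}" for g in model.groups]]
scores.columns = model.groups
print("\none-vs-rest ROC on LOO held-out scores:")
print(roc_table(one_vs_rest_roc(scores, dataset.outcome)).round(3).to_string(index=False))
print("-> stability is the fraction of LOO folds selecting each miRNA;"
      " AUCs near 1 mean the signature separates that dose arm from the rest.")
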