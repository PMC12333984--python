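"""Generate a synthetic irradiated-mouse cohort and inspect its structure.

Simulates the default study design — four dose arms (0/20/40/80 Gy) of 15
animals profiled on a ~300-assay plasma miRNA RT-qPCR panel plus a clinical
block — and shows the dose-dependent lymphocyte drop the clinical block plants.
"""

from mirsig import SimulationParams, kruskal_wallis, simulate_cohort

params = SimulationParams(seed=1)
ct, clinical, truth = simulate_cohort(params, timepoint="D1")

print(f"Ct matrix: {ct.values.shape[0]} samples x {ct.values.shape[1]} assays")
print(f"missing (above the {params.detection_limit}-cycle detection limit): "
      f"{int(ct.values.isna().sum().sum())} values")
print(f"planted signature assays: {len(truth.signature_assays)}  "
      f"(e.g. {truth.signature_assays[:3]})")
print(f"housekeeping cluster: {truth.housekeeping_assays}")
print(f"hemolysed samples: {truth.hemolysed_samples or 'none'}")

tab = clinical.dropna(subset=["lymphocytes"])
h, p = kruskal_wallis(tab["lymphocytes"], tab["dose_gy"])
print("\nlymphocytes (10^9/L) by dose group:")
print(tab.groupby("dose_gy")["lymphocytes"].mean().round(2).to_string())
print(f"Kruskal-Wallis H = {h:.2f}, p = {p:.2g}")
print("-> the drop concentrates in the 80 Gy arm, as in the modelled design;"
      " a small p confirms the planted dose effect on lymphocytes.")
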