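"""Generate a synthetic spontaneous-report database and inspect its truth.

Builds the default JADER-style scenario at a small size, writes the three
linked tables (DEMO/DRUG/REAC) plus the ground-truth sidecar, and prints the
bookkeeping counts.  The printed exposure check shows that empirical drug
frequencies track the configured marginal probabilities.
"""

import pvsignal as pv

config = pv.default_scenario(n_cases=10_000, seed=1)
demo, drug, reac, truth = pv.generate_cohort(config)
paths = pv.write_fixture((demo, drug, reac), "example-output/tables", truth)

print(f"cases (DEMO rows):        {len(demo):>7}")
print(f"DRUG rows (with dups):    {len(drug):>7}  ({truth.n_dup_drug_rows} duplicates)")
print(f"REAC rows (with dups):    {len(reac):>7}  ({truth.n_dup_reac_rows} duplicates)")
print(f"fracture cases (truth):   {truth.n_target_cases:>7}")
print(f"planted BMI outliers:     {len(truth.outlier_case_ids):>7}")
print()
print("drug             configured p   empirical p")
for spec in config.drugs[:6]:
    emp = truth.exposure_counts[spec.name] / config.n_cases
    print(f"{spec.name:<22} {spec.p_exposure:.3f}        {emp:.3f}")
print()
print("files:", ", ".join(str(p) for p in paths.values()))
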