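"""Map drugs and fracture sites onto shared mechanism axes with lnROR PCA.

The block scenario plants two mechanisms: bone-resorption inhibitors elevate
an osteoclast-type event block (atypical femur, jaw, ulna, atypical
fractures) while sedatives and dopaminergics elevate a fall-type block
(femoral neck, upper limb, cervical vertebral, rib).  The drug x event
ln(ROR) matrix is decomposed by correlation-matrix PCA; events sharing a
mechanism load together, and drug scores cluster by block.
"""

import pvsignal as pv
from pvsignal.pca import biplot

demo, drug, reac, _ = pv.generate_cohort(pv.pca_block_scenario(n_cases=60_000, seed=5))
rows, _ = pv.build_analysis_table(demo, drug, reac)

signal_drugs = [r.drug_name for r in pv.screen_drugs(rows) if r.is_signal]
drugs, events = pv.select_entities(rows, signal_drugs,
                                   drug_min_reports=15, event_min_reports=20)
matrix = pv.build_ror_matrix(rows, drugs, events)
pca_map = pv.pca_correlation(matrix)

evr = pca_map.explained_variance_ratio
print(f"matrix: {len(drugs)} drugs x {len(events)} events")
print(f"PC1 explains {100 * evr[0]:.1f}% of variance, PC2 {100 * evr[1]:.1f}%")
print()
print("event loadings (correlation with PC1/PC2):")
print(pca_map.loadings_frame().iloc[:, :2].round(2).to_string())
print()
print("drug scores (PC1/PC2):")
print(pca_map.scores_frame().iloc[:, :2].round(2).to_string())

paths = biplot(pca_map, "example-output/pca_loadings.png",
               "example-output/pca_scores.png")
print()
print("figures:", ", ".join(str(p) for p in paths))
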