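"""Compare demographics between fracture and non-fracture rows.

The default scenario plants demographic confounding: older, female and
higher-BMI cases are more likely to report fracture events.  The univariate
comparison (Wilcoxon rank-sum for continuous variables, Fisher exact for
sex) should therefore show the fracture group as older, more female and
slightly heavier-set, each with its complete-case n in parentheses.
"""

import pvsignal as pv

demo, drug, reac, _ = pv.generate_cohort(pv.default_scenario(n_cases=40_000, seed=3))
rows, _ = pv.build_analysis_table(demo, drug, reac)

table = pv.characteristics_table(rows)
print("characteristic            fracture group        other rows            p")
for _, r in table.iterrows():
    print(f"{r['variable']:<25} {r['target']:<21} {r['other']:<21} "
          f"{r['p_value']:.3g} ({r['test']})")

sex = pv.compare_sex(rows)
print()
print(f"female share: {100 * sex.group_means[0]:.1f}% (fracture) vs "
      f"{100 * sex.group_means[1]:.1f}% (other); Fisher p = {sex.p_value:.3g}")
age = pv.compare_continuous(rows, "age")
print(f"mean age:     {age.group_means[0]:.1f} y (fracture) vs "
      f"{age.group_means[1]:.1f} y (other); rank-sum p = {age.p_value:.3g}")
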