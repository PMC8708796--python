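# Methods

`pvsignal` analyses spontaneous adverse-event report databases of the JADER
family, in which one report (a *case*) links demographic fields (DEMO), the
drugs the reporter recorded with an involvement judgement (DRUG), and the
adverse reactions coded as MedDRA-style preferred terms (REAC).  The package
implements the full path from raw tables to three complementary readouts of a
drug-event association — a disproportionality screen, a covariate-adjusted
logistic confirmation, and a drug x event ln(ROR) principal-component map —
together with a synthetic-report generator that plants known effects so every
stage has a parameter-recovery test.

## Unit of analysis

The analysis row is the (case, suspected drug, adverse event) triple.
Spontaneous-report "records" outnumber cases because a report can name
several suspected drugs and several reactions; the triple is the finest unit
consistent with both per-drug and per-event tabulations, and all 2x2 counts,
group comparisons and regressions operate on these rows.  Rows of one case
are treated as independent in the logistic stage; this is a recognised
limitation of report-level modelling (see *Limitations*).

## Cohort construction

Stages run in a fixed order:

1. keep DRUG rows with involvement `suspected` (concomitant/interaction
   rows are discarded);
2. drop exact duplicate rows within DRUG (key: case, drug, involvement) and
   within REAC (key: case, term), first occurrence kept — duplicate handling
   is deliberately minimal and pluggable, with no cross-report fuzzy linkage;
3. inner-join DRUG x REAC x DEMO on the case id (rows whose case is absent
   from DEMO are dropped and logged);
4. convert banded demographics: decade age bands to midpoints ("60s" → 65,
   "under 10" → 5) and banded weights ("60 kg range" → 65); numeric values
   pass through;
5. compute BMI = weight / (height/100)² where both fields are present;
6. exclude rows with BMI < 10 or > 100 (strict inequalities; rows with
   missing BMI are *retained* — only a computable BMI can be implausible —
   and drop out only of analyses that need BMI);
7. flag the target event class: by default any preferred term containing
   "fracture" case-insensitively; an explicit allow-list (the bundled
   58-term tabulation) is available for exact replication.

Every stage's count is recorded in a `CohortReport` so the flow is auditable
(`n_final = n_joined − n_bmi_low − n_bmi_high`, etc.).

## Disproportionality screen

For drug *i*, the 2x2 table splits rows by {names drug *i*} x {target
event}.  With cells (a, b, c, d):

* **ROR** = (a′d′)/(b′c′) on Haldane–Anscombe-corrected cells
  (x′ = x + 0.5, applied unconditionally to every table, so the ROR and its
  log are always finite);
* **95% CI** = exp(ln ROR ± 1.96·√(1/a′ + 1/b′ + 1/c′ + 1/d′)) (Woolf on
  corrected cells — the CI method is a package choice, stated here because
  disproportionality software varies);
* **p** = two-sided Fisher exact on the *raw* integer counts
  (sum-of-smaller-probabilities definition; correcting an exact test would
  be incoherent, so the ½-correction applies only to the ROR/CI);
* **signal rule**: ROR ≥ 1 and p ≤ 0.05 (boundary inclusive).  No
  multiple-testing adjustment is part of the rule; a Benjamini–Hochberg
  column is emitted as clearly-supplementary output.

All drugs appearing in the analysis rows are screened by default, including
drugs with zero target reports (their corrected ROR is small but defined);
`min_reports` can restrict the output.  The volcano plot shows ln(ROR)
against −log10(p) with a dotted reference at p = 0.05 and point colour
encoding log10 of the drug's report count.

## Univariate comparison

Continuous variables (age, height, weight, BMI) are compared between target
and non-target rows with the two-sided Wilcoxon rank-sum test; sex with a
two-sided Fisher exact test.  Each variable is complete-case: rows missing
that variable leave that comparison only, and the per-group n used is
reported.  Exact rank-sum enumeration is used when both groups have ≤ 25
observations and the pooled sample is untied; otherwise the normal
approximation with tie and continuity correction (scipy's implementation).

## Multivariable logistic confirmation

The fracture indicator is regressed on female sex (male reference), age,
BMI and one 0/1 indicator per drug passing the screen, on complete-case
rows, by plain maximum likelihood (Newton–Raphson, BFGS fallback; Wald CIs
and p-values; no interactions or regularisation).  Because one report
contributes several analysis rows (one per suspected drug and event) and
those rows duplicate the case's outcome and covariates, the pipeline's
standard inference uses the case-level cluster-robust sandwich covariance;
model-based (independence) covariance is available but understates the
standard errors of report-level data (verified against a case-resampling
bootstrap in development).  Point estimates are identical either way.  For continuous
covariates two summaries are reported: the unit OR exp(β) and the range OR
exp(β·(max − min)) over the observed range of the analysed rows — the range
convention is stated here because reporting software differs.  All-zero
drug indicators are dropped with a warning; a non-converged fit is flagged
and its inference withheld.

## Mechanism map (lnROR PCA)

Rows: screened drugs with strictly more than `drug_min_reports` (default
50) target-class reports.  Columns: target-class terms with strictly more
than `event_min_reports` (default 70) occurrences.  Entry (i, j) is the
ln(ROR) of drug i for the *single* term j, with b/c/d taken against the full
cohort (not only the fracture subset) — a stated convention.  Columns are
standardised with the sample SD (n−1) and the correlation matrix
eigendecomposed.  Scores are the standardised data projected on the
eigenvectors; loadings are reported as variable–component correlations
(eigenvector × √eigenvalue).  Each component is oriented so its
largest-magnitude loading is positive, making outputs deterministic; signs
may be flipped relative to other software.  Eigen identities (trace = number
of events, orthonormal eigenvectors, exact reconstruction of the
standardised matrix) are enforced in tests at 1e-8.

## Synthetic-report generator

The generator emulates the structure of a JADER-like extract:

* **Demographics**: sex (default 55% female), decade age bands skewed to
  older ages (the latent age is the band midpoint), and sex-specific normal
  height/weight (female 152 ± 7 cm, 51 ± 10 kg; male 165 ± 7 cm,
  63 ± 11 kg), clamped to a plausible BMI band of 12.5–60 so the only
  implausible anthropometrics are the deliberately injected outliers
  (BMI forced < 10 or > 100 at rate `outlier_rate`).
* **Exposure**: independent Bernoulli per catalog drug with the configured
  marginal probability (a case with no drugs simply emits no DRUG rows);
  each DRUG row receives an involvement category from `involvement_mix`.
* **Events**: each target term fires per case from a logistic model whose
  linear predictor is the term's baseline log-odds, plus the planted
  log-odds ratios of the case's drugs for that term, plus confounding
  contributions (per year of age from 60, female indicator, per BMI unit
  from 22).  A case with a fired target term reports its fracture term(s)
  only; other cases report background terms drawn per-term from baselines
  (at least one).  This *exclusive event profile* makes the row-level
  reporting odds ratio equal the planted case-level odds ratio exactly;
  real reports can mix fracture and non-fracture terms, which would shift
  the row-level estimand toward a risk ratio.
* **Nuisances**: exact duplicate DRUG/REAC rows at `duplicate_rate`;
  per-field missing demographics (height and weight share one latent
  uniform so anthropometric fields go missing together, keeping both
  marginal rates exact and the joint BMI-missingness realistic); optional
  banded weight emission ("60 kg range") to exercise the conversion rules.

The default scenario's parameter values are chosen to match the published
study conditions where those are stated (fracture rows ≈ 0.6% of the
cohort; missingness giving ≈ 97% observed sex, ≈ 93% age, ≈ 42% height,
≈ 49% weight; confounding of roughly OR 2 for female and OR 1.02 per year
of age; duplicate/outlier rates of a few per mille; planted drug effects of
the order seen for resorption inhibitors, corticosteroids, sedatives,
dopaminergics, antivirals and aromatase inhibitors) and to field-typical
conventions elsewhere (per-case drug and event multiplicities, involvement
mix 55/40/5, the drug catalog itself), since the source database does not
publish those distributions.

What the generator does **not** emulate: real MedDRA hierarchies and term
granularity, temporal reporting dynamics, dose, correlated exposure
(channelling), non-random missingness, and near-duplicate reports that
differ in a field.  Passing recovery tests therefore demonstrate that the
pipeline's estimators are correct under the stated generative model, not
that real-database biases (under-reporting, masking, confounding by
indication) are overcome.

## Recovery-scenario sizing

The recovery presets were sized a priori from two closed forms: the
delta-method SE of lnROR (√Σ 1/cell) and the co-exposure attenuation
−ln(1 + (OR−1)·p_x) that row-level analysis suffers because rows of an
exposed case naming a co-prescribed drug carry the elevated outcome with
indicator 0 (the spontaneous-report "masking" phenomenon).  The ROR
scenario (n = 50,000; planted drug exposure 0.02; single target term at
baseline 0.17) gives SE ≈ 0.05 and bias ≈ −0.04 against a ±0.15 recovery
band; the logistic scenario (n = 100,000; exposure 0.004; baseline 0.13;
confounding on age/sex/BMI; 5% missingness per field) gives a
cluster-robust SE(β) near 0.12 against an attenuation bias of a few
hundredths, so the planted odds ratio is recovered to within roughly 15%
per replicate.  The common
(non-rare) outcome in these presets is a deliberate statistical design to
concentrate information at desk scale; the *default* scenario keeps the
realistic 0.6% rate.

## Numerical choices and degenerate inputs

Fisher p-values are clipped into (0, 1]; enumeration-vs-implementation
agreement is enforced exhaustively for all 2x2 tables with total ≤ 60.
A PCA column whose SD is ≤ 1e-12 of its scale is treated as constant and
rejected with the offending term named.  Band parsing is lenient:
unparseable age/weight strings become missing with a logged warning, never
an error.  Ties in screen ordering break by descending ROR.  The pipeline
writes a manifest of SHA-256 digests, and identical configurations
(including seeds) reproduce identical artifacts byte for byte.

Problem sizes used by the shipped acceptance script — 50,000 cases for the
screen recovery, 10 × 100,000 for the logistic replicates, 20 × 200 drugs
for the null calibration, 80,000 cases for the end-to-end default run — are
the package's chosen desk-scale study conditions; they keep every quantity's
sampling error small relative to the bands being checked.

## Limitations

* Rows within a case are modelled as independent in the likelihood; the
  cluster-robust covariance repairs the standard errors but the row-level
  coefficient for a drug remains mildly attenuated (a few percent at the
  exposure levels simulated) by co-exposure masking, and the attenuation
  fluctuates with the realised co-prescription pattern, so coverage of the
  planted case-level odds ratio runs a few points below nominal.
* The screen's crude ROR is attenuated by co-exposure masking and, for
  common outcomes with mixed event profiles, drifts from an odds ratio
  toward a risk ratio; the adjusted logistic stage mitigates confounding
  but not masking.
* Exact-duplicate removal cannot detect re-submitted reports that differ in
  any field.
* Disproportionality statistics are reporting associations, not incidence
  or causal effects; the denominator of exposed patients is unknown in
  spontaneous-report data.
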