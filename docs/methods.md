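# Methods

`memscreen` implements a membrane-proteome candidate-biomarker discovery
pipeline for label-free LC-MS/MS quantification data, together with the
downstream clinical-association and pharmacology analyses such a screen
feeds into. This note records the models, the defaults and why they were
chosen, and what the synthetic data does and does not establish.

## Label-free normalization

Protein-level quantification is consumed as exported precursor peak
areas, one column per biological replicate (one LC-MS/MS run). Each
column is normalized independently by total-ion normalization:

    normalized_area = protein_area / total_area x 10^6

where `total_area` sums the *present* values of that column. The unit is
therefore parts-per-10^6 of the run's summed precursor signal, and each
normalized column sums to exactly 10^6 over present entries. The
operation is scale-free and idempotent; both properties are enforced by
property tests at 1e-9 relative tolerance.

Missingness is a first-class concept: a cell that is empty, `NA`, or a
literal 0 in the export means the protein was not identified in that run.
Peak areas of unidentified proteins are absent — not zero — in
search-engine exports, so missing cells are excluded from the
normalization denominator and from means and SDs. Per-protein summaries
report, per replicate set: the detection count at an inclusive
normalized-area floor (default 70; a value exactly at the floor counts),
the mean and sample standard deviation (n-1 denominator; with 4
biological replicates the sample SD is the standard choice, though the
population form cannot be ruled out for historical tables) over
identified replicates, and %CV = 100 x SD / mean. The %CV is explicitly
undefined (NaN) with fewer than two identified replicates or a zero mean,
and an undefined %CV fails the consistency filter below because the
criterion cannot be verified.

## Candidate screen

The screen composes four filters, applied to per-protein summaries of a
cancer cell line and a benign control line computed at the same
detection floor:

1. **Membrane refinement.** Keep proteins whose subcellular-localization
   annotation intersects a configurable membrane vocabulary (`membrane`,
   `cell membrane`, `plasma membrane`, `mitochondrion membrane`,
   `endoplasmic reticulum membrane`, `golgi membrane`). Unannotated
   accessions are dropped but counted in the filter report, never
   silently.
2. **Cancer detection.** Detected fraction of replicates at or above the
   floor must reach `presence_fraction` (default 0.75; the comparison is
   `>=`, so 3 of 4 replicates passes).
3. **Exclusivity.** The protein must *fail* the control-expression rule:
   detection in at least `control_min_detected_reps` (default 3) control
   replicates at the floor. Exclusivity is deliberately rule-based
   rather than requiring total absence from the control export, because
   control expression is defined by that replicate rule; a protein seen
   once in control at trace level still counts as cancer-exclusive.
4. **Consistency.** %CV across identified cancer replicates at or below
   `cv_max_percent` (default 40, inclusive).

Survivors are ranked by mean normalized area descending and truncated to
`top_n` (default 30). Ties are broken by accession lexicographic order so
tables are bit-reproducible.

A consequence of the rule-based exclusivity worth knowing: the candidate
count is monotone non-increasing in the presence fraction and in the %CV
ceiling, but **not** in the detection floor. Raising the floor tightens
cancer detection *and* weakens the control-expression rule, so borderline
proteins expressed near the floor in both lines can enter the candidate
set at a higher floor. This is a real property of the filter cascade, not
an implementation artifact; the test suite asserts monotonicity for all
three knobs and the detection-floor case documents the violation.

Venn partitions of detected membrane proteins between two lines are
plain set algebra (`common`, `unique_a`, `unique_b`) with the partition
laws property-tested. Published pool sizes and Venn counts for the
original cell lines depend on the deposited raw data and are reproduced
only when those exports are supplied; the synthetic worlds test the
structure, not those numbers.

## Tissue-microarray association

IHC staining is scored 1-4 (negative, weak, moderate, strong). Two
binarizations exist: the *intensity* rule (low 1-2 / high 3-4) and the
*positivity* rule (negative = 1, positive = 2-4). The positivity rule is
the default for association tables; which scores count as "positive" is
not fixed by convention, so the rule is configurable and recorded in
every report. The reconstructed clinical cohort (0/17 benign, 20/21
carcinoma positive/negative) is consistent with this choice.

Association between positivity and each clinicopathological covariate is
tested with Pearson's chi-square on the r x 2 table, **without** Yates
continuity correction — recomputation of the published 2 x 2 tables
confirms the uncorrected statistic (e.g. the lymph-node table
[[7,13],[13,7]] gives p = 0.0578 uncorrected but ~0.11 corrected).
Cases missing a covariate, or with an unevaluable core, are dropped per
comparison and counted; nothing is imputed. Any expected count below 5
raises a warning flag but does not switch the test. Covariate tests are
run among carcinoma cases only; the benign-vs-carcinoma comparison uses
the full cohort.

As an independent check, a margin-fixed Monte-Carlo permutation null is
provided (hypergeometric draws for 2 x 2, `scipy.stats.random_table`
otherwise). Note its p-value is the *exact conditional* tail, which
differs from the asymptotic chi-square tail by the O(1/N) approximation
error — typically 0.005-0.07 at N <= 60 even with all expected counts
>= 5, far exceeding Monte-Carlo noise at 1e5 draws. Agreement should
therefore be judged at the few-hundredths level, not at Monte-Carlo
standard-error resolution.

## Dose-response pharmacology

MTT readings are background-corrected (OD570 - OD650) and divided by the
vehicle-control mean; viability is floored at 0 but not capped at 1
(stimulation is real signal). Dose-response curves use the
four-parameter logistic

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

fitted by least squares on the log10-concentration axis (doses span 3.5
orders of magnitude). Initialization: top and bottom from the extreme
mean responses, IC50 at the dose nearest half-maximal response, hill 1.
Bounds: IC50 within [min_dose/100, max_dose x 100], hill within
[0.1, 10]. An IC50 is flagged *extrapolated* when it exceeds the tested
dose ceiling (iron-chelator monotherapy is the motivating case) and
*unidentifiable* when the fitted dynamic range is under 5% of the top
response. Each independent experiment is fitted separately and the
per-experiment IC50s pooled as mean ± SD (a pooled-points mode exists);
condition comparisons use the two-sided, equal-variance Student's t-test
on per-experiment IC50s, with the fold-shift and the maximal growth
inhibition (100 x (1 - min mean viability)) of the combination curve.
Growth-curve (siRNA knockdown) comparisons are per-timepoint Student's
t-tests against the reference, starred at 0.05 / 0.01 / 0.001, with NA
for groups lacking the timepoint or having fewer than two replicates.

A design-information caveat established during development: with a free
4PL on an 8-point 0.01-30 µM grid in triplicate and viability noise SD
0.05, the per-experiment IC50 estimator's Cramér–Rao bound is ~0.37 µM
at hill 1 and ~0.21 µM at hill 1.5 for a true IC50 of 2.3 µM (the fitter
operates at this bound). A 3-vs-3 t-test at α = 0.001 has critical t of
8.61 on 4 df, so a 2.3 → 1.0 µM shift is only detected at that strict
level in a fraction of runs (~85% at hill 1.5); very-high-power
detection of such shifts requires steeper curves, lower noise, or more
experiments than this design provides.

## Synthetic data

Each stage has its own seeded generator; all randomness flows from one
integer seed through named substreams (CRC-derived child seeds), and
ground truth is serialized alongside every dataset.

**Proteomics worlds.** A shared universe of 2,300 proteins (roughly the
per-line identification scale of the motivating experiment), of which
26% are membrane-annotated (~600). Base abundances are log-normal
(natural-log mean 11, SD 1 — arbitrary raw-intensity units; only ratios
matter after normalization). Four biological replicates per cell line
carry multiplicative log-normal noise with target CV 20%, loosely
matched to the 10-40% CV range of real top-candidate tables. Each of
the two cancer lines gets a disjoint planted set of 30 cancer-exclusive
membrane proteins, abundance-boosted 5x so they populate the ranking;
planted exclusives are entirely absent from the other lines' exports
("absent" mode), or present at sub-floor abundance in the control in
"trace" mode, which exercises the rule-based exclusivity reading.
Dropout is abundance-dependent, as in data-dependent acquisition: the
missingness probability is `dropout / (1 + (a / a_median)^slope)`, i.e.
it approaches the configured maximum for the faintest proteins and
`dropout/2` at the median. Proteins missing in every replicate of a line
are dropped from that line's export, as an identification engine would.
At the defaults, roughly 9% of proteins sit below the 70-ppm floor, so
the detection filter is meaningfully exercised. Recovery tests run the
no-dropout case at replicate CV 10% — at CV 20% a sample CV over 4
replicates legitimately exceeds the 40% ceiling for ~1% of proteins, so
exact set equality is only a fair expectation when true CVs sit safely
below the ceiling.

**TMA cohorts.** 18 benign and 42 carcinoma cases (one unevaluable core
per group by default), positivity probability 0 in benign and 0.49 in
carcinoma; positive cases draw scores from {2,3,4} with weights
(0.5, 0.3, 0.2). Covariate level frequencies and per-covariate
missingness default to the margins of the motivating cohort; covariates
act on positivity through a logistic model whose effects are log odds
ratios (0 by default, giving a null cohort for type-I-error checks,
which come out at the nominal ~5%).

**Dose-response plates.** Viability = 4PL(true parameters) + Gaussian
noise (SD 0.05), truncated at 0, over 8 log-spaced doses (0.01-30 µM),
3 experiments x 3 replicates. Default conditions emulate a monotherapy
(bottom 0.20, top 1, IC50 2.3 µM) against a fixed-dose combination
(bottom 0.40, IC50 1.0 µM, ~60% maximal inhibition). The hill slope
default of 1.5 is calibrated so the fitted per-experiment IC50s
reproduce with a between-experiment SD of ~0.2 µM, matching the
reported reproducibility of the emulated assays; the true slope of the
underlying assays is unpublished.

**What passing tests show.** Synthetic worlds have independent
log-normal abundances, exchangeable replicates and exactly planted
exclusivity. Real exports additionally carry correlated abundances
(shared complexes), run-order and batch effects, peptide-level roll-up
artifacts and annotation errors; recovery of planted truth here
validates the filter logic and its boundary behavior, not performance
on real cohorts. Likewise the TMA generator draws covariates
independently, so it validates the contingency/test machinery, not
clinical effect-size estimates.

## Numerical and interface choices

- Proteomic tables are TSV (engine-export convention); clinical and
  plate tables are CSV; all UTF-8 with required headers. Readers and
  writers are mutual inverses on valid data (round-trip tested).
- Duplicate accessions, missing required columns and non-numeric areas
  are hard errors naming the offending accession / row / column.
- All dropped or coerced records are counted in reports or the run log;
  p-values are rounded to 4 decimals in tabular reports and kept at full
  precision in JSON.
- Problem sizes in the test suite (world sizes of 300-2,300 proteins,
  20-200 simulation seeds, 2-5 x 10^4 permutation draws for unit checks
  and 10^5 for the oracle comparison) are chosen so the full suite runs
  in well under a minute while keeping Monte-Carlo error far below every
  asserted tolerance.

## Known limitations

- No peptide-to-protein roll-up, retention-time alignment or FDR
  control: the pipeline starts from protein-level exports.
- No enrichment analysis, survival modelling or formal synergy indices
  (Bliss/Loewe/Chou-Talalay); combination effects are summarized as
  IC50 shift plus maximal inhibition only.
- The chi-square test is asymptotic; for the small strata typical of
  TMA cohorts the exact conditional tail can differ by a few hundredths
  (see above), and the package reports low-expected-count warnings
  rather than switching tests.
- The 4PL fitter reports but does not correct extrapolated IC50s; doses
  beyond the tested ceiling are the experimenter's problem.
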