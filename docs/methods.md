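# Methods

## The association model

The unit of analysis is the mother–baby **dyad**: one linked maternal and
neonatal record pair with a single pregnancy episode.  For a drug entity
*d* and phenotype *p*, case status of the baby is regressed on gestational
exposure of the mother:

    logit P(case_ip) = β₀ + β₁ · exposed_id ,   OR_dp = exp(β₁)

an unadjusted univariate logistic regression.  Controls for each drug are
simply all eligible dyads without a recorded exposure to it — no matching
or propensity scoring.  With a single binary predictor the model is
saturated, so the ML estimate of exp(β₁) equals the 2×2 cross-product odds
ratio and the Wald variance of β₁ equals 1/a + 1/b + 1/c + 1/d; the engine
fits by Newton–Raphson on the two-covariate-pattern (aggregated-count)
likelihood, which converges to this closed form to ~1e-12 and is fast
enough to fit hundreds of thousands of pairs in replicate studies.  The
test suite cross-checks the fits against iterative row-level
`statsmodels.Logit` (coefficients, standard errors, Wald and LR p-values to
1e-8).

Assumptions worth keeping in mind:

- **Exposure is a binary indicator** of ≥1 prescription dated inside the
  inferred gestational window; dose, duration and refill structure are
  ignored (duration appears only as a triage annotation).
- **Unadjusted**: no covariates are included by default, matching the
  screening character of the scan; naming `ScanConfig.covariates` (with
  dyad-aligned covariate data) switches the pair fits to row-level
  statsmodels GLM adjustment.  Confounding by indication is therefore *expected* to contaminate
  crude ORs — it is addressed at the triage stage (original-indication
  annotation), not in the model, and the simulator can generate it so the
  contamination is measurable.
- **Per-drug Bonferroni family**: the correction is α/m with m = size of
  the phenotype panel scanned for that drug (default), i.e. the family-wise
  error is controlled per drug across all neonatal diseases.  A global
  family (m = drugs × phenotypes) is available via `ScanConfig(family="global")`.

### Per-pair decision rules

| situation | behaviour |
| --- | --- |
| cases below `min_cases` (default 20) | emitted as `skipped_min_cases`, no fit |
| outcome constant (0 or all cases among included dyads) | `degenerate_outcome`, NaN estimates |
| any zero cell (separation) | `fisher_fallback`: Fisher exact two-sided p, OR from +0.5 (Haldane–Anscombe) corrected cells |
| otherwise | `logit`: Newton ML fit, two-sided Wald p (`p_method="lrt"` for the likelihood-ratio test) |

The +0.5 correction is applied only inside the Fisher fallback, never to
clean tables.  `min_cases=20` follows common PheWAS practice and suppresses
near-unary artifacts; the triage stage separately requires ≥2 exposed cases
("non-unary").  Bonferroni thresholds are compared inclusively (p ≤ α/m).

## Gestational-window inference

Dating is LMP-anchored (gestational day 0 = last menstrual period; term =
280 days), the convention under which ICD-10 `Z3A.NN` codes express
*completed weeks*.  For each mother:

1. **delivery date** = date of the latest delivery-coded event (`O80`-style
   or `Z37`-style tokens);
2. if a week code dated on/before delivery exists, the one nearest delivery
   wins (ties → larger week, since later dating is usually
   ultrasound-corrected), and
   `gestational_age_days = 7·weeks + (delivery − week_event_date)`;
3. the result is capped to [140, 315] days; outside the cap — or with no
   week code at all — the **arithmetic fallback** applies:
   exactly 280 days (40 weeks subtracted from the delivery date), flagged
   `method="arithmetic_default"`.

Mothers with no delivery-coded event have no determinable episode and their
dyads are excluded (tallied in the consort log).  Dyads dated by the
arithmetic fallback are retained but flagged, enabling sensitivity re-runs
that drop them.  Trimesters are the standard obstetric cutpoints at 14 and
28 completed weeks — half-open day intervals [0, 98), [98, 196),
[196, gestational_age_days) — truncated for episodes shorter than a
cutpoint.  The bundled gestation dictionary uses `Z3A.01`–`Z3A.44` week
tokens and a small set of delivery tokens; a site-specific dictionary can
be supplied as TSV (`code`, `kind`, `weeks`).

## Vocabulary semantics

**Phecodes.** A baby is a *case* for a phecode when events on
≥ `min_code_count` distinct dates map to it (same-day duplicate billing is
one clinical event); *excluded* when not a case but carrying any diagnosis
inside the phecode's exclusion range (which always contains the phecode
itself, so sub-threshold carriers never sit in the control pool); otherwise
a *control*.  Exclusion semantics are standard PheWAS practice and can be
switched off (`apply_exclusions=False`).  `min_code_count` defaults to 1 —
maximising power at the small synthetic scales used here — with 2
recommended for specificity on real data.

**Drugs.** Ingredient tokens aggregate to ATC level-4 classes (chemical
subgroup, e.g. `N03AX`): exposure to a class is the logical OR of exposures
to its member drugs.  Unmapped tokens route to a sentinel `UNMAPPED` class
(logged, and excluded from the default scan panel).  The repository bundles
only small, clearly synthetic vocabulary fixtures; real phecode/ATC tables
are loaded by path and never required.

## The synthetic-EHR generator

The generator emulates the statistical structure the model assumes, with
known ground truth written alongside the data (`truth.json`, never read by
the pipeline):

- **Population**: `n_dyads` dyads (default 2,000), one pregnancy episode
  each; delivery dates uniform over two years; gestational age drawn
  N(280, 10) days, rounded and clipped to [224, 308] so every episode has a
  non-empty third trimester (at the default draw the clip essentially never
  binds).
- **Delivery coding**: each mother (minus a `missing_delivery_code_rate`
  fraction, default 0) receives a delivery code at delivery and a
  completed-weeks code stamped at the last exact week boundary before
  delivery — i.e. within the delivery-encounter week, 0–6 days early.  This
  is the generator's dating convention: a completed-weeks code is exact on
  a week boundary, which makes the stated inference rule recover the true
  start date exactly; a code stamped on the delivery date itself would
  carry a ±6-day truncation error by construction.
- **Exposures**: per-drug gestational exposure with probability
  `exposure_prevalence` (default 0.10 per drug, 20 drugs); trimester drawn
  from `trimester_exposure_weights` (default uniform) and the date uniform
  within that trimester — no within-trimester timing model is claimed.
- **Outcomes**: per-phecode case indicator from
  `logit P = logit(π_p) + Σ_d log(OR_dp)·exposed_d (+ confounding)`,
  baseline prevalence π_p default 0.05; cases receive two diagnosis rows on
  distinct post-natal dates using the two synthetic ICD tokens of the
  phecode.
- **Confounding by indication** (optional): a maternal indication diagnosis
  (prevalence `indication_prevalence`) multiplies the odds of receiving a
  *specific* drug by `or_exposure` and, independently, the odds of the
  neonatal phenotype by `or_outcome` — the mechanism that makes a null drug
  show a spurious crude association.
- **Notes**: 1–3 postpartum well-child notes per baby.

Default prevalences are chosen for statistical testability (≈100 cases per
phenotype and ≈200 exposed mothers per drug at n = 2,000, giving a log-OR
sampling SE ≈ 0.2), not to mimic any particular institution's code-frequency
distribution.  A single root seed fans out to one substream per table
family, so identical configs are byte-identical and adding a table would
not perturb existing ones.

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real data: realistic ICD code-frequency and co-occurrence
structure, free-text notes, multi-parity and twin gestations,
exposure-misclassification (prescriptions not taken), differential
missingness, or demographic confounding beyond the indication mechanism.
Planted-effect recovery shows the machinery is correct, not that real EHR
signals are causal.

## Inclusion rule and ablation bookkeeping

A dyad is retained iff (a) a mother–baby link exists, (b) the episode is
determinable, (c) ≥1 maternal medication falls inside the window, (d) the
baby has ≥1 note on/after delivery.  Exclusions are tallied once each,
under the *first* failing rule in that order (consort-style log).  The
test utility `ablate_population` knocks out prerequisites for disjoint
dyad sets drawn only from dyads currently passing the full rule, so each
planted ablation shifts exactly one tally by exactly one — making the
bookkeeping exactly checkable.

## Signal triage

Rules are evaluated per signal, in a fixed declaration order, and recorded
as named boolean verdicts plus a rationale listing every fired rule:

- **hard filters** → `parsed`: nutraceutical/OTC drug (EHR capture of
  supplement use is unreliable), or phenotype not plausibly manifest in the
  perinatal period (e.g. neurocognitive diagnoses);
- **soft constraints** (verdicts, not removals): p ≤ 0.05 (inclusive),
  Bonferroni flag, OR > 1, coincidence rate ≥ 1% (inclusive — "at least
  1%"), ≥2 exposed cases;
- **high yield** = nominally significant ∧ OR > 1 ∧ coincidence ≥ 1% ∧
  non-unary ∧ plausible first-trimester prescription ∧ not
  intrapartum/immediate-postpartum ∧ not regionally sparse ∧ FDA class in
  {C, unknown} (the machine-readable proxy for "unclear prescriptive
  guidance" — the underlying judgment is human and the annotation is
  user-supplied);
- everything else surviving the hard filters is **low yield**.

Bonferroni significance is deliberately *soft*: a signal keeps its
Bonferroni flag for ranking, but nominal significance suffices for high
yield, with the evidence filters carrying the rest of the vetting.  Missing
annotations default to the conservative side (no first-trimester
plausibility assumed, flags false), so automation can never promote an
unannotated signal to high yield.  Pharmacokinetic-implausibility removal
is a user-supplied drop list, not computed.  The high/low conjunction is
one defensible codification of a partly judgment-based workflow and is kept
configurable (`PrioritizationConfig`).

## Reproducibility

Every stage consumes and produces files only, enabling resume-from-stage.
The run manifest records the config hash, seed, panel sizes, package
version and sha256 checksums of every artifact; the determinism contract is
that re-running with the same config and seed reproduces identical
checksums for every *data* artifact (the manifest's own timestamp is the
only wall-clock field).  Calibration studies derive per-replicate seeds
from a single root seed.

## Problem sizes used in the checks

The replicate studies run 200 replicates of the full pipeline at n = 2,000
dyads, 20 drugs × 50 phecodes (≈1,000 fits per replicate) — large enough
that the null per-drug family-wise error (nominal 0.05) and the planted
OR = 4 detection rate (analytically ≈ 1 at these margins) are measured with
Monte-Carlo SEs of a few points, while one full study completes in about a
minute on one CPU.  Estimator-identity checks use 1,000 random tables;
gestational recovery uses 500 mothers; determinism uses a 500-dyad
pipeline run twice.

## Known limitations

- One episode per mother; multi-parity, twins, abortion/stillbirth episodes
  are out of scope.
- Exposure timing uses the prescription date only; duration/refill
  expansion is not modelled.
- The control pool for a class-level scan treats exposure to any sibling
  drug in the class as exposed (class defines the entity); scans at
  ingredient level are available via `level="token"`.
- Wald p-values are slightly anti-conservative for extreme cell
  imbalances; the LR test is available, and separation always falls back to
  Fisher.
- The gestation dictionary bundled here is a compact reconstruction of the
  week/delivery-code approach, not any institution's full dictionary;
  supply a site dictionary for real data.
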