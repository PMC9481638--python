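# medwas

Medication history-wide association scans (MedWAS) for pharmacovigilance in
pregnancy: a PheWAS-style screen in which the predictor is **maternal drug
exposure during gestation** and the outcomes are **neonatal phenotypes**,
built on linked mother–baby EHR tables.

Drug safety in pregnancy is chronically under-studied — pregnant people are
excluded from most trials, and the literature advances one
drug–one disease–one publication at a time.  A MedWAS instead screens *every*
drug prescribed to mothers against *every* phenotype coded in their babies'
records, producing ranked teratogenicity hypotheses for clinical review.
Because real linked mother–baby EHR corpora are protected health
information, the package ships a synthetic-EHR generator with known ground
truth, so the entire pipeline is testable end to end.

## What it computes

For each drug entity *d* (an ATC level-4 class, aggregating ingredient-level
exposures) and each phenotype *p* (a phecode, aggregating ICD-9/10 billing
codes with control-exclusion ranges), the engine fits the univariate
logistic regression

```
logit P(case_p) = β₀ + β₁ · exposed_d
```

over the eligible mother–baby dyads and reports

- **OR** = exp(β₁), identical to the 2×2 cross-product odds ratio for this
  saturated model;
- a two-sided **Wald p-value** (likelihood-ratio optional), with Fisher's
  exact test + Haldane–Anscombe correction as the separation fallback;
- a **Bonferroni flag** at α/m, where the family is by default the phenotype
  panel scanned per drug;
- the **coincidence rate** — the fraction of cases whose mothers were
  exposed.

Upstream, each mother's gestational window is inferred from coded events
(`Z3A.NN` completed-week codes anchored to the latest delivery code, with a
280-day arithmetic fallback when week codes are missing), and a dyad enters
the study only if it has a mother–baby link, a determinable pregnancy
episode, ≥1 medication dated inside the window, and ≥1 postpartum note in
the baby's record.  Downstream, a rules engine codifies signal triage:
hard filters (nutraceutical/OTC drugs, perinatally implausible phenotypes),
soft statistical constraints (p ≤ 0.05, OR > 1, coincidence ≥ 1%, non-unary
exposed cases), and high/low-yield classification driven by an
evidence-annotation spreadsheet (FDA class, trimester of prescription,
intrapartum flag, regional prescribing).

## Worked example

```python
from medwas import SimulationConfig
from medwas.calibration import scan_population

cfg = SimulationConfig(
    n_dyads=2000, n_drugs=20, n_phecodes=50,
    baseline_prevalence=0.05, exposure_prevalence=0.10,
    true_effects=[("drug_003", "012.0", 4.0)],   # one planted OR=4 effect
    seed=11,
)
res = scan_population(cfg)       # simulate → infer episodes → include → scan
print(res.summary(top=5))
```

```
MedWAS scan results
============================================================
pairs tested: 1000 of 1000 (0 below min_cases, 0 degenerate)
alpha=0.05, Bonferroni family=per_drug (m=50, threshold=0.001)
Bonferroni-significant pairs: 3

    drug phecode  odds_ratio   p_value  coincidence_rate method
drug_003   012.0       3.103 6.808e-07            0.2655  logit
drug_013   030.0       3.066 2.091e-05            0.2821  logit
drug_002   038.0       2.632 0.0003106            0.2381  logit
drug_009   016.0       2.301  0.001864            0.2439  logit
drug_006   034.0       2.415  0.001937            0.2048  logit
```

The planted drug_003 → 012.0 effect tops the scan (this replicate estimates
OR ≈ 3.1 against a generative OR of 4; the sampling SE of a log cross-product
OR at these cell sizes is ≈ 0.2, and across replicates the estimate centres
on log 4).  The two other flagged pairs are the false positives a 1,000-test
scan at a per-drug threshold of 0.001 occasionally produces — exactly why
the triage stage exists.

The same stages run from the shell:

```bash
medwas simulate --config sim.yaml --out data/ --seed 11
medwas scan --data data/ --phecode-map data/phecode_map.csv \
            --drug-map data/drug_map.tsv --out results.tsv
medwas prioritize --results results.tsv --annotations ann.tsv --out triage.tsv
medwas report --triage triage.tsv
medwas run --config pipeline.yaml --out artifacts/   # all stages + manifest
```

As a library, the scan follows the model/results idiom:
`MedWAS.from_tables(tables, phecode_map, drug_map).fit()` returns a
`MedWASResults` with the association table, `summary()`, and
`to_tsv()`/`from_tsv()` round-tripping (run metadata in `#` header lines).

## Layout

| module | role |
| --- | --- |
| `medwas.simulate` | synthetic linked mother–baby EHR tables + ground truth |
| `medwas.pregnancy` | gestational-window inference (dictionary + arithmetic fallback) |
| `medwas.vocab` | ICD→phecode (with exclusion ranges), drug→ATC-4 |
| `medwas.cohort` | inclusion rule, consort log, exposure cohorts |
| `medwas.scan` | the MedWAS engine (`MedWAS` / `MedWASResults`) |
| `medwas.prioritize` | hard filters, soft constraints, yield classes, triage report |
| `medwas.calibration` | replicate-level FWER / power studies |
| `medwas.pipeline`, `medwas.cli` | simulate → scan → prioritize → report, with a run manifest |

See `docs/methods.md` for the statistical model, the generator's design and
its limits, and the numerical choices.
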