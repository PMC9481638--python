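"""Signal prioritization: hard filters, soft constraints, yield classes.

A scan over thousands of drug-disease pairs produces far more statistical
signals than can be reviewed; prioritization codifies the vetting ledger
applied on top of the statistics:

* **hard filters** remove signals that cannot be trusted at all — drugs that
  are nutraceuticals/OTC products (EHR capture of supplement use is
  unreliable) and phenotypes implausibly manifest in the perinatal period
  (e.g. neurocognitive diagnoses such as dyslexia).  Filtered signals are
  marked ``parsed``.
* **soft constraints** are boolean verdicts, not removals: nominal
  significance (p <= 0.05), Bonferroni significance, OR > 1, coincidence
  rate >= 1% (fraction of cases with maternal exposure), and a non-unary
  exposed-case count (>= 2).
* **yield classification**: a surviving signal is ``high`` when it is
  nominally significant with OR > 1, >= 1% coincidence, non-unary, the drug
  is plausibly prescribed in the first trimester, the prescription is not
  intrapartum/immediately postpartum, and prescriptive guidance is unclear
  (FDA class C or unknown).  Everything else surviving the hard filters is
  ``low`` — the rationale records which de-prioritizers fired (OTC
  reliability, regionally sparse prescribing, intrapartum timing, or simply
  failing a high-yield condition).

Annotations (indication, FDA class, trimesters of prescription, etc.) are
user-supplied; missing annotations default to the conservative side so that
automation can never promote a signal to high yield.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FDA_CLASSES = {"A", "B", "C", "D", "X", "unknown"}

#: hard-filter rule ids, in declaration order.
HARD_RULES = ("otc_nutraceutical", "perinatally_implausible")

#: soft-constraint verdict columns.
SOFT_RULES = (
    "significant_p",
    "bonferroni_flag",
    "or_gt_1",
    "coincidence_ge_1pct",
    "non_unary",
)

#: low-yield de-prioritizer rule ids.
LOW_RULES = ("otc_reliability", "sparsely_prescribed", "intrapartum")


@dataclass
class PrioritizationConfig:
    alpha: float = 0.05
    coincidence_threshold: float = 0.01  # "at least 1%", inclusive
    min_exposed_cases: int = 2  # non-unary
    high_yield_fda_classes: frozenset = frozenset({"C", "unknown"})


@dataclass(frozen=True)
class SignalAnnotation:
    """Evidence-spreadsheet fields for one drug entity."""

    drug: str
    drug_original_indication: str = ""
    fda_class: str = "unknown"
    trimester_of_prescription: frozenset = frozenset()
    intrapartum_or_immediate_postpartum: bool = False
    duration_of_prescription_days: float | None = None
    perinatally_plausible_phenotype: bool = True
    nutraceutical_or_otc: bool = False
    sparsely_prescribed_regionally: bool = False

    def __post_init__(self) -> None:
        if self.fda_class not in FDA_CLASSES:
            raise ValueError(f"fda_class must be one of {sorted(FDA_CLASSES)}")
        object.__setattr__(
            self,
            "trimester_of_prescription",
            frozenset(int(t) for t in self.trimester_of_prescription),
        )
        if not self.trimester_of_prescription <= {1, 2, 3}:
            raise ValueError("trimester_of_prescription must be a subset of {1,2,3}")


#: conservative default when a signal has no annotation: flags that could
#: promote stay false/unknown, flags that de-prioritize stay false too, and
#: first-trimester prescription is *not* assumed — the signal cannot be high.
def conservative_default(drug: str) -> SignalAnnotation:
    return SignalAnnotation(drug=drug)


def load_annotations(path: str | Path) -> dict[str, SignalAnnotation]:
    """Load a SignalAnnotation TSV keyed by drug/class id.

    Columns: drug, drug_original_indication, fda_class,
    trimester_of_prescription (e.g. "1,2"), intrapartum_or_immediate_postpartum,
    duration_of_prescription_days, perinatally_plausible_phenotype,
    nutraceutical_or_otc, sparsely_prescribed_regionally.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    truthy = {"1", "true", "yes", "y"}
    out: dict[str, SignalAnnotation] = {}

    def flag(row, col, default=False):
        v = str(row.get(col, "")).strip().lower()
        return default if v == "" else v in truthy

    for _, row in df.iterrows():
        tri = frozenset(
            int(t) for t in str(row.get("trimester_of_prescription", "")).split(",") if t.strip()
        )
        dur = row.get("duration_of_prescription_days", "").strip()
        out[row["drug"].strip()] = SignalAnnotation(
            drug=row["drug"].strip(),
            drug_original_indication=row.get("drug_original_indication", "").strip(),
            fda_class=(row.get("fda_class", "").strip() or "unknown"),
            trimester_of_prescription=tri,
            intrapartum_or_immediate_postpartum=flag(
                row, "intrapartum_or_immediate_postpartum"
            ),
            duration_of_prescription_days=float(dur) if dur else None,
            perinatally_plausible_phenotype=flag(
                row, "perinatally_plausible_phenotype", default=True
            ),
            nutraceutical_or_otc=flag(row, "nutraceutical_or_otc"),
            sparsely_prescribed_regionally=flag(row, "sparsely_prescribed_regionally"),
        )
    return out


def _annotations_for(
    drugs, annotations: dict[str, SignalAnnotation]
) -> list[SignalAnnotation]:
    resolved: dict[str, SignalAnnotation] = {}
    for d in pd.unique(pd.Series(list(drugs), dtype=object)):
        ann = annotations.get(d)
        if ann is None:
            logger.warning("signal drug %r has no annotation; conservative defaults", d)
            ann = conservative_default(d)
        resolved[d] = ann
    return [resolved[d] for d in drugs]


def apply_soft_constraints(
    results: pd.DataFrame, config: PrioritizationConfig | None = None
) -> pd.DataFrame:
    """Add boolean soft-constraint verdict columns to a result table.

    Thresholds are inclusive (p <= alpha, coincidence >= 1%).
    """
    config = config or PrioritizationConfig()
    out = results.copy()
    p = out["p_value"]
    out["significant_p"] = (p <= config.alpha).fillna(False)
    out["bonferroni_flag"] = out["bonferroni_significant"].fillna(False).astype(bool)
    out["or_gt_1"] = (out["odds_ratio"] > 1).fillna(False)
    out["coincidence_ge_1pct"] = (
        out["coincidence_rate"] >= config.coincidence_threshold
    ).fillna(False)
    out["non_unary"] = out["n_exposed_case"] >= config.min_exposed_cases
    return out


def apply_hard_filters(
    results: pd.DataFrame, annotations: dict[str, SignalAnnotation]
) -> pd.DataFrame:
    """Add hard-filter verdict columns; a fired hard filter marks ``parsed``."""
    out = results.copy()
    anns = _annotations_for(out["drug"], annotations)
    out["otc_nutraceutical"] = [a.nutraceutical_or_otc for a in anns]
    out["perinatally_implausible"] = [not a.perinatally_plausible_phenotype for a in anns]
    out["parsed"] = out["otc_nutraceutical"] | out["perinatally_implausible"]
    return out


def classify_yield(
    results: pd.DataFrame,
    annotations: dict[str, SignalAnnotation],
    config: PrioritizationConfig | None = None,
) -> pd.DataFrame:
    """Classify every signal as high / low / parsed, with a rule rationale.

    High yield requires *all* of: nominal significance, OR > 1, coincidence
    rate >= 1%, non-unary exposed cases, plausible first-trimester
    prescription, no intrapartum/immediate-postpartum flag, and unclear
    guidance (FDA class in the configured set).  A fired hard filter yields
    ``parsed``; everything else is ``low``.  Classification of a signal
    depends only on its own fields and annotation.
    """
    config = config or PrioritizationConfig()
    out = results
    if not set(SOFT_RULES) <= set(out.columns):
        out = apply_soft_constraints(out, config)
    if "parsed" not in out.columns:
        out = apply_hard_filters(out, annotations)
    else:
        out = out.copy()

    anns = _annotations_for(out["drug"], annotations)
    out["first_trimester_plausible"] = [1 in a.trimester_of_prescription for a in anns]
    out["intrapartum"] = [a.intrapartum_or_immediate_postpartum for a in anns]
    out["fda_unclear"] = [a.fda_class in config.high_yield_fda_classes for a in anns]
    out["sparsely_prescribed"] = [a.sparsely_prescribed_regionally for a in anns]
    out["otc_reliability"] = [a.nutraceutical_or_otc for a in anns]

    high = (
        out["significant_p"]
        & out["or_gt_1"]
        & out["coincidence_ge_1pct"]
        & out["non_unary"]
        & out["first_trimester_plausible"]
        & ~out["intrapartum"]
        & ~out["sparsely_prescribed"]
        & out["fda_unclear"]
        & ~out["parsed"]
    )
    out["yield"] = np.where(out["parsed"], "parsed", np.where(high, "high", "low"))

    rationales = []
    for _, row in out.iterrows():
        fired = [r for r in HARD_RULES if row[r]]
        if not fired:
            if row["yield"] == "high":
                fired = ["high_yield_conjunction"]
            else:
                fired = [r for r in LOW_RULES if row[r]]
                fired += [
                    f"fails_{r}"
                    for r in (
                        "significant_p",
                        "or_gt_1",
                        "coincidence_ge_1pct",
                        "non_unary",
                        "first_trimester_plausible",
                        "fda_unclear",
                    )
                    if not row[r]
                ]
        rationales.append(";".join(fired))
    out["rationale"] = rationales
    return out


def triage_report(prioritized: pd.DataFrame) -> dict:
    """Summarise a prioritized table: per-yield counts, per-rule fire counts,
    and the high-yield table sorted by (bonferroni desc, p asc)."""
    counts = {y: 0 for y in ("high", "low", "parsed")}
    rule_cols = list(HARD_RULES) + list(SOFT_RULES) + list(LOW_RULES)
    if prioritized.empty:
        return {
            "yield_counts": counts,
            "rule_fire_counts": {r: 0 for r in rule_cols},
            "high_yield": prioritized,
        }
    counts.update(prioritized["yield"].value_counts().to_dict())
    fires = {
        r: int(prioritized[r].sum()) if r in prioritized.columns else 0 for r in rule_cols
    }
    high = (
        prioritized[prioritized["yield"] == "high"]
        .sort_values(["bonferroni_flag", "p_value"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return {"yield_counts": counts, "rule_fire_counts": fires, "high_yield": high}


def write_triage(prioritized: pd.DataFrame, path: str | Path) -> None:
    """Write the prioritized table as TSV with a summary header."""
    rep = triage_report(prioritized)
    with open(path, "w") as fh:
        for y in ("high", "low", "parsed"):
            fh.write(f"# yield_{y}: {rep['yield_counts'][y]}\n")
        prioritized.to_csv(fh, sep="\t", index=False, float_format="%.10g")
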