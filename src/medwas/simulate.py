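"""Synthetic linked mother-baby EHR generator with known ground truth.

Real mother-infant EHR corpora are protected health information, so every
downstream stage of the scan is exercised against simulated data whose
generating process mirrors the statistical structure the association model
assumes:

* one pregnancy episode per dyad, with gestational age drawn in days and the
  delivery anchored by coded diagnosis rows (a delivery code plus a
  completed-weeks gestational code);
* per-drug maternal exposures during gestation, dated uniformly within a
  trimester drawn from configurable weights;
* neonatal phenotypes drawn from a logistic model,
  ``logit P(case_p) = logit(pi_p) + sum_d log(OR_dp) * exposed_d (+ confounding)``,
  so planted drug→phenotype effects have a known odds ratio;
* optional confounding by maternal indication: an indication diagnosis raises
  both the probability of receiving a specific drug and, independently, the
  neonatal phenotype probability.

Output is five OMOP-flavoured TSV tables plus a ``truth.json`` that records
the generating truth (episodes, exposures, planted effects).  The truth file
is written alongside the data for recovery tests and is never read by the
analysis pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pregnancy import GestationDictionary, default_dictionary

logger = logging.getLogger(__name__)

TABLE_NAMES = (
    "person",
    "mother_baby_link",
    "drug_exposure",
    "condition_occurrence",
    "note_event",
)

_BASE_DATE = np.datetime64("2019-01-01")

#: gestational-age clip in days (32-44 completed weeks).  The clip keeps
#: every episode's third trimester non-empty so trimester-assigned exposures
#: can always be dated; at the default (280, 10) draw it essentially never
#: binds.
_GA_CLIP = (224, 308)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def drug_token(i: int) -> str:
    return f"drug_{i:03d}"


def phecode_id(i: int) -> str:
    return f"{i + 1:03d}.0"


def _atc4_for(i: int) -> str:
    letters = "ABCDGHJLMNPRSV"
    return f"{letters[i % len(letters)]}{i % 100:02d}AA"


@dataclass(frozen=True)
class ConfoundingEffect:
    """Confounding by indication: one maternal diagnosis, one drug, one outcome.

    The indication (prevalence ``indication_prevalence`` among mothers)
    multiplies the odds of receiving ``drug`` by ``or_exposure`` and,
    independently, the odds of the neonatal phenotype by ``or_outcome`` —
    inducing a spurious drug-outcome association when the drug itself is null.
    """

    indication_phecode: str
    drug: str
    neonatal_phecode: str
    or_exposure: float = 3.0
    or_outcome: float = 3.0
    indication_prevalence: float = 0.10


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mother-baby population."""

    n_dyads: int = 2000
    n_drugs: int = 20
    n_phecodes: int = 50
    baseline_prevalence: float | Sequence[float] = 0.05
    exposure_prevalence: float | Sequence[float] = 0.10
    true_effects: list[tuple] = field(default_factory=list)
    confounding_effects: list[ConfoundingEffect] = field(default_factory=list)
    nutraceutical_drug_ids: set = field(default_factory=set)
    trimester_exposure_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    gestational_age_days_mean: float = 280.0
    gestational_age_days_sd: float = 10.0
    missing_delivery_code_rate: float = 0.0
    seed: int = 0

    # --- normalised views -------------------------------------------------
    def drug_tokens(self) -> list[str]:
        return [drug_token(i) for i in range(self.n_drugs)]

    def phecode_ids(self) -> list[str]:
        return [phecode_id(i) for i in range(self.n_phecodes)]

    def _drug_index(self, d) -> int:
        if isinstance(d, (int, np.integer)):
            i = int(d)
        else:
            try:
                i = self.drug_tokens().index(str(d))
            except ValueError:
                raise ConfigurationError(f"true_effects: unknown drug {d!r}")
        if not 0 <= i < self.n_drugs:
            raise ConfigurationError(f"true_effects: drug index {i} out of range")
        return i

    def _phecode_index(self, p) -> int:
        if isinstance(p, (int, np.integer)):
            i = int(p)
        else:
            try:
                i = self.phecode_ids().index(str(p))
            except ValueError:
                raise ConfigurationError(f"true_effects: unknown phecode {p!r}")
        if not 0 <= i < self.n_phecodes:
            raise ConfigurationError(f"true_effects: phecode index {i} out of range")
        return i

    def effect_triples(self) -> list[tuple[int, int, float]]:
        out = []
        for d, p, orr in self.true_effects:
            if not float(orr) > 0:
                raise ConfigurationError(f"true_effects: odds_ratio must be > 0, got {orr}")
            out.append((self._drug_index(d), self._phecode_index(p), float(orr)))
        return out

    def baseline_vector(self) -> np.ndarray:
        v = np.broadcast_to(
            np.asarray(self.baseline_prevalence, dtype=float), (self.n_phecodes,)
        ).copy()
        if ((v < 0) | (v > 1)).any():
            raise ConfigurationError("baseline_prevalence: probabilities must be in [0, 1]")
        return v

    def exposure_vector(self) -> np.ndarray:
        v = np.broadcast_to(
            np.asarray(self.exposure_prevalence, dtype=float), (self.n_drugs,)
        ).copy()
        if ((v < 0) | (v > 1)).any():
            raise ConfigurationError("exposure_prevalence: probabilities must be in [0, 1]")
        return v

    def validate(self) -> None:
        if self.n_dyads < 0:
            raise ConfigurationError("n_dyads: must be >= 0")
        if self.n_drugs < 1 or self.n_phecodes < 1:
            raise ConfigurationError("n_drugs/n_phecodes: must be >= 1")
        w = np.asarray(self.trimester_exposure_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any():
            raise ConfigurationError("trimester_exposure_weights: need 3 non-negative values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("trimester_exposure_weights: must sum to 1 within 1e-9")
        if not 0 <= self.missing_delivery_code_rate <= 1:
            raise ConfigurationError("missing_delivery_code_rate: must be in [0, 1]")
        if self.gestational_age_days_sd < 0:
            raise ConfigurationError("gestational_age_days_sd: must be >= 0")
        self.baseline_vector()
        self.exposure_vector()
        self.effect_triples()
        for c in self.confounding_effects:
            if not isinstance(c, ConfoundingEffect):
                raise ConfigurationError(
                    "confounding_effects: entries must be ConfoundingEffect"
                )
            if c.or_exposure <= 0 or c.or_outcome <= 0:
                raise ConfigurationError("confounding_effects: odds ratios must be > 0")
            if not 0 <= c.indication_prevalence <= 1:
                raise ConfigurationError(
                    "confounding_effects: indication_prevalence must be in [0, 1]"
                )


@dataclass
class SyntheticTruth:
    """Generating truth: episodes, exposures and planted effects.

    Written next to the data tables for recovery tests; the analysis
    pipeline never reads it.
    """

    episodes: pd.DataFrame  # mother_id, baby_id, pregnancy_start, delivery_date, gestational_age_days
    exposures: pd.DataFrame  # baby_id, drug, trimester, drug_exposure_date
    effects: list[tuple[str, str, float]]

    def to_json(self) -> str:
        payload = {
            "episodes": self.episodes.astype(str).to_dict(orient="records"),
            "exposures": self.exposures.astype(str).to_dict(orient="records"),
            "effects": [[d, p, o] for d, p, o in self.effects],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        ep = pd.DataFrame(
            payload["episodes"],
            columns=[
                "mother_id",
                "baby_id",
                "pregnancy_start",
                "delivery_date",
                "gestational_age_days",
            ],
        )
        if len(ep):
            ep["gestational_age_days"] = ep["gestational_age_days"].astype(int)
        ex = pd.DataFrame(
            payload["exposures"],
            columns=["baby_id", "drug", "trimester", "drug_exposure_date"],
        )
        if len(ex):
            ex["trimester"] = ex["trimester"].astype(int)
        effects = [(d, p, float(o)) for d, p, o in payload["effects"]]
        return cls(episodes=ep, exposures=ex, effects=effects)


def _empty_tables() -> dict[str, pd.DataFrame]:
    cols = {
        "person": ["person_id", "role", "gender", "birth_date"],
        "mother_baby_link": ["mother_id", "baby_id"],
        "drug_exposure": ["person_id", "drug_token", "drug_exposure_date"],
        "condition_occurrence": ["person_id", "condition_code", "vocabulary", "condition_date"],
        "note_event": ["person_id", "note_type", "note_date"],
    }
    return {k: pd.DataFrame(columns=v) for k, v in cols.items()}


def generate_population(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate the five linked EHR tables and the generating truth.

    Identical ``config`` (including ``seed``) yields byte-identical tables.
    A single root seed fans out to one substream per table family, so adding
    a table does not perturb existing ones.
    """
    config.validate()
    n, D, P = config.n_dyads, config.n_drugs, config.n_phecodes

    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_epi = np.random.default_rng(streams[0])
    rng_ind = np.random.default_rng(streams[1])
    rng_exp = np.random.default_rng(streams[2])
    rng_out = np.random.default_rng(streams[3])
    rng_note = np.random.default_rng(streams[4])
    rng_person = np.random.default_rng(streams[5])

    effects = config.effect_triples()
    truth_effects = [
        (drug_token(d), phecode_id(p), o) for d, p, o in effects
    ]

    if n == 0:
        truth = SyntheticTruth(
            episodes=pd.DataFrame(
                columns=[
                    "mother_id",
                    "baby_id",
                    "pregnancy_start",
                    "delivery_date",
                    "gestational_age_days",
                ]
            ),
            exposures=pd.DataFrame(
                columns=["baby_id", "drug", "trimester", "drug_exposure_date"]
            ),
            effects=truth_effects,
        )
        return _empty_tables(), truth

    mother_ids = np.array([f"M{i:06d}" for i in range(n)])
    baby_ids = np.array([f"B{i:06d}" for i in range(n)])

    # --- pregnancy episodes ----------------------------------------------
    delivery = _BASE_DATE + rng_epi.integers(0, 731, size=n).astype("timedelta64[D]")
    ga = (
        np.round(
            rng_epi.normal(config.gestational_age_days_mean, config.gestational_age_days_sd, n)
        )
        .astype(int)
        .clip(*_GA_CLIP)
    )
    start = delivery - ga.astype("timedelta64[D]")
    missing_delivery = rng_epi.random(n) < config.missing_delivery_code_rate

    # --- maternal indications (confounding) -------------------------------
    indication = np.zeros((n, len(config.confounding_effects)), dtype=bool)
    for k, conf in enumerate(config.confounding_effects):
        indication[:, k] = rng_ind.random(n) < conf.indication_prevalence

    # --- gestational drug exposures ---------------------------------------
    p_exp = np.broadcast_to(config.exposure_vector(), (n, D)).copy()
    if config.confounding_effects:
        logit_exp = logit(np.clip(p_exp, 1e-12, 1 - 1e-12))
        for k, conf in enumerate(config.confounding_effects):
            di = config._drug_index(conf.drug)
            logit_exp[:, di] += np.log(conf.or_exposure) * indication[:, k]
        p_exp = expit(logit_exp)
    exposed = rng_exp.random((n, D)) < p_exp

    dyad_idx, drug_idx = np.nonzero(exposed)
    tri = rng_exp.choice(
        3, size=len(dyad_idx), p=np.asarray(config.trimester_exposure_weights, dtype=float)
    )
    lo = np.array([0, 98, 196])[tri]
    hi = np.where(tri == 0, 98, np.where(tri == 1, 196, ga[dyad_idx]))
    day = lo + (rng_exp.random(len(dyad_idx)) * (hi - lo)).astype(int)
    exp_date = start[dyad_idx] + day.astype("timedelta64[D]")

    drug_exposure = pd.DataFrame(
        {
            "person_id": mother_ids[dyad_idx],
            "drug_token": [drug_token(i) for i in drug_idx],
            "drug_exposure_date": exp_date,
        }
    )

    # --- neonatal outcomes -------------------------------------------------
    base = np.clip(config.baseline_vector(), 1e-12, 1 - 1e-12)
    L = np.broadcast_to(logit(base), (n, P)).copy()
    for d, p, orr in effects:
        L[:, p] += np.log(orr) * exposed[:, d]
    for k, conf in enumerate(config.confounding_effects):
        pi = config._phecode_index(conf.neonatal_phecode)
        L[:, pi] += np.log(conf.or_outcome) * indication[:, k]
    case = rng_out.random((n, P)) < expit(L)

    # --- condition_occurrence ----------------------------------------------
    cond_frames: list[pd.DataFrame] = []

    # baby diagnosis rows: two rows on two distinct post-natal dates per case,
    # using the two synthetic ICD-10 tokens that map to the phecode
    ci, cj = np.nonzero(case)
    d1 = rng_out.integers(1, 200, size=len(ci))
    d2 = d1 + rng_out.integers(1, 160, size=len(ci))
    for which, dd in ((0, d1), (1, d2)):
        cond_frames.append(
            pd.DataFrame(
                {
                    "person_id": baby_ids[ci],
                    "condition_code": [f"SYN{j:03d}.{which}" for j in cj],
                    "vocabulary": "ICD10",
                    "condition_date": delivery[ci] + dd.astype("timedelta64[D]"),
                }
            )
        )

    # maternal delivery coding: delivery code at delivery; completed-weeks
    # gestational code stamped at the last exact week boundary before delivery
    # (the delivery-encounter week), so that weeks*7 + offset-to-delivery
    # reconstructs gestational age exactly
    keep = ~missing_delivery
    weeks = ga[keep] // 7
    week_date = delivery[keep] - (ga[keep] % 7).astype("timedelta64[D]")
    cond_frames.append(
        pd.DataFrame(
            {
                "person_id": mother_ids[keep],
                "condition_code": "O80",
                "vocabulary": "ICD10",
                "condition_date": delivery[keep],
            }
        )
    )
    cond_frames.append(
        pd.DataFrame(
            {
                "person_id": mother_ids[keep],
                "condition_code": [f"Z3A.{w:02d}" for w in weeks],
                "vocabulary": "ICD10",
                "condition_date": week_date,
            }
        )
    )
    # ongoing-pregnancy marker at ~8 completed weeks for every mother
    cond_frames.append(
        pd.DataFrame(
            {
                "person_id": mother_ids,
                "condition_code": "Z33.1",
                "vocabulary": "ICD10",
                "condition_date": start + np.timedelta64(56, "D"),
            }
        )
    )
    # maternal indication diagnoses, dated in the first trimester
    for k, conf in enumerate(config.confounding_effects):
        who = np.nonzero(indication[:, k])[0]
        cond_frames.append(
            pd.DataFrame(
                {
                    "person_id": mother_ids[who],
                    "condition_code": f"SYNIND.{k}",
                    "vocabulary": "ICD10",
                    "condition_date": start[who]
                    + rng_ind.integers(0, 98, size=len(who)).astype("timedelta64[D]"),
                }
            )
        )

    condition_occurrence = pd.concat(cond_frames, ignore_index=True)

    # --- note events: 1-3 postpartum well-child notes per baby --------------
    n_notes = rng_note.integers(1, 4, size=n)
    note_baby = np.repeat(np.arange(n), n_notes)
    note_day = rng_note.integers(1, 61, size=len(note_baby))
    note_event = pd.DataFrame(
        {
            "person_id": baby_ids[note_baby],
            "note_type": "well_child",
            "note_date": delivery[note_baby] + note_day.astype("timedelta64[D]"),
        }
    )

    # --- persons ------------------------------------------------------------
    mother_age = rng_person.integers(18, 46, size=n)
    mother_birth = (
        delivery
        - (mother_age * 365).astype("timedelta64[D]")
        - rng_person.integers(0, 365, size=n).astype("timedelta64[D]")
    )
    baby_gender = rng_person.choice(["F", "M"], size=n)
    person = pd.concat(
        [
            pd.DataFrame(
                {
                    "person_id": mother_ids,
                    "role": "mother",
                    "gender": "F",
                    "birth_date": mother_birth,
                }
            ),
            pd.DataFrame(
                {
                    "person_id": baby_ids,
                    "role": "baby",
                    "gender": baby_gender,
                    "birth_date": delivery,
                }
            ),
        ],
        ignore_index=True,
    )

    tables = {
        "person": person,
        "mother_baby_link": pd.DataFrame({"mother_id": mother_ids, "baby_id": baby_ids}),
        "drug_exposure": drug_exposure,
        "condition_occurrence": condition_occurrence,
        "note_event": note_event,
    }
    for name in ("drug_exposure", "condition_occurrence", "note_event"):
        date_col = [c for c in tables[name].columns if c.endswith("date")][0]
        tables[name] = (
            tables[name]
            .sort_values(["person_id", date_col] + (["condition_code"] if name == "condition_occurrence" else []))
            .reset_index(drop=True)
        )

    truth = SyntheticTruth(
        episodes=pd.DataFrame(
            {
                "mother_id": mother_ids,
                "baby_id": baby_ids,
                "pregnancy_start": start,
                "delivery_date": delivery,
                "gestational_age_days": ga,
            }
        ),
        exposures=pd.DataFrame(
            {
                "baby_id": baby_ids[dyad_idx],
                "drug": [drug_token(i) for i in drug_idx],
                "trimester": tri + 1,
                "drug_exposure_date": exp_date,
            }
        ),
        effects=truth_effects,
    )
    return tables, truth


# --------------------------------------------------------------------------
# synthetic vocabulary matching the generated codes
# --------------------------------------------------------------------------

def synthetic_phecode_frame(config: SimulationConfig) -> pd.DataFrame:
    """Phecode-map rows (phecode-map CSV dialect) for the synthetic ICD codes."""
    rows = []
    for i in range(config.n_phecodes):
        p = phecode_id(i)
        for which in (0, 1):
            rows.append(
                {
                    "icd": f"SYN{i:03d}.{which}",
                    "vocabulary": "ICD10",
                    "phecode": p,
                    "exclusion_range": p,
                    "label": f"synthetic phenotype {i}",
                }
            )
    return pd.DataFrame(rows)


def synthetic_drug_frame(config: SimulationConfig) -> pd.DataFrame:
    """Drug-map rows (token, atc4, nutraceutical, otc) for the synthetic drugs."""
    nutr = {
        drug_token(d) if isinstance(d, (int, np.integer)) else str(d)
        for d in config.nutraceutical_drug_ids
    }
    rows = []
    for i in range(config.n_drugs):
        tok = drug_token(i)
        rows.append(
            {
                "token": tok,
                "atc4": _atc4_for(i),
                "nutraceutical": int(tok in nutr),
                "otc": int(tok in nutr),
            }
        )
    return pd.DataFrame(rows)


def write_population(
    tables: dict[str, pd.DataFrame],
    truth: SyntheticTruth,
    outdir: str | Path,
    config: SimulationConfig | None = None,
) -> Path:
    """Write tables as TSV (ISO-8601 dates), truth.json, and — when the
    config is given — the matching synthetic vocabulary files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        df = tables[name].copy()
        for c in df.columns:
            if np.issubdtype(df[c].dtype, np.datetime64):
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    if config is not None:
        synthetic_phecode_frame(config).to_csv(outdir / "phecode_map.csv", index=False)
        synthetic_drug_frame(config).to_csv(outdir / "drug_map.tsv", sep="\t", index=False)
    return outdir


def load_population(datadir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five TSV tables back, parsing dates."""
    datadir = Path(datadir)
    tables = {}
    for name in TABLE_NAMES:
        df = pd.read_csv(datadir / f"{name}.tsv", sep="\t", dtype=str)
        for c in df.columns:
            if c.endswith("date"):
                df[c] = pd.to_datetime(df[c])
        tables[name] = df
    return tables


# --------------------------------------------------------------------------
# targeted ablation for inclusion-rule tests
# --------------------------------------------------------------------------

def ablate_population(
    tables: dict[str, pd.DataFrame],
    n_unlink: int = 0,
    n_drop_delivery: int = 0,
    n_drop_medications: int = 0,
    n_drop_notes: int = 0,
    dictionary: GestationDictionary | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Knock out inclusion-rule prerequisites for disjoint sets of dyads.

    Targets are drawn only among dyads that currently satisfy the full
    inclusion rule, so each ablated dyad fails exactly the rule whose data
    were removed and the consort tally shifts by exactly the planted counts.

    Returns the ablated tables and the planted counts keyed by the consort
    exclusion reason.
    """
    from .cohort import apply_inclusion_rule  # local import to avoid a cycle

    dictionary = dictionary or default_dictionary()
    dyads, _ = apply_inclusion_rule(tables, dictionary)
    eligible = [d.baby_id for d in dyads]
    total = n_unlink + n_drop_delivery + n_drop_medications + n_drop_notes
    if total > len(eligible):
        raise ValueError(
            f"cannot ablate {total} dyads: only {len(eligible)} pass the inclusion rule"
        )
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(eligible, size=total, replace=False))
    groups = {
        "no_mother_baby_link": set(picked[:n_unlink]),
        "no_determinable_episode": set(picked[n_unlink : n_unlink + n_drop_delivery]),
        "no_gestational_medication": set(
            picked[n_unlink + n_drop_delivery : n_unlink + n_drop_delivery + n_drop_medications]
        ),
        "no_postpartum_note": set(picked[n_unlink + n_drop_delivery + n_drop_medications :]),
    }

    link = tables["mother_baby_link"]
    baby_to_mother = dict(zip(link["baby_id"], link["mother_id"]))
    out = {k: v.copy() for k, v in tables.items()}

    out["mother_baby_link"] = link[~link["baby_id"].isin(groups["no_mother_baby_link"])]

    mothers_no_epi = {baby_to_mother[b] for b in groups["no_determinable_episode"]}
    cond = out["condition_occurrence"]
    is_delivery = cond["condition_code"].isin(dictionary.delivery_codes)
    out["condition_occurrence"] = cond[
        ~(cond["person_id"].isin(mothers_no_epi) & is_delivery)
    ]

    mothers_no_med = {baby_to_mother[b] for b in groups["no_gestational_medication"]}
    de = out["drug_exposure"]
    out["drug_exposure"] = de[~de["person_id"].isin(mothers_no_med)]

    ne = out["note_event"]
    out["note_event"] = ne[~ne["person_id"].isin(groups["no_postpartum_note"])]

    for name in out:
        out[name] = out[name].reset_index(drop=True)
    planted = {k: len(v) for k, v in groups.items()}
    return out, planted
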