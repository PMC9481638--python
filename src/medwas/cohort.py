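"""Cohort construction: inclusion phenotyping rule and exposure cohorts.

The unit of analysis is the mother-baby *dyad*.  A dyad enters the study
population when (a) a mother-baby link exists, (b) the mother's pregnancy
episode is determinable from coded events, (c) at least one maternal
medication is dated inside the gestational window, and (d) the baby's record
shows at least one postpartum clinic note (evidence of neonatal care at the
institution, i.e. outcomes are observable).  Exclusions are tallied by their
first failing rule into a consort-style log.

For each drug entity (ingredient token or ATC-4 class) the exposed cohort is
every eligible dyad with >= 1 gestational exposure to it; the control cohort
is simply every other eligible dyad — no matching or propensity scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pregnancy import (
    TRIMESTER_CUTPOINTS,
    GestationDictionary,
    PregnancyEpisode,
)
from .vocab import DrugMap, map_drug_to_atc4

logger = logging.getLogger(__name__)

#: consort-log exclusion reasons, in evaluation order.
EXCLUSION_REASONS = (
    "no_mother_baby_link",
    "no_determinable_episode",
    "no_gestational_medication",
    "no_postpartum_note",
)


@dataclass(frozen=True)
class ExposureRecord:
    """One retained (gestational) maternal exposure."""

    drug_token: str
    atc4: str
    date: object
    gestational_day: int
    trimester: int


@dataclass
class MotherBabyDyad:
    """A linked maternal and neonatal record pair with one pregnancy episode."""

    mother_id: str
    baby_id: str
    episode: PregnancyEpisode
    exposures: list[ExposureRecord] = field(default_factory=list)

    @property
    def arithmetic_default(self) -> bool:
        """True when the episode was dated by the 280-day fallback (flagged
        for sensitivity re-runs; such dyads are retained)."""
        return self.episode.method == "arithmetic_default"

    def exposed_entities(self, level: str = "atc4", window: object = "all") -> set[str]:
        """Drug entities this dyad is exposed to within a window.

        ``level`` is ``"atc4"`` or ``"token"``; ``window`` is ``"all"`` or a
        trimester number 1-3.
        """
        out = set()
        for e in self.exposures:
            if window != "all" and e.trimester != window:
                continue
            out.add(e.atc4 if level == "atc4" else e.drug_token)
        return out


@dataclass
class ExposureCohort:
    """Exposed / control dyad split for one drug entity."""

    drug: str
    exposed: set[str]
    control: set[str]

    def __post_init__(self) -> None:
        if self.exposed & self.control:
            raise ValueError("exposed and control cohorts overlap")


def _infer_episodes_bulk(
    cond: pd.DataFrame, mothers: pd.Index, dictionary: GestationDictionary
) -> pd.DataFrame:
    """Vectorised episode inference for many mothers at once.

    Replicates :func:`medwas.pregnancy.infer_episode` exactly (delivery =
    latest delivery-coded event; week code nearest on/before delivery, ties
    to the larger week; gestational-age cap with 280-day fallback).  Mothers
    without a delivery code are absent from the result.
    """
    from .pregnancy import DEFAULT_GESTATIONAL_AGE_DAYS, GESTATIONAL_AGE_CAP

    ev = cond[cond["person_id"].isin(mothers)].copy()
    codes = ev["condition_code"].astype(str).str.strip()
    dates = pd.to_datetime(ev["condition_date"])

    is_deliv = codes.isin(dictionary.delivery_codes)
    delivery = (
        pd.DataFrame({"person_id": ev.loc[is_deliv, "person_id"], "d": dates[is_deliv]})
        .groupby("person_id")["d"]
        .max()
    )
    if delivery.empty:
        return pd.DataFrame(
            columns=["delivery_date", "gestational_age_days", "method"]
        )

    weeks = codes.map(dictionary.week_codes)
    wk = pd.DataFrame(
        {
            "person_id": ev.loc[weeks.notna(), "person_id"],
            "date": dates[weeks.notna()],
            "weeks": weeks[weeks.notna()].astype(int),
        }
    )
    wk = wk.merge(
        delivery.rename("delivery"), left_on="person_id", right_index=True
    ).reset_index(drop=True)
    wk = wk[wk["date"] <= wk["delivery"]]
    # nearest to delivery, ties -> larger week value
    wk = wk.sort_values(["person_id", "date", "weeks"]).groupby("person_id").tail(1)
    wk["ga"] = 7 * wk["weeks"] + (wk["delivery"] - wk["date"]).dt.days

    epi = delivery.rename("delivery_date").to_frame()
    epi["gestational_age_days"] = epi.index.map(wk.set_index("person_id")["ga"])
    epi["method"] = np.where(epi["gestational_age_days"].notna(), "dictionary", "arithmetic_default")
    out_of_cap = epi["gestational_age_days"].notna() & ~epi["gestational_age_days"].between(
        *GESTATIONAL_AGE_CAP
    )
    if out_of_cap.any():
        logger.warning(
            "%d mothers: dictionary gestational age outside cap %s; using %d-day fallback",
            int(out_of_cap.sum()),
            GESTATIONAL_AGE_CAP,
            DEFAULT_GESTATIONAL_AGE_DAYS,
        )
        epi.loc[out_of_cap, "method"] = "arithmetic_default"
        epi.loc[out_of_cap, "gestational_age_days"] = np.nan
    epi["gestational_age_days"] = (
        epi["gestational_age_days"].fillna(DEFAULT_GESTATIONAL_AGE_DAYS).astype(int)
    )
    return epi


def apply_inclusion_rule(
    tables: dict[str, pd.DataFrame],
    dictionary: GestationDictionary,
    drug_map: DrugMap | None = None,
) -> tuple[list[MotherBabyDyad], pd.DataFrame]:
    """Apply the inclusion phenotyping rule; return retained dyads + consort log.

    The consort log is a DataFrame ``(reason, count)`` covering, in order:
    babies without a mother link, undeterminable episodes, no gestational
    medication, no postpartum note, and the retained count.  Each excluded
    dyad is counted once, under its first failing rule.
    """
    import datetime as _dt

    person = tables["person"]
    link = tables["mother_baby_link"]
    cond = tables["condition_occurrence"]
    meds = tables["drug_exposure"]
    notes = tables["note_event"]

    tally = {r: 0 for r in EXCLUSION_REASONS}

    babies = set(person.loc[person["role"] == "baby", "person_id"])
    linked_babies = set(link["baby_id"])
    tally["no_mother_baby_link"] = len(babies - linked_babies)

    epi = _infer_episodes_bulk(cond, pd.Index(link["mother_id"]), dictionary)
    has_episode = link["mother_id"].isin(epi.index)
    tally["no_determinable_episode"] = int((~has_episode).sum())
    link_ok = link[has_episode]

    # gestational exposures, vectorised across all mothers with an episode
    m = meds.merge(epi, left_on="person_id", right_index=True, how="inner").reset_index(
        drop=True
    )
    if len(m):
        m = m.assign(
            _date=pd.to_datetime(m["drug_exposure_date"]),
            _delivery=pd.to_datetime(m["delivery_date"]),
        )
        m["gestational_day"] = (
            m["_date"] - (m["_delivery"] - pd.to_timedelta(m["gestational_age_days"], "D"))
        ).dt.days
        m = m[(m["gestational_day"] >= 0) & (m["gestational_day"] < m["gestational_age_days"])]
        c1, c2 = TRIMESTER_CUTPOINTS
        m["trimester"] = np.select(
            [m["gestational_day"] < c1, m["gestational_day"] < c2], [1, 2], default=3
        )
    exposures_by_mother: dict[str, list[ExposureRecord]] = {}
    if len(m):
        atc_cache: dict[str, str] = {}
        for mid, tok, date, day, tri in zip(
            m["person_id"], m["drug_token"], m["_date"], m["gestational_day"], m["trimester"]
        ):
            tok = str(tok)
            if drug_map is not None:
                atc4 = atc_cache.get(tok)
                if atc4 is None:
                    atc4 = map_drug_to_atc4(tok, drug_map)
                    atc_cache[tok] = atc4
            else:
                atc4 = tok
            exposures_by_mother.setdefault(mid, []).append(
                ExposureRecord(
                    drug_token=tok,
                    atc4=atc4,
                    date=date,
                    gestational_day=int(day),
                    trimester=int(tri),
                )
            )
    has_med = link_ok["mother_id"].isin(exposures_by_mother)
    tally["no_gestational_medication"] = int((~has_med).sum())
    link_ok = link_ok[has_med]

    # postpartum note: any baby note dated on/after the mother's delivery
    nt = notes.merge(link_ok, left_on="person_id", right_on="baby_id")
    nt = nt.merge(epi["delivery_date"], left_on="mother_id", right_index=True)
    postpartum_babies = set(
        nt.loc[pd.to_datetime(nt["note_date"]) >= nt["delivery_date"], "baby_id"]
    )
    has_note = link_ok["baby_id"].isin(postpartum_babies)
    tally["no_postpartum_note"] = int((~has_note).sum())
    link_ok = link_ok[has_note]

    dyads: list[MotherBabyDyad] = []
    epi_ok = epi.loc[link_ok["mother_id"]]
    for (mid, bid), delivery, ga, method in zip(
        link_ok.itertuples(index=False),
        epi_ok["delivery_date"],
        epi_ok["gestational_age_days"],
        epi_ok["method"],
    ):
        delivery_d = delivery.date() if hasattr(delivery, "date") else delivery
        episode = PregnancyEpisode(
            mother_id=mid,
            pregnancy_start=delivery_d - _dt.timedelta(days=int(ga)),
            delivery_date=delivery_d,
            gestational_age_days=int(ga),
            method=method,
        )
        dyads.append(
            MotherBabyDyad(
                mother_id=mid,
                baby_id=bid,
                episode=episode,
                exposures=exposures_by_mother[mid],
            )
        )

    consort = pd.DataFrame(
        [{"reason": r, "count": tally[r]} for r in EXCLUSION_REASONS]
        + [{"reason": "retained", "count": len(dyads)}]
    )
    return dyads, consort


def build_exposure_cohorts(
    dyads: list[MotherBabyDyad],
    drug: str,
    window: object = "all",
    level: str = "atc4",
) -> ExposureCohort:
    """Split eligible dyads into exposed / control for one drug entity.

    ``window="all"`` (the scan default) counts any gestational exposure;
    a trimester number restricts to exposures in that trimester.  Exposure
    to any member drug of an ATC-4 class counts once (set semantics).
    """
    if window not in ("all", 1, 2, 3):
        raise ValueError(f"window must be 'all' or 1-3, got {window!r}")
    exposed = {d.baby_id for d in dyads if drug in d.exposed_entities(level, window)}
    control = {d.baby_id for d in dyads} - exposed
    if not exposed:
        logger.warning("drug %r: no exposed dyads", drug)
    return ExposureCohort(drug=drug, exposed=exposed, control=control)


def exposure_matrix(
    dyads: list[MotherBabyDyad], panel: list[str], window: object = "all", level: str = "atc4"
) -> pd.DataFrame:
    """Boolean dyad × drug-entity exposure matrix (index: baby_id)."""
    idx = pd.Index([d.baby_id for d in dyads], name="person_id")
    col_pos = {c: j for j, c in enumerate(panel)}
    arr = np.zeros((len(dyads), len(panel)), dtype=bool)
    for i, d in enumerate(dyads):
        for ent in d.exposed_entities(level, window):
            j = col_pos.get(ent)
            if j is not None:
                arr[i, j] = True
    return pd.DataFrame(arr, index=idx, columns=list(panel))


def write_consort(consort: pd.DataFrame, path: str | Path) -> None:
    consort.to_csv(path, sep="\t", index=False)
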