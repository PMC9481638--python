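"""Vocabulary mapping: ICD→phecode with exclusion semantics, drug→ATC-4.

Phecodes aggregate ICD-9/10 billing codes into clinically coherent
phenotypes and attach *exclusion ranges*: a child who is not a case for a
phecode but carries a diagnosis in its exclusion range is removed from the
control pool for that phenotype (standard PheWAS case/control semantics).
Drugs are aggregated to ATC level 4 (chemical subgroup, e.g. ``N03AX``),
the representation that balances granularity against power — agent classes
rather than formulations.

The package never ships licensed vocabularies; loaders read the standard
phecode-map CSV dialect and a simple drug-map TSV, and a small synthetic
fixture is bundled for tests and simulations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED_ATC4 = "UNMAPPED"

_ATC4_RE = re.compile(r"^[A-Z]\d\d[A-Z]{1,2}$")
_VOCABULARIES = {"ICD9", "ICD10"}


class PhecodeMapError(ValueError):
    """Malformed phecode-map file."""


class UnknownPhenotypeError(KeyError):
    """Phecode absent from the loaded map."""


def _parse_range(token: str) -> tuple[float, float]:
    token = token.strip()
    if "-" in token:
        lo, hi = token.split("-", 1)
        return float(lo), float(hi)
    v = float(token)
    return v, v


@dataclass
class PhecodeMap:
    """ICD→phecode map with control-exclusion ranges.

    Attributes
    ----------
    entries
        ``(icd_code, vocabulary)`` → set of phecode ids (strings).
    exclusion_ranges
        phecode id → list of numeric ``(lo, hi)`` phecode ranges whose
        carriers are ineligible controls.  Always includes the phecode
        itself.
    labels
        phecode id → display string.
    """

    entries: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    exclusion_ranges: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def phecodes(self) -> list[str]:
        out: set[str] = set()
        for v in self.entries.values():
            out |= v
        return sorted(out)

    def codes_for(self, icd: str, vocabulary: str) -> set[str]:
        return self.entries.get((str(icd).strip(), vocabulary), set())

    def in_exclusion_range(self, phecode: str, other: str) -> bool:
        """Does phecode ``other`` fall in ``phecode``'s exclusion range?"""
        if phecode not in self.exclusion_ranges:
            raise UnknownPhenotypeError(phecode)
        try:
            val = float(other)
        except ValueError:
            return other == phecode
        return any(lo <= val <= hi for lo, hi in self.exclusion_ranges[phecode])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"icd": icd, "vocabulary": voc, "phecode": p}
            for (icd, voc), ps in self.entries.items()
            for p in ps
        ]
        return pd.DataFrame(rows, columns=["icd", "vocabulary", "phecode"])


def load_phecode_map(path: str | Path) -> PhecodeMap:
    """Load a phecode map from CSV (columns: icd, vocabulary, phecode,
    exclusion_range optional, label optional).

    Duplicate rows are deduplicated; rows with an empty phecode are counted
    and logged as unmapped.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"icd", "vocabulary", "phecode"}
    missing = required - set(df.columns)
    if missing:
        raise PhecodeMapError(f"{path}: missing columns {sorted(missing)}")

    pmap = PhecodeMap()
    n_unmapped = 0
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        icd = row["icd"].strip()
        voc = row["vocabulary"].strip()
        phe = row["phecode"].strip()
        if voc not in _VOCABULARIES:
            raise PhecodeMapError(
                f"{path} line {line}: unknown vocabulary {voc!r} (expected ICD9|ICD10)"
            )
        if not phe:
            n_unmapped += 1
            continue
        try:
            float(phe)
        except ValueError:
            raise PhecodeMapError(f"{path} line {line}: non-numeric phecode {phe!r}")
        pmap.entries.setdefault((icd, voc), set()).add(phe)
        ranges = pmap.exclusion_ranges.setdefault(phe, [])
        excl = row.get("exclusion_range", "")
        if excl:
            try:
                rng = _parse_range(excl)
            except ValueError:
                raise PhecodeMapError(
                    f"{path} line {line}: malformed exclusion_range {excl!r}"
                )
            if rng not in ranges:
                ranges.append(rng)
        self_rng = (float(phe), float(phe))
        if not any(lo <= self_rng[0] <= hi for lo, hi in ranges):
            ranges.append(self_rng)
        label = row.get("label", "")
        if label:
            pmap.labels[phe] = label

    if not pmap.entries:
        logger.warning("%s: phecode map is empty", path)
    if n_unmapped:
        logger.info("%s: %d rows without a phecode (unmapped)", path, n_unmapped)
    return pmap


@dataclass
class DrugMap:
    """Drug token → ATC-4 class, with nutraceutical / OTC flags."""

    atc4: dict[str, str] = field(default_factory=dict)
    nutraceutical: set[str] = field(default_factory=set)
    otc: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.atc4.items() if not _ATC4_RE.match(c)}
        if bad:
            raise ValueError(f"non-ATC-4 class codes: {bad}")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.atc4.values()))


def load_drug_map(path: str | Path) -> DrugMap:
    """Load a drug map from TSV (columns: token, atc4, nutraceutical, otc)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"token", "atc4"}
    if required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    truthy = {"1", "true", "yes", "y"}
    dm = DrugMap(
        atc4={r["token"].strip(): r["atc4"].strip() for _, r in df.iterrows()},
        nutraceutical={
            r["token"].strip()
            for _, r in df.iterrows()
            if str(r.get("nutraceutical", "")).strip().lower() in truthy
        },
        otc={
            r["token"].strip()
            for _, r in df.iterrows()
            if str(r.get("otc", "")).strip().lower() in truthy
        },
    )
    return dm


def map_drug_to_atc4(token: str, drug_map: DrugMap) -> str:
    """ATC-4 class for a drug token; unmapped tokens route to ``"UNMAPPED"``."""
    cls = drug_map.atc4.get(str(token).strip())
    if cls is None:
        logger.info("drug token %r has no ATC-4 mapping; routed to %s", token, UNMAPPED_ATC4)
        return UNMAPPED_ATC4
    return cls


@dataclass(frozen=True)
class PhenotypeStatus:
    """Case/control/excluded assignment of one baby for one phecode."""

    baby_id: str
    phecode: str
    status: str  # "case" | "control" | "excluded"
    code_count: int


def assign_phenotype_status(
    baby_events: pd.DataFrame,
    phecode: str,
    phecode_map: PhecodeMap,
    min_code_count: int = 1,
    apply_exclusions: bool = True,
    baby_id: str = "",
) -> PhenotypeStatus:
    """Assign case/control/excluded status for one baby and one phecode.

    A baby is a **case** if events on at least ``min_code_count`` distinct
    dates map to the phecode (same-day duplicate billing counts once);
    **excluded** if not a case but some event maps into the phecode's
    exclusion range; otherwise a **control**.
    """
    if min_code_count < 1:
        raise ValueError("min_code_count must be >= 1")
    if phecode not in phecode_map.exclusion_ranges:
        raise UnknownPhenotypeError(phecode)

    dates_with_code: set = set()
    excluded_hit = False
    for _, row in baby_events.iterrows():
        voc = row.get("vocabulary", "ICD10")
        mapped = phecode_map.codes_for(row["condition_code"], voc)
        if phecode in mapped:
            dates_with_code.add(row["condition_date"])
        if apply_exclusions and any(
            phecode_map.in_exclusion_range(phecode, m) for m in mapped
        ):
            excluded_hit = True

    count = len(dates_with_code)
    if count >= min_code_count:
        status = "case"
    elif excluded_hit:
        status = "excluded"
    else:
        status = "control"
    return PhenotypeStatus(baby_id=baby_id, phecode=phecode, status=status, code_count=count)


def phenotype_status_matrix(
    condition_occurrence: pd.DataFrame,
    baby_ids: pd.Index | list[str],
    phecode_panel: list[str],
    phecode_map: PhecodeMap,
    min_code_count: int = 1,
    apply_exclusions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised case/excluded matrices over a baby cohort and phecode panel.

    Returns ``(case, excluded)`` boolean DataFrames indexed by ``baby_ids``
    with one column per panel phecode.  ``excluded`` is True only where
    ``case`` is False, so the three statuses partition every cell.
    """
    baby_ids = pd.Index(baby_ids, name="person_id")
    for p in phecode_panel:
        if p not in phecode_map.exclusion_ranges:
            raise UnknownPhenotypeError(p)

    case = pd.DataFrame(False, index=baby_ids, columns=list(phecode_panel))
    excl = pd.DataFrame(False, index=baby_ids, columns=list(phecode_panel))

    ev = condition_occurrence[condition_occurrence["person_id"].isin(baby_ids)]
    if ev.empty:
        return case, excl

    map_df = phecode_map.to_frame()
    voc = ev["vocabulary"] if "vocabulary" in ev.columns else "ICD10"
    ev = ev.assign(vocabulary=voc)
    merged = ev.merge(
        map_df,
        left_on=["condition_code", "vocabulary"],
        right_on=["icd", "vocabulary"],
        how="inner",
    )
    if merged.empty:
        return case, excl

    # distinct-date counting per (baby, phecode)
    counts = (
        merged.drop_duplicates(["person_id", "phecode", "condition_date"])
        .groupby(["person_id", "phecode"])
        .size()
    )
    cases = counts[counts >= min_code_count].reset_index()[["person_id", "phecode"]]
    for p in phecode_panel:
        ids = cases.loc[cases["phecode"] == p, "person_id"]
        case.loc[case.index.isin(ids), p] = True

    if apply_exclusions:
        carried = merged[["person_id", "phecode"]].drop_duplicates()
        carried_val = carried.assign(val=carried["phecode"].astype(float))
        for p in phecode_panel:
            mask = np.zeros(len(carried_val), dtype=bool)
            for lo, hi in phecode_map.exclusion_ranges[p]:
                mask |= (carried_val["val"].to_numpy() >= lo) & (
                    carried_val["val"].to_numpy() <= hi
                )
            ids = carried_val.loc[mask, "person_id"].unique()
            excl.loc[excl.index.isin(ids), p] = True
        excl &= ~case  # cases stay cases

    return case, excl
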