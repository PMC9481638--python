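"""Gestational-window inference from coded EHR events.

Defining the period of gestation is the central data-engineering problem in
EHR pharmacoepidemiology of pregnancy: prescriptions can only be classified
as gestational exposures once each mother's pregnancy window is known.  Two
strategies are implemented here:

* **dictionary inference** — a data dictionary of gestational-period ICD-10
  codes (``Z3A.NN`` completed-week codes, delivery codes such as ``O80`` /
  ``Z37``) anchors the window: the delivery date is the latest delivery-coded
  event, and gestational age is reconstructed from the week code nearest the
  delivery plus the day offset between that event and delivery;
* **arithmetic fallback** — when no week code is available, gestational age
  defaults to 280 days (40 weeks subtracted from the delivery date), the
  crude first-pass estimate used when dictionary signals are missing.

Dating is LMP-anchored: gestational day 0 is the first day of the last
menstrual period, the clinical convention under which term is 280 days and
``Z3A`` week codes are expressed.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: gestational ages outside this range (in days) are treated as dictionary
#: noise and replaced by the arithmetic default.
GESTATIONAL_AGE_CAP = (140, 315)

#: arithmetic fallback: 40 weeks.
DEFAULT_GESTATIONAL_AGE_DAYS = 280

#: completed-week trimester cutpoints (14 and 28 weeks), half-open intervals.
TRIMESTER_CUTPOINTS = (98, 196)

OUT_OF_WINDOW = None


class EpisodeUndeterminableError(ValueError):
    """No delivery-coded event: the pregnancy episode cannot be anchored."""


@dataclass(frozen=True)
class GestationDictionary:
    """Code dictionary driving dictionary-based gestational inference.

    Parameters
    ----------
    week_codes
        Map from code token (e.g. ``"Z3A.32"``) to completed weeks of
        gestation, an integer in ``[1, 45]``.
    delivery_codes
        Code tokens signalling a delivery (e.g. ``"O80"``, ``"Z37.0"``).
    pregnancy_marker_codes
        Codes signalling an ongoing pregnancy; carried for completeness,
        not used by the inference rule itself.
    """

    week_codes: dict[str, int]
    delivery_codes: frozenset[str]
    pregnancy_marker_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.week_codes or not self.delivery_codes:
            raise ValueError(
                "GestationDictionary requires non-empty week_codes and delivery_codes"
            )
        bad = {c: w for c, w in self.week_codes.items() if not 1 <= int(w) <= 45}
        if bad:
            raise ValueError(f"week codes outside [1, 45]: {bad}")
        object.__setattr__(self, "delivery_codes", frozenset(self.delivery_codes))
        object.__setattr__(
            self, "pregnancy_marker_codes", frozenset(self.pregnancy_marker_codes)
        )


def default_dictionary() -> GestationDictionary:
    """Bundled dictionary with Z3A-style week tokens and O80/Z37-style delivery tokens."""
    weeks = {f"Z3A.{w:02d}": w for w in range(1, 45)}
    delivery = {"O80", "O81", "O82", "O84", "Z37.0", "Z37.2", "Z37.9"}
    markers = {"Z33.1", "Z34.9"}
    return GestationDictionary(weeks, frozenset(delivery), frozenset(markers))


def load_dictionary(path: str | Path) -> GestationDictionary:
    """Load a dictionary from TSV with columns ``code``, ``kind``, ``weeks``.

    ``kind`` is one of ``week`` (requires ``weeks``), ``delivery``, ``marker``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"code": str, "kind": str})
    week_codes: dict[str, int] = {}
    delivery: set[str] = set()
    markers: set[str] = set()
    for i, row in df.iterrows():
        kind = str(row["kind"]).strip().lower()
        code = str(row["code"]).strip()
        if kind == "week":
            if pd.isna(row.get("weeks")):
                raise ValueError(f"{path} line {i + 2}: week row without 'weeks' value")
            week_codes[code] = int(row["weeks"])
        elif kind == "delivery":
            delivery.add(code)
        elif kind == "marker":
            markers.add(code)
        else:
            raise ValueError(f"{path} line {i + 2}: unknown kind {kind!r}")
    return GestationDictionary(week_codes, frozenset(delivery), frozenset(markers))


@dataclass(frozen=True)
class PregnancyEpisode:
    """One inferred pregnancy episode (LMP-anchored gestational window)."""

    mother_id: str
    pregnancy_start: _dt.date
    delivery_date: _dt.date
    gestational_age_days: int
    method: str  # "dictionary" | "arithmetic_default"

    def __post_init__(self) -> None:
        if self.pregnancy_start >= self.delivery_date:
            raise ValueError("pregnancy_start must precede delivery_date")
        if (self.delivery_date - self.pregnancy_start).days != self.gestational_age_days:
            raise ValueError("gestational_age_days inconsistent with dates")

    @property
    def trimester_bounds(self) -> tuple[tuple[int, int], ...]:
        """Three half-open day intervals partitioning ``[0, gestational_age_days)``."""
        ga = self.gestational_age_days
        c1 = min(TRIMESTER_CUTPOINTS[0], ga)
        c2 = min(TRIMESTER_CUTPOINTS[1], ga)
        return ((0, c1), (c1, c2), (c2, ga))


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return pd.Timestamp(d).date()


def infer_episode(
    mother_events: pd.DataFrame | Iterable[tuple[str, object]],
    dictionary: GestationDictionary,
    mother_id: str = "",
) -> PregnancyEpisode:
    """Infer a :class:`PregnancyEpisode` from a mother's dated diagnosis events.

    Parameters
    ----------
    mother_events
        Either a DataFrame with columns ``condition_code`` and
        ``condition_date`` (any pandas-parsable dates), or an iterable of
        ``(code, date)`` pairs.  Event order is irrelevant.
    dictionary
        The gestational code dictionary.

    Raises
    ------
    EpisodeUndeterminableError
        If no delivery-coded event is present.

    Notes
    -----
    Delivery date is the **latest** delivery-coded event.  If at least one
    gestational-week code dated on/before delivery exists, the one closest to
    delivery wins (ties broken toward the larger week value — later dating is
    usually ultrasound-corrected), and

    ``gestational_age_days = 7 * weeks + (delivery_date - week_event_date)``

    capped to ``[140, 315]``; values outside the cap, or a missing week code,
    fall back to exactly 280 days (``method="arithmetic_default"``).
    """
    if isinstance(mother_events, pd.DataFrame):
        pairs = zip(
            mother_events["condition_code"].astype(str),
            mother_events["condition_date"],
        )
    else:
        pairs = iter(mother_events)

    delivery_dates: list[_dt.date] = []
    week_events: list[tuple[_dt.date, int]] = []
    for code, date in pairs:
        code = str(code).strip()
        if code in dictionary.delivery_codes:
            delivery_dates.append(_as_date(date))
        elif code in dictionary.week_codes:
            week_events.append((_as_date(date), dictionary.week_codes[code]))

    if not delivery_dates:
        raise EpisodeUndeterminableError(
            f"mother {mother_id or '<unknown>'}: no delivery-coded event"
        )
    delivery = max(delivery_dates)

    candidates = [(d, w) for d, w in week_events if d <= delivery]
    method = "dictionary"
    if candidates:
        # nearest to delivery; ties -> larger week value
        event_date, weeks = max(candidates, key=lambda t: (t[0], t[1]))
        ga = 7 * weeks + (delivery - event_date).days
        if not GESTATIONAL_AGE_CAP[0] <= ga <= GESTATIONAL_AGE_CAP[1]:
            logger.warning(
                "mother %s: dictionary gestational age %d days outside cap %s; "
                "falling back to %d",
                mother_id,
                ga,
                GESTATIONAL_AGE_CAP,
                DEFAULT_GESTATIONAL_AGE_DAYS,
            )
            ga = DEFAULT_GESTATIONAL_AGE_DAYS
            method = "arithmetic_default"
    else:
        ga = DEFAULT_GESTATIONAL_AGE_DAYS
        method = "arithmetic_default"

    return PregnancyEpisode(
        mother_id=mother_id,
        pregnancy_start=delivery - _dt.timedelta(days=ga),
        delivery_date=delivery,
        gestational_age_days=ga,
        method=method,
    )


def gestational_day(episode: PregnancyEpisode, d) -> int | None:
    """Day of gestation for date ``d`` (0-based), or ``None`` if out of window.

    The window is half-open: the delivery date itself is out of window.
    """
    offset = (_as_date(d) - episode.pregnancy_start).days
    if 0 <= offset < episode.gestational_age_days:
        return offset
    return OUT_OF_WINDOW


def trimester_of(episode: PregnancyEpisode, d) -> int | None:
    """Trimester (1, 2 or 3) containing date ``d``, or ``None`` if out of window."""
    day = gestational_day(episode, d)
    if day is None:
        return OUT_OF_WINDOW
    for t, (lo, hi) in enumerate(episode.trimester_bounds, start=1):
        if lo <= day < hi:
            return t
    return OUT_OF_WINDOW  # pragma: no cover - bounds partition the window
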