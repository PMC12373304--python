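"""Treatment-session construction and pre-treatment cohort derivation.

A treatment session is a continuous period of exposure to generally the same
active ingredients, built by a greedy chronological merge of raw exposure
records. A candidate record joins the open session when any of three rules
holds, all parameterized by a 40-day threshold:

1. its ingredient set equals the session's ingredient union and the gap from
   the session's latest end to the record's start is <= 40 days;
2. its ingredients are a proper subset of the union (a dropped component of
   the same regimen), the record is <= 40 days long, and the gap is <= 40;
3. it adds at least one new ingredient, starts within 40 days of the
   session's start, and is <= 40 days long (an early add-on).

Otherwise the record opens a new session. "Gap" is start_B minus the latest
end among session members; overlapping or abutting records (gap <= 0) always
satisfy the gap condition. All intervals are closed on both ends, so a
record's exposure length is end - start + 1.

Before session building, short isolated off-label records are removed: an
off-label record under 30 days long with no other record sharing an
ingredient within 30 days of its span is treated as occasional use for an
unrelated purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aomphen.errors import ContractError

GAP_DAYS = 40
SHORT_RECORD_DAYS = 40
OAOM_MIN_DAYS = 30
OAOM_NEIGHBOR_DAYS = 30
MEDIUM_EXPOSURE_DAYS = 112
PRE_PERIOD_DAYS = 365
INDEX_LEAD_DAYS = 4


@dataclass(frozen=True, order=True)
class ExposureRecord:
    person_id: int
    start_day: int
    end_day: int
    ingredients: frozenset = field(compare=False)
    is_off_label: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ContractError(f"record end_day {self.end_day} before start_day {self.start_day}")
        if not self.ingredients:
            raise ContractError("record must carry at least one ingredient")

    @property
    def length_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass
class TreatmentSession:
    session_id: int
    person_id: int
    member_records: list[ExposureRecord]

    @property
    def start_day(self) -> int:
        return min(r.start_day for r in self.member_records)

    @property
    def end_day(self) -> int:
        return max(r.end_day for r in self.member_records)

    @property
    def exposure_length_days(self) -> int:
        return self.end_day - self.start_day + 1

    @property
    def ingredients(self) -> frozenset:
        out: set = set()
        for r in self.member_records:
            out |= r.ingredients
        return frozenset(out)


@dataclass(frozen=True)
class PreAOMPeriod:
    period_id: int
    session_id: int
    person_id: int
    window_start: int  # inclusive
    window_end: int    # exclusive: the session start day
    index_day: int

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != PRE_PERIOD_DAYS:
            raise ContractError("pre-treatment window must span exactly 365 days")
        if not self.window_start <= self.index_day < self.window_end:
            raise ContractError("index day must fall inside the window")


@dataclass(frozen=True)
class MatchedPair:
    case_period_id: int
    control_period_id: int
    gender_match: bool
    age_diff_years: float
    date_diff_days: int


# ---------------------------------------------------------------------------
# record IO helpers

def records_from_frame(df: pd.DataFrame) -> list[ExposureRecord]:
    """Parse a drug_exposure table (ingredient_set as 'a|b|c') into records."""
    recs = [
        ExposureRecord(
            person_id=int(row.person_id),
            start_day=int(row.start_day),
            end_day=int(row.end_day),
            ingredients=frozenset(str(row.ingredient_set).split("|")),
            is_off_label=bool(row.is_off_label),
        )
        for row in df.itertuples(index=False)
    ]
    return sorted(recs)


def sessions_to_frame(sessions: list[TreatmentSession]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "person_id": [s.person_id for s in sessions],
            "start_day": [s.start_day for s in sessions],
            "end_day": [s.end_day for s in sessions],
            "exposure_length_days": [s.exposure_length_days for s in sessions],
            "n_records": [len(s.member_records) for s in sessions],
            "ingredient_set": ["|".join(sorted(s.ingredients)) for s in sessions],
        }
    )


def periods_to_frame(periods: list[PreAOMPeriod]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "period_id": [p.period_id for p in periods],
            "session_id": [p.session_id for p in periods],
            "person_id": [p.person_id for p in periods],
            "window_start": [p.window_start for p in periods],
            "window_end": [p.window_end for p in periods],
            "index_day": [p.index_day for p in periods],
        }
    )


# ---------------------------------------------------------------------------
# cohort operations

def _span_gap(a: ExposureRecord, b: ExposureRecord) -> int:
    """Days between the closed spans of two records; <= 0 when they overlap."""
    if b.start_day > a.end_day:
        return b.start_day - a.end_day
    if a.start_day > b.end_day:
        return a.start_day - b.end_day
    return 0


def filter_oaom_records(
    records: list[ExposureRecord],
    *,
    min_days: int = OAOM_MIN_DAYS,
    neighbor_days: int = OAOM_NEIGHBOR_DAYS,
) -> list[ExposureRecord]:
    """Drop short isolated off-label records.

    An off-label record shorter than ``min_days`` is removed unless some
    other record of the same patient shares an ingredient and comes within
    ``neighbor_days`` of its span. Everything else passes through unchanged.
    """
    by_person: dict[int, list[ExposureRecord]] = {}
    for r in records:
        by_person.setdefault(r.person_id, []).append(r)
    kept: list[ExposureRecord] = []
    for r in records:
        if not (r.is_off_label and r.length_days < min_days):
            kept.append(r)
            continue
        has_neighbor = any(
            other is not r
            and other.ingredients & r.ingredients
            and _span_gap(r, other) <= neighbor_days
            for other in by_person[r.person_id]
        )
        if has_neighbor:
            kept.append(r)
    return kept


def build_sessions(
    records: list[ExposureRecord],
    *,
    gap_days: int = GAP_DAYS,
    short_record_days: int = SHORT_RECORD_DAYS,
    first_session_id: int = 0,
) -> list[TreatmentSession]:
    """Greedy chronological merge of exposure records into treatment sessions.

    Records may span multiple patients; within each patient they must be
    sorted by start day. The open session's reference state is its
    ingredient union, its start day, and the latest end among its members.
    """
    by_person: dict[int, list[ExposureRecord]] = {}
    for r in records:
        by_person.setdefault(r.person_id, []).append(r)
    sessions: list[TreatmentSession] = []
    sid = first_session_id
    for pid in sorted(by_person):
        recs = by_person[pid]
        if any(recs[i].start_day > recs[i + 1].start_day for i in range(len(recs) - 1)):
            raise ContractError(f"records of person {pid} are not sorted by start_day")
        open_members: list[ExposureRecord] = []
        union: frozenset = frozenset()
        sess_start = sess_end = 0

        def close() -> None:
            nonlocal sid
            if open_members:
                sessions.append(TreatmentSession(sid, pid, list(open_members)))
                sid += 1

        for rec in recs:
            if not open_members:
                open_members = [rec]
                union, sess_start, sess_end = rec.ingredients, rec.start_day, rec.end_day
                continue
            gap = rec.start_day - sess_end
            rule1 = rec.ingredients == union and gap <= gap_days
            rule2 = (
                rec.ingredients < union
                and rec.length_days <= short_record_days
                and gap <= gap_days
            )
            rule3 = (
                bool(rec.ingredients - union)
                and rec.start_day - sess_start <= gap_days
                and rec.length_days <= short_record_days
            )
            if rule1 or rule2 or rule3:
                open_members.append(rec)
                union = union | rec.ingredients
                sess_end = max(sess_end, rec.end_day)
            else:
                close()
                open_members = [rec]
                union, sess_start, sess_end = rec.ingredients, rec.start_day, rec.end_day
        close()
    return sessions


def select_medium_long(
    sessions: list[TreatmentSession],
    *,
    min_days: int = MEDIUM_EXPOSURE_DAYS,
    strict_gt: bool = False,
) -> list[TreatmentSession]:
    """Keep sessions of medium-to-long exposure (>= 112 days by default)."""
    if strict_gt:
        return [s for s in sessions if s.exposure_length_days > min_days]
    return [s for s in sessions if s.exposure_length_days >= min_days]


def derive_pre_aom_periods(sessions: list[TreatmentSession]) -> list[PreAOMPeriod]:
    """One 365-day pre-treatment window per session; index day = start - 4."""
    return [
        PreAOMPeriod(
            period_id=i,
            session_id=s.session_id,
            person_id=s.person_id,
            window_start=s.start_day - PRE_PERIOD_DAYS,
            window_end=s.start_day,
            index_day=s.start_day - INDEX_LEAD_DAYS,
        )
        for i, s in enumerate(sessions)
    ]


def match_controls(
    case_periods: pd.DataFrame,
    control_candidates: pd.DataFrame,
    seed: int,
    *,
    max_age_diff_years: float = 1.0,
    max_date_diff_days: int = 365,
) -> tuple[list[MatchedPair], list[int]]:
    """Greedy 1:1 matching of case periods to normal-BMI control candidates.

    A pair requires identical gender, age within one year, and anchor dates
    within one year. Cases are visited in seeded random order; each picks the
    eligible unused candidate with the smallest (|age diff|, |date diff|).
    Returns (pairs, unmatched case period ids).
    """
    rng = np.random.default_rng(seed)
    case_order = case_periods.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    cands = control_candidates.reset_index(drop=True)
    used: set[int] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[int] = []
    c_gender = cands["gender"].to_numpy()
    c_age = cands["age_years"].to_numpy(dtype=float)
    c_day = cands["anchor_day"].to_numpy(dtype=int)
    c_id = cands["control_id"].to_numpy(dtype=int)
    for row in case_order.itertuples(index=False):
        age_diff = c_age - float(row.age_years)
        date_diff = c_day - int(row.anchor_day)
        eligible = (
            (c_gender == row.gender)
            & (np.abs(age_diff) <= max_age_diff_years)
            & (np.abs(date_diff) <= max_date_diff_days)
            & np.array([cid not in used for cid in c_id])
        )
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            unmatched.append(int(row.period_id))
            continue
        best = idx[np.lexsort((c_id[idx], np.abs(date_diff[idx]), np.abs(age_diff[idx])))[0]]
        used.add(int(c_id[best]))
        pairs.append(
            MatchedPair(
                case_period_id=int(row.period_id),
                control_period_id=int(c_id[best]),
                gender_match=True,
                age_diff_years=float(age_diff[best]),
                date_diff_days=int(date_diff[best]),
            )
        )
    return pairs, unmatched


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_period_id": [p.case_period_id for p in pairs],
            "control_period_id": [p.control_period_id for p in pairs],
            "age_diff_years": [p.age_diff_years for p in pairs],
            "date_diff_days": [p.date_diff_days for p in pairs],
        }
    )
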