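"""Prescription exposure episodes, the eight-state drug-exposure model, and
state transitions.

A patient's year of prescription fills for the three drug classes of
interest — opioids (O), benzodiazepines (B) and sedative-hypnotics (S) — is
reduced to a piecewise-constant trajectory over eight states: the empty
state, the three single-class states, the three two-class states, and the
all-three state (O+B+S), the riskiest form of polypharmacy.

The processing chain is:

1. :func:`merge_refills` joins refill chains of the same drug into merged
   exposure episodes using a 20%-of-previous-supply gap rule, so that a
   short gap before a refill is not mistaken for a discontinuation.
2. :func:`segment_intervals` cuts the study year into intervals on which the
   set of active drug classes is constant.
3. :func:`state_transitions` lists the boundaries at which the state
   changes; :func:`extract_prescribing_transitions` attaches responsible
   physicians to the transitions that add drug classes (prescribing).
   Down-transitions are attributed separately (see
   :mod:`presnet.deprescribe`).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DRUG_CLASSES",
    "STATE_CLASSES",
    "classify_state",
    "state_classes",
    "drug_count",
    "merge_refills",
    "segment_intervals",
    "state_transitions",
    "extract_prescribing_transitions",
]

#: the three monitored drug classes
DRUG_CLASSES = ("O", "B", "S")

#: year length in days (single study-year calendar)
YEAR_DAYS = 365

# state numbering: empty, singletons, pairs (by class order), full set
_STATE_ORDER = [
    frozenset(),
    frozenset("O"),
    frozenset("B"),
    frozenset("S"),
    frozenset("OB"),
    frozenset("OS"),
    frozenset("BS"),
    frozenset("OBS"),
]
_STATE_OF = {classes: i + 1 for i, classes in enumerate(_STATE_ORDER)}

#: state -> set of active classes (1-based state index)
STATE_CLASSES = {i + 1: classes for i, classes in enumerate(_STATE_ORDER)}

# number of active drug classes per state, indexed by state-1
_DRUG_COUNT = np.array([0, 1, 1, 1, 2, 2, 2, 3])


def classify_state(classes: Iterable[str]) -> int:
    """Map a set of active drug classes to the state index 1..8.

    The empty set is state 1 ("state zero", no monitored drugs); singleton
    classes O, B, S are states 2-4; pairs OB, OS, BS are states 5-7; the
    full set is state 8.
    """
    key = frozenset(classes)
    try:
        return _STATE_OF[key]
    except KeyError:
        raise ValueError(f"unknown drug classes: {set(classes)!r}") from None


def state_classes(state: int) -> frozenset:
    """Inverse of :func:`classify_state`."""
    return STATE_CLASSES[int(state)]


def drug_count(state: int | np.ndarray) -> int | np.ndarray:
    """Number of drug classes a patient is exposed to in ``state`` (0..3)."""
    return _DRUG_COUNT[np.asarray(state) - 1][()] if np.isscalar(state) else _DRUG_COUNT[np.asarray(state) - 1]


def merge_refills(fills: pd.DataFrame, buffer_fraction: float = 0.2) -> pd.DataFrame:
    """Merge refill chains of the same drug into exposure episodes.

    Scanning each patient's fills of one drug chronologically, a subsequent
    fill is treated as a refill of the running episode when it starts no
    later than the episode's current end plus ``buffer_fraction`` times the
    *preceding fill's* days supply; refills extend the episode and keep the
    initiating prescriber, regardless of who signed the refill. Otherwise a
    new episode begins.

    Parameters
    ----------
    fills
        Columns ``patient_id, prescriber_id, drug_id, drug_class,
        start_day, days_supply``.
    buffer_fraction
        Allowed gap, as a fraction of the preceding fill's supply
        (default 0.2).

    Returns
    -------
    DataFrame with columns ``patient_id, drug_id, drug_class, start_day,
    end_day, initiating_physician`` using half-open day intervals
    ``[start_day, end_day)``.
    """
    if (fills["days_supply"] < 1).any():
        raise ValueError("days_supply must be >= 1 for every fill")

    records = []
    ordered = fills.sort_values(
        ["patient_id", "drug_id", "start_day", "prescriber_id"], kind="mergesort"
    )
    for (pid, drug), grp in ordered.groupby(["patient_id", "drug_id"], sort=True):
        cur = None
        prev_supply = None
        for row in grp.itertuples(index=False):
            start = int(row.start_day)
            supply = int(row.days_supply)
            if cur is not None and start <= cur["end_day"] + buffer_fraction * prev_supply:
                cur["end_day"] = max(cur["end_day"], start + supply)
            else:
                if cur is not None:
                    records.append(cur)
                cur = {
                    "patient_id": pid,
                    "drug_id": drug,
                    "drug_class": row.drug_class,
                    "start_day": start,
                    "end_day": start + supply,
                    "initiating_physician": row.prescriber_id,
                }
            prev_supply = supply
        if cur is not None:
            records.append(cur)
    return pd.DataFrame(
        records,
        columns=[
            "patient_id",
            "drug_id",
            "drug_class",
            "start_day",
            "end_day",
            "initiating_physician",
        ],
    )


def segment_intervals(
    exposures: pd.DataFrame, year_days: int = YEAR_DAYS
) -> pd.DataFrame:
    """Cut patients' years into intervals of constant drug-class exposure.

    Breakpoints are placed at every exposure start and end (clipped to the
    study year); consecutive intervals with an identical class set are
    coalesced, so each returned row is a maximal interval of constant
    state. Every patient's intervals tile ``[0, year_days)`` exactly.

    Returns a DataFrame with columns ``patient_id, start_day, end_day,
    classes`` (sorted string, e.g. ``"OB"``) ``, state``.
    """
    rows = []
    for pid, grp in exposures.groupby("patient_id", sort=True):
        rows.extend(_segment_one(pid, grp, year_days))
    return pd.DataFrame(
        rows, columns=["patient_id", "start_day", "end_day", "classes", "state"]
    )


def _segment_one(pid, exposures: pd.DataFrame, year_days: int):
    # delta counting per class handles overlapping same-class exposures
    events: dict[int, dict[str, int]] = {}
    for row in exposures.itertuples(index=False):
        s = max(0, int(row.start_day))
        e = min(year_days, int(row.end_day))
        if e <= s:
            continue
        events.setdefault(s, {}).setdefault(row.drug_class, 0)
        events[s][row.drug_class] += 1
        events.setdefault(e, {}).setdefault(row.drug_class, 0)
        events[e][row.drug_class] -= 1
    cuts = sorted(d for d in events if 0 < d < year_days)
    counts = {c: 0 for c in DRUG_CLASSES}
    for c, k in events.get(0, {}).items():
        counts[c] += k
    out = []
    prev = 0
    prev_classes = frozenset(c for c, k in counts.items() if k > 0)
    for day in cuts + [year_days]:
        for c, k in events.get(day, {}).items():
            counts[c] += k
        classes = frozenset(c for c, k in counts.items() if k > 0)
        if day == year_days or classes != prev_classes:
            out.append(
                {
                    "patient_id": pid,
                    "start_day": prev,
                    "end_day": day,
                    "classes": "".join(c for c in "OBS" if c in prev_classes),
                    "state": classify_state(prev_classes),
                }
            )
            prev = day
            prev_classes = classes
    return out


def state_transitions(intervals: pd.DataFrame) -> pd.DataFrame:
    """All state-change boundaries per patient, in chronological order.

    Each row is one prescription-change occasion ``s`` of a patient: the
    day, the state before and after, and the direction — ``prescribing``
    when the state index increases (a class-set gaining at least one drug
    class always does) and ``deprescribing`` when it decreases.
    """
    rows = []
    for pid, grp in intervals.groupby("patient_id", sort=True):
        grp = grp.sort_values("start_day")
        states = grp["state"].to_numpy()
        days = grp["start_day"].to_numpy()
        for s in range(1, len(states)):
            rows.append(
                {
                    "patient_id": pid,
                    "occasion": s - 1,
                    "from_state": int(states[s - 1]),
                    "to_state": int(states[s]),
                    "day": int(days[s]),
                    "direction": "prescribing"
                    if states[s] > states[s - 1]
                    else "deprescribing",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "occasion", "from_state", "to_state", "day", "direction"],
    )


def extract_prescribing_transitions(
    intervals: pd.DataFrame, exposures: pd.DataFrame
) -> pd.DataFrame:
    """Attribute responsibility for transitions that add drug classes.

    At every boundary where the patient's class set gains at least one
    class (state index increases), the transition is attributed to the
    initiating physicians of the exposures of the *gained* classes starting
    that day. When ``N`` distinct physicians initiate at the same boundary
    they are co-responsible with weight ``1/N`` each.

    Returns the long transition table with one row per (transition,
    responsible physician): ``patient_id, occasion, from_state, to_state,
    day, direction, physician_id, weight, n_responsible``.
    """
    boundaries = state_transitions(intervals)
    ups = boundaries[boundaries["direction"] == "prescribing"]
    starts = exposures.groupby(["patient_id", "start_day"], sort=False)

    rows = []
    for row in ups.itertuples(index=False):
        gained = state_classes(row.to_state) - state_classes(row.from_state)
        try:
            today = starts.get_group((row.patient_id, row.day))
        except KeyError:
            today = None
        physicians: list = []
        if today is not None:
            physicians = sorted(
                set(today.loc[today["drug_class"].isin(gained), "initiating_physician"])
            )
        n = len(physicians)
        base = row._asdict()
        if n == 0:
            rows.append({**base, "physician_id": None, "weight": 0.0, "n_responsible": 0})
        else:
            for k in physicians:
                rows.append(
                    {**base, "physician_id": k, "weight": 1.0 / n, "n_responsible": n}
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "occasion",
            "from_state",
            "to_state",
            "day",
            "direction",
            "physician_id",
            "weight",
            "n_responsible",
        ],
    )
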