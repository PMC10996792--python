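"""Heuristic identification and attribution of deprescribing events.

Claims data record prescribing but not deprescribing: stopping a drug
triggers no claim. Deprescribing is therefore inferred — a long-term
prescription that is never refilled, whose end follows a clinical visit
closely, is taken as a likely intentional discontinuation attributable to
the most recently visited physician(s).

Rules (thresholds configurable, defaults 30/30 days):

* **eligibility** — the merged exposure must be longer than 30 days (to
  exclude prescriptions for acute conditions) and must not be followed by
  a later exposure of the same drug within the year (refill chains are
  already merged, so a later exposure means the drug was resumed, not
  deprescribed);
* **attribution** — the candidate visit is the patient's latest encounter
  strictly before the exposure's end; the discontinuation must occur
  within 30 days (inclusive) of that visit. All physicians seen on the
  candidate day are co-responsible with equal weights. Failing either
  rule, the patient's state transition is still recorded but carries no
  responsible physician.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import state_transitions

__all__ = ["DeprescribingDiagnostics", "eligible_targets", "attribute_deprescribing"]


@dataclass
class DeprescribingDiagnostics:
    """Counts from one attribution pass."""

    n_down_transitions: int
    n_eligible_targets: int
    n_attributed_transitions: int
    n_unattributed_transitions: int


def eligible_targets(
    exposures: pd.DataFrame, min_length: int = 30
) -> pd.DataFrame:
    """Merged exposures that could plausibly have been deprescribed.

    Keeps exposures strictly longer than ``min_length`` days with no
    subsequent same-drug exposure for the same patient.
    """
    exp = exposures.sort_values(
        ["patient_id", "drug_id", "start_day"], kind="mergesort"
    ).reset_index(drop=True)
    is_last = (
        exp.groupby(["patient_id", "drug_id"])["start_day"].transform("max")
        == exp["start_day"]
    )
    long_enough = (exp["end_day"] - exp["start_day"]) > min_length
    return exp[is_last & long_enough].reset_index(drop=True)


def attribute_deprescribing(
    targets: pd.DataFrame,
    encounters: pd.DataFrame,
    intervals: pd.DataFrame,
    visit_window: int = 30,
) -> tuple[pd.DataFrame, DeprescribingDiagnostics]:
    """Attribute down-transitions to recently visited physicians.

    Parameters
    ----------
    targets
        Output of :func:`eligible_targets`.
    encounters
        Full encounter table (``patient_id, physician_id, day``).
    intervals
        Exposure intervals of all patients (:func:`presnet.states.segment_intervals`);
        supplies the state before/after each discontinuation.
    visit_window
        Maximum days (inclusive) between the candidate visit and the
        exposure end.

    Returns
    -------
    (transitions, diagnostics)
        Long-format transition rows (direction ``deprescribing``), one row
        per responsible physician — or a single zero-weight row when no
        qualifying visit exists — and attribution counts. When several
        eligible drugs end on the same day a single combined transition is
        emitted and each ended drug's candidates pool into one responsible
        set with equal weights.
    """
    boundaries = state_transitions(intervals)
    downs = boundaries[boundaries["direction"] == "deprescribing"]

    target_ends = {
        (row.patient_id, row.end_day) for row in targets.itertuples(index=False)
    }
    enc_days = {
        pid: np.sort(grp["day"].unique())
        for pid, grp in encounters.groupby("patient_id", sort=False)
    }
    docs_on_day = (
        encounters.groupby(["patient_id", "day"])["physician_id"]
        .agg(lambda s: sorted(set(s)))
        .to_dict()
    )

    rows = []
    n_attr = 0
    n_unattr = 0
    for row in downs.itertuples(index=False):
        base = row._asdict()
        physicians: list = []
        if (row.patient_id, row.day) in target_ends:
            days = enc_days.get(row.patient_id)
            if days is not None:
                prior = days[days < row.day]
                if prior.size and row.day - prior[-1] <= visit_window:
                    physicians = docs_on_day[(row.patient_id, int(prior[-1]))]
        if physicians:
            n_attr += 1
            n = len(physicians)
            for k in physicians:
                rows.append(
                    {**base, "physician_id": k, "weight": 1.0 / n, "n_responsible": n}
                )
        else:
            n_unattr += 1
            rows.append({**base, "physician_id": None, "weight": 0.0, "n_responsible": 0})
    out = pd.DataFrame(
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
    diag = DeprescribingDiagnostics(
        n_down_transitions=len(downs),
        n_eligible_targets=len(targets),
        n_attributed_transitions=n_attr,
        n_unattributed_transitions=n_unattr,
    )
    return out, diag
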