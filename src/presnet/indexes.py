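"""Physician transition responsibility count matrices and prescribing
indexes.

Each physician ``k`` gets an 8x8 matrix ``C(k)`` whose entry ``C_ij`` is
the weighted number of patient state transitions ``i -> j`` attributed to
them (co-responsible physicians share a unit weight equally). Rows above
the diagonal are prescribing transitions, rows below are deprescribing;
the diagonal is identically zero because same-state continuations are
absorbed at the refill-merge stage.

Six scalar indexes summarize a matrix:

``I0``, ``I1``
    Prescribe-deprescribe balance ``(P - D) / (P + D)``, where the alpha=1
    variant weights each transition by the number of drug classes changed
    ``|n_i - n_j|`` (``n`` = drugs held in a state). Bounded in (-1, 1];
    undefined when the physician has no (weighted) transitions.
``IOBS``, ``IeverOBS``
    Share of a physician's transitions that move a patient *into* the
    all-three-classes state, and its binarization.
``Ipresc2mr``, ``Idepresc2mr``
    Among prescribing (resp. deprescribing) transitions, the fraction
    changing two or more drug classes at once. A physician with no
    deprescribing mass gets ``Idepresc2mr = 0`` by convention; the other
    empty-denominator indexes are undefined (NaN) and such physicians are
    dropped, with a logged count, from models using that attribute.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .states import drug_count

__all__ = [
    "build_ptrcm",
    "index_alpha",
    "index_obs",
    "ever_obs",
    "two_or_more",
    "prescribing_profiles",
    "summarize_by_group",
]

logger = logging.getLogger(__name__)

N_STATES = 8

# |drug_count(i) - drug_count(j)| over state pairs (0-based indices)
_COUNTS = np.asarray(drug_count(np.arange(1, N_STATES + 1)))
_NDIFF = np.abs(_COUNTS[:, None] - _COUNTS[None, :]).astype(float)
_UPPER = np.triu(np.ones((N_STATES, N_STATES)), k=1).astype(bool)
_LOWER = np.tril(np.ones((N_STATES, N_STATES)), k=-1).astype(bool)


def build_ptrcm(transitions: pd.DataFrame) -> dict[str, np.ndarray]:
    """Accumulate per-physician 8x8 responsibility matrices.

    ``transitions`` is the long table (one row per transition and
    responsible physician, with fractional weights for co-responsibility);
    rows without a responsible physician contribute to no matrix.
    """
    out: dict[str, np.ndarray] = {}
    attributed = transitions[transitions["physician_id"].notna()]
    for row in attributed.itertuples(index=False):
        if row.weight <= 0:
            continue
        C = out.get(row.physician_id)
        if C is None:
            C = out[row.physician_id] = np.zeros((N_STATES, N_STATES))
        C[row.from_state - 1, row.to_state - 1] += row.weight
    return out


def index_alpha(C: np.ndarray, alpha: int) -> float:
    """Prescribe-deprescribe balance index (alpha in {0, 1}).

    ``(P - D) / (P + D)`` with P (D) the drug-change-weighted mass above
    (below) the diagonal; weights are ``|n_i - n_j| ** alpha`` with
    ``0 ** 0 = 1``. NaN when P + D = 0.
    """
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 or 1")
    W = np.ones_like(_NDIFF) if alpha == 0 else _NDIFF
    P = float((C * W)[_UPPER].sum())
    D = float((C * W)[_LOWER].sum())
    if P + D == 0:
        return float("nan")
    return (P - D) / (P + D)


def index_obs(C: np.ndarray) -> float:
    """Share of attributed transitions that bring a patient into the
    all-three state (state 8). NaN when the physician has no transitions."""
    total = float(C[_UPPER].sum() + C[_LOWER].sum())
    if total == 0:
        return float("nan")
    return float(C[:-1, -1].sum()) / total


def ever_obs(C: np.ndarray) -> int:
    """1 iff the physician ever moved a patient into state 8."""
    return int(C[:-1, -1].sum() > 0)


def two_or_more(C: np.ndarray, direction: str) -> float:
    """Fraction of same-direction transitions changing >= 2 drug classes.

    ``direction`` is ``prescribing`` (above-diagonal mass; NaN when there
    is none) or ``deprescribing`` (below-diagonal; defined as 0 when there
    is none).
    """
    if direction == "prescribing":
        mask = _UPPER
    elif direction == "deprescribing":
        mask = _LOWER
    else:
        raise ValueError("direction must be 'prescribing' or 'deprescribing'")
    denom = float(C[mask].sum())
    if denom == 0:
        return 0.0 if direction == "deprescribing" else float("nan")
    num = float(C[mask & (_NDIFF >= 2)].sum())
    return num / denom


def prescribing_profiles(ptrcms: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """All six indexes per physician, NaN marking undefined values."""
    rows = []
    for k in sorted(ptrcms):
        C = ptrcms[k]
        rows.append(
            {
                "physician_id": k,
                "I0": index_alpha(C, 0),
                "I1": index_alpha(C, 1),
                "IOBS": index_obs(C),
                "IeverOBS": ever_obs(C),
                "Ipresc2mr": two_or_more(C, "prescribing"),
                "Idepresc2mr": two_or_more(C, "deprescribing"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["physician_id", "I0", "I1", "IOBS", "IeverOBS", "Ipresc2mr", "Idepresc2mr"],
    )
    n_undef = int(df[["I0", "I1", "IOBS", "Ipresc2mr"]].isna().any(axis=1).sum())
    if n_undef:
        logger.info("%d physician(s) have at least one undefined index", n_undef)
    return df.set_index("physician_id", drop=False)


def summarize_by_group(
    profiles: pd.DataFrame, grouping: Mapping | pd.Series
) -> pd.DataFrame:
    """Per-group mean and standard error of each index.

    Means and SE = SD / sqrt(n) are computed over defined (non-NaN) values
    only; groups with a single defined value get SE = NaN.
    """
    value_cols = [c for c in profiles.columns if c != "physician_id"]
    groups = profiles["physician_id"].map(
        grouping if not isinstance(grouping, pd.Series) else grouping.to_dict()
    )
    rows = []
    for g, grp in profiles.groupby(groups):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "group": g,
                    "index": col,
                    "mean": vals.mean() if n else float("nan"),
                    "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan"),
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["group", "index", "mean", "se", "n"])
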