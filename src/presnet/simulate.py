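"""Synthetic claims generator with planted network and prescribing structure.

The real study data (Medicare fee-for-service + Part D claims) cannot be
shared, so analyses are exercised on synthetic cohorts that reproduce the
statistical features the pipeline relies on:

* every prescription fill coincides with a same-day encounter between the
  patient and the prescriber (fills imply visits);
* refill chains of the same drug, overlapping or separated by short gaps,
  so the refill-merging rule has work to do;
* concurrent multi-class exposure whose intensity increases with the
  latent risky-prescribing propensity of a patient's physicians;
* planted deprescribing: a tunable fraction of long exposures end with a
  clinical visit shortly before supply exhaustion and no refill afterwards,
  with the visiting physician recorded as ground truth so attribution
  sensitivity can be measured;
* assortative patient-sharing: the chance that two physicians share a
  patient decays with the distance between their latent risk propensities,
  at a rate set by ``homophily_strength`` — the planted analogue of the
  absdiff homophily the ERGM estimates.

The module also simulates networks directly from a dyad-independent ERGM
(:func:`generate_dyad_independent_network`) for parameter-recovery and
coverage experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ergm import TermSpec, dyad_change_matrix
from scipy.special import expit

__all__ = ["SimConfig", "Cohort", "generate_cohort", "generate_dyad_independent_network"]

SPECIALTIES = ("primary care", "emergency medicine", "neurology", "psychiatry", "other")


@dataclass
class SimConfig:
    """Cohort-simulation settings.

    Defaults produce a cohort of a few hundred physicians and a few
    thousand patients over a single 365-day study year, with moderate
    refill, escalation and deprescribing activity.
    """

    n_physicians: int = 300
    n_patients: int = 3000
    n_regions: int = 4
    specialty_probs: tuple = (0.35, 0.15, 0.10, 0.10, 0.30)
    homophily_strength: float = 2.0
    refill_rate: float = 0.5
    risky_escalation_rate: float = 0.35
    deprescribe_rate: float = 0.3
    products_per_class: int = 3
    year_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_physicians, self.n_patients, self.n_regions) <= 0:
            raise ValueError("n_physicians, n_patients and n_regions must be positive")
        probs = np.asarray(self.specialty_probs, dtype=float)
        if len(probs) != len(SPECIALTIES):
            raise ValueError(f"specialty_probs must have {len(SPECIALTIES)} entries")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("specialty_probs must be a probability vector (sum 1)")
        for name in ("refill_rate", "risky_escalation_rate", "deprescribe_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.homophily_strength < 0:
            raise ValueError("homophily_strength must be >= 0")


@dataclass
class Cohort:
    """Synthetic cohort tables plus generator ground truth.

    ``deprescribing_truth`` lists the planted deprescribing events
    (patient, drug, exposure end, visiting physician, visit day); it is a
    test harness artifact, not an input to any analysis stage.
    """

    fills: pd.DataFrame
    encounters: pd.DataFrame
    physicians: pd.DataFrame
    patients: pd.DataFrame
    deprescribing_truth: pd.DataFrame
    config: SimConfig


def _simulate_physicians(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(cfg.n_physicians))
    ids = [f"d{i:0{width}d}" for i in range(cfg.n_physicians)]
    return pd.DataFrame(
        {
            "physician_id": ids,
            "specialty": rng.choice(SPECIALTIES, size=cfg.n_physicians, p=cfg.specialty_probs),
            "region": [f"R{rng.integers(cfg.n_regions)}" for _ in ids],
            "latent_risk": rng.beta(2.0, 5.0, size=cfg.n_physicians),
        }
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate one study year of claims-like records.

    Fully deterministic given ``config`` (including its seed). See the
    module docstring for the planted structure.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    physicians = _simulate_physicians(cfg, rng)
    risk = physicians["latent_risk"].to_numpy()
    doc_region = physicians["region"].to_numpy()
    doc_ids = physicians["physician_id"].to_numpy()

    pwidth = len(str(cfg.n_patients))
    patient_rows = []
    fill_rows: list[dict] = []
    enc_rows: list[dict] = []
    truth_rows: list[dict] = []

    for p in range(cfg.n_patients):
        pid = f"p{p:0{pwidth}d}"
        region = f"R{rng.integers(cfg.n_regions)}"
        patient_rows.append({"patient_id": pid, "region": region})

        # physician panel: a primary physician (region-biased), then extras
        # drawn with weight decaying in latent-risk distance -> assortative
        # patient-sharing
        same_region = np.flatnonzero(doc_region == region)
        if rng.random() < 0.8 and same_region.size:
            primary = int(rng.choice(same_region))
        else:
            primary = int(rng.integers(cfg.n_physicians))
        n_extra = min(1 + rng.poisson(1.2), 6, cfg.n_physicians - 1)
        w = np.exp(-cfg.homophily_strength * np.abs(risk - risk[primary]))
        w *= np.where(doc_region == region, 3.0, 1.0)
        w[primary] = 0.0
        w = w / w.sum()
        extras = rng.choice(cfg.n_physicians, size=n_extra, replace=False, p=w)
        panel = [primary] + [int(e) for e in extras]

        # routine encounters
        for d in panel:
            for day in rng.integers(0, cfg.year_days, size=1 + rng.poisson(0.8)):
                enc_rows.append(
                    {"patient_id": pid, "physician_id": doc_ids[d], "day": int(day)}
                )

        # prescriptions: per-class inclusion scales with the panel's mean
        # latent risk -> concurrent multi-class exposure clusters on risky
        # physicians' patients
        panel_risk = float(risk[panel].mean())
        p_class = min(1.0, 0.15 + cfg.risky_escalation_rate * panel_risk * 2.0)
        chains = []  # (drug_id, drug_class, fills list, chain_end)
        used_drugs: set[str] = set()
        for c in ("O", "B", "S"):
            if rng.random() >= p_class:
                continue
            product = int(rng.integers(cfg.products_per_class))
            drug = f"{c}{product}"
            if drug in used_drugs:
                continue
            used_drugs.add(drug)
            pr_w = 0.2 + risk[panel]
            prescriber = panel[int(rng.choice(len(panel), p=pr_w / pr_w.sum()))]
            start = int(rng.integers(0, 270))
            supply = int(rng.choice([30, 60, 90], p=[0.5, 0.3, 0.2]))
            fills = [(start, supply, prescriber)]
            end = start + supply
            while rng.random() < cfg.refill_rate and len(fills) < 6:
                # overlap or a gap within the 20% refill buffer
                gap = int(rng.integers(-5, max(1, int(0.2 * supply))))
                nxt = end + gap
                if nxt >= cfg.year_days:
                    break
                signer = prescriber
                if rng.random() < 0.2 and len(panel) > 1:
                    signer = panel[int(rng.integers(1, len(panel)))]
                fills.append((nxt, supply, signer))
                end = max(end, nxt + supply)
            chains.append({"drug_id": drug, "drug_class": c, "fills": fills, "end": end})

        # planted deprescribing: only where the discontinuation is visible
        # as a state change at the chain end (class becomes inactive, no
        # other exposure starts that day) and the end lies inside the year
        ends = {ch["end"] for ch in chains}
        starts_all = {f[0] for ch in chains for f in ch["fills"]}
        for ch in chains:
            length = ch["end"] - ch["fills"][0][0]
            if length <= 30 or ch["end"] >= cfg.year_days:
                continue
            other_active = any(
                o is not ch
                and o["drug_class"] == ch["drug_class"]
                and o["fills"][0][0] <= ch["end"] - 1
                and o["end"] > ch["end"]
                for o in chains
            )
            if other_active or ch["end"] in starts_all:
                continue
            if rng.random() < cfg.deprescribe_rate:
                deprescriber = doc_ids[panel[int(rng.integers(len(panel)))]]
                visit_day = ch["end"] - 1
                enc_rows.append(
                    {"patient_id": pid, "physician_id": deprescriber, "day": visit_day}
                )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "drug_id": ch["drug_id"],
                        "drug_class": ch["drug_class"],
                        "end_day": ch["end"],
                        "physician_id": deprescriber,
                        "visit_day": visit_day,
                    }
                )

        for ch in chains:
            for start, supply, signer in ch["fills"]:
                fill_rows.append(
                    {
                        "patient_id": pid,
                        "prescriber_id": doc_ids[signer],
                        "drug_id": ch["drug_id"],
                        "drug_class": ch["drug_class"],
                        "start_day": start,
                        "days_supply": supply,
                    }
                )
                enc_rows.append(
                    {"patient_id": pid, "physician_id": doc_ids[signer], "day": start}
                )

    fills = pd.DataFrame(
        fill_rows,
        columns=["patient_id", "prescriber_id", "drug_id", "drug_class", "start_day", "days_supply"],
    ).sort_values(["patient_id", "drug_id", "start_day", "prescriber_id"], kind="mergesort")
    encounters = (
        pd.DataFrame(enc_rows, columns=["patient_id", "physician_id", "day"])
        .drop_duplicates()
        .sort_values(["patient_id", "physician_id", "day"], kind="mergesort")
    )
    patients = pd.DataFrame(patient_rows, columns=["patient_id", "region"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "drug_id", "drug_class", "end_day", "physician_id", "visit_day"],
    )
    return Cohort(
        fills=fills.reset_index(drop=True),
        encounters=encounters.reset_index(drop=True),
        physicians=physicians,
        patients=patients,
        deprescribing_truth=truth,
        config=cfg,
    )


def generate_dyad_independent_network(
    attributes: pd.DataFrame,
    terms: Sequence[TermSpec],
    eta: Sequence[float],
    seed: int = 0,
) -> nx.Graph:
    """Draw a network from a dyad-independent ERGM.

    Each unordered dyad is an independent Bernoulli draw with tie
    probability ``logistic(eta . change statistics)`` — the exact sampling
    distribution of the model, no MCMC required. ``attributes`` is indexed
    by node id; its columns become node attributes of the returned graph.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    nodes = list(attributes.index)
    X, dyads = dyad_change_matrix(nodes, attributes, terms)
    p = expit(X @ eta)
    rng = np.random.default_rng(seed)
    present = rng.random(len(dyads)) < p
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for col in attributes.columns:
        nx.set_node_attributes(g, attributes[col].to_dict(), col)
    g.add_edges_from(d for d, keep in zip(dyads, present) if keep)
    return g
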