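"""End-to-end pipeline: claims -> network -> states -> attribution ->
indexes -> homophily models -> triadic tests.

Stage order mirrors the study workflow: simulate or ingest claims; build
the mutual shared-patient prescriber network and reduce to its largest
connected component; merge refills and segment prescription states;
attribute prescribing and deprescribing transitions; accumulate
responsibility matrices and prescribing indexes; fit dyad-independent
homophily ERGMs (one index at a time, adjusting for density, specialty
main effects and specialty homophily); and run the triadic permutation
tests on the ever-OBS attribute. Every artifact lands in the run
directory together with a manifest recording the configuration hash.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import deprescribe, indexes, network, states, triads
from .ergm import TermSpec, fit_ergm
from .io import PipelineConfig, config_hash, read_claims, write_graph, write_table
from .simulate import SimConfig, generate_cohort

__all__ = ["run_pipeline", "homophily_terms"]

logger = logging.getLogger(__name__)


def homophily_terms(index_name: str, specialties, ref_specialty: str) -> list[TermSpec]:
    """Model specification for one prescribing index.

    Adjusts for density (``edges``), specialty main effects relative to a
    reference level, and uniform specialty homophily; the index enters as
    a main effect plus a homophily term — match terms for the binary
    ever-OBS indicator, nodecov + absdiff for continuous indexes.
    """
    terms = [TermSpec("edges")]
    for s in sorted(specialties):
        if s != ref_specialty:
            terms.append(TermSpec("nodefactor", "specialty", s))
    terms.append(TermSpec("nodematch", "specialty"))
    if index_name == "IeverOBS":
        terms.append(TermSpec("nodefactor", index_name, 1))
        terms.append(TermSpec("nodematch_diff", index_name, 1))
    else:
        terms.append(TermSpec("nodecov", index_name))
        terms.append(TermSpec("absdiff", index_name))
    return terms


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate or ingest -------------------------------------
    if config.input_dir is None:
        sim = SimConfig(**{"seed": config.seed, **config.simulation})
        cohort = generate_cohort(sim)
        fills, encounters = cohort.fills, cohort.encounters
        physicians, patients = cohort.physicians, cohort.patients
        write_table(fills, out / "fills.csv")
        write_table(encounters, out / "encounters.csv")
        write_table(physicians, out / "physicians.csv")
        write_table(patients, out / "patients.csv")
        write_table(cohort.deprescribing_truth, out / "deprescribing_truth.csv")
    else:
        d = Path(config.input_dir)
        fills, encounters, physicians, patients = read_claims(
            d / "fills.csv", d / "encounters.csv", d / "physicians.csv",
            d / "patients.csv", config.year_days,
        )

    # --- stage 2: network -------------------------------------------------
    directed = network.build_directed_network(encounters)
    mutual = network.to_mutual_binary(directed)
    prescriber_net = network.restrict_to_prescribers(mutual, fills)
    lcc = network.largest_connected_component(prescriber_net)
    logger.info(
        "funnel: %d physicians -> %d in mutual net -> %d prescribers -> %d in LCC",
        physicians["physician_id"].nunique(), mutual.number_of_nodes(),
        prescriber_net.number_of_nodes(), lcc.number_of_nodes(),
    )
    region_of = network.assign_regions(encounters, patients)
    subnets = network.region_subnetworks(lcc, region_of, config.min_region_nodes)
    summaries = pd.DataFrame(
        {name: network.network_summary(g).to_series()
         for name, g in [("mutual", mutual), ("prescribing", prescriber_net), ("lcc", lcc)]}
    )
    summaries.to_csv(out / "network_summary.csv")
    write_graph(lcc, out / "lcc")

    # --- stage 3: states --------------------------------------------------
    exposures = states.merge_refills(fills, config.merge_buffer_fraction)
    intervals = states.segment_intervals(exposures, config.year_days)
    write_table(exposures, out / "exposures.csv")

    # --- stage 4: transitions + attribution -------------------------------
    presc = states.extract_prescribing_transitions(intervals, exposures)
    targets = deprescribe.eligible_targets(exposures, config.deprescribe_min_length)
    depresc, diag = deprescribe.attribute_deprescribing(
        targets, encounters, intervals, config.deprescribe_visit_window
    )
    transitions = pd.concat([presc, depresc], ignore_index=True).sort_values(
        ["patient_id", "occasion", "physician_id"], kind="mergesort", na_position="last"
    )
    write_table(transitions, out / "transitions.csv")
    logger.info("deprescribing attribution: %s", diag)

    # --- stage 5: PTRCM + indexes ----------------------------------------
    ptrcms = indexes.build_ptrcm(transitions)
    profiles = indexes.prescribing_profiles(ptrcms)
    write_table(profiles, out / "profiles.csv")
    specialty_of = physicians.set_index("physician_id")["specialty"].to_dict()
    by_specialty = indexes.summarize_by_group(profiles, specialty_of)
    write_table(by_specialty, out / "indexes_by_specialty.csv")

    # --- stage 6: attach attributes, fit homophily ERGMs ------------------
    nx.set_node_attributes(lcc, specialty_of, "specialty")
    for col in ("I0", "I1", "IOBS", "IeverOBS", "Ipresc2mr", "Idepresc2mr"):
        nx.set_node_attributes(lcc, profiles[col].to_dict(), col)
    specialties = sorted(set(specialty_of.get(v) for v in lcc.nodes) - {None})
    counts = pd.Series([specialty_of.get(v) for v in lcc.nodes]).value_counts()
    ref = counts.index[0] if len(counts) else None
    coef_tables = []
    for index_name in config.ergm_indexes:
        vals = {v: lcc.nodes[v].get(index_name) for v in lcc.nodes}
        keep = [v for v, x in vals.items()
                if x is not None and not (isinstance(x, float) and math.isnan(x))
                and specialty_of.get(v) is not None]
        dropped = lcc.number_of_nodes() - len(keep)
        if dropped:
            logger.info("ERGM %s: dropping %d node(s) with undefined attribute",
                        index_name, dropped)
        sub = lcc.subgraph(keep)
        if sub.number_of_nodes() < 10 or sub.number_of_edges() == 0:
            logger.warning("ERGM %s skipped: too little data", index_name)
            continue
        try:
            fit = fit_ergm(sub, homophily_terms(index_name, specialties, ref))
        except ValueError as exc:  # e.g. an index constant across the cohort
            logger.warning("ERGM %s skipped: %s", index_name, exc)
            continue
        tab = fit.coefficients.copy()
        tab.insert(0, "model", index_name)
        coef_tables.append(tab)
    if coef_tables:
        write_table(pd.concat(coef_tables, ignore_index=True), out / "ergm_coefficients.csv")

    # --- stage 7: triadic homophily ---------------------------------------
    triad_rows = []
    nodes = sorted(lcc.nodes)
    xever = np.array([float(lcc.nodes[v].get("IeverOBS") or 0.0) for v in nodes])
    for stat in ("tri1", "tri2"):
        try:
            res = triads.permutation_test(
                lcc, xever, statistic=stat, n_perm=config.n_perm, seed=config.seed
            )
        except ValueError as exc:  # undefined on sparse synthetic nets
            logger.warning("permutation test %s skipped: %s", stat, exc)
            continue
        triad_rows.append(
            {"statistic": stat, "observed": res.observed, "n_perm": res.n_perm,
             "p_value": res.p_value, "seed": res.seed}
        )
        np.savetxt(out / f"null_draws_{stat}.txt", res.null_draws)
    if triad_rows:
        write_table(pd.DataFrame(triad_rows), out / "triadic_tests.csv")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_region_subnetworks": len(subnets),
        "stages": ["ingest", "network", "states", "attribution", "indexes", "ergm", "triads"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
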