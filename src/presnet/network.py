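"""Shared-patient physician network construction and descriptive statistics.

A directed shared-patient graph is built from physician-patient encounter
records: an arc i -> j carries the number of distinct patients with an
encounter with physician i on a day strictly earlier than an encounter
with physician j. The analyzed network keeps only *mutual* dyads — both
orders observed, each supported by at least one patient — binarized into an
undirected graph, restricted to physicians who prescribe in the monitored
drug classes, and reduced to its largest connected component. Region
(e.g. hospital-referral-region-like) sub-networks keep only edges whose
endpoints share the region of the plurality of their patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkSummary",
    "build_directed_network",
    "to_mutual_binary",
    "restrict_to_prescribers",
    "largest_connected_component",
    "assign_regions",
    "region_subnetworks",
    "network_summary",
]


def build_directed_network(encounters: pd.DataFrame) -> nx.DiGraph:
    """Directed shared-patient graph from an encounter table.

    Arc ``i -> j`` is present with weight equal to the number of distinct
    patients having at least one encounter with ``i`` strictly before one
    with ``j``. Same-day visits to two physicians provide no ordering
    evidence in either direction. An empty table yields an empty graph.
    """
    g = nx.DiGraph()
    if len(encounters) == 0:
        return g
    g.add_nodes_from(sorted(encounters["physician_id"].unique()))
    pair_patients: dict[tuple, set] = {}
    grouped = encounters.groupby("patient_id", sort=True)
    for pid, grp in grouped:
        # first/last encounter day per physician: i precedes j iff
        # first(i) < last(j)
        first = grp.groupby("physician_id")["day"].min()
        last = grp.groupby("physician_id")["day"].max()
        docs = list(first.index)
        for i in docs:
            fi = first[i]
            for j in docs:
                if i != j and fi < last[j]:
                    pair_patients.setdefault((i, j), set()).add(pid)
    for (i, j), pats in pair_patients.items():
        g.add_edge(i, j, weight=len(pats))
    return g


def to_mutual_binary(g: nx.DiGraph) -> nx.Graph:
    """Binarize to mutual ties: undirected edge iff both arcs exist.

    A weight threshold of zero is applied — each direction must be
    supported by at least one patient.
    """
    net = nx.Graph()
    net.add_nodes_from(g.nodes(data=True))
    for i, j in g.edges:
        if i < j and g.has_edge(j, i):
            net.add_edge(i, j)
    return net


def restrict_to_prescribers(net: nx.Graph, fills: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on physicians with >= 1 fill in the monitored classes."""
    prescribers = set(fills["prescriber_id"].unique())
    keep = [v for v in net.nodes if v in prescribers]
    return net.subgraph(keep).copy()


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component.

    Size ties are broken deterministically in favor of the component
    containing the lexicographically smallest node. The empty graph maps
    to an empty graph.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    comps = sorted(
        nx.connected_components(net), key=lambda c: (-len(c), sorted(c))
    )
    return net.subgraph(comps[0]).copy()


def assign_regions(
    encounters: pd.DataFrame, patients: pd.DataFrame
) -> dict[Hashable, str]:
    """Map each physician to the region of the plurality of their patients.

    Counts distinct patients per (physician, patient-region); ties break to
    the lexicographically smallest region label. Physicians without
    encounters are absent from the mapping.
    """
    merged = encounters[["patient_id", "physician_id"]].drop_duplicates().merge(
        patients[["patient_id", "region"]], on="patient_id", how="left"
    )
    counts = (
        merged.groupby(["physician_id", "region"])["patient_id"]
        .nunique()
        .reset_index(name="n")
    )
    out: dict[Hashable, str] = {}
    for doc, grp in counts.groupby("physician_id"):
        grp = grp.sort_values(["n", "region"], ascending=[False, True])
        out[doc] = grp.iloc[0]["region"]
    return out


def region_subnetworks(
    net: nx.Graph,
    region_of: Mapping[Hashable, str],
    min_nodes: int = 100,
) -> dict[str, nx.Graph]:
    """One induced sub-network per region, with cross-region edges removed.

    An edge belongs to a region's sub-network only when both endpoints are
    assigned to that region; regions with fewer than ``min_nodes`` assigned
    nodes are dropped. Sub-networks are *not* re-restricted to their own
    largest component (they may be disconnected).
    """
    by_region: dict[str, list] = {}
    for v in net.nodes:
        r = region_of.get(v)
        if r is not None:
            by_region.setdefault(r, []).append(v)
    out = {}
    for r in sorted(by_region):
        members = by_region[r]
        if len(members) < min_nodes:
            continue
        out[r] = net.subgraph(members).copy()
    return out


@dataclass
class NetworkSummary:
    """Descriptive statistics of an undirected network."""

    n_nodes: int
    n_edges: int
    density: float
    n_components: int
    lcc_size: int
    degree_mean: float
    degree_iqr: float
    degree_sd: float
    global_clustering: float
    avg_path_length: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Density, components, degree spread, transitivity and path length.

    Global clustering is 3 x (closed triangles) / (2-stars); the average
    path length is taken over all reachable ordered pairs, i.e. within
    components. Degenerate values (no nodes, no pairs) are NaN.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    density = m / (n * (n - 1) / 2) if n > 1 else float("nan")
    comps = list(nx.connected_components(net)) if n else []
    degs = np.array([d for _, d in net.degree]) if n else np.array([])
    if degs.size:
        q75, q25 = np.percentile(degs, [75, 25])
        deg_mean, deg_iqr, deg_sd = float(degs.mean()), float(q75 - q25), float(degs.std(ddof=0))
    else:
        deg_mean = deg_iqr = deg_sd = float("nan")
    clustering = nx.transitivity(net) if n else float("nan")
    total_len = 0
    total_pairs = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(lengths.values())
            total_pairs += len(lengths) - 1  # drop self-distance
    apl = total_len / total_pairs if total_pairs else float("nan")
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        density=density,
        n_components=len(comps),
        lcc_size=max((len(c) for c in comps), default=0),
        degree_mean=deg_mean,
        degree_iqr=deg_iqr,
        degree_sd=deg_sd,
        global_clustering=float(clustering),
        avg_path_length=float(apl),
    )
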