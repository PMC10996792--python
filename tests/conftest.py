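import networkx as nx
import numpy as np
import pandas as pd
import pytest

import presnet as pn


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared across read-only tests."""
    return pn.generate_cohort(pn.SimConfig(n_physicians=80, n_patients=600, seed=1))


@pytest.fixture(scope="session")
def risky_subgraph():
    """Six-physician network with four risky prescribers (A-D) forming one
    all-risky triangle (A-B-C) and five risky 2-stars; E, F are non-risky
    and attach without creating further triangles."""
    g = nx.Graph([("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("D", "E"), ("E", "F")])
    x = {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0, "E": 0.0, "F": 0.0}
    return g, x


def fills_frame(rows):
    """rows: (patient, prescriber, drug, cls, start, supply)"""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "prescriber_id", "drug_id", "drug_class", "start_day", "days_supply"],
    )


def encounters_frame(rows):
    """rows: (patient, physician, day)"""
    return pd.DataFrame(rows, columns=["patient_id", "physician_id", "day"])


@pytest.fixture
def make_fills():
    return fills_frame


@pytest.fixture
def make_encounters():
    return encounters_frame


def brute_force_triads(g: nx.Graph, x: dict):
    """O(n^3) triple enumeration oracle for the triadic statistics."""
    nodes = sorted(g.nodes)
    tri_w = tri_n = 0.0
    twostar_w = closed_w = 0.0
    import itertools

    for i, j, k in itertools.combinations(nodes, 3):
        closed = g.has_edge(i, j) and g.has_edge(j, k) and g.has_edge(i, k)
        if closed:
            tri_n += 1
            tri_w += x[i] * x[j] * x[k]
    for c in nodes:
        nbrs = sorted(g.neighbors(c))
        for a, b in itertools.combinations(nbrs, 2):
            w = x[c] * x[a] * x[b]
            twostar_w += w
            if g.has_edge(a, b):
                closed_w += w
    t1 = tri_w / tri_n if tri_n else float("nan")
    t2 = closed_w / twostar_w if twostar_w else float("nan")
    return t1, t2, tri_n, tri_w, twostar_w
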