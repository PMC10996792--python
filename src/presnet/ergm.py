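r"""Dyad-independent exponential random graph models (ERGMs) for undirected
networks.

An ERGM assigns probability proportional to ``exp(sum_p eta_p g_p(a, x))``
to each graph ``a`` on a fixed node set with node attributes ``x``. This
module implements the dyad-independent family: every supported statistic
``g_p`` decomposes into a sum of per-dyad contributions depending only on
the two incident nodes' attributes, so the likelihood factorizes into
independent Bernoulli-logistic terms per dyad and the exact maximum
likelihood estimate is a logistic regression on the per-dyad change
statistics. Dyad-dependent statistics (triangles, k-stars) are rejected:
they are notoriously prone to model degeneracy and are handled
descriptively by :mod:`presnet.triads` instead.

Supported terms (for an unordered dyad {i, j} with attribute values
``x_i, x_j``):

========================  =================================================
``edges``                 1 (density intercept)
``nodefactor`` (level k)  1[x_i = k] + 1[x_j = k]
``nodecov``               x_i + x_j
``nodematch``             1[x_i = x_j]          (uniform homophily)
``nodematch_diff`` (l)    1[x_i = l] 1[x_j = l] (differential homophily)
``absdiff``               \|x_i - x_j\|          (continuous homophily)
========================  =================================================

For a binary attribute, the ``edges``, ``nodefactor`` and the two
differential ``nodematch`` columns are linearly dependent (the level-0
match column equals edges - nodefactor + level-1 match), so that design is
never identifiable; :func:`check_identifiability` detects and names such
collinear sets before fitting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

__all__ = [
    "TermSpec",
    "RankReport",
    "ERGMFit",
    "dyad_change_matrix",
    "dyad_design",
    "network_statistics",
    "check_identifiability",
    "fit_ergm",
    "exact_small_graph_loglik",
]

_DYAD_INDEPENDENT_KINDS = {
    "edges",
    "nodefactor",
    "nodecov",
    "nodematch",
    "nodematch_diff",
    "absdiff",
}


@dataclass(frozen=True)
class TermSpec:
    """One model statistic.

    Parameters
    ----------
    kind
        One of ``edges, nodefactor, nodecov, nodematch, nodematch_diff,
        absdiff``.
    attr
        Node-attribute name (all kinds except ``edges``).
    level
        Attribute level for ``nodefactor`` / ``nodematch_diff``.
    """

    kind: str
    attr: str | None = None
    level: Hashable | None = None

    def __post_init__(self):
        if self.kind not in _DYAD_INDEPENDENT_KINDS:
            raise ValueError(
                f"unsupported (dyad-dependent?) term kind: {self.kind!r}; "
                f"supported: {sorted(_DYAD_INDEPENDENT_KINDS)}"
            )
        if self.kind != "edges" and self.attr is None:
            raise ValueError(f"term {self.kind!r} requires an attribute name")
        if self.kind in ("nodefactor", "nodematch_diff") and self.level is None:
            raise ValueError(f"term {self.kind!r} requires a level")

    @property
    def name(self) -> str:
        parts = [self.kind]
        if self.attr is not None:
            parts.append(str(self.attr))
        if self.level is not None:
            parts.append(str(self.level))
        return ".".join(parts)


def _attribute_matrix(
    attrs: Mapping[str, Sequence] | pd.DataFrame, nodes: Sequence, name: str
) -> np.ndarray:
    if isinstance(attrs, pd.DataFrame):
        vals = attrs.loc[list(nodes), name].to_numpy()
    else:
        vals = np.asarray([attrs[name][v] for v in nodes])
    return vals


def dyad_change_matrix(
    nodes: Sequence,
    attrs: pd.DataFrame | Mapping,
    terms: Sequence[TermSpec],
) -> tuple[np.ndarray, list[tuple]]:
    """Change-statistic design matrix over all unordered dyads.

    Row ``d`` holds, for dyad ``{i, j}``, each term's contribution to its
    network statistic when the tie is present. Returns ``(X, dyads)`` with
    dyads ordered by ``itertools.combinations`` over ``nodes``.
    """
    nodes = list(nodes)
    n = len(nodes)
    dyads = list(itertools.combinations(range(n), 2))
    iu = np.array([d[0] for d in dyads], dtype=int)
    ju = np.array([d[1] for d in dyads], dtype=int)
    cols = []
    for t in terms:
        if t.kind == "edges":
            cols.append(np.ones(len(dyads)))
            continue
        x = _attribute_matrix(attrs, nodes, t.attr)
        if t.kind == "nodefactor":
            cols.append((x[iu] == t.level).astype(float) + (x[ju] == t.level).astype(float))
        elif t.kind == "nodecov":
            cols.append(x[iu].astype(float) + x[ju].astype(float))
        elif t.kind == "nodematch":
            cols.append((x[iu] == x[ju]).astype(float))
        elif t.kind == "nodematch_diff":
            cols.append(((x[iu] == t.level) & (x[ju] == t.level)).astype(float))
        elif t.kind == "absdiff":
            cols.append(np.abs(x[iu].astype(float) - x[ju].astype(float)))
    X = np.column_stack(cols) if cols else np.empty((len(dyads), 0))
    return X, [(nodes[i], nodes[j]) for i, j in dyads]


def _node_attr_frame(net: nx.Graph, terms: Sequence[TermSpec]) -> pd.DataFrame:
    names = sorted({t.attr for t in terms if t.attr is not None})
    data = {}
    for name in names:
        vals = nx.get_node_attributes(net, name)
        missing = [v for v in net.nodes if v not in vals]
        if missing:
            raise KeyError(
                f"attribute {name!r} missing on {len(missing)} node(s), e.g. {missing[:3]}"
            )
        data[name] = [vals[v] for v in net.nodes]
    return pd.DataFrame(data, index=list(net.nodes))


def dyad_design(
    net: nx.Graph, terms: Sequence[TermSpec]
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Per-dyad change statistics and tie indicators for a network.

    Returns ``(X, a, dyads)``; summing the rows of ``X`` where ``a == 1``
    reproduces :func:`network_statistics` exactly.
    """
    nodes = sorted(net.nodes)
    X, dyads = dyad_change_matrix(nodes, _node_attr_frame(net, terms), terms)
    a = np.array([1.0 if net.has_edge(i, j) else 0.0 for i, j in dyads])
    return X, a, dyads


def network_statistics(net: nx.Graph, terms: Sequence[TermSpec]) -> np.ndarray:
    """Evaluate each term's network statistic ``g_p(a, x)``.

    Every unordered edge is counted once: ``edges`` is the edge count,
    ``nodefactor`` counts level-k endpoints over edges, ``nodecov`` /
    ``absdiff`` sum ``x_i + x_j`` / ``|x_i - x_j|`` over edges, and the
    match terms count attribute-matching edges.
    """
    out = np.zeros(len(terms))
    for p, t in enumerate(terms):
        if t.kind == "edges":
            out[p] = net.number_of_edges()
            continue
        x = nx.get_node_attributes(net, t.attr)
        tot = 0.0
        for i, j in net.edges:
            xi, xj = x[i], x[j]
            if t.kind == "nodefactor":
                tot += (xi == t.level) + (xj == t.level)
            elif t.kind == "nodecov":
                tot += xi + xj
            elif t.kind == "nodematch":
                tot += xi == xj
            elif t.kind == "nodematch_diff":
                tot += (xi == t.level) and (xj == t.level)
            elif t.kind == "absdiff":
                tot += abs(xi - xj)
        out[p] = tot
    return out


@dataclass
class RankReport:
    """Numeric rank diagnosis of a change-statistic design matrix."""

    n_columns: int
    rank: int
    term_names: list[str]
    collinear_sets: list[list[str]] = field(default_factory=list)

    @property
    def deficiency(self) -> int:
        return self.n_columns - self.rank

    @property
    def full_rank(self) -> bool:
        return self.deficiency == 0


def check_identifiability(
    X: np.ndarray, term_names: Sequence[str], tol_factor: float = 1e-8
) -> RankReport:
    """Detect linear dependence among design columns.

    Rank is the number of singular values above ``tol_factor`` times the
    largest. For each deficiency, the columns loading on the corresponding
    null-space vector are reported as a named collinear set (e.g. the
    edges/nodefactor/differential-nodematch dependence for a binary
    attribute).
    """
    names = list(term_names)
    if X.size == 0:
        return RankReport(X.shape[1], 0, names)
    # economy SVD unless rows < columns (then Vt must still be p x p)
    u, s, vt = np.linalg.svd(X, full_matrices=X.shape[0] < X.shape[1])
    tol = tol_factor * s[0] if s.size else 0.0
    rank = int(np.sum(s > tol))
    sets = []
    for r in range(rank, X.shape[1]):
        v = vt[r]
        involved = [names[k] for k in np.flatnonzero(np.abs(v) > 1e-6)]
        sets.append(involved)
    return RankReport(X.shape[1], rank, names, sets)


@dataclass
class ERGMFit:
    """Maximum-likelihood fit of a dyad-independent ERGM.

    ``coefficients`` has one row per term: estimate, standard error from
    the observed information, Wald z and two-sided p. ``diverged`` names
    terms whose estimates ran to the boundary (perfect separation, e.g.
    the edges coefficient on an empty or complete graph).
    """

    terms: list[TermSpec]
    coefficients: pd.DataFrame
    loglik: float
    n_dyads: int
    rank_report: RankReport
    diverged: list[str] = field(default_factory=list)

    @property
    def eta(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Newton-Raphson logistic MLE with step halving.

    Hand-rolled (rather than a statsmodels call) so that separation is
    detected by coefficient escape instead of an exception, and so fits
    stay cheap inside simulation loops.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu)
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood monotone
        ll0 = _bernoulli_loglik(X, y, beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _bernoulli_loglik(X, y, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    mu = expit(X @ beta)
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None])
    return beta, H


def _bernoulli_loglik(X, y, beta):
    z = X @ beta
    # log p = y*z - log(1+e^z), numerically stable
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def fit_ergm(net: nx.Graph, terms: Sequence[TermSpec]) -> ERGMFit:
    """Exact MLE of a dyad-independent ERGM by per-dyad logistic regression.

    Raises ``ValueError`` naming the collinear term set if the design is
    rank deficient. Coefficients whose magnitude escapes past 30 (tie
    probabilities numerically 0/1) are flagged as diverged with infinite
    sign-matched estimates and undefined standard errors.
    """
    terms = list(terms)
    X, a, dyads = dyad_design(net, terms)
    names = [t.name for t in terms]
    report = check_identifiability(X, names)
    if not report.full_rank:
        raise ValueError(
            "design is rank deficient; collinear term sets: "
            + "; ".join("{" + ", ".join(s) + "}" for s in report.collinear_sets)
        )
    beta, H = _newton_logistic(X, a)
    diverged = [names[k] for k in np.flatnonzero(np.abs(beta) > 30.0)]
    se = np.full(len(beta), np.nan)
    try:
        cov = np.linalg.inv(H)
        ok = np.diag(cov) > 0
        se[ok] = np.sqrt(np.diag(cov)[ok])
    except np.linalg.LinAlgError:
        pass
    est = beta.copy()
    for k in np.flatnonzero(np.abs(beta) > 30.0):
        est[k] = math.inf if beta[k] > 0 else -math.inf
        se[k] = np.nan
    z = np.where(np.isfinite(est) & (se > 0), est / se, np.nan)
    from scipy.stats import norm

    pvals = np.where(np.isnan(z), np.nan, 2 * norm.sf(np.abs(z)))
    coef = pd.DataFrame(
        {"term": names, "estimate": est, "se": se, "z": z, "p": pvals}
    ).set_index("term", drop=False)
    return ERGMFit(
        terms=terms,
        coefficients=coef,
        loglik=_bernoulli_loglik(X, a, beta),
        n_dyads=len(dyads),
        rank_report=report,
        diverged=diverged,
    )


def exact_small_graph_loglik(
    nodes: Sequence,
    attrs: pd.DataFrame | Mapping,
    terms: Sequence[TermSpec],
    eta: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized log-probability of every graph on ``nodes`` (n <= 5).

    Enumerates all ``2^(n(n-1)/2)`` graphs, computes each graph's statistic
    vector and returns ``(log_probs, edge_masks)`` where ``edge_masks`` is
    the boolean dyad-inclusion matrix (dyads in ``itertools.combinations``
    order). The normalizing constant is evaluated by direct summation, so
    probabilities sum to one to machine precision.
    """
    nodes = list(nodes)
    n = len(nodes)
    if n > 5:
        raise ValueError("exact enumeration is limited to n <= 5 nodes")
    X, dyads = dyad_change_matrix(nodes, attrs, terms)
    eta = np.asarray(eta, dtype=float)
    m = len(dyads)
    n_graphs = 1 << m
    masks = (
        (np.arange(n_graphs)[:, None] >> np.arange(m)[None, :]) & 1
    ).astype(bool)
    # dyad-independence: g(a) = sum of included rows of X
    g = masks.astype(float) @ X
    unnorm = g @ eta
    log_kappa = logsumexp(unnorm)
    return unnorm - log_kappa, masks
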