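"""Network topology: centralities, degree-distribution fit, hubs, role contrasts.

Centralities are the standard unweighted ones: degree, betweenness
(fraction of all-pairs shortest paths through a node) and closeness
((n-1) over the summed shortest-path distances, computed per connected
component).  The degree distribution is summarised by an ordinary
least-squares line on log10(frequency) vs log10(degree); hubs are the top
10% of nodes by degree (round-half-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, normalized betweenness and closeness centrality.

    Closeness is computed within each connected component
    ((n_comp - 1) / sum of distances; 0 for isolated nodes).  Betweenness
    is normalized by the number of node pairs (n-1)(n-2)/2.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=True)
    # wf_improved=False yields (n_comp - 1) / sum(d) within each component
    closeness = nx.closeness_centrality(net, wf_improved=False)
    nodes = sorted(net.nodes)
    return pd.DataFrame(
        {
            "node": nodes,
            "role": [net.nodes[n].get("role") for n in nodes],
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
        }
    ).set_index("node")


@dataclass
class PowerLawFit:
    exponent: float
    r_squared: float
    fitted_points: list[tuple[float, float]]  # (log10 degree, log10 frequency)


def fit_power_law(degrees) -> PowerLawFit:
    """OLS fit of log10(frequency) on log10(degree) over distinct degrees.

    Degree-zero nodes are ignored (log undefined).  The exponent is the
    negated slope; r_squared is the coefficient of determination of the
    line.  Requires at least 3 distinct positive degrees.
    """
    vals, counts = np.unique(np.asarray(list(degrees), dtype=int), return_counts=True)
    mask = vals > 0
    vals, counts = vals[mask], counts[mask]
    if len(vals) < 3:
        raise ValueError("underdetermined fit: need >= 3 distinct positive degrees")
    lx = np.log10(vals)
    ly = np.log10(counts)
    fit = stats.linregress(lx, ly)
    return PowerLawFit(
        exponent=float(-fit.slope),
        r_squared=float(fit.rvalue**2),
        fitted_points=list(zip(lx.tolist(), ly.tolist())),
    )


def hub_count(n: int, fraction: float = 0.10) -> int:
    """Number of hubs for an n-node network: round-half-up(fraction * n), >= 1."""
    if n < 1:
        raise ValueError("empty network")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    # floor(x + 0.5) implements round-half-up without banker's rounding
    return max(1, math.floor(n * fraction + 0.5))


def select_hubs(
    table: pd.DataFrame, fraction: float = 0.10, net: nx.Graph | None = None
):
    """Top-``fraction`` of nodes by degree (ties broken by node id ascending).

    Returns ``(hub_ids, hub_subgraph)``; the induced hub subgraph is None
    when no graph is supplied.
    """
    if len(table) == 0:
        raise ValueError("empty centrality table")
    k = hub_count(len(table), fraction)
    # mergesort is stable; pre-sorting by id gives the deterministic tie-break
    ranked = (
        table.sort_index()
        .sort_values(by="degree", ascending=False, kind="mergesort")
    )
    hubs = list(ranked.index[:k])
    sub = nx.Graph(net.subgraph(hubs)) if net is not None else None
    return hubs, sub


_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def wilcoxon_rank_sum(group_a, group_b, alternative: str = "two_sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample is small
    (nA + nB <= 20) and tie-free, otherwise the normal approximation with
    midranks, tie correction and continuity correction.  Returns the
    Mann-Whitney U statistic of group A and the p-value.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=_ALTERNATIVES[alternative], method=method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def compare_roles(
    table: pd.DataFrame,
    metric: str,
    role_a: str,
    role_b: str,
    restrict_to=None,
    alternative: str = "two_sided",
) -> dict:
    """Rank-sum comparison of a centrality metric between two node roles."""
    if metric not in ("degree", "closeness", "betweenness"):
        raise ValueError(f"unknown metric {metric!r}")
    t = table if restrict_to is None else table.loc[table.index.isin(set(restrict_to))]
    va = t.loc[t["role"] == role_a, metric].to_numpy()
    vb = t.loc[t["role"] == role_b, metric].to_numpy()
    for role, v in ((role_a, va), (role_b, vb)):
        if v.size == 0:
            raise ValueError(f"role {role!r} absent from table")
    stat, p = wilcoxon_rank_sum(va, vb, alternative=alternative)
    return {
        "metric": metric,
        "role_a": role_a,
        "role_b": role_b,
        "n_a": int(va.size),
        "n_b": int(vb.size),
        "median_a": float(np.median(va)),
        "median_b": float(np.median(vb)),
        "statistic": stat,
        "p_value": p,
    }
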