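"""Characterise IceNet topology: centralities, degree-distribution fit, hubs.

Computes degree, betweenness and closeness per node, fits a power law to
the degree distribution by log-log least squares, selects the top 10% of
nodes by degree as hubs, and contrasts centralities between inflammatory
genes and their ceRNA partners (Wilcoxon rank-sum).

Usage: python analysis/04_topology.py [--network results/run/icenet.graphml] [--out results/run]
"""

import argparse
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from icenet.topology import (
    compare_roles,
    compute_centralities,
    fit_power_law,
    select_hubs,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--network", type=Path, default=Path("results/run/icenet.graphml"))
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--hub-fraction", type=float, default=0.10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ice = nx.read_graphml(args.network)
    table = compute_centralities(ice)
    fit = fit_power_law(table["degree"])
    hubs, hub_net = select_hubs(table, args.hub_fraction, net=ice)

    comparisons = {}
    for metric in ("degree", "closeness"):
        comparisons[metric] = compare_roles(table, metric, "mRNA", "inflammatory")
    hub_roles = set(table.loc[table.index.isin(hubs), "role"])
    if {"mRNA", "inflammatory"} <= hub_roles:
        comparisons["betweenness_hubs"] = compare_roles(
            table, "betweenness", "mRNA", "inflammatory", restrict_to=hubs
        )

    table.to_csv(args.out / "centralities.tsv", sep="\t", float_format="%.17g")
    (args.out / "power_law.json").write_text(
        json.dumps({"exponent": fit.exponent, "r_squared": fit.r_squared}, indent=2)
    )
    pd.Series(hubs, name="hub").to_csv(args.out / "hubs.tsv", sep="\t", index=False)
    nx.write_graphml(hub_net, args.out / "hub_subnetwork.graphml")
    (args.out / "role_comparisons.json").write_text(json.dumps(comparisons, indent=2))

    print(f"{len(table)} nodes; degree distribution log-log fit: "
          f"exponent {fit.exponent:.2f}, R^2 {fit.r_squared:.3f}")
    print(f"hubs (top {args.hub_fraction:.0%} by degree): {len(hubs)}")
    for metric, rep in comparisons.items():
        print(f"  {metric}: median mRNA {rep['median_a']:.3g} vs "
              f"inflammatory {rep['median_b']:.3g}, rank-sum p={rep['p_value']:.3g}")


if __name__ == "__main__":
    main()
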