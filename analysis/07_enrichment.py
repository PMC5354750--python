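"""Over-representation of the prognostic module's network neighborhood.

A stand-in for web-service pathway annotation: gene sets are the planted
functional groups of the synthetic scenario (modules, hub regulons) plus
random decoy sets, the universe is every molecule in the expression
matrix, and the query is the best module's members and first neighbors
in IceNet.  The planted sets containing the module should surface with
small q-values; decoys should not.

Usage: python analysis/07_enrichment.py [--data results/data] [--run results/run]
"""

import argparse
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from icenet import scenario
from icenet.enrichment import GeneSetCollection, ora_hypergeometric
from icenet.synthetic import read_fixture_bundle


def build_gene_sets(universe: set[str], seed: int) -> GeneSetCollection:
    rng = np.random.default_rng(seed)
    sets = {
        "planted_prognostic_module": set(scenario.PROGNOSTIC_MODULE),
        "planted_decoy_module_1": set(scenario.DECOY_MODULE_1),
        "planted_decoy_module_2": set(scenario.DECOY_MODULE_2),
    }
    for hub, leaves in scenario.HUB_STARS.items():
        sets[f"hub_regulon_{hub}"] = {hub, *leaves}
    pool = sorted(universe)
    for i in range(5):
        sets[f"random_set_{i}"] = set(rng.choice(pool, size=15, replace=False))
    return GeneSetCollection(sets=sets, universe=universe)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    bundle = read_fixture_bundle(args.data)
    universe = set(bundle["expression"].index)
    modules = pd.read_csv(args.run / "modules.tsv", sep="\t")
    screen = pd.read_csv(args.run / "module_screen.tsv", sep="\t")
    best_members = set(
        modules.set_index("module_index")
        .loc[int(screen["module_index"].iloc[0]), "members"]
        .split(",")
    )
    ice = nx.read_graphml(args.run / "icenet.graphml")
    neighbors = {
        n for m in best_members if m in ice for n in ice.neighbors(m)
    }
    query = best_members | neighbors

    coll = build_gene_sets(universe, seed=bundle["config"].seed)
    report = ora_hypergeometric(query, coll)
    report.to_csv(args.run / "enrichment.tsv", sep="\t", index=False,
                  float_format="%.17g")

    print(f"query: {len(query)} molecules (module + first neighbors)")
    print("top enriched sets (q < 0.05):")
    for r in report[report["q"] < 0.05].itertuples():
        print(f"  {r.set_name}: overlap {r.overlap}/{r.set_size}, "
              f"p={r.p:.2e}, q={r.q:.2e}")


if __name__ == "__main__":
    main()
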