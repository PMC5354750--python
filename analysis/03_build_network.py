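"""Infer ceRNA pairs and extract the inflammatory subnetwork (IceNet).

Candidate pairs share at least one miRNA; a pair is accepted when the
shared-regulator overlap is hypergeometrically significant (P < 0.05) and
the pair is positively co-expressed (Pearson rho > 0.5).  The
inflammatory subnetwork is the largest connected component of the
inflammatory genes plus their first neighbors.

Usage: python analysis/03_build_network.py [--data results/data] [--out results/run]
"""

import argparse
from pathlib import Path

import networkx as nx
import pandas as pd

from icenet.cerna import (
    MiRNATargetMap,
    build_cerna_network,
    extract_icenet,
    infer_cerna_pairs,
)
from icenet.synthetic import read_fixture_bundle


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--p-thresh", type=float, default=0.05)
    ap.add_argument("--rho-thresh", type=float, default=0.5)
    ap.add_argument("--tail", choices=("gt", "ge"), default="gt")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = read_fixture_bundle(args.data)
    tmap = MiRNATargetMap.from_frame(bundle["interactions"])
    expr = bundle["expression"]
    inflammatory = set(bundle["inflammatory_genes"])
    types = bundle["config"].molecule_types

    pairs = infer_cerna_pairs(
        tmap, expr, p_thresh=args.p_thresh, rho_thresh=args.rho_thresh,
        tail=args.tail,
    )
    accepted = pairs[pairs["accepted"]]
    net = build_cerna_network(pairs, inflammatory, types)
    ice = extract_icenet(net, inflammatory)

    pairs.to_csv(args.out / "pairs.tsv", sep="\t", index=False,
                 float_format="%.17g")
    nx.write_graphml(net, args.out / "cerna_network.graphml")
    nx.write_graphml(ice, args.out / "icenet.graphml")
    roles = pd.DataFrame(
        {
            "node": sorted(ice.nodes),
            "role": [ice.nodes[n]["role"] for n in sorted(ice.nodes)],
            "degree": [ice.degree(n) for n in sorted(ice.nodes)],
        }
    )
    roles.to_csv(args.out / "icenet_nodes.tsv", sep="\t", index=False)

    n_lnc = (accepted[["a", "b"]].apply(lambda c: c.map(types)) == "lncRNA").any(axis=1)
    print(f"candidates with >=1 shared miRNA: {len(pairs)}")
    print(f"accepted ceRNA pairs: {len(accepted)} "
          f"({int(n_lnc.sum())} lncRNA-mRNA, {int((~n_lnc).sum())} mRNA-mRNA)")
    print(f"full network: {net.number_of_nodes()} nodes / {net.number_of_edges()} edges")
    print(f"IceNet: {ice.number_of_nodes()} nodes / {ice.number_of_edges()} edges, "
          f"{sum(1 for n in ice if ice.nodes[n]['role'] == 'inflammatory')} inflammatory")


if __name__ == "__main__":
    main()
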