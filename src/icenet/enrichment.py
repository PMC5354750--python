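"""Over-representation analysis against user-supplied gene sets.

A generic hypergeometric enrichment test (one-sided, P(X >= overlap)) with
Benjamini-Hochberg FDR control, applied to any GMT-style collection
restricted to a declared gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeometric_overlap_p

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        restricted = {}
        for name, genes in self.sets.items():
            g = set(genes) & self.universe
            if g:
                restricted[name] = g
            else:
                logger.warning("gene set %r empty after universe restriction", name)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe: set[str]) -> "GeneSetCollection":
        """Read a GMT file (set name, description, then member genes per line)."""
        sets: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = set(fields[2:])
        return cls(sets=sets, universe=universe)


def ora_hypergeometric(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Per-set overlap and hypergeometric p-value P(X >= overlap).

    The query is restricted to the collection universe (violations are
    dropped with a log entry).  Returns a frame with columns
    (set_name, overlap, set_size, query_size, p, q) sorted by p; q is the
    BH-adjusted p-value.
    """
    q = set(query) & collection.universe
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("%d query genes outside the universe dropped", dropped)
    if not q:
        raise ValueError("query empty after restriction to universe")
    N = len(collection.universe)
    M = len(q)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        x = len(q & genes)
        p = hypergeometric_overlap_p(N=N, K=K, M=M, x=x, tail="ge")
        rows.append(
            {"set_name": name, "overlap": x, "set_size": K, "query_size": M, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "set_name"]).reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clamped to <= 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
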