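"""Inference of miRNA-mediated ceRNA pairs and the inflammatory subnetwork.

Two transcripts are called a candidate ceRNA pair when at least one miRNA
regulates both of them.  A candidate is accepted when (i) the overlap of
their regulator sets is larger than expected by chance under a
hypergeometric null and (ii) the pair is positively co-expressed
(sample Pearson correlation above a threshold).  Accepted pairs form an
undirected co-regulation network from which the inflammatory-gene-related
subnetwork ("IceNet") is extracted: inflammatory genes plus their first
neighbors, reduced to the largest connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats

logger = logging.getLogger(__name__)

VALID_TYPES = ("mRNA", "lncRNA")


@dataclass
class MiRNATargetMap:
    """Bipartite miRNA -> target map.

    Parameters
    ----------
    entries
        Mapping from miRNA id to the set of its target molecule ids.
        miRNAs with no recorded targets may appear with an empty set and
        still count toward the universe size ``n_mirna``.
    target_types
        Mapping from molecule id to ``"mRNA"`` or ``"lncRNA"``.  Every
        molecule of the universe appears here, including molecules with
        no regulators.
    """

    entries: dict[str, set[str]]
    target_types: dict[str, str]
    _regulators: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for mol, t in self.target_types.items():
            if t not in VALID_TYPES:
                raise ValueError(f"unknown target type {t!r} for {mol!r}")
        rev: dict[str, set[str]] = {m: set() for m in self.target_types}
        for mirna, targets in self.entries.items():
            for t in targets:
                if t not in rev:
                    raise ValueError(
                        f"target {t!r} of {mirna!r} missing from target_types"
                    )
                rev[t].add(mirna)
        self._regulators = rev

    @property
    def n_mirna(self) -> int:
        """Universe size N: the number of distinct miRNAs in the map."""
        return len(self.entries)

    @property
    def molecules(self) -> list[str]:
        return sorted(self.target_types)

    def regulators_of(self, molecule: str) -> set[str]:
        return self._regulators[molecule]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MiRNATargetMap":
        """Build from a long table with columns (miRNA, target, target_type)."""
        entries: dict[str, set[str]] = {}
        types: dict[str, str] = {}
        for mirna, target, ttype in df.itertuples(index=False):
            entries.setdefault(mirna, set()).add(target)
            prev = types.setdefault(target, ttype)
            if prev != ttype:
                raise ValueError(f"conflicting types for target {target!r}")
        return cls(entries=entries, target_types=types)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (mirna, t, self.target_types[t])
            for mirna in sorted(self.entries)
            for t in sorted(self.entries[mirna])
        ]
        return pd.DataFrame(rows, columns=["miRNA", "target", "target_type"])


@dataclass(frozen=True)
class CeRNAPair:
    """An accepted or candidate ceRNA pair with its test evidence."""

    a: str
    b: str
    x: int  # shared miRNAs
    K: int  # regulators of a
    M: int  # regulators of b
    N: int  # miRNA universe size
    p_value: float
    rho: float


def hypergeometric_overlap_p(
    N: int, K: int, M: int, x: int, tail: str = "gt"
) -> float:
    """Tail probability of the shared-regulator overlap test.

    The null draws M regulators of one molecule from a universe of N
    miRNAs, of which K regulate the other molecule; ``x`` is the observed
    overlap.  ``tail="gt"`` returns P(X > x) (one minus the CDF at x);
    ``tail="ge"`` returns P(X >= x).

    Computed with the hypergeometric survival function, clamped to [0, 1].
    """
    if not (0 <= K <= N and 0 <= M <= N):
        raise ValueError(f"need 0 <= K, M <= N; got N={N}, K={K}, M={M}")
    lo, hi = max(0, K + M - N), min(K, M)
    if not lo <= x <= hi:
        raise ValueError(
            f"overlap x={x} outside support [{lo}, {hi}] for N={N}, K={K}, M={M}"
        )
    if tail == "gt":
        p = stats.hypergeom.sf(x, N, K, M)
    elif tail == "ge":
        p = stats.hypergeom.sf(x - 1, N, K, M)
    else:
        raise ValueError(f"tail must be 'gt' or 'ge', got {tail!r}")
    return float(min(1.0, max(0.0, p)))


def pearson_correlation(xvec, yvec) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(xvec, dtype=float)
    y = np.asarray(yvec, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined (sigma = 0)")
    return float(stats.pearsonr(x, y).statistic)


def _allowed_pair(ta: str, tb: str, allow_lnc_lnc: bool) -> bool:
    # mirrors the reported pair classes: mRNA-mRNA and lncRNA-mRNA only
    if ta == "lncRNA" and tb == "lncRNA":
        return allow_lnc_lnc
    return True


def infer_cerna_pairs(
    tmap: MiRNATargetMap,
    expr: pd.DataFrame,
    p_thresh: float = 0.05,
    rho_thresh: float = 0.5,
    tail: str = "gt",
    allow_lnc_lnc: bool = False,
) -> pd.DataFrame:
    """Score every candidate ceRNA pair and apply both filters.

    Candidates are unordered molecule pairs sharing at least one miRNA,
    restricted to mRNA-mRNA and lncRNA-mRNA combinations unless
    ``allow_lnc_lnc``.  A pair is accepted when ``p < p_thresh`` and
    ``rho > rho_thresh`` (both strict).

    Returns a frame with columns (a, b, x, K, M, N, p, rho, accepted),
    sorted by (p, -rho, a, b).  Molecules in the map but absent from
    ``expr`` (or with constant expression) are skipped with a log entry.
    """
    universe = tmap.molecules
    present = [m for m in universe if m in expr.index]
    skipped = len(universe) - len(present)
    if skipped:
        logger.warning("%d map molecules absent from expression; skipped", skipped)

    X = expr.loc[present].to_numpy(dtype=float)
    const = np.ptp(X, axis=1) == 0
    if const.any():
        logger.warning(
            "%d molecules with constant expression skipped", int(const.sum())
        )
        present = [m for m, c in zip(present, const) if not c]
        X = expr.loc[present].to_numpy(dtype=float)

    n_mol = len(present)
    cols = ["a", "b", "x", "K", "M", "N", "p", "rho", "accepted"]
    if n_mol < 2:
        return pd.DataFrame(columns=cols)

    mirnas = sorted(tmap.entries)
    midx = {m: i for i, m in enumerate(mirnas)}
    rows, colixs = [], []
    for j, mol in enumerate(present):
        for mi in tmap.regulators_of(mol):
            rows.append(midx[mi])
            colixs.append(j)
    A = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, colixs)),
        shape=(len(mirnas), n_mol),
    )
    shared = (A.T @ A).tocoo()  # shared-regulator counts between molecules
    K_counts = np.asarray(A.sum(axis=0)).ravel()
    N = tmap.n_mirna

    types = [tmap.target_types[m] for m in present]
    ii, jj, xx = [], [], []
    for i, j, v in zip(shared.row, shared.col, shared.data):
        if i < j and v >= 1 and _allowed_pair(types[i], types[j], allow_lnc_lnc):
            ii.append(i)
            jj.append(j)
            xx.append(int(v))
    if not ii:
        return pd.DataFrame(columns=cols)
    ii = np.array(ii)
    jj = np.array(jj)
    xx = np.array(xx)
    K = K_counts[ii]
    M = K_counts[jj]
    if tail == "gt":
        p = stats.hypergeom.sf(xx, N, K, M)
    elif tail == "ge":
        p = stats.hypergeom.sf(xx - 1, N, K, M)
    else:
        raise ValueError(f"tail must be 'gt' or 'ge', got {tail!r}")
    p = np.clip(p, 0.0, 1.0)

    Z = X - X.mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    rho = np.einsum("ij,ij->i", Z[ii], Z[jj])
    rho = np.clip(rho, -1.0, 1.0)

    names = np.array(present)
    out = pd.DataFrame(
        {
            "a": names[ii],
            "b": names[jj],
            "x": xx,
            "K": K,
            "M": M,
            "N": N,
            "p": p,
            "rho": rho,
        }
    )
    out["accepted"] = (out["p"] < p_thresh) & (out["rho"] > rho_thresh)
    out = out.sort_values(
        by=["p", "rho", "a", "b"], ascending=[True, False, True, True]
    ).reset_index(drop=True)
    return out


def build_cerna_network(
    pairs: pd.DataFrame,
    inflammatory_genes: set[str],
    molecule_types: dict[str, str],
) -> nx.Graph:
    """Assemble the undirected ceRNA network from accepted pairs.

    Node roles follow the precedence inflammatory > lncRNA > mRNA: an
    inflammatory gene keeps the role "inflammatory" even though it is an
    mRNA.  Edges carry the pair evidence (x, K, M, N, p, rho).
    """
    if len(pairs) == 0:
        raise ValueError("no pairs supplied")
    if "accepted" in pairs.columns:
        pairs = pairs[pairs["accepted"]]
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        for mol in (row.a, row.b):
            if mol not in molecule_types:
                raise ValueError(f"unknown molecule type for {mol!r}")
        g.add_edge(
            row.a,
            row.b,
            x=int(row.x),
            K=int(row.K),
            M=int(row.M),
            N=int(row.N),
            p=float(row.p),
            rho=float(row.rho),
        )
    for node in g.nodes:
        if node in inflammatory_genes:
            role = "inflammatory"
        else:
            role = molecule_types[node]
        g.nodes[node]["role"] = role
    return g


def extract_icenet(net: nx.Graph, inflammatory_genes: set[str]) -> nx.Graph:
    """First neighbors of inflammatory genes, largest connected component.

    The subnetwork is induced on the inflammatory genes present in the
    network plus their direct neighbors; of its connected components the
    largest by node count is returned (ties broken by edge count, then by
    lexicographically smallest member id).
    """
    infl = [n for n in net.nodes if n in inflammatory_genes]
    if not infl:
        raise ValueError("empty IceNet: no inflammatory gene present in network")
    keep = set(infl)
    for n in infl:
        keep.update(net.neighbors(n))
    sub = net.subgraph(keep)
    comps = list(nx.connected_components(sub))
    best = min(
        comps,
        key=lambda c: (-len(c), -sub.subgraph(c).number_of_edges(), min(c)),
    )
    return nx.Graph(sub.subgraph(best))
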