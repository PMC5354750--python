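"""Probe-to-lncRNA re-annotation of microarray expression.

Microarray probes designed against mRNAs can be repurposed to measure
lncRNAs: a probe whose genomic interval falls entirely inside exactly one
lncRNA gene span (on the matching strand) is assigned to that gene, and
multiple probes per gene are collapsed by the per-sample median.  All
internal coordinates are 0-based half-open; conversion from GTF's 1-based
closed convention happens at the I/O boundary only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "strand"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


def _validate_bed(path) -> None:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: BED6 needs 6 fields, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")


def read_intervals(path, format: str) -> pd.DataFrame:
    """Read probe (BED6) or gene (GTF) intervals into a coordinate frame.

    GTF records other than feature type "gene" are skipped (count logged);
    GTF 1-based closed coordinates become 0-based half-open.  An empty
    file yields an empty frame.  BED strand "." is kept as "unknown".
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "bed":
        if path.stat().st_size == 0:
            return pd.DataFrame(columns=PROBE_COLUMNS)
        _validate_bed(path)
        g = pr.read_bed(str(path)).df
        out = pd.DataFrame(
            {
                "probe_id": g["Name"].astype(str),
                "chrom": g["Chromosome"].astype(str),
                "start": g["Start"].astype(int),
                "end": g["End"].astype(int),
                "strand": g["Strand"].astype(str).replace({".": "unknown"}),
            }
        )
        return out
    if fmt == "gtf":
        if path.stat().st_size == 0:
            return pd.DataFrame(columns=GENE_COLUMNS)
        try:
            g = pr.read_gtf(str(path)).df  # pyranges already shifts to 0-based
        except Exception as err:
            raise ValueError(f"malformed GTF {path}: {err}") from err
        n_other = int((g["Feature"] != "gene").sum())
        if n_other:
            logger.info("%s: skipped %d non-gene GTF records", path, n_other)
        g = g[g["Feature"] == "gene"]
        if "gene_type" not in g.columns:
            g = g.assign(gene_type="")
        out = pd.DataFrame(
            {
                "gene_id": g["gene_id"].astype(str),
                "chrom": g["Chromosome"].astype(str),
                "start": g["Start"].astype(int),
                "end": g["End"].astype(int),
                "strand": g["Strand"].astype(str).replace({".": "unknown"}),
                "biotype": g["gene_type"].astype(str),
            }
        ).reset_index(drop=True)
        return out
    raise ValueError(f"format must be 'bed' or 'gtf', got {format!r}")


def assign_probes_to_genes(
    probes: pd.DataFrame, genes: pd.DataFrame, mode: str = "containment"
):
    """Assign each probe to the unique gene whose span contains it.

    A probe is assigned iff its interval lies fully inside exactly one
    gene span (``mode="containment"``; ``"any_overlap"`` relaxes to any
    intersection) on the same strand; strand "unknown" matches either.
    Returns ``(mapping, drop_log)`` where ``mapping`` is probe_id ->
    gene_id and ``drop_log`` is a frame (probe_id, reason) with reasons
    in {"no_overlap", "strand", "ambiguous"}.
    """
    if len(probes) == 0 or len(genes) == 0:
        raise ValueError("probe and gene collections must be non-empty")
    if mode not in ("containment", "any_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.gene_id, row.strand)
        )
    mapping: dict[str, str] = {}
    drops = []
    for row in probes.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = tree.overlap(row.start, row.end) if tree is not None else set()
        if mode == "containment":
            hits = {h for h in hits if h.begin <= row.start and row.end <= h.end}
        if not hits:
            drops.append((row.probe_id, "no_overlap"))
            continue
        stranded = {
            h
            for h in hits
            if row.strand == "unknown"
            or h.data[1] == "unknown"
            or h.data[1] == row.strand
        }
        if not stranded:
            drops.append((row.probe_id, "strand"))
            continue
        gene_ids = {h.data[0] for h in stranded}
        if len(gene_ids) > 1:
            drops.append((row.probe_id, "ambiguous"))
            continue
        mapping[row.probe_id] = next(iter(gene_ids))
    drop_log = pd.DataFrame(drops, columns=["probe_id", "reason"])
    return mapping, drop_log


def collapse_probes_median(
    probe_expr: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Collapse probe-level expression to gene level by per-sample median.

    Genes measured by a single probe copy through unchanged; genes with an
    even probe count take the mean of the two central values (the usual
    median convention).  Genes with no mapped probe are absent from the
    output.
    """
    missing = [p for p in mapping if p not in probe_expr.index]
    if missing:
        raise KeyError(f"mapped probes absent from expression: {missing}")
    if not mapping:
        return pd.DataFrame(columns=probe_expr.columns)
    sub = probe_expr.loc[list(mapping)]
    gene_of = pd.Series(mapping)
    out = sub.groupby(gene_of).median()
    out.index.name = "gene_id"
    return out.sort_index()
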