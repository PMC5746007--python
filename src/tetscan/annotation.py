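"""Probe annotation from tabular alignment hits.

Probes were aligned against a cDNA database and exported in the tabular
format ``qseqid sseqid evalue pident stitle``. This module filters hits
(100% identity, e-value <= 1e-20 by default), extracts gene ids from the hit
description field, and builds a unique probe -> gene map joined to gene
coordinates. Running the aligner itself is out of scope; only the tabular
output is consumed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "read_hits",
    "filter_hits",
    "build_probe_gene_map",
    "compare_annotations",
    "ProbeGeneMap",
]

log = logging.getLogger(__name__)

HIT_COLUMNS = ["qseqid", "sseqid", "evalue", "pident", "stitle"]
# gene ids look like FlyBase gene identifiers in the description field;
# configurable because description formats drift between database releases
DEFAULT_GENE_REGEX = r"(FBgn\d+)"


class HitParseError(ValueError):
    """Raised for malformed hit rows, carrying the offending line number."""


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a headerless tabular hit file with columns qseqid sseqid evalue
    pident stitle, validating numeric fields row by row."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise HitParseError(f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}")
            try:
                evalue = float(parts[2])
                pident = float(parts[3])
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: non-numeric evalue/pident") from exc
            if evalue < 0 or not (0 <= pident <= 100):
                raise HitParseError(f"line {lineno}: evalue/pident out of range")
            rows.append((parts[0], parts[1], evalue, pident, "\t".join(parts[4:])))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = 100.0,
    max_evalue: float = 1e-20,
) -> pd.DataFrame:
    """Retain hits with identity >= min_identity and e-value <= max_evalue
    (both boundaries inclusive, exact decimal comparison), preserving input
    order."""
    keep = (hits["pident"] >= min_identity) & (hits["evalue"] <= max_evalue)
    return hits.loc[keep].reset_index(drop=True)


@dataclass
class ProbeGeneMap:
    """A unique probe -> gene assignment with gene coordinates attached.

    ``table`` has one row per probe: probe_id, gene_id, chrom, start, end.
    ``dropped_no_coords`` counts probes whose gene was absent from the gene
    table.
    """

    table: pd.DataFrame
    dropped_no_coords: int = 0

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["gene_id"]))


def build_probe_gene_map(
    retained_hits: pd.DataFrame,
    gene_table: pd.DataFrame,
    gene_regex: str = DEFAULT_GENE_REGEX,
) -> ProbeGeneMap:
    """One gene per probe from filtered hits.

    The gene id is captured from ``stitle`` with ``gene_regex``. A probe with
    several retained hits resolves to the lowest e-value, ties to the first
    occurrence (mirroring a single-best-hit aligner setting); conflicting
    assignments are logged. Probes whose gene has no coordinates in
    ``gene_table`` are dropped with a logged count.
    """
    hits = retained_hits.copy()
    hits["gene_id"] = hits["stitle"].str.extract(gene_regex, flags=re.ASCII)[0]
    n_unparsed = int(hits["gene_id"].isna().sum())
    if n_unparsed:
        log.warning("%d retained hits had no gene id matching %r in stitle", n_unparsed, gene_regex)
    hits = hits.dropna(subset=["gene_id"])

    # stable argmin on e-value within probe: first occurrence wins ties
    hits = hits.reset_index(drop=True)
    best_idx = hits.groupby("qseqid", sort=False)["evalue"].idxmin()
    best = hits.loc[best_idx]
    multi = hits.groupby("qseqid")["gene_id"].nunique()
    n_conflicts = int((multi > 1).sum())
    if n_conflicts:
        log.info("%d probes had retained hits to >1 gene; resolved by lowest e-value", n_conflicts)

    merged = best.merge(gene_table[["gene_id", "chrom", "start", "end"]], on="gene_id", how="left")
    has_coords = merged["chrom"].notna()
    dropped = int((~has_coords).sum())
    if dropped:
        log.info("%d probes dropped: mapped gene lacks coordinates", dropped)
    table = (
        merged.loc[has_coords, ["qseqid", "gene_id", "chrom", "start", "end"]]
        .rename(columns={"qseqid": "probe_id"})
        .reset_index(drop=True)
    )
    return ProbeGeneMap(table=table, dropped_no_coords=dropped)


def compare_annotations(
    map_a: ProbeGeneMap | dict[str, str],
    map_b: ProbeGeneMap | dict[str, str],
    universe: set[str],
    restrict_to: set[str] | None = None,
) -> dict:
    """Fraction of universe probes whose gene assignment differs between two
    annotations; a probe mapped in one and absent in the other counts as a
    mismatch. Optionally also reported after restricting to a retained-probe
    subset (e.g. the probes surviving the expression filter)."""
    if not universe:
        raise ValueError("empty probe universe")
    a = map_a.mapping if isinstance(map_a, ProbeGeneMap) else map_a
    b = map_b.mapping if isinstance(map_b, ProbeGeneMap) else map_b

    def frac(probes: set[str]) -> tuple[int, int]:
        mism = sum(1 for p in probes if a.get(p) != b.get(p))
        return mism, len(probes)

    mism, n = frac(universe)
    out = {"n": n, "n_mismatch": mism, "mismatch_fraction": mism / n}
    if restrict_to is not None:
        sub = universe & restrict_to
        if sub:
            m2, n2 = frac(sub)
            out["restricted"] = {"n": n2, "n_mismatch": m2, "mismatch_fraction": m2 / n2}
        else:
            out["restricted"] = {"n": 0, "n_mismatch": 0, "mismatch_fraction": float("nan")}
    return out
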