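"""Sliding-window scan for positional clustering of DE genes.

If an insertion influenced transcription of physically nearby genes (a cis
effect), DE genes would cluster along the chromosome. The scan orders genes
by position, slides a 10-gene window one gene at a time (neighbouring windows
share 9 genes, giving single-gene resolution), flags windows whose DE
proportion exceeds 30% (i.e. >= 4 of 10), and assesses the flagged-window
count against a permutation null in which gene positions are shuffled
uniformly within each chromosome (or chromosome arm), conserving the number
of DE genes per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneOrder",
    "WindowSet",
    "ScanResult",
    "PermutationResult",
    "order_genes",
    "build_windows",
    "flag_windows",
    "permutation_test",
    "cis_power",
]


@dataclass(frozen=True)
class GeneOrder:
    """Chromosome-ordered gene ids.

    ``per_chrom`` maps chromosome label -> tuple of gene ids sorted by start
    (ties by gene id); ``genome`` concatenates chromosomes in lexicographic
    label order.
    """

    per_chrom: dict[str, tuple[str, ...]]

    @property
    def genome(self) -> tuple[str, ...]:
        out: list[str] = []
        for chrom in sorted(self.per_chrom):
            out.extend(self.per_chrom[chrom])
        return tuple(out)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.per_chrom.values())


@dataclass(frozen=True)
class WindowSet:
    """Sliding windows of ``w`` consecutive genes, step 1.

    Each window is (scope_label, start_index, gene ids); scope is either a
    chromosome label or "GENOME".
    """

    windows: list[tuple[str, int, tuple[str, ...]]]
    w: int


@dataclass
class ScanResult:
    """Per-window DE counts and flags plus per-scope flagged totals."""

    table: pd.DataFrame  # scope, start, de_count, de_prop, flagged
    w: int
    tau: float

    @property
    def flagged_per_scope(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=int)
        return self.table.groupby("scope")["flagged"].sum().astype(int)

    @property
    def flagged_total(self) -> int:
        return int(self.table["flagged"].sum()) if len(self.table) else 0


@dataclass
class PermutationResult:
    """Per-stratum permutation outcome: observed flagged-window count,
    exceedance count over N iterations, and p = (1 + exceed)/(N + 1)."""

    per_stratum: pd.DataFrame  # stratum, observed, n_de, n_windows, exceedance, p
    n_iterations: int
    seed: int


def order_genes(gene_table: pd.DataFrame) -> GeneOrder:
    """Order genes by start within each chromosome, ties by gene id.

    ``gene_table`` needs columns gene_id, chrom, start. Duplicate gene ids
    are rejected.
    """
    if gene_table["gene_id"].duplicated().any():
        dups = gene_table.loc[gene_table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    ordered = gene_table.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    per_chrom = {
        str(chrom): tuple(sub["gene_id"]) for chrom, sub in ordered.groupby("chrom", sort=True)
    }
    return GeneOrder(per_chrom=per_chrom)


def build_windows(order: GeneOrder, w: int = 10, scope: str = "chromosome") -> WindowSet:
    """All w-gene sliding windows (step 1).

    scope="genome": windows over the concatenated order, n - w + 1 of them.
    scope="chromosome": windows within each chromosome, none spanning a
    boundary; a block shorter than w contributes zero windows.
    """
    if w < 2:
        raise ValueError("window size must be >= 2")
    windows: list[tuple[str, int, tuple[str, ...]]] = []
    if scope == "genome":
        genes = order.genome
        for i in range(max(len(genes) - w + 1, 0)):
            windows.append(("GENOME", i, genes[i : i + w]))
    elif scope == "chromosome":
        for chrom in sorted(order.per_chrom):
            genes = order.per_chrom[chrom]
            for i in range(max(len(genes) - w + 1, 0)):
                windows.append((chrom, i, genes[i : i + w]))
    else:
        raise ValueError("scope must be 'genome' or 'chromosome'")
    return WindowSet(windows=windows, w=w)


def flag_windows(windows: WindowSet, de: dict[str, bool] | pd.Series, tau: float = 0.30) -> ScanResult:
    """Flag windows whose DE proportion strictly exceeds tau.

    For w=10, tau=0.30 a window is flagged iff it holds more than 3 DE genes.
    Every window gene must have a DE label.
    """
    labels = de if isinstance(de, dict) else de.to_dict()
    rows = []
    for scope, start, genes in windows.windows:
        try:
            count = sum(bool(labels[g]) for g in genes)
        except KeyError as exc:
            raise ValueError(f"gene {exc.args[0]!r} has no DE label") from None
        prop = count / windows.w
        rows.append((scope, start, count, prop, prop > tau))
    table = pd.DataFrame(rows, columns=["scope", "start", "de_count", "de_prop", "flagged"])
    return ScanResult(table=table, w=windows.w, tau=tau)


ARM_PATTERN = ("2L", "2R", "3L", "3R")


def _strata(order: GeneOrder, stratum: str) -> dict[str, tuple[str, ...]]:
    """Stratify gene blocks for permutation. "arm" keeps 2L/2R/3L/3R separate
    (they already are separate chromosome labels when the gene table names
    arms); "chromosome" merges arms of the same numbered chromosome."""
    if stratum == "arm":
        return dict(order.per_chrom)
    if stratum == "chromosome":
        merged: dict[str, list[str]] = {}
        for chrom in sorted(order.per_chrom):
            key = chrom[:-1] if chrom.endswith(("L", "R")) and chrom[:-1].isdigit() else chrom
            merged.setdefault(key, []).extend(order.per_chrom[chrom])
        return {k: tuple(v) for k, v in merged.items()}
    raise ValueError("stratum must be 'arm' or 'chromosome'")


def _flagged_count(labels: np.ndarray, w: int, min_de: int) -> int:
    """Number of w-windows with DE count >= min_de in a 0/1 label array."""
    if len(labels) < w:
        return 0
    c = np.concatenate(([0], np.cumsum(labels)))
    window_counts = c[w:] - c[:-w]
    return int((window_counts >= min_de).sum())


def permutation_test(
    order: GeneOrder,
    de: dict[str, bool] | pd.Series,
    w: int = 10,
    tau: float = 0.30,
    n_iterations: int = 10_000,
    seed: int = 0,
    stratum: str = "arm",
) -> PermutationResult:
    """Chromosome-stratified permutation test of positional DE clustering.

    Within each stratum the observed flagged-window count is compared with
    the counts obtained after uniformly permuting the DE labels over the
    stratum's positions (equivalent to randomly placing the genes along the
    chromosome), ``n_iterations`` times. The DE-gene total per stratum is
    conserved by construction. One-sided exceedance (count >= observed) with
    the add-one correction: p = (1 + exceedance) / (N + 1). A stratum with
    zero windows reports p = 1 with a warning.
    """
    if n_iterations < 1:
        raise ValueError("need >= 1 iteration")
    labels = de if isinstance(de, dict) else de.to_dict()
    rng = np.random.default_rng(seed)
    min_de = int(np.floor(tau * w)) + 1  # smallest count with proportion > tau
    rows = []
    for name, genes in sorted(_strata(order, stratum).items()):
        lab = np.array([bool(labels[g]) for g in genes], dtype=np.int8)
        n_windows = max(len(lab) - w + 1, 0)
        if n_windows == 0:
            warnings.warn(f"stratum {name!r} has fewer than w genes; p reported as 1")
            rows.append((name, 0, int(lab.sum()), 0, n_iterations, 1.0))
            continue
        observed = _flagged_count(lab, w, min_de)
        exceed = 0
        for _ in range(n_iterations):
            if _flagged_count(rng.permutation(lab), w, min_de) >= observed:
                exceed += 1
        p = (1 + exceed) / (n_iterations + 1)
        rows.append((name, observed, int(lab.sum()), n_windows, exceed, p))
    per_stratum = pd.DataFrame(
        rows, columns=["stratum", "observed", "n_de", "n_windows", "exceedance", "p"]
    )
    return PermutationResult(per_stratum=per_stratum, n_iterations=n_iterations, seed=seed)


def cis_power(
    n_genes_chrom: int,
    cluster_size: int,
    background_rate: float = 0.01,
    w: int = 10,
    tau: float = 0.30,
    n_iterations: int = 1_000,
    n_replicates: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Power of the scan to detect an implanted cis cluster.

    Simulates a single chromosome of ``n_genes_chrom`` genes in which
    ``cluster_size`` consecutive genes at a central locus are DE and the
    remaining genes are DE independently at ``background_rate``; returns the
    fraction of replicates whose stratum permutation p is <= alpha.
    """
    if cluster_size > n_genes_chrom:
        raise ValueError("cluster exceeds chromosome size")
    rng = np.random.default_rng(seed)
    min_de = int(np.floor(tau * w)) + 1
    hits = 0
    start = (n_genes_chrom - cluster_size) // 2
    for _ in range(n_replicates):
        lab = (rng.random(n_genes_chrom) < background_rate).astype(np.int8)
        lab[start : start + cluster_size] = 1
        observed = _flagged_count(lab, w, min_de)
        exceed = 0
        for _ in range(n_iterations):
            if _flagged_count(rng.permutation(lab), w, min_de) >= observed:
                exceed += 1
        if (1 + exceed) / (n_iterations + 1) <= alpha:
            hits += 1
    return hits / n_replicates
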