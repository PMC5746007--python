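"""Cross-strain comparison of expressed and differentially expressed genes.

Three questions about consistency across genomic insertion sites: which genes
are shared between the strains' expressed / DE sets (membership-pattern
counts, the UpSet-style summary); whether shared DE genes change in the same
direction in every strain (fold change > 1 meaning higher expression off
tetracycline); and whether genome-wide tet-off-minus-tet-on difference
vectors correlate between strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "OverlapSummary",
    "set_intersections",
    "direction_consistency",
    "pairwise_diff_correlation",
]


@dataclass
class OverlapSummary:
    """Membership-pattern counts over named gene sets.

    ``patterns`` maps a frozenset of set names to the number of genes with
    exactly that membership; ``totals`` gives per-set sizes.
    """

    names: list[str]
    patterns: dict[frozenset, int]
    totals: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.patterns.values())

    @property
    def intersection_size(self) -> int:
        return self.patterns.get(frozenset(self.names), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(k)), len(k), v)
            for k, v in sorted(self.patterns.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["pattern", "n_sets", "count"])


def set_intersections(sets: dict[str, set]) -> OverlapSummary:
    """Exact count of every non-empty membership pattern over the named sets."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    names = list(sets)
    patterns: dict[frozenset, int] = {}
    universe = set().union(*sets.values())
    for gene in universe:
        member = frozenset(name for name in names if gene in sets[name])
        patterns[member] = patterns.get(member, 0) + 1
    return OverlapSummary(
        names=names,
        patterns=patterns,
        totals={name: len(s) for name, s in sets.items()},
    )


def direction_consistency(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Classify each shared DE gene by the direction of its fold changes.

    ``fold_changes`` is gene x strain on the ratio scale (tet_off / tet_on).
    A gene is consistent-up iff all fold changes > 1, consistent-down iff all
    < 1, else opposite (a fold change exactly 1 counts as opposite). Returns
    the table with a ``classification`` column; summary counts are attached
    as ``DataFrame.attrs['summary']``.
    """
    if fold_changes.isna().any().any():
        raise ValueError("missing fold-change cell(s); every gene needs a value in every strain")
    fc = fold_changes.to_numpy(dtype=float)
    up = (fc > 1).all(axis=1)
    down = (fc < 1).all(axis=1)
    cls = np.where(up, "consistent-up", np.where(down, "consistent-down", "opposite"))
    out = fold_changes.copy()
    out["classification"] = cls
    out.attrs["summary"] = {
        "consistent-up": int(up.sum()),
        "consistent-down": int(down.sum()),
        "opposite": int(len(fc) - up.sum() - down.sum()),
    }
    return out


def pairwise_diff_correlation(diffs: dict[str, pd.Series]) -> pd.DataFrame:
    """Pearson correlation of per-gene expression differences between every
    pair of strains, on each pair's common gene universe (pairwise-complete).

    Returns a long table (strain_a, strain_b, n, r, p); zero-variance vectors
    yield NaN with a warning. p values follow the exact t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 df, two-sided.
    """
    if len(diffs) < 2:
        raise ValueError("need >= 2 difference vectors")
    rows = []
    for a, b in combinations(diffs, 2):
        common = diffs[a].index.intersection(diffs[b].index)
        x = diffs[a].loc[common].to_numpy(dtype=float)
        y = diffs[b].loc[common].to_numpy(dtype=float)
        n = len(common)
        if n < 3:
            raise ValueError(f"pair ({a}, {b}): common universe too small (n={n})")
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"pair ({a}, {b}): zero-variance vector, correlation undefined")
            rows.append((a, b, n, np.nan, np.nan))
            continue
        r, p = pearsonr(x, y)
        rows.append((a, b, n, float(r), float(p)))
    return pd.DataFrame(rows, columns=["strain_a", "strain_b", "n", "r", "p"])


def correlation_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Symmetric unit-diagonal matrix view of the long correlation table."""
    strains = sorted(set(long["strain_a"]) | set(long["strain_b"]))
    mat = pd.DataFrame(np.eye(len(strains)), index=strains, columns=strains)
    for row in long.itertuples(index=False):
        mat.loc[row.strain_a, row.strain_b] = row.r
        mat.loc[row.strain_b, row.strain_a] = row.r
    return mat
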