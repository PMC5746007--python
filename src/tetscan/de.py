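"""Empirical-Bayes moderated t-tests, FDR adjustment and gene collapse.

Each contrast compares tet-off vs tet-on samples within one strain and life
stage. Per-probe pooled two-group statistics are shrunk toward a prior
variance (d0, s0^2) estimated from all probes by moment matching on the log
sample variances (the scaled-inverse-chi-squared hierarchical model). The
moderated t statistic beta / (s_tilde * sqrt(v)) is referred to a t
distribution with d0 + d_g degrees of freedom, p values are adjusted by the
Benjamini-Hochberg step-up procedure, probes are collapsed to one per gene,
and genes are called differentially expressed at adjusted p <= q (default
FDR 10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastSpec",
    "ModerationParams",
    "probe_level_stats",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "collapse_to_genes",
    "call_de",
    "run_contrast",
]

log = logging.getLogger(__name__)

DF_CAP = 1e6  # t reference treated as normal beyond this
VAR_FLOOR = 1e-12


class ContrastError(ValueError):
    pass


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastSpec:
    """tet-off (group A) vs tet-on (group B) within one strain and stage;
    the effect sign convention is mean(A) - mean(B), so positive log2FC means
    higher expression without tetracycline (circuit active)."""

    strain: str
    stage: str
    group_a: tuple[str, ...]  # tet_off sample ids
    group_b: tuple[str, ...]  # tet_on sample ids

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ContrastError("both groups must be non-empty")


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom d0 (possibly +inf) and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (0 disables moderation; +inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def probe_level_stats(matrix: pd.DataFrame, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-probe two-group statistics for one contrast.

    Returns columns ``beta`` (mean A - mean B), ``s_sq`` (pooled variance),
    ``df`` (n_A + n_B - 2) and ``v`` (1/n_A + 1/n_B).
    """
    a_cols = [c for c in contrast.group_a if c in matrix.columns]
    b_cols = [c for c in contrast.group_b if c in matrix.columns]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ContrastError(
            f"{contrast.strain}/{contrast.stage}: need >= 2 samples per group "
            f"(got {len(a_cols)} vs {len(b_cols)})"
        )
    A = matrix[a_cols].to_numpy(dtype=float)
    B = matrix[b_cols].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    beta = A.mean(axis=1) - B.mean(axis=1)
    ss_a = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    s_sq = (ss_a + ss_b) / df
    return pd.DataFrame(
        {"beta": beta, "s_sq": s_sq, "df": float(df), "v": 1.0 / n_a + 1.0 / n_b},
        index=matrix.index,
    )


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(variances: np.ndarray, dfs: np.ndarray | float) -> ModerationParams:
    """Moment-matching estimate of (d0, s0^2) from per-probe sample variances.

    Works on e_g = log s_g^2 - psi(d_g/2) + log(d_g/2): the excess dispersion
    var(e) - mean(trigamma(d_g/2)) determines d0 through the trigamma inverse
    (no excess dispersion => d0 = +inf with s0^2 the mean sample variance),
    and otherwise s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2)).
    """
    s_sq = np.asarray(variances, dtype=float)
    if s_sq.size < 2:
        raise EstimationError("need >= 2 variances to estimate the prior")
    if np.all(s_sq <= 0):
        raise EstimationError("all variances are zero")
    d_g = np.broadcast_to(np.asarray(dfs, dtype=float), s_sq.shape)
    s_sq = np.maximum(s_sq, VAR_FLOOR)
    e = np.log(s_sq) - psi(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(np.mean(_trigamma(d_g / 2.0)))
    if excess <= 0:
        # no excess dispersion: the prior absorbs everything and the prior
        # variance is simply the average sample variance
        return ModerationParams(d0=np.inf, s0_sq=float(np.mean(s_sq)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(stats: pd.DataFrame, prior: ModerationParams) -> pd.DataFrame:
    """Moderated t statistics and two-sided p values.

    s_tilde^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g); t = beta/(s_tilde sqrt(v))
    with d0 + d_g df. d0 = 0 recovers the ordinary pooled t-test; d0 = +inf
    uses s0^2 with the reference capped at 1e6 df (effectively normal).
    """
    beta = stats["beta"].to_numpy(dtype=float)
    s_sq = stats["s_sq"].to_numpy(dtype=float)
    d_g = stats["df"].to_numpy(dtype=float)
    v = stats["v"].to_numpy(dtype=float)
    d0 = prior.d0
    if np.isinf(d0) or d0 >= DF_CAP:
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.minimum(d_g + DF_CAP, DF_CAP)
    else:
        s_tilde_sq = (d0 * prior.s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = np.minimum(d0 + d_g, DF_CAP)
    t_stat = beta / np.sqrt(s_tilde_sq * v)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    p = np.minimum(p, 1.0)
    out = stats.copy()
    out["s_tilde_sq"] = s_tilde_sq
    out["t"] = t_stat
    out["df_total"] = df_total
    out["p"] = p
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_to_genes(
    probe_stats: pd.DataFrame,
    probe_gene: pd.Series | dict[str, str],
    straddle_alpha: float = 0.05,
    identity_col: str | None = None,
) -> pd.DataFrame:
    """Reduce probe-level statistics to one probe per gene.

    Step 1 (straddle rule): groups of identical probes — same value of
    ``identity_col`` if given (e.g. a probe-sequence column), else replicated
    probe ids — whose raw p values fall on both sides of ``straddle_alpha``
    are removed entirely. Step 2: per gene, the surviving probe with the
    lowest raw p is retained (ties to the first occurrence). Probes absent
    from the map are dropped with a logged count. The retained probe carries
    its probe-level adjusted p into the gene table.
    """
    stats = probe_stats.copy()
    stats["probe_id"] = stats.index
    stats = stats.reset_index(drop=True)  # probe ids may repeat on the array
    key = stats[identity_col] if identity_col else stats["probe_id"]
    grp = stats.groupby(key.to_numpy())["p"]
    straddles = grp.transform(lambda s: (s < straddle_alpha).any() and (s >= straddle_alpha).any())
    stats = stats.loc[~straddles.to_numpy(dtype=bool)]

    mapping = probe_gene if isinstance(probe_gene, pd.Series) else pd.Series(probe_gene)
    stats["gene_id"] = mapping.reindex(stats["probe_id"]).to_numpy()
    n_unmapped = int(stats["gene_id"].isna().sum())
    if n_unmapped:
        log.info("%d probes without gene assignment dropped in collapse", n_unmapped)
    stats = stats.dropna(subset=["gene_id"])

    best = stats.loc[stats.groupby("gene_id", sort=False)["p"].idxmin()]
    cols = ["gene_id", "probe_id", "beta", "t", "p"]
    if "adj_p" in best.columns:
        cols.append("adj_p")
    return best[cols].set_index("gene_id").sort_index()


def call_de(gene_stats: pd.DataFrame, q: float = 0.10) -> pd.DataFrame:
    """Flag genes with BH-adjusted p <= q (inclusive boundary). Returns the
    gene table with a boolean ``de`` column added."""
    out = gene_stats.copy()
    out["de"] = out["adj_p"] <= q if len(out) else pd.Series(dtype=bool)
    return out


def run_contrast(
    matrix: pd.DataFrame,
    contrast: ContrastSpec,
    probe_gene: pd.Series | dict[str, str],
    q: float = 0.10,
    straddle_alpha: float = 0.05,
    prior: ModerationParams | None = None,
) -> pd.DataFrame:
    """The full per-contrast chain: probe stats -> prior -> moderated t ->
    probe-level BH -> gene collapse -> DE call."""
    stats = probe_level_stats(matrix, contrast)
    if prior is None:
        prior = estimate_prior(stats["s_sq"].to_numpy(), stats["df"].to_numpy())
    stats = moderated_t(stats, prior)
    stats["adj_p"] = bh_adjust(stats["p"].to_numpy())
    genes = collapse_to_genes(stats, probe_gene, straddle_alpha=straddle_alpha)
    return call_de(genes, q=q)
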