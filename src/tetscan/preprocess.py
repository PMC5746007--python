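"""Background correction, quantile normalization, expression filtering, QC.

Single-channel intensities are modelled as exponential true signal plus
Gaussian background (the "normexp" convolution model). Background parameters
are estimated per sample from negative-control probes by method of moments,
the corrected value is the closed-form posterior mean of the signal, log2 is
taken, and samples of one life stage are quantile-normalized together. The
expression filter then removes probes that sit at least 10% below the 95th
percentile of the negative controls on at least ``min_arrays`` arrays of the
stage, after which control probes themselves are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import norm

__all__ = [
    "NormexpParams",
    "estimate_normexp_params",
    "normexp_correct",
    "normalize_stage",
    "quantile_normalize",
    "low_intensity_filter",
    "qc_summaries",
]

SIGMA_FLOOR = 1e-2
ALPHA_FLOOR = 1.0


class EstimationError(ValueError):
    """Raised when a sample has too few probes to estimate parameters."""


@dataclass(frozen=True)
class NormexpParams:
    """Per-sample convolution-model parameters, all in intensity units:
    background mean ``mu``, background sd ``sigma`` (>= SIGMA_FLOOR) and
    exponential signal mean ``alpha`` (>= ALPHA_FLOOR)."""

    mu: float
    sigma: float
    alpha: float


def estimate_normexp_params(column: np.ndarray, mask: np.ndarray, sample: str = "") -> NormexpParams:
    """Method-of-moments estimates from negative controls.

    mu = mean of controls; sigma = sd of controls floored at SIGMA_FLOOR;
    alpha = mean of regular probes minus mu, floored at ALPHA_FLOOR.
    """
    column = np.asarray(column, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    neg = column[mask]
    reg = column[~mask]
    if len(neg) < 10 or len(reg) < 10:
        raise EstimationError(
            f"sample {sample!r}: need >= 10 negative-control and >= 10 regular probes "
            f"(got {len(neg)} controls, {len(reg)} regular)"
        )
    mu = float(neg.mean())
    sigma = max(float(neg.std(ddof=1)), SIGMA_FLOOR)
    alpha = float(reg.mean()) - mu
    if alpha < ALPHA_FLOOR:
        warnings.warn(f"sample {sample!r}: regular-probe mean at or below background; alpha floored")
        alpha = ALPHA_FLOOR
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_correct(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior mean of the exponential signal given observed intensity.

    With a = x - mu - sigma^2/alpha, the corrected value is
    a + sigma * phi(a/sigma) / Phi(a/sigma). Strictly positive and monotone
    increasing in x for any valid parameters.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensities passed to normexp_correct")
    a = x - params.mu - params.sigma**2 / params.alpha
    z = a / params.sigma
    # phi/Phi via logs for numerical stability far in the left tail
    mills = np.exp(norm.logpdf(z) - log_ndtr(z))
    out = a + params.sigma * mills
    # the closed form is positive; guard against float rounding at z << 0
    return np.maximum(out, 1e-12)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common reference distribution (the across-
    column mean of sorted values); ties within a column receive the mean of
    the reference values their ranks span."""
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in matrix")
    n, m = values.shape
    sorted_cols = np.sort(values, axis=0)
    reference = sorted_cols.mean(axis=1)

    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference values over runs of tied input values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_stage(
    intensities: pd.DataFrame,
    control_mask: pd.Series,
    offset: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, NormexpParams]]:
    """Full per-stage normalization: estimate background per sample, apply the
    normexp correction, log2(+offset), quantile-normalize across the stage's
    samples. Control probes stay in the matrix (the filter needs them)."""
    mask = control_mask.reindex(intensities.index).to_numpy(dtype=bool)
    corrected = {}
    params = {}
    for sample in intensities.columns:
        p = estimate_normexp_params(intensities[sample].to_numpy(), mask, sample=sample)
        params[sample] = p
        corrected[sample] = np.log2(normexp_correct(intensities[sample].to_numpy(), p) + offset)
    log2_mat = pd.DataFrame(corrected, index=intensities.index)
    return quantile_normalize(log2_mat), params


def low_intensity_filter(
    matrix: pd.DataFrame,
    control_mask: pd.Series,
    min_arrays: int = 3,
    factor: float = 0.9,
    convention: str = "paper",
) -> tuple[pd.Index, pd.DataFrame]:
    """Remove dim probes, then all control probes.

    Per array, the threshold is ``factor`` times the 95th percentile of that
    array's negative-control values (same scale as ``matrix``). Under the
    default "paper" convention a probe is removed iff its value falls below
    the threshold on at least ``min_arrays`` arrays of the stage; the
    "bright" convention instead *keeps* a probe iff it exceeds the threshold
    on at least ``min_arrays`` arrays. Returns (retained non-control probe
    index, per-array report of thresholds and below-threshold counts).
    """
    if min_arrays > matrix.shape[1]:
        raise ValueError("min_arrays exceeds the number of arrays in the stage")
    if convention not in ("paper", "bright"):
        raise ValueError("convention must be 'paper' or 'bright'")
    mask = control_mask.reindex(matrix.index).to_numpy(dtype=bool)
    controls = matrix.loc[mask]
    thresholds = factor * controls.quantile(0.95, axis=0)
    below = matrix.lt(thresholds, axis=1)
    if convention == "paper":
        removed = below.sum(axis=1) >= min_arrays
        retained = matrix.index[~removed & ~mask]
    else:
        kept = (~below).sum(axis=1) >= min_arrays
        retained = matrix.index[kept & ~mask]
    report = pd.DataFrame(
        {
            "threshold": thresholds,
            "n_below": below.loc[~mask].sum(axis=0),
        }
    )
    return retained, report


def qc_summaries(matrix: pd.DataFrame) -> dict:
    """Sample-level QC: relative-log-expression (RLE) medians/IQRs and the
    first two principal-component coordinates of the samples.

    RLE subtracts each probe's median across samples; outlying samples show
    RLE medians far from zero. PCA is computed on sample vectors (probes as
    features, mean-centred); variance-explained fractions are reported.
    """
    if matrix.shape[1] < 2:
        raise ValueError("QC needs >= 2 samples")
    rle = matrix.sub(matrix.median(axis=1), axis=0)
    rle_median = rle.median(axis=0)
    rle_iqr = rle.quantile(0.75, axis=0) - rle.quantile(0.25, axis=0)

    X = matrix.to_numpy(dtype=float).T  # samples x probes
    Xc = X - X.mean(axis=0)
    u, s, _vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    coords = u[:, :2] * s[:2]
    return {
        "rle_median": rle_median,
        "rle_iqr": rle_iqr,
        "pc_coords": pd.DataFrame(
            coords, index=matrix.columns, columns=["PC1", "PC2"]
        ),
        "variance_explained": frac[:2].tolist(),
    }
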