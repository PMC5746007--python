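"""Mendelian backcross simulation and log-logistic rescue-curve fitting.

The survival assay crosses heterozygous transgene-carrying (red-eyed) males
to wild-type (white-eyed) females, so each offspring inherits the transgene
with probability 1/2. Without antibiotic the circuit is active and carriers
die; with antibiotic at concentration c a carrier survives with relative
viability v(c), while non-carriers always survive. The per-vial survivability
statistic is red/(red + white), which therefore has expectation
v/(1 + v) — at full rescue (v = 1) half the emerging flies carry the
transgene, the design's ceiling.

The rescue curve is the log-logistic (Hill) form
``v(c) = floor + (ceiling - floor) * c^h / (c^h + EC50^h)``; the fitted
half-maximal concentration is reported as both EC50 and IC50 (the latter
matching the field's labelling of the rescue threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ViabilityParams",
    "CrossConfig",
    "viability",
    "simulate_cross",
    "survivability",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ViabilityParams:
    """Hill-curve parameters: half-maximal concentration ``ec50`` (ug/mL),
    slope ``hill`` (> 0), and floor/ceiling viabilities in [0, 1]."""

    ec50: float
    hill: float = 1.0
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")
        if not (0 <= self.floor <= self.ceiling <= 1):
            raise ValueError("need 0 <= floor <= ceiling <= 1")


@dataclass(frozen=True)
class CrossConfig:
    """Crossing-experiment configuration: mean offspring per vial (Poisson),
    vials per dose, and the dose series in ug/mL."""

    doses: tuple[float, ...]
    vials_per_dose: int = 10
    offspring_mean: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vials_per_dose < 1:
            raise ValueError("need >= 1 vial per dose")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")


def viability(c: np.ndarray | float, params: ViabilityParams) -> np.ndarray | float:
    """Relative carrier viability at concentration c (Hill curve); v(0) is the
    floor, v(EC50) the floor/ceiling midpoint."""
    c_arr = np.asarray(c, dtype=float)
    if (c_arr < 0).any():
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        ch = np.power(c_arr, params.hill)
    v = params.floor + (params.ceiling - params.floor) * ch / (ch + params.ec50**params.hill)
    return v if np.ndim(c) else float(v)


def simulate_cross(config: CrossConfig, params: ViabilityParams) -> pd.DataFrame:
    """Simulate vial counts for the F2 backcross at each dose.

    Each conceived offspring carries the transgene (red) with probability
    1/2; red offspring survive to adulthood with probability v(c), white
    offspring always. Returns one row per vial: dose_ugml, vial, red, white.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for dose in config.doses:
        v = float(viability(dose, params))
        for vial in range(1, config.vials_per_dose + 1):
            n = rng.poisson(config.offspring_mean)
            red_conceived = rng.binomial(n, 0.5)
            red = rng.binomial(red_conceived, v) if red_conceived else 0
            white = n - red_conceived
            rows.append((dose, vial, int(red), int(white)))
    return pd.DataFrame(rows, columns=["dose_ugml", "vial", "red", "white"])


def survivability(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vial survivability s = red/(red + white) plus per-dose boxplot
    statistics (median and quartiles). Vials that produced no flies at all
    are excluded (not scored as zero), with a logged count."""
    counts = counts.copy()
    total = counts["red"] + counts["white"]
    empty = total == 0
    if empty.any():
        log.info("%d empty vials excluded from survivability", int(empty.sum()))
    kept = counts.loc[~empty].copy()
    kept["survivability"] = kept["red"] / (kept["red"] + kept["white"])
    per_dose = (
        kept.groupby("dose_ugml")["survivability"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75), n="count")
        .reset_index()
    )
    return kept, per_dose


def _hill(c: np.ndarray, log_ec50: float, log_h: float, ceiling: float) -> np.ndarray:
    ec50 = np.exp(log_ec50)
    h = np.exp(log_h)
    ch = np.power(c, h)
    return ceiling * ch / (ch + ec50**h)


class DoseResponseModel:
    """Least-squares log-logistic rescue model on the survivability scale.

    The floor is fixed at 0 (no rescue without antibiotic) and the ceiling is
    free in (0, 0.5] — the backcross design caps survivability at 1/2.
    Construct from per-vial doses and survivabilities and call :meth:`fit`.
    """

    def __init__(self, doses: np.ndarray, survivabilities: np.ndarray, compound: str = ""):
        self.doses = np.asarray(doses, dtype=float)
        self.surv = np.asarray(survivabilities, dtype=float)
        self.compound = compound
        if len(self.doses) != len(self.surv):
            raise ValueError("doses and survivabilities differ in length")
        if len(np.unique(self.doses)) < 4:
            raise FitError("need >= 4 distinct doses to fit a dose-response curve")
        if not (self.surv > 0).any():
            raise FitError("no rescue observed: all survivabilities are zero")

    @classmethod
    def from_vials(cls, vials: pd.DataFrame, compound: str = "") -> "DoseResponseModel":
        kept, _ = survivability(vials)
        return cls(kept["dose_ugml"].to_numpy(), kept["survivability"].to_numpy(), compound)

    def fit(self) -> "DoseResponseResults":
        pos = self.doses > 0
        ceiling0 = min(max(float(self.surv.max()), 1e-3), 0.5)
        # initialise EC50 where survivability crosses half its maximum
        order = np.argsort(self.doses[pos])
        d_sorted = self.doses[pos][order]
        s_sorted = self.surv[pos][order]
        half = ceiling0 / 2.0
        above = np.nonzero(s_sorted >= half)[0]
        ec50_0 = float(d_sorted[above[0]]) if len(above) else float(np.median(d_sorted))
        p0 = [np.log(ec50_0), 0.0, ceiling0]
        bounds = ([-np.inf, -np.inf, 1e-6], [np.inf, np.log(50.0), 0.5])
        converged = True
        try:
            popt, pcov = curve_fit(
                _hill, self.doses, self.surv, p0=p0, bounds=bounds, maxfev=20_000
            )
        except RuntimeError:
            converged = False
            popt, pcov = np.array(p0), np.full((3, 3), np.nan)
        params = ViabilityParams(
            ec50=float(np.exp(popt[0])),
            hill=float(np.exp(popt[1])),
            floor=0.0,
            ceiling=float(popt[2]),
        )
        resid = self.surv - _hill(self.doses, *popt)
        extrapolated = not (
            self.doses[pos].min() <= params.ec50 <= self.doses.max()
        )
        return DoseResponseResults(
            model=self,
            params=params,
            rss=float(np.sum(resid**2)),
            converged=converged,
            extrapolated=extrapolated,
            cov=pcov,
        )


@dataclass
class DoseResponseResults:
    """Fitted rescue curve: parameters, residual sum of squares, convergence
    flag, and whether the EC50 fell outside the tested dose range."""

    model: DoseResponseModel
    params: ViabilityParams
    rss: float
    converged: bool
    extrapolated: bool
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def ec50(self) -> float:
        return self.params.ec50

    # the half-maximal rescue concentration is conventionally printed as IC50
    ic50 = ec50

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return np.asarray(viability(doses, self.params))

    def summary(self) -> str:
        lines = [
            f"Dose-response fit{' (' + self.model.compound + ')' if self.model.compound else ''}",
            "=" * 40,
            f"  EC50 (IC50)   {self.params.ec50:10.4g} ug/mL"
            + ("  [extrapolated]" if self.extrapolated else ""),
            f"  Hill slope    {self.params.hill:10.4g}",
            f"  ceiling       {self.params.ceiling:10.4g}",
            f"  RSS           {self.rss:10.4g}",
            f"  n points      {len(self.model.doses):10d}",
            f"  converged     {str(self.converged):>10s}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "compound": self.model.compound,
            "ic50": self.params.ec50,
            "hill": self.params.hill,
            "ceiling": self.params.ceiling,
            "rss": self.rss,
            "converged": self.converged,
            "extrapolated": self.extrapolated,
        }


def fit_dose_response(
    doses: np.ndarray, survivabilities: np.ndarray, compound: str = ""
) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`DoseResponseModel` and fit it."""
    return DoseResponseModel(doses, survivabilities, compound).fit()
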