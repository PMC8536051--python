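"""Regression stage: population GRS vs vitamin D concentration vs latitude.

Inputs are population-level rows (label, mean 25(OH)D3 in ng/mL, latitude
in degrees, mean composite GRS).  Three fits are exposed: an ordinary
least-squares line, a quadratic (the concentration-vs-GRS "U curve"), and
the paired difference regressions Δconcentration ~ ΔGRS and
Δconcentration ~ Δlatitude against a reference population, whose R² values
are the quantities compared to decide whether genetics or latitude tracks
the concentration differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PopulationPhenotype",
    "FitResult",
    "DifferenceFits",
    "linear_fit",
    "quadratic_fit",
    "difference_analysis",
    "phenotypes_from_frame",
]


@dataclass(frozen=True)
class PopulationPhenotype:
    """One population's phenotype row for the regression stage."""

    population: str
    concentration: float  # mean serum 25(OH)D3, ng/mL
    latitude: float       # degrees, signed
    grs: float            # mean composite score

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"{self.population}: concentration must be positive")
        if abs(self.latitude) > 90:
            raise ValueError(f"{self.population}: |latitude| must be <= 90")


def phenotypes_from_frame(df: pd.DataFrame) -> list[PopulationPhenotype]:
    """Build phenotype rows from a TSV-shaped DataFrame.

    Expected columns: ``population, concentration_ng_per_ml, latitude_deg,
    grs``.
    """
    return [
        PopulationPhenotype(
            population=str(r.population),
            concentration=float(r.concentration_ng_per_ml),
            latitude=float(r.latitude_deg),
            grs=float(r.grs),
        )
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class FitResult:
    """Least-squares coefficients with goodness of fit.

    ``coefficients`` is ordered (intercept, slope[, quadratic]);
    ``stderr`` holds the matching standard errors.
    """

    coefficients: tuple[float, ...]
    stderr: tuple[float, ...]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0,1]")
        if self.n_points < len(self.coefficients):
            raise ValueError("fewer points than coefficients")

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    @property
    def slope_se(self) -> float:
        return self.stderr[1]

    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "stderr": list(self.stderr),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def _ols(design: np.ndarray, y: np.ndarray) -> FitResult:
    with np.errstate(divide="ignore", invalid="ignore"):  # exact interpolation
        model = sm.OLS(y, design).fit()
        model.bse
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("response is constant; r_squared defined as 0", stacklevel=3)
        r2 = 0.0
    else:
        r2 = min(max(float(model.rsquared), 0.0), 1.0)
    return FitResult(
        coefficients=tuple(float(b) for b in model.params),
        stderr=tuple(float(s) for s in model.bse),
        r_squared=r2,
        n_points=len(y),
    )


def linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least-squares line y = a + b·x with R² = 1 − SSres/SStot.

    A constant predictor raises; a constant response yields R² = 0 with a
    warning (the fit is degenerate but the slope, 0, is well defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    return _ols(sm.add_constant(x), y)


def quadratic_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Least-squares parabola y = a + b·x + c·x², for the U-shaped
    concentration-vs-GRS relation.  Three distinct x interpolate exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least three points")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least three distinct x values")
    design = np.column_stack([np.ones_like(x), x, x**2])
    return _ols(design, y)


@dataclass(frozen=True)
class DifferenceFits:
    """Paired difference regressions against a reference population."""

    reference: str
    grs_fit: FitResult        # Δconcentration ~ ΔGRS
    latitude_fit: FitResult   # Δconcentration ~ Δlatitude
    deltas: pd.DataFrame = field(compare=False)


def difference_analysis(
    phenotypes: list[PopulationPhenotype], reference: str = "EUR"
) -> DifferenceFits:
    """Regress concentration differences on GRS and latitude differences.

    For every non-reference population, Δ = value − reference value.  The
    two R² values answer which factor better explains between-population
    concentration differences.  Differences make the fits invariant to any
    constant shift of concentrations or latitudes.
    """
    by_label = {p.population: p for p in phenotypes}
    if reference not in by_label:
        raise ValueError(f"reference population {reference!r} not in phenotypes")
    ref = by_label[reference]
    others = [p for p in phenotypes if p.population != reference]
    if len(others) < 2:
        raise ValueError("need at least two non-reference populations")
    deltas = pd.DataFrame(
        {
            "population": [p.population for p in others],
            "d_concentration": [p.concentration - ref.concentration for p in others],
            "d_grs": [p.grs - ref.grs for p in others],
            "d_latitude": [p.latitude - ref.latitude for p in others],
        }
    )
    grs_fit = linear_fit(deltas["d_grs"].to_numpy(), deltas["d_concentration"].to_numpy())
    latitude_fit = linear_fit(
        deltas["d_latitude"].to_numpy(), deltas["d_concentration"].to_numpy()
    )
    return DifferenceFits(reference, grs_fit, latitude_fit, deltas)
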