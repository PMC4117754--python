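"""Apparent Kd estimation from nitrocellulose filter-binding titrations.

Trace amounts of labelled RNA (2-4 nM) are titrated with protein over a
wide concentration range (roughly 1-2200 nM).  With protein in large excess
over RNA the single-site law gives a straight line through the origin::

    bound/free = [P] / Kd

so the apparent dissociation constant is the reciprocal of the slope of
bound/free versus protein concentration.  The intercept is left free to
absorb background retention on the filters; only the slope enters Kd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError, NoBindingError

__all__ = [
    "BindingIsotherm",
    "KdModel",
    "KdResults",
    "bound_free_ratio",
    "fit_kd",
]


def bound_free_ratio(fraction_bound: float) -> float:
    """Bound/free RNA ratio f / (1 - f) from a bound fraction f in [0, 1)."""
    if not 0.0 <= fraction_bound < 1.0:
        raise DomainError(
            f"fraction bound must lie in [0, 1), got {fraction_bound}"
        )
    return fraction_bound / (1.0 - fraction_bound)


@dataclass
class BindingIsotherm:
    """One filter-binding titration: protein series and bound fractions."""

    protein_nM: np.ndarray
    fraction_bound: np.ndarray
    rna_nM: float = 3.0

    def __post_init__(self) -> None:
        self.protein_nM = np.asarray(self.protein_nM, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.protein_nM.shape != self.fraction_bound.shape:
            raise DomainError("protein and fraction-bound series differ in length")
        if np.any(self.protein_nM <= 0):
            raise DomainError("protein concentrations must be positive")
        if np.any((self.fraction_bound < 0) | (self.fraction_bound >= 1)):
            raise DomainError("bound fractions must lie in [0, 1)")

    @property
    def bound_free(self) -> np.ndarray:
        return self.fraction_bound / (1.0 - self.fraction_bound)


@dataclass
class KdResults:
    """Linear bound/free-vs-concentration fit and the derived apparent Kd."""

    kd_nM: float
    kd_se_nM: float
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd_nM,
            "kd_se_nM": self.kd_se_nM,
            "slope_per_nM": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        return (
            "Filter-binding Kd fit (bound/free vs [protein])\n"
            f"  points      : {self.n_points}\n"
            f"  slope       : {self.slope:.4g} /nM (se {self.slope_se:.2g})\n"
            f"  intercept   : {self.intercept:.4g}\n"
            f"  r-squared   : {self.r_squared:.4f}\n"
            f"  Kd          : {self.kd_nM:.3g} +/- {self.kd_se_nM:.2g} nM"
            " (fit standard error)"
        )


class KdModel:
    """Least-squares line of bound/free versus protein concentration.

    Kd = 1/slope.  The Kd standard error is propagated from the slope
    standard error (se_Kd = se_slope / slope**2) and labelled as a fit
    error, not a replicate SD.  A warning is issued when the lowest protein
    concentration is not at least 10x the nominal RNA concentration, since
    the linear model assumes protein excess.
    """

    def __init__(self, iso: BindingIsotherm):
        if iso.protein_nM.size < 2:
            raise InsufficientDataError("need at least two titration points")
        self.iso = iso
        if np.min(iso.protein_nM) < 10.0 * iso.rna_nM:
            warnings.warn(
                "lowest protein concentration is below 10x the RNA "
                "concentration; the excess-protein linear model may bias Kd",
                stacklevel=2,
            )
        if np.any(iso.fraction_bound > 0.98):
            warnings.warn(
                "titration contains near-saturated points (fraction bound > "
                "0.98); their bound/free ratios have extreme leverage on the "
                "fitted slope",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, df, rna_nM: float = 3.0) -> "KdModel":
        """Build from a table with columns protein_nM and fraction_bound."""
        return cls(
            BindingIsotherm(
                protein_nM=df["protein_nM"].to_numpy(),
                fraction_bound=df["fraction_bound"].to_numpy(),
                rna_nM=rna_nM,
            )
        )

    def plot(self, results: "KdResults | None" = None, ax=None):
        """Bound/free versus protein concentration with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.iso.protein_nM
        ax.plot(x, self.iso.bound_free, "o")
        if results is None:
            results = self.fit()
        xs = np.linspace(0, x.max(), 2)
        ax.plot(xs, results.intercept + results.slope * xs, "-",
                label=f"Kd = {results.kd_nM:.3g} nM")
        ax.set_xlabel("[protein] (nM)")
        ax.set_ylabel("bound/free RNA")
        ax.legend()
        return ax

    def fit(self) -> KdResults:
        x = self.iso.protein_nM
        y = self.iso.bound_free
        res = stats.linregress(x, y)
        if res.slope <= 0:
            raise NoBindingError(
                "non-positive slope of bound/free vs concentration: no "
                "measurable binding in this titration"
            )
        slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        kd = 1.0 / res.slope
        return KdResults(
            kd_nM=float(kd),
            kd_se_nM=float(slope_se / res.slope**2),
            slope=float(res.slope),
            slope_se=slope_se,
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            n_points=int(x.size),
        )


def fit_kd(iso: BindingIsotherm) -> KdResults:
    """Convenience wrapper: ``KdModel(iso).fit()``."""
    return KdModel(iso).fit()
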