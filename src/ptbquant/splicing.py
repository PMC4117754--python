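"""Exon-skipping quantification from splicing-product band intensities.

In vitro splicing of a three-exon pre-mRNA yields three diagnostic products
detected by primer extension: the skipped product joining exons 5 and 7
(``s57``) and the two inclusion junctions 5-6 (``s56``) and 6-7 (``s67``).
Percent exon skipping weights the two inclusion junctions by one half, since
each included transcript contributes both::

    % skipping = 100 * s57 / (s57 + 0.5 * (s56 + s67))

Repressor activity of a mutant protein is expressed relative to wild type
after subtracting the no-protein baseline::

    % activity = 100 * (skip_mut - skip_none) / (skip_wt - skip_none)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "SplicingQuant",
    "ActivityResult",
    "percent_skipping",
    "percent_activity",
    "summarize_replicates",
]


def percent_skipping(s57: float, s56: float, s67: float) -> float:
    """Percent exon skipping from the three product band intensities."""
    if min(s57, s56, s67) < 0:
        raise DomainError("band intensities must be non-negative")
    denom = s57 + 0.5 * (s56 + s67)
    if denom == 0:
        raise DomainError("all three product intensities are zero; ratio undefined")
    return 100.0 * s57 / denom


@dataclass
class SplicingQuant:
    """One lane's splicing-product intensities and derived percent skipping."""

    s57: float
    s56: float
    s67: float

    def __post_init__(self) -> None:
        self.pct_skip = percent_skipping(self.s57, self.s56, self.s67)


@dataclass
class ActivityResult:
    """Percent activity of a mutant relative to wild type.

    ``pct_activity`` keeps full precision; ``rounded`` matches the integer
    presentation used in lane-by-lane reports.
    """

    pct_activity: float
    skip_mut: float
    skip_wt: float
    skip_none: float

    @property
    def rounded(self) -> int:
        return int(round(self.pct_activity))

    def summary(self) -> str:
        return (
            f"% activity = 100*({self.skip_mut:g} - {self.skip_none:g})"
            f"/({self.skip_wt:g} - {self.skip_none:g}) = {self.rounded}%"
            f" (unrounded {self.pct_activity:.2f})"
        )


def percent_activity(skip_mut: float, skip_wt: float, skip_none: float) -> ActivityResult:
    """Mutant repressor activity relative to wild type, baseline-subtracted."""
    if skip_wt == skip_none:
        raise DomainError(
            "wild-type and no-protein skipping are equal; activity undefined"
        )
    pct = 100.0 * (skip_mut - skip_none) / (skip_wt - skip_none)
    return ActivityResult(pct, skip_mut, skip_wt, skip_none)


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of replicates."""
    vals = [float(v) for v in values]
    n = len(vals)
    if n < 2:
        raise InsufficientDataError("need at least two replicates for mean +/- SD")
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return mean, sd
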