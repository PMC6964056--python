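"""Inbreeding depression from the genomic-homozygosity covariate.

The regression coefficient b of a trait on individual genomic homozygosity
(trait units per unit homozygosity; negative under depression) is turned
into a relative depression b_R = −b / trait mean, and into the expected
performance gap between the most- and least-inbred tails of the population,
|b| × (q95 − q05) of the homozygosity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reml import FitResult

__all__ = ["DepressionSummary", "depression_summary", "relative_depression"]


def relative_depression(b: float, trait_mean: float) -> float:
    """Relative inbreeding depression b_R = −b / mean (dimensionless)."""
    if trait_mean == 0:
        raise ValueError("trait mean is zero; relative depression undefined")
    return -b / trait_mean


@dataclass
class DepressionSummary:
    """Inbreeding-depression summary for one trait.

    ``difference`` = |b| × (q95 − q05): the expected performance difference
    in trait units between the upper and lower 5-percentiles of genomic
    homozygosity in the population.
    """

    b: float
    b_se: float | None
    trait_mean: float
    b_r: float
    q05: float
    q95: float
    gap: float
    difference: float

    @classmethod
    def from_regression(
        cls,
        b: float,
        b_se: float | None,
        phenotypes: np.ndarray,
        homozygosity: np.ndarray,
    ) -> "DepressionSummary":
        """Summary from a fitted coefficient and raw phenotype/homozygosity vectors.

        The trait mean is the raw phenotypic mean (before any fixed-effect
        adjustment); quantiles use linear interpolation between order
        statistics.
        """
        phen = np.asarray(phenotypes, dtype=float)
        hom = np.asarray(homozygosity, dtype=float)
        mean = float(np.mean(phen))
        q05, q95 = (float(q) for q in np.quantile(hom, [0.05, 0.95]))
        gap = q95 - q05
        return cls(
            b=float(b),
            b_se=None if b_se is None else float(b_se),
            trait_mean=mean,
            b_r=relative_depression(b, mean),
            q05=q05,
            q95=q95,
            gap=gap,
            difference=abs(b) * gap,
        )

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "b_se": self.b_se,
            "trait_mean": self.trait_mean,
            "b_R": self.b_r,
            "q05": self.q05,
            "q95": self.q95,
            "gap": self.gap,
            "difference": self.difference,
        }


def depression_summary(
    fit: FitResult,
    homozygosity: np.ndarray,
    phenotypes: np.ndarray,
    covariate: str = "homozygosity",
) -> DepressionSummary:
    """Extract the depression summary from a fit that includes the covariate.

    ``phenotypes`` must be the raw trait records of the analysed individuals
    and ``homozygosity`` their genomic homozygosity.
    """
    sol = fit.fixed_solutions
    match = sol[sol["term"] == covariate]
    if match.empty:
        raise ValueError(
            f"fit has no {covariate!r} covariate; refit with include_homozygosity=True"
        )
    b = float(match["estimate"].iloc[0])
    b_se = float(match["se"].iloc[0])
    return DepressionSummary.from_regression(b, b_se, phenotypes, homozygosity)
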