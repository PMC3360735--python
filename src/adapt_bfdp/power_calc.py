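"""Statistical power of reaching a BFDP threshold.

BFDP is monotone decreasing in Z², so the event BFDP ≤ γ is equivalent to
Z² exceeding a critical value z²_crit that depends on (PO, W, V, γ). Under
a true log odds ratio θ, Z² follows a non-central χ² with 1 degree of
freedom and non-centrality θ²/V, so

    power = P( χ²₁(θ²/V) > z²_crit ).

Under the null (θ = 0) this reduces to the central χ²₁ tail. The critical
value is found by bisection on the monotone map z² ↦ BFDP rather than by
algebraic rearrangement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bayes_rank import approximate_bayes_factor, bfdp, default_prior_variance

__all__ = [
    "PowerSettings",
    "variance_from_design",
    "z2_critical",
    "bfdp_power",
    "power_curve",
]


@dataclass(frozen=True)
class PowerSettings:
    """Inputs for one power evaluation.

    theta : true log odds ratio
    V     : sampling variance of θ̂ (encodes sample size and allele freq.)
    W     : prior variance of θ under the alternative
    po    : prior odds of the null
    gamma : BFDP threshold in (0, 1)
    """

    theta: float
    V: float
    W: float
    po: float
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if self.V <= 0 or self.W <= 0:
            raise ValueError("V and W must be positive")
        if self.po < 0:
            raise ValueError("prior odds must be non-negative")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")


def variance_from_design(cases: int, controls: int, maf: float) -> float:
    """Approximate per-allele log OR variance for a case-control design,
    V ≈ 1/(2·n₁·f(1−f)) + 1/(2·n₀·f(1−f)) at minor allele frequency f."""
    if cases <= 0 or controls <= 0:
        raise ValueError("cases and controls must be positive")
    if not 0 < maf < 0.5:
        raise ValueError("minor allele frequency must lie in (0, 0.5)")
    denom = 2.0 * maf * (1.0 - maf)
    return 1.0 / (cases * denom) + 1.0 / (controls * denom)


def z2_critical(
    po: float, W: float, V: float, gamma: float, tol: float = 1e-12
) -> float:
    """Smallest z² at which BFDP(z²) ≤ γ; 0 if already below γ at Z = 0."""
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")

    def f(z2: float) -> float:
        return bfdp(approximate_bayes_factor(math.sqrt(z2), V, W), po) - gamma

    if f(0.0) <= 0.0:
        return 0.0
    hi = 1.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket the BFDP threshold")
    return float(optimize.brentq(f, 0.0, hi, xtol=tol))


def bfdp_power(settings: PowerSettings) -> float:
    """Probability that a SNP with true effect θ attains BFDP ≤ γ."""
    crit = z2_critical(settings.po, settings.W, settings.V, settings.gamma)
    ncp = settings.theta**2 / settings.V
    if ncp == 0.0:
        return float(stats.chi2.sf(crit, df=1))
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def power_curve(
    v_grid: np.ndarray | list[float],
    po_by_category: dict[str, float],
    theta: float,
    W: float | None = None,
    gamma: float = 0.8,
    flat_po: float | None = None,
) -> pd.DataFrame:
    """Power per (V grid point, category), plus an optional flat-prior
    comparator in which every SNP shares one prior odds value.

    Returns a tidy table with columns V, category, po, power.
    """
    if W is None:
        W = default_prior_variance()
    v_arr = np.asarray(v_grid, dtype=float)
    if v_arr.size == 0:
        raise ValueError("grid must be non-empty")
    columns: dict[str, float] = dict(po_by_category)
    if flat_po is not None:
        columns["flat"] = flat_po
    rows = []
    for v in v_arr:
        for cat, po in columns.items():
            power = bfdp_power(
                PowerSettings(theta=theta, V=float(v), W=W, po=po, gamma=gamma)
            )
            rows.append({"V": float(v), "category": cat, "po": po, "power": power})
    return pd.DataFrame(rows, columns=["V", "category", "po", "power"])
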