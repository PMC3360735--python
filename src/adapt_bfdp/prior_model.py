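"""Category prior probabilities and prior odds of the null.

Given the number of SNPs falling in each literature-evidence category
(N_j) and an analyst-assumed number of truly associated SNPs in the panel
(N*), split across categories as N*_j, the prior probability that a SNP
in category j is associated is

    Pr(H1 | C_j) = N*_j / N_j

and the prior odds of the null for category j are

    PO_j = (N_j - N*_j) / N*_j = (1 - Pr(H1|C_j)) / Pr(H1|C_j).

N* is an assumption, not an estimate; it is varied over a sensitivity set
(50 / 100 / 500 by default) downstream. The ranking of SNPs within a
category does not depend on N*, only on which categories exist and their
relative priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_TRUE = 100.0
DEFAULT_SENSITIVITY = (50.0, 100.0, 500.0)

__all__ = [
    "PriorSpec",
    "prior_probabilities",
    "prior_odds",
    "DEFAULT_N_TRUE",
    "DEFAULT_SENSITIVITY",
]


@dataclass(frozen=True)
class PriorSpec:
    """Category counts, true-SNP allocation, and the derived priors.

    categories : ordered category labels (e.g. C1, C2, C3)
    counts     : N_j, number of SNPs per category (positive)
    n_true     : N*, assumed number of truly associated SNPs
    allocation : N*_j per category, summing to N*
    pr_h1      : Pr(H1|C_j) = N*_j / N_j
    po         : PO_j = (N_j - N*_j) / N*_j (inf where N*_j = 0)
    """

    categories: tuple[str, ...]
    counts: tuple[float, ...]
    n_true: float
    allocation: tuple[float, ...]
    pr_h1: tuple[float, ...] = field(default=())
    po: tuple[float, ...] = field(default=())

    @property
    def n_total(self) -> float:
        return float(sum(self.counts))

    def pr_h1_for(self, category: str) -> float:
        return self.pr_h1[self.categories.index(category)]

    def po_for(self, category: str) -> float:
        return self.po[self.categories.index(category)]


def prior_probabilities(
    counts: dict[str, float] | list[float],
    n_true: float = DEFAULT_N_TRUE,
    allocation: str | list[float] = "even",
) -> PriorSpec:
    """Build a PriorSpec from category counts and an assumed N*.

    allocation:
      "even"         — N*_j = N*/J for each of the J categories (baseline)
      "proportional" — N*_j ∝ N_j, i.e. a flat prior across all SNPs
      explicit list  — user-supplied N*_j summing to N*

    Raises if any N*_j exceeds its category count (a prior probability
    above 1 is impossible).
    """
    if isinstance(counts, dict):
        cats = tuple(counts.keys())
        n_j = np.asarray(list(counts.values()), dtype=float)
    else:
        n_j = np.asarray(counts, dtype=float)
        cats = tuple(f"C{i + 1}" for i in range(len(n_j)))
    if len(n_j) == 0:
        raise ValueError("at least one category is required")
    if np.any(n_j <= 0):
        raise ValueError("category counts must be positive")
    if n_true <= 0:
        raise ValueError("n_true must be positive")

    j = len(n_j)
    if isinstance(allocation, str):
        if allocation == "even":
            alloc = np.full(j, n_true / j)
        elif allocation == "proportional":
            alloc = n_true * n_j / n_j.sum()
        else:
            raise ValueError(f"unknown allocation scheme {allocation!r}")
    else:
        alloc = np.asarray(allocation, dtype=float)
        if len(alloc) != j:
            raise ValueError("allocation length must match number of categories")
        if np.any(alloc < 0):
            raise ValueError("allocation entries must be non-negative")
        if not np.isclose(alloc.sum(), n_true, rtol=1e-9):
            raise ValueError(
                f"allocation sums to {alloc.sum()}, expected n_true = {n_true}"
            )
    if np.any(alloc > n_j):
        raise ValueError(
            "allocation exceeds category count: prior probability > 1 impossible"
        )

    with np.errstate(divide="ignore"):
        pr_h1 = alloc / n_j
        po = np.where(alloc > 0, (n_j - alloc) / np.where(alloc > 0, alloc, 1.0), np.inf)
    return PriorSpec(
        categories=cats,
        counts=tuple(n_j),
        n_true=float(n_true),
        allocation=tuple(alloc),
        pr_h1=tuple(pr_h1),
        po=tuple(po),
    )


def prior_odds(spec: PriorSpec) -> dict[str, float]:
    """Per-category prior odds of the null, PO_j = (N_j - N*_j)/N*_j.

    Raises for categories allocated zero true SNPs: their prior odds are
    infinite and such categories carry no prior mass for H1.
    """
    for cat, a in zip(spec.categories, spec.allocation):
        if a <= 0:
            raise ValueError(
                f"category {cat}: N*_j = 0 gives infinite prior odds"
            )
    return dict(zip(spec.categories, spec.po))
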