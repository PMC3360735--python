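"""Approximate Bayes factors, BFDP, sensitivity ranges, ranking & selection.

For a single log odds ratio θ with estimate θ̂, sampling variance V and a
zero-mean normal prior N(0, W) under the alternative, the approximate
Bayes factor is

    ABF = exp(-Z² r / 2) / sqrt(1 - r),   r = W / (V + W),   Z = θ̂ / √V.

Values below 1 favour association. Combined with the prior odds of the
null PO, the Bayes false discovery probability is

    BFDP = ABF · PO / (ABF · PO + 1),

the posterior probability that a reported association is a false
discovery. SNPs are ranked by BFDP, and those whose BFDP stays below a
threshold γ for every assumed N* in a sensitivity set are selected for
replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prior_model import PriorSpec

Z_975 = float(stats.norm.ppf(0.975))  # 1.959964 at the precision that matters

__all__ = [
    "AssocRecord",
    "default_prior_variance",
    "z_from_p",
    "variance_from_summary",
    "approximate_bayes_factor",
    "bfdp",
    "bfdp_sensitivity",
    "score_table",
    "rank_and_select",
    "read_summary_stats",
]


@dataclass(frozen=True)
class AssocRecord:
    """One SNP's association summary on the log odds ratio scale."""

    rsid: str
    theta_hat: float
    V: float
    Z: float
    p: float
    or_point: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"{self.rsid}: variance must be positive")


def default_prior_variance(or_quantile: float = 2.0) -> float:
    """Prior variance W for which the 97.5% prior quantile of the OR is
    ``or_quantile`` (default 2: 95% prior belief that the OR lies in
    [1/2, 2])."""
    if or_quantile <= 1:
        raise ValueError("or_quantile must exceed 1")
    return (math.log(or_quantile) / Z_975) ** 2


def z_from_p(p: float | np.ndarray) -> float | np.ndarray:
    """Non-negative Z recovered from a two-sided p-value."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("two-sided p-value must satisfy 0 < p <= 1")
    z = stats.norm.isf(p_arr / 2.0)
    return float(z) if np.isscalar(p) else z


def variance_from_summary(
    or_point: float | None = None,
    p: float | None = None,
    ci_lo: float | None = None,
    ci_hi: float | None = None,
    route: str = "p",
) -> float:
    """Recover the sampling variance V of the log OR from published summaries.

    route="p":  V = (ln OR / Z)² with Z from the two-sided p-value; needs
                OR ≠ 1 (Z = 0 would divide by zero).
    route="ci": V = ((ln ci_hi − ln ci_lo) / (2 · z_0.975))², assuming a
                symmetric Wald interval on the log scale.
    """
    if route == "p":
        if or_point is None or p is None:
            raise ValueError("p-route needs or_point and p")
        if or_point <= 0:
            raise ValueError("odds ratio must be positive")
        if or_point == 1.0:
            raise ValueError("OR = 1 gives Z = 0; cannot recover V via p-route")
        z = z_from_p(p)
        return (math.log(or_point) / z) ** 2
    if route == "ci":
        if ci_lo is None or ci_hi is None:
            raise ValueError("ci-route needs ci_lo and ci_hi")
        if not 0 < ci_lo < ci_hi:
            raise ValueError("require 0 < ci_lo < ci_hi")
        return ((math.log(ci_hi) - math.log(ci_lo)) / (2 * Z_975)) ** 2
    raise ValueError(f"unknown route {route!r}")


def approximate_bayes_factor(
    z: float | np.ndarray, V: float | np.ndarray, W: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form approximate Bayes factor for a single log odds ratio.

    Smaller values are stronger evidence against the null; W = 0 gives a
    vacuous prior and ABF = 1 regardless of Z.
    """
    V_arr = np.asarray(V, dtype=float)
    W_arr = np.asarray(W, dtype=float)
    if np.any(V_arr <= 0):
        raise ValueError("V must be positive")
    if np.any(W_arr < 0):
        raise ValueError("W must be non-negative")
    r = W_arr / (V_arr + W_arr)
    z2 = np.square(np.asarray(z, dtype=float))
    out = np.exp(-z2 * r / 2.0) / np.sqrt(1.0 - r)
    return float(out) if out.ndim == 0 else out


def bfdp(abf: float | np.ndarray, po: float | np.ndarray) -> float | np.ndarray:
    """Posterior probability of a false discovery, ABF·PO / (ABF·PO + 1)."""
    abf_arr = np.asarray(abf, dtype=float)
    po_arr = np.asarray(po, dtype=float)
    if np.any(abf_arr <= 0):
        raise ValueError("ABF must be positive")
    if np.any(po_arr < 0):
        raise ValueError("prior odds must be non-negative")
    post = abf_arr * po_arr
    out = post / (post + 1.0)
    return float(out) if out.ndim == 0 else out


def bfdp_sensitivity(
    z: float, V: float, W: float, category: str, specs: list[PriorSpec]
) -> tuple[float, float]:
    """(low, high) BFDP over the N* sensitivity set.

    BFDP decreases monotonically in N* (more assumed true SNPs, lower
    prior odds of the null), so the low bound comes from the largest N*
    and the high bound from the smallest.
    """
    if not specs:
        raise ValueError("sensitivity set must be non-empty")
    abf = approximate_bayes_factor(z, V, W)
    values = [bfdp(abf, spec.po_for(category)) for spec in specs]
    return (min(values), max(values))


def read_summary_stats(path: str) -> pd.DataFrame:
    """Read TSV summary statistics: rsid, or (or beta), p, optional
    ci_lo/ci_hi, optional se."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    if "rsid" not in df.columns:
        raise ValueError(f"{path}: missing rsid column")
    if "or" not in df.columns and "beta" not in df.columns:
        raise ValueError(f"{path}: need an 'or' or 'beta' column")
    return df


def _theta_and_variance(row: pd.Series, route: str) -> tuple[float, float]:
    """Per-row (θ̂, V); raw beta/se columns take precedence when present."""
    if "beta" in row.index and pd.notna(row.get("beta")):
        theta = float(row["beta"])
    else:
        theta = math.log(float(row["or"]))
    if "se" in row.index and pd.notna(row.get("se")):
        return theta, float(row["se"]) ** 2
    if route == "ci":
        v = variance_from_summary(
            ci_lo=float(row["ci_lo"]), ci_hi=float(row["ci_hi"]), route="ci"
        )
    else:
        v = variance_from_summary(
            or_point=math.exp(theta), p=float(row["p"]), route="p"
        )
    return theta, v


def score_table(
    summary: pd.DataFrame,
    categories: pd.DataFrame,
    central_spec: PriorSpec,
    sensitivity_specs: list[PriorSpec] | None = None,
    W: float | None = None,
    gamma: float = 0.8,
    v_route: str = "p",
    priors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Join summary statistics with categories and score every SNP.

    ``priors`` optionally overrides the derived per-category Pr(H1|C_j)
    with user-supplied values (e.g. probabilities printed in a published
    table); prior odds are then (1 − prior)/prior.

    Returns a ranked table with columns rsid, category, prior, po, abf,
    bfdp, bfdp_lo, bfdp_hi, rank_bfdp, rank_p, selected.
    """
    if W is None:
        W = default_prior_variance()
    merged = summary.merge(categories[["rsid", "category"]], on="rsid", how="left")
    orphans = merged.loc[merged["category"].isna(), "rsid"].tolist()
    if orphans:
        raise ValueError(
            f"{len(orphans)} SNPs lack category annotations: {orphans[:10]}"
        )

    rows = []
    for _, row in merged.iterrows():
        theta, v = _theta_and_variance(row, v_route)
        z = theta / math.sqrt(v)
        p = float(row["p"]) if "p" in row.index and pd.notna(row.get("p")) else float(
            2 * stats.norm.sf(abs(z))
        )
        cat = row["category"]
        if priors is not None:
            prior = priors[cat]
            po = (1.0 - prior) / prior
        else:
            prior = central_spec.pr_h1_for(cat)
            po = central_spec.po_for(cat)
        abf = approximate_bayes_factor(z, v, W)
        central = bfdp(abf, po)
        if sensitivity_specs:
            lo, hi = bfdp_sensitivity(z, v, W, cat, sensitivity_specs)
            lo, hi = min(lo, central), max(hi, central)
        else:
            lo = hi = central
        rows.append(
            {
                "rsid": row["rsid"],
                "category": cat,
                "theta_hat": theta,
                "V": v,
                "Z": z,
                "p": p,
                "prior": prior,
                "po": po,
                "abf": abf,
                "bfdp": central,
                "bfdp_lo": lo,
                "bfdp_hi": hi,
            }
        )
    table = pd.DataFrame(rows)
    return rank_and_select(table, gamma=gamma)


def rank_and_select(table: pd.DataFrame, gamma: float = 0.8) -> pd.DataFrame:
    """Rank by central BFDP and flag SNPs selected for replication.

    Selection requires the worst-case BFDP over the sensitivity set
    (bfdp_hi) to fall below γ — a SNP must remain noteworthy for every
    assumed N*. Ties break by p ascending, then rsid.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    if table.empty:
        out = table.copy()
        out["rank_bfdp"] = pd.Series(dtype=int)
        out["rank_p"] = pd.Series(dtype=int)
        out["selected"] = pd.Series(dtype=int)
        return out
    out = table.sort_values(
        ["bfdp", "p", "rsid"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank_bfdp"] = np.arange(1, len(out) + 1)
    p_order = out.sort_values(["p", "rsid"], kind="mergesort").index
    ranks = np.empty(len(out), dtype=int)
    ranks[p_order] = np.arange(1, len(out) + 1)
    out["rank_p"] = ranks
    hi = out["bfdp_hi"] if "bfdp_hi" in out.columns else out["bfdp"]
    out["selected"] = (hi < gamma).astype(int)
    return out
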