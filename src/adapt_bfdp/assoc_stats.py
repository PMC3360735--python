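"""Frequentist layer: trend logistic regression, HWE, QC, heterogeneity.

Association is modelled per-rare-allele log-additively: genotype enters a
logistic regression as 0/1/2 copies of the minor allele and the odds
ratio is per additional copy. The Bayesian layer consumes the Wald
estimate and standard error from this fit. Quality control mirrors the
standard GWAS pipeline: per-SNP call rate, per-sample completion rate and
a Hardy–Weinberg equilibrium filter among controls deep in the tail
(p < 1e-7 flags genotyping artifacts, not biology).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bayes_rank import AssocRecord

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

__all__ = [
    "GenotypeCounts",
    "StratumEstimate",
    "trend_logistic",
    "fit_trend_many",
    "hwe_test",
    "qc_filter",
    "cochran_q",
    "genomic_inflation",
    "read_genotype_counts",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control genotype counts for one SNP (0/1/2 minor alleles)."""

    rsid: str
    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    stratum: str | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError(f"{self.rsid}: negative genotype count")


@dataclass(frozen=True)
class StratumEstimate:
    """A per-stratum log OR estimate with its variance."""

    stratum: str
    theta_hat: float
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"{self.stratum}: variance must be positive")


def trend_logistic(counts: GenotypeCounts | list[GenotypeCounts]) -> AssocRecord:
    """Per-allele log-additive logistic fit with Wald inference.

    Accepts one table or a list of per-stratum tables for the same SNP;
    strata enter as indicator covariates. Raises on a SNP whose minor
    allele is absent or whose likelihood is monotone (separation).
    """
    tables = [counts] if isinstance(counts, GenotypeCounts) else list(counts)
    if not tables:
        raise ValueError("no genotype tables supplied")
    rsid = tables[0].rsid

    minor = sum(t.cases[1] + t.cases[2] + t.controls[1] + t.controls[2] for t in tables)
    if minor == 0:
        raise ValueError(f"{rsid}: minor allele absent; trend model undefined")

    rows = []
    for i, t in enumerate(tables):
        for g in range(3):
            rows.append((i, g, t.cases[g], t.controls[g]))
    df = pd.DataFrame(rows, columns=["stratum", "g", "cases", "controls"])
    df = df[(df.cases + df.controls) > 0]

    exog = pd.DataFrame({"const": 1.0, "g": df.g.astype(float)})
    if len(tables) > 1:
        for i in range(1, len(tables)):
            exog[f"s{i}"] = (df.stratum == i).astype(float)
    endog = df[["cases", "controls"]].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog.to_numpy(), family=sm.families.Binomial())
        try:
            fit = model.fit(tol=1e-10, maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels internal
            raise ValueError(f"{rsid}: trend fit failed: {exc}")
    theta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(theta) or not np.isfinite(se) or se > 50 or abs(theta) > 50:
        raise ValueError(f"{rsid}: separation or monotone likelihood")
    z = theta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssocRecord(
        rsid=rsid,
        theta_hat=theta,
        V=se**2,
        Z=z,
        p=p,
        or_point=math.exp(theta),
        ci_lo=math.exp(theta - 1.959964 * se),
        ci_hi=math.exp(theta + 1.959964 * se),
    )


def fit_trend_many(
    cases: np.ndarray, controls: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> pd.DataFrame:
    """Vectorized per-allele logistic fits for many SNPs at once.

    cases, controls : (n_snps, 3) genotype count arrays.
    Returns a DataFrame with theta_hat, se, Z, p; NaN rows mark SNPs with
    an absent minor allele or a non-converging (separated) likelihood.
    Used by the simulation experiments, where per-SNP model objects would
    dominate the runtime; agrees with trend_logistic to optimizer
    tolerance.
    """
    y = np.asarray(cases, dtype=float)
    z = np.asarray(controls, dtype=float)
    if y.shape != z.shape or y.ndim != 2 or y.shape[1] != 3:
        raise ValueError("expected (n_snps, 3) case and control count arrays")
    n = y.shape[0]
    t = y + z
    g = np.array([0.0, 1.0, 2.0])

    ok = (y.sum(axis=1) > 0) & (z.sum(axis=1) > 0) & (t[:, 1] + t[:, 2] > 0)
    # also require the minor allele in both affection classes is not fully
    # determining: monotone tables are caught by the divergence check below

    a = np.where(ok, np.log((y.sum(axis=1) + 0.5) / (z.sum(axis=1) + 0.5)), 0.0)
    b = np.zeros(n)
    converged = np.zeros(n, dtype=bool)

    for _ in range(max_iter):
        eta = a[:, None] + b[:, None] * g[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = t * p * (1.0 - p)
        resid = y - t * p
        ga = resid.sum(axis=1)
        gb = (resid * g).sum(axis=1)
        haa = w.sum(axis=1)
        hab = (w * g).sum(axis=1)
        hbb = (w * g**2).sum(axis=1)
        det = haa * hbb - hab**2
        safe = ok & ~converged & (det > 1e-12)
        da = np.where(safe, (hbb * ga - hab * gb) / np.where(det > 0, det, 1.0), 0.0)
        db = np.where(safe, (haa * gb - hab * ga) / np.where(det > 0, det, 1.0), 0.0)
        step = np.clip(np.stack([da, db]), -5.0, 5.0)
        a = a + step[0]
        b = b + step[1]
        newly = safe & (np.abs(step[0]) < tol) & (np.abs(step[1]) < tol)
        converged |= newly
        if converged[ok].all():
            break

    diverged = np.abs(b) > 20
    good = ok & converged & ~diverged
    # final Hessian for Wald SEs
    eta = a[:, None] + b[:, None] * g[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = t * p * (1.0 - p)
    haa = w.sum(axis=1)
    hab = (w * g).sum(axis=1)
    hbb = (w * g**2).sum(axis=1)
    det = haa * hbb - hab**2
    var_b = np.where(good & (det > 0), haa / np.where(det > 0, det, 1.0), np.nan)

    theta = np.where(good, b, np.nan)
    se = np.sqrt(var_b)
    zstat = theta / se
    pval = 2 * stats.norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {"theta_hat": theta, "se": se, "Z": zstat, "p": pval}
    )


def hwe_test(controls: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square goodness of fit to Hardy–Weinberg proportions.

    Returns (chi2, p). A monomorphic SNP carries no HWE information:
    chi2 = 0, p = 1, with a warning.
    """
    m0, m1, m2 = controls
    n = m0 + m1 + m2
    if n <= 0:
        raise ValueError("no control genotypes")
    q = (m1 + 2 * m2) / (2.0 * n)  # minor allele frequency
    if q == 0.0 or q == 1.0:
        warnings.warn("monomorphic SNP: HWE test undefined, returning p = 1")
        return 0.0, 1.0
    p_ = 1.0 - q
    expected = np.array([n * p_**2, n * 2 * p_ * q, n * q**2])
    observed = np.array([m0, m1, m2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    counts: pd.DataFrame,
    snp_call_rate: pd.Series | None = None,
    sample_call_rate: pd.Series | None = None,
    min_call_rate: float = 0.95,
    min_sample_rate: float = 0.95,
    hwe_threshold: float = 1e-7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the standard exclusion rules; return (kept counts, report).

    counts columns: rsid, case0..case2, ctrl0..ctrl2. The report lists one
    row per exclusion with its reason ("call_rate", "hwe") — and one row
    per dropped sample ("sample_call_rate") when sample rates are given.
    Idempotent: rerunning on the kept table excludes nothing further.
    """
    report_rows = []
    if sample_call_rate is not None:
        for sample, rate in sample_call_rate.items():
            if rate < min_sample_rate:
                report_rows.append(
                    {"unit": "sample", "id": sample, "reason": "sample_call_rate",
                     "value": float(rate)}
                )

    keep = pd.Series(True, index=counts.index)
    if snp_call_rate is not None:
        aligned = counts["rsid"].map(snp_call_rate)
        low = aligned < min_call_rate
        for _, row in counts.loc[low].iterrows():
            report_rows.append(
                {"unit": "snp", "id": row["rsid"], "reason": "call_rate",
                 "value": float(aligned.loc[row.name])}
            )
        keep &= ~low

    for idx, row in counts.iterrows():
        if not keep.loc[idx]:
            continue
        _, p = hwe_test((int(row["ctrl0"]), int(row["ctrl1"]), int(row["ctrl2"])))
        if p < hwe_threshold:
            report_rows.append(
                {"unit": "snp", "id": row["rsid"], "reason": "hwe", "value": p}
            )
            keep.loc[idx] = False

    report = pd.DataFrame(report_rows, columns=["unit", "id", "reason", "value"])
    return counts.loc[keep].reset_index(drop=True), report


def cochran_q(estimates: list[StratumEstimate]) -> tuple[float, float]:
    """Cochran's Q heterogeneity test across strata or study phases.

    Q = Σ wᵢ(θᵢ − θ̄_w)² with wᵢ = 1/Vᵢ and θ̄_w the inverse-variance
    weighted mean; p from χ² with k−1 degrees of freedom.
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least two estimates")
    theta = np.array([e.theta_hat for e in estimates])
    w = np.array([1.0 / e.V for e in estimates])
    mean = float((w * theta).sum() / w.sum())
    q = float((w * (theta - mean) ** 2).sum())
    p = float(stats.chi2.sf(q, df=len(estimates) - 1))
    return q, p


def genomic_inflation(
    p_values: np.ndarray | None = None, chi2_stats: np.ndarray | None = None
) -> float:
    """Genomic inflation factor λ = median(χ²₁) / 0.4549…

    Accepts either two-sided p-values (converted to 1-df chi-square) or
    the chi-square statistics directly.
    """
    if chi2_stats is None:
        if p_values is None:
            raise ValueError("supply p_values or chi2_stats")
        p_arr = np.asarray(p_values, dtype=float)
        if p_arr.size == 0:
            raise ValueError("empty p-value vector")
        chi2_stats = stats.chi2.isf(p_arr, df=1)
    arr = np.asarray(chi2_stats, dtype=float)
    if arr.size == 0:
        raise ValueError("empty statistic vector")
    return float(np.median(arr) / CHI2_1_MEDIAN)


def read_genotype_counts(path: str) -> pd.DataFrame:
    """Read TSV genotype counts: rsid, optional stratum, case0..2, ctrl0..2."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    needed = {"rsid", "case0", "case1", "case2", "ctrl0", "ctrl1", "ctrl2"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
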