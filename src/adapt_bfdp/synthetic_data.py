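"""Synthetic corpora and case-control GWAS data with known ground truth.

Emulates the inputs of the literature-prior workflow end to end: per-gene
document corpora whose planted keywords yield known prior categories, and
case-control genotype counts under a per-allele log-additive odds model.
The subsampling experiment mirrors the validation design of running a
GWAS on random 50%/75% subsets of the subjects many times and comparing
each planted susceptibility SNP's rank by p-value against its rank by
BFDP.

Simulated loci are independent (no linkage disequilibrium), so
subject-level subsampling is performed marginally per SNP by hypergeometric
draws from the genotype counts — exactly equivalent per SNP to drawing the
same subject subset, and the analyses are all per-SNP.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_stats import fit_trend_many
from .bayes_rank import approximate_bayes_factor, bfdp, default_prior_variance
from .keyword_corpus import Document, GeneDocument, KeywordConfig
from .prior_model import prior_probabilities
from .snp_annotation import SnpLocus

__all__ = [
    "SimulationConfig",
    "default_keyword_config",
    "generate_corpus",
    "simulate_gwas",
    "subsample_experiment",
    "summarize_experiment",
]

# Keyword tiers emulating a study of oral cancer: tier 1 phenotype-specific,
# tier 2 strongly relevant risk factors, tier 3 generic cancer biology.
_G1 = ["oral cancer", "mouth neoplasm", "oral carcinoma"]
_G2 = ["smoking", "alcohol", "nicotine dependence"]
_G3 = ["carcinogen", "dna damage", "apoptosis"]

# Filler vocabulary whose stems never collide with the keyword stems.
_FILLER = (
    "the enzyme was expressed in cultured tissue and protein levels were "
    "measured across replicates suggesting a role in cellular membrane "
    "transport with further experiments planned"
).split()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic GWAS.

    Defaults follow the scanned-panel composition used throughout the
    method's power analysis (category fractions 0.875/0.10/0.025) at a
    desk scale of 10,000 independent SNPs and 1000/1000 subjects, with
    planted susceptibility SNPs of per-allele OR 1.25 — the intermediate
    effect size typical of common cancer variants.
    """

    n_snps: int = 10_000
    fractions: tuple[float, float, float] = (0.875, 0.10, 0.025)
    n_true: dict = field(
        default_factory=lambda: {"C1": 1, "C2": 4, "C3": 4}
    )
    true_or: float | str = 1.25
    maf_range: tuple[float, float] = (0.10, 0.40)
    n_cases: int = 1000
    n_controls: int = 1000
    subsample_fractions: tuple[float, ...] = (0.5, 0.75)
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if not 0 < self.maf_range[0] < self.maf_range[1] < 0.5:
            raise ValueError("MAF range must satisfy 0 < lo < hi < 0.5")
        if sum(self.n_true.values()) > self.n_snps:
            raise ValueError("more true SNPs than SNPs")


def default_keyword_config(date_cutoff: _dt.date | None = None) -> KeywordConfig:
    return KeywordConfig(g1=_G1, g2=_G2, g3=_G3, date_cutoff=date_cutoff)


def _planted_categories(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_snps
    n1 = int(round(config.fractions[0] * n))
    n2 = int(round(config.fractions[1] * n))
    n3 = n - n1 - n2
    cats = np.array(["C1"] * n1 + ["C2"] * n2 + ["C3"] * n3)
    rng.shuffle(cats)
    return cats


def _doc_for_category(
    category: str, rng: np.random.Generator, doc_id: str
) -> Document:
    """One document whose keyword content pins the gene to ``category``."""
    words = list(rng.choice(_FILLER, size=12))
    if category == "C3":
        groups = [_G1, _G2, _G3]
    elif category == "C2":
        k = int(rng.integers(1, 3))  # 1 or 2 tiers, never all three
        groups = [[_G1, _G2, _G3][i] for i in rng.choice(3, size=k, replace=False)]
    else:
        groups = []
    for tier in groups:
        phrase = tier[int(rng.integers(len(tier)))]
        pos = int(rng.integers(len(words) + 1))
        words.insert(pos, phrase)
    return Document(doc_id=doc_id, text=" ".join(words), date=_dt.date(2005, 6, 1))


def generate_corpus(
    config: SimulationConfig, seed: int
) -> tuple[list[GeneDocument], KeywordConfig, list[SnpLocus], pd.DataFrame]:
    """Corpus, keyword config, SNP loci and planted truth categories.

    One gene per SNP, spaced far enough apart that the 50 kb window maps
    each SNP to exactly its own gene; each gene's single document carries
    keywords from exactly the tiers its planted category implies.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cats = _planted_categories(config, rng)
    spacing = 300_000  # > 2*window + gene length: no cross-gene mapping
    genes, snps, rows = [], [], []
    for i, cat in enumerate(cats):
        chrom = str(1 + i % 22)
        start = 1 + (i // 22) * spacing
        end = start + 20_000
        gid = f"G{i:05d}"
        rsid = f"rs{i:06d}"
        docs = [] if (cat == "C1" and rng.random() < 0.5) else [
            _doc_for_category(cat, rng, doc_id=f"PM{i:07d}")
        ]
        genes.append(
            GeneDocument(
                gene_id=gid, symbol=gid, chrom=chrom, start=start, end=end,
                documents=docs,
            )
        )
        snps.append(SnpLocus(rsid=rsid, chrom=chrom, pos=start + 10_000))
        rows.append({"rsid": rsid, "gene_id": gid, "category": cat})
    truth = pd.DataFrame(rows)
    return genes, default_keyword_config(), snps, truth


def _case_probs(maf: np.ndarray, or_: np.ndarray) -> np.ndarray:
    """Case genotype probabilities under the retrospective tilt:
    proportional to HWE frequency times ORᵍ."""
    f = maf[:, None]
    hwe = np.concatenate(
        [(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1
    )
    tilt = or_[:, None] ** np.array([0.0, 1.0, 2.0])[None, :]
    probs = hwe * tilt
    return probs / probs.sum(axis=1, keepdims=True)


def simulate_gwas(
    config: SimulationConfig, seed: int, prior_variance: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype counts per SNP plus the ground-truth table.

    Controls are drawn at Hardy–Weinberg proportions for each SNP's MAF;
    cases from the tilted per-allele odds model. Null SNPs have OR = 1.
    ``config.true_or`` may be a fixed odds ratio or the string "prior",
    which draws each true SNP's log OR from N(0, W) — the distribution the
    Bayes factor's alternative assumes, used for calibration studies.
    """
    rng = np.random.default_rng(seed)
    n = config.n_snps
    cats = _planted_categories(config, rng)
    maf = rng.uniform(*config.maf_range, size=n)

    is_true = np.zeros(n, dtype=bool)
    for cat, k in config.n_true.items():
        idx = np.flatnonzero(cats == cat)
        if k > idx.size:
            raise ValueError(f"cannot plant {k} true SNPs in category {cat}")
        is_true[rng.choice(idx, size=k, replace=False)] = True

    or_ = np.ones(n)
    if config.true_or == "prior":
        w = prior_variance if prior_variance is not None else default_prior_variance()
        or_[is_true] = np.exp(rng.normal(0.0, np.sqrt(w), size=is_true.sum()))
    else:
        or_[is_true] = float(config.true_or)

    ctrl_probs = _case_probs(maf, np.ones(n))  # HWE, no tilt
    case_probs = _case_probs(maf, or_)
    controls = rng.multinomial(config.n_controls, ctrl_probs)
    cases = rng.multinomial(config.n_cases, case_probs)

    rsids = [f"rs{i:06d}" for i in range(n)]
    counts = pd.DataFrame(
        {
            "rsid": rsids,
            "case0": cases[:, 0], "case1": cases[:, 1], "case2": cases[:, 2],
            "ctrl0": controls[:, 0], "ctrl1": controls[:, 1], "ctrl2": controls[:, 2],
        }
    )
    truth = pd.DataFrame(
        {"rsid": rsids, "category": cats, "maf": maf, "true_or": or_,
         "is_true": is_true}
    )
    return counts, truth


def _subsample_counts(
    counts: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k subjects without replacement from each SNP's genotype counts
    (chained hypergeometric; vectorized over SNPs)."""
    c0, c1, c2 = counts[:, 0], counts[:, 1], counts[:, 2]
    x0 = rng.hypergeometric(c0, c1 + c2, k)
    x1 = rng.hypergeometric(c1, c2, k - x0)
    x2 = k - x0 - x1
    return np.stack([x0, x1, x2], axis=1)


def _ranks(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """1-based ranks ascending by primary, ties broken by secondary then index."""
    order = np.lexsort((np.arange(primary.size), secondary, primary))
    ranks = np.empty(primary.size, dtype=int)
    ranks[order] = np.arange(1, primary.size + 1)
    return ranks


def subsample_experiment(
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    fractions: tuple[float, ...] = (0.5, 0.75),
    n_replicates: int = 100,
    seed: int = 0,
    n_true_assumed: float = 100.0,
    W: float | None = None,
) -> pd.DataFrame:
    """Rank planted SNPs by p-value and by BFDP across random subsamples.

    For each fraction and replicate, cases and controls are subsampled in
    equal proportion without replacement, the trend model is refit for
    every SNP, and all SNPs are ranked by p and by BFDP (prior odds from
    the realized category counts, N* = ``n_true_assumed`` split evenly).
    SNPs whose subsampled table is degenerate rank last under both
    orderings. Returns one row per (fraction, replicate, planted SNP).
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("subsample fractions must lie in (0, 1]")
    if W is None:
        W = default_prior_variance()
    rng = np.random.default_rng(seed)

    case_mat = counts[["case0", "case1", "case2"]].to_numpy()
    ctrl_mat = counts[["ctrl0", "ctrl1", "ctrl2"]].to_numpy()
    n_cases = int(case_mat[0].sum())
    n_controls = int(ctrl_mat[0].sum())

    cat_counts = truth["category"].value_counts().to_dict()
    spec = prior_probabilities(cat_counts, n_true=n_true_assumed, allocation="even")
    po = truth["category"].map(dict(zip(spec.categories, spec.po))).to_numpy()

    planted = truth["is_true"].to_numpy()
    planted_idx = np.flatnonzero(planted)

    rows = []
    for frac in fractions:
        k_cases = int(round(frac * n_cases))
        k_controls = int(round(frac * n_controls))
        for rep in range(n_replicates):
            if frac == 1.0:
                sub_cases, sub_ctrls = case_mat, ctrl_mat
            else:
                sub_cases = _subsample_counts(case_mat, k_cases, rng)
                sub_ctrls = _subsample_counts(ctrl_mat, k_controls, rng)
            fit = fit_trend_many(sub_cases, sub_ctrls)
            z = fit["Z"].to_numpy()
            v = fit["se"].to_numpy() ** 2
            p = fit["p"].to_numpy()
            bad = ~np.isfinite(p)
            p = np.where(bad, 1.0, p)
            bf = np.ones(len(p))
            good = ~bad
            bf[good] = bfdp(
                approximate_bayes_factor(z[good], v[good], W), po[good]
            )
            rank_p = _ranks(p, np.zeros_like(p))
            rank_b = _ranks(bf, p)
            for i in planted_idx:
                rows.append(
                    {
                        "fraction": frac,
                        "replicate": rep,
                        "rsid": truth["rsid"].iloc[i],
                        "category": truth["category"].iloc[i],
                        "rank_p": int(rank_p[i]),
                        "rank_bfdp": int(rank_b[i]),
                    }
                )
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Per (SNP, fraction) rank summaries: median/mean/min/max by each
    ranking plus the median and mean deltas (BFDP rank − p rank; negative
    means the literature prior moved the SNP up)."""
    def agg(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "category": group["category"].iloc[0],
                "median_rank_p": group["rank_p"].median(),
                "mean_rank_p": group["rank_p"].mean(),
                "min_rank_p": group["rank_p"].min(),
                "max_rank_p": group["rank_p"].max(),
                "median_rank_bfdp": group["rank_bfdp"].median(),
                "mean_rank_bfdp": group["rank_bfdp"].mean(),
                "min_rank_bfdp": group["rank_bfdp"].min(),
                "max_rank_bfdp": group["rank_bfdp"].max(),
                "median_delta": group["rank_bfdp"].median()
                - group["rank_p"].median(),
                "mean_delta": group["rank_bfdp"].mean() - group["rank_p"].mean(),
            }
        )

    out = (
        results.groupby(["rsid", "fraction"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out
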