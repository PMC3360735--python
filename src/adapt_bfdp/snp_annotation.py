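"""SNP-to-gene mapping and prior-category assignment.

A SNP inherits literature evidence from every gene within a window (50 kb
by default) of its position: the per-gene tier flags are pooled by OR,
which is equivalent to classifying the pooled documents of all mapped
genes. The 8 possible flag combinations collapse into three prior
categories:

    C1 — no tier matched        (no literature evidence)
    C2 — some but not all tiers (partial evidence)
    C3 — all three tiers        (evidence at every level of specificity)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .keyword_corpus import GeneDocument, GroupFlags, KeywordConfig, classify_gene

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000

__all__ = [
    "SnpLocus",
    "DEFAULT_WINDOW",
    "map_snp_to_genes",
    "snp_flags",
    "assign_category",
    "annotate_snps",
    "read_snp_table",
    "write_category_table",
]


@dataclass(frozen=True)
class SnpLocus:
    """One SNP: rsid, chromosome label and 1-based position."""

    rsid: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")


def map_snp_to_genes(
    snp: SnpLocus,
    genes: list[GeneDocument],
    window: int = DEFAULT_WINDOW,
) -> list[str]:
    """Gene ids whose closed interval lies within ``window`` bp of the SNP.

    Distance is 0 for a SNP inside [start, end]; the window boundary is
    inclusive (a gene exactly ``window`` bp away is mapped).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits = []
    for gene in genes:
        if gene.chrom != snp.chrom:
            continue
        if snp.pos < gene.start:
            dist = gene.start - snp.pos
        elif snp.pos > gene.end:
            dist = snp.pos - gene.end
        else:
            dist = 0
        if dist <= window:
            hits.append(gene.gene_id)
    return hits


def snp_flags(mapped_flags: list[GroupFlags]) -> GroupFlags:
    """Pool gene-level flags to SNP level by element-wise OR."""
    out = GroupFlags()
    for f in mapped_flags:
        out = out | f
    return out


def assign_category(flags: GroupFlags) -> str:
    """Collapse the 8 flag combinations into C1 / C2 / C3."""
    n = int(flags.g1) + int(flags.g2) + int(flags.g3)
    if n == 0:
        return "C1"
    if n == 3:
        return "C3"
    return "C2"


def annotate_snps(
    snps: list[SnpLocus],
    genes: list[GeneDocument],
    config: KeywordConfig,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Classify every SNP: mapped genes, pooled tier flags, prior category.

    Gene classification is computed once per gene and reused across SNPs.
    Returns a DataFrame with columns rsid, mapped_genes (comma-joined),
    g1, g2, g3, category. The full flag combination is kept so users can
    redefine the collapsing rule downstream.
    """
    gene_flags = {g.gene_id: classify_gene(g, config) for g in genes}
    rows = []
    for snp in snps:
        mapped = map_snp_to_genes(snp, genes, window)
        flags = snp_flags([gene_flags[gid] for gid in mapped])
        rows.append(
            {
                "rsid": snp.rsid,
                "mapped_genes": ",".join(mapped),
                "g1": int(flags.g1),
                "g2": int(flags.g2),
                "g3": int(flags.g3),
                "category": assign_category(flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["rsid", "mapped_genes", "g1", "g2", "g3", "category"]
    )


def read_snp_table(path: str, bed: bool = False) -> list[SnpLocus]:
    """Read SNP loci from TSV (rsid, chrom, pos; header required).

    With ``bed=True`` the file is read as BED (chrom, start, end, name;
    0-based half-open) and converted to 1-based positions.
    """
    if bed:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
        )
        logger.info("BED input: converting 0-based starts to 1-based positions")
        return [
            SnpLocus(rsid=str(r.name_), chrom=str(r.chrom), pos=int(r.start) + 1)
            for r in df.rename(columns={"name": "name_"}).itertuples()
        ]
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    missing = {"rsid", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SnpLocus(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos))
        for r in df.itertuples()
    ]


def write_category_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
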