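"""Summary-level transcriptome-wide association.

Combines GWAS SNP z-scores with SNP-expression weights into a gene-level
association Z without individual genotypes:

    Z_g = sum_l w_lg * (sigma_l / sigma_g) * z_l

where sigma_l = sqrt(2 p_l (1-p_l)) is the SNP's genotype SD and
sigma_g^2 = w' Sigma w is the predicted-expression variance over the LD
reference covariance Sigma. Weight alleles are aligned to the summary
statistics' effect allele before combining. Includes region filtering
(e.g. the chr17q21.31 inversion) and FDR over gene-tissue pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

#: default 17q21.31 inversion interval (GRCh37, ~1.5 Mb)
INV_17Q21_GRCH37 = {"chrom": 17, "start": 43_500_000, "end": 45_000_000}


@dataclass
class WeightTable:
    """SNP-expression weights: records (gene, tissue, snp, a1, weight)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"GENE", "TISSUE", "SNP", "A1", "WEIGHT"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"weight table needs columns {sorted(need)}")
        nz = self.df.groupby(["GENE", "TISSUE"])["WEIGHT"].apply(
            lambda w: np.any(w != 0)
        )
        if not nz.all():
            raise ValueError("every gene must have at least one nonzero weight")

    @classmethod
    def read_tsv(cls, path) -> "WeightTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def spredixcan_assoc(
    s: SummaryStats,
    weights: WeightTable,
    panel,
    min_coverage_flag: float = 0.5,
) -> pd.DataFrame:
    """Gene-tissue association Z from SNP z-scores and expression weights.

    Weight SNPs absent from the summary statistics or panel are dropped and
    sigma_g renormalized over the retained SNPs; genes with coverage below
    ``min_coverage_flag`` are flagged. Returns a frame with one row per
    gene-tissue pair (zscore, pval, n_snps_used, coverage, low_coverage).
    """
    loc_of = panel.snp_location()
    zmap = s.df.set_index("snp")[["z", "a1", "a2"]]
    rows = []
    for (gene, tissue), grp in weights.df.groupby(["GENE", "TISSUE"]):
        n_model = len(grp)
        grp = grp[grp["SNP"].isin(zmap.index) & grp["SNP"].isin(loc_of)]
        if len(grp) == 0:
            logger.warning("gene %s/%s: no usable SNPs, skipped", gene, tissue)
            continue
        w, zz, sig = [], [], []
        per_block: dict[int, list[tuple[int, float]]] = {}
        usable = True
        for _, r in grp.iterrows():
            srec = zmap.loc[r["SNP"]]
            if r["A1"] == srec["a1"]:
                wk = float(r["WEIGHT"])
            elif r["A1"] == srec["a2"]:
                wk = -float(r["WEIGHT"])
            else:
                continue  # allele mismatch: drop the SNP
            bi, j = loc_of[r["SNP"]]
            maf = panel.blocks[bi].maf[j]
            sk = np.sqrt(2.0 * maf * (1.0 - maf))
            w.append(wk)
            zz.append(float(srec["z"]))
            sig.append(sk)
            per_block.setdefault(bi, []).append((j, wk * sk))
        if not w:
            logger.warning("gene %s/%s: no allele-consistent SNPs", gene, tissue)
            continue
        # predicted-expression variance w' Sigma w, block-diagonal Sigma
        var_g = 0.0
        for bi, items in per_block.items():
            idx = np.array([j for j, _ in items])
            ws = np.array([v for _, v in items])  # weights already scaled by sigma_l
            Rsub = panel.blocks[bi].corr[np.ix_(idx, idx)]
            var_g += float(ws @ Rsub @ ws)
        if var_g <= 0:
            logger.warning("gene %s/%s: non-positive expression variance", gene, tissue)
            continue
        sigma_g = np.sqrt(var_g)
        zg = float(np.sum(np.array(w) * np.array(sig) * np.array(zz)) / sigma_g)
        coverage = len(w) / n_model
        rows.append(
            dict(
                gene=gene,
                tissue=tissue,
                zscore=zg,
                pval=2.0 * stats.norm.sf(abs(zg)),
                n_snps_used=len(w),
                coverage=coverage,
                low_coverage=coverage < min_coverage_flag,
            )
        )
    return pd.DataFrame(rows)


def filter_region(
    obj,
    region: dict = INV_17Q21_GRCH37,
    weights: WeightTable | None = None,
):
    """Remove SNPs (for SummaryStats input) or gene-tissue results whose
    model contains any SNP inside ``region`` ({chrom, start, end}; half-open
    on the end internally, so a SNP at end+1 bp is retained)."""
    chrom, start, end = region["chrom"], region["start"], region["end"]
    if isinstance(obj, SummaryStats):
        df = obj.df
        inside = (
            (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)
        )
        logger.info("filter_region: removed %d SNPs", int(inside.sum()))
        if inside.all():
            raise ValueError("filter_region removed every SNP")
        return obj.replace(df[~inside])
    # gene-level results: need the weight table to locate model SNPs
    if weights is None:
        raise ValueError("filtering TWAS results requires the weight table")
    results = obj
    wdf = weights.df
    if {"CHR", "BP"}.issubset(wdf.columns):
        in_region = (
            (wdf["CHR"] == chrom) & (wdf["BP"] >= start) & (wdf["BP"] < end)
        )
        bad_genes = set(wdf.loc[in_region, "GENE"])
    else:
        raise ValueError(
            "weight table needs CHR/BP columns to filter results by region"
        )
    kept = results[~results["gene"].isin(bad_genes)].reset_index(drop=True)
    logger.info(
        "filter_region: removed %d gene-tissue pairs", len(results) - len(kept)
    )
    return kept
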