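"""GWAS summary-statistics containers, harmonisation and locus utilities.

The central object is :class:`SummaryStats`, a validated per-variant table of
association results for one trait (alleles, effect-allele frequency, beta,
SE, z, p, sample sizes). Operations cover the standard preprocessing steps
of a cross-trait summary-level analysis: allele harmonisation of a trait
pair, sign-flipping a trait to its mirrored definition (e.g. rhythm ability
-> rhythm impairment), genomic-control correction, HapMap3-style SNP
filtering with MHC exclusion, locus definition (distance merge or greedy LD
clumping) and padded interval intersection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df, used for lambda_GC
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


def two_sided_p(z) -> np.ndarray:
    """Two-sided normal p-value, floored at the smallest positive float so
    extreme statistics never underflow to an invalid p of 0."""
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)

#: canonical TSV column dialect (external name -> internal name)
TSV_COLUMNS = {
    "SNP": "snp",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "a1",
    "A2": "a2",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "Z": "z",
    "P": "pval",
    "N": "n",
    "N_CASES": "n_cases",
    "N_EFF": "n_eff",
}

REQUIRED = ["snp", "chrom", "pos", "a1", "a2", "eaf", "beta", "se"]
OPTIONAL = ["z", "pval", "n", "n_cases", "n_eff"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table."""


@dataclass
class SummaryStats:
    """Validated per-variant association records for a single trait.

    ``df`` holds one row per SNP with internal column names
    ``snp, chrom, pos, a1, a2, eaf, beta, se, z, pval`` and optionally
    ``n, n_cases, n_eff``. Betas are per-allele effects (log-odds for
    binary traits analysed on the observed scale); ``z = beta/se``.
    """

    df: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp(self) -> pd.Series:
        return self.df["snp"]

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(float)

    def median_n(self) -> float:
        """Median per-SNP sample size (the convention for varying-N files)."""
        return float(self.df["n"].median())

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise SumstatsError(f"missing required columns: {missing}")
        if df["snp"].duplicated().any():
            first = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
            raise SumstatsError(f"duplicate snp_id (first duplicate: {first!r})")
        if "z" not in df.columns:
            df["z"] = df["beta"] / df["se"]
        if "pval" not in df.columns:
            df["pval"] = two_sided_p(df["z"])
        bad = (
            ~df["eaf"].between(0, 1, inclusive="neither")
            | (df["se"] <= 0)
            | ~df["pval"].between(0, 1, inclusive="right")
        )
        if bad.any():
            raise SumstatsError(
                f"{int(bad.sum())} rows violate eaf/(0,1), se>0 or p in (0,1]"
            )

    def replace(self, df: pd.DataFrame, trait: str | None = None) -> "SummaryStats":
        return SummaryStats(df, self.trait if trait is None else trait)


@dataclass
class LocusSet:
    """Non-overlapping genomic intervals, each with a lead SNP.

    Intervals are 1-based inclusive in ``df`` (columns ``chrom, start, end,
    lead_snp, lead_p``); BED I/O converts to 0-based half-open.
    """

    df: pd.DataFrame
    tag: str = ""

    def __post_init__(self) -> None:
        df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts > ends).any():
                raise ValueError("locus with start > end")
            if (starts[1:] <= ends[:-1]).any():
                raise ValueError("overlapping loci on one chromosome")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_bed(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "start": self.df["start"] - 1,  # 0-based half-open
                "end": self.df["end"],
                "name": self.df.get("lead_snp", pd.Series([""] * len(self.df))),
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, tag: str = "") -> "LocusSet":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = pd.DataFrame(
            {
                "chrom": bed[0].astype(str).str.replace("chr", "", regex=False).astype(int),
                "start": bed[1].astype(int) + 1,
                "end": bed[2].astype(int),
            }
        )
        if bed.shape[1] > 3:
            df["lead_snp"] = bed[3]
        return cls(df, tag=tag)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict | None = None, trait: str = "") -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file header names onto the canonical dialect
    (``SNP, CHR, BP, A1, A2, EAF, BETA, SE, Z, P, N, N_CASES``). Rows that
    fail numeric parsing or basic validation are dropped with a logged
    count; a missing *required* column is fatal.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    df = df.rename(columns=TSV_COLUMNS)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SumstatsError(f"missing required column(s): {missing}")
    for col in ["chrom", "pos", "eaf", "beta", "se"] + [
        c for c in ("z", "pval", "n", "n_cases", "n_eff") if c in df.columns
    ]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["chrom", "pos", "eaf", "beta", "se"])
    ok = (
        df["eaf"].between(0, 1, inclusive="neither")
        & (df["se"] > 0)
        & df["a1"].isin(list("ACGT"))
        & df["a2"].isin(list("ACGT"))
    )
    df = df[ok]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning("read_sumstats: dropped %d invalid rows", n_dropped)
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    return SummaryStats(df.reset_index(drop=True), trait=trait)


def write_sumstats(s: SummaryStats, path) -> None:
    inv = {v: k for k, v in TSV_COLUMNS.items()}
    out = s.df.rename(columns=inv)
    cols = [c for c in TSV_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonisation and transforms
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


@dataclass
class HarmonizeReport:
    n_common: int
    n_flipped: int
    n_ambiguous_dropped: int
    n_mismatched_dropped: int


def harmonize_pair(
    a: SummaryStats, b: SummaryStats
) -> tuple[SummaryStats, SummaryStats, HarmonizeReport]:
    """Align two traits' summary statistics on shared SNPs and alleles.

    SNPs are intersected by id; where ``b``'s alleles are swapped relative
    to ``a``, its beta/z are negated and eaf complemented. Strand-ambiguous
    (A/T, C/G) SNPs are dropped, as are SNPs whose alleles do not match
    under either orientation.
    """
    common = a.snp[a.snp.isin(set(b.snp))]
    if len(common) == 0:
        raise SumstatsError("empty SNP intersection between traits")
    da = a.df.set_index("snp").loc[common].reset_index()
    db = b.df.set_index("snp").loc[common].reset_index()

    amb = _is_ambiguous(da["a1"], da["a2"]) | _is_ambiguous(db["a1"], db["a2"])
    same = (da["a1"] == db["a1"]) & (da["a2"] == db["a2"])
    swapped = (da["a1"] == db["a2"]) & (da["a2"] == db["a1"])
    keep = ~amb & (same | swapped)
    n_amb = int((amb & (same | swapped)).sum())
    n_bad = int((~same & ~swapped).sum())

    da, db = da[keep].copy(), db[keep].copy()
    flip = swapped[keep].to_numpy()
    db.loc[flip, "beta"] *= -1
    db.loc[flip, "z"] *= -1
    db.loc[flip, "eaf"] = 1.0 - db.loc[flip, "eaf"]
    db.loc[flip, ["a1", "a2"]] = db.loc[flip, ["a2", "a1"]].to_numpy()

    report = HarmonizeReport(int(keep.sum()), int(flip.sum()), n_amb, n_bad)
    if report.n_common == 0:
        raise SumstatsError("no SNPs left after allele harmonisation")
    logger.info("harmonize_pair: %s", report)
    return a.replace(da), b.replace(db), report


def flip_effects(s: SummaryStats, trait: str | None = None) -> SummaryStats:
    """Multiply effect sizes by −1 to redefine the trait in the opposite
    direction (e.g. beat-synchronisation ability -> rhythm impairment).

    Beta and z are negated; SE, p, allele frequency and alleles are
    untouched, so the flip is an involution.
    """
    df = s.df.copy()
    df["beta"] = -df["beta"]
    df["z"] = -df["z"]
    new_trait = trait if trait is not None else (s.trait + "_flipped" if s.trait else "")
    return SummaryStats(df, trait=new_trait)


def genomic_control(
    s: SummaryStats, lam: float | None = None
) -> tuple[SummaryStats, float]:
    """Apply genomic-control deflation to the test statistics.

    If ``lam`` is not supplied it is estimated as ``median(chi2)/0.4549``
    (the conventional lambda_GC). Corrected chi2 = z^2/lambda with the sign
    of z preserved, SE scaled by sqrt(lambda), p recomputed.
    """
    chi2 = s.z ** 2
    lambda_gc = float(np.median(chi2) / CHI2_MEDIAN_1DF) if lam is None else float(lam)
    if lambda_gc <= 0:
        raise SumstatsError("lambda_GC must be positive")
    df = s.df.copy()
    scale = np.sqrt(lambda_gc)
    df["z"] = df["z"] / scale
    df["se"] = df["se"] * scale
    df["pval"] = two_sided_p(df["z"])
    return SummaryStats(df, trait=s.trait), lambda_gc


def effective_n(n_cases: float, n_total: float) -> float:
    """Effective sample size of a case-control GWAS.

    ``4*N_cases*(1 - N_cases/N_total)``, the balanced-design equivalent N;
    algebraically equal to ``4/(1/N_cases + 1/N_controls)``.
    """
    if not 0 < n_cases < n_total:
        raise ValueError("require 0 < n_cases < n_total")
    return 4.0 * n_cases * (1.0 - n_cases / n_total)


#: default MHC exclusion interval, GRCh37 (chr6:25-34 Mb)
MHC_GRCH37 = {"chrom": 6, "start": 25_000_000, "end": 34_000_000}


def snp_filter(
    s: SummaryStats,
    keep_list: set | None = None,
    exclude_regions: LocusSet | None = None,
) -> SummaryStats:
    """Restrict to a SNP keep-list (e.g. HapMap3) outside excluded regions
    (e.g. the MHC). An empty/None keep-list keeps everything."""
    df = s.df
    mask = np.ones(len(df), dtype=bool)
    if keep_list:
        mask &= df["snp"].isin(keep_list).to_numpy()
    if exclude_regions is not None and len(exclude_regions):
        for _, r in exclude_regions.df.iterrows():
            mask &= ~(
                (df["chrom"].to_numpy() == r["chrom"])
                & (df["pos"].to_numpy() >= r["start"])
                & (df["pos"].to_numpy() <= r["end"])
            )
    n_removed = int((~mask).sum())
    if mask.sum() == 0:
        raise SumstatsError("snp_filter removed every SNP")
    if n_removed:
        logger.info("snp_filter: removed %d SNPs", n_removed)
    return s.replace(df[mask])


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------

def define_loci(
    s: SummaryStats,
    p_thresh: float = 5e-8,
    mode: str = "distance",
    merge_bp: int = 250_000,
    r2_thresh: float = 0.06,
    panel=None,
) -> LocusSet:
    """Delimit association loci from significant SNPs.

    ``distance`` mode merges significant SNPs within ``merge_bp`` of each
    other into one locus. ``ld_clump`` mode is the greedy clumping used for
    e.g. conservation scatters: take the most significant unassigned SNP as
    index, assign every SNP with r^2 > ``r2_thresh`` (from ``panel``) to it,
    repeat. The lead SNP of each locus is its smallest-p member.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0,1)")
    sig = s.df[s.df["pval"] < p_thresh].sort_values(["chrom", "pos"])
    if len(sig) == 0:
        return LocusSet(
            pd.DataFrame(columns=["chrom", "start", "end", "lead_snp", "lead_p"]),
            tag=f"P<{p_thresh:g}",
        )
    if mode == "distance":
        rows = []
        for chrom, grp in sig.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            new_locus = np.concatenate([[True], np.diff(pos) > merge_bp])
            for _, loc in grp.groupby(np.cumsum(new_locus)):
                lead = loc.loc[loc["pval"].idxmin()]
                rows.append(
                    dict(
                        chrom=int(chrom),
                        start=int(loc["pos"].min()),
                        end=int(loc["pos"].max()),
                        lead_snp=lead["snp"],
                        lead_p=float(lead["pval"]),
                        n_snps=len(loc),
                    )
                )
    elif mode == "ld_clump":
        if panel is None:
            raise ValueError("ld_clump mode requires an LD panel")
        rows = _greedy_clump(sig, panel, r2_thresh)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LocusSet(pd.DataFrame(rows), tag=f"P<{p_thresh:g}")


def _greedy_clump(sig: pd.DataFrame, panel, r2_thresh: float) -> list[dict]:
    loc_of = panel.snp_location()  # snp -> (block index, within-block index)
    sig = sig[sig["snp"].isin(loc_of)].sort_values("pval")
    assigned: set[str] = set()
    rows = []
    for _, row in sig.iterrows():
        if row["snp"] in assigned:
            continue
        bi, j = loc_of[row["snp"]]
        block = panel.blocks[bi]
        r2 = block.corr[j] ** 2
        members = [row["snp"]]
        for k, sid in enumerate(block.snp_ids):
            if sid == row["snp"] or sid in assigned:
                continue
            if r2[k] > r2_thresh and sid in set(sig["snp"]):
                members.append(sid)
        assigned.update(members)
        mem = sig[sig["snp"].isin(members)]
        rows.append(
            dict(
                chrom=int(row["chrom"]),
                start=int(mem["pos"].min()),
                end=int(mem["pos"].max()),
                lead_snp=row["snp"],
                lead_p=float(row["pval"]),
                n_snps=len(mem),
            )
        )
    return rows


def pad_and_intersect(a: LocusSet, b: LocusSet, pad_bp: int = 0) -> list[tuple[int, int]]:
    """Pairs (i, j) of loci where a_i, padded by ``pad_bp`` on both sides,
    overlaps b_j (bedtools-intersect semantics; half-open internally)."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    pairs = []
    for i, ra in a.df.iterrows():
        a_start = ra["start"] - 1 - pad_bp  # half-open, padded
        a_end = ra["end"] + pad_bp
        for j, rb in b.df.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            if a_start < rb["end"] and (rb["start"] - 1) < a_end:
                pairs.append((int(i), int(j)))
    return pairs


def generations_to_years(generations: float, years_per_generation: float = 25.0) -> float:
    """Convert an allele age in generations to years."""
    if generations < 0 or years_per_generation < 0:
        raise ValueError("inputs must be non-negative")
    return generations * years_per_generation
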