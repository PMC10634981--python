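"""Bivariate common-factor multivariate GWAS with per-SNP heterogeneity.

The measurement model puts a single shared genetic factor F behind the two
traits with both loadings fixed to 1, so the factor variance equals the
genetic covariance (just-identified on a standardized 2x2 S). Each SNP is
then fit twice:

* Common Pathway Model (CPM): the SNP affects both traits only through F.
  One free parameter b (the SNP -> F path), estimated by generalized least
  squares of the SNP-trait genetic covariances (g1, g2) on the design
  (sigma2_snp, sigma2_snp) with error covariance [[v11, v12], [v12, v22]].
* Independent Pathways Model (IPM): separate direct SNP -> trait paths;
  saturated for two traits, so its chi-square is 0.

The per-SNP heterogeneity statistic is Q_b = chi2_CPM - chi2_IPM =
chi2_CPM, distributed chi2(1) under effect homogeneity; in closed form
Q_b = (g1 - g2)^2 / (v11 + v22 - 2 v12). Large Q_b flags SNPs whose
effects are not mediated by the shared factor. Factor-level summary
statistics (b, SE, z, p) are emitted as a new GWAS, optionally with
genomic-control correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import GenCovEstimate
from .sumstats import LocusSet, SummaryStats, genomic_control, two_sided_p


@dataclass
class BaseModelFit:
    var_F: float
    se_var_F: float
    resid_u1: float
    resid_u2: float
    converged: bool = True


def standardize_snp_effects(
    s: SummaryStats, panel
) -> pd.DataFrame:
    """Per-SNP genetic covariance g and its sampling variance v on the
    partially standardized scale (trait variance 1, genotype in allele
    counts): g = beta * sigma2_snp, v = (se * sigma2_snp)^2, with
    sigma2_snp = 2p(1-p) from the reference panel MAF. SNPs absent from
    the panel are dropped with a count."""
    maf = pd.DataFrame({"snp": panel.snp_ids, "maf": panel.maf})
    d = s.df.merge(maf, on="snp", how="inner")
    n_dropped = len(s) - len(d)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "standardize_snp_effects: %d SNPs missing from panel", n_dropped
        )
    sigma2 = 2.0 * d["maf"] * (1.0 - d["maf"])
    out = d[["snp", "chrom", "pos", "a1", "a2", "eaf"]].copy()
    out["sigma2_snp"] = sigma2
    out["g"] = d["beta"] * sigma2
    out["v"] = (d["se"] * sigma2) ** 2
    out["se_orig"] = d["se"]
    return out


def fit_base_model(gencov: GenCovEstimate) -> BaseModelFit:
    """Fit the measurement model (loadings fixed to 1) to the 2x2 genetic
    covariance matrix by WLS against (S11, S12, S22) with weights
    diag(V)^-1. Just-identified, so var_F = S12 exactly and the residual
    variances are S_ii - S12. A negative S12 is allowed but flagged: align
    trait directions (sign-flip) first if the factor is meant to represent
    shared risk."""
    S, V = gencov.S, gencov.V
    svec = np.array([S[0, 0], S[0, 1], S[1, 1]])
    A = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 1.0]])
    W = np.diag(1.0 / np.maximum(np.diag(V), 1e-12))
    AtWA = A.T @ W @ A
    theta = np.linalg.solve(AtWA, A.T @ W @ svec)
    # sandwich: exact sampling covariance of the WLS solution under V
    H = np.linalg.solve(AtWA, A.T @ W)
    cov_theta = H @ V @ H.T
    fit = BaseModelFit(
        var_F=float(theta[0]),
        se_var_F=float(np.sqrt(cov_theta[0, 0])),
        resid_u1=float(theta[1]),
        resid_u2=float(theta[2]),
    )
    if fit.var_F < 0:
        import logging

        logging.getLogger(__name__).warning(
            "fit_base_model: negative factor variance (S12 < 0); "
            "flip one trait to align effect directions"
        )
    return fit


def fit_snp_models(
    g1: np.ndarray,
    g2: np.ndarray,
    v11: np.ndarray,
    v22: np.ndarray,
    v12: np.ndarray,
    sigma2_snp: np.ndarray,
) -> pd.DataFrame:
    """Vectorized per-SNP CPM and IPM fits.

    CPM by GLS: b = (1' Vg^-1 g) / (sigma2_snp * 1' Vg^-1 1) with
    chi2_cpm the GLS residual quadratic form; IPM is saturated
    (beta_i = g_i / sigma2_snp, chi2 = 0). Q_b = chi2_cpm - chi2_ipm,
    p from the upper chi2(1) tail. SNPs with singular Vg yield NaN.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    v11 = np.asarray(v11, float)
    v22 = np.asarray(v22, float)
    v12 = np.broadcast_to(np.asarray(v12, float), g1.shape).copy()
    sigma2 = np.asarray(sigma2_snp, float)

    det = v11 * v22 - v12 ** 2
    ok = (v11 > 0) & (v22 > 0) & (det > 0)
    det_safe = np.where(ok, det, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        one_Vi_one = (v11 + v22 - 2.0 * v12) / det_safe
        one_Vi_g = (v22 * g1 + v11 * g2 - v12 * (g1 + g2)) / det_safe
        g_Vi_g = (v22 * g1 ** 2 - 2.0 * v12 * g1 * g2 + v11 * g2 ** 2) / det_safe

        b = one_Vi_g / (sigma2 * one_Vi_one)
        se_b = 1.0 / (sigma2 * np.sqrt(one_Vi_one))
        chi2_cpm = g_Vi_g - one_Vi_g ** 2 / one_Vi_one
        chi2_cpm = np.maximum(chi2_cpm, 0.0)  # guard tiny negative round-off

        z_b = b / se_b
    p_cpm = two_sided_p(z_b)
    qb = chi2_cpm  # chi2_IPM = 0 (saturated)
    p_qb = stats.chi2.sf(qb, 1)

    for arr in (b, se_b, z_b, p_cpm, qb, p_qb):
        arr[~ok] = np.nan

    return pd.DataFrame(
        {
            "g1": g1,
            "g2": g2,
            "v11": v11,
            "v22": v22,
            "v12": v12,
            "b_common": b,
            "se_b": se_b,
            "z_b": z_b,
            "p_cpm": p_cpm,
            "chi2_cpm": chi2_cpm,
            "beta1_ind": g1 / sigma2,
            "beta2_ind": g2 / sigma2,
            "chi2_ipm": 0.0,
            "qb": qb,
            "p_qb": p_qb,
        }
    )


def run_mvgwas(
    a: SummaryStats,
    b: SummaryStats,
    panel,
    gencov: GenCovEstimate,
    effects_aligned: bool = False,
    gc_correct: bool = False,
    gc_correct_qb: bool = False,
    sig_thresh: float = 5e-8,
) -> tuple[SummaryStats, pd.DataFrame, float | None]:
    """Run the common-factor mvGWAS over all shared SNPs.

    ``effects_aligned`` must be set to confirm both traits are coded in the
    same direction (impairment/risk); flip one trait first if not. The
    cross-trait sampling covariance v12 uses the LDSC cross-trait intercept
    (constant across SNPs). Returns (factor summary statistics, per-SNP
    fit table, lambda_GC applied or None).

    The factor summary statistics carry an expected effective N implied by
    the factor SEs, median over SNPs of 1/(se^2 * 2p(1-p)).
    """
    if not effects_aligned:
        raise ValueError(
            "run_mvgwas requires effects_aligned=True: both traits must be "
            "coded in the same (risk/impairment) direction, e.g. via flip_effects"
        )
    ga = standardize_snp_effects(a, panel)
    gb = standardize_snp_effects(b, panel)
    d = ga.merge(
        gb[["snp", "g", "v", "se_orig"]], on="snp", suffixes=("_1", "_2")
    ).rename(columns={"g_1": "g1", "g_2": "g2", "v_1": "v11", "v_2": "v22"})
    rho_int = float(gencov.intercepts[0, 1])
    if abs(rho_int) > 0.99:
        # the cross-trait intercept estimates a correlation of estimation
        # noise, so |rho| < 1 by definition; clamp a noisy estimate
        import logging

        logging.getLogger(__name__).warning(
            "run_mvgwas: cross-trait intercept %.2f clamped to +-0.99", rho_int
        )
        rho_int = float(np.clip(rho_int, -0.99, 0.99))
    v12 = rho_int * d["se_orig_1"] * d["se_orig_2"] * d["sigma2_snp"] ** 2

    fits = fit_snp_models(
        d["g1"], d["g2"], d["v11"], d["v22"], v12, d["sigma2_snp"]
    )
    fits.insert(0, "snp", d["snp"].to_numpy())
    fits.insert(1, "chrom", d["chrom"].to_numpy())
    fits.insert(2, "pos", d["pos"].to_numpy())

    n_bad = int(fits["b_common"].isna().sum())
    if n_bad:
        import logging

        logging.getLogger(__name__).warning(
            "run_mvgwas: skipped %d SNPs with singular sampling covariance", n_bad
        )
    good = fits.dropna(subset=["b_common"])

    n_implied = 1.0 / (
        good["se_b"].to_numpy() ** 2 * d.loc[good.index, "sigma2_snp"].to_numpy()
    )
    n_eff_factor = float(np.median(n_implied))
    factor_df = pd.DataFrame(
        {
            "snp": good["snp"],
            "chrom": good["chrom"],
            "pos": good["pos"],
            "a1": d.loc[good.index, "a1"],
            "a2": d.loc[good.index, "a2"],
            "eaf": d.loc[good.index, "eaf"],
            "beta": good["b_common"],
            "se": good["se_b"],
            "z": good["z_b"],
            "pval": good["p_cpm"],
            "n": n_eff_factor,
            "n_eff": n_eff_factor,
        }
    )
    factor = SummaryStats(factor_df, trait="common_factor")

    lam = None
    if gc_correct:
        factor, lam = genomic_control(factor)
    if gc_correct_qb:
        lam_qb = float(np.median(fits["qb"].dropna()) / stats.chi2.ppf(0.5, 1))
        fits["qb"] = fits["qb"] / lam_qb
        fits["p_qb"] = stats.chi2.sf(fits["qb"], 1)

    # per-SNP class labels at the genome-wide threshold
    label = np.where(
        fits["p_qb"] < sig_thresh,
        "heterogeneous",
        np.where(fits["p_cpm"] < sig_thresh, "homogeneous", "unclassified"),
    )
    fits["class"] = label
    return factor, fits, lam


def classify_loci(
    fits: pd.DataFrame,
    factor_loci: LocusSet,
    qb_loci: LocusSet,
    pad_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Label factor loci heterogeneous when they fall within ``pad_bp`` of
    a heterogeneity (Q_b) locus, homogeneous (putatively pleiotropic)
    otherwise."""
    from .sumstats import pad_and_intersect

    pairs = pad_and_intersect(factor_loci, qb_loci, pad_bp)
    het = {i for i, _ in pairs}
    out = factor_loci.df.copy()
    out["class"] = [
        "heterogeneous" if i in het else "homogeneous" for i in range(len(out))
    ]
    return out
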