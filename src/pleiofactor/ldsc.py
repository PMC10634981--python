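"""LD score regression engine.

Implements the regression of per-SNP association chi-square (or cross-trait
z-score products) on LD scores:

    E[chi2_j]    = 1 + N*a + (N*h2/M) * l_j
    E[z1j * z2j] = rho_int + (sqrt(N1*N2) * S12 / M) * l_j

giving SNP-heritability, genetic covariance/correlation, and intercepts
that absorb confounding and sample-overlap terms. Standard errors and full
coefficient sampling covariances come from a delete-one block jackknife
over contiguous SNP blocks (200 by default). A stratified extension
partitions heritability over binary annotations and reports enrichment.

Numerical conventions: weights are 1/(l_j * (1 + N*h2*l_j/M)^2) with h2
iterated from an unweighted first pass; M is the number of regression SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import CHI2_MEDIAN_1DF, SummaryStats
from .corr import fdr_adjust


@dataclass
class H2Estimate:
    h2_obs: float
    se_obs: float
    intercept: float
    se_intercept: float
    n_snps: int
    lambda_gc: float
    h2_liab: float | None = None
    se_liab: float | None = None
    mean_n: float = np.nan
    # delete-block estimates of (intercept, h2), kept for shared jackknives
    delete_values: np.ndarray | None = field(default=None, repr=False)


@dataclass
class GenCovEstimate:
    """2x2 genetic covariance S, sampling covariance V of (S11,S12,S22),
    2x2 intercept matrix (cross-trait intercept off-diagonal), and r_g."""

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    rg: float
    se_rg: float
    p_rg: float
    n_snps: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if abs(self.rg) > 1.05:
            self.flagged = True

    def standardized(self) -> "GenCovEstimate":
        """Rescale S to unit diagonal (correlation scale), propagating V by
        the delta method with the diagonal held fixed."""
        d = np.sqrt(np.diag(self.S))
        D = np.outer(d, d)
        S_std = self.S / D
        # jacobian of (s11,s12,s22)->(1, s12/sqrt(s11*s22), 1)
        s11, s12, s22 = self.S[0, 0], self.S[0, 1], self.S[1, 1]
        J = np.array(
            [
                [0.0, 0.0, 0.0],
                [-0.5 * s12 / (s11 * np.sqrt(s11 * s22)),
                 1.0 / np.sqrt(s11 * s22),
                 -0.5 * s12 / (s22 * np.sqrt(s11 * s22))],
                [0.0, 0.0, 0.0],
            ]
        )
        V_std = J @ self.V @ J.T
        return GenCovEstimate(
            S=S_std, V=V_std, intercepts=self.intercepts, rg=self.rg,
            se_rg=self.se_rg, p_rg=self.p_rg, n_snps=self.n_snps,
        )


@dataclass
class PartitionedResult:
    """Per-annotation stratified-heritability results."""

    table: pd.DataFrame  # annotation, tau, se_tau, prop_snps, prop_h2,
    #                      enrichment, se_enrichment, p_enrichment, q_fdr
    h2_total: float
    intercept: float


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def compute_ld_scores(panel, annotations: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP LD scores l_j = sum_k r^2_jk within each block; with an
    M x C annotation indicator matrix, also annotation-specific scores
    l(j,c) = sum_{k in c} r^2_jk."""
    out = {"snp": panel.snp_ids, "l2": panel.ld_scores}
    if annotations is not None:
        annotations = np.asarray(annotations)
        if annotations.ndim == 1:
            annotations = annotations[:, None]
        cols = []
        for b, sl in zip(panel.blocks, panel.block_slices()):
            r2 = b.corr ** 2
            cols.append(r2 @ annotations[sl])
        part = np.vstack(cols)
        for c in range(part.shape[1]):
            out[f"l2_anno{c}"] = part[:, c]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Core weighted jackknife regression
# ---------------------------------------------------------------------------

def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    if n_blocks > n:
        raise ValueError("fewer SNPs than jackknife blocks")
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _jackknife_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """WLS fit with delete-one-block jackknife.

    Returns (theta, cov_theta, delete_values) where delete_values is
    (n_blocks, p) of delete-block estimates.
    """
    n, p = X.shape
    bounds = _block_bounds(n, n_blocks)
    Xw = X * w[:, None]
    XtX = Xw.T @ X
    Xty = Xw.T @ y
    theta = np.linalg.solve(XtX, Xty)
    delete = np.empty((n_blocks, p))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        XtX_b = Xw[sl].T @ X[sl]
        Xty_b = Xw[sl].T @ y[sl]
        delete[b] = np.linalg.solve(XtX - XtX_b, Xty - Xty_b)
    pseudo = n_blocks * theta - (n_blocks - 1) * delete
    cov = np.atleast_2d(np.cov(pseudo, rowvar=False)) / n_blocks
    return theta, cov, delete


def _ldsc_weights(l2: np.ndarray, n: float, h2: float, m: int) -> np.ndarray:
    l2c = np.maximum(l2, 1.0)
    return 1.0 / (l2c * (1.0 + n * max(h2, 0.0) * l2c / m) ** 2)


def _align(s: SummaryStats, ld: pd.DataFrame) -> pd.DataFrame:
    merged = s.df.merge(ld, on="snp", how="inner")
    if len(merged) == 0:
        raise ValueError("no overlap between summary statistics and LD scores")
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Univariate heritability
# ---------------------------------------------------------------------------

def fit_h2(
    s: SummaryStats,
    ld: pd.DataFrame,
    n_blocks_jk: int = 200,
    K: float | None = None,
    P: float | None = None,
) -> H2Estimate:
    """Univariate LDSC: regress chi2 on LD scores.

    The slope estimates N*h2/M, the intercept 1 plus any confounding
    inflation. Jackknife SEs over ``n_blocks_jk`` contiguous SNP blocks.
    With population (K) and sample (P) prevalences the observed-scale
    estimate is also converted to the liability scale.
    """
    if len(s) < 200:
        raise ValueError("need at least 200 SNPs for LDSC")
    d = _align(s, ld)
    l2 = d["l2"].to_numpy(float)
    chi2 = d["z"].to_numpy(float) ** 2
    N = float(d["n"].median())
    M = len(d)

    X = np.column_stack([np.ones(M), N * l2 / M])
    # unweighted pass, then two weighted passes
    h2 = float(np.linalg.lstsq(X, chi2, rcond=None)[0][1])
    for _ in range(2):
        w = _ldsc_weights(l2, N, h2, M)
        theta, cov, delete = _jackknife_wls(X, chi2, w, n_blocks_jk)
        h2 = float(theta[1])

    est = H2Estimate(
        h2_obs=h2,
        se_obs=float(np.sqrt(cov[1, 1])),
        intercept=float(theta[0]),
        se_intercept=float(np.sqrt(cov[0, 0])),
        n_snps=M,
        lambda_gc=float(np.median(chi2) / CHI2_MEDIAN_1DF),
        mean_n=N,
        delete_values=delete,
    )
    if K is not None and P is not None:
        mult = liability_multiplier(K, P)
        est.h2_liab = h2 * mult
        est.se_liab = est.se_obs * mult
    return est


def liability_multiplier(K: float, P: float) -> float:
    """Observed-to-liability scale conversion factor
    K^2 (1-K)^2 / (P(1-P) z^2), z the normal density at the K threshold."""
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("prevalences must be in (0,1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return K ** 2 * (1 - K) ** 2 / (P * (1 - P) * z ** 2)


def obs_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale case-control h2 to the liability scale."""
    return h2_obs * liability_multiplier(K, P)


# ---------------------------------------------------------------------------
# Bivariate: genetic covariance / correlation
# ---------------------------------------------------------------------------

def multivariable_ldsc(
    a: SummaryStats,
    b: SummaryStats,
    ld: pd.DataFrame,
    n_blocks_jk: int = 200,
) -> GenCovEstimate:
    """Multivariable LDSC: the 2x2 genetic covariance matrix S, its 3x3
    sampling covariance V for (S11, S12, S22) from a shared delete-block
    jackknife, and the 2x2 intercept matrix (cross-trait intercept
    off-diagonal)."""
    da = _align(a, ld)
    db = _align(b, ld)
    merged = da.merge(db, on="snp", suffixes=("_1", "_2"))
    if len(merged) < 200:
        raise ValueError("need at least 200 shared SNPs")
    merged = merged.sort_values(["chrom_1", "pos_1"]).reset_index(drop=True)
    l2 = merged["l2_1"].to_numpy(float)
    z1 = merged["z_1"].to_numpy(float)
    z2 = merged["z_2"].to_numpy(float)
    n1 = float(merged["n_1"].median())
    n2 = float(merged["n_2"].median())
    M = len(merged)

    l2c = np.maximum(l2, 1.0)

    def fit_uni(y, n):
        """Two weight iterations from an unweighted pass; returns the fit
        and the h2 that generated the final weights (needed so the cross
        fit with a == b uses identical weights)."""
        X = np.column_stack([np.ones(M), n * l2 / M])
        est = float(np.linalg.lstsq(X, y, rcond=None)[0][1])
        for _ in range(2):
            w_h2 = est
            w = _ldsc_weights(l2, n, w_h2, M)
            theta, cov, delete = _jackknife_wls(X, y, w, n_blocks_jk)
            est = float(theta[1])
        return theta, cov, delete, w_h2

    th1, cov1, del1, wh1 = fit_uni(z1 ** 2, n1)
    th2, cov2, del2, wh2 = fit_uni(z2 ** 2, n2)
    h2_1, h2_2 = float(th1[1]), float(th2[1])

    Xc = np.column_stack([np.ones(M), np.sqrt(n1 * n2) * l2 / M])
    w_cross = 1.0 / (
        l2c
        * (1.0 + n1 * max(wh1, 0.0) * l2c / M)
        * (1.0 + n2 * max(wh2, 0.0) * l2c / M)
    )
    th12, cov12, del12 = _jackknife_wls(Xc, z1 * z2, w_cross, n_blocks_jk)
    s12 = float(th12[1])

    S = np.array([[h2_1, s12], [s12, h2_2]])
    intercepts = np.array([[float(th1[0]), float(th12[0])],
                           [float(th12[0]), float(th2[0])]])

    # shared-block jackknife for V and r_g
    nb_ = del1.shape[0]
    trip_del = np.column_stack([del1[:, 1], del12[:, 1], del2[:, 1]])
    trip_full = np.array([h2_1, s12, h2_2])
    pseudo = nb_ * trip_full - (nb_ - 1) * trip_del
    V = np.cov(pseudo, rowvar=False) / nb_

    flagged = h2_1 <= 0 or h2_2 <= 0
    if flagged:
        rg, se_rg, p_rg = np.nan, np.nan, np.nan
    else:
        rg = s12 / np.sqrt(h2_1 * h2_2)
        with np.errstate(invalid="ignore"):
            rg_del = trip_del[:, 1] / np.sqrt(
                np.maximum(trip_del[:, 0], 1e-12) * np.maximum(trip_del[:, 2], 1e-12)
            )
        rg_pseudo = nb_ * rg - (nb_ - 1) * rg_del
        se_rg = float(np.sqrt(np.var(rg_pseudo, ddof=1) / nb_))
        p_rg = float(2.0 * stats.norm.sf(abs(rg) / se_rg)) if se_rg > 0 else np.nan

    est = GenCovEstimate(
        S=S, V=V, intercepts=intercepts, rg=float(rg), se_rg=float(se_rg),
        p_rg=p_rg, n_snps=M,
    )
    est.flagged = est.flagged or flagged
    return est


def fit_rg(
    a: SummaryStats, b: SummaryStats, ld: pd.DataFrame, n_blocks_jk: int = 200
) -> GenCovEstimate:
    """Bivariate LDSC genetic correlation (wrapper over the multivariable
    fit; the intercept of the cross regression absorbs sample overlap)."""
    return multivariable_ldsc(a, b, ld, n_blocks_jk=n_blocks_jk)


# ---------------------------------------------------------------------------
# Stratified (partitioned) heritability
# ---------------------------------------------------------------------------

def stratified_h2(
    s: SummaryStats,
    ld_by_annotation: pd.DataFrame,
    annotations: np.ndarray,
    annotation_names: list[str] | None = None,
    n_blocks_jk: int = 200,
    fdr_m: int | None = None,
) -> PartitionedResult:
    """Stratified LDSC: joint regression of chi2 on annotation-specific LD
    scores; per-annotation coefficients tau_c, heritability shares and
    enrichment = prop_h2 / prop_snps with jackknife SEs and BH-FDR.

    ``annotations`` is an M x C indicator matrix whose first column must be
    the base (all-SNPs) annotation; ``ld_by_annotation`` is the matching
    output of :func:`compute_ld_scores`.
    """
    annotations = np.asarray(annotations)
    if annotations.ndim == 1:
        annotations = annotations[:, None]
    C = annotations.shape[1]
    if not np.all(annotations[:, 0] == 1):
        raise ValueError("first annotation must be the base (all SNPs)")
    names = annotation_names or [f"anno{c}" for c in range(C)]
    if names[0] not in ("base",) and annotation_names is None:
        names[0] = "base"

    d = _align(s, ld_by_annotation)
    order = s.df.merge(
        pd.DataFrame({"snp": ld_by_annotation["snp"], "_i": np.arange(len(ld_by_annotation))}),
        on="snp",
    ).sort_values(["chrom", "pos"])["_i"].to_numpy()
    A = annotations[order]
    Lc = d[[f"l2_anno{c}" for c in range(C)]].to_numpy(float)
    chi2 = d["z"].to_numpy(float) ** 2
    N = float(d["n"].median())
    M = len(d)

    # fit only a non-collinear subset of columns (base always kept);
    # heritability shares are still reported for every annotation, from
    # the per-SNP h2 implied by the fitted coefficients
    keep = [0]
    for c in range(1, C):
        cand = Lc[:, keep + [c]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(c)
    dropped = [names[c] for c in range(C) if c not in keep]
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "stratified_h2: collinear annotations not fitted directly: %s",
            dropped,
        )
    A_fit = A[:, keep]
    Lc_fit = Lc[:, keep]
    Ck = len(keep)

    l2_base = Lc[:, 0]
    X = np.column_stack([np.ones(M), N * Lc_fit])
    h2_rough = float(np.linalg.lstsq(X, chi2, rcond=None)[0][1:].sum())
    w = _ldsc_weights(l2_base, N, h2_rough, M)
    theta, cov, delete = _jackknife_wls(X, chi2, w, n_blocks_jk)

    def summarize(tau_fit):
        per_snp_h2 = A_fit @ tau_fit
        h2_tot = per_snp_h2.sum()
        prop_h2 = np.array(
            [per_snp_h2[A[:, c] == 1].sum() for c in range(C)]
        ) / h2_tot
        return h2_tot, prop_h2

    tau_fit = theta[1:]
    h2_tot, prop_h2 = summarize(tau_fit)
    prop_snps = A.mean(axis=0)
    enrich = prop_h2 / prop_snps

    nb_ = delete.shape[0]
    enrich_del = np.empty((nb_, C))
    for bk in range(nb_):
        _, ph = summarize(delete[bk, 1:])
        enrich_del[bk] = ph / prop_snps
    pseudo = nb_ * enrich - (nb_ - 1) * enrich_del
    se_enrich = np.sqrt(np.var(pseudo, axis=0, ddof=1) / nb_)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_enr = (enrich - 1.0) / se_enrich
        p_enrich = 2.0 * stats.norm.sf(np.abs(z_enr))
    p_enrich[0] = np.nan  # base enrichment is 1 by construction

    tau = np.full(C, np.nan)
    se_tau = np.full(C, np.nan)
    tau[keep] = tau_fit
    se_tau[keep] = np.sqrt(np.diag(cov)[1:])
    q = np.full(C, np.nan)
    nonbase = np.arange(1, C)
    if len(nonbase):
        q[nonbase] = fdr_adjust(p_enrich[nonbase], m=fdr_m)

    table = pd.DataFrame(
        {
            "annotation": names,
            "tau": tau,
            "se_tau": se_tau,
            "prop_snps": prop_snps,
            "prop_h2": prop_h2,
            "enrichment": enrich,
            "se_enrichment": se_enrich,
            "p_enrichment": p_enrich,
            "q_fdr": q,
        }
    )
    return PartitionedResult(table=table, h2_total=float(h2_tot), intercept=float(theta[0]))
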