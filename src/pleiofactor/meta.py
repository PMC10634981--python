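"""Cross-method validation statistics for two-trait meta-analysis.

Two independent routes to a combined association signal, both correcting
for correlated estimation error from sample overlap:

* ``shom_test`` — the homogeneous-effect cross-phenotype statistic: a
  correlated fixed-effects combination S_hom = (w'R^-1 z)^2 / (w'R^-1 w),
  chi-square(1) under the joint null, with w = sqrt(N) and R the z-score
  correlation estimated from null SNPs (|z| <= 1.96 in both traits).
* ``ngwama`` — sqrt(h2*N)-weighted z-score meta-analysis whose denominator
  uses the LDSC cross-trait intercept matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import SummaryStats


@dataclass
class NullCorrMatrix:
    R: np.ndarray
    n_null_snps: int

    def __post_init__(self) -> None:
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("null correlation matrix must have unit diagonal")


def estimate_null_correlation(
    a: SummaryStats, b: SummaryStats, z_cut: float = 1.96
) -> NullCorrMatrix:
    """Correlation of the two traits' z-scores over SNPs null in both
    (|z| <= z_cut), capturing overlap-induced dependence."""
    d = a.df.merge(b.df[["snp", "z"]], on="snp", suffixes=("", "_b"))
    mask = (d["z"].abs() <= z_cut) & (d["z_b"].abs() <= z_cut)
    n = int(mask.sum())
    if n < 100:
        raise ValueError(f"only {n} null SNPs (|z|<={z_cut}); need >= 100")
    r = float(np.corrcoef(d.loc[mask, "z"], d.loc[mask, "z_b"])[0, 1])
    return NullCorrMatrix(np.array([[1.0, r], [r, 1.0]]), n)


def shom_test(
    z: np.ndarray, n: np.ndarray, R: NullCorrMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous cross-phenotype test.

    ``z``: (M, 2) matrix of per-SNP z-scores (or a length-2 vector);
    ``n``: per-trait sample sizes (the median N per file, per convention);
    weights w_k = sqrt(n_k). Returns (S_hom, p) with p from chi2(1).
    """
    Rm = R.R if isinstance(R, NullCorrMatrix) else np.asarray(R, float)
    Ri = np.linalg.inv(Rm)
    z = np.atleast_2d(np.asarray(z, float))
    w = np.sqrt(np.asarray(n, float))
    denom = float(w @ Ri @ w)
    if denom <= 0:
        raise ValueError("non-positive weight quadratic form")
    num = (z @ Ri @ w) ** 2
    s = num / denom
    p = stats.chi2.sf(s, 1)
    if s.shape == (1,):
        return float(s[0]), float(p[0])
    return s, p


def ngwama(
    z: np.ndarray,
    n: np.ndarray,
    h2: np.ndarray,
    cti: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """N-weighted GWAMA with cross-trait-intercept correction.

    Per SNP: z_meta = sum_i w_i z_i / sqrt(w' CTI w) with w_i =
    sqrt(h2_i * n_i); CTI is the LDSC cross-trait intercept matrix
    (unit diagonal, symmetric). p two-sided normal.
    """
    cti = np.asarray(cti, float)
    if not np.allclose(cti, cti.T) or not np.allclose(np.diag(cti), 1.0):
        raise ValueError("CTI must be symmetric with unit diagonal")
    z = np.atleast_2d(np.asarray(z, float))
    n = np.asarray(n, float)
    h2 = np.asarray(h2, float)
    w = np.sqrt(h2 * n)
    denom2 = float(w @ cti @ w)
    if denom2 <= 0:
        raise ValueError("w' CTI w must be positive")
    z_meta = (z @ w) / np.sqrt(denom2)
    p = 2.0 * stats.norm.sf(np.abs(z_meta))
    if z_meta.shape == (1,):
        return float(z_meta[0]), float(p[0])
    return z_meta, p
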