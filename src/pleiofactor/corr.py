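"""Correlation utilities: LD-block rank correlation with bootstrap SEs,
Benjamini-Hochberg FDR with a configurable denominator, and genetic-
correlation-based trait clustering with representative selection.

The block Spearman procedure quantifies shared signal between two GWASs
from unsigned statistics alone: average -log10(p) per approximately
independent LD block, rank-correlate the block means, and bootstrap the
blocks (jointly, as pairs) for a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sumstats import LocusSet, SummaryStats


@dataclass
class BlockCorrResult:
    rho_spearman: float
    se_bootstrap: float
    n_blocks: int
    n_boot: int


@dataclass
class TraitClusterResult:
    traits: list
    distance: np.ndarray
    linkage_tree: np.ndarray | None
    k: int
    labels: dict
    representatives: list
    reduced_traits: list


def block_average_logp(s: SummaryStats, blocks: LocusSet) -> pd.DataFrame:
    """Mean -log10(p) over SNPs within each block; empty blocks dropped.

    Returns a frame (block index, chrom, start, end, mean_logp, n_snps).
    """
    rows = []
    df = s.df
    n_outside = len(df)
    for i, r in blocks.df.iterrows():
        mask = (
            (df["chrom"] == r["chrom"])
            & (df["pos"] >= r["start"])
            & (df["pos"] <= r["end"])
        )
        n_in = int(mask.sum())
        n_outside -= n_in
        if n_in == 0:
            continue
        rows.append(
            dict(
                block=int(i),
                chrom=int(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                mean_logp=float(-np.log10(df.loc[mask, "pval"]).mean()),
                n_snps=n_in,
            )
        )
    if not rows:
        raise ValueError("no block contains any SNP")
    return pd.DataFrame(rows)


def spearman_bootstrap(
    x: np.ndarray, y: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> BlockCorrResult:
    """Spearman correlation of paired block means, SE from resampling the
    blocks with replacement (pairs resampled jointly)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    if len(x) < 10:
        raise ValueError("need at least 10 blocks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(xb, yb).statistic
    se = float(np.nanstd(boots, ddof=1))
    return BlockCorrResult(rho, se, n, n_boot)


def fdr_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with denominator ``m``
    (defaults to len(p); a larger m supports correcting a subset of a
    bigger family of tests)."""
    p = np.asarray(p, float)
    n = len(p)
    if n == 0:
        return p.copy()
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= len(p)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _within_cluster_ss(points: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        ss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return ss


def cluster_and_represent(
    rg_matrix: pd.DataFrame, high_thresh: float = 0.80, k: int | None = None
) -> TraitClusterResult:
    """Reduce a set of traits to genetically independent representatives.

    Traits with any |r_g| > ``high_thresh`` to another trait are clustered:
    Ward linkage on distance d = 1 - r_g, number of clusters chosen by the
    elbow rule (maximal second difference of the within-cluster sum of
    squares over k) unless ``k`` is given, and each cluster contributes the
    trait most correlated (in absolute value) with the cluster's first
    principal component. Representatives plus never-clustered traits form
    the reduced trait set.
    """
    traits = list(rg_matrix.index)
    R = rg_matrix.to_numpy(float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("rg matrix must be square symmetric")

    off = R - np.eye(len(R))
    hot = np.abs(off).max(axis=1) > high_thresh
    clustered = [t for t, h in zip(traits, hot) if h]
    passthrough = [t for t, h in zip(traits, hot) if not h]

    if len(clustered) < 2:
        return TraitClusterResult(
            traits=traits, distance=1.0 - R, linkage_tree=None, k=min(1, len(clustered)),
            labels={t: 1 for t in clustered}, representatives=list(clustered),
            reduced_traits=sorted(clustered + passthrough, key=traits.index),
        )

    sub_idx = [traits.index(t) for t in clustered]
    C = R[np.ix_(sub_idx, sub_idx)]
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")

    n = len(clustered)
    if k is None:
        kmax = min(n - 1, 10)
        wcss = {}
        for kk in range(1, kmax + 2):
            labels = fcluster(Z, t=min(kk, n), criterion="maxclust")
            wcss[kk] = _within_cluster_ss(C, labels)
        candidates = range(2, kmax + 1)
        k = max(
            candidates,
            key=lambda kk: wcss[kk - 1] - 2 * wcss[kk] + wcss[kk + 1],
            default=2,
        )
    labels = fcluster(Z, t=k, criterion="maxclust")

    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = C[np.ix_(members, members)]
        if len(members) == 1:
            reps.append(clustered[members[0]])
            continue
        vals, vecs = np.linalg.eigh(sub)
        pc = sub @ vecs[:, -1]  # first-PC scores of cluster members
        best, best_corr = None, -np.inf
        for i, mi in enumerate(members):
            if np.ptp(sub[i]) == 0 or np.ptp(pc) == 0:
                corr = 0.0
            else:
                with np.errstate(invalid="ignore"):
                    corr = abs(float(np.corrcoef(sub[i], pc)[0, 1]))
                if np.isnan(corr):
                    corr = 0.0
            name = clustered[mi]
            if corr > best_corr or (corr == best_corr and name < best):
                best, best_corr = name, corr
        reps.append(best)

    reduced = sorted(set(passthrough) | set(reps), key=traits.index)
    return TraitClusterResult(
        traits=traits, distance=1.0 - R, linkage_tree=Z, k=int(k),
        labels={clustered[i]: int(labels[i]) for i in range(n)},
        representatives=reps, reduced_traits=reduced,
    )
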