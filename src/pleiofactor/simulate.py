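"""Synthetic two-trait GWAS study generator.

Builds the full testbed for the pipeline without any external downloads:
an AR(1) block-LD reference panel, per-SNP true effects following a
common-factor architecture (a shared genetic factor plus trait-specific
components, with optional MAF-dependent effect-size scaling), a pair of
overlapping case-control summary-statistic sets consistent with the LD
score regression equations, plus synthetic functional annotations and
expression-weight tables.

Generative model
----------------
For causal SNP j (causal with probability ``pi_causal``), standardized
per-SNP effects are

    f_j   ~ N(0, var_factor  * c_j)          (shared factor component)
    u_ij  ~ N(0, var_unique_i * c_j)         (trait-specific component)
    beta_1j = f_j + u_1j
    beta_2j = factor_sign_2 * f_j + u_2j

with c_j proportional to [2 p_j (1-p_j)]^S_sel, normalized so that the
expected heritabilities are var_factor + var_unique_i. Marginal effects are
b = R beta per LD block, and z-scores are z_i = sqrt(N_i) b_i + eps with
block-correlated noise; sample overlap induces Cov(eps_1j, eps_2j) =
rho_ov R with rho_ov = pheno_corr_overlap * n_overlap / sqrt(N1 N2) —
exactly the cross-trait LDSC intercept term.

Binary traits are simulated directly on the observed (0/1-regression)
scale; prevalences feed the liability conversion and effective-N
bookkeeping downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats, effective_n, two_sided_p


@dataclass
class Block:
    """One LD block: contiguous SNPs with an AR(1)-like correlation matrix."""

    chrom: int
    start_bp: int
    end_bp: int
    snp_ids: np.ndarray
    maf: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.corr.shape != (m, m):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix diagonal != 1")

    @property
    def ld_scores(self) -> np.ndarray:
        return (self.corr ** 2).sum(axis=1)


@dataclass
class LDPanel:
    """Block-diagonal LD reference: correlation structure + MAF per SNP."""

    blocks: list[Block]

    def __len__(self) -> int:
        return sum(len(b.snp_ids) for b in self.blocks)

    @property
    def snp_ids(self) -> np.ndarray:
        return np.concatenate([b.snp_ids for b in self.blocks])

    @property
    def maf(self) -> np.ndarray:
        return np.concatenate([b.maf for b in self.blocks])

    @property
    def sigma2_snp(self) -> np.ndarray:
        """Per-SNP genotype variance 2p(1-p)."""
        maf = self.maf
        return 2.0 * maf * (1.0 - maf)

    @property
    def ld_scores(self) -> np.ndarray:
        return np.concatenate([b.ld_scores for b in self.blocks])

    def snp_location(self) -> dict:
        """snp_id -> (block index, within-block index)."""
        out = {}
        for bi, b in enumerate(self.blocks):
            for j, sid in enumerate(b.snp_ids):
                out[sid] = (bi, j)
        return out

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + len(b.snp_ids)))
            start += len(b.snp_ids)
        return out

    # -- plain-text serialization ---------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        index = []
        for i, b in enumerate(self.blocks):
            pd.DataFrame(
                {"snp": b.snp_ids, "maf": b.maf}
            ).to_csv(path / f"block{i:04d}.snps.tsv", sep="\t", index=False)
            np.savetxt(path / f"block{i:04d}.corr.tsv", b.corr, delimiter="\t")
            index.append(
                dict(block=i, chrom=b.chrom, start_bp=b.start_bp, end_bp=b.end_bp,
                     n_snps=len(b.snp_ids))
            )
        pd.DataFrame(index).to_csv(path / "index.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "LDPanel":
        path = Path(path)
        index = pd.read_csv(path / "index.tsv", sep="\t")
        blocks = []
        for _, row in index.iterrows():
            i = int(row["block"])
            snps = pd.read_csv(path / f"block{i:04d}.snps.tsv", sep="\t")
            corr = np.loadtxt(path / f"block{i:04d}.corr.tsv", delimiter="\t", ndmin=2)
            blocks.append(
                Block(int(row["chrom"]), int(row["start_bp"]), int(row["end_bp"]),
                      snps["snp"].to_numpy(), snps["maf"].to_numpy(float), corr)
            )
        return cls(blocks)


@dataclass
class SimConfig:
    """Full generative parameterization of the synthetic two-trait study.

    Defaults emulate the rhythm-impairment/dyslexia setting at desk scale:
    M = n_blocks*snps_per_block = 20,000 SNPs; sample sizes, prevalences,
    overlap and its phenotypic correlation follow the source cohorts
    (606,825 / 1,138,870 participants, sample prevalences 0.085 / 0.045,
    population prevalences 0.048 / 0.050, ~363k shared participants with
    phenotypic correlation 0.04 after impairment alignment); heritabilities
    0.15 per trait with genetic correlation 0.28 via the shared factor, and
    MAF-effect coupling S = -0.5 (moderate negative selection).
    """

    n_blocks: int = 400
    snps_per_block: int = 50
    rho_ld: float | tuple = (0.0, 0.9)
    maf_range: tuple = (0.05, 0.5)
    pi_causal: float = 0.05
    var_factor: float = 0.042
    var_unique_1: float = 0.108
    var_unique_2: float = 0.108
    factor_sign_2: int = 1
    s_sel: float = -0.5
    n1: int = 606_825
    n2: int = 1_138_870
    n_overlap: int = 363_287
    pheno_corr_overlap: float = 0.04
    k1: float = 0.048
    k2: float = 0.050
    p1: float = 0.085
    p2: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rho_bounds
        if not (0 <= lo <= hi < 1):
            raise ValueError("rho_ld must be in [0,1)")
        if min(self.var_factor, self.var_unique_1, self.var_unique_2) < 0:
            raise ValueError("variance components must be >= 0")
        for h2 in (self.h2_1, self.h2_2):
            if h2 > 1:
                raise ValueError("implied heritability exceeds 1")
        if not 0 <= self.n_overlap <= min(self.n1, self.n2):
            raise ValueError("n_overlap out of range")
        for prev in (self.k1, self.k2, self.p1, self.p2):
            if not 0 < prev < 1:
                raise ValueError("prevalences must be in (0,1)")
        if self.factor_sign_2 not in (1, -1):
            raise ValueError("factor_sign_2 must be +1 or -1")
        if self.s_sel > 0:
            raise ValueError("s_sel must be <= 0")

    @property
    def rho_bounds(self) -> tuple:
        if np.isscalar(self.rho_ld):
            return (float(self.rho_ld), float(self.rho_ld))
        lo, hi = self.rho_ld
        return (float(lo), float(hi))

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def h2_1(self) -> float:
        return self.var_factor + self.var_unique_1

    @property
    def h2_2(self) -> float:
        return self.var_factor + self.var_unique_2

    @property
    def rg_true(self) -> float:
        denom = np.sqrt(self.h2_1 * self.h2_2)
        return float(self.factor_sign_2 * self.var_factor / denom) if denom else 0.0

    @property
    def rho_overlap(self) -> float:
        """Expected cross-trait LDSC intercept from sample overlap."""
        return self.pheno_corr_overlap * self.n_overlap / np.sqrt(self.n1 * self.n2)


@dataclass
class TruthRecord:
    """Ground-truth effects and realized architecture of one simulation."""

    f: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    causal: np.ndarray
    beta1: np.ndarray = field(init=False)
    beta2: np.ndarray = field(init=False)
    factor_sign_2: int = 1

    def __post_init__(self) -> None:
        self.beta1 = self.f + self.u1
        self.beta2 = self.factor_sign_2 * self.f + self.u2

    @property
    def h2_1(self) -> float:
        return float((self.beta1 ** 2).sum())

    @property
    def h2_2(self) -> float:
        return float((self.beta2 ** 2).sum())

    @property
    def gencov(self) -> float:
        return float((self.beta1 * self.beta2).sum())

    @property
    def rg(self) -> float:
        d = np.sqrt(self.h2_1 * self.h2_2)
        return self.gencov / d if d > 0 else np.nan


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_ld_panel(cfg: SimConfig) -> LDPanel:
    """AR(1) block LD panel: r_jk = rho_b^|j-k| within block b.

    When ``cfg.rho_ld`` is a scalar every block uses that coefficient
    (closed-form LD scores); when it is a (lo, hi) pair — the default —
    each block's coefficient is drawn uniformly from the range, so LD
    scores vary across the genome the way the LD score regression needs
    them to. Blocks are laid out round-robin over chromosomes 1-22, 2 Mb
    apart, SNPs 5 kb apart, so distance-based locus logic behaves
    sensibly. MAF is uniform on ``maf_range``. Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.snps_per_block
    idx = np.arange(m)
    lo, hi = cfg.rho_bounds
    blocks = []
    per_chrom_count = {}
    for b in range(cfg.n_blocks):
        chrom = (b % 22) + 1
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        pos0 = 1_000_000 + k * 2_000_000
        rho = lo if lo == hi else rng.uniform(lo, hi)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
        snp_ids = np.array([f"rs{b * m + j + 1}" for j in range(m)])
        maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
        blocks.append(
            Block(chrom, pos0, pos0 + (m - 1) * 5_000, snp_ids, maf, corr)
        )
    return LDPanel(blocks)


def panel_positions(panel: LDPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (chrom, bp) arrays implied by the block layout."""
    chroms, pos = [], []
    for b in panel.blocks:
        m = len(b.snp_ids)
        chroms.append(np.full(m, b.chrom))
        pos.append(b.start_bp + 5_000 * np.arange(m))
    return np.concatenate(chroms), np.concatenate(pos)


def simulate_genetic_effects(cfg: SimConfig, panel: LDPanel) -> TruthRecord:
    """Draw per-SNP true effects under the common-factor architecture."""
    rng = np.random.default_rng(cfg.seed + 1)
    M = len(panel)
    causal = rng.random(M) < cfg.pi_causal
    if causal.sum() == 0:
        causal[rng.integers(0, M)] = True
    sigma2 = panel.sigma2_snp
    w = np.where(causal, sigma2 ** cfg.s_sel, 0.0)
    c = w / w.sum()  # sums to 1 over causal SNPs -> E[h2_i] = var_factor+var_unique_i
    f = rng.normal(0.0, 1.0, M) * np.sqrt(cfg.var_factor * c)
    u1 = rng.normal(0.0, 1.0, M) * np.sqrt(cfg.var_unique_1 * c)
    u2 = rng.normal(0.0, 1.0, M) * np.sqrt(cfg.var_unique_2 * c)
    return TruthRecord(f, u1, u2, causal, factor_sign_2=cfg.factor_sign_2)


def simulate_sumstats_pair(
    cfg: SimConfig, panel: LDPanel, truth: TruthRecord
) -> tuple[SummaryStats, SummaryStats]:
    """Generate the two traits' summary statistics.

    Per block, marginal standardized effects are b_i = R beta_i and
    z_i = sqrt(N_i) b_i + eps_i with eps ~ N(0, R) and cross-trait noise
    correlation rho_ov = pheno_corr_overlap * n_overlap / sqrt(N1 N2).
    Per-allele beta/SE are back-computed from z and 2p(1-p).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rho = cfg.rho_overlap
    z1, z2 = [], []
    for b, sl in zip(panel.blocks, panel.block_slices()):
        R = b.corr
        L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
        m1 = R @ truth.beta1[sl]
        m2 = R @ truth.beta2[sl]
        a = rng.standard_normal(len(R))
        bnoise = rng.standard_normal(len(R))
        e1 = L @ a
        e2 = L @ (rho * a + np.sqrt(max(0.0, 1.0 - rho ** 2)) * bnoise)
        z1.append(np.sqrt(cfg.n1) * m1 + e1)
        z2.append(np.sqrt(cfg.n2) * m2 + e2)
    z1 = np.concatenate(z1)
    z2 = np.concatenate(z2)

    chroms, pos = panel_positions(panel)
    out = []
    for zi, n, psamp, trait in (
        (z1, cfg.n1, cfg.p1, "trait1"),
        (z2, cfg.n2, cfg.p2, "trait2"),
    ):
        se = 1.0 / np.sqrt(n * panel.sigma2_snp)
        beta = zi * se
        n_cases = int(round(psamp * n))
        df = pd.DataFrame(
            {
                "snp": panel.snp_ids,
                "chrom": chroms,
                "pos": pos,
                "a1": "A",
                "a2": "G",
                "eaf": panel.maf,
                "beta": beta,
                "se": se,
                "z": zi,
                "pval": two_sided_p(zi),
                "n": n,
                "n_cases": n_cases,
                "n_eff": effective_n(n_cases, n),
            }
        )
        out.append(SummaryStats(df, trait=trait))
    return out[0], out[1]


def simulate_study(cfg: SimConfig):
    """Convenience wrapper: panel, truth and the summary-statistics pair."""
    panel = simulate_ld_panel(cfg)
    truth = simulate_genetic_effects(cfg, panel)
    s1, s2 = simulate_sumstats_pair(cfg, panel, truth)
    return panel, truth, s1, s2


def simulate_annotation(
    panel: LDPanel,
    truth: TruthRecord,
    frac_genome: float,
    frac_causal_captured: float,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Binary annotation covering ``frac_genome`` of SNPs and
    ``frac_causal_captured`` of causal SNPs.

    Returns the indicator vector and an info dict with the analytically
    expected enrichment = (captured h2 share)/(SNP share), per trait.
    """
    if not (0 <= frac_genome <= 1 and 0 <= frac_causal_captured <= 1):
        raise ValueError("fractions must be in [0,1]")
    rng = np.random.default_rng(seed)
    M = len(panel)
    causal_idx = np.flatnonzero(truth.causal)
    noncausal_idx = np.flatnonzero(~truth.causal)
    n_target = int(round(frac_genome * M))
    n_causal_in = int(round(frac_causal_captured * len(causal_idx)))
    if n_causal_in > n_target:
        raise ValueError("cannot capture that many causal SNPs at this genome fraction")
    if n_target - n_causal_in > len(noncausal_idx):
        raise ValueError("not enough non-causal SNPs to fill the annotation")
    chosen_causal = rng.choice(causal_idx, size=n_causal_in, replace=False)
    chosen_null = rng.choice(noncausal_idx, size=n_target - n_causal_in, replace=False)
    anno = np.zeros(M, dtype=int)
    anno[chosen_causal] = 1
    anno[chosen_null] = 1
    prop_snps = anno.mean()
    info = {}
    for name, beta in (("trait1", truth.beta1), ("trait2", truth.beta2)):
        h2_tot = (beta ** 2).sum()
        frac_h2 = (beta[anno == 1] ** 2).sum() / h2_tot if h2_tot > 0 else np.nan
        info[f"expected_enrichment_{name}"] = (
            frac_h2 / prop_snps if prop_snps > 0 else np.nan
        )
    info["prop_snps"] = float(prop_snps)
    return anno, info


def simulate_expression_weights(
    panel: LDPanel, n_genes: int, snps_per_gene: int, seed: int = 0
) -> pd.DataFrame:
    """Sparse per-gene expression weights, each gene within a single LD
    block so predicted-expression variance w'Rw is computable and > 0.

    Returns the weight table in the TWAS dialect
    (GENE, TISSUE, SNP, A1, WEIGHT).
    """
    if snps_per_gene > min(len(b.snp_ids) for b in panel.blocks):
        raise ValueError("snps_per_gene exceeds block size")
    rng = np.random.default_rng(seed)
    rows = []
    block_ids = rng.choice(len(panel.blocks), size=n_genes, replace=n_genes > len(panel.blocks))
    for gi, bi in enumerate(block_ids):
        b = panel.blocks[bi]
        start = rng.integers(0, len(b.snp_ids) - snps_per_gene + 1)
        w = rng.normal(0.0, 1.0, snps_per_gene)
        while np.allclose(w, 0):  # all-zero weights rejected
            w = rng.normal(0.0, 1.0, snps_per_gene)
        for k in range(snps_per_gene):
            rows.append(
                dict(
                    GENE=f"GENE{gi + 1:04d}",
                    TISSUE="synthetic_tissue",
                    SNP=b.snp_ids[start + k],
                    A1="A",
                    WEIGHT=w[k],
                )
            )
    return pd.DataFrame(rows)
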