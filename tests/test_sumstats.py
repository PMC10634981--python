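"""Summary-statistics container, harmonisation, GC, loci and conversions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pleiofactor as pf
from pleiofactor.simulate import Block, LDPanel
from pleiofactor.sumstats import SumstatsError

from conftest import make_sumstats


class TestReadWrite:
    def test_roundtrip_and_z_derivation(self, tmp_path):
        path = tmp_path / "ss.tsv"
        df = pd.DataFrame(
            {
                "SNP": ["rs1", "rs2"],
                "CHR": [1, 1],
                "BP": [1000, 2000],
                "A1": ["A", "C"],
                "A2": ["G", "T"],
                "EAF": [0.3, 0.5],
                "BETA": [0.05, -0.01],
                "SE": [0.02, 0.02],
            }
        )
        df.to_csv(path, sep="\t", index=False)
        ss = pf.read_sumstats(path)
        assert ss.df.loc[0, "z"] == pytest.approx(2.5)  # beta/se
        assert ss.df.loc[0, "pval"] == pytest.approx(2 * stats.norm.sf(2.5))
        out = tmp_path / "out.tsv"
        pf.write_sumstats(ss, out)
        back = pf.read_sumstats(out)
        pd.testing.assert_frame_equal(back.df, ss.df, check_dtype=False)

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"SNP": ["rs1"], "CHR": [1], "BP": [1], "A1": ["A"],
                      "A2": ["G"], "EAF": [0.2], "BETA": [0.1]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="se"):
            pf.read_sumstats(path)

    def test_duplicate_snp_id_named_in_error(self):
        df = make_sumstats(4).df
        df.loc[3, "snp"] = "rs1"
        with pytest.raises(SumstatsError, match="rs1"):
            pf.SummaryStats(df)


class TestHarmonize:
    def test_swapped_alleles_flip_effects_and_eaf(self):
        a = make_sumstats(4, seed=1)
        bdf = a.df.copy()
        bdf.loc[0, ["a1", "a2"]] = ["G", "A"]
        beta0, eaf0 = bdf.loc[0, "beta"], bdf.loc[0, "eaf"]
        b = pf.SummaryStats(bdf)
        _, b2, rep = pf.harmonize_pair(a, b)
        assert rep.n_flipped == 1
        row = b2.df.set_index("snp").loc["rs1"]
        assert row["beta"] == pytest.approx(-beta0)
        assert row["eaf"] == pytest.approx(1 - eaf0)
        assert row["a1"] == "A" and row["a2"] == "G"

    def test_identical_inputs_pass_through(self):
        a = make_sumstats(5, seed=2)
        a2, b2, rep = pf.harmonize_pair(a, a)
        assert rep.n_flipped == 0 and rep.n_ambiguous_dropped == 0
        pd.testing.assert_frame_equal(a2.df, b2.df)
        pd.testing.assert_frame_equal(a2.df, a.df)

    def test_strand_ambiguous_snp_dropped(self):
        a = make_sumstats(4, seed=3)
        adf = a.df.copy()
        adf.loc[1, ["a1", "a2"]] = ["A", "T"]  # ambiguous
        a = pf.SummaryStats(adf)
        _, _, rep = pf.harmonize_pair(a, a)
        assert rep.n_ambiguous_dropped == 1
        assert rep.n_common == 3

    def test_empty_intersection_fatal(self):
        a = make_sumstats(3)
        bdf = make_sumstats(3).df
        bdf["snp"] = ["rsX", "rsY", "rsZ"]
        with pytest.raises(SumstatsError):
            pf.harmonize_pair(a, pf.SummaryStats(bdf))


class TestFlipAndGC:
    def test_flip_negates_beta_and_z_only(self):
        ss = make_sumstats(5, seed=4)
        flipped = pf.flip_effects(ss)
        assert np.allclose(flipped.df["beta"], -ss.df["beta"])
        assert np.allclose(flipped.df["z"], -ss.df["z"])
        assert np.allclose(flipped.df["pval"], ss.df["pval"])
        assert np.allclose(flipped.df["eaf"], ss.df["eaf"])

    def test_flip_is_involution(self):
        ss = make_sumstats(5, seed=5)
        twice = pf.flip_effects(pf.flip_effects(ss))
        pd.testing.assert_frame_equal(twice.df, ss.df)

    def test_gc_lambda_one_is_identity(self):
        ss = make_sumstats(6, seed=6)
        out, lam = pf.genomic_control(ss, lam=1.0)
        assert lam == 1.0
        pd.testing.assert_frame_equal(out.df, ss.df)

    def test_gc_deflates_chi2_by_lambda(self):
        # chi2 = 10 corrected by the reported inflation 1.62 -> 6.173
        df = make_sumstats(3, seed=7).df
        df["z"] = np.sqrt(10.0)
        df["beta"] = df["z"] * df["se"]
        out, _ = pf.genomic_control(pf.SummaryStats(df), lam=1.62)
        assert np.allclose(out.df["z"] ** 2, 10.0 / 1.62)
        assert out.df["z"].iloc[0] ** 2 == pytest.approx(6.173, abs=5e-4)

    def test_lambda_estimate_from_chi2_median(self):
        df = make_sumstats(5, seed=8).df
        df["z"] = np.sqrt(stats.chi2.ppf(0.5, 1))  # median chi2 -> lambda 1
        df["beta"] = df["z"] * df["se"]
        _, lam = pf.genomic_control(pf.SummaryStats(df))
        assert lam == pytest.approx(1.0, abs=1e-9)

    def test_gc_is_idempotent_correction(self):
        ss = make_sumstats(200, seed=9)
        once, lam1 = pf.genomic_control(ss)
        _, lam2 = pf.genomic_control(once)
        assert lam2 == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_lambda_fatal(self):
        with pytest.raises(SumstatsError):
            pf.genomic_control(make_sumstats(3), lam=0.0)


class TestEffectiveN:
    def test_reported_cohort_value(self):
        # case/control counts as printed for the dyslexia cohort
        assert pf.effective_n(51_800, 1_138_870) == pytest.approx(197_775.7, abs=0.5)

    def test_balanced_design_equals_total(self):
        assert pf.effective_n(5_000, 10_000) == pytest.approx(10_000)

    @given(
        n_cases=st.integers(min_value=1, max_value=10**6),
        n_controls=st.integers(min_value=1, max_value=10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_harmonic_mean_identity(self, n_cases, n_controls):
        n_total = n_cases + n_controls
        expected = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
        assert pf.effective_n(n_cases, n_total) == pytest.approx(
            expected, rel=1e-9
        )

    def test_invalid_counts_fatal(self):
        with pytest.raises(ValueError):
            pf.effective_n(10, 10)


class TestSnpFilter:
    def test_keep_list_and_exclusion_counts(self):
        ss = make_sumstats(10, seed=10)
        keep = {f"rs{i}" for i in (1, 2, 3, 4)}
        # rs2 lies inside the excluded interval
        regions = pf.LocusSet(pd.DataFrame(
            {"chrom": [1], "start": [1_005_000], "end": [1_015_000]}))
        out = pf.snp_filter(ss, keep_list=keep, exclude_regions=regions)
        assert set(out.df["snp"]) == {"rs1", "rs3", "rs4"}

    def test_noop_with_empty_filters(self):
        ss = make_sumstats(5, seed=11)
        out = pf.snp_filter(ss, keep_list=set(), exclude_regions=None)
        pd.testing.assert_frame_equal(out.df, ss.df)

    def test_removing_everything_fatal(self):
        ss = make_sumstats(3, seed=12)
        with pytest.raises(SumstatsError):
            pf.snp_filter(ss, keep_list={"nope"})


def _sig_sumstats(positions, pvals, chrom=1):
    n = len(positions)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i+1}" for i in range(n)],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "eaf": 0.3,
            "se": 0.01,
            "pval": pvals,
        }
    )
    df["z"] = stats.norm.isf(np.array(pvals) / 2)
    df["beta"] = df["z"] * df["se"]
    return pf.SummaryStats(df)


class TestLoci:
    def test_distance_merge_joins_nearby_significant_snps(self):
        ss = _sig_sumstats([1_000_000, 1_100_000], [1e-9, 1e-10])
        loci = pf.define_loci(ss, merge_bp=250_000)
        assert len(loci) == 1
        assert loci.df.loc[0, "start"] == 1_000_000
        assert loci.df.loc[0, "end"] == 1_100_000
        assert loci.df.loc[0, "lead_snp"] == "rs2"

    def test_distance_merge_splits_distant_snps(self):
        ss = _sig_sumstats([1_000_000, 1_100_000], [1e-9, 1e-10])
        loci = pf.define_loci(ss, merge_bp=50_000)
        assert len(loci) == 2

    def test_no_significant_snps_gives_empty_set(self):
        ss = _sig_sumstats([1_000_000], [0.5])
        assert len(pf.define_loci(ss)) == 0

    def test_every_significant_snp_in_exactly_one_locus(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 10**7, 1000), 50, replace=False))
        pvals = 10.0 ** rng.uniform(-12, -2, 50)
        ss = _sig_sumstats(pos, pvals)
        loci = pf.define_loci(ss, p_thresh=5e-8, merge_bp=100_000)
        sig = ss.df[ss.df["pval"] < 5e-8]
        counts = [
            ((sig["pos"] >= r["start"]) & (sig["pos"] <= r["end"])).sum()
            for _, r in loci.df.iterrows()
        ]
        assert sum(counts) == len(sig)
        assert loci.df["n_snps"].sum() == len(sig)

    def test_ld_clump_collapses_correlated_block(self):
        # 3 SNPs, pairwise r^2 = 0.8 > 0.06: one index SNP retained
        r = np.sqrt(0.8)
        corr = np.full((3, 3), r)
        np.fill_diagonal(corr, 1.0)
        panel = LDPanel([Block(1, 1_000_000, 1_010_000,
                               np.array(["rs1", "rs2", "rs3"]),
                               np.full(3, 0.3), corr)])
        ss = _sig_sumstats([1_000_000, 1_005_000, 1_010_000],
                           [1e-3, 1e-5, 1e-2])
        loci = pf.define_loci(ss, p_thresh=0.05, mode="ld_clump",
                              r2_thresh=0.06, panel=panel)
        assert len(loci) == 1
        assert loci.df.loc[0, "lead_snp"] == "rs2"
        assert loci.df.loc[0, "n_snps"] == 3


class TestPadIntersect:
    def test_padding_creates_overlap(self):
        a = pf.LocusSet(pd.DataFrame({"chrom": [1], "start": [1_000_000], "end": [1_200_000]}))
        b = pf.LocusSet(pd.DataFrame({"chrom": [1], "start": [1_900_000], "end": [2_000_000]}))
        assert pf.pad_and_intersect(a, b, pad_bp=1_000_000) == [(0, 0)]
        assert pf.pad_and_intersect(a, b, pad_bp=0) == []

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        def rand_loci(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.integers(1, 10**7, 5))
            return pf.LocusSet(pd.DataFrame(
                {"chrom": 1, "start": starts * 10, "end": starts * 10 + 5_000}))
        a, b = rand_loci(2), rand_loci(3)
        ab = set(pf.pad_and_intersect(a, b, pad_bp=20_000))
        ba = {(j, i) for i, j in pf.pad_and_intersect(b, a, pad_bp=20_000)}
        assert ab == ba

    def test_identity_gives_diagonal(self):
        a = pf.LocusSet(pd.DataFrame(
            {"chrom": [1, 2], "start": [100, 100], "end": [200, 200]}))
        assert pf.pad_and_intersect(a, a, pad_bp=0) == [(0, 0), (1, 1)]


class TestGenerationsToYears:
    @pytest.mark.parametrize(
        "gens,ypg,expected",
        [(11_199, 25, 279_975), (0, 25, 0), (10, 30, 300)],
    )
    def test_conversion(self, gens, ypg, expected):
        assert pf.generations_to_years(gens, ypg) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pf.generations_to_years(-1, 25)


class TestBedIO:
    def test_locusset_bed_roundtrip_offsets(self, tmp_path):
        ls = pf.LocusSet(pd.DataFrame(
            {"chrom": [1], "start": [1001], "end": [2000], "lead_snp": ["rs1"]}))
        path = tmp_path / "loci.bed"
        ls.to_bed(path)
        fields = path.read_text().split()
        assert fields[1] == "1000" and fields[2] == "2000"  # 0-based half-open
        back = pf.LocusSet.from_bed(path)
        assert back.df.loc[0, "start"] == 1001
        assert back.df.loc[0, "end"] == 2000
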