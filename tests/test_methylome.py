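import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import allelomethyl as am
from _oracles import contexts_bruteforce, region_level_bruteforce, revcomp
from conftest import make_calls, make_genes, random_genome

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


def sites_as_dict(sites: pd.DataFrame) -> dict:
    return {(r.pos, r.strand): r.context for r in sites.itertuples()}


class TestClassifyContexts:
    @pytest.mark.parametrize("seq,expected", [
        # palindromic CpG: the C at +1 and the C opposite the G at +2
        ("ACGT", {(1, "+"): "CG", (2, "-"): "CG"}),
        # reverse complement of CAG is CTG: the minus-strand C is CHG too
        ("CAG", {(0, "+"): "CHG", (2, "-"): "CHG"}),
        ("CAT", {(0, "+"): "CHH"}),
        ("CC", {(0, "+"): "ambiguous", (1, "+"): "ambiguous"}),
        ("CG", {(0, "+"): "ambiguous", (1, "-"): "ambiguous"}),
        ("CNGT", {(0, "+"): "ambiguous", (2, "-"): "ambiguous"}),
    ])
    def test_definition_cases(self, seq, expected):
        got = sites_as_dict(am.classify_contexts({"c": seq}))
        for key, ctx in expected.items():
            assert got[key] == ctx, (seq, key)

    def test_matches_bruteforce_scanner(self):
        rng = np.random.default_rng(0)
        for with_n in (False, True):
            seq = random_genome(rng, 1000, with_n=with_n)
            got = sites_as_dict(am.classify_contexts({"c": seq}))
            assert got == contexts_bruteforce(seq)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(dna)
    def test_partition_counts_all_cytosines(self, seq):
        sites = am.classify_contexts({"c": seq})
        # one context per C on each strand: forward Cs plus reverse Cs (G's)
        assert len(sites) == seq.count("C") + seq.count("G")
        assert set(sites["context"]) <= {"CG", "CHG", "CHH", "ambiguous"}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        fwd = sites_as_dict(am.classify_contexts({"c": seq}))
        rev = sites_as_dict(am.classify_contexts({"c": revcomp(seq)}))
        n = len(seq)
        flipped = {(n - 1 - pos, "+" if strand == "-" else "-"): ctx
                   for (pos, strand), ctx in rev.items()}
        assert fwd == flipped

    def test_rejects_non_nucleotides(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            am.classify_contexts({"c": "ACGU"})


class TestLoadCalls:
    sites = am.classify_contexts({"c": "ACGTCAT"})  # CG at 1+, CHH at 4+

    def test_matching_row_accepted(self):
        calls = make_calls([("c", 1, "+", "CG", 10, 5)])
        accepted, n_rej = am.load_calls(calls, self.sites)
        assert len(accepted) == 1 and n_rej == 0

    def test_non_cytosine_position_rejected(self):
        calls = make_calls([("c", 0, "+", "CG", 10, 5)])  # 'A' position
        accepted, n_rej = am.load_calls(calls, self.sites)
        assert len(accepted) == 0 and n_rej == 1

    def test_context_mismatch_beyond_tolerance_raises(self):
        calls = make_calls([("c", 4, "+", "CG", 10, 5)])  # genome says CHH
        with pytest.raises(ValueError, match="mismatch"):
            am.load_calls(calls, self.sites)

    def test_counts_out_of_range_raise(self):
        calls = make_calls([("c", 1, "+", "CG", 5, 9)])
        with pytest.raises(ValueError):
            am.load_calls(calls, self.sites)

    def test_synthetic_dataset_fully_consistent(self, clean_dataset):
        ds = clean_dataset
        sites = am.classify_contexts(ds.genomes["MC"])
        calls, n_rej = am.load_calls(ds.methylation[("MC", "flower")], sites)
        assert n_rej == 0
        assert len(calls) == len(ds.methylation[("MC", "flower")])


class TestRegionLevels:
    genes = make_genes([("g1", "c", 3000, 5000, "+")])

    def test_pooled_ratio_hand_example(self):
        calls = make_calls([("c", 3100, "+", "CG", 10, 3),
                            ("c", 3200, "-", "CG", 10, 2)])
        lv = am.region_levels(calls, self.genes, min_cov=1)
        body_cg = lv.query("region == 'body' and context == 'CG'").iloc[0]
        assert body_cg.level == pytest.approx(5 / 20)  # pooled, not mean of ratios
        assert body_cg.n_sites == 2

    def test_empty_region_gives_missing_level(self):
        calls = make_calls([("c", 3100, "+", "CG", 10, 3)])
        lv = am.region_levels(calls, self.genes, min_cov=1)
        up = lv.query("region == 'upstream' and context == 'CG'").iloc[0]
        assert np.isnan(up.level) and up.n_sites == 0

    def test_min_cov_excludes_sites(self):
        calls = make_calls([("c", 3100, "+", "CG", 3, 3),
                            ("c", 3200, "+", "CG", 10, 1)])
        lv = am.region_levels(calls, self.genes, min_cov=4)
        body_cg = lv.query("region == 'body' and context == 'CG'").iloc[0]
        assert body_cg.level == pytest.approx(0.1) and body_cg.n_sites == 1

    def test_strand_orientation_of_upstream(self):
        minus = make_genes([("g1", "c", 3000, 5000, "-")])
        calls = make_calls([("c", 5500, "+", "CHG", 10, 8)])  # 5' of minus TSS
        lv = am.region_levels(calls, minus, min_cov=1)
        assert lv.query("region == 'upstream' and context == 'CHG'").iloc[0].n_sites == 1
        assert lv.query("region == 'downstream' and context == 'CHG'").iloc[0].n_sites == 0

    def test_split_rows_leave_level_invariant(self):
        whole = make_calls([("c", 3100, "+", "CG", 12, 9)])
        split = make_calls([("c", 3100, "+", "CG", 8, 6), ("c", 3100, "+", "CG", 4, 3)])
        lv_w = am.region_levels(whole, self.genes, min_cov=1)
        lv_s = am.region_levels(split, self.genes, min_cov=1)
        pd.testing.assert_series_equal(lv_w["level"], lv_s["level"])

    def test_matches_per_base_bruteforce(self, clean_dataset):
        ds = clean_dataset
        calls = ds.methylation[("MC", "flower")]
        genes = ds.genes["MC"].iloc[:3]
        lv = am.region_levels(calls, genes, min_cov=4)
        for row in lv.itertuples():
            g = genes[genes.gene_id == row.gene_id].iloc[0]
            spans = {"+": {"upstream": (g.start - 2000, g.start), "body": (g.start, g.end),
                           "downstream": (g.end, g.end + 2000)},
                     "-": {"upstream": (g.end, g.end + 2000), "body": (g.start, g.end),
                           "downstream": (g.start - 2000, g.start)}}[g.strand]
            lo, hi = spans[row.region]
            exp_level, exp_n = region_level_bruteforce(
                calls, g.chrom, max(lo, 0), hi, row.context, 4)
            assert row.n_sites == exp_n
            if exp_n:
                assert row.level == pytest.approx(exp_level)

    def test_estimates_match_planted_truth(self, clean_dataset):
        """Planted body/upstream CG level 0.6 at coverage 30 -> within 0.05."""
        ds = clean_dataset
        lv = am.region_levels(ds.methylation[("MC", "flower")], ds.genes["MC"])
        truth = ds.truth.gene_levels.query(
            "haplotype == 'MC' and tissue == 'flower'")
        merged = lv.merge(truth, on=["gene_id", "region", "context"],
                          suffixes=("", "_true"))
        strong = merged[merged.n_sites >= 50]
        assert len(strong) > 30
        assert (strong.level - strong.level_true).abs().max() < 0.05
        body_cg = strong.query("region == 'body' and context == 'CG'")
        assert np.allclose(body_cg.level_true, 0.6)


class TestMetaprofile:
    def test_flat_profile(self):
        genes = make_genes([("g1", "c", 2000, 4000, "+")])
        rng = np.random.default_rng(3)
        pos = rng.choice(np.arange(0, 6000), size=400, replace=False)
        calls = make_calls([("c", int(p), "+", "CG", 10, 5) for p in pos])
        prof = am.metaprofile(calls, genes, flank_bins=5, body_bins=10, min_cov=1)
        cg = prof.query("context == 'CG' and n_genes > 0")
        assert np.allclose(cg.mean_level, 0.5)

    def test_upstream_only_sites(self):
        genes = make_genes([("g1", "c", 5000, 7000, "+")])
        calls = make_calls([("c", 3500, "+", "CG", 10, 5)])
        prof = am.metaprofile(calls, genes, flank_bins=4, body_bins=8, min_cov=1)
        cg = prof[prof.context == "CG"]
        assert cg[cg.segment == "upstream"].n_genes.sum() == 1
        assert cg[cg.segment != "upstream"].n_genes.sum() == 0

    def test_minus_strand_bins_are_mirrored(self):
        # site just upstream of a minus-strand TSS must land in the last
        # upstream bin (closest to the gene), not the first
        genes = make_genes([("g1", "c", 5000, 7000, "-")])
        calls = make_calls([("c", 7010, "+", "CG", 10, 5),   # 10 bp upstream
                            ("c", 8990, "+", "CHG", 10, 5)])  # 1990 bp upstream
        prof = am.metaprofile(calls, genes, flank_bins=4, body_bins=4, min_cov=1)
        assert prof.query("context == 'CG' and bin == 3").n_genes.iloc[0] == 1
        assert prof.query("context == 'CHG' and bin == 0").n_genes.iloc[0] == 1

    def test_short_gene_is_binned_not_skipped(self):
        genes = make_genes([("g1", "c", 5000, 5004, "+")])  # 4 bp gene, 8 bins
        calls = make_calls([("c", 5001, "+", "CG", 10, 10)])
        prof = am.metaprofile(calls, genes, flank_bins=2, body_bins=8, min_cov=1)
        assert prof.query("segment == 'body' and context == 'CG'").n_genes.sum() == 1

    def test_planted_step_between_flank_and_body(self):
        """Body level 0.6 vs flank level 0.2 -> step at the TSS within 0.05."""
        cfg = am.SimulationConfig(
            seed=11, n_chroms=1, chrom_len=180_000, n_genes=20,
            context_means={"CG": 0.2, "CHH": 0.12, "CHG": 0.1},
            body_means={"CG": 0.6, "CHH": 0.3, "CHG": 0.2},
            gene_jitter_sd=0.0, gene_propensity_range=(0.45, 0.45),
            dmr_spec=(), de_fraction=0.0,
        )
        ds = am.simulate_dataset(cfg)
        prof = am.metaprofile(ds.methylation[("MC", "flower")], ds.genes["MC"])
        cg = prof[prof.context == "CG"].set_index("bin")
        body = cg[cg.segment == "body"].mean_level
        flank = cg[cg.segment != "body"].mean_level
        assert (body - 0.6).abs().max() < 0.05
        assert (flank - 0.2).abs().max() < 0.05
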