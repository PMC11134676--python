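import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import allelomethyl as am
from allelomethyl import synthetic

TINY = dict(n_chroms=1, chrom_len=120_000, n_genes=12, de_fraction=0.25,
            dmr_spec=(am.DmrSpec(count=5),))


def _hash_dir(d: Path) -> dict:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir())}


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for sub in ("one", "two"):
            ds = am.simulate_dataset(am.SimulationConfig(seed=9, **TINY))
            am.write_dataset(ds, tmp_path / sub)
        assert _hash_dir(tmp_path / "one") == _hash_dir(tmp_path / "two")

    def test_different_seed_changes_output(self, tmp_path):
        am.write_dataset(am.simulate_dataset(am.SimulationConfig(seed=9, **TINY)),
                         tmp_path / "one")
        am.write_dataset(am.simulate_dataset(am.SimulationConfig(seed=10, **TINY)),
                         tmp_path / "two")
        assert _hash_dir(tmp_path / "one") != _hash_dir(tmp_path / "two")


class TestStatisticalStructure:
    def test_realized_context_levels_match_configured_means(self):
        """Pooled per-context levels within 3 binomial SE of the configured
        means (binomial sampling, neutral gene effects), and ordered
        CG > CHH > CHG."""
        means = {"CG": 0.6, "CHH": 0.3, "CHG": 0.2}
        cfg = am.SimulationConfig(seed=5, n_chroms=1, chrom_len=150_000, n_genes=15,
                                  context_means=means, meth_rho=0.0,
                                  gene_jitter_sd=0.0, gene_propensity_range=(0.45, 0.45),
                                  dmr_spec=(), de_fraction=0.0)
        ds = am.simulate_dataset(cfg)
        calls = ds.methylation[("MC", "flower")]
        pooled = calls.groupby("context").agg(m=("methylated", "sum"),
                                              c=("coverage", "sum"))
        realized = pooled.m / pooled.c
        for ctx, mu in means.items():
            se = np.sqrt(mu * (1 - mu) / pooled.c[ctx])
            assert abs(realized[ctx] - mu) < 3 * se, ctx
        assert realized["CG"] > realized["CHH"] > realized["CHG"]

    def test_default_conditions_keep_context_ordering(self, default_dataset):
        for (hap, tissue), calls in default_dataset.methylation.items():
            pooled = calls.groupby("context").agg(m=("methylated", "sum"),
                                                  c=("coverage", "sum"))
            realized = pooled.m / pooled.c
            assert realized["CG"] > realized["CHH"] > realized["CHG"], (hap, tissue)

    def test_planted_dmr_realized_delta(self, dmr_benchmark):
        """Pooled realized |delta| within 0.05 of the configured 0.3 for
        every planted interval at coverage 30."""
        ds = dmr_benchmark
        fl = ds.methylation[("MC", "flower")].set_index(["chrom", "pos", "strand"])
        lf = ds.methylation[("MC", "leaf")].set_index(["chrom", "pos", "strand"])
        for t in ds.truth.dmrs.itertuples():
            a = fl.loc[t.chrom]
            b = lf.loc[t.chrom]
            in_a = a[(a.index.get_level_values("pos") >= t.start)
                     & (a.index.get_level_values("pos") < t.end)]
            in_b = b[(b.index.get_level_values("pos") >= t.start)
                     & (b.index.get_level_values("pos") < t.end)]
            delta = in_a.methylated.sum() / in_a.coverage.sum() \
                - in_b.methylated.sum() / in_b.coverage.sum()
            assert delta == pytest.approx(t.delta, abs=0.05)

    def test_every_gff_gene_in_expression_and_vice_versa(self, default_dataset):
        ds = default_dataset
        gff_genes = set(ds.genes["MC"].gene_id) | set(ds.genes["MM"].gene_id)
        expr_genes = set(ds.expression.gene_id)
        assert gff_genes == expr_genes

    def test_empty_effects_give_empty_truth(self):
        cfg = am.SimulationConfig(seed=2, **{**TINY, "de_fraction": 0.0,
                                             "dmr_spec": ()})
        ds = am.simulate_dataset(cfg)
        assert ds.truth.de_pairs.empty
        assert ds.truth.dmrs.empty

    def test_truth_de_pairs_exist_in_anchor_table(self, default_dataset):
        ds = default_dataset
        anchors = set(zip(ds.anchors.gene_a, ds.anchors.gene_b))
        planted = set(zip(ds.truth.de_pairs.gene_a, ds.truth.de_pairs.gene_b))
        assert planted <= anchors

    def test_planted_dmrs_lie_within_chromosomes(self, default_dataset):
        ds = default_dataset
        for t in ds.truth.dmrs.itertuples():
            assert 0 <= t.start < t.end <= ds.config.chrom_len


class TestTruthIO:
    def test_roundtrip_is_lossless(self, default_dataset, tmp_path):
        path = tmp_path / "truth.tsv"
        synthetic.write_truth(default_dataset.truth, path)
        back = synthetic.read_truth(path)
        pd.testing.assert_frame_equal(back.dmrs, default_dataset.truth.dmrs)
        pd.testing.assert_frame_equal(back.de_pairs, default_dataset.truth.de_pairs)
        pd.testing.assert_frame_equal(back.gene_levels, default_dataset.truth.gene_levels)
        assert back.params == default_dataset.truth.params

    def test_empty_truth_writes_header_only(self, tmp_path):
        empty = synthetic.TruthTable(
            dmrs=pd.DataFrame(), de_pairs=pd.DataFrame(),
            gene_levels=pd.DataFrame(), params={})
        path = tmp_path / "truth.tsv"
        synthetic.write_truth(empty, path)
        assert len(path.read_text().splitlines()) == 1

    def test_dmr_rows_written_one_per_planted_region(self, tmp_path):
        dmrs = pd.DataFrame({
            "chrom": ["MC_chr1"] * 10, "start": range(0, 10_000, 1000),
            "end": range(500, 10_500, 1000), "haplotype": "MC",
            "tissue_a": "flower", "tissue_b": "leaf", "delta": 0.3})
        truth = synthetic.TruthTable(dmrs=dmrs, de_pairs=pd.DataFrame(),
                                     gene_levels=pd.DataFrame(), params={})
        path = tmp_path / "truth.tsv"
        synthetic.write_truth(truth, path)
        assert len(path.read_text().splitlines()) == 11  # header + 10 rows


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(n_genes=0), dict(chrom_len=-5), dict(gene_len_range=(0, 100)),
        dict(de_fraction=1.5), dict(coverage_mean=0),
        dict(dmr_spec=(am.DmrSpec(length=0),)),
        dict(dmr_spec=(am.DmrSpec(haplotype="XX"),)),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            am.simulate_dataset(am.SimulationConfig(**{**TINY, **bad}))

    def test_genome_too_small_for_genes(self):
        with pytest.raises(ValueError, match="too small"):
            am.simulate_dataset(am.SimulationConfig(
                n_chroms=1, chrom_len=50_000, n_genes=20))

    def test_config_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            synthetic.config_from_dict({"seeds": 3})
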