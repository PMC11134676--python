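"""Joint analysis of allelic expression and methylation, plus assembly metrics.

For every differentially expressed allele pair the methylation levels of the
two alleles are oriented by expression (level of the higher- vs the
lower-expressed allele) per gene region and context. The summary then asks,
per tissue x region x context:

* is the higher-expressed allele less methylated? (paired one-sided Wilcoxon
  signed-rank on level_high - level_low; a paired nonparametric test matches
  the paired-allele design), and
* does the expression ratio co-vary with the methylation difference?
  (Spearman correlation of the signed A-over-B log2 expression ratio with
  the A-minus-B methylation-level difference; negative under
  methylation-mediated repression).

Both statistics are invariant to relabelling the haplotypes.

The module also houses the haplotype assembly/annotation metric report
(cross-haplotype arithmetic means of per-haplotype summary values).
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

RECORD_COLUMNS = ["gene_a", "gene_b", "tissue", "region", "context", "call",
                  "log2_ratio", "level_a", "level_b", "level_high", "level_low"]


def integrate(calls_de: pd.DataFrame, region_levels_a: pd.DataFrame,
              region_levels_b: pd.DataFrame):
    """Join DE calls with per-allele region methylation levels.

    Only pairs classed ``A_high``/``B_high`` contribute. The level tables are
    the ``methylome.region_levels`` output for each haplotype; if they carry
    a ``tissue`` column the join is tissue-matched, otherwise levels apply to
    every tissue. Pairs with a missing level in a region/context are dropped
    from that cell only; drop counts are included in the summary.

    Returns ``(records, summary)``.
    """
    de = calls_de[calls_de["call"].isin(["A_high", "B_high"])]

    def _prep(levels, side):
        cols = {"gene_id": f"gene_{side}", "level": f"level_{side}"}
        keep = ["gene_id", "region", "context", "level"]
        if "tissue" in levels.columns:
            keep.append("tissue")
        return levels[keep].rename(columns=cols)

    la, lb = _prep(region_levels_a, "a"), _prep(region_levels_b, "b")
    on_a = ["gene_a"] + (["tissue"] if "tissue" in la.columns else [])
    rec = de[["gene_a", "gene_b", "tissue", "call", "log2_ratio"]].merge(la, on=on_a)
    on_b = ["gene_b", "region", "context"] + (["tissue"] if "tissue" in lb.columns else [])
    rec = rec.merge(lb, on=on_b)
    n_cells_before = rec.groupby(["tissue", "region", "context"]).size()
    rec = rec.dropna(subset=["level_a", "level_b"]).reset_index(drop=True)

    if rec.empty:
        warnings.warn("no differentially expressed pairs with methylation data; "
                      "integration summary is empty")
    a_high = rec["call"] == "A_high"
    rec["level_high"] = np.where(a_high, rec["level_a"], rec["level_b"])
    rec["level_low"] = np.where(a_high, rec["level_b"], rec["level_a"])
    records = rec[RECORD_COLUMNS]

    rows = []
    for (tissue, region, context), grp in records.groupby(
            ["tissue", "region", "context"], sort=True):
        diff = grp["level_high"].to_numpy() - grp["level_low"].to_numpy()
        if len(diff) and np.any(diff != 0):
            wp = stats.wilcoxon(diff, alternative="less").pvalue
        else:
            wp = 1.0  # all ties (or empty): no evidence either way
        meth_diff = grp["level_a"].to_numpy() - grp["level_b"].to_numpy()
        ratio = grp["log2_ratio"].to_numpy()
        if len(grp) >= 3 and np.unique(meth_diff).size > 1 and np.unique(ratio).size > 1:
            rho, sp = stats.spearmanr(ratio, meth_diff)
        else:
            rho, sp = np.nan, np.nan  # undefined on constant input
        dropped = int(n_cells_before.get((tissue, region, context), len(grp)) - len(grp))
        rows.append((tissue, region, context, len(grp), dropped,
                     grp["level_high"].mean(), grp["level_low"].mean(),
                     wp, rho, sp))
    summary = pd.DataFrame(rows, columns=[
        "tissue", "region", "context", "n_pairs", "n_dropped",
        "mean_level_high", "mean_level_low", "wilcoxon_p",
        "spearman_rho", "spearman_p"])
    return records, summary


def summarize_haplotype_metrics(metrics_a: Mapping[str, float],
                                metrics_b: Mapping[str, float]) -> pd.DataFrame:
    """Cross-haplotype arithmetic means of assembly/annotation metrics.

    Both mappings must carry the same keys; means are reported to three
    decimals (e.g. contig N50 of 15.08 and 9.77 Mb -> 12.425 Mb).
    """
    if set(metrics_a) != set(metrics_b):
        raise ValueError("haplotype metric keys differ: "
                         f"{set(metrics_a) ^ set(metrics_b)}")
    rows = [(k, metrics_a[k], metrics_b[k], round((metrics_a[k] + metrics_b[k]) / 2, 3))
            for k in metrics_a]
    return pd.DataFrame(rows, columns=["metric", "value_a", "value_b", "mean"])
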