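"""TPM filtering and allelic differential-expression calls.

Expression arrives as a long table (gene_id, tissue, replicate, tpm). Two
filters are applied before any comparison:

1. genes whose mean TPM is 0 in every tissue are discarded as non-expressed;
2. within every expressed tissue the replicate spread statistic
   d = (max - min) / mean must stay below 0.5 ("< 50% difference across
   replicates"); the mean is used as the denominator as the least biased of
   the candidate references.

Allelic differential expression compares the replicate-mean TPM of the two
alleles of a pair in one tissue: with pseudocount ``pseudo`` the ratio
r = (max + pseudo) / (min + pseudo) must exceed ``fold`` (default 2) for an
A_high/B_high call; pairs with both means zero are not_expressed, everything
else is balanced.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .alleles import pair_expression_coverage

CLASSES = ("A_high", "B_high", "balanced", "not_expressed")


def _tissue_stats(expr: pd.DataFrame) -> pd.DataFrame:
    if expr["tpm"].isna().any():
        raise ValueError("missing TPM values in expression table")
    if (expr["tpm"] < 0).any():
        raise ValueError("negative TPM values in expression table")
    counts = expr.groupby(["gene_id", "tissue"])["tpm"].count()
    if counts.groupby("tissue").nunique().gt(1).any():
        raise ValueError("unequal replicate counts within a tissue")
    return expr.groupby(["gene_id", "tissue"])["tpm"].agg(["mean", "max", "min"])


def filter_genes(expr: pd.DataFrame):
    """Apply the non-expression and replicate-consistency filters.

    Returns ``(retained, report)`` where ``retained`` is the set of retained
    gene ids and ``report`` has one row per gene with the rule outcomes
    (``reason`` in {retained, nonexpressed, replicate_inconsistent}).
    """
    st = _tissue_stats(expr)
    means = st["mean"].unstack("tissue")
    nonexpressed = (means == 0).all(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        d = (st["max"] - st["min"]) / st["mean"]
    d = d.where(st["mean"] > 0)  # spread is only assessed in expressed tissues
    max_d = d.groupby("gene_id").max()
    inconsistent = (d >= 0.5).groupby("gene_id").any()

    report = pd.DataFrame({
        "gene_id": means.index,
        "nonexpressed": nonexpressed.to_numpy(),
        "max_d": max_d.reindex(means.index).to_numpy(),
        "retained": (~nonexpressed & ~inconsistent.reindex(means.index, fill_value=False)).to_numpy(),
    })
    report["reason"] = np.where(
        report["nonexpressed"], "nonexpressed",
        np.where(report["retained"], "retained", "replicate_inconsistent"))
    retained = set(report.loc[report["retained"], "gene_id"])
    return retained, report


def call_allelic_de(pairs: pd.DataFrame, expr: pd.DataFrame, tissue: str,
                    fold: float = 2.0, pseudo: float = 0.1,
                    expressed_min: float = 0.0) -> pd.DataFrame:
    """Classify allelic expression of each pair in one tissue.

    Pairs whose genes are absent from the expression table (e.g. removed by
    filtering) are dropped. ``log2_ratio`` is the signed A-over-B ratio with
    pseudocounts. A pair is ``expressed`` if at least one allele mean exceeds
    ``expressed_min``.
    """
    if tissue not in set(expr["tissue"]):
        raise ValueError(f"tissue {tissue!r} not present in expression table")
    means = (expr[expr["tissue"] == tissue]
             .groupby("gene_id")["tpm"].mean())
    out = pairs[["gene_a", "gene_b"]].copy()
    out["tissue"] = tissue
    out["mean_a"] = out["gene_a"].map(means).to_numpy()
    out["mean_b"] = out["gene_b"].map(means).to_numpy()
    out = out.dropna(subset=["mean_a", "mean_b"]).reset_index(drop=True)

    hi = np.maximum(out["mean_a"], out["mean_b"])
    lo = np.minimum(out["mean_a"], out["mean_b"])
    ratio = (hi + pseudo) / (lo + pseudo)
    out["log2_ratio"] = np.log2((out["mean_a"] + pseudo) / (out["mean_b"] + pseudo))
    out["expressed"] = hi > expressed_min
    out["call"] = np.where(
        (out["mean_a"] == 0) & (out["mean_b"] == 0), "not_expressed",
        np.where(ratio <= fold, "balanced",
                 np.where(out["mean_a"] > out["mean_b"], "A_high", "B_high")))
    return out


def de_summary(calls: pd.DataFrame) -> dict:
    """Per-tissue counts and the expressed-pair coverage percentage."""
    n = len(calls)
    n_expressed = int(calls["expressed"].sum())
    counts = calls["call"].value_counts().to_dict()
    return {
        "n_pairs": n,
        "n_expressed": n_expressed,
        "expressed_pct": pair_expression_coverage(n_expressed, n) if n else float("nan"),
        **{f"n_{cls}": int(counts.get(cls, 0)) for cls in CLASSES},
    }
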