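"""Cytosine context classification and weighted methylation-level summaries.

Plant DNA methylation occurs in three sequence contexts -- CpG, CHG and CHH
(H = A, C or T) -- maintained by different pathways and therefore analysed
separately throughout this package. This module

* classifies every cytosine of a genome (both strands) into its context,
* joins per-cytosine methylation call tables to those sites, validating the
  stated context against the genome,
* computes *weighted methylation levels* (pooled methylated reads divided by
  pooled coverage) for strand-oriented gene regions (2 kb upstream flank,
  gene body, 2 kb downstream flank), and
* computes binned TSS->TTS metaprofiles per context.

The weighted (pooled-count) estimator is used rather than a mean of per-site
fractions: it is robust to coverage heterogeneity, and splitting a site's
reads across rows leaves it invariant.

The two strands of a symmetric CpG are kept as separate sites, matching
per-strand caller output; merge them upstream if a caller reports combined
counts.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
REGIONS = ("upstream", "body", "downstream")
AMBIGUOUS = "ambiguous"

_VALID = np.frombuffer(b"ACGTN", dtype="S1")
_CTX_CODE = {c: i for i, c in enumerate(CONTEXTS)}


def classify_contexts(genome: Mapping[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of ``genome``.

    ``pos`` is the forward-strand coordinate of the cytosine residue (for the
    minus strand this is the position of the G on the forward strand).
    Cytosines with fewer than two downstream bases on their strand, or with
    an N anywhere in their trinucleotide, get context ``"ambiguous"``.

    Raises ``ValueError`` on characters outside A/C/G/T/N.
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        if not np.isin(arr, _VALID).all():
            bad = arr[~np.isin(arr, _VALID)][0].decode()
            raise ValueError(f"{chrom}: non-nucleotide character {bad!r}")
        n = arr.size

        # forward strand: C followed by two downstream bases
        ic = np.flatnonzero(arr == b"C")
        b1 = np.where(ic + 1 < n, arr[np.minimum(ic + 1, n - 1)], b"N")
        b2 = np.where(ic + 2 < n, arr[np.minimum(ic + 2, n - 1)], b"N")
        ctx_f = np.where(b1 == b"G", "CG", np.where(b2 == b"G", "CHG", "CHH"))
        ctx_f = np.where((b1 == b"N") | (b2 == b"N"), AMBIGUOUS, ctx_f)

        # minus strand: a C sits opposite each forward G; its downstream
        # bases are the forward bases at pos-1, pos-2, complemented, and the
        # complement is G exactly when the forward base is C.
        ig = np.flatnonzero(arr == b"G")
        d1 = np.where(ig - 1 >= 0, arr[np.maximum(ig - 1, 0)], b"N")
        d2 = np.where(ig - 2 >= 0, arr[np.maximum(ig - 2, 0)], b"N")
        ctx_r = np.where(d1 == b"C", "CG", np.where(d2 == b"C", "CHG", "CHH"))
        ctx_r = np.where((d1 == b"N") | (d2 == b"N"), AMBIGUOUS, ctx_r)

        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([ic, ig]),
            "strand": np.repeat(["+", "-"], [ic.size, ig.size]),
            "context": np.concatenate([ctx_f, ctx_r]),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    sites = pd.concat(frames, ignore_index=True)
    return sites.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def load_calls(calls, sites: pd.DataFrame, max_mismatch: float = 0.01):
    """Join a methylation call table to genome-classified sites.

    ``calls`` is a DataFrame or a path to a TSV in the declared dialect
    (chrom, pos, strand, context, coverage, methylated). Rows whose position
    is not a classified cytosine, or whose stated context disagrees with the
    genome-derived context, are rejected and counted.

    Returns ``(accepted, n_rejected)``. If more than ``max_mismatch`` of the
    rows disagree on context the genome and calls are considered mismatched
    and a ``ValueError`` is raised.
    """
    if not isinstance(calls, pd.DataFrame):
        from . import io
        calls = io.read_methylation(calls)
    if ((calls["methylated"] < 0) | (calls["methylated"] > calls["coverage"])).any():
        raise ValueError("methylated count outside [0, coverage]")

    merged = calls.merge(
        sites.rename(columns={"context": "genome_context"}),
        on=["chrom", "pos", "strand"], how="left",
    )
    ok = merged["genome_context"].notna() & (merged["context"] == merged["genome_context"])
    ok &= merged["genome_context"] != AMBIGUOUS
    n_rejected = int((~ok).sum())
    n_mismatch = int(
        (merged["genome_context"].notna() & (merged["context"] != merged["genome_context"])).sum()
    )
    if len(calls) and n_mismatch / len(calls) > max_mismatch:
        raise ValueError(
            f"{n_mismatch}/{len(calls)} rows disagree with genome-derived context; "
            "genome and call table appear mismatched"
        )
    accepted = merged.loc[ok, list(calls.columns)].reset_index(drop=True)
    return accepted, n_rejected


def _calls_by_chrom(calls: pd.DataFrame, min_cov: int):
    """Index calls per chromosome as position-sorted numpy arrays."""
    c = calls[(calls["coverage"] >= min_cov) & calls["context"].isin(CONTEXTS)]
    out = {}
    for chrom, sub in c.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        out[chrom] = (
            sub["pos"].to_numpy(np.int64),
            sub["context"].map(_CTX_CODE).to_numpy(np.int64),
            sub["methylated"].to_numpy(np.float64),
            sub["coverage"].to_numpy(np.float64),
        )
    return out


def _gene_regions(start: int, end: int, strand: str, flank: int):
    if strand == "+":
        return {"upstream": (start - flank, start), "body": (start, end),
                "downstream": (end, end + flank)}
    return {"upstream": (end, end + flank), "body": (start, end),
            "downstream": (start - flank, start)}


def region_levels(calls: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000,
                  min_cov: int = 4) -> pd.DataFrame:
    """Weighted methylation level per gene x region x context.

    Regions are strand-oriented (upstream is 5' of the TSS on the gene's
    strand); flanks are truncated at chromosome starts. The level is the
    pooled ratio sum(methylated)/sum(coverage) over sites with coverage >=
    ``min_cov``; it is missing (NaN) when no site qualifies.
    """
    indexed = _calls_by_chrom(calls, min_cov)
    rows = []
    for g in genes.itertuples():
        data = indexed.get(g.chrom)
        for region, (a, b) in _gene_regions(g.start, g.end, g.strand, flank).items():
            a = max(a, 0)
            meth = np.zeros(3)
            cov = np.zeros(3)
            n = np.zeros(3, dtype=int)
            if data is not None and b > a:
                pos, code, m, c = data
                lo, hi = np.searchsorted(pos, [a, b])
                if hi > lo:
                    sl = slice(lo, hi)
                    meth = np.bincount(code[sl], weights=m[sl], minlength=3)
                    cov = np.bincount(code[sl], weights=c[sl], minlength=3)
                    n = np.bincount(code[sl], minlength=3)
            for k, ctx in enumerate(CONTEXTS):
                level = meth[k] / cov[k] if n[k] else np.nan
                rows.append((g.gene_id, region, ctx, level, int(n[k]), int(cov[k])))
    return pd.DataFrame(
        rows, columns=["gene_id", "region", "context", "level", "n_sites", "total_coverage"]
    )


def metaprofile(calls: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000,
                flank_bins: int = 20, body_bins: int = 40,
                min_cov: int = 4) -> pd.DataFrame:
    """Binned metagene methylation profile per context.

    Each flank is divided into ``flank_bins`` equal-width bins and the gene
    body into ``body_bins`` proportional bins; bin 0 is always the farthest
    upstream bin regardless of strand. A per-gene weighted level is computed
    per bin, then averaged over the genes with data in that bin. Genes
    shorter than ``body_bins`` simply populate a subset of body bins.
    """
    if len(genes) == 0:
        raise ValueError("metaprofile requires at least one gene")
    indexed = _calls_by_chrom(calls, min_cov)
    total_bins = 2 * flank_bins + body_bins
    parts = []
    for gi, g in enumerate(genes.itertuples()):
        data = indexed.get(g.chrom)
        if data is None:
            continue
        pos_all, code_all, m_all, c_all = data
        lo, hi = np.searchsorted(pos_all, [max(g.start - flank, 0), g.end + flank])
        if hi <= lo:
            continue
        pos = pos_all[lo:hi]
        glen = g.end - g.start
        if g.strand == "+":
            up = pos < g.start
            down = pos >= g.end
            bins = np.empty(pos.size, dtype=np.int64)
            bins[up] = flank_bins + np.floor(
                (pos[up] - g.start) / flank * flank_bins).astype(np.int64)
            body = ~up & ~down
            bins[body] = flank_bins + np.minimum(
                np.floor((pos[body] - g.start) / glen * body_bins).astype(np.int64),
                body_bins - 1)
            bins[down] = flank_bins + body_bins + np.minimum(
                np.floor((pos[down] - g.end) / flank * flank_bins).astype(np.int64),
                flank_bins - 1)
        else:
            up = pos >= g.end
            down = pos < g.start
            bins = np.empty(pos.size, dtype=np.int64)
            bins[up] = flank_bins - 1 - np.minimum(
                np.floor((pos[up] - g.end) / flank * flank_bins).astype(np.int64),
                flank_bins - 1)
            body = ~up & ~down
            bins[body] = flank_bins + np.minimum(
                np.floor((g.end - 1 - pos[body]) / glen * body_bins).astype(np.int64),
                body_bins - 1)
            bins[down] = flank_bins + body_bins + np.minimum(
                np.floor((g.start - 1 - pos[down]) / flank * flank_bins).astype(np.int64),
                flank_bins - 1)
        parts.append(pd.DataFrame({
            "gene": gi, "bin": bins, "context": code_all[lo:hi],
            "meth": m_all[lo:hi], "cov": c_all[lo:hi],
        }))

    grid = pd.MultiIndex.from_product(
        [CONTEXTS, range(total_bins)], names=["context", "bin"])
    if not parts:
        out = pd.DataFrame(index=grid).reset_index()
        out["mean_level"] = np.nan
        out["n_genes"] = 0
        return out

    per_gene = (pd.concat(parts, ignore_index=True)
                .groupby(["gene", "context", "bin"], sort=True)[["meth", "cov"]].sum())
    per_gene["level"] = per_gene["meth"] / per_gene["cov"]
    summary = per_gene.groupby(["context", "bin"])["level"].agg(["mean", "count"])
    summary.index = summary.index.set_levels(
        [np.array(CONTEXTS)[summary.index.levels[0]], summary.index.levels[1]])
    out = summary.reindex(grid).reset_index()
    out = out.rename(columns={"mean": "mean_level", "count": "n_genes"})
    out["n_genes"] = out["n_genes"].fillna(0).astype(int)
    seg = np.where(out["bin"] < flank_bins, "upstream",
                   np.where(out["bin"] < flank_bins + body_bins, "body", "downstream"))
    out["segment"] = seg
    return out
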