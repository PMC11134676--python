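"""Allelic gene pairing through collinear-block chaining of homology anchors.

In an allodiploid, each gene usually has a positional counterpart on the
complementary haplotype. Given a table of homology anchors (gene_a, gene_b,
similarity score, e.g. alignment bit-scores), this module

* orders genes along each chromosome and chains anchors into collinear
  blocks with a weighted longest-increasing-subsequence over gene ranks
  (both orientations tried, MCScanX-like minimum block size), and
* calls allelic gene pairs inside blocks with a best-homolog rule under a
  one-to-one constraint (greedy descending-score matching).

Homology search itself is out of scope: scores come from the input table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

BLOCK_COLUMNS = ["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "score"]


def _gene_ranks(genes: pd.DataFrame) -> pd.DataFrame:
    g = genes.sort_values(["chrom", "start", "gene_id"], kind="stable")
    return pd.DataFrame({
        "gene_id": g["gene_id"].to_numpy(),
        "chrom": g["chrom"].to_numpy(),
        "rank": g.groupby("chrom", sort=False).cumcount().to_numpy(),
    })


def _best_chain(rank_a, key_b, score, max_gap):
    """Highest-scoring chain with strictly increasing rank_a and key_b and
    rank gaps <= max_gap on both sides. O(n^2) dynamic program; ties resolved
    toward the earliest predecessor for determinism. Returns (indices, score).
    """
    n = rank_a.size
    best = score.astype(float).copy()
    parent = np.full(n, -1)
    order = np.lexsort((key_b, rank_a))
    ra, kb = rank_a[order], key_b[order]
    for ii in range(n):
        for jj in range(ii):
            if (ra[jj] < ra[ii] and kb[jj] < kb[ii]
                    and ra[ii] - ra[jj] <= max_gap and kb[ii] - kb[jj] <= max_gap):
                cand = best[order[jj]] + score[order[ii]]
                if cand > best[order[ii]]:
                    best[order[ii]] = cand
                    parent[order[ii]] = order[jj]
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    return chain[::-1], float(best[chain[0]])


def chain_anchors(anchors: pd.DataFrame, genes_a: pd.DataFrame,
                  genes_b: pd.DataFrame, min_anchors: int = 5,
                  max_gap: int = 25):
    """Chain homology anchors into collinear blocks.

    Within each chromosome pair, maximal-scoring chains are extracted
    greedily (best chain, remove its anchors, repeat); each anchor belongs
    to at most one block, and chains shorter than ``min_anchors`` are
    discarded. Both orientations are tried; for inverted blocks the B-side
    ranks decrease along the chain.

    Returns ``(blocks, members)``: a per-block summary and the anchor table
    with ``block_id``, ``rank_a`` and ``rank_b`` columns. Anchors naming
    genes absent from the annotations raise ``ValueError``.
    """
    ra = _gene_ranks(genes_a).rename(
        columns={"gene_id": "gene_a", "chrom": "chrom_a", "rank": "rank_a"})
    rb = _gene_ranks(genes_b).rename(
        columns={"gene_id": "gene_b", "chrom": "chrom_b", "rank": "rank_b"})
    anc = anchors.merge(ra, on="gene_a", how="left").merge(rb, on="gene_b", how="left")
    if anc["rank_a"].isna().any() or anc["rank_b"].isna().any():
        missing = anc.loc[anc["rank_a"].isna(), "gene_a"].tolist() \
            + anc.loc[anc["rank_b"].isna(), "gene_b"].tolist()
        raise ValueError(f"anchor genes missing from annotation: {missing[:5]}")
    if (anc["score"] <= 0).any():
        raise ValueError("anchor scores must be positive")
    # canonical order makes the result invariant to input row order
    anc = anc.sort_values(["chrom_a", "chrom_b", "rank_a", "rank_b", "gene_a", "gene_b"],
                          kind="stable").reset_index(drop=True)

    blocks = []
    members = []
    block_id = 0
    for (ca, cb), grp in anc.groupby(["chrom_a", "chrom_b"], sort=True):
        remaining = grp.reset_index(drop=True)
        while len(remaining) >= min_anchors:
            rank_a = remaining["rank_a"].to_numpy(np.int64)
            rank_b = remaining["rank_b"].to_numpy(np.int64)
            score = remaining["score"].to_numpy(float)
            cand = []
            for orientation, key_b in (("same", rank_b), ("inverted", -rank_b)):
                idx, total = _best_chain(rank_a, key_b, score, max_gap)
                cand.append((total, len(idx), orientation, idx))
            total, length, orientation, idx = max(cand, key=lambda t: (t[0], t[1]))
            if length < min_anchors:
                break
            chosen = remaining.iloc[idx].copy()
            chosen["block_id"] = block_id
            members.append(chosen)
            blocks.append((block_id, ca, cb, orientation, length, total))
            remaining = remaining.drop(remaining.index[idx]).reset_index(drop=True)
            block_id += 1
    blocks_df = pd.DataFrame(blocks, columns=BLOCK_COLUMNS)
    if members:
        members_df = pd.concat(members, ignore_index=True)
    else:
        members_df = anc.iloc[0:0].copy()
        members_df["block_id"] = pd.Series(dtype=int)
    return blocks_df, members_df


def call_allele_pairs(blocks: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Pair each gene with its best in-block homolog, one-to-one.

    Blocks are processed longest first (cross-block conflicts resolved in
    favour of the longer block); within a block, anchors are taken in
    descending score, ties broken by smaller rank distance then lexicographic
    gene ids. A gene already paired is skipped.
    """
    used_a: set = set()
    used_b: set = set()
    rows = []
    order = blocks.sort_values(["n_anchors", "block_id"],
                               ascending=[False, True])["block_id"]
    for bid in order:
        sub = members[members["block_id"] == bid].copy()
        sub["rank_dist"] = (sub["rank_a"] - sub["rank_b"]).abs()
        sub = sub.sort_values(["score", "rank_dist", "gene_a", "gene_b"],
                              ascending=[False, True, True, True], kind="stable")
        for a in sub.itertuples():
            if a.gene_a in used_a or a.gene_b in used_b:
                continue
            used_a.add(a.gene_a)
            used_b.add(a.gene_b)
            rows.append((a.gene_a, a.gene_b, bid, a.score))
    return (pd.DataFrame(rows, columns=["gene_a", "gene_b", "block_id", "score"])
            .sort_values(["gene_a"]).reset_index(drop=True))


def pair_expression_coverage(expressed: int, total: int) -> float:
    """Percentage of allele pairs expressed, to two decimals.

    E.g. 8099 expressed of 22034 pairs -> 36.76.
    """
    if total == 0:
        raise ValueError("total pair count must be positive")
    if not 0 <= expressed <= total:
        raise ValueError("expressed count must be within [0, total]")
    return round(100.0 * expressed / total, 2)
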