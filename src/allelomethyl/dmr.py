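"""Sliding-window differential methylation calling and genomic annotation.

Two per-cytosine call sets (e.g. flower vs leaf, or the two haplotypes) are
compared per sequence context with a pooled two-proportion z-test over
sliding windows, followed by Benjamini-Hochberg correction across all tested
windows of that context. Significant windows with the same sign of
difference that lie within one step of each other are merged into
differentially methylated regions (DMRs), whose summary statistics are
recomputed from the pooled counts of the merged span.

The windowed two-proportion test is a deliberately transparent statistic:
it is dependency-free, exactly calibrated on pooled binomial counts, and
directly testable against planted truth. It does not attempt the dispersion
shrinkage of smoothed beta-binomial DMR callers; overdispersion beyond
binomial shows up as mild anti-conservativeness that the delta_min effect
floor keeps in check.

DMRs are annotated to promoter (2 kb strand-aware upstream of the TSS),
gene-body or intergenic compartments with priority promoter > gene_body >
intergenic; any 1-bp overlap triggers a category.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

DMR_COLUMNS = ["chrom", "start", "end", "context", "n_sites",
               "mean_a", "mean_b", "delta", "p_value", "q_value"]


def _join_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame, context: str,
                min_cov: int) -> pd.DataFrame:
    """Inner-join the two call sets on site, keeping covered sites only."""
    a = calls_a[(calls_a["context"] == context) & (calls_a["coverage"] >= min_cov)]
    b = calls_b[(calls_b["context"] == context) & (calls_b["coverage"] >= min_cov)]
    j = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    return j.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _two_proportion_p(ma, ca, mb, cb):
    """Two-sided pooled two-proportion z-test, vectorised.

    Zero pooled variance (both proportions 0 or 1 and equal) gives p = 1 by
    convention.
    """
    ma, ca, mb, cb = (np.asarray(x, dtype=float) for x in (ma, ca, mb, cb))
    p1, p2 = ma / ca, mb / cb
    pool = (ma + mb) / (ca + cb)
    var = pool * (1.0 - pool) * (1.0 / ca + 1.0 / cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    return np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)


def window_stats(calls_a: pd.DataFrame, calls_b: pd.DataFrame, context: str,
                 window: int = 1000, step: int = 500, min_sites: int = 5,
                 min_cov: int = 4) -> pd.DataFrame:
    """Per-window pooled counts, deltas and (BH-adjusted) p-values.

    Windows start at multiples of ``step`` and span ``window`` bp; only
    windows with at least ``min_sites`` sites covered in both samples are
    tested. Raises ``ValueError`` if ``window < step`` (windows would leave
    gaps in the genome).
    """
    if window < step:
        raise ValueError(f"window ({window}) must be >= step ({step})")
    joined = _join_calls(calls_a, calls_b, context, min_cov)
    frames = []
    for chrom, sub in joined.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        cums = {k: np.concatenate([[0.0], np.cumsum(sub[k].to_numpy(float))])
                for k in ("methylated_a", "coverage_a", "methylated_b", "coverage_b")}
        starts = np.arange(0, pos[-1] + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + window)
        keep = (hi - lo) >= min_sites
        lo, hi, starts = lo[keep], hi[keep], starts[keep]
        if starts.size == 0:
            continue
        ma = cums["methylated_a"][hi] - cums["methylated_a"][lo]
        ca = cums["coverage_a"][hi] - cums["coverage_a"][lo]
        mb = cums["methylated_b"][hi] - cums["methylated_b"][lo]
        cb = cums["coverage_b"][hi] - cums["coverage_b"][lo]
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window,
            "n_sites": hi - lo,
            "meth_a": ma, "cov_a": ca, "meth_b": mb, "cov_b": cb,
            "mean_a": ma / ca, "mean_b": mb / cb,
            "delta": ma / ca - mb / cb,
            "p_value": _two_proportion_p(ma, ca, mb, cb),
        }))
    if not frames:
        cols = ["chrom", "start", "end", "n_sites", "meth_a", "cov_a", "meth_b",
                "cov_b", "mean_a", "mean_b", "delta", "p_value", "q_value"]
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _refine_segment(diff: np.ndarray, sign: int, penalty: float) -> tuple[int, int]:
    """Maximal-scoring run of sites for per-site score sign*diff - penalty.

    Kadane's algorithm; trims a merged window span to the sites that actually
    carry the methylation difference, since significant windows overlap a DMR
    by as little as the delta_min floor allows and their union over-extends
    the region by up to a window width on each side.
    """
    score = sign * diff - penalty
    best_sum = -np.inf
    best = (0, diff.size)
    run_sum = 0.0
    run_start = 0
    for i, s in enumerate(score):
        if run_sum <= 0:
            run_sum, run_start = s, i
        else:
            run_sum += s
        if run_sum > best_sum:
            best_sum, best = run_sum, (run_start, i + 1)
    return best


def call_dmrs(calls_a: pd.DataFrame, calls_b: pd.DataFrame, context: str,
              window: int = 1000, step: int = 500, min_sites: int = 5,
              min_cov: int = 4, delta_min: float = 0.1,
              alpha: float = 0.05, refine_boundaries: bool = True) -> pd.DataFrame:
    """Call DMRs between two samples for one context.

    Windows passing q <= ``alpha`` and |delta| >= ``delta_min`` are merged
    when they share the delta sign and are separated by at most ``step`` bp;
    merged DMR means and delta are recomputed from pooled counts over the
    merged (and, with ``refine_boundaries``, site-level trimmed) span, while
    p and q are reported as the minimum over member windows. Refined DMRs
    must still satisfy ``min_sites`` and ``delta_min``.
    """
    ws = window_stats(calls_a, calls_b, context, window, step, min_sites, min_cov)
    sig = ws[(ws["q_value"] <= alpha) & (ws["delta"].abs() >= delta_min)]
    if sig.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    joined = _join_calls(calls_a, calls_b, context, min_cov)

    merged = []
    cur = None
    for w in sig.sort_values(["chrom", "start"]).itertuples():
        sign = 1 if w.delta > 0 else -1
        if (cur is not None and w.chrom == cur["chrom"] and sign == cur["sign"]
                and w.start - cur["end"] <= step):
            cur["end"] = max(cur["end"], w.end)
            cur["p"] = min(cur["p"], w.p_value)
            cur["q"] = min(cur["q"], w.q_value)
        else:
            if cur is not None:
                merged.append(cur)
            cur = {"chrom": w.chrom, "start": w.start, "end": w.end,
                   "sign": sign, "p": w.p_value, "q": w.q_value}
    merged.append(cur)

    rows = []
    for m in merged:
        sub = joined[joined["chrom"] == m["chrom"]]
        pos = sub["pos"].to_numpy(np.int64)
        lo, hi = np.searchsorted(pos, [m["start"], m["end"]])
        sl = sub.iloc[lo:hi]
        if refine_boundaries and hi - lo >= min_sites:
            diff = (sl["methylated_a"].to_numpy(float) / sl["coverage_a"].to_numpy(float)
                    - sl["methylated_b"].to_numpy(float) / sl["coverage_b"].to_numpy(float))
            i, j = _refine_segment(diff, m["sign"], delta_min)
            if j - i >= min_sites:
                sl = sl.iloc[i:j]
        ma, ca = sl["methylated_a"].sum(), sl["coverage_a"].sum()
        mb, cb = sl["methylated_b"].sum(), sl["coverage_b"].sum()
        delta = ma / ca - mb / cb
        if len(sl) < min_sites or abs(delta) < delta_min:
            continue
        start = int(sl["pos"].iloc[0])        # covered-site extent
        end = int(sl["pos"].iloc[-1]) + 1
        rows.append((m["chrom"], start, end, context, len(sl),
                     ma / ca, mb / cb, delta, m["p"], m["q"]))
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def _region_trees(genes: pd.DataFrame, promoter_bp: int):
    promoters: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        if g.strand == "+":
            pa, pb = max(g.start - promoter_bp, 0), g.start
        else:
            pa, pb = g.end, g.end + promoter_bp
        if pb > pa:
            promoters.setdefault(g.chrom, IntervalTree()).addi(pa, pb, g.gene_id)
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    return promoters, bodies


def annotate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame,
                  promoter_bp: int = 2000) -> pd.DataFrame:
    """Assign each DMR to promoter, gene_body or intergenic.

    Priority is promoter > gene_body > intergenic; any overlap of at least
    1 bp triggers the category. Returns a copy with an ``annotation`` column.
    """
    promoters, bodies = _region_trees(genes, promoter_bp)
    ann = []
    for d in dmrs.itertuples():
        if d.chrom in promoters and promoters[d.chrom].overlap(d.start, d.end):
            ann.append("promoter")
        elif d.chrom in bodies and bodies[d.chrom].overlap(d.start, d.end):
            ann.append("gene_body")
        else:
            ann.append("intergenic")
    out = dmrs.copy()
    out["annotation"] = ann
    return out


def dmr_gene_table(dmrs: pd.DataFrame, genes: pd.DataFrame,
                   promoter_bp: int = 2000) -> pd.DataFrame:
    """Per-gene summary of overlapping promoter/gene-body DMRs.

    One row per gene overlapped by at least one DMR in its promoter or body,
    with counts per context and direction (hyper: delta > 0 in sample A) and
    a total. Genes without DMR overlap are omitted.
    """
    promoters, bodies = _region_trees(genes, promoter_bp)
    counts: dict[str, dict[str, int]] = {}
    cols = [f"{ctx}_{d}" for ctx in ("CG", "CHG", "CHH") for d in ("hyper", "hypo")]
    for d in dmrs.itertuples():
        hits = set()
        for trees in (promoters, bodies):
            if d.chrom in trees:
                hits |= {iv.data for iv in trees[d.chrom].overlap(d.start, d.end)}
        direction = "hyper" if d.delta > 0 else "hypo"
        for gene_id in hits:
            row = counts.setdefault(gene_id, {c: 0 for c in cols})
            row[f"{d.context}_{direction}"] += 1
    if not counts:
        return pd.DataFrame(columns=["gene_id", *cols, "n_dmrs"])
    out = pd.DataFrame.from_dict(counts, orient="index")
    out.index.name = "gene_id"
    out["n_dmrs"] = out[cols].sum(axis=1)
    return out.reset_index().sort_values("gene_id").reset_index(drop=True)


def dmrs_to_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6+ (name=context, score=-log10 q, strand='.')."""
    bed = pd.DataFrame({
        "chrom": dmrs["chrom"], "start": dmrs["start"], "end": dmrs["end"],
        "name": dmrs["context"],
        "score": (-np.log10(np.maximum(dmrs["q_value"], 1e-300))).round(3),
        "strand": ".",
        "mean_a": dmrs["mean_a"].round(5), "mean_b": dmrs["mean_b"].round(5),
        "delta": dmrs["delta"].round(5), "n_sites": dmrs["n_sites"],
    })
    if "annotation" in dmrs.columns:
        bed["annotation"] = dmrs["annotation"]
    bed.to_csv(path, sep="\t", index=False, header=False)
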