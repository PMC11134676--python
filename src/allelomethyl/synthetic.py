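"""Self-contained two-haplotype simulator with machine-readable planted truth.

The generator emulates the statistical structure the downstream analysis
assumes for an allodiploid with two collinear haplotypes:

* two genomes with identical gene order (homologous gene sequences reused on
  both haplotypes, intergenic sequence drawn independently) and GFF3 gene
  annotations on both strands;
* per-cytosine methylation call tables per haplotype and tissue, with
  context-specific base levels (CG highest, then CHH, then CHG), beta-binomial
  read counts around region-level means, tissue differences, and planted
  differentially methylated regions (DMRs);
* a replicate TPM expression table with log-normal noise, a configurable
  fraction of allele pairs planted with at least two-fold divergence, and a
  negative coupling between promoter/body methylation and log expression;
* a homology anchor table (all true pairs plus decoy anchors) for the
  synteny stage; and
* a truth table recording every planted effect.

Coupling model: each pair carries a planted log2 expression ratio ``r``
(zero unless the pair is a planted DE pair), and the allelic promoter/body
methylation difference is derived from it as ``d = r / meth_expr_slope``, so
log expression decreases in methylation with exactly the configured slope and
a slope of zero decouples methylation from expression entirely.

Contexts are assigned from the actual simulated sequence (via the same
definition the context caller implements), so the caller can be validated
against an independent oracle on these genomes.
"""
from __future__ import annotations

import ast
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .methylome import CONTEXTS, REGIONS, classify_contexts

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PROPENSITY_CENTER = 0.45  # gene propensity equal to this leaves base levels unchanged

DEFAULT_CONTEXT_MEANS = {
    # plant-typical pattern: CG > CHH > CHG everywhere; first haplotype
    # slightly more methylated in flowers, second in leaves
    "MC": {"flower": {"CG": 0.62, "CHH": 0.33, "CHG": 0.22},
           "leaf": {"CG": 0.58, "CHH": 0.31, "CHG": 0.20}},
    "MM": {"flower": {"CG": 0.55, "CHH": 0.28, "CHG": 0.18},
           "leaf": {"CG": 0.62, "CHH": 0.33, "CHG": 0.22}},
}


@dataclass(frozen=True)
class DmrSpec:
    """One planted-DMR request: ``count`` intervals of ``length`` bp on
    ``haplotype`` where ``tissue_a`` minus ``tissue_b`` methylation is
    shifted by ``delta``."""
    haplotype: str = "MC"
    tissue_a: str = "flower"
    tissue_b: str = "leaf"
    count: int = 50
    length: int = 1000
    delta: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 300_000
    n_genes: int = 80
    gene_len_range: tuple[int, int] = (1000, 3000)
    flank: int = 2000
    haplotypes: tuple[str, str] = ("MC", "MM")
    tissues: tuple[str, ...] = ("flower", "leaf")
    context_means: dict = field(default_factory=lambda: DEFAULT_CONTEXT_MEANS)
    body_means: dict | None = None
    dmr_spec: tuple[DmrSpec, ...] = (DmrSpec(),)
    coverage_mean: float = 30.0
    n_replicates: int = 3
    de_fraction: float = 0.25
    meth_expr_slope: float = -6.0   # log2 TPM per unit methylation fraction
    tpm_sigma: float = 0.2          # log-normal replicate noise (natural log)
    meth_rho: float = 0.05          # beta-binomial overdispersion
    decoy_fraction: float = 0.1
    gene_jitter_sd: float = 0.03    # per gene x region x tissue level jitter
    gene_propensity_range: tuple[float, float] = (0.2, 0.55)
    silent_fraction: float = 0.1    # non-DE pairs silenced per tissue
    base_log2_tpm: float = np.log2(20.0)
    log2_tpm_sd: float = 1.0
    tissue_effect_sd: float = 0.3


@dataclass
class TruthTable:
    """Planted effects, written alongside the dataset as the oracle."""
    dmrs: pd.DataFrame         # chrom,start,end,haplotype,tissue_a,tissue_b,delta
    de_pairs: pd.DataFrame     # gene_a,gene_b,direction,log2_fold,meth_delta
    gene_levels: pd.DataFrame  # gene_id,haplotype,tissue,region,context,level
    params: dict


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: dict              # hap -> {chrom: sequence}
    genes: dict                # hap -> gene DataFrame
    methylation: dict          # (hap, tissue) -> calls DataFrame
    expression: pd.DataFrame
    anchors: pd.DataFrame
    truth: TruthTable


def _normalize_means(means, haplotypes, tissues) -> dict:
    """Accept {context: level} shorthand or the full nested mapping."""
    if means is None:
        return None
    if all(k in CONTEXTS for k in means):
        return {h: {t: dict(means) for t in tissues} for h in haplotypes}
    return means


def _validate(cfg: SimulationConfig, means, body_means):
    if cfg.n_chroms <= 0 or cfg.chrom_len <= 0 or cfg.n_genes <= 0:
        raise ValueError("n_chroms, chrom_len and n_genes must be positive")
    if cfg.gene_len_range[0] <= 0 or cfg.gene_len_range[0] > cfg.gene_len_range[1]:
        raise ValueError("invalid gene_len_range")
    if cfg.flank < 0 or cfg.coverage_mean <= 0 or cfg.n_replicates < 2:
        raise ValueError("flank/coverage_mean/n_replicates out of range")
    for frac in (cfg.de_fraction, cfg.decoy_fraction, cfg.silent_fraction, cfg.meth_rho):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    for m in (means, body_means):
        if m is None:
            continue
        for h in cfg.haplotypes:
            for t in cfg.tissues:
                for ctx in CONTEXTS:
                    v = m[h][t][ctx]
                    if not 0 <= v <= 1:
                        raise ValueError(f"context mean out of [0,1]: {h}/{t}/{ctx}={v}")
    for spec in cfg.dmr_spec:
        if spec.count < 0 or spec.length <= 0:
            raise ValueError("dmr_spec count/length must be positive")
        if spec.haplotype not in cfg.haplotypes or \
                {spec.tissue_a, spec.tissue_b} - set(cfg.tissues):
            raise ValueError("dmr_spec names unknown haplotype or tissue")
    genes_per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_len // genes_per_chrom
    if slot < cfg.gene_len_range[1] + 2 * cfg.flank + 2:
        raise ValueError(
            "chrom_len too small for n_genes with the requested gene lengths and flanks")


def _random_seq(rng, n) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset bundle and its truth table (in memory).

    Identical config and seed give byte-identical outputs when written with
    :func:`write_dataset`.
    """
    cfg = config
    means = _normalize_means(cfg.context_means, cfg.haplotypes, cfg.tissues)
    body_means = _normalize_means(cfg.body_means, cfg.haplotypes, cfg.tissues) or means
    _validate(cfg, means, body_means)
    rng = np.random.default_rng(cfg.seed)
    hap_a, hap_b = cfg.haplotypes

    # ---- gene plan: pair i sits at slot i // n_chroms on chrom i % n_chroms
    chrom_of = np.arange(cfg.n_genes) % cfg.n_chroms
    slot_of = np.arange(cfg.n_genes) // cfg.n_chroms
    genes_per_chrom = np.bincount(chrom_of, minlength=cfg.n_chroms)
    lengths = rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1, cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    gene_seqs = [_random_seq(rng, ln) for ln in lengths]

    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, pd.DataFrame] = {}
    for hap in cfg.haplotypes:
        chrom_seqs = {}
        rows = []
        for c in range(cfg.n_chroms):
            seq = _random_seq(rng, cfg.chrom_len)
            idx = np.flatnonzero(chrom_of == c)
            slot_w = cfg.chrom_len // genes_per_chrom[c]
            for i in idx:
                room = slot_w - lengths[i] - 2 * cfg.flank
                start = int(slot_of[i] * slot_w + cfg.flank + rng.integers(0, room + 1))
                seq[start:start + lengths[i]] = gene_seqs[i]
                rows.append((f"{hap}.g{i:04d}", f"{hap}_chr{c + 1}",
                             start, start + int(lengths[i]), strands[i]))
            chrom_seqs[f"{hap}_chr{c + 1}"] = seq.tobytes().decode("ascii")
        genomes[hap] = chrom_seqs
        genes[hap] = pd.DataFrame(rows, columns=io.GENE_COLUMNS) \
            .sort_values(["chrom", "start"]).reset_index(drop=True)

    # ---- anchors: every true pair, plus decoys with random partners
    true_scores = rng.uniform(200, 1000, cfg.n_genes)
    anchors = pd.DataFrame({
        "gene_a": [f"{hap_a}.g{i:04d}" for i in range(cfg.n_genes)],
        "gene_b": [f"{hap_b}.g{i:04d}" for i in range(cfg.n_genes)],
        "score": np.round(true_scores, 2),
    })
    n_decoys = int(round(cfg.decoy_fraction * cfg.n_genes))
    decoys = []
    while len(decoys) < n_decoys:
        ia = int(rng.integers(0, cfg.n_genes))
        ib = int(rng.integers(0, cfg.n_genes))
        if ib == ia:
            continue
        decoys.append((f"{hap_a}.g{ia:04d}", f"{hap_b}.g{ib:04d}",
                       round(float(rng.uniform(50, 400)), 2)))
    if decoys:
        anchors = pd.concat(
            [anchors, pd.DataFrame(decoys, columns=io.ANCHOR_COLUMNS)],
            ignore_index=True)
    anchors = anchors.drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True)

    # ---- expression plan and methylation coupling
    p0 = rng.uniform(*cfg.gene_propensity_range, cfg.n_genes)
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.permutation(cfg.n_genes)[:n_de]
    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[de_idx] = True
    r = np.zeros(cfg.n_genes)  # planted log2(A/B) expression ratio
    # planted folds sit clearly above the two-fold decision threshold
    # (2.3x-5.7x), so recovery measures the caller, not boundary noise
    r[de_idx] = rng.choice([-1.0, 1.0], n_de) * rng.uniform(1.2, 2.5, n_de)
    d = r / cfg.meth_expr_slope if cfg.meth_expr_slope != 0 else np.zeros(cfg.n_genes)
    prop = {hap_a: np.clip(p0 + d / 2, 0.05, 0.9),
            hap_b: np.clip(p0 - d / 2, 0.05, 0.9)}

    # per gene x region x tissue level jitter, independent per haplotype
    jitter = {hap: rng.normal(0.0, cfg.gene_jitter_sd,
                              (cfg.n_genes, len(REGIONS), len(cfg.tissues)))
              for hap in cfg.haplotypes}

    # ---- planted DMR intervals (non-overlapping, >= 2 kb apart per haplotype)
    dmr_rows = []
    placed: dict[str, list[tuple[str, int, int]]] = {h: [] for h in cfg.haplotypes}
    for spec in cfg.dmr_spec:
        n_placed = 0
        tries = 0
        while n_placed < spec.count:
            tries += 1
            if tries > 100 * max(spec.count, 1):
                raise ValueError("cannot place requested DMRs; genome too small")
            c = int(rng.integers(0, cfg.n_chroms))
            chrom = f"{spec.haplotype}_chr{c + 1}"
            start = int(rng.integers(0, cfg.chrom_len - spec.length))
            end = start + spec.length
            if any(ch == chrom and start < e + 2000 and end > s - 2000
                   for ch, s, e in placed[spec.haplotype]):
                continue
            placed[spec.haplotype].append((chrom, start, end))
            dmr_rows.append((chrom, start, end, spec.haplotype,
                             spec.tissue_a, spec.tissue_b, spec.delta))
            n_placed += 1
    truth_dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "haplotype",
                           "tissue_a", "tissue_b", "delta"])

    # ---- methylation calls per haplotype x tissue
    methylation: dict[tuple[str, str], pd.DataFrame] = {}
    region_code = {r: k for k, r in enumerate(REGIONS)}
    for hap in cfg.haplotypes:
        sites = classify_contexts(genomes[hap])
        sites = sites[sites["context"].isin(CONTEXTS)].reset_index(drop=True)
        ctx_code = sites["context"].map({c: k for k, c in enumerate(CONTEXTS)}).to_numpy()

        # map each site to (gene index, region code) or intergenic (-1)
        gene_idx = np.full(len(sites), -1)
        reg_idx = np.full(len(sites), -1)
        gdf = genes[hap]
        gene_num = gdf["gene_id"].str.slice(-4).astype(int).to_numpy()
        for chrom, sub in sites.groupby("chrom", sort=False):
            gsub = gdf[gdf["chrom"] == chrom]
            ivals = []
            for gi, g in zip(gene_num[gdf["chrom"] == chrom], gsub.itertuples()):
                if g.strand == "+":
                    spans = {"upstream": (g.start - cfg.flank, g.start),
                             "body": (g.start, g.end),
                             "downstream": (g.end, g.end + cfg.flank)}
                else:
                    spans = {"upstream": (g.end, g.end + cfg.flank),
                             "body": (g.start, g.end),
                             "downstream": (g.start - cfg.flank, g.start)}
                for rname, (a, b) in spans.items():
                    ivals.append((max(a, 0), b, gi, region_code[rname]))
            ivals.sort()
            starts = np.array([v[0] for v in ivals])
            ends = np.array([v[1] for v in ivals])
            gis = np.array([v[2] for v in ivals])
            rcs = np.array([v[3] for v in ivals])
            pos = sub["pos"].to_numpy()
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & (pos < ends[np.maximum(k, 0)])
            rows_here = sub.index.to_numpy()
            gene_idx[rows_here[ok]] = gis[k[ok]]
            reg_idx[rows_here[ok]] = rcs[k[ok]]

        genic = gene_idx >= 0
        coupled = genic & (reg_idx < 2)  # upstream and body carry the coupling
        levels = {}
        for ti, tissue in enumerate(cfg.tissues):
            base_cg = means[hap][tissue]["CG"]
            base = np.array([means[hap][tissue][c] for c in CONTEXTS])[ctx_code]
            bodyb = np.array([body_means[hap][tissue][c] for c in CONTEXTS])[ctx_code]
            lv = base.copy()
            body_sites = genic & (reg_idx == 1)
            lv[body_sites] = bodyb[body_sites]
            p_eff = np.full(len(sites), _PROPENSITY_CENTER)
            p_eff[coupled] = prop[hap][gene_idx[coupled]]
            p_eff[genic] += jitter[hap][gene_idx[genic], reg_idx[genic], ti]
            lv[genic] *= 1.0 + (p_eff[genic] - _PROPENSITY_CENTER) / base_cg
            levels[tissue] = np.clip(lv, 0.02, 0.98)

        # plant DMRs: recentre the tissue pair, preserving the exact delta
        pos_arr = sites["pos"].to_numpy()
        chrom_arr = sites["chrom"].to_numpy()
        for t in truth_dmrs[truth_dmrs["haplotype"] == hap].itertuples():
            mask = (chrom_arr == t.chrom) & (pos_arr >= t.start) & (pos_arr < t.end)
            la, lb = levels[t.tissue_a][mask], levels[t.tissue_b][mask]
            mid = (la + lb) / 2.0
            la, lb = mid + t.delta / 2.0, mid - t.delta / 2.0
            over = np.maximum(np.maximum(la, lb) - 0.98, 0.0)
            under = np.maximum(0.02 - np.minimum(la, lb), 0.0)
            levels[t.tissue_a][mask] = la - over + under
            levels[t.tissue_b][mask] = lb - over + under

        for tissue in cfg.tissues:
            lv = levels[tissue]
            cov = rng.poisson(cfg.coverage_mean, len(sites))
            if cfg.meth_rho > 0:
                k = (1.0 - cfg.meth_rho) / cfg.meth_rho
                pv = rng.beta(lv * k, (1.0 - lv) * k)
            else:
                pv = lv
            meth = rng.binomial(cov, pv)
            calls = sites.copy()
            calls["coverage"] = cov
            calls["methylated"] = meth
            methylation[(hap, tissue)] = calls[io.METHYLATION_COLUMNS]

    # ---- truth: per-gene region levels by context and tissue
    gl_rows = []
    for hap in cfg.haplotypes:
        for i in range(cfg.n_genes):
            for ri, region in enumerate(REGIONS):
                p_eff_base = prop[hap][i] if region != "downstream" else _PROPENSITY_CENTER
                for ti, tissue in enumerate(cfg.tissues):
                    base_cg = means[hap][tissue]["CG"]
                    src = body_means if region == "body" else means
                    p_eff = p_eff_base + jitter[hap][i, ri, ti]
                    for ctx in CONTEXTS:
                        lv = src[hap][tissue][ctx] * (
                            1.0 + (p_eff - _PROPENSITY_CENTER) / base_cg)
                        gl_rows.append((f"{hap}.g{i:04d}", hap, tissue, region, ctx,
                                        float(np.clip(lv, 0.02, 0.98))))
    gene_levels = pd.DataFrame(
        gl_rows, columns=["gene_id", "haplotype", "tissue", "region", "context", "level"])

    # ---- expression
    b = rng.normal(cfg.base_log2_tpm, cfg.log2_tpm_sd, cfg.n_genes)
    t_eff = rng.normal(0.0, cfg.tissue_effect_sd, (cfg.n_genes, len(cfg.tissues)))
    silent = (rng.random((cfg.n_genes, len(cfg.tissues))) < cfg.silent_fraction) & \
        ~planted[:, None]
    expr_rows = []
    for ti, tissue in enumerate(cfg.tissues):
        for hap, sign in ((hap_a, 0.5), (hap_b, -0.5)):
            mu = b + t_eff[:, ti] + sign * r
            for rep in range(1, cfg.n_replicates + 1):
                tpm = np.exp2(mu) * np.exp(rng.normal(0.0, cfg.tpm_sigma, cfg.n_genes))
                tpm = np.where(silent[:, ti], 0.0, tpm)
                expr_rows.append(pd.DataFrame({
                    "gene_id": [f"{hap}.g{i:04d}" for i in range(cfg.n_genes)],
                    "tissue": tissue, "replicate": rep, "tpm": tpm}))
    expression = pd.concat(expr_rows, ignore_index=True)

    de_pairs = pd.DataFrame({
        "gene_a": [f"{hap_a}.g{i:04d}" for i in sorted(de_idx)],
        "gene_b": [f"{hap_b}.g{i:04d}" for i in sorted(de_idx)],
        "direction": ["A_high" if r[i] > 0 else "B_high" for i in sorted(de_idx)],
        "log2_fold": [abs(float(r[i])) for i in sorted(de_idx)],
        "meth_delta": [float(prop[hap_a][i] - prop[hap_b][i]) for i in sorted(de_idx)],
    })

    truth = TruthTable(
        dmrs=truth_dmrs, de_pairs=de_pairs, gene_levels=gene_levels,
        params={"seed": cfg.seed, "meth_expr_slope": cfg.meth_expr_slope,
                "de_fraction": cfg.de_fraction, "coverage_mean": cfg.coverage_mean},
    )
    return SyntheticDataset(config=cfg, genomes=genomes, genes=genes,
                            methylation=methylation, expression=expression,
                            anchors=anchors, truth=truth)


# ---------------------------------------------------------------- truth I/O

_TRUTH_COLUMNS = ["record_type", "chrom", "start", "end", "haplotype",
                  "tissue_a", "tissue_b", "delta", "gene_a", "gene_b",
                  "direction", "log2_fold", "meth_delta", "gene_id", "tissue",
                  "region", "context", "level", "key", "value"]


def write_truth(truth: TruthTable, path) -> None:
    """Write the truth table as a single TSV (one row per planted record)."""
    parts = []
    for rtype, df in (("dmr", truth.dmrs), ("de_pair", truth.de_pairs),
                      ("gene_level", truth.gene_levels)):
        if len(df):
            part = df.copy()
            part.insert(0, "record_type", rtype)
            parts.append(part)
    if truth.params:
        parts.append(pd.DataFrame({
            "record_type": "param",
            "key": list(truth.params),
            "value": [repr(v) for v in truth.params.values()]}))
    if parts:
        out = pd.concat(parts, ignore_index=True).reindex(columns=_TRUTH_COLUMNS)
    else:
        out = pd.DataFrame(columns=_TRUTH_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    raw = pd.read_csv(path, sep="\t", dtype={"value": str})
    def take(rtype, cols, ints=()):
        sub = raw[raw["record_type"] == rtype][cols].reset_index(drop=True)
        for c in ints:
            sub[c] = sub[c].astype(np.int64)
        return sub
    dmrs = take("dmr", ["chrom", "start", "end", "haplotype", "tissue_a",
                        "tissue_b", "delta"], ints=("start", "end"))
    de_pairs = take("de_pair", ["gene_a", "gene_b", "direction", "log2_fold",
                                "meth_delta"])
    gene_levels = take("gene_level", ["gene_id", "haplotype", "tissue",
                                      "region", "context", "level"])
    prm = raw[raw["record_type"] == "param"]
    params = {k: ast.literal_eval(v)  # values written with repr()
              for k, v in zip(prm["key"], prm["value"])}
    return TruthTable(dmrs=dmrs, de_pairs=de_pairs, gene_levels=gene_levels,
                      params=params)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the full bundle; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for hap in ds.config.haplotypes:
        paths[f"fasta_{hap}"] = str(outdir / f"genome_{hap}.fasta")
        io.write_fasta(ds.genomes[hap], paths[f"fasta_{hap}"])
        paths[f"gff_{hap}"] = str(outdir / f"genes_{hap}.gff3")
        io.write_gff3(ds.genes[hap], paths[f"gff_{hap}"])
        for tissue in ds.config.tissues:
            key = f"methylation_{hap}_{tissue}"
            paths[key] = str(outdir / f"{key}.tsv")
            io.write_methylation(ds.methylation[(hap, tissue)], paths[key])
    paths["expression"] = str(outdir / "expression.tsv")
    io.write_expression(ds.expression, paths["expression"])
    paths["anchors"] = str(outdir / "anchors.tsv")
    io.write_anchors(ds.anchors, paths["anchors"])
    paths["truth"] = str(outdir / "truth.tsv")
    write_truth(ds.truth, paths["truth"])
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from plain data (e.g. parsed YAML)."""
    d = dict(d)
    if "dmr_spec" in d:
        d["dmr_spec"] = tuple(
            s if isinstance(s, DmrSpec) else DmrSpec(**s) for s in d["dmr_spec"])
    for key in ("gene_len_range", "haplotypes", "tissues", "gene_propensity_range"):
        if key in d:
            d[key] = tuple(d[key])
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**d)
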