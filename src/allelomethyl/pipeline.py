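"""Pipeline orchestration: structured config, logging and run manifests.

A YAML config names the input files (two genomes, two gene annotations,
per-haplotype/tissue methylation call tables, an expression table and an
anchor table) and per-stage parameter blocks mirroring each module's
defaults. ``run_pipeline`` executes the stages in order

    contexts -> profile -> dmr -> pairs -> allelediff -> integrate

writing each stage's outputs as TSV plus a JSON manifest entry (parameters,
input checksums, output row counts). Stage outputs are pure functions of the
inputs, parameters and seed, so a rerun with an identical config reproduces
identical bytes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import alleles, dmr, expression, integration, io, methylome

log = logging.getLogger("allelomethyl")

STAGES = ("contexts", "profile", "dmr", "pairs", "allelediff", "integrate")

DEFAULT_PARAMS = {
    "flank": 2000,
    "min_cov": 4,
    "profile": {"flank_bins": 20, "body_bins": 40},
    "dmr": {"window": 1000, "step": 500, "min_sites": 5, "delta_min": 0.1,
            "alpha": 0.05, "promoter_bp": 2000,
            "contrast": {"haplotype": None, "tissue_a": None, "tissue_b": None}},
    "alleles": {"min_anchors": 5, "max_gap": 25},
    "expression": {"fold": 2.0, "pseudo": 0.1, "expressed_min": 0.0},
}


class PipelineError(RuntimeError):
    pass


def _merge(defaults, override):
    out = dict(defaults)
    for k, v in (override or {}).items():
        out[k] = _merge(out[k], v) if isinstance(v, dict) and isinstance(out.get(k), dict) else v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg, base=Path(path).parent)


def validate_config(cfg: dict, base: Path | None = None) -> dict:
    """Resolve paths, fill parameter defaults and check inputs exist."""
    cfg = dict(cfg)
    base = Path(base or ".")
    inputs = cfg.get("inputs", {})
    haps = list(inputs.get("methylation", {}))
    if len(haps) != 2:
        raise PipelineError("config must name methylation tables for exactly two haplotypes")
    resolved = {}
    flat_paths = []
    for key in ("fasta", "gff"):
        resolved[key] = {h: str(base / inputs[key][h]) for h in haps}
        flat_paths += list(resolved[key].values())
    resolved["methylation"] = {
        h: {t: str(base / p) for t, p in inputs["methylation"][h].items()} for h in haps}
    for h in haps:
        flat_paths += list(resolved["methylation"][h].values())
    for key in ("expression", "anchors"):
        resolved[key] = str(base / inputs[key])
        flat_paths.append(resolved[key])
    missing = [p for p in flat_paths if not Path(p).exists()]
    if missing:
        raise PipelineError(f"missing input files: {missing}")

    params = _merge(DEFAULT_PARAMS, cfg.get("params"))
    contrast = params["dmr"]["contrast"]
    tissues = sorted(next(iter(resolved["methylation"].values())))
    contrast.setdefault("haplotype", None)
    if contrast["haplotype"] is None:
        contrast["haplotype"] = haps[0]
    if contrast["tissue_a"] is None or contrast["tissue_b"] is None:
        if len(tissues) < 2:
            raise PipelineError("dmr contrast needs two tissues or an explicit contrast")
        contrast["tissue_a"], contrast["tissue_b"] = tissues[0], tissues[1]
    cfg["inputs_resolved"] = resolved
    cfg["params"] = params
    cfg["haplotypes"] = haps
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "results")
    cfg["outdir"] = str(base / cfg["outdir"])
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    ``config`` is a validated config dict or a path to a YAML file. A stage
    failure halts the run with the failing stage named; the manifest marks
    the run incomplete.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    elif "inputs_resolved" not in config:
        config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs_resolved"]
    params = config["params"]
    haps = config["haplotypes"]
    manifest = {"seed": config["seed"], "stages": [], "complete": False,
                "input_checksums": {}}

    def record(stage, stage_params, outputs):
        entry = {"stage": stage, "params": stage_params,
                 "outputs": {name: {"path": str(Path(p).name), "rows": int(rows)}
                             for name, (p, rows) in outputs.items()}}
        manifest["stages"].append(entry)
        log.info("stage %s complete (%d outputs)", stage, len(outputs))

    def save(df: pd.DataFrame, name: str):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path, len(df)

    current = "(setup)"
    try:
        for group in inputs.values():
            if isinstance(group, str):
                manifest["input_checksums"][group] = _sha256(group)
            else:
                for v in group.values():
                    if isinstance(v, str):
                        manifest["input_checksums"][v] = _sha256(v)
                    else:
                        for p in v.values():
                            manifest["input_checksums"][p] = _sha256(p)

        # stage 1: contexts ------------------------------------------------
        current = "contexts"
        genomes = {h: io.read_fasta(inputs["fasta"][h]) for h in haps}
        genes = {h: io.read_gff3(inputs["gff"][h]) for h in haps}
        sites = {h: methylome.classify_contexts(genomes[h]) for h in haps}
        calls = {}
        rejected = {}
        for h in haps:
            for t, path in inputs["methylation"][h].items():
                calls[(h, t)], rejected[f"{h}/{t}"] = methylome.load_calls(path, sites[h])
        ctx_counts = pd.concat(
            [sites[h].assign(haplotype=h) for h in haps]
        ).groupby(["haplotype", "context"]).size().rename("n_sites").reset_index()
        record("contexts", {"rejected_rows": rejected},
               {"context_counts": save(ctx_counts, "context_counts")})

        # stage 2: profile -------------------------------------------------
        current = "profile"
        flank, min_cov = params["flank"], params["min_cov"]
        levels = {}
        profiles = []
        level_frames = []
        for (h, t), c in calls.items():
            lv = methylome.region_levels(c, genes[h], flank=flank, min_cov=min_cov)
            lv.insert(0, "haplotype", h)
            lv.insert(1, "tissue", t)
            levels[(h, t)] = lv
            level_frames.append(lv)
            prof = methylome.metaprofile(c, genes[h], flank=flank,
                                         min_cov=min_cov, **params["profile"])
            prof.insert(0, "haplotype", h)
            prof.insert(1, "tissue", t)
            profiles.append(prof)
        region_levels_all = pd.concat(level_frames, ignore_index=True)
        record("profile", {"flank": flank, "min_cov": min_cov, **params["profile"]},
               {"region_levels": save(region_levels_all, "region_levels"),
                "metaprofiles": save(pd.concat(profiles, ignore_index=True),
                                     "metaprofiles")})

        # stage 3: dmr -----------------------------------------------------
        current = "dmr"
        dp = params["dmr"]
        ct = dp["contrast"]
        ca = calls[(ct["haplotype"], ct["tissue_a"])]
        cb = calls[(ct["haplotype"], ct["tissue_b"])]
        dmr_frames = []
        for context in methylome.CONTEXTS:
            d = dmr.call_dmrs(ca, cb, context, window=dp["window"], step=dp["step"],
                              min_sites=dp["min_sites"], min_cov=min_cov,
                              delta_min=dp["delta_min"], alpha=dp["alpha"])
            dmr_frames.append(d)
        dmrs = pd.concat(dmr_frames, ignore_index=True)
        dmrs = dmr.annotate_dmrs(dmrs, genes[ct["haplotype"]],
                                 promoter_bp=dp["promoter_bp"])
        gene_table = dmr.dmr_gene_table(dmrs, genes[ct["haplotype"]],
                                        promoter_bp=dp["promoter_bp"])
        record("dmr", dp, {"dmrs": save(dmrs, "dmrs"),
                           "dmr_genes": save(gene_table, "dmr_genes")})

        # stage 4: pairs ---------------------------------------------------
        current = "pairs"
        anchors = io.read_anchors(inputs["anchors"])
        blocks, members = alleles.chain_anchors(
            anchors, genes[haps[0]], genes[haps[1]], **params["alleles"])
        pairs = alleles.call_allele_pairs(blocks, members)
        record("pairs", params["alleles"],
               {"blocks": save(blocks, "blocks"), "pairs": save(pairs, "pairs")})

        # stage 5: allelediff ----------------------------------------------
        current = "allelediff"
        expr = io.read_expression(inputs["expression"])
        retained, filter_report = expression.filter_genes(expr)
        expr_f = expr[expr["gene_id"].isin(retained)]
        ep = params["expression"]
        tissues = sorted(expr["tissue"].unique())
        de_frames = [expression.call_allelic_de(pairs, expr_f, t, **ep)
                     for t in tissues]
        de_calls = pd.concat(de_frames, ignore_index=True)
        record("allelediff", ep,
               {"filter_report": save(filter_report, "filter_report"),
                "allelic_de": save(de_calls, "allelic_de")})

        # stage 6: integrate -------------------------------------------------
        current = "integrate"
        la = pd.concat([levels[(haps[0], t)] for t in inputs["methylation"][haps[0]]],
                       ignore_index=True)
        lb = pd.concat([levels[(haps[1], t)] for t in inputs["methylation"][haps[1]]],
                       ignore_index=True)
        records_df, summary = integration.integrate(de_calls, la, lb)
        record("integrate", {},
               {"integration_records": save(records_df, "integration_records"),
                "integration_summary": save(summary, "integration_summary")})
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
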