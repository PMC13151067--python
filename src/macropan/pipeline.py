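"""End-to-end orchestration: simulate → ingest → enrichment → features →
kinetics → report, driven by one structured YAML config.

Every run writes its tables with a comment header carrying the seed and a
hash of the config snapshot, plus a ``manifest.json`` recording inputs,
per-stage row counts and the package version — enough to reproduce the run
byte-for-byte for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    abundance_scatter,
    consensus_hits,
    diversity_profile,
    validate_pool_table,
    venn_regions,
    write_pool_table,
)
from .features import default_scales, descriptor_table, embed_and_cluster
from .ingest import DemuxSheet, ingest_fastq
from .kinetics import classify_alascan, fit_global_1to1, sensorgrams_from_frame
from .schema import LibrarySchema, acrk_10mer_schema, camcbt_12mer_schema
from .simulate import default_config, run_campaign, write_fastq

__all__ = ["ConfigError", "load_config", "run_pipeline", "write_report"]

_BUILTIN_SCHEMAS = {
    "acrk-10mer": acrk_10mer_schema,
    "camcbt-12mer": camcbt_12mer_schema,
}

_DEFAULTS = {
    "seed": 0,
    "outdir": "macropan-run",
    "schema": "camcbt-12mer",
    "simulate": {
        "enabled": True,
        "n_clones": 2000,
        "n_binders": 5,
        "depth": 20000,
        "emit": "fastq",
    },
    "ingest": {"min_quality": 20.0, "flank_mismatch": 0},
    "enrichment": {"consensus_threshold": 1e-3, "top_n": 100},
    "features": {"method": "pca", "ph": 7.0, "eps": 0.5, "min_samples": 5},
    "kinetics": {"sensorgrams": None, "alascan": None},
    "plots": True,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


def load_config(source) -> dict:
    """Load and validate a pipeline config (path, YAML string or dict).

    Unknown keys and out-of-range values are collected and reported
    together, so one pass shows every problem.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if path.exists():
            raw = yaml.safe_load(path.read_text()) or {}
        else:
            raise ConfigError(f"config file not found: {source}")

    config = json.loads(json.dumps(_DEFAULTS))  # deep copy
    errors: list[str] = []
    for key, value in raw.items():
        if key not in config:
            errors.append(f"unknown config key {key!r}")
            continue
        if isinstance(config[key], dict):
            if not isinstance(value, dict):
                errors.append(f"{key} must be a mapping")
                continue
            for sub, sub_value in value.items():
                if sub not in config[key]:
                    errors.append(f"unknown config key {key}.{sub}")
                else:
                    config[key][sub] = sub_value
        else:
            config[key] = value

    if config["schema"] not in _BUILTIN_SCHEMAS and not Path(str(config["schema"])).exists():
        errors.append(f"schema {config['schema']!r} is neither built-in nor a file")
    sim = config["simulate"]
    if sim["enabled"]:
        if int(sim["n_clones"]) <= 0:
            errors.append("simulate.n_clones must be positive")
        if int(sim["depth"]) <= 0:
            errors.append("simulate.depth must be positive")
        if sim["emit"] not in ("fastq", "counts"):
            errors.append("simulate.emit must be 'fastq' or 'counts'")
    if not 0 <= float(config["ingest"]["min_quality"]) <= 41:
        errors.append("ingest.min_quality must lie in [0, 41]")
    if config["ingest"]["flank_mismatch"] not in (0, 1):
        errors.append("ingest.flank_mismatch must be 0 or 1")
    if config["features"]["method"] not in ("pca", "umap"):
        errors.append("features.method must be 'pca' or 'umap'")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return config


def _resolve_schema(name: str) -> LibrarySchema:
    if name in _BUILTIN_SCHEMAS:
        return _BUILTIN_SCHEMAS[name]()
    return LibrarySchema.from_yaml(name)


def _config_hash(config: dict) -> str:
    # outdir is run placement, not an analysis setting
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(source, outdir: str | Path | None = None) -> Path:
    """Execute every configured stage in dependency order.

    Returns the output directory; raises with the failing stage named.
    The manifest is written last, so its presence marks a complete run.
    """
    config = load_config(source)
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = _config_hash(config)
    header = [f"seed={seed}", f"config_hash={chash}"]
    schema = _resolve_schema(config["schema"])
    manifest: dict = {
        "config": config,
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "stages": {},
        "inputs": {},
    }

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    sim_cfg = config["simulate"]
    table = None
    result = None
    if sim_cfg["enabled"]:
        sim = default_config(
            seed=seed,
            schema=schema,
            n_clones=int(sim_cfg["n_clones"]),
            n_binders=int(sim_cfg["n_binders"]),
        )
        for rounds in sim.campaigns.values():
            for i, spec in enumerate(rounds):
                rounds[i] = type(spec)(**{**spec.__dict__, "depth": int(sim_cfg["depth"])})
        result = run_campaign(sim, emit=sim_cfg["emit"])
        manifest["stages"][stage] = {"clones": len(result.naive_pool)}
        result.manifest.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        result.demux_sheet().to_csv(outdir / "demux_sheet.tsv", sep="\t", index=False)
        if sim_cfg["emit"] == "fastq":
            fastq_dir = outdir / "fastq"
            fastq_dir.mkdir(exist_ok=True)
            for (strategy, rnd), records in result.reads.items():
                write_fastq(records, fastq_dir / f"{strategy}_r{rnd}.fastq")

    # --- ingest -----------------------------------------------------------
    stage = "ingest"
    if result is not None and sim_cfg["emit"] == "fastq":
        sheet = DemuxSheet.from_frame(result.demux_sheet())
        reads = [rec for records in result.reads.values() for rec in records]
        table, stats = ingest_fastq(
            reads,
            schema,
            sheet,
            min_quality=float(config["ingest"]["min_quality"]),
            flank_mismatch=int(config["ingest"]["flank_mismatch"]),
        )
        stats.to_frame().to_csv(outdir / "ingest_stats.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"reads": stats.total, "kept": stats.kept}
    elif result is not None:
        table = result.pool_table()
        manifest["stages"][stage] = {"rows": len(table), "mode": "counts"}
    else:
        raise ConfigError("stage ingest: no input (simulation disabled, no FASTQ)")
    validate_pool_table(table)
    write_pool_table(table, outdir / "pool_table.tsv", header)
    manifest["inputs"]["pool_table"] = _sha256(outdir / "pool_table.tsv")

    # --- enrichment -------------------------------------------------------
    stage = "enrichment"
    strategies = sorted(table["strategy"].unique())
    final_rounds = {s: int(table[table.strategy == s]["round"].max()) for s in strategies}
    profiles = {
        f"{s} r{final_rounds[s]}": diversity_profile(table, s, final_rounds[s])
        for s in strategies
    }
    peptide_sets = {
        s: set(table[(table.strategy == s) & (table["round"] == final_rounds[s])].peptide)
        for s in strategies[:3]
    }
    overlap = venn_regions(
        peptide_sets, table, {s: (s, final_rounds[s]) for s in peptide_sets}
    )
    overlap.to_frame().to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
    consensus = consensus_hits(
        table,
        strategies,
        final_rounds,
        threshold=float(config["enrichment"]["consensus_threshold"]),
    )
    consensus.to_csv(outdir / "consensus_hits.tsv", sep="\t", index=False)
    manifest["stages"][stage] = {
        "strategies": strategies,
        "consensus_candidates": len(consensus),
    }

    # --- features ---------------------------------------------------------
    stage = "features"
    feat_cfg = config["features"]
    top_n = int(config["enrichment"]["top_n"])
    top_peptides: list[str] = []
    for s in strategies:
        prof = profiles[f"{s} r{final_rounds[s]}"]
        top_peptides.extend(prof["peptide"].head(top_n))
    top_peptides = sorted(set(top_peptides))
    embedding = None
    if len(top_peptides) >= 5:
        desc = descriptor_table(top_peptides, default_scales(), ph=float(feat_cfg["ph"]))
        desc.to_csv(outdir / "descriptors.tsv", sep="\t")
        embedding = embed_and_cluster(
            desc,
            method=feat_cfg["method"],
            seed=seed,
            eps=float(feat_cfg["eps"]),
            min_samples=int(feat_cfg["min_samples"]),
        )
        embedding.coordinates.to_csv(outdir / "embedding.tsv", sep="\t")
        manifest["stages"][stage] = {
            "peptides": len(top_peptides),
            "clusters": int(embedding.coordinates.cluster.max() + 1),
        }

    # --- kinetics (optional) ---------------------------------------------
    stage = "kinetics"
    kin_cfg = config["kinetics"]
    fit = None
    if kin_cfg["sensorgrams"]:
        frame = pd.read_csv(kin_cfg["sensorgrams"])
        manifest["inputs"]["sensorgrams"] = _sha256(Path(kin_cfg["sensorgrams"]))
        fit = fit_global_1to1(sensorgrams_from_frame(frame))
        pd.DataFrame(
            [
                {
                    "k_on": fit.k_on,
                    "k_off": fit.k_off,
                    "k_d": fit.k_d,
                    "r_max": fit.r_max,
                    "rmse": fit.rmse,
                    "converged": fit.converged,
                }
            ]
        ).to_csv(outdir / "kinetic_fit.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"k_d": fit.k_d, "converged": fit.converged}
    if kin_cfg["alascan"]:
        scan = pd.read_csv(kin_cfg["alascan"], sep="\t")
        parent = float(scan[scan.variant == "parent"].k_d.iloc[0])
        variants = {
            row.variant: float(row.k_d)
            for row in scan.itertuples()
            if row.variant != "parent"
        }
        classify_alascan(parent, variants).to_csv(
            outdir / "alascan_classes.tsv", sep="\t", index=False
        )

    # --- plots & report ---------------------------------------------------
    if config["plots"]:
        from . import plots

        plots.rank_abundance_plot(profiles, outdir / "rank_abundance.png")
        plots.venn_plot(overlap, outdir / "venn.png")
        if len(strategies) >= 2:
            sx, sy = strategies[0], strategies[1]
            pairs = abundance_scatter(table, (sx, final_rounds[sx]), (sy, final_rounds[sy]))
            plots.scatter_plot(pairs, outdir / "scatter.png", sx, sy)
        if embedding is not None:
            plots.embedding_plot(embedding.coordinates, outdir / "embedding.png")

    write_report(outdir, profiles, overlap, consensus, fit)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def write_report(
    outdir: Path,
    profiles: dict[str, pd.DataFrame],
    overlap,
    consensus: pd.DataFrame,
    fit=None,
) -> Path:
    """Assemble a human-readable Markdown summary of a run.

    Missing stages appear as explicit gaps rather than being omitted.
    """
    lines = ["# Selection campaign report", ""]
    lines.append("## Diversity")
    for label, prof in profiles.items():
        k = min(4, len(prof))
        lines.append(
            f"- {label}: {len(prof)} unique peptides; top-{k} fraction "
            f"{prof.cumulative_fraction.iloc[k - 1]:.1%}"
        )
    lines.append("")
    lines.append("## Overlap")
    for region in overlap.regions:
        frac = (
            f", {region.abundance_fraction:.1%} of pooled reads"
            if np.isfinite(region.abundance_fraction)
            else ""
        )
        lines.append(
            f"- {' & '.join(sorted(region.members_of))}: {region.size} peptides{frac}"
        )
    lines.append("")
    lines.append("## Consensus hits")
    if consensus.empty:
        lines.append("No peptide exceeded the consensus threshold.")
    else:
        top = consensus[~consensus.strategy_restricted].head(10)
        for row in top.itertuples():
            lines.append(
                f"- rank {row.consensus_rank}: `{row.peptide}` "
                f"(mean frequency {row.mean_frequency:.2%})"
            )
        n_flagged = int(consensus.strategy_restricted.sum())
        lines.append(f"- strategy-restricted (parasite-suspect) peptides: {n_flagged}")
    lines.append("")
    lines.append("## Kinetics")
    if fit is None:
        lines.append("No sensorgrams provided; kinetics section empty.")
    else:
        lines.append(
            f"- global 1:1 fit: k_on={fit.k_on:.3g} 1/(M s), k_off={fit.k_off:.3g} 1/s, "
            f"K_D={fit.k_d * 1e9:.1f} nM, RMSE={fit.rmse:.3g} nm"
        )
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
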