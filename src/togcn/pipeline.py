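"""End-to-end runs: normalize -> filter -> TO-GCN per condition -> compare
-> level sets -> enrichment, driven by one validated config and one seed.

Every artifact is written through the io module and listed in a manifest
JSON with a SHA-256 content hash, so a rerun with the same config and
seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import compare as compare_mod
from . import io, levelsets, network, preprocess
from .datatypes import ExpressionMatrix
from .errors import ConfigError, PipelineError

log = logging.getLogger("togcn")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    expression: str
    samples: str
    tf_list: str
    out_dir: str
    unit: str = "TPM"
    gene_lengths: str | None = None
    gmt: str | None = None
    condition_a: str = "embryonic"
    condition_b: str = "juvenile"
    seed_gene_a: str | None = None
    seed_gene_b: str | None = None
    fixed_cutoff_a: float | None = None
    fixed_cutoff_b: float | None = None
    alpha: float = 0.05
    n_permutations: int = 2000
    tpm_threshold: float = 1.0
    filter_scope: str = "global"       # "global" | "per-condition"
    normalization: str = "uq"          # "uq" | "none"
    replicate_mode: str = "mean"       # "mean" | "all"
    t: int = 3
    enrich_alpha: float = 0.05
    fdr_family: str = "per-level"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_scope not in ("global", "per-condition"):
            raise ConfigError(f"unknown filter_scope {self.filter_scope!r}")
        if self.normalization not in ("uq", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.replicate_mode not in ("mean", "all"):
            raise ConfigError(f"unknown replicate_mode {self.replicate_mode!r}")
        if self.unit == "counts" and not self.gene_lengths:
            raise ConfigError("counts input requires gene_lengths for TPM computation")
        for name in ("expression", "samples", "tf_list", "gmt", "gene_lengths"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = [k for k in ("expression", "samples", "tf_list", "out_dir") if k not in d]
        if missing:
            raise ConfigError(f"config missing required key(s): {missing}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@dataclass
class _ConditionRun:
    name: str
    togcn: network.TOGCN
    profiles: pd.DataFrame
    zscores: pd.DataFrame
    cutoff: network.CoexpressionCutoff
    seed_suggested: bool


def _build_condition(
    cfg: RunConfig, mat: ExpressionMatrix, samples, condition: str,
    fixed_cutoff: float | None, seed_gene: str | None, tfs: set[str], rng_seed: int,
) -> _ConditionRun:
    samples.require_timecourse(condition)
    if cfg.replicate_mode == "mean":
        profiles = preprocess.condition_mean_profiles(mat, samples, condition).values
    else:
        profiles = mat.values[samples.samples_in_time_order(condition)]
    tf_profiles = profiles.loc[[g for g in profiles.index if g in tfs]]
    if fixed_cutoff is not None:
        cutoff = network.CoexpressionCutoff.fixed(fixed_cutoff)
    else:
        cutoff = network.determine_cutoff(
            tf_profiles, alpha=cfg.alpha, n_permutations=cfg.n_permutations,
            rng_seed=rng_seed,
        )
    pcc = network.pairwise_pcc(tf_profiles)
    gcn = network.build_gcn(pcc, cutoff)
    suggested = seed_gene is None
    if seed_gene is None:
        seed_gene = network.suggest_seed(tf_profiles.loc[list(pcc.index)])[0]
    togcn = network.assign_levels_bfs(gcn, seed_gene)
    z = preprocess.zscore_rows(profiles)
    log.info(
        "condition %s: %d TFs, %d edges, %d levels, %d unreachable (cutoff %.4f)",
        condition, len(gcn.nodes), gcn.graph.number_of_edges(), togcn.n_levels,
        len(togcn.excluded), cutoff.pcc_threshold,
    )
    return _ConditionRun(condition, togcn, profiles, z, cutoff, suggested)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, object] = {}

    @_stage("load")
    def load():
        mat = io.read_expression(config.expression, config.unit)
        samples = io.read_samples(config.samples)
        tfs = io.read_tf_list(config.tf_list)
        annotation = io.read_gmt(config.gmt, tf_set=tfs) if config.gmt else None
        return mat, samples, tfs, annotation

    mat, samples, tfs, annotation = load()

    @_stage("normalize")
    def normalize(mat):
        if config.unit == "counts":
            lengths = pd.read_csv(
                config.gene_lengths, sep="\t", comment="#", index_col=0
            ).iloc[:, 0].to_dict()
            mat = preprocess.compute_tpm(mat, lengths)
        n_before = len(mat.genes)
        if config.filter_scope == "global":
            mat = preprocess.filter_expressed(mat, config.tpm_threshold)
        else:
            keep = set()
            for cond in (config.condition_a, config.condition_b):
                ids = samples.samples_in_time_order(cond)
                sub = mat.subset_samples([s for s in ids if s in mat.values.columns])
                keep |= set(preprocess.filter_expressed(sub, config.tpm_threshold).genes)
            mat = ExpressionMatrix(mat.values.loc[[g for g in mat.genes if g in keep]], mat.unit)
        counts["genes_total"] = n_before
        counts["genes_expressed"] = len(mat.genes)
        if config.normalization == "uq":
            mat = preprocess.upper_quartile_normalize(mat)
        io.write_expression(mat, outdir / "normalized.tsv")
        artifacts["normalized"] = outdir / "normalized.tsv"
        log.info("normalize: %d / %d genes pass TPM >= %g",
                 len(mat.genes), n_before, config.tpm_threshold)
        return mat

    mat = normalize(mat)
    expressed = set(mat.genes)
    tfs_expressed = tfs & expressed
    counts["tfs_expressed"] = len(tfs_expressed)

    runs: dict[str, _ConditionRun] = {}
    for label, cond, fixed, seedg in (
        ("A", config.condition_a, config.fixed_cutoff_a, config.seed_gene_a),
        ("B", config.condition_b, config.fixed_cutoff_b, config.seed_gene_b),
    ):
        build = _stage(f"togcn-{cond}")(_build_condition)
        run = build(
            config, mat, samples, cond, fixed, seedg, tfs_expressed,
            rng_seed=(config.rng_seed * 2 + (0 if label == "A" else 1)) % (2**31),
        )
        runs[label] = run
        prefix = outdir / f"togcn_{cond}"
        io.write_edge_list(run.togcn.gcn, f"{prefix}.edges.tsv")
        io.write_level_table(run.togcn, f"{prefix}.levels.tsv")
        lp = network.level_profiles(
            run.togcn, run.zscores
        ).to_frame()
        lp.to_csv(f"{prefix}.level_profiles.tsv", sep="\t")
        io.write_results_json(
            {
                "condition": cond,
                "seed_gene": run.togcn.seed_gene,
                "seed_suggested": run.seed_suggested,
                "cutoff": run.cutoff.to_dict(),
                "n_levels": run.togcn.n_levels,
                "level_counts": {str(k): v for k, v in run.togcn.level_counts().items()},
                "excluded": sorted(run.togcn.excluded),
                "rng_seed": config.rng_seed,
            },
            f"{prefix}.meta.json",
        )
        for suffix in ("edges.tsv", "levels.tsv", "level_profiles.tsv", "meta.json"):
            artifacts[f"togcn_{cond}.{suffix}"] = Path(f"{prefix}.{suffix}")
        counts[f"levels_{cond}"] = run.togcn.n_levels
        counts[f"edges_{cond}"] = run.togcn.gcn.graph.number_of_edges()

    @_stage("compare")
    def do_compare():
        paired = compare_mod.align_networks(runs["A"].togcn, runs["B"].togcn)
        comparison = compare_mod.classify_tfs(paired, t=config.t)
        summary = compare_mod.summarize_classes(comparison)
        out = comparison.table.reset_index()
        out.to_csv(outdir / "compare.tsv", sep="\t", index=False)
        io.write_results_json(summary, outdir / "compare_summary.json")
        artifacts["compare.tsv"] = outdir / "compare.tsv"
        artifacts["compare_summary.json"] = outdir / "compare_summary.json"
        counts["classes"] = summary["counts"]
        log.info("compare: %s", summary["counts"])
        return comparison

    comparison = do_compare()

    if annotation is not None:
        for label, cond in (("A", config.condition_a), ("B", config.condition_b)):
            @_stage(f"enrich-{cond}")
            def do_enrich(run=runs[label], cond=cond):
                candidates = expressed - tfs_expressed
                sets = levelsets.assign_level_genes(
                    run.togcn, run.profiles, candidates, run.cutoff
                )
                sets.to_frame().to_csv(
                    outdir / f"levelsets_{cond}.tsv", sep="\t", index=False
                )
                enr = levelsets.fisher_enrich(
                    sets, annotation, expressed,
                    alpha=config.enrich_alpha, family=config.fdr_family,
                )
                enr.to_csv(outdir / f"enrich_{cond}.tsv", sep="\t", index=False)
                artifacts[f"levelsets_{cond}.tsv"] = outdir / f"levelsets_{cond}.tsv"
                artifacts[f"enrich_{cond}.tsv"] = outdir / f"enrich_{cond}.tsv"
                n_sig = int(enr["significant"].sum()) if len(enr) else 0
                counts[f"significant_terms_{cond}"] = n_sig
                log.info("enrich %s: %d significant (level, term) pairs", cond, n_sig)

            do_enrich()

    manifest = {
        "config": config.to_dict(),
        "counts": counts,
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    io.write_results_json(manifest, outdir / "manifest.json")
    return manifest
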