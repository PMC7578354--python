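"""Run configuration and the umbrella pipeline driver.

A run is described by a :class:`RunConfig` (YAML on disk) naming the
stages to execute, their parameters, the input paths and a single seed.
``run_pipeline`` executes the stages in order, writes every artifact
under the output directory, and finishes with a JSON manifest listing
each artifact with its SHA-256 checksum plus the resolved configuration
— identical config and seed reproduce identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assays, atlas, io, proteomics, synthetic
from .errors import ConfigError

log = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate-atlas", "simulate-lfq", "map-atlas",
                "lfq-contrast", "qpcr-quant", "viability", "densitometry")


@dataclass
class RunConfig:
    """Serializable description of one reproducible run."""

    stages: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "hsrpipe_out"
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; "
                              f"choose from {list(KNOWN_STAGES)}")
        if not self.stages:
            raise ConfigError("no stages requested")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {key!r} not found: {path}")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ConfigError(f"unknown config key(s): {sorted(stray)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = io.ensure_dir(config.out_dir)
    artifacts: list[dict] = []
    state: dict = {}
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            _STAGES[stage](config, out, state, artifacts)
        except Exception as exc:
            _write_manifest(config, out, artifacts, complete=False)
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    manifest = _write_manifest(config, out, artifacts, complete=True)
    return manifest


def _record(artifacts, path, stage) -> None:
    artifacts.append({"path": str(path), "stage": stage,
                      "sha256": io.sha256_of(path)})


def _write_manifest(config, out, artifacts, complete) -> dict:
    config.to_yaml(out / "config.resolved.yaml")
    manifest = {"complete": complete,
                "seed": config.seed,
                "stages": list(config.stages),
                "artifacts": artifacts}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate_atlas(config, out, state, artifacts):
    p = config.params.get("atlas", {})
    spec = synthetic.AtlasSpec(**{**p, "seed": config.seed})
    matrix, truth = synthetic.generate_atlas(spec)
    io.write_expression_tsv(matrix, out / "atlas.tsv")
    io.write_sample_meta(matrix.sample_meta, out / "atlas_meta.tsv")
    qp = config.params.get("queries", {})
    category = tuple(qp.get("category", (spec.regions[0], spec.stages[0])))
    queries = synthetic.generate_queries(
        truth, category, n_queries=qp.get("n_queries", 3),
        effect_scale=qp.get("effect_scale", 1.0), seed=config.seed + 1)
    io.write_expression_tsv(queries, out / "queries.tsv")
    with open(out / "atlas_truth.json", "w", encoding="utf-8") as fh:
        json.dump({"category": list(category),
                   "signatures": {f"{r}|{s}": list(g)
                                  for (r, s), g in truth.signatures.items()}},
                  fh, indent=2)
    state["atlas"], state["queries"] = matrix, queries
    for name in ("atlas.tsv", "atlas_meta.tsv", "queries.tsv",
                 "atlas_truth.json"):
        _record(artifacts, out / name, "simulate-atlas")


def _stage_map_atlas(config, out, state, artifacts):
    p = config.params.get("map_atlas", {})
    if "query" in config.inputs:
        query = io.read_expression_tsv(config.inputs["query"])
        atlas_m = io.read_expression_tsv(config.inputs["atlas"])
        meta = io.read_sample_meta(config.inputs["atlas_meta"])
        atlas_m = atlas.ExpressionMatrix(atlas_m.values, meta)
    else:
        query, atlas_m = state.get("queries"), state.get("atlas")
        if query is None or atlas_m is None:
            raise ConfigError("map-atlas needs either input paths or a "
                              "preceding simulate-atlas stage")
    if p.get("average_replicates", False):
        query = atlas.ExpressionMatrix(
            query.values.mean(axis=1).to_frame("query_mean"))
    q, a = atlas.intersect_genes(query, atlas_m,
                                 min_genes=p.get("min_genes", atlas.MIN_GENES))
    corr = atlas.correlate_all_pairs(q, a)
    io.write_table(corr, out / "pairwise_correlations.tsv")
    scores = atlas.category_enrichment(
        corr, a.sample_meta,
        granularity=p.get("granularity", "region_x_stage"),
        alternative=p.get("alternative", "greater"),
        background=p.get("background", "inclusive"))
    io.write_table(scores, out / "category_scores.tsv")
    atlas.write_score_map(scores, out / "score_map.tsv",
                          mask_alpha=p.get("mask_alpha"))
    for name in ("pairwise_correlations.tsv", "category_scores.tsv",
                 "score_map.tsv"):
        _record(artifacts, out / name, "map-atlas")


def _stage_simulate_lfq(config, out, state, artifacts):
    p = config.params.get("lfq", {})
    spec = synthetic.LfqSpec(**{**p, "seed": config.seed})
    table, truth = synthetic.generate_lfq(spec)
    io.write_protein_groups(table, out / "proteinGroups.tsv")
    with open(out / "lfq_truth.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
    state["lfq"] = table
    for name in ("proteinGroups.tsv", "lfq_truth.json"):
        _record(artifacts, out / name, "simulate-lfq")


def _stage_lfq_contrast(config, out, state, artifacts):
    p = config.params.get("lfq_contrast", {})
    if "protein_table" in config.inputs:
        design = _read_design(config.inputs["design"])
        table = io.read_protein_groups(config.inputs["protein_table"], design)
    else:
        table = state.get("lfq")
        if table is None:
            raise ConfigError("lfq-contrast needs an input table or a "
                              "preceding simulate-lfq stage")
    filtered = proteomics.filter_flags(table)
    logged = proteomics.log10_transform(filtered)
    results = proteomics.two_sample_ttest(
        logged, min_valid_per_group=p.get("min_valid_per_group", 2),
        equal_var=not p.get("welch", False))
    io.write_table(results.reset_index(), out / "ttest_results.tsv")
    io.write_table(proteomics.volcano_table(results).reset_index(),
                   out / "volcano.tsv")
    excl = proteomics.exclusivity_sets(
        filtered, min_present=p.get("min_present", 2))
    with open(out / "exclusive_sets.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(excl), fh, indent=2)
    names = ["ttest_results.tsv", "volcano.tsv", "exclusive_sets.json"]
    if "gmt" in config.inputs:
        sets = io.read_gmt(config.inputs["gmt"])
        universe = logged.protein_ids
        for tag, selected in (("a", excl.exclusive_a),
                              ("b", excl.exclusive_b)):
            if selected:
                ora = proteomics.ora_hypergeometric(
                    selected, universe, sets,
                    min_set_size=p.get("min_set_size", 5))
                io.write_table(ora, out / f"ora_exclusive_{tag}.tsv")
                names.append(f"ora_exclusive_{tag}.tsv")
    for name in names:
        _record(artifacts, out / name, "lfq-contrast")


def _read_design(path):
    import pandas as pd
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    if df.shape[1] < 2:
        raise ConfigError(f"design file {path} needs sample and group columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _stage_qpcr_quant(config, out, state, artifacts):
    p = config.params.get("qpcr", {})
    ct = io.read_long_csv(config.inputs["ct_table"],
                          ("line", "condition", "gene", "ct"))
    hk = p.get("housekeeping", list(synthetic.HOUSEKEEPING_GENES))
    eff = p.get("efficiency", 2.0)
    rel = assays.relative_expression(
        ct, housekeeping=hk, reference_line=p["reference_line"],
        efficiency=eff)
    if p.get("baseline_condition"):
        # ddCt fold over each line's own baseline, computed from the
        # un-anchored housekeeping-normalized quantities
        qty = assays.relative_expression(ct, housekeeping=hk,
                                         reference_line=None, efficiency=eff)
        fob = assays.fold_over_baseline(qty, p["baseline_condition"])
        rel = rel.merge(fob[["line", "condition", "gene",
                             "fold_over_baseline"]],
                        on=["line", "condition", "gene"], how="left")
    io.write_table(rel, out / "qpcr_fold_changes.tsv")
    _record(artifacts, out / "qpcr_fold_changes.tsv", "qpcr-quant")


def _stage_viability(config, out, state, artifacts):
    p = config.params.get("viability", {})
    trace = io.read_long_csv(config.inputs["viability"],
                             ("well", "line", "time_h", "signal",
                              "negative_control"))
    trace["negative_control"] = trace["negative_control"].astype(bool)
    pct = assays.viability_percent(
        trace, subtract_floor=p.get("subtract_floor", True))
    io.write_table(pct, out / "viability_percent.tsv")
    _record(artifacts, out / "viability_percent.tsv", "viability")


def _stage_densitometry(config, out, state, artifacts):
    p = config.params.get("densitometry", {})
    d = io.read_long_csv(config.inputs["densitometry"],
                         ("lane", "band_intensity",
                          "loading_control_intensity"))
    norm = assays.densitometry_normalize(d, reference_lane=p["reference_lane"])
    io.write_table(norm, out / "densitometry_normalized.tsv")
    _record(artifacts, out / "densitometry_normalized.tsv", "densitometry")


_STAGES = {
    "simulate-atlas": _stage_simulate_atlas,
    "simulate-lfq": _stage_simulate_lfq,
    "map-atlas": _stage_map_atlas,
    "lfq-contrast": _stage_lfq_contrast,
    "qpcr-quant": _stage_qpcr_quant,
    "viability": _stage_viability,
    "densitometry": _stage_densitometry,
}
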