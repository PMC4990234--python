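"""End-to-end orchestration: simulate or load inputs, build blocks,
test differential expression, and write tables plus a JSON run manifest.

The manifest records the seed, the thresholds and the stage-by-stage
block-count trajectory (initial coverage blocks -> after merging ->
after single-read deletion -> after junction joining -> after gene-model
refinement), in the same order the narrative of a mapping report would
present them.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Any

import yaml

import mossdge
from mossdge import blocks as blk
from mossdge import de as de_mod
from mossdge import io as io_mod
from mossdge import simulate as sim

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "max_gap": 500,
    "max_junction_span": 10_000,
    "min_fold": 3.0,
    "min_reads": 50,
    "q": None,
}

_TOP_KEYS = {"simulation", "inputs", "thresholds", "seed", "outdir"}
_INPUT_KEYS = {
    "alignments",
    "format",
    "junctions",
    "models",
    "sample1",
    "sample2",
    "n1",
    "n2",
}
_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimConfig)}


def validate_config(config: dict | str | os.PathLike) -> dict:
    """Normalize a pipeline configuration: inject defaults, reject
    unknown keys, non-positive thresholds and contradictory sections."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    has_sim = "simulation" in config and config["simulation"] is not None
    has_inputs = "inputs" in config and config["inputs"] is not None
    if has_sim and has_inputs:
        raise ValueError(
            "exactly one of 'simulation' and 'inputs' must be specified"
        )
    if not has_sim and not has_inputs:
        # documented default: a default-parameter simulation run
        config = dict(config)
        config["simulation"] = {}
        has_sim = True

    thresholds = dict(DEFAULT_THRESHOLDS)
    extra = config.get("thresholds") or {}
    unknown = set(extra) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    thresholds.update(extra)
    bad = [
        k
        for k in ("max_gap", "max_junction_span", "min_fold", "min_reads")
        if thresholds[k] is None or thresholds[k] <= 0
    ]
    if thresholds["q"] is not None and not (0 < thresholds["q"] <= 1):
        bad.append("q")
    if bad:
        raise ValueError(f"non-positive or invalid thresholds: {sorted(bad)}")

    out: dict[str, Any] = {
        "seed": int(config.get("seed", 0)),
        "outdir": str(config.get("outdir", "mossdge_run")),
        "thresholds": thresholds,
    }
    if has_sim:
        simcfg = dict(config["simulation"])
        unknown = set(simcfg) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        simcfg.setdefault("seed", out["seed"])
        for key in ("fold_changes", "expression_weights", "gene_length_range"):
            if key in simcfg and simcfg[key] is not None:
                simcfg[key] = tuple(simcfg[key])
        sim.SimConfig(**simcfg)  # validates
        out["simulation"] = simcfg
    else:
        inputs = dict(config["inputs"])
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        for key in ("alignments", "n1", "n2"):
            if key not in inputs:
                raise ValueError(f"inputs section is missing {key!r}")
        inputs.setdefault("format", "tsv")
        inputs.setdefault("sample1", sim.CONTROL)
        inputs.setdefault("sample2", sim.TREATED)
        inputs.setdefault("junctions", None)
        inputs.setdefault("models", None)
        out["inputs"] = inputs
    return out


def run_block_pipeline(
    alignments,
    junctions,
    models,
    max_gap: int = 500,
    max_junction_span: int = 10_000,
):
    """The five-stage block construction; returns (blocks, stage counts)."""
    stage_counts: dict[str, int] = {}
    blocks = blk.build_coverage_blocks(alignments)
    stage_counts["initial"] = len(blocks)
    blocks = blk.merge_adjacent(blocks, max_gap=max_gap)
    stage_counts["after_merge"] = len(blocks)
    blocks = blk.prune_singletons(blocks)
    stage_counts["after_prune"] = len(blocks)
    blocks = blk.join_by_junctions(blocks, junctions or [], max_span=max_junction_span)
    stage_counts["after_junction_join"] = len(blocks)
    blocks = blk.refine_with_gene_models(blocks, models or [])
    stage_counts["after_model_refine"] = len(blocks)
    blocks = blk.annotate_overlap(blocks, models or [])
    blocks = blk.assign_block_ids(blocks)
    stage_counts["overlapping_models"] = sum(
        1 for b in blocks if b.overlap_gene_ids
    )
    return blocks, stage_counts


def run_pipeline(config: dict | str | os.PathLike) -> Path:
    """Execute an end-to-end run; returns the run directory.

    Writes: blocks.bed, blocks.tsv, de.tsv, up.txt, down.txt and
    manifest.json (plus the simulated inputs when in simulation mode).
    Outputs are byte-identical for a fixed configuration.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg["thresholds"]

    if "simulation" in cfg:
        simcfg = sim.SimConfig(**cfg["simulation"])
        truth, alignments = sim.simulate_experiment(simcfg)
        junctions, models = truth.junctions, truth.gene_models
        sample1, sample2 = sim.CONTROL, sim.TREATED
        n1, n2 = simcfg.lib_size_control, simcfg.lib_size_treated
        io_mod.write_gene_models_gff3(models, outdir / "gene_models.gff3")
        io_mod.write_junctions_bed(junctions, outdir / "junctions.bed")
        io_mod.write_alignments_tsv(alignments, outdir / "alignments.tsv")
    else:
        inp = cfg["inputs"]
        if not Path(inp["alignments"]).exists():
            raise FileNotFoundError(f"alignments file not found: {inp['alignments']}")
        alignments = io_mod.read_alignments(inp["alignments"], inp["format"])
        junctions = (
            io_mod.read_junctions(inp["junctions"]) if inp["junctions"] else []
        )
        models = io_mod.read_gene_models(inp["models"]) if inp["models"] else []
        sample1, sample2 = inp["sample1"], inp["sample2"]
        n1, n2 = int(inp["n1"]), int(inp["n2"])

    blocks, stage_counts = run_block_pipeline(
        alignments,
        junctions,
        models,
        max_gap=thr["max_gap"],
        max_junction_span=thr["max_junction_span"],
    )
    counts = de_mod.count_reads_per_block(
        blocks, alignments, sample1, sample2, n1, n2
    )
    results = de_mod.compute_differential_expression(counts)
    results = de_mod.classify_de(
        results,
        min_fold=thr["min_fold"],
        min_reads=thr["min_reads"],
        q_threshold=thr["q"],
    )

    blk.write_blocks_bed(blocks, str(outdir / "blocks.bed"))
    blk.write_blocks_tsv(blocks, str(outdir / "blocks.tsv"), [sample1, sample2])
    io_mod.write_de_table(results, outdir / "de.tsv")
    up = [r.block_id for r in results if r.direction == "up"]
    down = [r.block_id for r in results if r.direction == "down"]
    (outdir / "up.txt").write_text("".join(f"{b}\n" for b in up))
    (outdir / "down.txt").write_text("".join(f"{b}\n" for b in down))

    manifest = {
        "package": "mossdge",
        "version": mossdge.__version__,
        "seed": cfg["seed"],
        "thresholds": thr,
        "mode": "simulation" if "simulation" in cfg else "real",
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "library_sizes": {sample1: n1, sample2: n2},
        "stage_block_counts": stage_counts,
        "n_up": len(up),
        "n_down": len(down),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return outdir
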