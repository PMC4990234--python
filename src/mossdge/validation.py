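"""Reference inputs and end-to-end validation experiments.

This module holds the published count inputs the package's headline
statistics are computed from (colony counts for the gene-targeting
panel, read-mapping totals for the sequencing run) and the simulation
experiments used to validate the pipeline: null-calibration of the
digital-expression test, recovery of known fold changes through the
full block pipeline, qPCR fold recovery and plate-image quantification.

Every function recomputes its result from scratch at call time; seeds
are taken as arguments so runs are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from mossdge import de as de_mod
from mossdge.phenotype import TargetingCounts, growth_index, gt_frequency, segment_plate
from mossdge.pipeline import run_block_pipeline
from mossdge.qpcr import ddct_fold_change, fit_standard_curve
from mossdge.simulate import (
    CONTROL,
    TREATED,
    SimConfig,
    render_colony_plate,
    simulate_experiment,
    simulate_qpcr_plate,
)

# Colony counts for the knockout panel (strain -> (HygR, 2-FAR)):
# stable transformants and 2-fluoroadenine-resistant (targeted) plants.
GT_PANEL_COUNTS: dict[str, tuple[int, int]] = {
    "ctip-KO": (285, 64),
    "teb-KO": (1149, 910),
    "ercc6-KO": (2680, 1739),
    "srs2-KO": (1266, 923),
    "chd5-KO": (1600, 1081),
}

# Read-mapping totals of the sequencing run (40-base reads).
LIBRARY_TOTALS = {
    "total_reads": 30_487_204,
    "mapped_reads": 21_399_712,
    "unique_reads": 20_931_284,
    "read_length": 40,
}

# Fold-change spectrum used for the recovery experiment: the induction
# strengths observed across the up-regulated DNA-repair / replication /
# helicase panel (3x to 149x) and a handful of strongly down-regulated
# cell-cycle genes. Deliberately includes genes at the 3-fold filter
# boundary and at 6-fold.
RECOVERY_UP_FOLDS: tuple[float, ...] = (
    149, 52, 27, 21, 20, 19, 15, 14, 14, 13, 11, 9, 8, 8, 8, 8,
    7, 7, 7, 7, 6, 6, 6, 6, 6, 5, 5, 5, 5, 5, 5, 4, 4, 4, 3, 3,
)
RECOVERY_DOWN_FOLDS: tuple[float, ...] = (5, 5, 6, 44)
RECOVERY_N_NULL = 40


def gt_panel_results() -> dict[str, float]:
    """%GT recomputed from the panel's colony counts."""
    return {
        strain: gt_frequency(TargetingCounts(strain, hyg, fa))
        for strain, (hyg, fa) in GT_PANEL_COUNTS.items()
    }


def typeI_error_experiment(
    seed: int, n_blocks: int = 10_000, depth: float = 300.0
) -> float:
    """Fraction of null blocks with p < 0.05.

    Equal Poisson means in both conditions, equal library sizes;
    per-block depth is lognormal around ``depth`` reads (the average
    per-sample block depth of a 10M-read library over ~30k blocks).
    """
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(math.log(depth), 0.7, size=n_blocks)
    x = rng.poisson(lam)
    y = rng.poisson(lam)
    p = de_mod.audic_claverie_p(x, y, 10**6, 10**6)
    return float((p < 0.05).mean())


def recovery_config(seed: int) -> tuple[SimConfig, list[float]]:
    folds = (
        [float(f) for f in RECOVERY_UP_FOLDS]
        + [1.0 / f for f in RECOVERY_DOWN_FOLDS]
        + [1.0] * RECOVERY_N_NULL
    )
    n = len(folds)
    cfg = SimConfig(
        n_chroms=4,
        chrom_length=120_000,
        n_genes=n,
        lib_size_control=20_000,
        lib_size_treated=20_000,
        fold_changes=tuple(folds),
        expression_weights=tuple([1.0] * n),
        fraction_spliced=0.25,
        seed=seed,
    )
    return cfg, folds


def recovery_experiment(seed: int) -> dict[str, float]:
    """Full-pipeline recovery of known fold changes.

    Simulates the two-condition experiment, runs block construction and
    the differential-expression filters, and reports the percentage of
    truly changed genes (with >= 50 expected reads in at least one
    condition) whose block passes the >= 3-fold / >= 50-read filter in
    the correct direction.
    """
    cfg, folds = recovery_config(seed)
    truth, aln = simulate_experiment(cfg)
    blocks, _ = run_block_pipeline(aln, truth.junctions, truth.gene_models)
    counts = de_mod.count_reads_per_block(
        blocks, aln, CONTROL, TREATED, cfg.lib_size_control, cfg.lib_size_treated
    )
    results = de_mod.classify_de(de_mod.compute_differential_expression(counts))
    by_id = {r.block_id: r for r in results}
    gene_directions: dict[str, set[str]] = {}
    for b in blocks:
        if len(b.overlap_gene_ids) == 1:
            r = by_id[b.block_id]
            if r.passes_filters:
                gene_directions.setdefault(b.overlap_gene_ids[0], set()).add(
                    r.direction
                )
    recovered = total = 0
    for gi, model in enumerate(truth.gene_models):
        if folds[gi] == 1.0:
            continue
        if max(truth.mean_control[gi], truth.mean_treated[gi]) < 50:
            continue
        total += 1
        want = "up" if folds[gi] > 1 else "down"
        if want in gene_directions.get(model.id, set()):
            recovered += 1
    return {
        "recovered": recovered,
        "total": total,
        "pct": 100.0 * recovered / total,
    }


def qpcr_recovery_experiment(
    seed: int, true_fold: float = 30.0, noise_sd: float = 0.15, n_plates: int = 12
) -> dict[str, float]:
    """ddCt recovery of an injected induction over replicate 3-replicate
    plates; returns the grand mean fold and its standard error."""
    folds = []
    for k in range(n_plates):
        plate = simulate_qpcr_plate(
            ["rad51"],
            "cap50",
            effect_sizes={"rad51": true_fold},
            noise_sd=noise_sd,
            seed=seed * 1000 + k,
        )
        folds.append(ddct_fold_change(plate, "rad51", "cap50")[0])
    return {
        "mean_fold": float(np.mean(folds)),
        "se": float(np.std(folds, ddof=1) / math.sqrt(len(folds))),
        "true_fold": true_fold,
    }


def standard_curve_experiment() -> dict[str, float]:
    """Slope and efficiency of a perfect tenfold dilution series."""
    dilutions = (1e-1, 1e-2, 1e-3, 1e-4)
    cqs = [10.0 + math.log2(10) * k for k in range(1, 5)]
    curve = fit_standard_curve(dilutions, cqs)
    return {
        "slope": curve.slope,
        "efficiency_pct": 100.0 * curve.efficiency,
    }


def growth_index_experiment(seed: int | None = None) -> float:
    """Growth index of one 50 px colony disk in a 500 px dish."""
    img = render_colony_plate(500, [(520, 520, 50)], seed=seed)
    plant, dish = segment_plate(img)
    return growth_index(plant, dish)
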