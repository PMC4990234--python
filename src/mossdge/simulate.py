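"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design: a two-condition experiment
(control vs genotoxin-treated), 36-40 nt reads uniquely mapped to a toy
genome with non-overlapping gene models, a subset of genes carrying one
intron (whose spliced reads produce split alignments and a splice
junction), Poisson count sampling at configurable per-gene fold changes
and library sizes, qPCR quantification-cycle tables with a tenfold
spike-in dilution series, and culture-dish images containing plant
colony disks.

One master seed drives per-stage derived streams, so fixed-seed runs
are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mossdge._util import stage_rng
from mossdge.io import AlignmentInterval, GeneModel, SpliceJunction

CONTROL = "control"
TREATED = "treated"

_MIN_EXON = 60
_MIN_INTRON = 60


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the toy two-condition short-read experiment.

    Library sizes are the expected total read counts under no change;
    they double as the RPM normalization constants, so the true RPM
    ratio of gene g equals fold_changes[g] exactly.
    """

    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (600, 3_000)
    min_intergenic_gap: int = 500
    read_length: int = 40
    lib_size_control: int = 50_000
    lib_size_treated: int = 50_000
    fold_changes: tuple[float, ...] | None = None
    fraction_spliced: float = 0.3
    seed: int = 0
    expression_weights: tuple[float, ...] | None = None  # default: lognormal
    dispersion: float | None = None  # None = Poisson; else NB with this size

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.lib_size_control < 1 or self.lib_size_treated < 1:
            raise ValueError("library sizes must be >= 1")
        if self.n_genes < 0 or self.n_chroms < 1:
            raise ValueError("n_genes must be >= 0 and n_chroms >= 1")
        if not (0 <= self.fraction_spliced <= 1):
            raise ValueError("fraction_spliced must be in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (lo, hi) with lo <= hi")
        if self.fold_changes is not None:
            if len(self.fold_changes) != self.n_genes:
                raise ValueError("fold_changes length must equal n_genes")
            if any(f < 0 for f in self.fold_changes):
                raise ValueError("fold changes must be >= 0")

    def resolved_folds(self) -> np.ndarray:
        if self.fold_changes is None:
            return np.ones(self.n_genes)
        return np.asarray(self.fold_changes, dtype=float)


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated experiment."""

    gene_models: list[GeneModel]
    junctions: list[SpliceJunction]
    introns: dict[str, tuple[int, int]]  # gene id -> intron [start, end)
    mean_control: np.ndarray  # expected read count per gene, control
    mean_treated: np.ndarray
    log2_fold_change: np.ndarray
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[GeneModel], list[SpliceJunction]]:
    """Place non-overlapping gene models (gap >= min_intergenic_gap) and
    one intron per spliced gene; raises when the genes cannot fit."""
    models, junctions, _ = _simulate_annotation_full(config)
    return models, junctions


def _simulate_annotation_full(
    config: SimConfig,
) -> tuple[list[GeneModel], list[SpliceJunction], dict[str, tuple[int, int]]]:
    rng = stage_rng(config.seed, "annotation")
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    lo, hi = config.gene_length_range
    models: list[GeneModel] = []
    introns: dict[str, tuple[int, int]] = {}
    gene_idx = 0
    n_spliced_target = int(round(config.fraction_spliced * config.n_genes))
    spliced_ids = set(
        rng.choice(config.n_genes, size=n_spliced_target, replace=False)
        if config.n_genes
        else []
    )

    for ci in range(config.n_chroms):
        k = per_chrom[ci]
        chrom = f"chr{ci + 1}"
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        slack = config.chrom_length - int(lengths.sum()) - (k + 1) * config.min_intergenic_gap
        if slack < 0:
            raise ValueError(
                f"genes cannot fit on {chrom}: need "
                f"{int(lengths.sum()) + (k + 1) * config.min_intergenic_gap} bases, "
                f"have {config.chrom_length}"
            )
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        cursor = 0
        for gi in range(k):
            cursor += config.min_intergenic_gap + int(extra[gi])
            start, end = cursor, cursor + int(lengths[gi])
            gid = f"gene{gene_idx + 1:04d}"
            models.append(GeneModel(chrom, start, end, gid))
            glen = end - start
            if gene_idx in spliced_ids and glen >= 2 * _MIN_EXON + _MIN_INTRON:
                max_intron = glen - 2 * _MIN_EXON
                intron_len = int(rng.integers(_MIN_INTRON, max_intron + 1))
                exon1 = int(rng.integers(_MIN_EXON, glen - intron_len - _MIN_EXON + 1))
                introns[gid] = (start + exon1, start + exon1 + intron_len)
            cursor = end
            gene_idx += 1

    junctions = [
        SpliceJunction(m.chrom, introns[m.id][0], introns[m.id][1])
        for m in models
        if m.id in introns
    ]
    return models, junctions, introns


def simulate_truth(config: SimConfig) -> SimTruth:
    """Annotation plus per-gene expected counts and true fold changes."""
    models, junctions, introns = _simulate_annotation_full(config)
    folds = config.resolved_folds()
    rng = stage_rng(config.seed, "expression")
    n = config.n_genes
    if n == 0:
        weights = np.zeros(0)
    elif config.expression_weights is not None:
        if len(config.expression_weights) != n:
            raise ValueError("expression_weights length must equal n_genes")
        weights = np.asarray(config.expression_weights, dtype=float)
    else:
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    e = weights / weights.sum() if n else weights
    mean_control = e * config.lib_size_control
    mean_treated = e * folds * config.lib_size_treated
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.where(folds > 0, folds, np.nan))
    return SimTruth(
        gene_models=models,
        junctions=junctions,
        introns=introns,
        mean_control=mean_control,
        mean_treated=mean_treated,
        log2_fold_change=lfc,
        seed=config.seed,
        metadata={"lib_size_control": config.lib_size_control,
                  "lib_size_treated": config.lib_size_treated},
    )


def _place_gene_reads(
    rng: np.random.Generator,
    model: GeneModel,
    intron: tuple[int, int] | None,
    n_reads: int,
    read_length: int,
    sample: str,
    prefix: str,
) -> list[AlignmentInterval]:
    """Uniform read starts on the mature transcript, mapped to the genome;
    reads crossing the intron become two split segments."""
    out: list[AlignmentInterval] = []
    glen = model.end - model.start
    if intron is None:
        mature = glen
    else:
        mature = glen - (intron[1] - intron[0])
    max_start = max(mature - read_length, 0)
    starts = rng.integers(0, max_start + 1, size=n_reads)
    exon1 = (intron[0] - model.start) if intron is not None else mature
    intron_len = (intron[1] - intron[0]) if intron is not None else 0
    for i, t0 in enumerate(starts):
        t0 = int(t0)
        t1 = min(t0 + read_length, mature)
        rid = f"{prefix}_{i + 1}"
        if intron is None or t1 <= exon1:
            out.append(
                AlignmentInterval(
                    model.chrom, model.start + t0, model.start + t1, sample, rid
                )
            )
        elif t0 >= exon1:
            out.append(
                AlignmentInterval(
                    model.chrom,
                    model.start + intron_len + t0,
                    model.start + intron_len + t1,
                    sample,
                    rid,
                )
            )
        else:
            out.append(
                AlignmentInterval(
                    model.chrom, model.start + t0, model.start + exon1, sample, rid
                )
            )
            out.append(
                AlignmentInterval(
                    model.chrom,
                    model.start + exon1 + intron_len,
                    model.start + intron_len + t1,
                    sample,
                    rid,
                )
            )
    return out


def simulate_alignments(
    config: SimConfig, truth: SimTruth
) -> list[AlignmentInterval]:
    """Draw per-gene read counts (Poisson, or negative binomial when a
    dispersion size is configured) and place reads uniformly on each
    gene's mature transcript. Deterministic for a fixed seed."""
    rng = stage_rng(config.seed, "alignments")
    out: list[AlignmentInterval] = []
    for gi, model in enumerate(truth.gene_models):
        intron = truth.introns.get(model.id)
        for sample, mean in (
            (CONTROL, truth.mean_control[gi]),
            (TREATED, truth.mean_treated[gi]),
        ):
            if mean <= 0:
                continue
            if config.dispersion is None:
                n = int(rng.poisson(mean))
            else:
                size = config.dispersion
                n = int(rng.negative_binomial(size, size / (size + mean)))
            if n == 0:
                continue
            out.extend(
                _place_gene_reads(
                    rng,
                    model,
                    intron,
                    n,
                    config.read_length,
                    sample,
                    prefix=f"{sample}_{model.id}",
                )
            )
    return out


def simulate_experiment(config: SimConfig) -> tuple[SimTruth, list[AlignmentInterval]]:
    truth = simulate_truth(config)
    return truth, simulate_alignments(config, truth)


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(
    targets: Sequence[str],
    ref_gene: str,
    spike_dilutions: Sequence[float] = (1e-1, 1e-2, 1e-3, 1e-4),
    effect_sizes: Sequence[float] | dict[str, float] = (),
    noise_sd: float = 0.1,
    seed: int = 0,
    n_bio: int = 3,
    n_tech: int = 2,
    spike_gene: str = "spike",
    base_cq: float = 22.0,
    spike_base_cq: float = 10.0,
) -> pd.DataFrame:
    """Simulate a Cq table for a two-condition qPCR experiment.

    Cq drops by log2(10) per tenfold increase in template (100%
    amplification efficiency); an effect size f lowers the treated Cq of
    its target by log2(f). The reference gene is condition-invariant up
    to Gaussian noise. Spike-in rows carry a ``dilution`` value and
    condition "spike".
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dil = np.asarray(spike_dilutions, dtype=float)
    if np.any(dil <= 0):
        raise ValueError("spike dilutions must be positive")
    if isinstance(effect_sizes, dict):
        effects = dict(effect_sizes)
    else:
        effects = dict(zip(targets, effect_sizes))
    for g, f in effects.items():
        if f <= 0:
            raise ValueError(f"effect size for {g} must be > 0")
    rng = stage_rng(seed, "qpcr")
    rows = []
    genes = list(targets) + [ref_gene]
    for k, gene in enumerate(genes):
        gene_base = base_cq + 0.5 * k  # offset so genes are distinguishable
        for condition in (CONTROL, TREATED):
            shift = 0.0
            if condition == TREATED and gene in effects:
                shift = math.log2(effects[gene])
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    cq = gene_base - shift + rng.normal(0.0, noise_sd) if noise_sd else gene_base - shift
                    rows.append((gene, condition, b, t, np.nan, cq))
    for d in dil:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                cq = spike_base_cq - math.log2(d) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rows.append((spike_gene, "spike", b, t, d, cq))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "bio_rep", "tech_rep", "dilution", "cq"]
    )


# ---------------------------------------------------------------------------
# Plate images


def render_colony_plate(
    dish_radius_px: int,
    colony_specs: Sequence[tuple[int, int, int]] = (),
    background: tuple[int, int, int] = (30, 30, 30),
    seed: int | None = None,
    margin: int = 20,
    dish_color: tuple[int, int, int] = (205, 205, 205),
    colony_color: tuple[int, int, int] = (70, 170, 70),
) -> np.ndarray:
    """Render an RGB dish image with green plant-colony disks.

    colony_specs are (cx, cy, radius) in image coordinates; every colony
    disk must lie fully inside the dish. Colony pixels are
    green-dominant, the dish is neutral grey, the background dark.
    """
    if dish_radius_px < 1:
        raise ValueError("dish radius must be >= 1")
    size = 2 * (dish_radius_px + margin)
    cx0 = cy0 = size // 2
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = background
    yy, xx = np.mgrid[0:size, 0:size]
    dish = (xx - cx0) ** 2 + (yy - cy0) ** 2 <= dish_radius_px**2
    img[dish] = dish_color
    for cx, cy, r in colony_specs:
        if r < 1:
            raise ValueError("colony radius must be >= 1")
        if math.hypot(cx - cx0, cy - cy0) + r > dish_radius_px:
            raise ValueError(f"colony at ({cx},{cy}) r={r} lies outside the dish")
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[disk] = colony_color
    if seed is not None:
        rng = stage_rng(seed, "image")
        noise = rng.normal(0.0, 2.0, size=img.shape)
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)
    return img
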