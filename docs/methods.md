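# Methods

This note documents the models, conventions and design choices behind
`mossdge`, and what the validation experiments do and do not show.

## Coverage blocks as expression units

The pipeline's expression unit is the *coverage block*: a maximal
genomic stretch with uniquely-mapped read coverage ≥ 1, post-processed
by four rules. All coordinates are 0-based half-open; GFF3 (1-based
inclusive) and SAM (1-based POS) are converted at the I/O boundary so
every gap/midpoint computation uses a single convention. Reads are
treated as unstranded, as in non-stranded library protocols; blocks
carry no strand.

Rule order and the interpretation of each rule:

1. **Build.** Blocks are maximal unions of read segments; two reads
   abutting exactly (`[0,40)` + `[40,80)`) are continuous coverage.
   Spliced reads contribute one segment per exonic part and are
   anchored — for counting and for all reassignment — at their leftmost
   aligned base, so each read is counted exactly once with no
   fractional-overlap rules.
2. **Merge (gap ≤ 500 bp).** "Within 500 bp" is read as inclusive of the
   bound. The merged block is the single interval spanning both inputs:
   the gap is retained inside the span, so a later read starting in the
   gap still counts to the block.
3. **Prune.** Blocks with exactly one read are deleted. This is the only
   stage that changes the total read count, and it removes exactly one
   read per deleted block.
4. **Junction join (intron span < 10 kb, strict).** A junction's exonic
   anchors are the base before the intron start (donor − 1) and the base
   at the intron end (acceptor); when they fall in two distinct
   same-chromosome blocks the blocks are joined into one multi-interval
   block, transitively (union–find). Junctions with either anchor
   outside all blocks are ignored. Anchors rather than the intron
   endpoints are used because junction evidence lives in transcribed
   sequence.
5. **Gene-model refinement (to fixpoint).** (i) Blocks whose spans (the
   convex hull of their intervals) intersect the same model are joined —
   intersection, not containment, because blocks are ragged relative to
   models. (ii) A block crossing ≥ 2 models is split at
   `floor((upstream model end + downstream model start) / 2)` for each
   consecutive crossed pair; integer floor ties the midpoint toward the
   upstream part; reads move to the part containing their leftmost base.
   Joins are applied to fixpoint before each split pass; the loop
   terminates because after one split pass every part intersects at most
   one model, and joining parts that share a model cannot re-create a
   multi-model block when models are non-overlapping (overlapping models
   are rejected). Blocks never join across chromosomes.

Conservation law: build, merge, junction-join and refinement conserve
the total read count exactly; the tests verify this, along with
idempotence of merge and refinement, on every random instance. The full
pipeline is additionally held equal to a brute-force reference
(per-base coverage array, one exhaustive rule application at a time) on
100+ random instances.

## The digital-expression test

For block counts x (library size N₁) and y (N₂), the test statistic is
the posterior predictive law of y given x under Poisson sampling with a
flat prior on the rate:

    P(Y = y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),  r = N₂/N₁,

which is NB(x+1, p₁) with p₁ = N₁/(N₁+N₂). Implementation notes:

- Tails are evaluated with the regularized incomplete beta function
  (`scipy.special.betainc`, log-gamma based): finite and accurate for
  counts beyond 10⁶, and verified against a direct log-gamma summation
  oracle at 10⁻¹⁰ relative error for x + y ≤ 30 and against
  `scipy.stats.nbinom` on random instances.
- **Two-sidedness.** The smaller conditional tail is doubled and capped
  at 1. Because the conditional tails count the observed point's mass in
  both directions, the doubled-tail p-value is not exactly exchangeable
  in (x, N₁) ↔ (y, N₂) at small counts. The statistic is therefore
  evaluated in both orientations (y given x, and x given y with the
  library sizes swapped) and the smaller doubled tail is taken. This
  makes symmetry exact (bit-identical, since p₁ and p₂ are each computed
  directly from N₁ and N₂) while leaving the canonical values unchanged
  (x = 0, y = 0 → p = 1; x = 10, y = 0, N₁ = N₂ → p = 2/2048).
- **Calibration.** On a 10,000-block null simulation (equal Poisson
  means, lognormal depth centred at 300 reads per block per sample — the
  depth scale of a 10M-read library over ~30k blocks), the fraction of
  p < 0.05 measures 0.048–0.055 across seeds; the test is slightly
  conservative at low counts because of discreteness.

**RPM and fold change.** RPM = count × 10⁶ / N with N the uniquely
mapped library size. The log fold change is log₂ of the RPM ratio
(treated/control). When either count is zero, half a read in RPM units
(0.5 × 10⁶/Nᵢ, per library) is added to both sides so the fold filter
stays evaluable for blocks observed in only one condition; with both
counts positive the plain ratio is used, so reported fold changes are
not shrunk. **Multiple testing** is Benjamini–Hochberg step-up
(via `statsmodels`; the tests hold it to a hand-rolled step-up oracle).
**Filters.** The up/down report requires RPM ratio ≥ 3 in either
direction and ≥ 50 reads in at least one condition; a q-value threshold
is available but off by default, since the defining filters of the
published lists are the fold and count cutoffs.

In simulation mode the pipeline normalizes by the configured library
sizes (the generator's normalization constants) rather than realized
totals, so true RPM ratios equal the configured fold changes exactly;
with real inputs the uniquely-mapped totals are supplied by the user.

## The synthetic-data generator

The generator emulates the study design: a two-condition experiment
(control vs genotoxin-treated), one pooled library per condition,
40-base reads (36 available), non-overlapping gene models separated by
≥ 500 bp (configurable), a configurable fraction of genes carrying one
intron, Poisson per-gene counts with mean (relative expression) ×
(fold change) × (library size), and uniform read starts on the mature
transcript — the simplest model producing continuous coverage at
moderate depth. Reads crossing the intron become split alignments and
the intron is emitted as a BED12 junction. An optional
negative-binomial switch adds overdispersion for robustness
experiments; it is off by default because the significance test assumes
Poisson sampling. One master seed drives per-stage derived streams
(annotation, expression, alignments, qPCR, images), so fixed-seed runs
are bit-identical.

What it does **not** emulate: sequencing errors and quality scores,
multi-mapping reads, paired ends, non-uniform (3'-biased or
GC-dependent) coverage, overlapping or nested gene models, and
composition effects (library sizes are normalization constants, not a
fixed sequencing budget). Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and rules under the stated
sampling model, not robustness to real-library artefacts.

qPCR plates are simulated with Cq = base − log₂(template multiplier) +
Gaussian noise (perfect doubling per cycle), a condition-invariant
reference gene, and a tenfold spike-in dilution series (10⁻¹–10⁻⁴).
Plate images are rasterized disks: a neutral-grey dish on a dark
background with green-dominant colony disks, so any reasonable
green-dominance segmentation recovers them.

## Phenotype and qPCR quantification

- **%GT** = 100 × 2-FAᴿ/Hygᴿ, rounded half-up to one decimal (the
  rounding used by printed tables; Python's banker's rounding would
  differ at ties). The validation panel reproduces the five published
  rows that are exact under this rule; two further rows appear truncated
  rather than rounded in print and are checked within 0.1; the published
  wild-type row is inconsistent with its own counts (probable typo) and
  excluded.
- **Growth index** = plant pixels / dish pixels. Segmentation: Otsu
  threshold on mean intensity, largest bright connected component with
  holes filled = dish; pixels inside the dish whose green channel
  exceeds red and blue by ≥ 10 grey levels = plant. Deterministic; scale
  invariant to ~2% for dish radii ≥ 200 px (rasterization error).
- **ΔΔCt.** Technical replicates are averaged before any
  biological-replicate statistics; per biological replicate
  ΔCq = Cq(target) − Cq(reference), ΔΔCq = ΔCq(treated) − ΔCq(control),
  fold = E^(−ΔΔCq) with E = 2 unless a standard-curve efficiency is
  supplied. The external spike-in series and the internal reference gene
  are kept as separate, documented modes (standard curve vs ΔΔCt);
  reference-gene stability is ranked by the cross-condition standard
  deviation of replicate-mean Cq — the simplest defensible metric where
  no specific one is prescribed.

## Validation experiment design and problem sizes

The validation suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses deliberately scaled-down problem sizes
chosen to give stable statistics in seconds: 100 random oracle
instances of up to a few thousand reads; a 10,000-block null; a
recovery experiment with 80 genes over 4 × 120 kb chromosomes at
20,000-read libraries (≈ 250 expected reads per gene per condition, so
every changed gene clears the 50-read cutoff); 12 three-replicate qPCR
plates; a 500 px dish image.

The recovery experiment's changed genes use the induction spectrum
observed across the study's up-regulated DNA-repair/replication and
helicase panels (3× to 149×, n = 36) plus four strongly down-regulated
cell-cycle genes (5×, 5×, 6×, 44×), with 40 unchanged genes. A gene
whose true fold change sits exactly at the 3-fold filter boundary has
~50% probability of passing at any depth — the threshold sits at the
median of its sampling distribution — so perfect recovery is
impossible in principle at the boundary; with the realistic spectrum
above, measured recovery is 95–100% across seeds. Recovery is scored
per gene: a changed gene counts as recovered when a block overlapping
it (and only it) passes the filters in the true direction.

## Known limitations

- Replicate-aware, overdispersion-robust testing (negative-binomial
  GLMs) is out of scope; the test assumes Poisson sampling of pooled
  libraries, as the block pipeline's design era did.
- Only CIGAR M and N are consumed when reading SAM; BAM/CRAM and full
  CIGAR algebra are not supported.
- Blocks are unstranded and transcript isoforms are not assembled;
  a block can legitimately aggregate overlapping transcription.
- The midpoint split uses model boundaries, not block-intersection
  boundaries; where a block barely grazes one of two models this can
  apportion intergenic coverage asymmetrically.
- Plate segmentation measures total green area; it does not separate
  touching colonies.
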