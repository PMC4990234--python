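"""Readers/writers for the formats the pipeline touches, and library summaries.

All coordinates are held internally as 0-based half-open intervals.
GFF3 (1-based inclusive) and SAM (1-based POS) are converted at the
boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam

from mossdge._util import round_half_up


@dataclass(frozen=True)
class AlignmentInterval:
    """One aligned segment of a uniquely mapped read.

    A spliced read contributes several segments sharing one ``read_id``;
    an unspliced read is a single segment. ``sample`` is the condition
    label (e.g. ``"control"`` / ``"treated"``).
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sample: str
    read_id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: ``[donor, acceptor)`` in 0-based genomic coordinates."""

    chrom: str
    donor: int  # first intronic base
    acceptor: int  # one past the last intronic base

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError("junction donor must precede acceptor")

    @property
    def span(self) -> int:
        return self.acceptor - self.donor


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene model {self.id}: start must be < end")


@dataclass(frozen=True)
class LibrarySummary:
    """Read-mapping bookkeeping for a sequencing run.

    Percentages are rounded half-up to the nearest integer, matching the
    convention of printed mapping summaries.
    """

    total_reads: int
    mapped_reads: int
    unique_reads: int
    per_sample_uniques: dict[str, int] = field(default_factory=dict)
    read_length: int = 40

    def __post_init__(self) -> None:
        if min(self.total_reads, self.mapped_reads, self.unique_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.unique_reads > self.mapped_reads:
            raise ValueError("unique reads cannot exceed mapped reads")
        if self.mapped_reads > self.total_reads:
            raise ValueError("mapped reads cannot exceed total reads")
        if self.per_sample_uniques:
            s = sum(self.per_sample_uniques.values())
            if s != self.unique_reads:
                raise ValueError(
                    f"per-sample unique reads sum to {s}, expected {self.unique_reads}"
                )

    @property
    def mapped_pct(self) -> int:
        return int(round_half_up(100.0 * self.mapped_reads / self.total_reads))

    @property
    def unique_pct(self) -> int:
        return int(round_half_up(100.0 * self.unique_reads / self.total_reads))

    @property
    def total_bases(self) -> int:
        return self.total_reads * self.read_length


def summarize_libraries(
    total_reads: int,
    mapped_reads: int,
    unique_reads: int,
    per_sample_uniques: dict[str, int] | None = None,
    read_length: int = 40,
) -> LibrarySummary:
    """Build a :class:`LibrarySummary` from raw mapping counts."""
    return LibrarySummary(
        total_reads=total_reads,
        mapped_reads=mapped_reads,
        unique_reads=unique_reads,
        per_sample_uniques=dict(per_sample_uniques or {}),
        read_length=read_length,
    )


# ---------------------------------------------------------------------------
# Alignments


_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


def read_alignments(
    path: str | os.PathLike,
    format: str = "tsv",
    sample: str | None = None,
) -> list[AlignmentInterval]:
    """Load uniquely mapped primary alignments as genomic intervals.

    format="sam": unmapped / secondary / supplementary records are
    skipped; CIGAR M consumes reference into aligned segments, N splits
    a read across an intron into several segments with a shared read id.
    The sample label is taken from the RG tag when present, else from
    ``sample``.

    format="tsv": tab-separated ``chrom  start  end  sample  [read_id]``
    with 0-based half-open coordinates (header optional).
    """
    fmt = format.lower()
    if fmt == "sam":
        return _read_sam(str(path), sample)
    if fmt in ("tsv", "interval-tsv"):
        return _read_tsv(str(path), sample)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_sam(path: str, sample: str | None) -> list[AlignmentInterval]:
    out: list[AlignmentInterval] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.flag & _EXCLUDE_FLAGS:
                continue
            if rec.cigartuples is None:
                continue
            try:
                rg = rec.get_tag("RG")
            except KeyError:
                rg = None
            label = str(rg) if rg is not None else sample
            if label is None:
                raise ValueError(
                    f"record {rec.query_name}: no RG tag and no sample label given"
                )
            pos = rec.reference_start  # pysam converts POS to 0-based
            chrom = rec.reference_name
            seg_start = pos
            cursor = pos
            for op, ln in rec.cigartuples:
                if op == 0:  # M
                    cursor += ln
                elif op == 3:  # N: close current segment, jump the intron
                    if cursor > seg_start:
                        out.append(
                            AlignmentInterval(
                                chrom, seg_start, cursor, label, rec.query_name
                            )
                        )
                    cursor += ln
                    seg_start = cursor
                elif op in (1, 4, 5):  # I, S, H: no reference consumed
                    continue
                else:
                    raise ValueError(
                        f"record {rec.query_name}: unsupported CIGAR op {op}"
                    )
            if cursor > seg_start:
                out.append(
                    AlignmentInterval(chrom, seg_start, cursor, label, rec.query_name)
                )
    return out


def _read_tsv(path: str, sample: str | None) -> list[AlignmentInterval]:
    out: list[AlignmentInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("chrom", "chr"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 and fields[3] else sample
                read_id = fields[4] if len(fields) > 4 else None
                if label is None:
                    raise ValueError("no sample column and no sample label given")
                out.append(AlignmentInterval(chrom, start, end, label, read_id))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
    return out


def write_alignments_tsv(
    alignments: Iterable[AlignmentInterval], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\tread_id\n")
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.sample}\t{a.read_id or ''}\n")


def write_alignments_sam(
    alignments: Sequence[AlignmentInterval],
    path: str | os.PathLike,
    chrom_lengths: dict[str, int],
) -> None:
    """Write segments as SAM; segments sharing a read id become one
    record with an N-gapped CIGAR."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        "RG": [
            {"ID": s} for s in sorted({a.sample for a in alignments})
        ],
    }
    by_read: dict[str, list[AlignmentInterval]] = {}
    order: list[str] = []
    for i, a in enumerate(alignments):
        key = a.read_id if a.read_id is not None else f"__anon{i}"
        if key not in by_read:
            by_read[key] = []
            order.append(key)
        by_read[key].append(a)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for key in order:
            segs = sorted(by_read[key], key=lambda s: s.start)
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = key
            rec.reference_name = segs[0].chrom
            rec.reference_start = segs[0].start
            rec.mapping_quality = 50
            rec.flag = 0
            cigar: list[tuple[int, int]] = []
            for j, s in enumerate(segs):
                if j > 0:
                    gap = s.start - segs[j - 1].end
                    if gap <= 0:
                        raise ValueError(f"read {key}: overlapping segments")
                    cigar.append((3, gap))
                cigar.append((0, s.end - s.start))
            rec.cigartuples = cigar
            qlen = sum(ln for op, ln in cigar if op == 0)
            rec.query_sequence = "N" * qlen
            rec.set_tag("RG", segs[0].sample)
            fh.write(rec)


# ---------------------------------------------------------------------------
# Junctions (BED12, TopHat junctions.bed dialect)


def read_junctions(path: str | os.PathLike) -> list[SpliceJunction]:
    """Parse TopHat-style BED12 junctions.

    Each line has two blocks (the exonic anchors); the intron is
    ``donor = chromStart + blockSizes[0]`` to
    ``acceptor = chromStart + blockStarts[1]``.
    """
    out: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            try:
                chrom, chrom_start = f[0], int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if n_blocks != 2 or len(sizes) != 2 or len(starts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: junction must have exactly 2 blocks"
                )
            donor = chrom_start + sizes[0]
            acceptor = chrom_start + starts[1]
            out.append(SpliceJunction(chrom, donor, acceptor))
    return out


def write_junctions_bed(
    junctions: Iterable[SpliceJunction],
    path: str | os.PathLike,
    anchor: int = 40,
) -> None:
    """Write junctions as 2-block BED12 with fixed-width exonic anchors."""
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            chrom_start = max(0, j.donor - anchor)
            size0 = j.donor - chrom_start
            chrom_end = j.acceptor + anchor
            fh.write(
                "\t".join(
                    [
                        j.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        f"JUNC{i + 1:05d}",
                        "1",
                        "+",
                        str(chrom_start),
                        str(chrom_end),
                        "255,0,0",
                        "2",
                        f"{size0},{anchor}",
                        f"0,{j.acceptor - chrom_start}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def read_gene_models(
    path: str | os.PathLike, feature_type: str = "gene"
) -> list[GeneModel]:
    """Load gene features from GFF3 and convert to 0-based half-open."""
    import gffutils

    if os.path.getsize(path) == 0:
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        out.append(GeneModel(feat.seqid, feat.start - 1, feat.end, feat.id))
    return out


def write_gene_models_gff3(
    models: Iterable[GeneModel], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tmossdge\tgene\t{m.start + 1}\t{m.end}\t.\t+\t.\tID={m.id}\n"
            )


# ---------------------------------------------------------------------------
# DE result table round-trip

DE_COLUMNS = [
    "block_id",
    "x",
    "y",
    "rpm1",
    "rpm2",
    "fold",
    "log2_fc",
    "p",
    "q",
    "direction",
    "passes_filters",
]


def write_de_table(results: Iterable, path: str | os.PathLike) -> None:
    """Write DE results as a TSV that round-trips through read_de_table."""
    rows = []
    for r in results:
        rows.append({c: getattr(r, c) for c in DE_COLUMNS})
    df = pd.DataFrame(rows, columns=DE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
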