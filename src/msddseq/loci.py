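"""Genome-dependent locus catalog and count matrix.

Aligned reads from all samples are pooled into an experiment-wise
annotation: each alignment contributes the reference interval it covers,
redundant/overlapping intervals are merged per strand (bookended intervals
merge too — fragment ends emanating from one restriction site belong to one
locus), and the merged intervals become the catalog rows of a locus ×
sample count matrix.

"Unique mapping" is operationalized as MAPQ >= ``min_mapq`` (default 20)
and neither secondary nor supplementary flags set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes that consume the reference
_REF_OPS = {0, 2, 7, 8}  # M, D, =, X
_QUERY_ONLY_OPS = {1, 4, 5}  # I, S, H


@dataclass(frozen=True)
class ReadInterval:
    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    unique: bool


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str


class LocusCatalog:
    """Sorted, per-strand non-overlapping merged intervals."""

    def __init__(self, loci: list[Locus], context: str = "none") -> None:
        self.loci = sorted(loci, key=lambda l: (l.chrom, l.start, l.strand))
        self.context = context
        self._by_id = {l.locus_id: l for l in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> Locus:
        return self._by_id[locus_id]

    def to_gff(self, path) -> None:
        """GFF3 (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for l in self.loci:
                fh.write(
                    f"{l.chrom}\tmsddseq\tsequence_feature\t{l.start + 1}\t{l.end}"
                    f"\t.\t{l.strand}\t.\tID={l.locus_id}\n"
                )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for l in self.loci:
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t{l.strand}\n")


def intervals_from_cigar(
    reference_start: int, cigartuples: list[tuple[int, int]]
) -> tuple[int, int]:
    """Reference interval covered by an alignment: clips and insertions do
    not consume reference; deletions do."""
    span = 0
    for op, length in cigartuples:
        if length <= 0:
            raise ValueError("CIGAR block lengths must be positive")
        if op in _REF_OPS:
            span += length
    if span == 0:
        raise ValueError("alignment covers no reference bases")
    return reference_start, reference_start + span


def intervals_from_alignment(segment: pysam.AlignedSegment) -> tuple[int, int]:
    return intervals_from_cigar(segment.reference_start, segment.cigartuples)


def read_sam(path, sample_id: str, min_mapq: int = 20) -> list[ReadInterval]:
    """Read intervals from one sample's SAM/BAM, flagging uniqueness."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            start, end = intervals_from_alignment(seg)
            unique = (
                seg.mapping_quality >= min_mapq
                and not seg.is_secondary
                and not seg.is_supplementary
            )
            out.append(
                ReadInterval(
                    chrom=seg.reference_name,
                    start=start,
                    end=end,
                    strand="-" if seg.is_reverse else "+",
                    sample_id=sample_id,
                    unique=unique,
                )
            )
    return out


def merge_intervals(
    intervals: list[tuple[str, int, int, str]]
) -> list[tuple[str, int, int, str]]:
    """Merge overlapping or bookended intervals per (chrom, strand)."""
    merged: list[tuple[str, int, int, str]] = []
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, start, end, strand in intervals:
        by_key.setdefault((chrom, strand), []).append((start, end))
    for (chrom, strand), ivs in by_key.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e, strand))
    merged.sort()
    return merged


def build_catalog(
    segments: list[ReadInterval], context: str = "none"
) -> LocusCatalog:
    """Pool uniquely mapped reads from all samples and merge their intervals
    strand-aware into the experiment-wise locus catalog."""
    unique = [s for s in segments if s.unique]
    if not unique:
        warnings.warn("no uniquely mapped reads; catalog is empty")
        return LocusCatalog([], context)
    merged = merge_intervals([(s.chrom, s.start, s.end, s.strand) for s in unique])
    loci = [
        Locus(f"locus_{i + 1:06d}", chrom, start, end, strand)
        for i, (chrom, start, end, strand) in enumerate(merged)
    ]
    logger.info(
        "catalog: %d loci from %d uniquely mapped reads (%d dropped)",
        len(loci), len(unique), len(segments) - len(unique),
    )
    return LocusCatalog(loci, context)


def count_reads(
    segments: list[ReadInterval], catalog: LocusCatalog
) -> tuple[pd.DataFrame, pd.Series]:
    """Locus × sample matrix: every retained read increments exactly one
    same-strand locus; a read overlapping two loci goes to the larger
    overlap, ties are discarded.  Returns (matrix, per-sample totals of
    retained reads)."""
    samples = sorted({s.sample_id for s in segments})
    mat = pd.DataFrame(
        0, index=[l.locus_id for l in catalog], columns=samples, dtype=int
    )
    by_key: dict[tuple[str, str], list[Locus]] = {}
    for l in catalog:
        by_key.setdefault((l.chrom, l.strand), []).append(l)
    starts = {
        k: [l.start for l in ls] for k, ls in by_key.items()
    }
    import bisect

    totals = pd.Series(0, index=samples, dtype=int)
    n_unassigned = 0
    for seg in segments:
        if not seg.unique:
            continue
        totals[seg.sample_id] += 1
        ls = by_key.get((seg.chrom, seg.strand))
        if not ls:
            n_unassigned += 1
            continue
        st = starts[(seg.chrom, seg.strand)]
        i = bisect.bisect_right(st, seg.start) - 1
        cands = [ls[j] for j in range(max(i, 0), min(i + 2, len(ls)))]
        overlaps = [
            (min(l.end, seg.end) - max(l.start, seg.start), l) for l in cands
        ]
        overlaps = [(o, l) for o, l in overlaps if o > 0]
        if not overlaps:
            n_unassigned += 1
            continue
        best = max(o for o, _ in overlaps)
        hits = [l for o, l in overlaps if o == best]
        if len(hits) != 1:
            n_unassigned += 1
            continue
        mat.loc[hits[0].locus_id, seg.sample_id] += 1
    if n_unassigned:
        logger.info("count_reads: %d retained reads not assigned", n_unassigned)
    return mat, totals
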