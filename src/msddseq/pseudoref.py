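"""Reference-free workflow: demultiplexing and pseudo-reference contigs.

Reads carry a 7-bp sample barcode at the methylation-sensitive end.  After
demultiplexing, reads are collapsed into contigs that act as a
pseudo-reference genome when no assembly is available; per-contig,
per-sample read counts then feed the same locus-counting statistics as the
genome-dependent workflow.

The collapser is a transparent greedy clusterer (most abundant sequence
first, join the first contig whose representative is at least
``identity_threshold`` identical, else seed a new contig).  Identity is
Hamming identity for equal-length sequences and edit-distance identity
(edlib) otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY = 0.94


@dataclass(frozen=True)
class Barcode:
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 7:
            raise ValueError("barcodes must be 7 bp")


@dataclass
class Contig:
    contig_id: str
    representative: str
    abundance: int = 0
    member_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.representative:
            raise ValueError("contig representative must be non-empty")


def _check_barcode_table(barcodes: dict[str, str], max_mismatch: int) -> None:
    items = sorted(barcodes.items())
    seqs = [s for _, s in items]
    if len(set(seqs)) != len(seqs):
        raise ValueError("barcodes must be unique")
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {seqs[i]} and {seqs[j]} are only {d} mismatches "
                    f"apart; demultiplexing at max_mismatch={max_mismatch} "
                    "would be ambiguous"
                )


def demultiplex_reads(
    fastq_path,
    barcodes: dict[str, str],
    out_dir,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Assign each read to the unique barcode within ``max_mismatch`` of its
    7-bp prefix, strip the prefix, and write one FASTQ per sample plus a
    discard file.  Returns per-sample assigned/discarded counts."""
    _check_barcode_table(barcodes, max_mismatch)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bc_len = len(next(iter(barcodes.values())))
    by_seq = {seq: sample for sample, seq in barcodes.items()}

    handles = {
        s: open(out_dir / f"{s}.fastq", "w") for s in sorted(barcodes)
    }
    discard = open(out_dir / "discarded.fastq", "w")
    counts = {s: 0 for s in barcodes}
    n_discarded = 0
    try:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            prefix = str(rec.seq[:bc_len])
            sample = by_seq.get(prefix)
            if sample is None and max_mismatch > 0:
                best = [
                    s
                    for seq, s in by_seq.items()
                    if sum(a != b for a, b in zip(prefix, seq)) <= max_mismatch
                ]
                sample = best[0] if len(best) == 1 else None
            if sample is None:
                n_discarded += 1
                SeqIO.write(rec, discard, "fastq")
            else:
                counts[sample] += 1
                SeqIO.write(rec[bc_len:], handles[sample], "fastq")
    finally:
        for fh in handles.values():
            fh.close()
        discard.close()
    logger.info(
        "demultiplexed %d reads (%d discarded)", sum(counts.values()), n_discarded
    )
    rows = [(s, counts[s]) for s in sorted(counts)] + [("__discarded__", n_discarded)]
    return pd.DataFrame(rows, columns=["sample", "n_reads"])


def sequence_identity(a: str, b: str) -> float:
    """Hamming identity on equal lengths, edit-distance identity otherwise."""
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def collapse_reads(
    reads: list[str], identity_threshold: float = DEFAULT_IDENTITY
) -> list[Contig]:
    """Greedy collapsing: unique sequences ordered by (abundance desc,
    sequence asc); each joins the first contig at/above the identity
    threshold, else seeds a new one."""
    if not reads:
        raise ValueError("no reads to collapse")
    abundance: dict[str, int] = {}
    for r in reads:
        abundance[r] = abundance.get(r, 0) + 1
    ordered = sorted(abundance, key=lambda s: (-abundance[s], s))
    contigs: list[Contig] = []
    for seq in ordered:
        placed = False
        for c in contigs:
            if sequence_identity(seq, c.representative) >= identity_threshold:
                c.abundance += abundance[seq]
                placed = True
                break
        if not placed:
            contigs.append(
                Contig(f"contig_{len(contigs) + 1}", seq, abundance[seq])
            )
    return contigs


def assign_reads_to_contigs(
    per_sample_reads: dict[str, list[str]],
    contigs: list[Contig],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> pd.DataFrame:
    """Count each read toward its best-identity contig; reads that tie
    between contigs or fall below the threshold are discarded (only
    uniquely placed reads are retained)."""
    index = [c.contig_id for c in contigs]
    mat = pd.DataFrame(
        0, index=index, columns=sorted(per_sample_reads), dtype=int
    )
    exact = {c.representative: c.contig_id for c in contigs}
    n_ambiguous = 0
    cache: dict[str, str | None] = {}
    for sample in sorted(per_sample_reads):
        for read in per_sample_reads[sample]:
            cid = exact.get(read)
            if cid is None:
                if read in cache:
                    cid = cache[read]
                else:
                    scores = [
                        (sequence_identity(read, c.representative), c.contig_id)
                        for c in contigs
                    ]
                    best = max(s for s, _ in scores)
                    hits = [cid_ for s, cid_ in scores if s == best]
                    cid = (
                        hits[0]
                        if best >= identity_threshold and len(hits) == 1
                        else None
                    )
                    cache[read] = cid
            if cid is None:
                n_ambiguous += 1
            else:
                mat.loc[cid, sample] += 1
    if n_ambiguous:
        logger.info("discarded %d ambiguous/unassigned reads", n_ambiguous)
    for c in contigs:
        c.member_counts = mat.loc[c.contig_id].to_dict()
    return mat


def read_fastq_sequences(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_pseudo_reference(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} abundance={c.abundance}\n{c.representative}\n")
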