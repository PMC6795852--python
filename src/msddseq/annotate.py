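"""Gene-context annotation of methylation features.

Genes are extended into EGBs (extended gene bodies): the transcribed span
plus a fixed flank upstream of the TSS and downstream of the TTS,
strand-aware.  Positions are classified into {upstream, exon, intron,
downstream, intergenic}; differentially methylated genes (DMGs) are genes
whose EGB is overlapped by at least one DMR; and feature enrichment per
partition is assessed with a two-sided exact binomial test against the
partition distribution of the whole locus catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

PARTITIONS = ("upstream", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open gene span
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene span must be non-empty")
        prev = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e or s < prev:
                raise ValueError("exons must be sorted, disjoint, within the gene")
            prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class EGB:
    gene: GeneModel
    start: int
    end: int
    flank: int

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def chrom(self) -> str:
        return self.gene.chrom


@dataclass
class EnrichmentResult:
    partition: str
    expected_proportion: float
    n_trials: int
    observed: int
    p_value: float
    q_value: float = np.nan

    @property
    def direction(self) -> str:
        expected = self.expected_proportion * self.n_trials
        if self.observed > expected:
            return "enriched"
        if self.observed < expected:
            return "depleted"
        return "neutral"


def load_genes(gff3_path) -> list[GeneModel]:
    """Gene models (with exons) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(g, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start - 1, end=g.end, exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def build_egbs(
    genes: list[GeneModel],
    flank: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[EGB]:
    """Gene spans extended by ``flank`` on both sides, clipped to
    chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    out = []
    for g in genes:
        start = max(0, g.start - flank)
        end = g.end + flank
        if chrom_lengths and g.chrom in chrom_lengths:
            end = min(end, chrom_lengths[g.chrom])
        out.append(EGB(gene=g, start=start, end=end, flank=flank))
    return out


def _zone(pos: int, egb: EGB) -> str:
    g = egb.gene
    if g.start <= pos < g.end:
        for s, e in g.exons:
            if s <= pos < e:
                return "exon"
        return "intron" if g.exons else "exon"
    upstream_side = pos < g.start if g.strand == "+" else pos >= g.end
    return "upstream" if upstream_side else "downstream"


def classify_position(
    pos: int | tuple[int, int], chrom: str, egbs: list[EGB]
) -> str:
    """Partition of a position (or of an interval's midpoint).  A position
    inside several EGBs is classified against the gene with the nearest
    TSS."""
    if isinstance(pos, tuple):
        pos = (pos[0] + pos[1] - 1) // 2
    hits = [e for e in egbs if e.chrom == chrom and e.start <= pos < e.end]
    if not hits:
        return "intergenic"
    best = min(hits, key=lambda e: (abs(pos - e.gene.tss), e.gene_id))
    return _zone(pos, best)


def call_dmgs(dmrs, egbs: list[EGB]) -> pd.DataFrame:
    """Per-gene counts of DMRs overlapping the upstream flank, gene body,
    and downstream flank (any overlap counts; a DMR spanning a boundary is
    counted in every zone it touches); genes with >= 1 overlap are DMGs."""
    rows = []
    for egb in egbs:
        g = egb.gene
        if g.strand == "+":
            up = (egb.start, g.start)
            down = (g.end, egb.end)
        else:
            up = (g.end, egb.end)
            down = (egb.start, g.start)
        zones = {"upstream": up, "body": (g.start, g.end), "downstream": down}
        counts = {z: 0 for z in zones}
        for d in dmrs:
            if d.chrom != egb.chrom:
                continue
            d_end = d.end if d.end > d.start else d.start + 1
            for z, (zs, ze) in zones.items():
                if max(d.start, zs) < min(d_end, ze):
                    counts[z] += 1
        total = sum(counts.values())
        if total:
            rows.append(
                {
                    "gene_id": g.gene_id, "chrom": g.chrom,
                    "upstream": counts["upstream"], "body": counts["body"],
                    "downstream": counts["downstream"], "total": total,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "upstream", "body", "downstream", "total"]
    )


def binomial_enrichment(
    feature_partitions: list[str],
    catalog_partitions: list[str],
    partitions: tuple[str, ...] = PARTITIONS,
) -> list[EnrichmentResult]:
    """Two-sided exact binomial test per partition: expected proportion p0
    from the whole locus catalog, observed k among the features."""
    if not catalog_partitions:
        raise ValueError("catalog partition list is empty")
    n = len(feature_partitions)
    cat = pd.Series(catalog_partitions).value_counts()
    results = []
    for part in partitions:
        p0 = float(cat.get(part, 0)) / len(catalog_partitions)
        k = sum(1 for f in feature_partitions if f == part)
        if n == 0 or (p0 == 0 and k == 0):
            p = 1.0
        else:
            p = binomtest(k, n, p0, alternative="two-sided").pvalue
        results.append(
            EnrichmentResult(
                partition=part, expected_proportion=p0, n_trials=n,
                observed=k, p_value=float(p),
            )
        )
    q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    """Emit gene models (with exons) as GFF3; used by the simulator."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmsddseq\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tmsddseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
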