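"""Allele-specific methylation-responsive (ASMR) sites.

At a heterozygous SNP inside a methylation-sensitive locus, the two
alleles contribute reads in proportion to their (un)methylation.  The
reference-allele frequency per sample,

    f = REF / (REF + ALT) ,

is compared between treatment groups with a two-sample Student's t-test
(Welch optional) and Benjamini-Hochberg correction; a significant shift
marks the site as ASMR.  Sites with raw coverage below ``min_cov``
(default 25 reads) are excluded.  Allele counts may be reads-per-million
normalized across samples for bookkeeping; the frequency itself is
scale-invariant, so the coverage filter is applied to raw depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AllelicCounts:
    chrom: str
    pos: int            # 0-based
    ref: str
    alt: str
    ref_depth: dict[str, int]
    alt_depth: dict[str, int]

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def total_depth(self, sample: str) -> int:
        return self.ref_depth[sample] + self.alt_depth[sample]


@dataclass
class ASMRSite:
    chrom: str
    pos: int
    frequencies: dict[str, float]
    mean_control: float
    mean_treated: float
    p_value: float
    q_value: float = np.nan
    is_asmr: bool = False
    dmp_overlap: bool = False
    egb_partition: str = ""
    degenerate: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def load_allele_counts(vcf_path) -> list[AllelicCounts]:
    """Biallelic SNPs with per-sample allele depths (AD) from a VCF;
    multi-allelic records, indels and records without depths are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    out = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None or ad.shape[1] < 2:
            logger.warning("site %s:%d has no AD field; skipped", rec.CHROM, rec.POS)
            n_skipped += 1
            continue
        ref_d = {s: int(max(ad[i, 0], 0)) for i, s in enumerate(samples)}
        alt_d = {s: int(max(ad[i, 1], 0)) for i, s in enumerate(samples)}
        out.append(
            AllelicCounts(
                chrom=rec.CHROM, pos=rec.POS - 1, ref=rec.REF, alt=rec.ALT[0],
                ref_depth=ref_d, alt_depth=alt_d,
            )
        )
    if n_skipped:
        logger.info("skipped %d non-biallelic/undepthed records", n_skipped)
    return out


def ref_allele_frequency(
    counts: AllelicCounts, min_cov: int = 25
) -> dict[str, float] | None:
    """Per-sample reference-allele frequency REF/(REF+ALT); ``None`` when
    any sample's raw coverage is below min_cov (site excluded)."""
    freqs = {}
    for s in counts.ref_depth:
        tot = counts.total_depth(s)
        if tot < min_cov:
            return None
        freqs[s] = counts.ref_depth[s] / tot
    return freqs


def test_allelic_shift(
    sites: list[AllelicCounts],
    design: dict[str, str],
    alpha: float = 0.05,
    min_cov: int = 25,
    equal_var: bool = True,
) -> list[ASMRSite]:
    """Student's t-test (Welch when equal_var=False) on per-replicate
    reference-allele frequencies between the two groups, BH-corrected;
    is_asmr iff adjusted p < alpha."""
    names = list(dict.fromkeys(design.values()))
    if len(names) != 2:
        raise ValueError("exactly two treatment groups are required")
    out: list[ASMRSite] = []
    pvals = []
    for site in sites:
        freqs = ref_allele_frequency(site, min_cov=min_cov)
        if freqs is None:
            continue
        f1 = np.array([freqs[s] for s in freqs if design.get(s) == names[0]])
        f2 = np.array([freqs[s] for s in freqs if design.get(s) == names[1]])
        if len(f1) < 2 or len(f2) < 2:
            raise ValueError("at least two replicates per group are required")
        degenerate = False
        if f1.std(ddof=1) < 1e-12 and f2.std(ddof=1) < 1e-12:
            degenerate = True
            p = 1.0 if abs(f1.mean() - f2.mean()) < 1e-12 else 0.0
            if p == 0.0:
                logger.warning(
                    "site %s: both groups constant with different means", site.site_id
                )
        else:
            p = float(ttest_ind(f1, f2, equal_var=equal_var).pvalue)
        out.append(
            ASMRSite(
                chrom=site.chrom, pos=site.pos, frequencies=freqs,
                mean_control=float(f1.mean()), mean_treated=float(f2.mean()),
                p_value=p, degenerate=degenerate,
            )
        )
        pvals.append(p)
    if not out:
        return out
    q = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    for site, qv in zip(out, q):
        site.q_value = float(qv)
        site.is_asmr = qv < alpha
    logger.info(
        "test_allelic_shift: %d ASMR of %d tested sites",
        sum(s.is_asmr for s in out), len(out),
    )
    return out


def classify_asmr_overlap(
    asmr_sites: list[ASMRSite], dmps, catalog=None
) -> dict[str, int]:
    """Flag ASMR sites lying within a DMP-bearing locus; returns the
    DMP-overlap vs ASMR-only partition counts."""
    dmp_intervals = [(d.chrom, d.pos, max(d.end, d.pos + 1)) for d in dmps]
    n_overlap = 0
    for site in asmr_sites:
        if not site.is_asmr:
            continue
        hit = any(
            c == site.chrom and s <= site.pos < e for c, s, e in dmp_intervals
        )
        site.dmp_overlap = hit
        n_overlap += hit
    total = sum(1 for s in asmr_sites if s.is_asmr)
    return {
        "dmp_asmr": n_overlap,
        "asmr_only": total - n_overlap,
        "total_asmr": total,
    }


def locate_asmr(asmr_sites: list[ASMRSite], egbs) -> pd.DataFrame:
    """Genomic partition of each ASMR site via the EGB classification."""
    from .annotate import classify_position

    rows = []
    for site in asmr_sites:
        if not site.is_asmr:
            continue
        site.egb_partition = classify_position(site.pos, site.chrom, egbs)
        rows.append((site.site_id, site.egb_partition))
    table = pd.DataFrame(rows, columns=["site_id", "partition"])
    return (
        table.groupby("partition").size().rename("n_sites").reset_index()
        if len(table)
        else pd.DataFrame(columns=["partition", "n_sites"])
    )


def asmr_to_tsv(sites: list[ASMRSite], path) -> None:
    rows = [
        {
            "chrom": s.chrom, "pos": s.pos,
            "mean_control": s.mean_control, "mean_treated": s.mean_treated,
            "p_value": s.p_value, "q_value": s.q_value,
            "is_asmr": s.is_asmr, "dmp_overlap": s.dmp_overlap,
            "egb_partition": s.egb_partition,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "mean_control", "mean_treated", "p_value",
            "q_value", "is_asmr", "dmp_overlap", "egb_partition",
        ],
    ).to_csv(path, sep="\t", index=False)
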