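"""Differential methylation statistics.

The locus × sample count matrix is normalized to reads per million,
filtered (raw total >= ``min_total``; summed normalized coverage >=
``min_locus_coverage``; within-replicate-group relative-count standard
deviation <= ``max_sd``), and rescaled to relative methylation levels: per
locus, the sample with the highest normalized count is taken as the fully
unmethylated reference (level 0) and the others scale proportionally,

    level_s = (c_max - c_s) / c_max .

Differentially methylated positions (DMPs) are called per locus by a
binomial logistic regression of methylation on treatment group.  With a
single two-level factor the maximum-likelihood fits are the pooled group
proportions, so the likelihood-ratio test against the intercept-only model
is computed in closed form (df = 1); this is also robust where iterative
fitting separates.  Successes are round(level × pseudo-coverage) with
pseudo-coverage the locus maximum normalized count (floored at
``min_total``).  Benjamini-Hochberg controls FDR across loci.

Differentially methylated regions (DMRs) cluster adjacent, direction-
concordant significant DMPs by a re-anchoring window scan and validate
each candidate region with the same logistic model on pooled member
counts.  The window length is chosen by scanning 100..2000 bp and keeping
the length that maximizes the DMR count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame            # locus × sample RPM values (pre-filter)
    raw: pd.DataFrame               # raw counts, same shape
    totals: pd.Series               # per-sample library totals
    retained: pd.Series | None = None      # bool mask after filter_loci
    discard_reason: pd.Series | None = None

    @property
    def filtered(self) -> pd.DataFrame:
        if self.retained is None:
            return self.values
        return self.values.loc[self.retained]


@dataclass
class MethylationLevels:
    levels: pd.DataFrame            # locus × sample in [0,1]
    reference_count: pd.Series      # per-locus max normalized count
    positions: pd.DataFrame | None = None  # chrom/start/end/strand per locus


@dataclass
class DMP:
    locus_id: str
    chrom: str
    pos: int
    end: int
    strand: str
    mean_control: float
    mean_treated: float
    delta: float
    p_value: float
    q_value: float

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    members: list[str]
    direction: str
    window_length: int
    p_value: float = np.nan
    q_value: float = np.nan


def normalize_rpm(
    counts: pd.DataFrame, totals: pd.Series | None = None
) -> NormalizedMatrix:
    """Reads-per-million: value = raw * 1e6 / library_total.  When totals
    are not given they default to column sums (then each column of RPM
    values sums to 1e6)."""
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    totals = totals.reindex(counts.columns).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for samples {bad}")
    if (totals < counts.sum(axis=0)).any():
        raise ValueError("library totals below column sums")
    values = counts * 1e6 / totals
    return NormalizedMatrix(values=values, raw=counts, totals=totals)


def filter_loci(
    norm: NormalizedMatrix,
    design: dict[str, str],
    min_locus_coverage: float = 10.0,
    min_total: int = 4,
    max_sd: float = 0.08,
) -> NormalizedMatrix:
    """Discard loci with raw total < min_total, summed normalized coverage
    < min_locus_coverage, or within-group relative-count standard deviation
    above max_sd (replicate counts divided by the locus total)."""
    raw_total = norm.raw.sum(axis=1)
    rpm_total = norm.values.sum(axis=1)
    reason = pd.Series("", index=norm.values.index, dtype=object)
    reason[raw_total < min_total] = "total_reads"
    low_cov = (reason == "") & (rpm_total < min_locus_coverage)
    reason[low_cov] = "low_coverage"

    rel = norm.values.div(rpm_total.replace(0, np.nan), axis=0)
    groups = pd.Series(design).reindex(norm.values.columns)
    noisy = pd.Series(False, index=norm.values.index)
    for g in groups.dropna().unique():
        cols = groups.index[groups == g]
        if len(cols) >= 2:
            noisy |= rel[cols].std(axis=1, ddof=1) > max_sd
    reason[(reason == "") & noisy.fillna(False)] = "replicate_sd"

    retained = reason == ""
    logger.info(
        "filter_loci: %d/%d retained (%s)",
        int(retained.sum()), len(retained),
        dict(reason[~retained].value_counts()),
    )
    return NormalizedMatrix(
        values=norm.values,
        raw=norm.raw,
        totals=norm.totals,
        retained=retained,
        discard_reason=reason,
    )


def rescale_to_methylation(
    norm: NormalizedMatrix, positions: pd.DataFrame | None = None
) -> MethylationLevels:
    """Max-count rescaling: the sample with the highest normalized count is
    the unmethylated reference (level exactly 0); levels lie in [0,1]."""
    vals = norm.filtered
    cmax = vals.max(axis=1)
    if (cmax <= 0).any():
        vals = vals.loc[cmax > 0]
        cmax = cmax.loc[cmax > 0]
    levels = (cmax.to_numpy()[:, None] - vals) / cmax.to_numpy()[:, None]
    if positions is not None:
        positions = positions.reindex(levels.index)
    return MethylationLevels(
        levels=levels, reference_count=cmax, positions=positions
    )


def _binom_ll(successes: np.ndarray, trials: np.ndarray) -> np.ndarray:
    p = np.clip(successes / trials, 1e-12, 1 - 1e-12)
    return successes * np.log(p) + (trials - successes) * np.log1p(-p)


def two_group_lrt(
    s1: np.ndarray, n1: np.ndarray, s2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Likelihood-ratio statistic of a binomial logistic regression on a
    two-level group factor versus the intercept-only model (closed form:
    the group MLEs are the pooled proportions)."""
    full = _binom_ll(s1, n1) + _binom_ll(s2, n2)
    null = _binom_ll(s1 + s2, n1 + n2)
    return np.maximum(2.0 * (full - null), 0.0)


def call_dmps(
    meth: MethylationLevels,
    design: dict[str, str],
    fdr: float = 0.05,
    min_delta: float = 0.0,
    min_total: int = 4,
) -> list[DMP]:
    """Per-locus binomial LRT of methylation on group, BH-corrected; a DMP
    has q <= fdr and |delta| >= min_delta (delta = treated - control mean
    level)."""
    groups = pd.Series(design)
    names = list(dict.fromkeys(groups.values))
    if len(names) != 2:
        raise ValueError("exactly two treatment groups are required")
    g_control, g_treated = names
    cols1 = [s for s in meth.levels.columns if design.get(s) == g_control]
    cols2 = [s for s in meth.levels.columns if design.get(s) == g_treated]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("at least two replicates per group are required")

    lev1 = meth.levels[cols1].to_numpy(float)
    lev2 = meth.levels[cols2].to_numpy(float)
    n = np.maximum(np.round(meth.reference_count.to_numpy()), min_total).astype(int)
    s1 = np.round(lev1 * n[:, None]).sum(axis=1)
    s2 = np.round(lev2 * n[:, None]).sum(axis=1)
    n1 = np.full_like(s1, 0) + n * len(cols1)
    n2 = np.full_like(s2, 0) + n * len(cols2)
    lrt = two_group_lrt(s1, n1, s2, n2)
    p = chi2.sf(lrt, df=1)
    p[(s1 + s2) == 0] = 1.0  # degenerate: all levels 0 everywhere
    q = multipletests(p, alpha=fdr, method="fdr_bh")[1]

    mean1 = lev1.mean(axis=1)
    mean2 = lev2.mean(axis=1)
    delta = mean2 - mean1
    pos = meth.positions
    out = []
    for i, locus_id in enumerate(meth.levels.index):
        if q[i] <= fdr and abs(delta[i]) >= min_delta and delta[i] != 0:
            if pos is not None:
                row = pos.loc[locus_id]
                chrom, start, end, strand = (
                    row["chrom"], int(row["start"]), int(row["end"]),
                    row.get("strand", "+"),
                )
            else:
                chrom, start, end, strand = locus_id, 0, 0, "+"
            out.append(
                DMP(
                    locus_id=locus_id, chrom=chrom, pos=start, end=end,
                    strand=strand,
                    mean_control=float(mean1[i]), mean_treated=float(mean2[i]),
                    delta=float(delta[i]),
                    p_value=float(p[i]), q_value=float(q[i]),
                )
            )
    logger.info("call_dmps: %d DMPs of %d loci", len(out), len(meth.levels))
    return out


def dmp_table(
    meth: MethylationLevels, design: dict[str, str], min_total: int = 4
) -> pd.DataFrame:
    """Per-locus test results for every locus (not only significant ones)."""
    groups = pd.Series(design)
    names = list(dict.fromkeys(groups.values))
    cols1 = [s for s in meth.levels.columns if design.get(s) == names[0]]
    cols2 = [s for s in meth.levels.columns if design.get(s) == names[1]]
    lev1 = meth.levels[cols1].to_numpy(float)
    lev2 = meth.levels[cols2].to_numpy(float)
    n = np.maximum(np.round(meth.reference_count.to_numpy()), min_total).astype(int)
    s1 = np.round(lev1 * n[:, None]).sum(axis=1)
    s2 = np.round(lev2 * n[:, None]).sum(axis=1)
    lrt = two_group_lrt(s1, n * len(cols1), s2, n * len(cols2))
    p = chi2.sf(lrt, df=1)
    p[(s1 + s2) == 0] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_control": lev1.mean(axis=1),
            "mean_treated": lev2.mean(axis=1),
            "delta": lev2.mean(axis=1) - lev1.mean(axis=1),
            "p_value": p,
            "q_value": q,
        },
        index=meth.levels.index,
    )


def direction_summary(dmps: list[DMP]) -> dict:
    """Hyper/hypo counts and their ratio (NaN when undefined)."""
    hyper = sum(1 for d in dmps if d.direction == "hyper")
    hypo = len(dmps) - hyper
    if hypo == 0:
        ratio = float("nan") if hyper == 0 else float("inf")
    else:
        ratio = hyper / hypo
    return {"hyper": hyper, "hypo": hypo, "ratio": ratio}


def _cluster_dmps(dmps: list[DMP], window_length: int) -> list[list[DMP]]:
    """Re-anchoring window scan.  Seed at the earliest unused significant
    DMP; repeatedly pull in the earliest unused DMP within window_length
    downstream of the current anchor whose direction matches; re-anchor at
    each inclusion; skipped discordant DMPs stay available to seed later
    clusters."""
    clusters: list[list[DMP]] = []
    by_chrom: dict[str, list[DMP]] = {}
    for d in dmps:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: d.pos)
        if any(a.pos > b.pos for a, b in zip(ds, ds[1:])):
            raise ValueError("DMPs must be position-sortable")
        used = [False] * len(ds)
        i = 0
        while i < len(ds):
            if used[i]:
                i += 1
                continue
            cluster = [ds[i]]
            used[i] = True
            anchor = ds[i].pos
            direction = ds[i].direction
            j = i + 1
            while j < len(ds):
                if used[j]:
                    j += 1
                    continue
                if ds[j].pos - anchor > window_length:
                    break
                if ds[j].direction == direction:
                    cluster.append(ds[j])
                    used[j] = True
                    anchor = ds[j].pos
                j += 1
            clusters.append(cluster)
            i += 1
    return clusters


def call_dmrs(
    dmps: list[DMP],
    meth: MethylationLevels,
    design: dict[str, str],
    window_length: int,
    min_dmps: int = 2,
    fdr: float = 0.05,
    min_total: int = 4,
) -> list[DMR]:
    """Cluster concordant significant DMPs with the re-anchoring scan, then
    validate each candidate (>= min_dmps members) by the region-level
    logistic regression on pooled member counts."""
    sig = [d for d in dmps if d.q_value <= fdr]
    candidates = [
        c for c in _cluster_dmps(sig, window_length) if len(c) >= min_dmps
    ]
    if not candidates:
        return []
    groups = pd.Series(design)
    names = list(dict.fromkeys(groups.values))
    cols1 = [s for s in meth.levels.columns if design.get(s) == names[0]]
    cols2 = [s for s in meth.levels.columns if design.get(s) == names[1]]
    n = np.maximum(
        np.round(meth.reference_count.to_numpy()), min_total
    ).astype(int)
    n_by_locus = pd.Series(n, index=meth.levels.index)

    stats = []
    for cluster in candidates:
        ids = [d.locus_id for d in cluster]
        lev1 = meth.levels.loc[ids, cols1].to_numpy(float)
        lev2 = meth.levels.loc[ids, cols2].to_numpy(float)
        nn = n_by_locus.loc[ids].to_numpy()[:, None]
        s1 = np.round(lev1 * nn).sum()
        s2 = np.round(lev2 * nn).sum()
        t1 = nn.sum() * len(cols1)
        t2 = nn.sum() * len(cols2)
        lrt = two_group_lrt(
            np.array([s1]), np.array([t1]), np.array([s2]), np.array([t2])
        )[0]
        stats.append(chi2.sf(lrt, df=1))
    q = multipletests(np.array(stats), alpha=fdr, method="fdr_bh")[1]

    out = []
    for cluster, p, qv in zip(candidates, stats, q):
        if qv > fdr:
            continue
        out.append(
            DMR(
                chrom=cluster[0].chrom,
                start=cluster[0].pos,
                end=cluster[-1].pos,
                members=[d.locus_id for d in cluster],
                direction=cluster[0].direction,
                window_length=window_length,
                p_value=float(p),
                q_value=float(qv),
            )
        )
    return out


def scan_window_lengths(
    dmps: list[DMP],
    meth: MethylationLevels,
    design: dict[str, str],
    lengths: range | list[int] = range(100, 2001, 100),
    min_dmps: int = 2,
    fdr: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """DMR count for each candidate window length; the chosen length is the
    argmax (ties -> smallest, the more conservative spans).  The table is
    returned for operator review."""
    rows = []
    for w in lengths:
        n = len(call_dmrs(dmps, meth, design, w, min_dmps=min_dmps, fdr=fdr))
        rows.append((w, n))
    table = pd.DataFrame(rows, columns=["window_length", "n_dmrs"])
    best = int(table.loc[table["n_dmrs"].idxmax(), "window_length"])
    return best, table


def dmrs_to_bed(dmrs: list[DMR], path) -> None:
    """BED6 with score = -log10(q)."""
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
            score = -np.log10(max(d.q_value, 1e-300))
            strand = "+" if d.direction == "hyper" else "-"
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end + 1}\t"
                f"{','.join(d.members)}\t{score:.2f}\t{strand}\n"
            )


def dmps_to_tsv(dmps: list[DMP], path) -> None:
    rows = [
        {
            "locus_id": d.locus_id, "chrom": d.chrom, "start": d.pos,
            "end": d.end, "strand": d.strand,
            "mean_control": d.mean_control, "mean_treated": d.mean_treated,
            "delta": d.delta, "p_value": d.p_value, "q_value": d.q_value,
            "direction": d.direction,
        }
        for d in dmps
    ]
    pd.DataFrame(
        rows,
        columns=[
            "locus_id", "chrom", "start", "end", "strand", "mean_control",
            "mean_treated", "delta", "p_value", "q_value", "direction",
        ],
    ).to_csv(path, sep="\t", index=False)
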