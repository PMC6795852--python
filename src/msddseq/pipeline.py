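"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes demultiplex -> catalog (or pseudo-reference) ->
count -> normalize -> filter -> rescale -> DMP -> DMR -> annotate -> ASMR,
writing every stage's output into a run directory so that stages are
individually re-runnable from saved intermediates.  Identical config and
inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, asmr, loci, methylation, pseudoref

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or malformed input (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    mode: str = "genome"                 # genome | reference_free
    context: str = "CG"
    groups: tuple[str, str] = ("WW", "DS")
    min_total: int = 4
    min_locus_coverage: float = 10.0
    max_sd: float = 0.08
    fdr: float = 0.05
    min_delta: float = 0.0
    window_range: tuple[int, int] = (100, 2000)
    window_step: int = 100
    window_length: int | None = None     # skip the scan when set
    min_dmps: int = 2
    size_select: tuple[int, int] = (250, 600)
    asmr_min_cov: int = 25
    asmr_alpha: float = 0.05
    egb_flank: int = 2000
    min_mapq: int = 20
    identity_threshold: float = 0.94
    max_mismatch: int = 1
    library_size: int | None = None      # RPM divisor override (else column sums)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("genome", "reference_free"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.fdr <= 1 or not 0 < self.asmr_alpha <= 1:
            raise ConfigError("fdr and asmr_alpha must lie in (0, 1]")
        if self.window_range[0] > self.window_range[1] or self.window_step <= 0:
            raise ConfigError("invalid window range/step")
        if self.size_select[0] > self.size_select[1]:
            raise ConfigError("invalid size-selection bounds")
        if self.min_dmps < 1 or self.min_total < 0 or self.asmr_min_cov < 0:
            raise ConfigError("count thresholds must be non-negative")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        for key in ("groups", "window_range", "size_select"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def design(self, samples: list[str]) -> dict[str, str]:
        d = {}
        for s in samples:
            g = s.rstrip("0123456789")
            if g not in self.groups:
                raise ConfigError(
                    f"sample {s!r} does not belong to groups {self.groups}"
                )
            d[s] = g
        return d


def _windows(config: PipelineConfig) -> range:
    lo, hi = config.window_range
    return range(lo, hi + 1, config.window_step)


def _positions_from_catalog(catalog: loci.LocusCatalog) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.locus_id, l.chrom, l.start, l.end, l.strand) for l in catalog],
        columns=["locus_id", "chrom", "start", "end", "strand"],
    ).set_index("locus_id")


def analyse_counts(
    counts: pd.DataFrame,
    positions: pd.DataFrame | None,
    config: PipelineConfig,
    out_dir: Path,
    totals: pd.Series | None = None,
    call_dmrs: bool = True,
) -> dict:
    """Shared statistics tail: normalize -> filter -> rescale -> DMP -> DMR."""
    design = config.design(list(counts.columns))
    if config.library_size is not None:
        totals = pd.Series(float(config.library_size), index=counts.columns)
    norm = methylation.normalize_rpm(counts, totals)
    filt = methylation.filter_loci(
        norm, design,
        min_locus_coverage=config.min_locus_coverage,
        min_total=config.min_total, max_sd=config.max_sd,
    )
    meth = methylation.rescale_to_methylation(filt, positions)
    meth.levels.to_csv(out_dir / "methylation_levels.tsv", sep="\t")
    filt.discard_reason.rename("reason").to_csv(out_dir / "locus_filter.tsv", sep="\t")

    dmps = methylation.call_dmps(
        meth, design, fdr=config.fdr, min_delta=config.min_delta,
        min_total=config.min_total,
    )
    methylation.dmps_to_tsv(dmps, out_dir / "dmps.tsv")
    table = methylation.dmp_table(meth, design, min_total=config.min_total)
    table.to_csv(out_dir / "dmp_table.tsv", sep="\t")

    dmrs: list[methylation.DMR] = []
    window = config.window_length
    if call_dmrs and positions is not None and dmps:
        if window is None:
            window, scan = methylation.scan_window_lengths(
                dmps, meth, design, _windows(config),
                min_dmps=config.min_dmps, fdr=config.fdr,
            )
            scan.to_csv(out_dir / "window_scan.tsv", sep="\t", index=False)
        dmrs = methylation.call_dmrs(
            dmps, meth, design, window,
            min_dmps=config.min_dmps, fdr=config.fdr,
        )
        methylation.dmrs_to_bed(dmrs, out_dir / "dmrs.bed")
    return {
        "design": design, "norm": norm, "filtered": filt, "meth": meth,
        "dmps": dmps, "dmrs": dmrs, "window_length": window,
        "summary": {
            "n_loci": int(len(counts)),
            "n_retained": int(filt.retained.sum()),
            "n_dmps": len(dmps),
            "n_dmrs": len(dmrs),
            "window_length": window,
            "direction": methylation.direction_summary(dmps),
        },
    }


def run_pipeline(config: PipelineConfig, inputs: dict, out_dir) -> dict:
    """Execute the full workflow for one methylation context.

    inputs (genome mode): sams={sample: path}, optionally genes (GFF3) and
    vcf.  inputs (reference-free): fastq, barcodes={sample: barcode}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_json(out_dir / "config.json")
    logging.basicConfig(level=logging.INFO)

    if config.mode == "genome":
        if "sams" not in inputs:
            raise ConfigError("genome mode requires per-sample alignments (sams)")
        segments = []
        for sample, path in sorted(inputs["sams"].items()):
            if not Path(path).exists():
                raise InputError(f"missing alignment file {path}")
            segments.extend(loci.read_sam(path, sample, min_mapq=config.min_mapq))
        catalog = loci.build_catalog(segments, context=config.context)
        catalog.to_gff(out_dir / "catalog.gff3")
        counts, totals = loci.count_reads(segments, catalog)
        positions = _positions_from_catalog(catalog)
    elif config.mode == "reference_free":
        if "fastq" not in inputs or "barcodes" not in inputs:
            raise ConfigError("reference-free mode requires fastq and barcodes")
        if not Path(inputs["fastq"]).exists():
            raise InputError(f"missing FASTQ {inputs['fastq']}")
        demux_dir = out_dir / "demux"
        demux_stats = pseudoref.demultiplex_reads(
            inputs["fastq"], inputs["barcodes"], demux_dir,
            max_mismatch=config.max_mismatch,
        )
        demux_stats.to_csv(out_dir / "demux_stats.tsv", sep="\t", index=False)
        per_sample = {
            s: pseudoref.read_fastq_sequences(demux_dir / f"{s}.fastq")
            for s in sorted(inputs["barcodes"])
        }
        pooled = [r for s in sorted(per_sample) for r in per_sample[s]]
        if not pooled:
            raise InputError("no reads survived demultiplexing")
        contigs = pseudoref.collapse_reads(pooled, config.identity_threshold)
        pseudoref.write_pseudo_reference(contigs, out_dir / "pseudo_reference.fa")
        counts = pseudoref.assign_reads_to_contigs(
            per_sample, contigs, config.identity_threshold
        )
        totals = None
        positions = None

    counts.to_csv(out_dir / "count_matrix.tsv", sep="\t")
    result = analyse_counts(
        counts, positions, config, out_dir, totals=totals,
        call_dmrs=config.mode == "genome",
    )

    # gene-context annotation
    if inputs.get("genes"):
        genes = annotate.load_genes(inputs["genes"])
        egbs = annotate.build_egbs(genes, flank=config.egb_flank)
        dmgs = annotate.call_dmgs(result["dmrs"], egbs)
        dmgs.to_csv(out_dir / "dmgs.tsv", sep="\t", index=False)
        result["dmgs"] = dmgs
        result["summary"]["n_dmgs"] = int(len(dmgs))
        if config.mode == "genome" and result["dmrs"]:
            catalog_parts = [
                annotate.classify_position(
                    (int(r.start), int(r.end)), r.chrom, egbs
                )
                for r in positions.itertuples()
            ]
            feature_parts = [
                annotate.classify_position((d.start, d.end + 1), d.chrom, egbs)
                for d in result["dmrs"]
            ]
            enr = annotate.binomial_enrichment(feature_parts, catalog_parts)
            pd.DataFrame(
                [dataclasses.asdict(e) | {"direction": e.direction} for e in enr]
            ).to_csv(out_dir / "dmr_enrichment.tsv", sep="\t", index=False)
            result["enrichment"] = enr
        result["egbs"] = egbs

    # allele-specific methylation response
    if inputs.get("vcf"):
        sites = asmr.load_allele_counts(inputs["vcf"])
        tested = asmr.test_allelic_shift(
            sites, result["design"], alpha=config.asmr_alpha,
            min_cov=config.asmr_min_cov,
        )
        overlap = asmr.classify_asmr_overlap(tested, result["dmps"])
        if "egbs" in result:
            asmr.locate_asmr(tested, result["egbs"])
        asmr.asmr_to_tsv(tested, out_dir / "asmr_sites.tsv")
        result["asmr"] = tested
        result["summary"]["asmr"] = overlap

    (out_dir / "summary.json").write_text(
        json.dumps(result["summary"], indent=1, default=float)
    )
    return result
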