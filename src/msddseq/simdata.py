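"""Synthetic methylation-sensitive double-digest experiments.

Generates everything a desk-scale run of the pipeline needs: a random
genome, per-sample methylomes with planted differential positions/regions,
methylation-dependent locus counts, barcoded single-end FASTQ, truth
alignments in SAM, per-sample allele depths in VCF, and machine-readable
truth tables.

Count model
-----------
A locus is a size-selected fragment end cut by the methylation-sensitive
enzyme.  Each library samples a roughly constant pool of DNA molecules per
locus (libraries are deliberately balanced at equimolar amounts), and a
molecule is cut — hence sequenced — only when its reporting base is
unmethylated.  The read count at locus *i* in sample *s* is therefore

    c_is ~ Binomial(n_i, 1 - level_is)

with ``n_i`` the molecule pool (``mean_coverage``).  Setting ``dispersion``
> 0 draws the pool itself from a negative binomial (gamma-Poisson) to add
library-level overdispersion; the default 0 keeps the pure thinning model.
Library totals are the size of the whole sequencing library, of which the
simulated loci are a small subset, so reads-per-million normalization
behaves as it would on real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import digest
from .digest import ENZYME_PAIRS, Fragment, default_registry, reverse_complement

PHRED_QUALITY = "I"  # fixed Q40; sequencing errors are not simulated


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-group experiment.

    Defaults emulate the drought-stress design: two groups (well-watered
    vs drought-stressed) of three biological replicates each, 7-bp
    barcodes, 1x150 single-end chemistry, 250-600 bp size selection.
    """

    seed: int = 0
    genome_length: int = 120_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.45
    context: str = "CG"
    groups: tuple[str, str] = ("WW", "DS")
    n_replicates: int = 3
    mean_coverage: float = 120.0
    library_size: int = 3_000_000
    dispersion: float = 0.0
    n_differential_loci: int = 20
    effect_size: float = 0.5
    n_dmr_regions: int = 0
    dmps_per_region: int = 3
    replicate_sd: float = 0.02
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    n_het_snps: int = 40
    n_asmr_sites: int = 8
    allelic_shift: float = 0.3
    snp_coverage: float = 60.0
    size_min: int = 250
    size_max: int = 600
    read_length: int = 150
    barcode_length: int = 7

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0,1]")
        for name in (
            "n_chromosomes", "n_replicates", "n_differential_loci",
            "n_dmr_regions", "n_het_snps", "n_asmr_sites",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.context not in ENZYME_PAIRS:
            raise ValueError(f"unknown methylation context {self.context!r}")

    @property
    def samples(self) -> list[str]:
        return [
            f"{g}{r}" for g in self.groups for r in range(1, self.n_replicates + 1)
        ]

    @property
    def design(self) -> dict[str, str]:
        return {s: s.rstrip("0123456789") for s in self.samples}


@dataclass
class SimLocus:
    """A size-selected fragment end cut by the sensitive enzyme."""

    locus_id: str
    chrom: str
    fragment_start: int
    fragment_end: int
    side: str            # 'left' or 'right': which fragment end is sensitive
    site_pos: int        # reporting-base position (forward strand)
    read_start: int      # interval covered by this locus's reads
    read_end: int
    strand: str

    @property
    def read_interval(self) -> tuple[int, int]:
        return self.read_start, self.read_end


@dataclass
class TruthTable:
    levels: pd.DataFrame                 # locus × sample true methylation
    dmps: list[dict] = field(default_factory=list)
    dmrs: list[dict] = field(default_factory=list)
    asmr_sites: list[dict] = field(default_factory=list)
    loci: list[SimLocus] = field(default_factory=list)

    def planted_dmp_ids(self) -> set[str]:
        return {d["locus_id"] for d in self.dmps}


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome with the requested length and GC content; the same seed
    always yields the same sequences."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    per_chrom = config.genome_length // config.n_chromosomes
    lengths = [per_chrom] * config.n_chromosomes
    lengths[-1] += config.genome_length - per_chrom * config.n_chromosomes
    genome = {}
    for i, n in enumerate(lengths, start=1):
        bases = rng.choice(np.array(list("ACGT")), size=n, p=probs)
        genome[f"chr{i}"] = "".join(bases)
    return genome


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def find_sim_loci(genome: dict[str, str], config: SimulationConfig) -> list[SimLocus]:
    """Digest the unmethylated genome, size-select, and emit one locus per
    sensitive fragment end.  Reads start at the sensitive cut and extend
    into the fragment."""
    registry = default_registry()
    sens_name, insens_name = ENZYME_PAIRS[config.context]
    sens, insens = registry[sens_name], registry[insens_name]
    read_span = config.read_length - config.barcode_length
    loci: list[SimLocus] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        frags = digest.double_digest(seq, sens, insens, chrom=chrom)
        selected = digest.size_select(frags, config.size_min, config.size_max)
        site_lookup = {
            s.cut_position(): s for s in digest.find_sites(seq, sens, chrom)
        }
        for frag in selected:
            for side, boundary in (("left", frag.start), ("right", frag.end)):
                enz = frag.left_enzyme if side == "left" else frag.right_enzyme
                if enz.name != sens.name:
                    continue
                site = site_lookup.get(boundary)
                if site is None:
                    continue
                span = min(read_span, len(frag))
                if side == "left":
                    read_start, read_end, strand = frag.start, frag.start + span, "+"
                else:
                    read_start, read_end, strand = frag.end - span, frag.end, "-"
                loci.append(
                    SimLocus(
                        locus_id=f"{chrom}:{boundary}:{side}",
                        chrom=chrom,
                        fragment_start=frag.start,
                        fragment_end=frag.end,
                        side=side,
                        site_pos=site.reporting_position(),
                        read_start=read_start,
                        read_end=read_end,
                        strand=strand,
                    )
                )
    loci.sort(key=lambda l: (l.chrom, l.read_start, l.side))
    return loci


def _plant_levels(
    loci: list[SimLocus], config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Baseline Beta levels, planted differential loci, planted regions."""
    n = len(loci)
    samples = config.samples
    a, b = config.baseline_beta
    base = rng.beta(a, b, size=n)
    g1 = base.copy()
    g2 = base.copy()

    available = list(range(n))
    dmr_truth: list[dict] = []
    planted_idx: list[int] = []
    planted_dir: list[str] = []

    # regions: runs of consecutive loci on one chromosome, concordant direction
    if config.n_dmr_regions > 0:
        k = config.dmps_per_region
        run_starts = [
            i
            for i in range(n - k + 1)
            if len({loci[j].chrom for j in range(i, i + k)}) == 1
        ]
        rng.shuffle(run_starts)
        used: set[int] = set()
        for start in run_starts:
            if len(dmr_truth) == config.n_dmr_regions:
                break
            members = list(range(start, start + k))
            if used.intersection(range(start - k, start + 2 * k)):
                continue
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            for i in members:
                planted_idx.append(i)
                planted_dir.append(direction)
            used.update(members)
            dmr_truth.append(
                {
                    "chrom": loci[start].chrom,
                    "start": loci[members[0]].read_start,
                    "end": loci[members[-1]].read_end,
                    "locus_ids": [loci[i].locus_id for i in members],
                    "direction": direction,
                }
            )
        available = [i for i in available if i not in used]

    n_single = min(config.n_differential_loci, len(available))
    singles = rng.choice(len(available), size=n_single, replace=False)
    for i in (available[j] for j in sorted(singles)):
        planted_idx.append(i)
        planted_dir.append("hyper" if rng.random() < 0.5 else "hypo")

    eff = config.effect_size
    dmp_truth: list[dict] = []
    for i, direction in zip(planted_idx, planted_dir):
        low = rng.uniform(0.05, max(0.05, 0.95 - eff))
        # hyper = treated group more methylated
        if direction == "hyper":
            g1[i], g2[i] = low, min(1.0, low + eff)
        else:
            g1[i], g2[i] = min(1.0, low + eff), low
        dmp_truth.append(
            {
                "locus_id": loci[i].locus_id,
                "chrom": loci[i].chrom,
                "pos": loci[i].read_start,
                "direction": direction,
                "delta": g2[i] - g1[i],
            }
        )

    group_means = {config.groups[0]: g1, config.groups[1]: g2}
    cols = {}
    for s in samples:
        g = config.design[s]
        jitter = rng.normal(0.0, config.replicate_sd, size=n)
        cols[s] = np.clip(group_means[g] + jitter, 0.0, 1.0)
    levels = pd.DataFrame(cols, index=[l.locus_id for l in loci])
    return levels, dmp_truth, dmr_truth


def plant_methylome(
    genome: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, dict[int, float]], TruthTable]:
    """Per-sample methylation levels at every sensitive reporting base of the
    simulated loci, plus the truth table of planted effects."""
    loci = find_sim_loci(genome, config)
    if not loci:
        raise ValueError(
            "no size-selected restriction loci in the simulated genome; "
            "increase genome_length"
        )
    rng = np.random.default_rng(config.seed + 1)
    levels, dmp_truth, dmr_truth = _plant_levels(loci, config, rng)
    methylomes: dict[str, dict[int, float]] = {}
    for s in config.samples:
        methylomes[s] = {
            (l.chrom, l.site_pos): levels.loc[l.locus_id, s] for l in loci
        }
    truth = TruthTable(levels=levels, dmps=dmp_truth, dmrs=dmr_truth, loci=loci)
    return methylomes, truth


def simulate_counts(
    levels: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Locus × sample read counts from the thinning model, plus library
    totals.  A fully methylated locus yields expected count 0."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lev = levels.to_numpy(float)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        pool = rng.poisson(
            rng.gamma(shape, config.mean_coverage / shape, size=lev.shape)
        )
    else:
        pool = np.full(lev.shape, int(round(config.mean_coverage)))
    counts = rng.binomial(pool, 1.0 - lev)
    mat = pd.DataFrame(counts, index=levels.index, columns=levels.columns)
    totals = pd.Series(config.library_size, index=levels.columns, dtype=float)
    return mat, totals


def make_barcodes(
    samples: list[str],
    rng: np.random.Generator,
    length: int = 7,
    min_distance: int = 3,
) -> dict[str, str]:
    """Random barcodes with pairwise Hamming distance >= min_distance so
    one-mismatch demultiplexing is unambiguous."""
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    while len(chosen) < len(samples):
        cand = "".join(rng.choice(bases, size=length))
        if all(
            sum(a != b for a, b in zip(cand, c)) >= min_distance for c in chosen
        ):
            chosen.append(cand)
    return dict(zip(samples, chosen))


def emit_reads(
    genome: dict[str, str],
    truth: TruthTable,
    counts: pd.DataFrame,
    barcodes: dict[str, str],
    path,
) -> pd.DataFrame:
    """Multiplexed FASTQ: per locus and sample, `count` single-end reads with
    the sample barcode prepended at the methylation-sensitive end.  Returns a
    provenance table (read_id, sample, locus_id)."""
    records = []
    with open(path, "w") as fh:
        for locus in truth.loci:
            seq = genome[locus.chrom][locus.read_start : locus.read_end]
            if locus.strand == "-":
                seq = reverse_complement(seq)
            for sample in counts.columns:
                bc = barcodes[sample]
                read = (bc + seq)[:150]
                n = int(counts.loc[locus.locus_id, sample])
                for i in range(n):
                    rid = f"{sample}|{locus.locus_id}|{i}"
                    fh.write(f"@{rid}\n{read}\n+\n{PHRED_QUALITY * len(read)}\n")
                    records.append((rid, sample, locus.locus_id))
    return pd.DataFrame(records, columns=["read_id", "sample", "locus_id"])


def emit_alignments(
    genome: dict[str, str],
    truth: TruthTable,
    counts: pd.DataFrame,
    out_dir,
) -> dict[str, Path]:
    """Truth alignments, one SAM per sample (alignment itself is out of
    scope: read provenance is known, so reads are placed at their true
    coordinates with MAPQ 60)."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = sorted(genome)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
        }
    )
    paths = {}
    for sample in counts.columns:
        p = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(p, "w", header=header) as fh:
            for locus in truth.loci:
                n = int(counts.loc[locus.locus_id, sample])
                span = locus.read_end - locus.read_start
                for i in range(n):
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{sample}|{locus.locus_id}|{i}"
                    seq = genome[locus.chrom][locus.read_start : locus.read_end]
                    a.query_sequence = seq
                    a.flag = 16 if locus.strand == "-" else 0
                    a.reference_id = chroms.index(locus.chrom)
                    a.reference_start = locus.read_start
                    a.mapping_quality = 60
                    a.cigarstring = f"{span}M"
                    a.query_qualities = pysam.qualitystring_to_array(
                        PHRED_QUALITY * span
                    )
                    fh.write(a)
        paths[sample] = p
    return paths


def simulate_allele_depths(
    genome: dict[str, str],
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Heterozygous SNPs inside locus read intervals with per-sample REF/ALT
    depths; a subset get a planted reference-allele-frequency shift between
    groups (allele-specific methylation response)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n_snps = config.n_het_snps
    if n_snps == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "sample", "ref_depth", "alt_depth"]
        )
    loci = truth.loci
    pick = rng.choice(len(loci), size=min(n_snps, len(loci)), replace=False)
    pick.sort()
    n_asmr = min(config.n_asmr_sites, len(pick))
    asmr_flags = np.zeros(len(pick), bool)
    asmr_flags[rng.choice(len(pick), size=n_asmr, replace=False)] = True

    alt_of = {"A": "G", "C": "T", "G": "A", "T": "C"}
    rows = []
    treated = config.groups[1]
    for flag, li in zip(asmr_flags, pick):
        locus = loci[li]
        lo, hi = locus.read_interval
        pos = int(rng.integers(lo, hi))
        ref = genome[locus.chrom][pos]
        alt = alt_of[ref]
        shift = config.allelic_shift * (1 if rng.random() < 0.5 else -1)
        for sample in config.samples:
            frac = 0.5
            if flag and config.design[sample] == treated:
                frac = float(np.clip(0.5 + shift, 0.02, 0.98))
            depth = rng.poisson(config.snp_coverage)
            ref_d = rng.binomial(depth, frac)
            rows.append(
                (locus.chrom, pos, ref, alt, sample, int(ref_d), int(depth - ref_d))
            )
        if flag:
            truth.asmr_sites.append(
                {
                    "chrom": locus.chrom,
                    "pos": pos,
                    "locus_id": locus.locus_id,
                    "shift": shift,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "ref_depth", "alt_depth"]
    )


def write_vcf(depths: pd.DataFrame, genome: dict[str, str], path) -> None:
    """Minimal VCF 4.2 with GT and per-sample allele depths (AD)."""
    samples = sorted(depths["sample"].unique()) if len(depths) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        if not len(depths):
            return
        for (chrom, pos, ref, alt), grp in depths.groupby(
            ["chrom", "pos", "ref", "alt"], sort=True
        ):
            by_sample = grp.set_index("sample")
            cells = []
            for s in samples:
                r = by_sample.loc[s]
                cells.append(f"0/1:{int(r.ref_depth)},{int(r.alt_depth)}")
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def export_truth(truth: TruthTable, out_dir) -> dict[str, Path]:
    """Lossless truth serialization: JSON for the tables, BED for intervals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_dir / "truth.json",
        "dmr_bed": out_dir / "truth_dmrs.bed",
        "dmp_bed": out_dir / "truth_dmps.bed",
    }
    payload = {
        "levels": {
            "index": list(truth.levels.index),
            "columns": list(truth.levels.columns),
            "values": truth.levels.to_numpy().tolist(),
        },
        "dmps": truth.dmps,
        "dmrs": truth.dmrs,
        "asmr_sites": truth.asmr_sites,
        "loci": [dataclasses.asdict(l) for l in truth.loci],
    }
    paths["json"].write_text(json.dumps(payload, indent=1))
    with open(paths["dmr_bed"], "w") as fh:
        for d in sorted(truth.dmrs, key=lambda d: (d["chrom"], d["start"])):
            fh.write(f"{d['chrom']}\t{d['start']}\t{d['end']}\t{d['direction']}\n")
    with open(paths["dmp_bed"], "w") as fh:
        for d in sorted(truth.dmps, key=lambda d: (d["chrom"], d["pos"])):
            fh.write(
                f"{d['chrom']}\t{d['pos']}\t{d['pos'] + 1}\t"
                f"{d['locus_id']}\t0\t{d['direction']}\n"
            )
    return paths


def load_truth(path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    levels = pd.DataFrame(
        payload["levels"]["values"],
        index=payload["levels"]["index"],
        columns=payload["levels"]["columns"],
    )
    return TruthTable(
        levels=levels,
        dmps=payload["dmps"],
        dmrs=payload["dmrs"],
        asmr_sites=payload["asmr_sites"],
        loci=[SimLocus(**l) for l in payload["loci"]],
    )


def plant_level_matrix(
    config: SimulationConfig,
    n_loci: int,
    n_regions: int = 0,
    dmps_per_region: int = 5,
    region_spacing: int = 80,
    locus_spacing: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-group methylation levels on a synthetic locus track, without a
    genome: Beta baseline, ``config.n_differential_loci`` singleton shifts
    of size ``config.effect_size``, and optionally planted regions of
    ``dmps_per_region`` concordant differential loci at ``region_spacing``
    bp.  Returns (levels, positions, truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if n_regions > 0:
        gap = max(n_loci // (n_regions + 1), 1)
    positions: list[int] = []
    region_members: list[list[int]] = [[] for _ in range(n_regions)]
    cursor = 0
    next_region = 0
    for i in range(n_loci):
        cursor += locus_spacing
        positions.append(cursor)
        if n_regions and next_region < n_regions and (i + 1) % gap == 0:
            members = []
            for _ in range(dmps_per_region):
                cursor += region_spacing
                members.append(len(positions))
                positions.append(cursor)
            region_members[next_region] = members
            cursor += locus_spacing
            next_region += 1
    n_total = len(positions)
    ids = [f"L{i + 1:06d}" for i in range(n_total)]
    pos_df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": positions,
            "end": [p + 1 for p in positions],
            "strand": "+",
        },
        index=ids,
    )

    a, b = config.baseline_beta
    g1 = rng.beta(a, b, size=n_total)
    g2 = g1.copy()
    eff = config.effect_size
    truth: dict = {"dmps": [], "dmrs": []}
    in_region = {i for ms in region_members for i in ms}

    def plant(i: int, direction: str) -> None:
        low = rng.uniform(0.05, max(0.05, 0.95 - eff))
        if direction == "hyper":
            g1[i], g2[i] = low, min(1.0, low + eff)
        else:
            g1[i], g2[i] = min(1.0, low + eff), low
        truth["dmps"].append(
            {"locus_id": ids[i], "pos": positions[i], "direction": direction}
        )

    for members in region_members:
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        for i in members:
            plant(i, direction)
        truth["dmrs"].append(
            {
                "chrom": "chr1",
                "start": positions[members[0]],
                "end": positions[members[-1]],
                "locus_ids": [ids[i] for i in members],
                "direction": direction,
            }
        )

    background = [i for i in range(n_total) if i not in in_region]
    n_single = min(config.n_differential_loci, len(background))
    for j in rng.choice(len(background), size=n_single, replace=False):
        plant(background[j], "hyper" if rng.random() < 0.5 else "hypo")

    cols = {}
    for s in config.samples:
        means = g1 if config.design[s] == config.groups[0] else g2
        cols[s] = np.clip(
            means + rng.normal(0.0, config.replicate_sd, size=n_total), 0.0, 1.0
        )
    levels = pd.DataFrame(cols, index=ids)
    return levels, pos_df, truth


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genome: dict[str, str]
    truth: TruthTable
    counts: pd.DataFrame
    totals: pd.Series
    barcodes: dict[str, str]
    depths: pd.DataFrame


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the whole generator in memory (no files)."""
    genome = generate_genome(config)
    _, truth = plant_methylome(genome, config)
    counts, totals = simulate_counts(truth.levels, config)
    rng = np.random.default_rng(config.seed + 4)
    barcodes = make_barcodes(config.samples, rng, config.barcode_length)
    depths = simulate_allele_depths(genome, truth, config)
    return SimulatedExperiment(
        config=config,
        genome=genome,
        truth=truth,
        counts=counts,
        totals=totals,
        barcodes=barcodes,
        depths=depths,
    )


def write_experiment(exp: SimulatedExperiment, out_dir) -> dict[str, object]:
    """Write every artifact of a simulated experiment to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(exp.genome, out_dir / "genome.fa")
    reads = emit_reads(
        exp.genome, exp.truth, exp.counts, exp.barcodes, out_dir / "reads.fastq"
    )
    sams = emit_alignments(exp.genome, exp.truth, exp.counts, out_dir / "alignments")
    write_vcf(exp.depths, exp.genome, out_dir / "variants.vcf")
    truth_paths = export_truth(exp.truth, out_dir / "truth")
    exp.counts.to_csv(out_dir / "true_counts.tsv", sep="\t")
    with open(out_dir / "barcodes.tsv", "w") as fh:
        for s, bc in exp.barcodes.items():
            fh.write(f"{s}\t{bc}\n")
    return {
        "fasta": out_dir / "genome.fa",
        "fastq": out_dir / "reads.fastq",
        "sams": sams,
        "vcf": out_dir / "variants.vcf",
        "truth": truth_paths,
        "provenance": reads,
    }
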