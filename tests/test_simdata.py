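"""Synthetic-experiment generator: determinism, planted truth, count model."""

import json

import numpy as np
import pandas as pd
import pytest

from msddseq import pseudoref, simdata
from msddseq.simdata import SimulationConfig


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=1, genome_length=5000)
        assert simdata.generate_genome(cfg) == simdata.generate_genome(cfg)

    def test_gc_zero_gives_at_only(self):
        cfg = SimulationConfig(seed=2, genome_length=2000, gc_fraction=0.0)
        for seq in simdata.generate_genome(cfg).values():
            assert set(seq) <= {"A", "T"}

    def test_requested_length_emitted(self):
        cfg = SimulationConfig(seed=3, genome_length=10_000, n_chromosomes=3)
        genome = simdata.generate_genome(cfg)
        assert sum(len(s) for s in genome.values()) == 10_000

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0)


class TestPlantedMethylome:
    def test_zero_effect_lists_no_nonzero_deltas(self):
        cfg = SimulationConfig(seed=4, genome_length=60_000, effect_size=0.0,
                               n_differential_loci=10)
        _, truth = simdata.plant_methylome(simdata.generate_genome(cfg), cfg)
        assert all(d["delta"] == 0 for d in truth.dmps)

    def test_requested_number_of_dmps_planted(self):
        cfg = SimulationConfig(seed=5, genome_length=60_000, n_differential_loci=5)
        _, truth = simdata.plant_methylome(simdata.generate_genome(cfg), cfg)
        assert len(truth.dmps) == 5
        locus_ids = {l.locus_id for l in truth.loci}
        assert {d["locus_id"] for d in truth.dmps} <= locus_ids

    def test_levels_in_unit_interval(self):
        cfg = SimulationConfig(seed=8, genome_length=60_000)
        _, truth = simdata.plant_methylome(simdata.generate_genome(cfg), cfg)
        vals = truth.levels.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()


class TestLevelMatrix:
    def test_group_difference_matches_effect_size(self):
        cfg = SimulationConfig(seed=6, n_differential_loci=100, effect_size=0.5)
        levels, _, truth = simdata.plant_level_matrix(cfg, n_loci=500)
        ww = levels[[s for s in levels if s.startswith("WW")]].mean(axis=1)
        ds = levels[[s for s in levels if s.startswith("DS")]].mean(axis=1)
        planted = [d["locus_id"] for d in truth["dmps"]]
        assert len(planted) == 100
        gap = (ds - ww).loc[planted].abs().mean()
        assert gap == pytest.approx(0.5, abs=0.03)

    def test_planted_regions_are_concordant_and_spaced(self):
        cfg = SimulationConfig(seed=9, n_differential_loci=0)
        levels, pos, truth = simdata.plant_level_matrix(
            cfg, n_loci=100, n_regions=4, dmps_per_region=5, region_spacing=80
        )
        assert len(truth["dmrs"]) == 4
        for region in truth["dmrs"]:
            starts = pos.loc[region["locus_ids"], "start"].to_numpy()
            assert (np.diff(starts) == 80).all()


class TestCountModel:
    def test_fully_methylated_yields_zero(self):
        cfg = SimulationConfig(seed=10)
        levels = pd.DataFrame(1.0, index=["a", "b"], columns=cfg.samples)
        counts, _ = simdata.simulate_counts(levels, cfg)
        assert (counts.to_numpy() == 0).all()

    def test_mean_ratio_two_between_zero_and_half_methylation(self):
        cfg = SimulationConfig(seed=11)
        levels = pd.DataFrame(
            {s: [0.0] * 200 + [0.5] * 200 for s in cfg.samples},
            index=[f"l{i}" for i in range(400)],
        )
        counts, _ = simdata.simulate_counts(levels, cfg)
        ratio = counts.iloc[:200].to_numpy().mean() / counts.iloc[200:].to_numpy().mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_identical_seeds_identical_matrices(self):
        cfg = SimulationConfig(seed=12)
        levels = pd.DataFrame(0.3, index=["a", "b"], columns=cfg.samples)
        c1, _ = simdata.simulate_counts(levels, cfg)
        c2, _ = simdata.simulate_counts(levels, cfg)
        assert c1.equals(c2)

    def test_calibration_slope_equals_coverage(self):
        # regression of mean count on (1 - level) over many loci
        cfg = SimulationConfig(seed=13, mean_coverage=80)
        rng = np.random.default_rng(13)
        lv = rng.uniform(0, 1, size=600)
        levels = pd.DataFrame({s: lv for s in cfg.samples},
                              index=[f"l{i}" for i in range(600)])
        counts, _ = simdata.simulate_counts(levels, cfg)
        x = 1 - lv
        y = counts.mean(axis=1).to_numpy()
        slope = (x * y).sum() / (x * x).sum()
        assert slope == pytest.approx(80, rel=0.1)

    def test_library_totals_bound_column_sums(self):
        cfg = SimulationConfig(seed=14, genome_length=60_000)
        exp = simdata.simulate_experiment(cfg)
        assert (exp.counts.sum(axis=0) <= exp.totals).all()


class TestReads:
    def test_reads_carry_sample_barcode_and_length_rule(self, tmp_path, small_experiment):
        exp = small_experiment
        fq = tmp_path / "reads.fastq"
        prov = simdata.emit_reads(exp.genome, exp.truth, exp.counts, exp.barcodes, fq)
        lines = fq.read_text().splitlines()
        seqs = lines[1::4]
        names = [l[1:] for l in lines[0::4]]
        assert len(seqs) == len(prov)
        for name, seq in zip(names[:200], seqs[:200]):
            sample = name.split("|")[0]
            assert seq.startswith(exp.barcodes[sample])
            locus_id = name.split("|")[1]
            locus = next(l for l in exp.truth.loci if l.locus_id == locus_id)
            frag_len = locus.fragment_end - locus.fragment_start
            assert len(seq) == min(150, 7 + frag_len)

    def test_demultiplex_round_trip_recovers_per_sample_totals(
        self, tmp_path, small_experiment
    ):
        exp = small_experiment
        fq = tmp_path / "reads.fastq"
        simdata.emit_reads(exp.genome, exp.truth, exp.counts, exp.barcodes, fq)
        stats = pseudoref.demultiplex_reads(fq, exp.barcodes, tmp_path / "demux")
        by_sample = stats.set_index("sample")["n_reads"]
        for s in exp.counts.columns:
            assert by_sample[s] == exp.counts[s].sum()
        assert by_sample["__discarded__"] == 0


class TestTruthSerialization:
    def test_round_trip(self, tmp_path, small_experiment):
        truth = small_experiment.truth
        paths = simdata.export_truth(truth, tmp_path)
        loaded = simdata.load_truth(paths["json"])
        pd.testing.assert_frame_equal(loaded.levels, truth.levels)
        assert loaded.dmps == truth.dmps
        assert loaded.dmrs == truth.dmrs
        assert loaded.loci == truth.loci

    def test_empty_truth_writes_valid_files(self, tmp_path):
        truth = simdata.TruthTable(levels=pd.DataFrame())
        paths = simdata.export_truth(truth, tmp_path)
        assert json.loads(paths["json"].read_text())["dmps"] == []
        assert paths["dmr_bed"].read_text() == ""

    def test_dmr_bed_sorted_half_open(self, tmp_path):
        truth = simdata.TruthTable(
            levels=pd.DataFrame(),
            dmrs=[
                {"chrom": "chr1", "start": 500, "end": 700, "direction": "hyper"},
                {"chrom": "chr1", "start": 100, "end": 200, "direction": "hypo"},
            ],
        )
        paths = simdata.export_truth(truth, tmp_path)
        rows = [l.split("\t") for l in paths["dmr_bed"].read_text().splitlines()]
        starts = [int(r[1]) for r in rows]
        assert starts == sorted(starts)
        assert all(int(r[2]) > int(r[1]) for r in rows)
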