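"""Normalization, filtering, max-count rescaling, DMP and DMR calling."""

import numpy as np
import pandas as pd
import pytest

from msddseq import methylation as meth
from msddseq.methylation import DMP
from msddseq.simdata import SimulationConfig, plant_level_matrix, simulate_counts

SAMPLES = ["WW1", "WW2", "WW3", "DS1", "DS2", "DS3"]
DESIGN = {s: s[:2] for s in SAMPLES}


def matrix(rows, index=None, columns=None):
    columns = columns or SAMPLES
    index = index or [f"l{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


def make_levels(rows, positions=None, ref_count=50):
    lv = matrix(rows)
    pos = None
    if positions is not None:
        pos = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": positions,
                "end": [p + 1 for p in positions],
                "strand": "+",
            },
            index=lv.index,
        )
    return meth.MethylationLevels(
        levels=lv,
        reference_count=pd.Series(float(ref_count), index=lv.index),
        positions=pos,
    )


class TestNormalization:
    def test_rpm_arithmetic(self):
        counts = matrix([[50, 0, 10, 20, 30, 40]])
        totals = pd.Series(2_000_000.0, index=SAMPLES)
        norm = meth.normalize_rpm(counts, totals)
        assert norm.values.iloc[0, 0] == 25.0
        assert norm.values.iloc[0, 1] == 0.0

    def test_columns_sum_to_1e6_with_default_totals(self):
        rng = np.random.default_rng(1)
        counts = matrix(rng.integers(1, 100, size=(30, 6)))
        norm = meth.normalize_rpm(counts)
        assert np.allclose(norm.values.sum(axis=0), 1e6)

    def test_zero_total_rejected(self):
        counts = matrix([[0, 0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="zero library total"):
            meth.normalize_rpm(counts)


class TestLocusFilter:
    def test_low_raw_total_discarded(self):
        counts = matrix([[1, 1, 1, 0, 0, 0], [50, 60, 55, 45, 50, 40]])
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=SAMPLES))
        filt = meth.filter_loci(norm, DESIGN)
        assert filt.discard_reason.iloc[0] == "total_reads"
        assert bool(filt.retained.iloc[1])

    def test_noisy_replicates_discarded(self):
        counts = matrix([[100, 100, 100, 100, 40, 160]])
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=SAMPLES))
        filt = meth.filter_loci(norm, DESIGN)
        # within-DS relative counts (1/6, 1/15, 4/15): sd 0.10 > 0.08
        assert filt.discard_reason.iloc[0] == "replicate_sd"

    def test_low_normalized_coverage_discarded(self):
        counts = matrix([[2, 1, 1, 1, 1, 1]])
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=SAMPLES))
        filt = meth.filter_loci(norm, DESIGN, min_locus_coverage=10)
        assert filt.discard_reason.iloc[0] == "low_coverage"

    def test_clean_high_coverage_locus_retained(self):
        counts = matrix([[80, 80, 80, 80, 80, 80]])
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=SAMPLES))
        filt = meth.filter_loci(norm, DESIGN)
        assert bool(filt.retained.iloc[0])


class TestRescaling:
    def test_stated_rule(self):
        counts = pd.DataFrame(
            [[200.0, 150.0, 100.0]], index=["l0"], columns=["a", "b", "c"]
        )
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=["a", "b", "c"]))
        levels = meth.rescale_to_methylation(norm).levels
        assert levels.iloc[0].tolist() == [0.0, 0.25, 0.5]

    def test_equal_counts_all_zero(self):
        counts = matrix([[60] * 6])
        norm = meth.normalize_rpm(counts, pd.Series(1e6, index=SAMPLES))
        levels = meth.rescale_to_methylation(norm).levels
        assert (levels.iloc[0] == 0).all()

    def test_scale_invariance_and_unit_interval(self):
        rng = np.random.default_rng(3)
        raw = rng.integers(1, 500, size=(40, 6)).astype(float)
        totals = pd.Series(1e6, index=SAMPLES)
        lv1 = meth.rescale_to_methylation(
            meth.normalize_rpm(matrix(raw), totals)
        ).levels
        lv2 = meth.rescale_to_methylation(
            meth.normalize_rpm(matrix(raw * 7), totals)
        ).levels
        assert np.allclose(lv1, lv2)
        assert ((lv1 >= 0) & (lv1 <= 1)).all().all()
        assert (lv1.min(axis=1) == 0).all()  # max-count sample is exactly 0


class TestDMPCalling:
    def test_identical_groups_not_called(self):
        m = make_levels([[0.3] * 6] * 5)
        assert meth.call_dmps(m, DESIGN) == []

    def test_extreme_separation_matches_closed_form(self):
        m = make_levels([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        table = meth.dmp_table(m, DESIGN)
        # independent two-proportion log-likelihood ratio: s1=0/150, s2=150/150
        from scipy.stats import chi2

        ll_null = 300 * np.log(0.5)
        expected_p = chi2.sf(2 * (0.0 - ll_null), df=1)
        assert table["p_value"].iloc[0] == pytest.approx(expected_p, rel=1e-10)

    def test_lrt_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        levels = [0.10, 0.20, 0.15, 0.60, 0.50, 0.55]
        n = 50
        m = make_levels([levels], ref_count=n)
        table = meth.dmp_table(m, DESIGN)
        succ = np.round(np.array(levels) * n)
        endog = np.column_stack([succ, n - succ])
        exog = sm.add_constant(np.array([0, 0, 0, 1, 1, 1]))
        full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        lrt = full.null_deviance - full.deviance
        from scipy.stats import chi2

        assert table["p_value"].iloc[0] == pytest.approx(
            chi2.sf(lrt, df=1), rel=1e-6
        )

    def test_all_zero_levels_give_p_one(self):
        m = make_levels([[0.0] * 6])
        table = meth.dmp_table(m, DESIGN)
        assert table["p_value"].iloc[0] == 1.0

    def test_min_delta_floor_applies(self):
        m = make_levels([[0.0, 0.01, 0.0, 0.30, 0.28, 0.29]], ref_count=500)
        assert meth.call_dmps(m, DESIGN, min_delta=0.0)
        assert not meth.call_dmps(m, DESIGN, min_delta=0.5)

    def test_q_values_monotone_in_p(self):
        cfg = SimulationConfig(seed=31, n_differential_loci=30)
        levels, pos, _ = plant_level_matrix(cfg, n_loci=300)
        counts, totals = simulate_counts(levels, cfg)
        norm = meth.normalize_rpm(counts, totals)
        m = meth.rescale_to_methylation(norm, pos)
        table = meth.dmp_table(m, DESIGN).sort_values("p_value")
        assert table["q_value"].is_monotonic_increasing
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()

    def test_two_replicates_required(self):
        lv = pd.DataFrame([[0.1, 0.9]], index=["l0"], columns=["WW1", "DS1"])
        m = meth.MethylationLevels(
            levels=lv, reference_count=pd.Series(50.0, index=["l0"])
        )
        with pytest.raises(ValueError):
            meth.call_dmps(m, {"WW1": "WW", "DS1": "DS"})


class TestDirectionSummary:
    def test_counts_and_ratio(self):
        dmps = [_dmp("l%d" % i, 0, 0.2) for i in range(30)]
        dmps += [_dmp("h%d" % i, 0, -0.2) for i in range(10)]
        s = meth.direction_summary(dmps)
        assert (s["hyper"], s["hypo"], s["ratio"]) == (30, 10, 3.0)

    def test_no_hypo_gives_infinite_flag(self):
        s = meth.direction_summary([_dmp("a", 0, 0.5)])
        assert s["ratio"] == float("inf")

    def test_empty(self):
        s = meth.direction_summary([])
        assert (s["hyper"], s["hypo"]) == (0, 0)
        assert np.isnan(s["ratio"])


def _dmp(locus_id, pos, delta, q=0.01, chrom="chr1"):
    return DMP(
        locus_id=locus_id, chrom=chrom, pos=pos, end=pos + 1, strand="+",
        mean_control=0.1, mean_treated=0.1 + delta, delta=delta,
        p_value=q / 2, q_value=q,
    )


def _strong_levels(directions, positions, ref_count=80):
    rows = []
    for d in directions:
        rows.append(
            [0.1, 0.12, 0.11, 0.7, 0.72, 0.71]
            if d == "hyper"
            else [0.7, 0.72, 0.71, 0.1, 0.12, 0.11]
        )
    m = make_levels(rows, positions=positions, ref_count=ref_count)
    m.levels.index = [f"L{p}" for p in positions]
    m.reference_count.index = m.levels.index
    m.positions.index = m.levels.index
    return m


class TestDMRScan:
    def hand_trace_dmps(self):
        specs = [
            ("L1000", 1000, 0.3, 0.01), ("L1060", 1060, 0.3, 0.03),
            ("L1140", 1140, 0.3, 0.04), ("L1500", 1500, -0.3, 0.01),
        ]
        return [_dmp(i, p, d, q) for i, p, d, q in specs]

    def test_hand_traced_scan(self):
        dmps = self.hand_trace_dmps()
        m = _strong_levels(
            ["hyper", "hyper", "hyper", "hypo"], [1000, 1060, 1140, 1500]
        )
        m.levels.index = ["L1000", "L1060", "L1140", "L1500"]
        m.reference_count.index = m.levels.index
        dmrs = meth.call_dmrs(dmps, m, DESIGN, window_length=100)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end) == (1000, 1140)
        assert d.members == ["L1000", "L1060", "L1140"]
        assert d.direction == "hyper"
        assert d.q_value <= 0.05

    def test_opposite_directions_never_cluster(self):
        dmps = [_dmp("La", 100, 0.3), _dmp("Lb", 150, -0.3)]
        m = _strong_levels(["hyper", "hypo"], [100, 150])
        m.levels.index = ["La", "Lb"]
        m.reference_count.index = m.levels.index
        assert meth.call_dmrs(dmps, m, DESIGN, window_length=100) == []

    def test_invariant_to_nonsignificant_insertions(self):
        dmps = self.hand_trace_dmps()
        m = _strong_levels(
            ["hyper", "hyper", "hyper", "hypo"], [1000, 1060, 1140, 1500]
        )
        m.levels.index = ["L1000", "L1060", "L1140", "L1500"]
        m.reference_count.index = m.levels.index
        noise = [_dmp("N1", 1030, 0.2, q=0.5), _dmp("N2", 1100, -0.2, q=0.9)]
        a = meth.call_dmrs(dmps, m, DESIGN, window_length=100)
        b = meth.call_dmrs(dmps + noise, m, DESIGN, window_length=100)
        assert [(x.start, x.end, x.members) for x in a] == [
            (x.start, x.end, x.members) for x in b
        ]

    def test_window_scan_hand_trace(self):
        # three concordant DMPs spaced 150 bp: invisible at 100, one DMR at 200
        positions = [0, 150, 300]
        m = _strong_levels(["hyper"] * 3, positions)
        dmps = [_dmp(f"L{p}", p, 0.3) for p in positions]
        assert meth.call_dmrs(dmps, m, DESIGN, window_length=100) == []
        assert len(meth.call_dmrs(dmps, m, DESIGN, window_length=200)) == 1
        best, table = meth.scan_window_lengths(
            dmps, m, DESIGN, lengths=[100, 200, 300]
        )
        assert best == 200
        assert table.set_index("window_length")["n_dmrs"].to_dict() == {
            100: 0, 200: 1, 300: 1,
        }

    def test_no_dmps_returns_smallest_length(self):
        m = _strong_levels(["hyper"], [0])
        best, table = meth.scan_window_lengths([], m, DESIGN, lengths=[100, 200])
        assert best == 100
        assert (table["n_dmrs"] == 0).all()

    def test_chosen_length_is_argmax_of_table(self):
        cfg = SimulationConfig(seed=41, n_differential_loci=0)
        levels, pos, _ = plant_level_matrix(
            cfg, n_loci=200, n_regions=5, dmps_per_region=4, region_spacing=120
        )
        counts, totals = simulate_counts(levels, cfg)
        norm = meth.normalize_rpm(counts, totals)
        m = meth.rescale_to_methylation(meth.filter_loci(norm, DESIGN), pos)
        dmps = meth.call_dmps(m, DESIGN, min_delta=0.25)
        best, table = meth.scan_window_lengths(dmps, m, DESIGN)
        t = table.set_index("window_length")["n_dmrs"]
        assert t[best] == t.max()
        assert best == min(w for w in t.index if t[w] == t.max())
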