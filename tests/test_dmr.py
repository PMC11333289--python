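"""Per-site testing, DMR segmentation, signature selection and region scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import eaclock as ea
from eaclock import dmr as dmrmod, simdata
from eaclock.dmr import Dmr
from conftest import random_count_matrix


def _cm_from_counts(meth_a, total_a, meth_b, total_b, gap=50):
    """3+3-sample matrix with per-site counts identical within each group."""
    n = len(meth_a)
    sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": np.arange(n) * gap})
    meth = np.column_stack([np.tile(np.asarray(meth_a)[:, None], 3),
                            np.tile(np.asarray(meth_b)[:, None], 3)])
    total = np.column_stack([np.tile(np.asarray(total_a)[:, None], 3),
                             np.tile(np.asarray(total_b)[:, None], 3)])
    samples = ["a0", "a1", "a2", "b0", "b1", "b2"]
    return ea.CountMatrix(sites, samples, meth, total)


class TestTestSites:
    def test_identical_groups_give_zero_z_unit_p(self):
        cm = _cm_from_counts([5, 3], [10, 10], [5, 3], [10, 10])
        st = ea.test_sites(cm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert np.allclose(st["z"], 0.0)
        assert np.allclose(st["p"], 1.0)

    def test_maximal_separation_is_extreme(self):
        cm = _cm_from_counts([0], [20], [20], [20])
        st = ea.test_sites(cm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert abs(st["z"].iloc[0]) > 5 and st["p"].iloc[0] < 1e-6

    def test_sign_follows_direction_of_change(self):
        cm = _cm_from_counts([2, 18], [20, 20], [18, 2], [20, 20])
        st = ea.test_sites(cm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert st["z"].iloc[0] > 0 and st["z"].iloc[1] < 0
        assert np.sign(st["z"]).equals(np.sign(st["mean_b"] - st["mean_a"]))

    def test_small_group_rejected(self):
        cm = _cm_from_counts([5], [10], [5], [10])
        with pytest.raises(ValueError):
            ea.test_sites(cm, ["a0"], ["b0", "b1", "b2"])

    def test_uncovered_group_gives_missing_stat(self):
        cm = _cm_from_counts([0, 5], [0, 10], [5, 5], [10, 10])
        st = ea.test_sites(cm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert np.isnan(st["z"].iloc[0]) and not np.isnan(st["z"].iloc[1])


class TestCallDmrs:
    def _stats(self, pos, z, chrom="chr1"):
        z = np.asarray(z, dtype=float)
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(pos),
                "pos": pos,
                "delta": np.sign(z) * 0.3,
                "z": z,
                "p": np.clip(2 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1),
            }
        )

    def test_no_candidates_no_dmrs(self):
        st = self._stats([0, 100, 200], [1.0, -1.0, 0.5])
        assert ea.call_dmrs(st) == []

    def test_eight_candidates_one_region_area_24(self):
        st = self._stats(np.arange(8) * 50, [3.0] * 8)
        dmrs = ea.call_dmrs(st)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.n_cpgs == 8
        assert d.area_stat == pytest.approx(24.0, abs=1e-12)
        assert (d.start, d.end) == (0, 351)
        assert d.direction == "gain"

    def test_distant_runs_never_merge(self):
        pos = list(np.arange(4) * 50) + list(1000 + np.arange(4) * 50)
        st = self._stats(pos, [3.0] * 8)
        assert len(ea.call_dmrs(st)) == 2

    def test_sign_change_splits_runs(self):
        st = self._stats(np.arange(8) * 50, [3.0] * 4 + [-3.0] * 4)
        dmrs = ea.call_dmrs(st)
        assert len(dmrs) == 2
        assert {d.direction for d in dmrs} == {"gain", "loss"}

    def test_min_cpg_drops_short_runs(self):
        st = self._stats([0, 50, 1000], [3.0, 3.0, 3.0])
        assert ea.call_dmrs(st, min_cpg=3) == []

    def test_nearby_same_sign_regions_merge(self):
        pos = list(np.arange(3) * 50) + list(180 + np.arange(3) * 50)
        st = self._stats(pos, [3.0] * 6)  # gap 80 bp < merge_dist 100
        dmrs = ea.call_dmrs(st, max_gap_bp=60, merge_dist_bp=100)
        assert len(dmrs) == 1 and dmrs[0].n_cpgs == 6

    def test_unsorted_input_rejected(self):
        st = self._stats([100, 0], [3.0, 3.0])
        with pytest.raises(ValueError):
            ea.call_dmrs(st)

    def test_area_equals_member_z_sum(self, small_stats):
        cmf, st = small_stats
        pos_z = st.set_index(["chrom", "pos"])["z"]
        for d in ea.call_dmrs(st):
            brute = sum(pos_z.loc[(d.chrom, p)] for p in d.member_pos)
            assert d.area_stat == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_chromosome_relabeling(self, small_stats):
        """Swapping chromosome names only relabels the called regions."""
        cmf, st = small_stats
        ref = {(d.chrom, d.start, d.area_stat) for d in ea.call_dmrs(st)}
        swap = {"chr1": "chr2", "chr2": "chr1"}
        st2 = st.assign(chrom=st["chrom"].map(swap)).sort_values(
            ["chrom", "pos"], ignore_index=True
        )
        got = {(swap[d.chrom], d.start, d.area_stat) for d in ea.call_dmrs(st2)}
        assert got == ref


class TestSelectTop:
    def _dmr(self, chrom, start, area):
        return Dmr(chrom, start, start + 100, 3, area, 0.1 * np.sign(area))

    def test_tie_break_by_coordinate(self):
        dmrs = [
            self._dmr("chr2", 500, 7.0),
            self._dmr("chr1", 100, 9.0),
            self._dmr("chr1", 900, -7.0),
            self._dmr("chr1", 50, 3.0),
            self._dmr("chr3", 10, 1.0),
        ]
        prog = ea.select_top(dmrs, k=3)
        assert [(d.chrom, d.start) for d in prog.dmrs] == [
            ("chr1", 100), ("chr1", 900), ("chr2", 500)
        ]

    def test_direction_filter(self):
        dmrs = [self._dmr("chr1", 0, 5.0), self._dmr("chr1", 500, -9.0)]
        prog = ea.select_top(dmrs, k=10, direction="gain")
        assert len(prog) == 1 and prog.dmrs[0].direction == "gain"

    def test_truncates_to_k(self, small_stats):
        _, st = small_stats
        dmrs = ea.call_dmrs(st)
        for k in (150, 139, 5):
            prog = ea.select_top(dmrs, k=k)
            assert len(prog) == min(k, len(dmrs))
            areas = [abs(d.area_stat) for d in prog.dmrs]
            assert areas == sorted(areas, reverse=True)


class TestRankMetric:
    def _dmr_with_p(self, gene, p, sign, chrom="chr1", start=0):
        # area chosen so the Stouffer region p equals the requested value
        area = sign * sps.norm.isf(p / 2) * np.sqrt(4)
        d = Dmr(chrom, start, start + 10, 4, area, sign * 0.2)
        d.gene = gene
        return d

    def test_positive_change_gives_positive_log_rank(self):
        r = ea.rank_metric([self._dmr_with_p("g1", 0.01, +1)])
        assert r["g1"] == pytest.approx(2.0)

    def test_negative_change_gives_negative_rank(self):
        r = ea.rank_metric([self._dmr_with_p("g1", 0.001, -1)])
        assert r["g1"] == pytest.approx(-3.0)

    def test_gene_represented_by_largest_absolute_rank(self):
        dmrs = [
            self._dmr_with_p("g1", 0.01, +1, start=0),
            self._dmr_with_p("g1", 0.001, -1, start=100),
        ]
        r = ea.rank_metric(dmrs)
        assert r["g1"] == pytest.approx(-3.0)

    def test_missing_gene_label_rejected(self):
        d = Dmr("chr1", 0, 10, 3, 5.0, 0.2)
        with pytest.raises(ValueError):
            ea.rank_metric([d])


class TestScoreRegions:
    def test_pooled_ratio(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 20]})
        cm = ea.CountMatrix(sites, ["a"], np.array([[5], [15]]), np.array([[10], [20]]))
        level, score = ea.score_regions(cm, [Dmr("chr1", 0, 30, 2, 1.0, 0.1)])
        assert level.iloc[0, 0] == pytest.approx(20 / 30)
        assert score["a"] == pytest.approx(20 / 30)

    def test_all_unmethylated_scores_zero(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [0, 10, 20]})
        cm = ea.CountMatrix(sites, ["a"], np.zeros((3, 1), int), np.full((3, 1), 10))
        _, score = ea.score_regions(cm, [Dmr("chr1", 0, 30, 3, 1.0, 0.1)])
        assert score["a"] == 0.0

    def test_uncovered_region_excluded_from_mean(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 1000]})
        cm = ea.CountMatrix(sites, ["a"], np.array([[5], [0]]), np.array([[10], [0]]))
        regions = [Dmr("chr1", 0, 100, 1, 1.0, 0.1), Dmr("chr1", 900, 1100, 1, 1.0, 0.1)]
        level, score = ea.score_regions(cm, regions)
        assert np.isnan(level.iloc[1, 0])
        assert score["a"] == pytest.approx(0.5)

    def test_split_region_pools_identically(self, small_cohort):
        """Pooled counts over two adjacent halves equal the whole region."""
        _, cm, _, truth = small_cohort
        reg = truth.gain_regions.iloc[0]
        whole = [Dmr(reg["chrom"], reg["start"], reg["end"], 1, 1.0, 0.1)]
        mid = (reg["start"] + reg["end"]) // 2
        halves = [Dmr(reg["chrom"], reg["start"], mid, 1, 1.0, 0.1),
                  Dmr(reg["chrom"], mid, reg["end"], 1, 1.0, 0.1)]
        lw, _ = ea.score_regions(cm, whole)
        lh, _ = ea.score_regions(cm, halves)
        # pooled identity: recombining the halves as counts gives the whole
        def counts(lo, hi):
            sel = (
                (cm.sites["chrom"] == reg["chrom"])
                & (cm.sites["pos"] >= lo)
                & (cm.sites["pos"] < hi)
            ).to_numpy()
            return cm.meth[sel].sum(axis=0), cm.total[sel].sum(axis=0)

        m1, t1 = counts(reg["start"], mid)
        m2, t2 = counts(mid, reg["end"])
        assert np.allclose(lw.iloc[0].to_numpy(), (m1 + m2) / (t1 + t2))
        assert np.allclose(lh.iloc[0].to_numpy(), m1 / t1)
        assert np.allclose(lh.iloc[1].to_numpy(), m2 / t2)
        # the naive mean of the half levels is NOT the pooled value in general

    def test_empty_region_set_rejected(self, small_cohort):
        _, cm, _, _ = small_cohort
        with pytest.raises(ValueError):
            ea.score_regions(cm, [])

    def test_monotone_in_divisions_on_ladder(self):
        design = simdata.ladder_design(divisions=(0, 2, 4, 8, 16), n=2)
        cfg = ea.SimConfig(n_sites=4000, samples=design, seed=5)
        cm, table, truth = ea.simulate_cohort(cfg)
        _, score = ea.score_regions(cm, truth.gain_regions)
        means = score.groupby(table.set_index("sample_id")["divisions"]).mean()
        assert means.sort_index().is_monotonic_increasing


class TestBedIO:
    def test_roundtrip(self, small_stats, tmp_path):
        _, st = small_stats
        prog = ea.select_top(ea.call_dmrs(st), k=20)
        path = tmp_path / "sig.bed"
        dmrmod.dmrs_to_bed(prog.dmrs, path, program=prog)
        back = dmrmod.read_bed(path)
        assert len(back) == len(prog)
        assert list(back["start"]) == [d.start for d in prog.dmrs]
        assert list(back["end"]) == [d.end for d in prog.dmrs]
        assert list(back["direction"]) == [d.direction for d in prog.dmrs]
        assert (tmp_path / "sig.bed.json").exists()
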