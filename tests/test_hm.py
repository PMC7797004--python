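"""ROH clusters, spectral trimming and cluster-phenotype association."""

import numpy as np
import pandas as pd
import pytest

import rohmap as rm
from rohmap.hm import roh_incidence
from scipy import stats


def marker_map(n=60, spacing=10_000, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": (np.arange(n) + 1) * spacing})


def roh_row(sample, start, end, chrom="1"):
    return {"sample": sample, "chrom": chrom, "start": start, "end": end,
            "length": end - start + 1, "n_snps": 0, "n_missing": 0}


def shared_block_rohs(n_carriers, start, end, chrom="1"):
    return pd.DataFrame([roh_row(f"C{i:02d}", start, end, chrom)
                         for i in range(n_carriers)])


class TestBuildClusters:
    def test_shared_block_yields_single_candidate(self):
        markers = marker_map()
        ids = [f"C{i:02d}" for i in range(12)] + ["X1", "X2"]
        rohs = shared_block_rohs(12, 200_000, 350_000)
        cands = rm.build_roh_clusters(rohs, markers, ids)
        assert len(cands) == 1
        c = cands[0]
        assert c["start"] == 200_000 and c["end"] == 350_000
        # brute-force per-marker count agrees with the candidate span
        counts = roh_incidence(rohs, markers, ids).sum(axis=0)
        inside = markers["pos"].between(c["start"], c["end"])
        assert (counts[inside.to_numpy()] >= 10).all()
        assert (counts[~inside.to_numpy()] < 10).all()

    def test_nine_carriers_insufficient(self):
        cands = rm.build_roh_clusters(
            shared_block_rohs(9, 200_000, 350_000), marker_map(),
            [f"C{i:02d}" for i in range(9)])
        assert cands == []

    def test_short_block_fails_length_rule(self):
        cands = rm.build_roh_clusters(
            shared_block_rohs(15, 200_000, 280_000), marker_map(),
            [f"C{i:02d}" for i in range(15)])
        assert cands == []

    def test_only_phenotyped_samples_counted(self):
        rohs = shared_block_rohs(12, 200_000, 350_000)
        phenotyped = [f"C{i:02d}" for i in range(8)]  # only 8 of the carriers
        assert rm.build_roh_clusters(rohs, marker_map(), phenotyped) == []


class TestTrimCluster:
    def _setup(self, rohs, ids, **kw):
        markers = marker_map(100)
        cands = rm.build_roh_clusters(rohs, markers, ids, **kw)
        inc = roh_incidence(rohs, markers, ids)
        return markers, cands, inc

    def test_aligned_block_returned_unchanged(self):
        ids = [f"C{i:02d}" for i in range(12)]
        rohs = shared_block_rohs(12, 200_000, 400_000)
        markers, cands, inc = self._setup(rohs, ids)
        cl = rm.trim_cluster(cands[0], inc, markers, rohs, ids)
        assert (cl.start, cl.end) == (200_000, 400_000)
        assert cl.carriers == frozenset(ids)
        assert cl.id == "ROH_S1_200000"

    def test_staggered_boundaries_trimmed_within_candidate(self):
        ids = [f"C{i:02d}" for i in range(12)]
        rng = np.random.default_rng(0)
        rows = []
        for i, s in enumerate(ids):
            rows.append(roh_row(s, 200_000 - int(rng.integers(0, 15) * 10_000),
                                400_000 + int(rng.integers(0, 15) * 10_000)))
        rohs = pd.DataFrame(rows)
        markers, cands, inc = self._setup(rohs, ids)
        cl = rm.trim_cluster(cands[0], inc, markers, rohs, ids)
        assert cl is not None
        assert cl.start >= cands[0]["start"] and cl.end <= cands[0]["end"]
        pretrim = len(rm.hm._covering_samples(rohs, "1", cands[0]["start"],
                                              cands[0]["end"]))
        assert len(cl.carriers) >= pretrim

    def test_single_sample_edge_removed_by_bipartition(self):
        # core block shared by 12 carriers; one sample extends far to the right
        ids = [f"C{i:02d}" for i in range(12)]
        rows = [roh_row(s, 200_000, 400_000) for s in ids]
        rows[0] = roh_row("C00", 200_000, 900_000)
        rohs = pd.DataFrame(rows)
        markers, cands, inc = self._setup(rohs, ids)
        assert cands[0]["end"] == 400_000  # the lone extension never had 10 carriers
        cl = rm.trim_cluster(cands[0], inc, markers, rohs, ids)
        assert cl.end <= 400_000 and len(cl.carriers) == 12

    def test_every_carrier_spans_trimmed_region(self, midsize_panel):
        panel, _ = midsize_panel
        det = rm.roh_marker_subset(panel)
        rohs = rm.detect_rohs(det, subset_markers=False)
        clusters = rm.find_clusters(rohs, det.markers, panel.sample_ids,
                                    min_carriers=3)
        for cl in clusters:
            assert cl.length >= 100_000 and len(cl.carriers) >= 3
            covering = rm.hm._covering_samples(rohs, cl.chrom, cl.start, cl.end)
            assert cl.carriers <= covering


class TestHmTest:
    def _blups_pcs(self, n=98, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"S{i:02d}" for i in range(n)]
        blups = pd.DataFrame({"nut": rng.normal(size=n)}, index=ids)
        pcs = pd.DataFrame(rng.normal(size=(n, 5)), index=ids,
                           columns=[f"PC{k+1}" for k in range(5)])
        return ids, blups, pcs

    def _cluster(self, carriers):
        return rm.ROHCluster(chrom="2", start=1_000_000, end=1_200_000,
                             carriers=frozenset(carriers), n_loci=20)

    def test_carrier_shift_detected(self):
        ids, blups, pcs = self._blups_pcs(seed=1)
        carriers = ids[:15]
        blups.loc[carriers, "nut"] += 1.0
        res = rm.hm_test([self._cluster(carriers)], blups, pcs)
        assert len(res) == 1
        assert res["fdr_p"].iloc[0] < 0.1
        assert res["beta"].iloc[0] == pytest.approx(1.0, abs=0.8)

    def test_small_groups_skipped(self):
        ids, blups, pcs = self._blups_pcs()
        res = rm.hm_test([self._cluster(ids[:1])], blups, pcs)
        assert res.empty

    def test_adjusted_p_monotone_and_single_cluster_unadjusted(self):
        ids, blups, pcs = self._blups_pcs(seed=2)
        res = rm.hm_test([self._cluster(ids[:12])], blups, pcs)
        assert res["fdr_p"].iloc[0] == pytest.approx(res["p"].iloc[0])
        many = [self._cluster(ids[k:k + 12]) for k in range(0, 60, 12)]
        res = rm.hm_test(many, blups, pcs)
        srt = res.sort_values("p")
        assert (srt["fdr_p"].diff().dropna() >= -1e-12).all()
        assert (res["fdr_p"] >= res["p"] - 1e-12).all()

    def test_no_clusters_gives_empty_result(self):
        _, blups, pcs = self._blups_pcs()
        assert rm.hm_test([], blups, pcs).empty


class TestCarrierTtest:
    def test_identical_groups_give_p_one(self):
        ids = [f"S{i}" for i in range(8)]
        blups = pd.Series([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0], index=ids)
        out = rm.carrier_ttest(rm.ROHCluster("1", 1, 200_000,
                                             frozenset(ids[:4]), 5), blups)
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_t_distribution_closed_form(self):
        rng = np.random.default_rng(3)
        ids = [f"S{i:02d}" for i in range(30)]
        blups = pd.Series(rng.normal(size=30), index=ids)
        blups.iloc[:10] += 0.8
        out = rm.carrier_ttest(rm.ROHCluster("1", 1, 200_000,
                                             frozenset(ids[:10]), 5), blups)
        a, b = blups.iloc[:10], blups.iloc[10:]
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert out["t"] == pytest.approx(t)
        assert out["p"] == pytest.approx(p)
        assert out["mean_carrier"] == pytest.approx(a.mean())
        assert out["se_carrier"] == pytest.approx(a.std(ddof=1) / np.sqrt(n1))

    def test_singleton_group_reports_means_without_p(self):
        ids = ["A", "B", "C"]
        blups = pd.Series([1.0, 2.0, 3.0], index=ids)
        out = rm.carrier_ttest(rm.ROHCluster("1", 1, 200_000,
                                             frozenset(["A"]), 5), blups)
        assert out["mean_carrier"] == 1.0 and np.isnan(out["p"])
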