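"""ROH detection and inbreeding quantification."""

import numpy as np
import pandas as pd
import pytest

import rohmap as rm
from rohmap.panel import MISSING
from conftest import make_panel, roh_string_oracle


def het_flanked(n_hom, span, n_samples=30):
    """One sample homozygous at n_hom consecutive SNPs spanning `span` bp,
    heterozygous flanks; remaining samples heterozygous throughout (keeps
    every marker polymorphic with MAF 0.5)."""
    L = n_hom + 2
    positions = np.concatenate([[1000], 2000 + np.linspace(0, span - 1, n_hom).astype(int),
                                [2000 + span + 1000]])
    d = np.ones((n_samples, L), dtype=np.int8)
    d[0, 1:-1] = 0
    return make_panel(d, positions=positions)


class TestDetectRohs:
    def test_single_run_with_het_flanks(self):
        panel = het_flanked(20, 150_000)
        rohs = rm.detect_rohs(panel, min_snps=15, min_length=100_000,
                              subset_markers=False)
        assert len(rohs) == 1
        r = rohs.iloc[0]
        assert (r["sample"], r.n_snps, r.n_missing) == ("S0", 20, 0)
        assert r.length == r.end - r.start + 1 >= 100_000

    def test_snp_count_rule(self):
        panel = het_flanked(14, 200_000)
        assert rm.detect_rohs(panel, subset_markers=False).empty

    def test_length_rule(self):
        panel = het_flanked(30, 90_000)
        assert rm.detect_rohs(panel, subset_markers=False).empty

    def test_gap_breaks_run(self):
        panel = het_flanked(30, 200_000)
        pos = panel.markers["pos"].to_numpy().copy()
        pos[16:] += 2_000_000  # open a >1 Mb gap inside the run
        panel = make_panel(panel.dosages, positions=pos)
        rohs = rm.detect_rohs(panel, min_snps=10, min_length=10_000,
                              subset_markers=False)
        assert len(rohs[rohs["sample"] == "S0"]) == 2

    def test_missing_allowed_inside_and_counted(self):
        panel = het_flanked(20, 150_000)
        d = panel.dosages.copy()
        d[0, 5] = d[0, 10] = MISSING
        panel = make_panel(d, positions=panel.markers["pos"].to_numpy())
        rohs = rm.detect_rohs(panel, subset_markers=False)
        assert len(rohs) == 1 and rohs.iloc[0].n_missing == 2

    def test_no_het_inside_any_reported_roh(self, midsize_panel):
        panel, _ = midsize_panel
        det = rm.roh_marker_subset(panel)
        rohs = rm.detect_rohs(det, subset_markers=False)
        assert len(rohs) > 0
        for r in rohs.itertuples():
            sub = det.markers[(det.markers["chrom"] == r.chrom)
                              & det.markers["pos"].between(r.start, r.end)]
            g = det.dosages[det.sample_ids.index(r.sample), sub.index.to_numpy()]
            assert (g != 1).all()

    def test_matches_independent_enumerator(self, midsize_panel):
        panel, _ = midsize_panel
        det = rm.roh_marker_subset(panel)
        rohs = rm.detect_rohs(det, subset_markers=False)
        mine = sorted((r.sample, r.chrom, r.start, r.end, r.n_snps)
                      for r in rohs.itertuples())
        assert mine == roh_string_oracle(det)

    def test_empty_maf_subset_raises(self):
        panel = make_panel(np.zeros((5, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="MAF"):
            rm.detect_rohs(panel)


class TestFPlink:
    def test_fully_homozygous_sample_has_f_one(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(40, 200)).astype(np.int8)
        d[0] = np.where(d[0] == 1, 2, d[0])
        panel = make_panel(d)
        assert rm.f_plink(panel)["S0"] == pytest.approx(1.0)

    def test_hand_worked_toy(self):
        # 4 loci at p=0.5 in many samples (correction ~ 1): E ~ 2 per sample;
        # a sample with 3 homozygous loci gives F = (3-2)/(4-2) = 0.5
        n = 2000
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(n, 4)).astype(np.int8)
        d[0] = [0, 2, 0, 1]
        panel = make_panel(d)
        p = panel.allele_freq
        n_l = panel.n_called().astype(float)
        e = (1 - 2 * p * (1 - p) * n_l / (n_l - 1)).sum()
        expected = (3 - e) / (4 - e)
        assert rm.f_plink(panel)["S0"] == pytest.approx(expected)
        assert expected == pytest.approx(0.5, abs=0.05)

    def test_homozygosity_at_expectation_gives_f_zero(self):
        # construct freq-0.5 loci where sample 0 has exactly E(hom) ~ L/2 homs
        n, L = 4000, 100
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, size=(n, L)).astype(np.int8)
        half = L // 2
        d[0, :half] = 1
        d[0, half:] = np.where(d[0, half:] == 1, 0, d[0, half:])
        panel = make_panel(d)
        assert rm.f_plink(panel)["S0"] == pytest.approx(0.0, abs=0.05)


class TestInbreedingReport:
    def test_zero_roh_sample_reported_as_zero(self):
        f = pd.Series({"A": 0.1, "B": 0.9})
        rohs = pd.DataFrame([{"sample": "B", "chrom": "1", "start": 1,
                              "end": 200_000, "length": 200_000,
                              "n_snps": 20, "n_missing": 0}])
        summary, _ = rm.inbreeding_report(rohs, f)
        assert summary.loc["A", "roh_count"] == 0
        assert summary.loc["A", "roh_total_length"] == 0
        assert summary.loc["B", "roh_total_length"] == 200_000

    def test_regression_positive_on_inbreeding_gradient(self, midsize_panel):
        panel, truth = midsize_panel
        det = rm.roh_marker_subset(panel)
        rohs = rm.detect_rohs(det, subset_markers=False)
        pruned = rm.ld_prune(panel)
        summary, stats = rm.inbreeding_report(rohs, rm.f_plink(pruned))
        assert stats["roh_count"]["slope"] > 0
        assert stats["roh_count"]["adj_r2"] > 0.5

    def test_fewer_than_three_samples_skips_regression(self):
        from rohmap.roh import ROH_COLUMNS
        f = pd.Series({"A": 0.1, "B": 0.2})
        _, stats = rm.inbreeding_report(pd.DataFrame(columns=ROH_COLUMNS), f)
        assert stats == {}
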