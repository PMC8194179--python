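"""Multi-contrast DE integration: filters, LCS, Venn lists, ORA recurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonotrace import fixtures, integration as ig
from clonotrace.stats import ORAResult


def table(dataset_id, rows):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "p_value", "fdr",
                                     "log2cpm"])
    return ig.DETable(dataset_id=dataset_id, data=df)


class TestReadDETable:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene\tlog2fc\tp_value\tfdr\tlog2cpm\n"
                     "A\t1.0\t0.01\t0.02\t5\nB\t-1\t0.2\t0.4\t3\nC\t0\t1\t1\t2\n")
        t = ig.read_de_table(p, "m")
        assert len(t.data) == 3

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene\tlog2fc\tp_value\tlog2cpm\nA\t1\t0.1\t5\n")
        with pytest.raises(ValueError, match="fdr"):
            ig.read_de_table(p, "m")

    def test_fdr_out_of_range(self):
        with pytest.raises(ValueError, match="fdr"):
            table("m", [("A", 1.0, 0.5, 1.2, 5.0)])

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            table("m", [("A", 1, 0.1, 0.1, 5), ("A", 2, 0.1, 0.1, 5)])


class TestConcordantOverlap:
    def test_stated_filters_enumeration(self):
        a = table("m", [("G1", 1.0, 0.001, 0.01, 5.0),
                        ("G2", 1.0, 0.001, 0.01, 5.0),
                        ("G3", 1.0, 0.001, 0.01, 1.0)])
        b = table("c", [("G1", 2.0, 0.001, 0.01, 4.0),
                        ("G2", -1.0, 0.001, 0.01, 4.0),
                        ("G3", 1.5, 0.001, 0.01, 4.0)])
        up, down = ig.concordant_overlap(a, b)
        assert up == ["G1"] and down == []

    def test_self_comparison_idempotence(self):
        a = table("m", [("U", 2.0, 0.001, 0.01, 5.0),
                        ("D", -1.0, 0.001, 0.01, 5.0),
                        ("NS", 1.0, 0.5, 0.8, 5.0),
                        ("LO", 1.0, 0.001, 0.01, 1.0)])
        up, down = ig.concordant_overlap(a, a)
        assert up == ["U"] and down == ["D"]

    def test_fixture_counts_and_membership(self):
        m, c = fixtures.two_dataset_tables()
        up, down = ig.concordant_overlap(m, c)
        assert tuple(up) == fixtures.UP_IN_BOTH
        assert tuple(down) == fixtures.DOWN_IN_BOTH

    def test_strict_cpm_boundary(self):
        rows = [("G", 1.0, 0.001, 0.01, 2.0)]  # exactly at the cut
        up, down = ig.concordant_overlap(table("m", rows), table("c", rows))
        assert up == [] and down == []


class TestIntegrationMatrix:
    def test_significance_counting(self):
        tables = []
        for ds in ig.DATASETS:
            fdr = 0.01 if ds in ("m", "c", "s") else 0.5
            tables.append(table(ds, [("G", 1.0, fdr / 2, fdr, 5.0)]))
        mat = ig.build_integration_matrix(tables)
        assert mat.loc["G", "n_significant"] == 3
        assert "G" in ig.filter_recurrent(mat, 3).index
        assert "G" not in ig.filter_recurrent(mat, 4).index

    def test_absent_gene_counts_as_untested(self):
        tables = [table(ds, [("G", 1.0, 0.001, 0.01, 5.0)] if ds in ("m", "c")
                        else [("H", 0.5, 0.5, 0.9, 5.0)])
                  for ds in ig.DATASETS]
        mat = ig.build_integration_matrix(tables)
        assert mat.loc["G", "n_significant"] == 2
        assert np.isnan(mat.loc["G", "log2fc_s"])
        # sign of missing contrasts contributes 0 to LCS
        assert mat.loc["G", "lcs"] == 2

    def test_recount_matches_bruteforce_on_synthetic_matrix(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(5000)]
        tables = []
        raw = {}
        for ds in ig.DATASETS:
            fdr = rng.uniform(size=5000)
            fc = rng.normal(size=5000)
            raw[ds] = fdr
            tables.append(table(ds, list(zip(genes, fc, fdr / 2, fdr,
                                             np.full(5000, 5.0)))))
        mat = ig.build_integration_matrix(tables)
        expected = sum((raw[ds] < 0.05).astype(int) for ds in ig.DATASETS)
        np.testing.assert_array_equal(
            mat.loc[genes, "n_significant"].to_numpy(), expected)

    def test_duplicate_dataset_rejected(self):
        tabs = [table(ds, [("G", 1, 0.1, 0.1, 5)])
                for ds in ("m", "m", "s", "l", "d")]
        with pytest.raises(ValueError, match="five contrasts"):
            ig.build_integration_matrix(tabs)


class TestLCS:
    def row(self, m=None, c=None, s=None, l=None, d=None):
        return {f"log2fc_{k}": v for k, v in
                dict(m=m, c=c, s=s, l=l, d=d).items()}

    def test_maximally_consistent_pattern(self):
        assert ig.lck_correlation_score(
            self.row(m=1.0, c=2.0, s=-1.0, l=-0.5, d=-2.0)) == 5

    def test_all_up_is_minus_one(self):
        assert ig.lck_correlation_score(
            self.row(m=1.0, c=1.0, s=1.0, l=1.0, d=1.0)) == -1

    def test_all_zero(self):
        assert ig.lck_correlation_score(
            self.row(m=0.0, c=0.0, s=0.0, l=0.0, d=0.0)) == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_antisymmetry(self, fcs):
        r = dict(zip([f"log2fc_{d}" for d in ig.DATASETS], fcs))
        neg = {k: -v for k, v in r.items()}
        assert ig.lck_correlation_score(neg) == -ig.lck_correlation_score(r)

    def test_sort_by_lcs_ordering(self):
        tables = []
        for ds in ig.DATASETS:
            sign = 1.0 if ds in ("m", "c") else -1.0
            tables.append(table(ds, [
                ("FULL", sign * 2.0, 0.001, 0.01, 5.0),    # |LCS| = 5
                ("WEAK", sign * 0.5, 0.001, 0.01, 5.0),    # |LCS| = 5, smaller fc
                ("FLAT", 0.3, 0.001, 0.01, 5.0),           # |LCS| = 1
            ]))
        mat = ig.sort_by_lcs(ig.build_integration_matrix(tables))
        assert list(mat.index) == ["FULL", "WEAK", "FLAT"]


class TestMeanSignedLog2fc:
    def test_negates_invasion_contrasts(self):
        row = {f"log2fc_{d}": v for d, v in
               zip(ig.DATASETS, [1.0, 1.0, -1.0, -1.0, -1.0])}
        assert ig.mean_signed_log2fc(row) == pytest.approx(-1.0)

    def test_all_zero(self):
        row = {f"log2fc_{d}": 0.0 for d in ig.DATASETS}
        assert ig.mean_signed_log2fc(row) == 0.0

    def test_single_dataset_mean(self):
        row = {"log2fc_s": 2.0}
        assert ig.mean_signed_log2fc(row) == pytest.approx(2.0)

    def test_no_values_is_nan(self):
        assert np.isnan(ig.mean_signed_log2fc({}))


class TestCandidateVenn:
    def test_fixture_counts_and_membership(self):
        mat = ig.build_integration_matrix(fixtures.five_dataset_tables())
        cands = ig.candidate_venn(mat)
        assert tuple(cands.up_in_invasion_down_on_inhibition) == fixtures.VENN_UP
        assert tuple(cands.down_in_invasion_up_on_inhibition) == fixtures.VENN_DOWN

    def test_lists_disjoint_and_recurrent_by_construction(self):
        mat = ig.build_integration_matrix(fixtures.five_dataset_tables())
        cands = ig.candidate_venn(mat)
        up = set(cands.up_in_invasion_down_on_inhibition)
        down = set(cands.down_in_invasion_up_on_inhibition)
        assert not up & down
        assert (mat.loc[sorted(up | down), "n_significant"] >= 2).all()

    def test_empty_matrix(self):
        tabs = [table(ds, []) for ds in ig.DATASETS]
        cands = ig.candidate_venn(ig.build_integration_matrix(tabs))
        assert cands.up_in_invasion_down_on_inhibition == []
        assert cands.down_in_invasion_up_on_inhibition == []

    def test_dual_pattern_gene_dropped_with_warning(self):
        # significant up in m, down in c, down in s, up in l: both patterns
        fcs = dict(m=1.0, c=-1.0, s=-1.0, l=1.0, d=0.1)
        sig = dict(m=0.01, c=0.01, s=0.01, l=0.01, d=0.9)
        tabs = [table(ds, [("X", fcs[ds], sig[ds] / 2, sig[ds], 5.0)])
                for ds in ig.DATASETS]
        with pytest.warns(UserWarning, match="both Venn patterns"):
            cands = ig.candidate_venn(ig.build_integration_matrix(tabs))
        assert cands.up_in_invasion_down_on_inhibition == []
        assert cands.down_in_invasion_up_on_inhibition == []

    def test_null_matrix_yields_near_empty_lists(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(2000)]
        sizes = []
        for rep in range(3):
            tabs = []
            for ds in ig.DATASETS:
                fdr = rng.uniform(size=2000)
                fc = rng.normal(size=2000)
                tabs.append(table(ds, list(zip(genes, fc, fdr / 2, fdr,
                                               np.full(2000, 5.0)))))
            cands = ig.candidate_venn(ig.build_integration_matrix(tabs),
                                      fdr_max=0.001)
            sizes.append(len(cands.up_in_invasion_down_on_inhibition)
                         + len(cands.down_in_invasion_up_on_inhibition))
        assert np.mean(sizes) < 2


def ora_res(term, fold, fdr):
    return ORAResult(term_id=term, hits_in_set=5, set_size=10, query_size=20,
                     universe_size=1000, fold_enrichment=fold, p_value=fdr / 2,
                     fdr=fdr)


class TestRecurrentProcesses:
    def test_two_of_three_runs_retained(self):
        runs = [[ora_res("kera", 4.0, 0.01)],
                [ora_res("kera", 3.5, 0.02)],
                [ora_res("other", 5.0, 0.01)]]
        assert ig.recurrent_processes(runs) == ["kera"]

    def test_joint_condition_per_run(self):
        # significant twice but > 3-fold only once: dropped
        runs = [[ora_res("kera", 4.0, 0.01)], [ora_res("kera", 2.5, 0.01)]]
        assert ig.recurrent_processes(runs) == []

    def test_no_overlap_empty(self):
        runs = [[ora_res("a", 4.0, 0.01)], [ora_res("b", 4.0, 0.01)]]
        assert ig.recurrent_processes(runs) == []

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ig.recurrent_processes([[ora_res("a", 4.0, 0.01)]])


class TestProcessGroupShares:
    def test_half_and_half(self):
        shares = ig.process_group_shares(
            ["t1", "t2", "t3", "t4"],
            {"t1": "immune response", "t2": "immune response"})
        assert shares == {"immune response": 0.5, "other": 0.5}

    def test_single_group(self):
        assert ig.process_group_shares(["a", "b"], {"a": "x", "b": "x"}) == {"x": 1.0}

    def test_random_groups_match_counting_oracle(self):
        rng = np.random.default_rng(14)
        groups = ["immune", "migration", "rho", "neuronal", "metabolism", "other"]
        terms = [f"t{i}" for i in range(60)]
        gmap = {t: groups[rng.integers(len(groups))] for t in terms}
        shares = ig.process_group_shares(terms, gmap)
        from collections import Counter
        counts = Counter(gmap[t] for t in terms)
        for g, share in shares.items():
            assert share == pytest.approx(counts[g] / 60)
        assert sum(shares.values()) == pytest.approx(1.0)


class TestGMT:
    def test_read_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("kera\tdesc\tKRT14\tKRT17\tIVL\nimmune\tdesc\tLCK\n")
        sets = ig.read_gmt(p)
        assert sets["kera"] == {"KRT14", "KRT17", "IVL"}
        assert sets["immune"] == {"LCK"}
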