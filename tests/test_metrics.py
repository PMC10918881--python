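"""Diversity, overlap, isotype and light-chain statistics.

Expected values are frozen from independent hand arithmetic (closed forms
noted inline); generator-derived ground truth covers the tallies.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrnet import metrics
from bcrnet.simulate import SimConfig, simulate_repertoires
from bcrnet.types import ChainRecord

from test_network import make_cell


class TestCloneSizes:
    def test_identical_paired_cdr3_cells_share_a_clone(self):
        cells = [
            make_cell("b1", "CARDYW", "CQQSYW"),
            make_cell("b2", "CARDYW", "CQQSYW"),
            make_cell("b3", "CARDFF", "CQQSYW"),
            make_cell("b4", "CARDYW", "CQQAAW"),
        ]
        sizes = sorted(metrics.clone_sizes(cells).values(), reverse=True)
        assert sizes == [2, 1, 1]
        assert sum(sizes) == len(cells)

    def test_all_unique_cells_are_singletons(self):
        cells = [make_cell(f"b{i}", f"CARD{c}W", "CQQSYW") for i, c in enumerate("ASDF")]
        assert set(metrics.clone_sizes(cells).values()) == {1}

    def test_sizes_match_generator_ground_truth(self):
        cfg = SimConfig(
            n_patients=1, tissues=("PB",), mode="single_cell", n_cells=50, seed=5
        )
        sample = simulate_repertoires(cfg)[0]
        truth = {}
        for cell in sample.cells:
            truth[cell.clone_id] = cell.clone_size
        observed = metrics.clone_sizes(sample.cells, definition="clone_id")
        assert observed == truth


class TestShannon:
    def test_single_clonotype_is_zero(self):
        assert metrics.shannon({"a": 5}) == 0.0

    def test_uniform_closed_form(self):
        assert metrics.shannon({c: 1 for c in "abcd"}) == pytest.approx(math.log(4), abs=1e-12)

    def test_worked_value_three_one(self):
        # -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.5623351446188083
        assert metrics.shannon({"a": 3, "b": 1}) == pytest.approx(0.5623351446188083, abs=1e-9)

    def test_zero_counts_ignored_and_all_zero_rejected(self):
        assert metrics.shannon({"a": 3, "b": 1, "c": 0}) == metrics.shannon({"a": 3, "b": 1})
        with pytest.raises(ValueError):
            metrics.shannon({"a": 0})

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8))
    def test_uniform_maximises_and_merging_never_increases(self, counts):
        k = len(counts)
        h = metrics.shannon(counts)
        assert h <= math.log(k) + 1e-12
        merged = [counts[0] + counts[1], *counts[2:]]
        assert metrics.shannon(merged) <= h + 1e-12


class TestAdjustedShannon:
    def test_all_singletons_is_exactly_one(self):
        assert metrics.adjusted_shannon({c: 1 for c in "abcdefg"}) == pytest.approx(1.0, abs=1e-12)

    def test_single_clone_is_zero(self):
        assert metrics.adjusted_shannon({"a": 10}) == 0.0

    def test_worked_composition(self):
        # 0.5623351446 / ln 4 = 0.4056390622295665
        assert metrics.adjusted_shannon({"a": 3, "b": 1}) == pytest.approx(
            0.5623351446188083 / math.log(4), abs=1e-9
        )

    def test_total_below_two_rejected(self):
        with pytest.raises(ValueError):
            metrics.adjusted_shannon({"a": 1})

    def test_raw_total_scale_option(self):
        assert metrics.adjusted_shannon({"a": 3, "b": 1}, scale="total") == pytest.approx(
            0.5623351446188083 / 4, abs=1e-12
        )

    def test_invariant_under_relabeling(self):
        a = {"x": 3, "y": 5, "z": 2}
        b = {"q": 5, "r": 2, "s": 3}
        assert metrics.adjusted_shannon(a) == metrics.adjusted_shannon(b)


class TestMorisitaHorn:
    def test_self_similarity_is_one(self):
        x = {"a": 7, "b": 2, "c": 11}
        assert metrics.morisita_horn(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_are_zero(self):
        assert metrics.morisita_horn({"a": 3}, {"b": 5}) == 0.0

    def test_worked_example(self):
        # 2*(2*1+1*3) / ((5/9 + 10/16) * 3 * 4) = 60/85 = 12/17
        assert metrics.morisita_horn({"A": 2, "B": 1}, {"A": 1, "B": 3}) == pytest.approx(
            12 / 17, abs=1e-9
        )

    def test_symmetry_and_rescaling_invariance(self):
        x = {"a": 2, "b": 1, "c": 4}
        y = {"a": 1, "b": 3, "d": 2}
        assert metrics.morisita_horn(x, y) == pytest.approx(metrics.morisita_horn(y, x), abs=1e-12)
        x10 = {k: 10 * v for k, v in x.items()}
        assert metrics.morisita_horn(x10, y) == pytest.approx(
            metrics.morisita_horn(x, y), abs=1e-12
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            metrics.morisita_horn({}, {"a": 1})


def bulk_chain(seq_id, locus, cdr3, c_gene, count):
    return ChainRecord(
        sequence_id=seq_id, sample_id="s", locus=locus,
        v_gene=f"{locus}V1-1", j_gene=f"{locus}J1", c_gene=c_gene,
        cdr3_aa=cdr3, read_count=count,
    )


class TestIsotypeUsage:
    def test_cell_population_fraction(self):
        cells = [
            make_cell(f"b{i}", f"CARD{i}W"[:4] + "W", isotype="IGHA1" if i < 4 else "IGHM")
            for i in range(10)
        ]
        usage = metrics.isotype_usage(cells)
        assert usage["IGHA1"] == pytest.approx(0.4)
        assert usage.sum() == pytest.approx(1.0)

    def test_read_count_weighting_matches_hand_tally(self):
        chains = [
            bulk_chain("r1", "IGH", "CARAW", "IGHA2", 7),
            bulk_chain("r2", "IGH", "CARBW", "IGHA2", 3),
            bulk_chain("r3", "IGH", "CARCW", "IGHG1", 10),
            bulk_chain("r4", "IGK", "CQQW", "IGKC", 99),
        ]
        usage = metrics.isotype_usage(chains, weight="read_count")
        assert usage["IGHA2"] == pytest.approx(10 / 20)
        assert usage["IGHG1"] == pytest.approx(10 / 20)
        record_usage = metrics.isotype_usage(chains, weight="record")
        assert record_usage["IGHA2"] == pytest.approx(2 / 3)

    def test_undetected_isotypes_report_zero(self):
        usage = metrics.isotype_usage([bulk_chain("r1", "IGH", "CARAW", "IGHM", 1)])
        assert usage["IGHE"] == 0.0 and len(usage) == 9

    def test_no_heavy_chains_rejected(self):
        with pytest.raises(ValueError):
            metrics.isotype_usage([bulk_chain("r1", "IGK", "CQQW", "IGKC", 1)])


class TestKappaLambdaRatio:
    def test_record_counts(self):
        chains = [bulk_chain(f"k{i}", "IGK", "CQQW", "IGKC", 1) for i in range(100)]
        chains += [bulk_chain(f"l{i}", "IGL", "CQAW", "IGLC2", 1) for i in range(50)]
        assert metrics.kappa_lambda_ratio(chains, weight="record") == pytest.approx(2.0)

    def test_zero_kappa_boundary(self):
        chains = [bulk_chain(f"l{i}", "IGL", "CQAW", "IGLC2", 1) for i in range(10)]
        assert metrics.kappa_lambda_ratio(chains) == 0.0

    def test_missing_when_no_lambda(self):
        chains = [bulk_chain("k1", "IGK", "CQQW", "IGKC", 5)]
        assert metrics.kappa_lambda_ratio(chains) is None

    def test_read_count_weighting_matches_hand_tally(self):
        chains = [
            bulk_chain("k1", "IGK", "CQQW", "IGKC", 6),
            bulk_chain("k2", "IGK", "CQQYW", "IGKC", 4),
            bulk_chain("l1", "IGL", "CQAW", "IGLC2", 5),
        ]
        assert metrics.kappa_lambda_ratio(chains) == pytest.approx(2.0)

    def test_no_light_chains_rejected(self):
        with pytest.raises(ValueError):
            metrics.kappa_lambda_ratio([bulk_chain("h1", "IGH", "CARW", "IGHM", 1)])


class TestMetricsTable:
    def test_reproduces_generator_tallies(self):
        cfg = SimConfig(n_patients=2, tissues=("SG_labial",), n_chains=120, seed=9)
        samples = simulate_repertoires(cfg)
        table = metrics.metrics_table(samples).set_index("sample_id")
        for sample in samples:
            row = table.loc[sample.sample_id]
            igh = sum(c.read_count for c in sample.chains if c.locus == "IGH")
            igk = sum(c.read_count for c in sample.chains if c.locus == "IGK")
            igl = sum(c.read_count for c in sample.chains if c.locus == "IGL")
            assert row["total_igh_count"] == igh
            assert row["total_igk_count"] == igk
            assert row["total_igl_count"] == igl
            if igl:
                assert row["kappa_lambda_ratio"] == pytest.approx(igk / igl)
            usage_cols = [c for c in table.columns if c.startswith("usage_")]
            assert np.nansum([row[c] for c in usage_cols]) == pytest.approx(1.0)
            assert 0.0 <= row["adjusted_shannon"] <= 1.0
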