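import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from balancerscan import io
from balancerscan import simulate as sim
from balancerscan import traits
from balancerscan.effects import VariantEffect
from balancerscan.errors import DegenerateInputError

from oracles import fisher_two_sided


class TestConservationTally:
    def test_curated_sixty_gene_table(self):
        counts = traits.conservation_tally(io.load_conservation_table())
        assert counts == {"N": 8, "N+I+M": 8, "N+I+M+F": 44, "other": 0}
        pct = traits.conservation_percentages(counts)
        assert pct["N+I+M+F"] == pytest.approx(73.3, abs=0.05)
        assert pct["N"] == pytest.approx(13.3, abs=0.05)

    def test_empty_input_all_zero(self):
        empty = pd.DataFrame(columns=["gene", "N", "I", "M", "F"])
        assert sum(traits.conservation_tally(empty).values()) == 0

    def test_all_flags_true_all_deep(self):
        frame = pd.DataFrame({"gene": list("abc"), "N": 1, "I": 1, "M": 1, "F": 1})
        assert traits.conservation_tally(frame)["N+I+M+F"] == 3

    def test_categories_partition_input(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.integers(0, 2, size=(50, 4)), columns=list("NIMF")
        )
        frame.insert(0, "gene", [f"g{i}" for i in range(50)])
        assert sum(traits.conservation_tally(frame).values()) == 50


class TestDuplicability:
    def pairs(self, pid, ev):
        return pd.DataFrame(
            dict(gene_a=["A"], gene_b=["B"], percent_identity=[pid],
                 e_value=[ev])
        )

    def test_strong_pair_both_duplicates(self):
        out = traits.classify_duplicability(self.pairs(55.0, 1e-30))
        assert out == {"A": "duplicate", "B": "duplicate"}

    def test_pid_boundary_exclusive_below(self):
        out = traits.classify_duplicability(self.pairs(49.9, 1e-40))
        assert out == {"A": "singleton", "B": "singleton"}

    def test_gene_without_pairs_is_singleton(self):
        out = traits.classify_duplicability(self.pairs(80.0, 1e-40), genes=["A", "B", "C"])
        assert out["C"] == "singleton"

    @given(st.floats(min_value=0, max_value=100),
           st.floats(min_value=0, max_value=100))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_pid_threshold(self, t1, t2):
        lo, hi = sorted([t1, t2])
        table = pd.DataFrame(
            dict(gene_a=list("ABCDE"), gene_b=list("VWXYZ"),
                 percent_identity=[10.0, 35.0, 50.0, 75.0, 99.0],
                 e_value=[1e-30] * 5)
        )
        at_lo = traits.classify_duplicability(table, pid_threshold=lo)
        at_hi = traits.classify_duplicability(table, pid_threshold=hi)
        for gene, cls in at_hi.items():
            if cls == "duplicate":
                assert at_lo[gene] == "duplicate"


class TestFisher:
    def test_diagonal_table(self):
        assert traits.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / 252, rel=1e-12
        )

    def test_balanced_table_is_one(self):
        assert traits.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            traits.fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(1, 21):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                table = [[a, b], [c, d]]
                assert traits.fisher_exact_2x2(table) == pytest.approx(
                    fisher_two_sided(table), abs=1e-12
                )

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(1)
        for _ in range(200):
            table = rng.integers(0, 30, size=(2, 2))
            if table.sum() == 0:
                continue
            assert traits.fisher_exact_2x2(table) == pytest.approx(
                fisher_exact(table)[1], abs=1e-9
            )


class TestGroupComparisons:
    def test_separated_proportions_highly_significant(self):
        groups = sim.simulate_gene_groups({"G1": 100, "G2": 100}, seed=0)
        rng = np.random.default_rng(3)
        trait = {
            row.gene_id: bool(rng.random() < (0.9 if row.group == "G1" else 0.5))
            for row in groups.itertuples()
        }
        out = traits.group_proportion_compare(trait, groups).set_index("group")
        assert out.loc["G2", "p_value"] < 0.001
        assert out.loc["G2", "stars"] == "***"

    def test_identical_groups_p_one(self):
        groups = sim.simulate_gene_groups({"G1": 20, "G2": 20}, seed=0)
        trait = {g: i % 2 == 0 for i, g in enumerate(groups.gene_id)}
        out = traits.group_proportion_compare(trait, groups).set_index("group")
        assert out.loc["G2", "p_value"] == pytest.approx(1.0)

    def test_uncovered_group_skipped(self, caplog):
        groups = sim.simulate_gene_groups({"G1": 10, "G3": 10}, seed=0)
        trait = {g: True for g in groups[groups.group == "G1"].gene_id}
        with caplog.at_level("WARNING"):
            out = traits.group_proportion_compare(trait, groups)
        assert list(out.group) == ["G1"]
        assert "G3" in caplog.text


class TestConnectivity:
    def test_all_hubs(self):
        groups = sim.simulate_gene_groups({"G1": 5}, seed=0)
        inter = pd.DataFrame(dict(gene_id=groups.gene_id, interactors=11))
        out = traits.connectivity_summary(inter, groups)
        assert out.loc[0, "frac_>10"] == 1.0

    def test_empty_interactions_all_zero(self, caplog):
        groups = sim.simulate_gene_groups({"G1": 5}, seed=0)
        with caplog.at_level("WARNING"):
            out = traits.connectivity_summary(
                pd.DataFrame(columns=["gene_id", "interactors"]), groups
            )
        assert out.loc[0, "n"] == 0

    def test_shifted_degree_distributions_detected(self):
        groups = sim.simulate_gene_groups({"G1": 500, "G4": 500}, seed=1)
        inter = sim.simulate_interaction_table(
            groups, {"G1": 14.0, "G4": 4.0}, seed=2
        )
        out = traits.connectivity_summary(inter, groups).set_index("group")
        assert out.loc["G1", "frac_>10"] > out.loc["G4", "frac_>10"]
        assert out.loc["G4", "hub_p_vs_G1"] < 0.05


class TestExpression:
    def test_constant_matrix(self):
        groups = sim.simulate_gene_groups({"G1": 10}, seed=0)
        matrix = pd.DataFrame(
            8.0, index=groups.gene_id, columns=[f"s{i}" for i in range(5)]
        )
        summary, slopes = traits.expression_summary(matrix, groups)
        assert np.allclose(summary["median"], np.log2(9.0))
        assert slopes["G1"] == pytest.approx(0.0, abs=1e-12)

    def test_single_stage_slope_undefined(self):
        groups = sim.simulate_gene_groups({"G1": 4}, seed=0)
        matrix = pd.DataFrame(1.0, index=groups.gene_id, columns=["only"])
        _, slopes = traits.expression_summary(matrix, groups)
        assert slopes["G1"] is None

    def test_fourfold_expression_separates_groups(self):
        groups = sim.simulate_gene_groups({"G1": 200, "G4": 200}, seed=3)
        matrix = sim.simulate_expression_matrix(
            groups, n_stages=8, multiplier_by_group={"G1": 4.0}, seed=4
        )
        summary, _ = traits.expression_summary(matrix, groups)
        piv = summary.pivot(index="stage", columns="group", values="median")
        assert (piv["G1"] > piv["G4"]).all()


class TestWindowConservation:
    def test_identical_rows_fully_conserved(self):
        aln = ["MKVLLDWKRT" * 15] * 10
        out = traits.window_conservation(aln, 75)
        assert out.window_mean == 1.0 and out.conserved
        assert (out.identities == 1.0).all()

    def test_window_spans_fifty_up_fortynine_down(self):
        aln = ["A" * 300, "A" * 300]
        out = traits.window_conservation(aln, 150)
        assert out.columns[0] == 100 and out.columns[-1] == 199
        assert len(out.columns) == 100

    def test_window_clipped_at_start(self):
        aln = ["A" * 300, "A" * 300]
        out = traits.window_conservation(aln, 10)
        assert out.columns[0] == 1 and out.columns[-1] == 59

    def test_random_alignment_quarter_identity(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACDE"), 200)) for _ in range(40)]
        out = traits.window_conservation(rows, 100)
        assert out.window_mean == pytest.approx(0.25, abs=0.03)
        assert not out.conserved

    def test_out_of_range_column(self):
        with pytest.raises(IndexError):
            traits.window_conservation(["AAA", "AAA"], 7)

    def test_gaps_excluded_from_denominator(self):
        aln = ["AAAA", "A-AA", "AC-A"]
        out = traits.window_conservation(aln, 2, window=2)
        # column 2: non-gap rows are '-'-> skipped and 'C' -> identity 0/1... row2 gap
        assert out.identities[-1] == pytest.approx(0.0)


def make_effects(nonsense, missense):
    effs = [
        VariantEffect("g", "t", "nonsense", relative_position=p)
        for p in nonsense
    ]
    effs += [
        VariantEffect("g", "t", "missense", relative_position=p)
        for p in missense
    ]
    return effs


class TestNonsensePositionStat:
    def test_separated_classes(self):
        effs = make_effects(np.linspace(0.05, 0.15, 12),
                            np.linspace(0.85, 0.95, 12))
        out = traits.nonsense_position_stat(effs, 10_000, seed=0)
        assert out.class_means["nonsense"] < out.class_means["missense"]
        assert out.p_value <= 1e-3

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        effs = make_effects(rng.random(15), rng.random(15))
        a = traits.nonsense_position_stat(effs, 2000, seed=9)
        b = traits.nonsense_position_stat(effs, 2000, seed=9)
        assert a.p_value == b.p_value

    def test_too_few_nonsense_skipped(self):
        effs = make_effects([0.4], np.linspace(0.1, 0.9, 10))
        out = traits.nonsense_position_stat(effs)
        assert out.skipped and out.p_value is None

    def test_null_calibration(self):
        """Under identical distributions the test rejects at ~nominal rate."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_null = 200
        for i in range(n_null):
            effs = make_effects(rng.random(20), rng.random(20))
            out = traits.nonsense_position_stat(effs, 400, seed=1000 + i)
            if out.p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_null <= 0.07
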