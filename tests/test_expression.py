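import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_panel
from pdpathways.expression import (
    CALL_DOWN,
    CALL_NONE,
    CALL_UP,
    adjacent_deltas,
    adjust_case_deltas,
    adjusted_delta_pvalues,
    benjamini_hochberg,
    call_differential,
    collect_gene_lists,
    control_average_deltas,
    differential_analysis,
)
from pdpathways.models import PipelineConfig


class TestAdjacentDeltas:
    def test_later_minus_earlier(self):
        values = np.zeros((1, 3, 2))
        values[0, 0] = [6.0, 8.0]  # DMV=6, next region=8
        panel = make_panel(values, 1, 2, regions=("DMV", "LCER"))
        d = adjacent_deltas(panel, "case0")
        assert d.loc["g0", "DMV->LCER"] == pytest.approx(2.0)

    def test_identical_values_give_zero(self):
        panel = make_panel(np.full((2, 3, 4), 7.5), 1, 2, regions=list("WXYZ"))
        assert (adjacent_deltas(panel, "case0").to_numpy() == 0).all()

    def test_five_regions_give_four_pairs(self):
        panel = make_panel(np.zeros((3, 3, 5)), 1, 2, regions=list("ABCDE"))
        assert adjacent_deltas(panel, "case0").shape == (3, 4)

    def test_unknown_subject_fails(self):
        panel = make_panel(np.zeros((1, 3, 2)), 1, 2, regions=("A", "B"))
        with pytest.raises(KeyError):
            adjacent_deltas(panel, "nobody")


class TestControlAverageDeltas:
    def _panel_with_control_deltas(self, deltas):
        """One gene, one pair; control raw deltas set to `deltas`."""
        n_ctrl = len(deltas)
        values = np.zeros((1, 1 + n_ctrl, 2))
        for j, d in enumerate(deltas):
            values[0, 1 + j] = [0.0, d]
        return make_panel(values, 1, n_ctrl, regions=("A", "B"))

    def test_mean_of_replicates(self):
        mean, _ = control_average_deltas(self._panel_with_control_deltas([0.4, 0.6, 0.5, 0.5]))
        assert mean.iloc[0, 0] == pytest.approx(0.5)

    def test_equal_replicates_have_zero_sd(self):
        _, sd = control_average_deltas(self._panel_with_control_deltas([0.3, 0.3, 0.3]))
        assert sd.iloc[0, 0] == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        mean, sd = control_average_deltas(self._panel_with_control_deltas([0.0, 1.0]))
        assert mean.iloc[0, 0] == pytest.approx(0.5)
        assert sd.iloc[0, 0] == pytest.approx(np.sqrt(0.5), abs=1e-12)  # ~0.7071


class TestAdjustCaseDeltas:
    @pytest.mark.parametrize(
        "raw,ctrl,expected", [(2.0, 0.5, 1.5), (0.5, 0.5, 0.0), (-1.0, -0.2, -0.8)]
    )
    def test_arithmetic(self, raw, ctrl, expected):
        case = pd.DataFrame({"A->B": [raw]}, index=["g0"])
        mean = pd.DataFrame({"A->B": [ctrl]}, index=["g0"])
        assert adjust_case_deltas(case, mean).iloc[0, 0] == pytest.approx(expected)

    def test_misaligned_tables_fail(self):
        case = pd.DataFrame({"A->B": [1.0]}, index=["g0"])
        mean = pd.DataFrame({"A->B": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            adjust_case_deltas(case, mean)


class TestZTest:
    def test_worked_example(self):
        z, p = adjusted_delta_pvalues(1.5, 0.5, 4)
        assert z == pytest.approx(2.6833, abs=1e-4)
        assert p == pytest.approx(0.00729, abs=1e-5)

    def test_zero_delta_is_null(self):
        z, p = adjusted_delta_pvalues(0.0, 0.5, 4)
        assert z == 0.0 and p == 1.0

    def test_zero_sd_uncallable(self):
        _, p = adjusted_delta_pvalues(5.0, 0.0, 4)
        assert p == 1.0


class TestBenjaminiHochberg:
    def test_step_up_formula(self):
        q = benjamini_hochberg([0.001, 0.01, 0.02, 0.04])
        assert q == pytest.approx([0.004, 0.02, 0.0267, 0.04], abs=1e-4)

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_out_of_range_fails(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def planted_panel(shift=2.0, noise=0.05, seed=0, n_genes=40, n_cases=2, n_ctrl=4):
    """First 10 genes carry a cumulative per-region case-only shift."""
    rng = np.random.default_rng(seed)
    regions = ("R1", "R2", "R3")
    base = rng.normal(8, 1, n_genes)
    values = base[:, None, None] + rng.normal(0, noise, (n_genes, n_cases + n_ctrl, 3))
    values[:10, :n_cases, :] += shift * np.arange(3)[None, None, :]
    return make_panel(values, n_cases, n_ctrl, regions=regions)


class TestCallDifferential:
    def test_fold_change_gate_blocks_small_deltas(self):
        # strong z but |delta| 0.5 < log2(1.6): never called
        panel = planted_panel(shift=0.5, noise=0.01)
        table = call_differential(panel, PipelineConfig())
        sig = table[(table["gene"].isin([f"g{i}" for i in range(10)]))]
        assert (sig["call"] == CALL_NONE).all()
        assert (sig.groupby("gene")["q_value"].min() < 0.05).any()

    def test_planted_up_shift_called_up(self):
        table = call_differential(planted_panel(), PipelineConfig())
        lists = collect_gene_lists(table)
        assert {f"g{i}" for i in range(10)} <= lists.up
        assert not lists.down

    def test_negating_panel_swaps_up_and_down(self):
        panel = planted_panel()
        neg = make_panel(-panel.values, 2, 4, regions=panel.regions)
        up = collect_gene_lists(call_differential(panel, PipelineConfig()))
        down = collect_gene_lists(call_differential(neg, PipelineConfig()))
        assert up.up == down.down and up.down == down.up

    def test_control_relabelling_is_invariant(self):
        panel = planted_panel()
        perm = panel.values.copy()
        perm[:, [2, 3, 4, 5]] = perm[:, [5, 4, 2, 3]]  # permute the 4 controls
        permuted = make_panel(perm, 2, 4, regions=panel.regions)
        a = call_differential(panel, PipelineConfig())
        b = call_differential(permuted, PipelineConfig())
        pd.testing.assert_frame_equal(a, b)

    def test_zero_control_sd_gene_is_uncallable(self):
        values = np.random.default_rng(1).normal(8, 0.3, (5, 5, 3))
        values[0, 1:, :] = 8.0  # controls identical -> sd 0 for gene 0
        values[0, 0, :] = [8.0, 12.0, 16.0]  # huge case delta
        panel = make_panel(values, 1, 4, regions=("A", "B", "C"))
        table = call_differential(panel, PipelineConfig())
        g0 = table[table["gene"] == "g0"]
        assert (g0["p_value"] == 1.0).all() and (g0["call"] == CALL_NONE).all()


class TestCollectGeneLists:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "subject", "pair", "call"])

    def test_single_call_reaches_up_and_merged(self):
        lists = collect_gene_lists(
            self._table([("g", "s1", "p2", CALL_UP), ("g", "s1", "p1", CALL_NONE)])
        )
        assert lists.up == {"g"} and lists.merged == {"g"} and not lists.down

    def test_no_calls_gives_empty_sets(self):
        lists = collect_gene_lists(self._table([("g", "s1", "p1", CALL_NONE)]))
        assert not lists.up and not lists.down and not lists.merged

    def test_gene_up_and_down_in_both_lists_merged_once(self):
        lists = collect_gene_lists(
            self._table([("g", "s1", "p1", CALL_UP), ("g", "s2", "p1", CALL_DOWN)])
        )
        assert lists.up == {"g"} == lists.down
        assert lists.merged == {"g"}


def test_null_call_rate_respects_bh_bound():
    """No planted signal: the fraction of calls stays within the BH allowance."""
    rates = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        values = rng.normal(8, 0.3, (400, 8, 5)) + rng.normal(8, 1, 400)[:, None, None]
        panel = make_panel(values, 4, 4, regions=list("ABCDE"))
        table = call_differential(panel, PipelineConfig())
        rates.append((table["call"] != CALL_NONE).mean())
    assert np.mean(rates) <= 0.08
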