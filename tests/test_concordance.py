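import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenoconcord as pc
from phenoconcord.concordance import (
    MeanConcordance,
    PresenceMatrix,
    observed_universe,
)

from conftest import make_survey


def matrix_from(values, survey="S1", level="general"):
    values = np.asarray(values, dtype=np.uint8)
    r, s, t = values.shape
    return PresenceMatrix(
        survey, level,
        [f"r{i}" for i in range(r)],
        [f"s{i}" for i in range(s)],
        [f"t{i}" for i in range(t)],
        values,
    )


class TestPresenceMatrix:
    def test_toy_cells(self, lexicon, hierarchy):
        table = make_survey("S1", [("A", "X", "curved tail")])
        h = pc.harmonize_table(table, lexicon, hierarchy)
        m = pc.presence_matrix(h, "general", raters=["A", "B"])
        assert m.cell("A", "X", "ZP:0001129") == 1
        assert m.cell("B", "X", "ZP:0001129") == 0

    def test_idempotent_build(self, lexicon, hierarchy):
        rows = [("A", "X", "curved tail"), ("B", "X", "cfin"), ("B", "Y", "short tail")]
        h = pc.harmonize_table(make_survey("S1", rows), lexicon, hierarchy)
        m1 = pc.presence_matrix(h, "granular")
        m2 = pc.presence_matrix(h, "granular")
        assert np.array_equal(m1.values, m2.values)

    def test_general_level_or_aggregates_children(self, lexicon, hierarchy):
        rows = [("A", "X", "curved tail"), ("A", "X", "short tail")]
        h = pc.harmonize_table(make_survey("S1", rows), lexicon, hierarchy)
        gran = pc.presence_matrix(h, "granular")
        gen = pc.presence_matrix(h, "general")
        assert gran.values.sum() == 2
        assert gen.values.sum() == 1  # both children OR into one general cell

    def test_empty_table_rejected(self, lexicon, hierarchy):
        h = pc.harmonize_table(
            make_survey("S1", [("A", "X", "gibberish")]), lexicon, hierarchy
        )
        with pytest.raises(ValueError):
            pc.presence_matrix(h, "general")


class TestMajorityCall:
    def test_strict_majority(self):
        m = matrix_from(np.array([1, 1, 1, 0, 0]).reshape(5, 1, 1))
        assert pc.majority_call(m, "s0", "t0") == 1

    def test_tie_resolves_absent(self, caplog):
        m = matrix_from(np.array([1, 1, 0, 0]).reshape(4, 1, 1))
        with caplog.at_level("INFO"):
            assert pc.majority_call(m, "s0", "t0") == 0
        assert any("tie" in r.message for r in caplog.records)

    def test_unanimous(self):
        assert pc.majority_call(matrix_from(np.ones((3, 1, 1))), "s0", "t0") == 1
        assert pc.majority_call(matrix_from(np.zeros((3, 1, 1))), "s0", "t0") == 0


class TestConcordanceCells:
    def test_single_dissenter(self):
        m = matrix_from(np.array([1, 1, 1, 1, 0]).reshape(5, 1, 1))
        cells = pc.concordance_cells(m)
        by_rater = cells.set_index("rater")["concordant"]
        assert by_rater["r4"] == 0
        assert by_rater.drop("r4").eq(1).all()

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_concordant_count_all_patterns(self, n):
        """Brute force over every 0/1 rater pattern: number concordant is
        max(k, n-k) without a tie, n-k at a tie (majority -> absent)."""
        for pattern in itertools.product([0, 1], repeat=n):
            m = matrix_from(np.array(pattern).reshape(n, 1, 1))
            got = int(pc.concordance_cells(m)["concordant"].sum())
            k = sum(pattern)
            expected = (n - k) if 2 * k == n else max(k, n - k)
            assert got == expected, pattern

    def test_universe_mask_restricts_columns(self):
        vals = np.zeros((3, 2, 2), dtype=np.uint8)
        vals[0, 0, 0] = 1
        m = matrix_from(vals)
        mask = observed_universe(m)
        cells = pc.concordance_cells(m, mask)
        # only the single tagged (specimen, trait) column is scored
        assert len(cells) == 3
        assert set(zip(cells["specimen"], cells["trait"])) == {("s0", "t0")}


class TestMeanConcordance:
    def cells(self, concordant, group="A"):
        return pd.DataFrame(
            {
                "rater": group,
                "specimen": "s",
                "trait": "t",
                "survey": "S1",
                "concordant": concordant,
            }
        )

    def test_simple_mean(self):
        mc = pc.mean_concordance(self.cells([1, 1, 0, 1]), "rater")
        assert mc.table.iloc[0]["mean"] == 0.75

    def test_all_concordant(self):
        cells = pd.concat([self.cells([1, 1], "A"), self.cells([1], "B")])
        mc = pc.mean_concordance(cells, "rater")
        assert (mc.table["mean"] == 1.0).all()
        assert mc.sd_across_groups == 0.0

    def test_pooled_equals_weighted_group_means(self):
        rng = np.random.default_rng(5)
        cells = pd.DataFrame(
            {
                "rater": rng.choice(list("ABCD"), 200),
                "specimen": rng.choice(list("xyz"), 200),
                "trait": rng.choice(list("pq"), 200),
                "survey": "S1",
                "concordant": rng.integers(0, 2, 200),
            }
        )
        for group_by in ("rater", "specimen", "trait"):
            mc = pc.mean_concordance(cells, group_by)
            weighted = (mc.table["mean"] * mc.table["n"]).sum() / mc.table["n"].sum()
            assert mc.pooled_mean == pytest.approx(weighted)

    def test_invariant_to_rater_relabeling(self):
        rng = np.random.default_rng(6)
        cells = pd.DataFrame(
            {
                "rater": rng.choice(list("AB"), 100),
                "specimen": rng.choice(list("xy"), 100),
                "trait": "t",
                "survey": "S1",
                "concordant": rng.integers(0, 2, 100),
            }
        )
        renamed = cells.assign(rater=cells["rater"].map({"A": "Z", "B": "Q"}))
        a = pc.mean_concordance(cells, "specimen")
        b = pc.mean_concordance(renamed.sample(frac=1, random_state=0), "specimen")
        pd.testing.assert_frame_equal(
            a.table.sort_values("group").reset_index(drop=True),
            b.table.sort_values("group").reset_index(drop=True),
        )

    def test_unknown_grouping(self):
        with pytest.raises(ValueError):
            pc.mean_concordance(self.cells([1]), "larva")


class TestFisherExact:
    def test_symmetric_table(self):
        assert pc.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_extreme_diagonal(self):
        assert pc.fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            1.0825e-5, rel=1e-3
        )

    def test_enumeration_example(self):
        assert pc.fisher_exact_2x2([[1, 9], [11, 3]]) == pytest.approx(
            0.00276, abs=1e-5
        )

    def test_zero_margin_convention(self):
        assert pc.fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0
        assert pc.fisher_exact_2x2([[2, 0], [3, 0]]) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            pc.fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            pc.fisher_exact_2x2([[0.5, 1], [1, 1]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 2))
            ours = pc.fisher_exact_2x2(t)
            ref = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)


class TestConcordanceChange:
    def two_surveys(self, conc1, conc2):
        def cells(vals, survey):
            return pd.DataFrame(
                {
                    "rater": "A",
                    "specimen": [f"s{i}" for i in range(len(vals))],
                    "trait": "t",
                    "survey": survey,
                    "concordant": vals,
                }
            )

        return cells(conc1, "S1"), cells(conc2, "S2")

    def test_delta_is_difference(self):
        c1, c2 = self.two_surveys([1] * 20 + [0] * 4, [1] * 22 + [0] * 2)
        out = pc.concordance_change(c1, c2, "rater")
        assert out.iloc[0]["delta"] == 2

    def test_identical_surveys_null(self):
        c1, c2 = self.two_surveys([1, 0, 1, 1], [1, 0, 1, 1])
        out = pc.concordance_change(c1, c2, "trait")
        assert out.iloc[0]["delta"] == 0
        assert out.iloc[0]["p_value"] == 1.0

    def test_extreme_change_p_value(self):
        c1, c2 = self.two_surveys([1] * 10 + [0] * 0, [0] * 10)
        out = pc.concordance_change(c1, c2, "rater")
        assert out.iloc[0]["p_value"] == pytest.approx(1.0825e-5, rel=1e-3)

    def test_delta_bounded_by_specimens(self, small_sim_analysis):
        res = small_sim_analysis
        n_specimens = res.cells[("general", "S1")]["specimen"].nunique()
        for tab in res.change.values():
            assert tab["delta"].abs().max() <= n_specimens

    def test_mismatched_axes_rejected(self):
        c1, c2 = self.two_surveys([1, 0], [1, 0])
        c2 = c2.assign(rater="B")
        with pytest.raises(ValueError):
            pc.concordance_change(c1, c2, "rater")


class TestPearson:
    def test_perfect_linearity(self):
        assert pc.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pc.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pc.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pc.pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            pc.pearson_r([1, 2], [3, 4])
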