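"""Cohort registry: loading, classification, summaries, suppression."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from limbcost.registry import (
    AmputationEvent,
    AmputationLevel,
    CasualtyRecord,
    CohortValidationError,
    PatternClass,
    SchemaError,
    SuppressionPolicy,
    apply_suppression,
    classify_pattern,
    level_marginals,
    read_cohort,
    summarize,
    write_cohort,
)


def _record(cid, levels, year=2010):
    return CasualtyRecord(
        cid, year, tuple(AmputationEvent(cid, lvl, year) for lvl in levels)
    )


L = AmputationLevel


class TestReadCohort:
    def test_groups_events_by_casualty(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "casualty_id,injury_year,level,side\n"
            "A,2010,transfemoral,unknown\n"
            "A,2010,transtibial,unknown\n"
            "B,2011,transtibial,left\n"
        )
        cohort = read_cohort(p)
        assert len(cohort) == 2
        by_id = {r.casualty_id: r for r in cohort}
        assert by_id["A"].n_limbs == 2
        assert by_id["B"].n_limbs == 1

    def test_empty_file_with_header_gives_empty_cohort(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("casualty_id,injury_year,level,side\n")
        assert read_cohort(p) == []

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("casualty_id,injury_year\nA,2010\n")
        with pytest.raises(SchemaError, match="level"):
            read_cohort(p)

    def test_unknown_level_reports_line_number(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "casualty_id,injury_year,level,side\n"
            "A,2010,transtibial,unknown\n"
            "B,2010,hip,unknown\n"
        )
        with pytest.raises(CohortValidationError, match="line 3"):
            read_cohort(p)

    def test_year_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("casualty_id,injury_year,level,side\nA,1999,foot,unknown\n")
        with pytest.raises(CohortValidationError, match="1999"):
            read_cohort(p)

    def test_write_read_round_trip(self, tmp_path, canonical):
        p = tmp_path / "out.csv"
        write_cohort(canonical, p)
        assert read_cohort(p) == canonical


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "n_levels,expected",
        [(1, PatternClass.SINGLE), (2, PatternClass.DOUBLE),
         (3, PatternClass.TRIPLE), (4, PatternClass.QUADRUPLE)],
    )
    def test_classes_match_event_count(self, n_levels, expected):
        rec = _record("x", [L.TRANSTIBIAL] * n_levels)
        assert classify_pattern(rec) is expected

    def test_more_than_four_events_rejected(self):
        rec = _record("x", [L.FOOT] * 5)
        with pytest.raises(CohortValidationError):
            classify_pattern(rec)

    def test_zero_event_record_unconstructible(self):
        with pytest.raises(CohortValidationError):
            CasualtyRecord("x", 2010, ())


class TestSummarize:
    def test_three_singles(self):
        cohort = [_record(str(i), [L.TRANSTIBIAL]) for i in range(3)]
        s = summarize(cohort)
        assert s.mean_limbs == 1.0
        assert s.sd_limbs == 0.0

    def test_composition_moments(self):
        # 140 singles, 101 doubles, 22 triples, 2 quadruples: moments computed
        # directly over the multiset {1^140, 2^101, 3^22, 4^2}.
        limbs = [1] * 140 + [2] * 101 + [3] * 22 + [4] * 2
        cohort = [_record(str(i), [L.FOOT] * n) for i, n in enumerate(limbs)]
        s = summarize(cohort)
        assert s.mean_limbs == pytest.approx(416 / 265, abs=1e-12)
        assert s.mean_limbs == pytest.approx(1.5698, abs=5e-5)
        assert s.sd_limbs_population == pytest.approx(0.6756, abs=5e-5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortValidationError):
            summarize([])

    def test_permutation_invariance(self, canonical):
        shuffled = list(canonical)
        random.Random(7).shuffle(shuffled)
        assert summarize(shuffled) == summarize(canonical)

    def test_limb_identity_over_patterns(self, canonical):
        s = summarize(canonical)
        assert s.n_limbs == sum(int(pc) * n for pc, n in s.by_pattern.items())
        assert s.n_limbs == sum(s.by_level.values())
        assert s.mean_limbs == pytest.approx(s.n_limbs / s.n_casualties)


class TestLevelMarginals:
    def test_derived_cells_on_mixed_cohort(self):
        cohort = [
            _record("a", [L.TRANSTIBIAL]),
            _record("b", [L.TRANSFEMORAL, L.TRANSFEMORAL]),
            _record("c", [L.TRANSFEMORAL, L.TRANSTIBIAL, L.FOOT]),
            _record("d", [L.FOOT] * 4),  # quadruple: excluded from the d+t cell
        ]
        m = level_marginals(cohort)
        assert m.transtibial_singles == 1
        assert m.transfemoral_in_doubles_and_triples == 3
        assert m.double_subpatterns == {(L.TRANSFEMORAL, L.TRANSFEMORAL): 1}
        assert m.by_level[L.FOOT] == 5


class TestSuppression:
    def test_small_cell_masked_and_column_protected(self):
        t = pd.DataFrame({"a": [2, 7]})
        out = apply_suppression(t, SuppressionPolicy(threshold=5))
        assert out.loc[0, "a"] == "#"
        # the published column total would expose the masked 2, so the 7 is
        # complementarily masked even though it clears the threshold
        assert out.loc[1, "a"] == "#"

    def test_basic_masking_in_wide_table(self):
        t = pd.DataFrame([[2, 9, 100], [7, 8, 50]])
        out = apply_suppression(t, SuppressionPolicy(threshold=5))
        assert out.iloc[0, 0] == "#"
        assert out.iloc[1, 2] == 50

    def test_complementary_row_suppression(self):
        # (1, 9, 100): the 1 is primary-masked; with the row total published
        # it would be recoverable, so the next-smallest cell (9) is masked.
        t = pd.DataFrame([[1, 9, 100]])
        out = apply_suppression(t, SuppressionPolicy(threshold=5))
        assert out.iloc[0, 0] == "#"
        assert out.iloc[0, 1] == "#"
        assert out.iloc[0, 2] == 100

    def test_zeros_not_primary_suppressed(self):
        t = pd.DataFrame([[0, 6, 7]])
        out = apply_suppression(t, SuppressionPolicy(threshold=5))
        assert list(out.iloc[0]) == [0, 6, 7]

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            apply_suppression(pd.DataFrame([[-1, 2]]), SuppressionPolicy())

    def test_idempotent(self):
        t = pd.DataFrame([[1, 9, 100], [4, 40, 2]])
        once = apply_suppression(t, SuppressionPolicy(threshold=5))
        twice = apply_suppression(once, SuppressionPolicy(threshold=5))
        assert once.equals(twice)

    @staticmethod
    def _recoverable_by_line(values, masked):
        """Brute-force: can any masked positive cell be recovered from a
        single row or column total?  Counts nonnegative-integer solutions of
        the line's masked cells given the published total, early-exiting at
        two."""

        def line_solutions(vals, mask):
            idx = [i for i, m in enumerate(mask) if m]
            if not idx:
                return 2  # nothing masked: nothing to recover
            remainder = sum(vals[i] for i in idx)
            # count compositions of remainder into len(idx) nonneg parts
            count = 0

            def rec(pos, left):
                nonlocal count
                if count >= 2:
                    return
                if pos == len(idx) - 1:
                    count += 1
                    return
                for v in range(left + 1):
                    rec(pos + 1, left - v)
                    if count >= 2:
                        return

            rec(0, remainder)
            return count

        nrow = len(values)
        ncol = len(values[0])
        for i in range(nrow):
            if any(masked[i][j] and values[i][j] > 0 for j in range(ncol)):
                if line_solutions(values[i], masked[i]) == 1:
                    return True
        for j in range(ncol):
            col_vals = [values[i][j] for i in range(nrow)]
            col_mask = [masked[i][j] for i in range(nrow)]
            if any(m and v > 0 for m, v in zip(col_mask, col_vals)):
                if line_solutions(col_vals, col_mask) == 1:
                    return True
        return False

    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=2, max_size=6),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_no_masked_positive_cell_recoverable(self, rows):
        t = pd.DataFrame(rows)
        out = apply_suppression(t, SuppressionPolicy(threshold=5))
        masked = [
            [isinstance(out.iloc[i, j], str) for j in range(t.shape[1])]
            for i in range(t.shape[0])
        ]
        assert not self._recoverable_by_line(rows, masked)
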