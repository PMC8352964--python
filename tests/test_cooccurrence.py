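"""Alteration calls, low-expression rule, Fisher test and H-score."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from oncodep.cooccurrence import (CohortTable, ContingencyTable2x2,
                                  alteration_summary, any_low,
                                  build_contingency, call_altered,
                                  call_low_expression, fisher_one_sided,
                                  h_score, read_cohort, write_cohort,
                                  zscore_vs_reference)


def enumerate_fisher_greater(table: ContingencyTable2x2) -> float:
    """Independent oracle: full hypergeometric enumeration over all tables
    with the observed margins, summing the probability of tables whose
    row-1 success count is >= the observed one."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    total = comb(n, col1, exact=True)
    p = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if x >= a:
            p += comb(row1, x, exact=True) * \
                 comb(n - row1, col1 - x, exact=True) / total
    return p


class TestAlteration:
    def test_printed_cohort_counts(self):
        """5 mutated + 32 amplified (no overlap) of 230 tumors: 37 altered,
        16% of the cohort."""
        mutation = np.zeros(230, bool)
        amplification = np.zeros(230, bool)
        mutation[:5] = True
        amplification[5:37] = True
        s = alteration_summary(mutation, amplification)
        assert s["n_altered"] == 37
        assert s["percent"] == pytest.approx(16.087, abs=1e-3)
        assert s["percent_rounded"] == 16

    def test_no_flags(self):
        s = alteration_summary(np.zeros(10, bool), np.zeros(10, bool))
        assert s["n_altered"] == 0 and s["percent"] == 0.0

    def test_or_matches_brute_force(self, rng):
        m = rng.random(100) < 0.3
        a = rng.random(100) < 0.2
        expected = sum(bool(x or y) for x, y in zip(m, a))
        assert call_altered(m, a).sum() == expected


class TestZScore:
    def test_mean_and_sd_units(self):
        diploid = np.array([True] * 4 + [False])
        expr = np.array([1.0, 2.0, 3.0, 4.0, 99.0])
        z = zscore_vs_reference(expr, diploid)
        ref = expr[:4]
        assert z[0] == pytest.approx((1.0 - ref.mean()) / ref.std(ddof=1))
        assert zscore_vs_reference(
            np.r_[ref, ref.mean()], diploid)[4] == pytest.approx(0.0)

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError, match="spread"):
            zscore_vs_reference([1.0, 1.0, 2.0], [True, True, False])


class TestLowExpression:
    def test_boundary_is_strict(self):
        # construct a column whose mean-sd boundary hits a value exactly
        x = np.array([0.0, 1.0, 2.0])  # mean 1, sd 1 -> threshold 0
        low = call_low_expression(x)
        assert not low[0]  # exactly at mean - sd: not low

    def test_gaussian_tail_fraction(self, rng):
        x = rng.normal(size=200_000)
        frac = call_low_expression(x).mean()
        assert frac == pytest.approx(0.1587, abs=0.005)

    def test_constant_column_warns_all_false(self):
        with pytest.warns(UserWarning, match="zero spread"):
            low = call_low_expression(np.full(5, 3.0))
        assert not low.any()

    def test_shift_invariance_and_scale_equivariance(self, rng):
        x = rng.normal(size=500)
        base = call_low_expression(x)
        assert np.array_equal(base, call_low_expression(x + 42.0))
        assert np.array_equal(base, call_low_expression(x * 3.0))


def _cohort(expr_by_gene, mutation=None, amplification=None):
    n = len(next(iter(expr_by_gene.values())))
    data = {"tumor_id": [f"T{i}" for i in range(n)],
            "mutation": mutation if mutation is not None else np.zeros(n, bool),
            "amplification": (amplification if amplification is not None
                              else np.zeros(n, bool)),
            "diploid": np.ones(n, bool)}
    for g, v in expr_by_gene.items():
        data[f"expr_{g}"] = v
    return CohortTable(pd.DataFrame(data))


class TestAnyLowAndContingency:
    def test_all_normal_false_one_low_true(self, rng):
        base = rng.normal(8, 1, size=50)
        low_col = base.copy()
        low_col[0] = -20.0  # far below mean - sd
        cohort = _cohort({"A": base, "B": low_col})
        flags = any_low(cohort, ["A", "B"])
        assert flags[0]
        cohort2 = _cohort({"A": base})
        assert not any_low(cohort2, ["A"])[
            np.argsort(np.abs(base - base.mean()))[0]]

    def test_absent_gene_is_named(self, rng):
        cohort = _cohort({"A": rng.normal(size=10)})
        with pytest.raises(KeyError, match="MISSING"):
            any_low(cohort, ["MISSING"])

    def test_contingency_matches_brute_force(self, rng):
        n = 120
        mutation = rng.random(n) < 0.2
        expr = {g: rng.normal(size=n) for g in ("A", "B", "C")}
        cohort = _cohort(expr, mutation=mutation)
        t = build_contingency(cohort, ("A", "B", "C"))
        low = any_low(cohort, ("A", "B", "C")).to_numpy()
        alt = mutation
        assert (t.a, t.b, t.c, t.d) == (
            int((alt & low).sum()), int((alt & ~low).sum()),
            int((~alt & low).sum()), int((~alt & ~low).sum()))
        assert t.a + t.b + t.c + t.d == n


class TestFisher:
    def test_printed_table_p(self):
        """28/37 altered vs 88/193 non-altered low: one-tailed p = 0.0006."""
        p = fisher_one_sided(ContingencyTable2x2(28, 9, 88, 105))
        assert round(p, 4) == 0.0006

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_one_sided(t) == pytest.approx(
                enumerate_fisher_greater(t), rel=1e-9, abs=1e-12)

    def test_most_extreme_table_closed_form(self):
        # row 1 all successes, row 2 all failures: p = 1 / C(n, k)
        t = ContingencyTable2x2(4, 0, 0, 6)
        assert fisher_one_sided(t) == pytest.approx(1 / comb(10, 4))

    def test_degenerate_margin_warns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_one_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_equal_proportions_tiny_table(self):
        t = ContingencyTable2x2(1, 1, 1, 1)
        assert fisher_one_sided(t) == pytest.approx(
            enumerate_fisher_greater(t))


class TestHScore:
    @pytest.mark.parametrize("bins,expected", [
        ({3: 100.0}, 300.0),
        ({}, 0.0),
        ({2: 50.0}, 100.0),
        ({1: 10.0, 2: 20.0, 3: 30.0}, 140.0),
    ])
    def test_formula(self, bins, expected):
        assert h_score(bins) == expected

    def test_over_100_percent_errors(self):
        with pytest.raises(ValueError, match="100"):
            h_score({1: 60.0, 3: 50.0})


class TestCohortIO:
    def test_round_trip(self, tmp_path, rng):
        cohort = _cohort({"A": rng.normal(size=8)},
                         mutation=rng.random(8) < 0.5)
        write_cohort(cohort, tmp_path / "cohort.csv")
        back = read_cohort(tmp_path / "cohort.csv")
        assert np.array_equal(back.altered, cohort.altered)
        assert np.allclose(back.expression("A"), cohort.expression("A"),
                           rtol=1e-5)

    def test_stored_altered_column_rejected(self, rng):
        df = _cohort({"A": rng.normal(size=5)}).data.copy()
        df["altered"] = False
        with pytest.raises(ValueError, match="derived"):
            CohortTable(df)
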