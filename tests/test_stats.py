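"""Exact-test correctness against independent oracles (exact-rational
enumeration and scipy), Monte-Carlo consistency, Welch's t against the
textbook formulas, and ddCt as the inverse of the qPCR generator."""

import math
from fractions import Fraction
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from introscan.stats import (
    ContingencyTable,
    ddct_fold_change,
    fisher_exact,
    monte_carlo_exact,
    welch_t,
)

# ---------------------------------------------------------------------------
# independent oracle: exact-rational enumeration over margin-fixed tables
# ---------------------------------------------------------------------------


def oracle_exact_p(counts) -> float:
    """Two-sided exact p by brute-force enumeration with Fraction arithmetic.

    Enumerates every table with the observed margins, computes each table's
    conditional probability as an exact rational, and sums those <= the
    observed table's probability (exact tie comparison)."""
    counts = np.asarray(counts, dtype=int)
    n_rows, n_cols = counts.shape
    row_m = [int(x) for x in counts.sum(axis=1)]
    col_m = [int(x) for x in counts.sum(axis=0)]
    total = int(counts.sum())

    margin_num = 1
    for m in row_m + col_m:
        margin_num *= factorial(m)

    def prob(cells) -> Fraction:
        den = factorial(total)
        for c in cells:
            den *= factorial(c)
        return Fraction(margin_num, den)

    tables: list[tuple[int, ...]] = []

    def rec(r, cols_left, acc):
        if r == n_rows - 1:
            if all(v >= 0 for v in cols_left):
                tables.append(tuple(acc + cols_left))
            return
        # enumerate row r cell by cell
        def fill(c, left_row, cols_left_now, row_acc):
            if c == n_cols - 1:
                if 0 <= left_row <= cols_left_now[-1]:
                    rec(
                        r + 1,
                        [
                            cl - v
                            for cl, v in zip(cols_left_now, row_acc + [left_row])
                        ],
                        acc + row_acc + [left_row],
                    )
                return
            for v in range(min(left_row, cols_left_now[c]) + 1):
                fill(c + 1, left_row - v, cols_left_now, row_acc + [v])

        fill(0, row_m[r], cols_left, [])

    rec(0, col_m, [])
    p_obs = prob(counts.ravel().tolist())
    return float(sum(p for t in tables if (p := prob(list(t))) <= p_obs))


# ---------------------------------------------------------------------------
# fisher_exact
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_homogeneous_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        """[[10,0],[0,10]]: p = 2 / C(20,10)."""
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert res.point_prob == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [5, 2]],
            [[12, 1], [2, 9]],
            [[1, 0], [0, 1]],
            [[0, 0], [3, 4]],
            [[2, 3, 4], [5, 1, 0]],
            [[1, 2, 3, 4], [4, 3, 2, 1]],
            [[2, 0, 1], [1, 3, 0], [0, 1, 2]],
        ],
    )
    def test_matches_rational_oracle(self, table):
        assert fisher_exact(table).p_value == pytest.approx(
            oracle_exact_p(table), abs=1e-12
        )

    @pytest.mark.parametrize(
        "table",
        [
            [[8, 2], [1, 5]],
            [[20, 10], [5, 30]],
            [[3, 11], [14, 2]],
            [[100, 40], [35, 90]],
        ],
    )
    def test_2x2_matches_scipy(self, table):
        """Independent cross-check against scipy's 2x2 implementation
        (scipy's RxC path is Monte-Carlo, so only 2x2 is deterministic)."""
        assert fisher_exact(table).p_value == pytest.approx(
            sps.fisher_exact(np.asarray(table)).pvalue, rel=1e-6, abs=1e-12
        )

    def test_rxc_matches_r_fisher_test(self):
        """Freeman-Halton enumeration agrees with R's fisher.test."""
        import subprocess

        tables = [
            [[2, 3, 4], [5, 1, 0]],
            [[1, 2, 3, 4], [4, 3, 2, 1]],
            [[6, 1, 0, 2], [2, 5, 4, 1]],
        ]
        for table in tables:
            arr = np.asarray(table)
            flat = ",".join(str(v) for v in arr.T.ravel())  # R fills by column
            script = (
                f"cat(sprintf('%.12g', fisher.test("
                f"matrix(c({flat}), nrow={arr.shape[0]}))$p.value))"
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                check=True,
            )
            r_p = float(out.stdout.strip())
            assert fisher_exact(table).p_value == pytest.approx(r_p, rel=1e-6)

    def test_random_2x4_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            table = rng.integers(0, 8, size=(2, 4))
            if table.sum() == 0:
                continue
            assert fisher_exact(table).p_value == pytest.approx(
                oracle_exact_p(table), abs=1e-12
            )

    def test_invariant_under_row_and_column_permutation(self):
        table = np.array([[4, 1, 3], [0, 5, 2]])
        p0 = fisher_exact(table).p_value
        for rp in permutations(range(2)):
            for cp in permutations(range(3)):
                p = fisher_exact(table[np.ix_(rp, cp)]).p_value
                assert p == pytest.approx(p0, abs=1e-12)

    def test_large_rxc_table_rejected_with_advice(self):
        big = [[60, 70, 80], [50, 40, 30]]
        with pytest.raises(ValueError, match="monte_carlo_exact"):
            fisher_exact(big)

    def test_large_2x2_allowed(self):
        res = fisher_exact([[300, 100], [120, 280]])
        assert 0 < res.p_value < 1e-10

    def test_from_cohort_frame(self):
        cohort = pd.DataFrame(
            {"genotype": ["a"] * 6 + ["b"] * 6,
             "sex": ["f"] * 5 + ["m"] + ["f"] + ["m"] * 5}
        )
        table = ContingencyTable.from_frame(cohort, "genotype", "sex")
        assert table.counts.tolist() == [[5, 1], [1, 5]]
        assert fisher_exact(table).p_value == pytest.approx(
            oracle_exact_p(table.counts), abs=1e-12
        )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2]])  # one row
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])  # empty
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])  # negative


class TestMonteCarloExact:
    def test_homogeneous_table_near_one(self):
        res = monte_carlo_exact([[10, 10], [10, 10]], n_draws=2000, seed=1)
        assert res.p_value > 0.9

    def test_within_three_standard_errors_of_exact(self):
        table = [[3, 8, 2], [7, 1, 6]]
        exact = fisher_exact(table).p_value
        res = monte_carlo_exact(table, n_draws=20_000, seed=2)
        se = math.sqrt(exact * (1 - exact) / res.n_draws)
        assert abs(res.p_value - exact) <= 3 * se + 1 / res.n_draws
        assert res.ci_low <= exact <= res.ci_high

    def test_reproducible_under_seed(self):
        table = [[5, 2, 1], [1, 4, 6]]
        a = monte_carlo_exact(table, n_draws=1500, seed=42)
        b = monte_carlo_exact(table, n_draws=1500, seed=42)
        assert a == b

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            monte_carlo_exact([[1, 2], [3, 4]], n_draws=10)


# ---------------------------------------------------------------------------
# welch_t
# ---------------------------------------------------------------------------


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formulas(self):
        """t, df and p recomputed by hand from the Welch equations."""
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        na, nb = len(a), len(b)
        va = float(np.var(a, ddof=1))
        vb = float(np.var(b, ddof=1))
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(va / na + vb / nb)
        df_hand = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        res = welch_t(a, b)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_antisymmetry(self):
        a = [3.1, 2.7, 5.0, 4.2]
        b = [1.1, 0.9, 2.0]
        fwd, rev = welch_t(a, b), welch_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        assert welch_t([2.0, 2.0], [3.0, 3.0]).p_value == 0.0


# ---------------------------------------------------------------------------
# ddct_fold_change
# ---------------------------------------------------------------------------


def _qpcr_frame(groups_cts: dict[str, list[tuple[float, float]]]) -> pd.DataFrame:
    """Build a long Ct table from {group: [(ct_target, ct_reference), ...]}."""
    rows = []
    i = 0
    for group, pairs in groups_cts.items():
        for ct_t, ct_r in pairs:
            i += 1
            rows.append((f"s{i}", group, "Tgt", ct_t))
            rows.append((f"s{i}", group, "Ref", ct_r))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


class TestDdctFoldChange:
    def test_calibrator_fold_change_is_one(self):
        data = _qpcr_frame(
            {"treated": [(24.0, 20.0)] * 3, "control": [(23.0, 20.0)] * 3}
        )
        res = ddct_fold_change(data, "Tgt", "Ref", "control")
        assert res.fold_change("control") == pytest.approx(1.0)

    def test_ddct_minus_one_doubles_expression(self):
        """Treated dCt one cycle below calibrator -> fold change 2."""
        data = _qpcr_frame(
            {"treated": [(22.0, 20.0)] * 3, "control": [(23.0, 20.0)] * 3}
        )
        res = ddct_fold_change(data, "Tgt", "Ref", "control")
        assert res.per_group.set_index("group").loc["treated", "ddct"] == pytest.approx(-1.0)
        assert res.fold_change("treated") == pytest.approx(2.0)

    def test_sample_missing_gene_excluded(self):
        data = _qpcr_frame({"g1": [(24.0, 20.0)] * 2, "g2": [(24.0, 20.0)] * 2})
        data = data.drop(data[(data["sample_id"] == "s1") & (data["gene"] == "Ref")].index)
        res = ddct_fold_change(data, "Tgt", "Ref", "g2")
        assert res.per_group.set_index("group").loc["g1", "n"] == 1

    def test_missing_calibrator_rejected(self):
        data = _qpcr_frame({"g1": [(24.0, 20.0)] * 2})
        with pytest.raises(ValueError, match="calibrator"):
            ddct_fold_change(data, "Tgt", "Ref", "nope")

    def test_nonfinite_ct_rejected(self):
        data = _qpcr_frame({"g1": [(24.0, float("nan"))] * 2})
        with pytest.raises(ValueError, match="finite"):
            ddct_fold_change(data, "Tgt", "Ref", "g1")

    def test_exact_inverse_of_generator_without_noise(self):
        """Zero-noise generated data returns the planted fold change exactly."""
        from introscan.simulate import QpcrConfig, generate_qpcr

        for planted in (0.5, 1.0, 3.0):
            config = QpcrConfig(
                true_fold_change=planted, ct_noise_sd=0.0, seed=4
            )
            data = generate_qpcr(config)
            res = ddct_fold_change(
                data, config.target_gene, config.reference_gene,
                config.calibrator_group,
            )
            assert res.fold_change("var/+") == pytest.approx(planted, rel=1e-12)

    def test_relative_quantities_feed_welch(self):
        data = _qpcr_frame(
            {"treated": [(22.0, 20.0), (22.2, 20.1), (21.9, 20.0)],
             "control": [(23.0, 20.0), (23.1, 20.0), (22.9, 19.9)]}
        )
        res = ddct_fold_change(data, "Tgt", "Ref", "control")
        wt = welch_t(
            res.relative_quantities("treated"), res.relative_quantities("control")
        )
        assert wt.statistic > 0  # treated expresses higher
        assert 0 < wt.p_value < 1
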