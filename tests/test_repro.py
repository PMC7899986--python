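import itertools
import math

import numpy as np
import pytest

import polmorph as pm
from polmorph.repro import PlantRecord


# ---------------------------------------------------------------- oracles
def chi2_oracle(table):
    """Textbook Pearson chi-square, written independently of the implementation."""
    table = [list(map(float, row)) for row in table]
    n = sum(map(sum, table))
    row_sums = [sum(row) for row in table]
    col_sums = [sum(col) for col in zip(*table)]
    chi2 = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = row_sums[i] * col_sums[j] / n
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def association_oracle(pairs):
    """First-principles association measures from individual (code, outcome)
    pairs: explicit loops, no library shortcuts."""
    n = len(pairs)
    codes = sorted({c for c, _ in pairs})
    outs = sorted({o for _, o in pairs})
    count = {(c, o): 0 for c in codes for o in outs}
    for c, o in pairs:
        count[(c, o)] += 1
    table = [[count[(c, o)] for o in outs] for c in codes]
    # Cramer's V-square
    v2 = chi2_oracle(table) / (n * (min(len(codes), len(outs)) - 1))
    # Pearson on raw values
    xs = [c for c, _ in pairs]
    ys = [o for _, o in pairs]

    def pearson(x, y):
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        return sxy / math.sqrt(sxx * syy)

    # Spearman: Pearson on midranks
    def midranks(values):
        order = sorted(range(n), key=lambda i: values[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rho = pearson(midranks(xs), midranks(ys))
    # Kendall tau-b by O(n^2) pair enumeration
    conc = disc = ties_x = ties_y = 0
    for (xa, ya), (xb, yb) in itertools.combinations(pairs, 2):
        if xa == xb and ya == yb:
            continue
        if xa == xb:
            ties_x += 1
        elif ya == yb:
            ties_y += 1
        elif (xa - xb) * (ya - yb) > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    pairs_tied_both = n0 - conc - disc - ties_x - ties_y
    tau_b = (conc - disc) / math.sqrt(
        (n0 - ties_x - pairs_tied_both) * (n0 - ties_y - pairs_tied_both)
    )
    # Goodman-Kruskal tau: proportional reduction in prediction error
    col_sums = [sum(row[j] for row in table) for j in range(len(outs))]
    row_sums = [sum(row) for row in table]
    e1 = sum(cs * (n - cs) / n for cs in col_sums)
    e2 = sum(
        table[i][j] * (row_sums[i] - table[i][j]) / row_sums[i]
        for i in range(len(codes))
        for j in range(len(outs))
        if row_sums[i] > 0
    )
    gk = (e1 - e2) / e1
    return {
        "cramers_v2": v2,
        "pearson_r": pearson(xs, ys),
        "spearman_rho": rho,
        "kendall_tau_b": tau_b,
        "goodman_kruskal_tau": gk,
    }


# ------------------------------------------------------------- tabulation
class TestTabulate:
    def test_category_by_year_margins(self, records):
        t = pm.tabulate(records, rows="category", cols="year")
        assert list(t.sum(axis=1)) == [45, 56, 64, 31, 16]
        assert list(t.sum(axis=0)) == [78, 70, 64]
        assert int(t.to_numpy().sum()) == 212

    def test_natural_cohort_margins(self, natural_records):
        flowers = pm.tabulate(natural_records, rows="category", cols="year")
        fruits = pm.tabulate(natural_records, rows="category", cols="year", value="fruits")
        assert list(flowers.sum(axis=1)) == [30, 30, 50, 12, 12]
        assert list(fruits.sum(axis=1)) == [4, 6, 9, 1, 1]
        by_patch = pm.tabulate(natural_records, rows="patch", cols="year", value="fruits")
        assert list(by_patch.sum(axis=1)) == [11, 6, 1, 1, 2]

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            pm.tabulate([], rows="category")

    def test_invalid_codes_rejected_at_construction(self):
        with pytest.raises(ValueError, match="category"):
            PlantRecord("p1", 2003, category=6)
        with pytest.raises(ValueError, match="patch"):
            PlantRecord("p1", 2003, category=1, patch=0)
        with pytest.raises(ValueError, match="viability"):
            PlantRecord("p1", 2003, category=1, viability_pct=50.0)


# ------------------------------------------------------------- chi-square
class TestChiSquare:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_flowering_heterogeneity_statistics(self, records):
        """Year-to-year heterogeneity of category counts, overall and per year pair."""
        t = pm.tabulate(records, rows="category", cols="year")
        chi2_all, df_all, _ = pm.chisq_rxc(t)
        assert chi2_all == pytest.approx(22.0, abs=0.05)
        assert df_all == 8
        pairs = {
            (2000, 2003): 7.8,
            (2003, 2004): 4.460,
            (2000, 2004): 19.346,
        }
        for (y1, y2), printed in pairs.items():
            chi2, df, _ = pm.chisq_rxc(t[[y1, y2]])
            assert df == 4
            assert chi2 == pytest.approx(printed, abs=5e-3 if printed != 7.8 else 0.05)

    def test_fruits_per_patch_uniform_gof(self, natural_records):
        fruits = pm.tabulate(natural_records, rows="patch", cols="year", value="fruits")
        chi2, df, p = pm.chisq_gof(fruits.sum(axis=1))
        assert chi2 == pytest.approx(17.8, abs=0.05)
        assert df == 4
        assert p < 0.01

    def test_gof_proportional_expected(self):
        chi2, df, _ = pm.chisq_gof([4, 6, 9], expected=[30, 30, 50])
        assert chi2 == pytest.approx(0.41, abs=5e-3)

    def test_proportional_rows_give_zero(self):
        chi2, _, p = pm.chisq_rxc([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pm.chisq_rxc([[0, 0], [3, 4]])

    def test_matches_textbook_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 11, size=(r, c))
            chi2, df, _ = pm.chisq_rxc(table)
            assert chi2 == pytest.approx(chi2_oracle(table), abs=1e-9)
            assert df == (r - 1) * (c - 1)

    def test_values_statistic(self):
        with pytest.warns(UserWarning, match="non-count"):
            chi2, df, _ = pm.chisq_on_values([13.3, 20.0, 18.0, 8.3, 8.3])
        assert chi2 == pytest.approx(8.6, abs=0.05)
        assert df == 4
        with pytest.warns(UserWarning):
            assert pm.chisq_on_values([5, 5, 5])[0] == 0.0
        with pytest.warns(UserWarning):
            assert pm.chisq_on_values([10, 20])[0] == pytest.approx(3.33, abs=5e-3)


# ------------------------------------------------------------- regression
class TestRegression:
    def test_fruits_on_flowers_by_category(self, natural_records):
        fl = pm.tabulate(natural_records, rows="category", cols="year").sum(axis=1)
        fr = pm.tabulate(
            natural_records, rows="category", cols="year", value="fruits"
        ).sum(axis=1)
        slope, intercept, r2 = pm.linreg(fl, fr)
        assert slope == pytest.approx(0.2119, abs=5e-5)
        assert intercept == pytest.approx(-1.4783, abs=5e-5)
        assert r2 == pytest.approx(0.9562, abs=5e-5)

    def test_fruits_on_flowers_by_patch(self, natural_records):
        fl = pm.tabulate(natural_records, rows="patch", cols="year").sum(axis=1)
        fr = pm.tabulate(natural_records, rows="patch", cols="year", value="fruits").sum(
            axis=1
        )
        slope, intercept, r2 = pm.linreg(fl, fr)
        assert slope == pytest.approx(0.0933, abs=5e-5)
        assert intercept == pytest.approx(1.6996, abs=5e-5)
        assert r2 == pytest.approx(0.1125, abs=5e-5)

    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = pm.linreg(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pm.linreg([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------ association
class TestAssociation:
    def test_perfect_association(self):
        pairs = [(1, 0)] * 5 + [(2, 1)] * 5
        m = pm.association_measures(pairs)
        assert m["cramers_v2"] == pytest.approx(1.0)
        assert abs(m["kendall_tau_b"]) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        pairs = [(1, 0)] * 2 + [(1, 1)] * 2 + [(2, 0)] * 3 + [(2, 1)] * 3
        m = pm.association_measures(pairs)
        for v in m.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_input_reported_undefined(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = pm.association_measures([(1, 0), (1, 1)])
        assert all(np.isnan(v) for v in m.values())

    def test_matches_brute_force_oracle_exhaustively(self):
        """All 2x2 tables with cell counts <= 4 (skipping degenerate margins),
        plus seeded 2x3 tables, agree with the first-principles oracle."""
        tables = [
            (a, b, c, d)
            for a in range(5)
            for b in range(5)
            for c in range(5)
            for d in range(5)
            if (a + b) and (c + d) and (a + c) and (b + d) and min(a + b + c + d, 4) >= 2
            and not (a + b == 0 or c + d == 0)
        ]
        for a, b, c, d in tables:
            if (a + c == 0) or (b + d == 0):
                continue
            pairs = [(1, 0)] * a + [(1, 1)] * b + [(2, 0)] * c + [(2, 1)] * d
            if len({p for p, _ in pairs}) < 2 or len({o for _, o in pairs}) < 2:
                continue
            got = pm.association_measures(pairs)
            want = association_oracle(pairs)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), (key, (a, b, c, d))

    def test_matches_oracle_on_wider_tables(self, natural_records):
        pairs = [(r.category, int(r.fruited)) for r in natural_records]
        got = pm.association_measures(pairs)
        want = association_oracle(pairs)
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-9)


# ----------------------------------------------------------- success rates
class TestSuccessRates:
    def test_overall_pooled_rate(self, natural_records):
        rates = pm.success_rates(natural_records, by="overall")
        assert rates["pooled_pct"].iloc[0] == pytest.approx(15.7, abs=0.05)
        assert rates["n_fruits"].iloc[0] == 21
        assert rates["n_flowers"].iloc[0] == 134

    def test_patch_one_yearly_and_mean(self, natural_records):
        rates = pm.success_rates(natural_records, by="patch")
        row = rates.loc[1]
        assert row["pct_2003"] == pytest.approx(33.3, abs=0.05)
        assert row["pct_2004"] == pytest.approx(30.0, abs=0.05)
        assert row["mean_pct"] == pytest.approx(31.7, abs=0.05)
        assert row["se_pct"] == pytest.approx(5 / 3, abs=0.05)  # half-range

    def test_pooled_equals_tabulation_ratio_everywhere(self, natural_records):
        for axis in ("category", "patch"):
            fl = pm.tabulate(natural_records, rows=axis, cols="year").sum(axis=1)
            fr = pm.tabulate(natural_records, rows=axis, cols="year", value="fruits").sum(
                axis=1
            )
            rates = pm.success_rates(natural_records, by=axis)
            for level in fl.index:
                assert rates.loc[level, "pooled_pct"] == pytest.approx(
                    100.0 * fr[level] / fl[level]
                )

    def test_single_year_has_no_se(self, natural_records):
        one_year = [r for r in natural_records if r.year == 2003]
        rates = pm.success_rates(one_year, by="overall")
        assert rates["mean_pct"].iloc[0] == pytest.approx(rates["pooled_pct"].iloc[0])
        assert np.isnan(rates["se_pct"].iloc[0])


# -------------------------------------------------------- KW and capsules
class TestKruskalWallis:
    def test_no_tie_hand_value(self):
        h, _ = pm.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups_give_zero(self):
        assert pm.kruskal_wallis([[5, 5], [5, 5]])[0] == 0.0

    def test_detects_large_viability_shift(self):
        rng = np.random.default_rng(11)
        low = np.clip(rng.normal(40, 10, 20), 0, 100)
        high = np.clip(rng.normal(70, 10, 20), 0, 100)
        _, p = pm.kruskal_wallis([low, high])
        assert p < 0.05


class TestCapsuleSummary:
    @staticmethod
    def _make_crosses(n_caps, n_none, n_grazed, n_moldy, n_lost):
        recs = []
        fates = (
            ["capsule"] * n_caps + ["none"] * n_none + ["grazed"] * n_grazed
            + ["moldy"] * n_moldy + ["lost"] * n_lost
        )
        for i, fate in enumerate(fates):
            recs.append(
                PlantRecord(
                    f"x{i}", 2000, category=1, treatment="artificial",
                    pollen_category=1, ovule_category=2, capsule_fate=fate,
                )
            )
        return recs

    def test_overall_rate_counts_all_crosses(self):
        # 70 capsules from 91 crosses (7 no-capsule, 8 grazed, 5 moldy, 1 lost)
        recs = self._make_crosses(70, 7, 8, 5, 1)
        _, overall = pm.capsule_summary(recs)
        assert overall == {"n_crosses": 91, "n_capsules": 70, "overall_pct": 77}

    def test_per_cell_percent_excludes_grazed_moldy_lost(self):
        recs = self._make_crosses(1, 2, 1, 1, 0)
        table, _ = pm.capsule_summary(recs)
        row = table.iloc[0]
        assert row["n_evaluable"] == 3
        assert row["pct_capsules"] == 33

    def test_all_grazed_cell_reported_no_data(self):
        recs = self._make_crosses(0, 0, 3, 0, 0)
        table, _ = pm.capsule_summary(recs)
        assert np.isnan(table.iloc[0]["pct_capsules"])

    def test_packaged_cross_fixture_margins(self):
        recs = pm.datasets.cross_records()
        table, overall = pm.capsule_summary(recs)
        assert overall["n_crosses"] == 91
        assert int(table["n_evaluable"].sum()) == 77
        cell = table.set_index(["category_a", "category_b"]).loc[(3, 5)]
        assert cell["pct_capsules"] == 33
        assert cell["n_evaluable"] == 3
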