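"""Rhythm statistics against closed forms and exhaustive-enumeration oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chronotarget import rhythm, synthdata
from chronotarget.rhythm import RhythmConfig

from conftest import bh_oracle


def jtk_oracle(y, t, min_period=20.0, max_period=28.0):
    """Independent JTK p by direct enumeration: for every (period, lag)
    reference cosine, p = fraction of all orderings of y with Kendall S at
    least the observed; Bonferroni over combinations."""
    y = np.round(np.asarray(y, float), 12)  # tie convention: equal within 1e-12
    t = np.asarray(t, float)
    n = len(y)
    dt = np.min(np.diff(np.unique(t)))
    combos = []
    period = dt * int(np.ceil(min_period / dt))
    while period <= max_period + 1e-9:
        if period >= min_period - 1e-9:
            for lag in np.arange(0.0, period - 1e-9, dt):
                combos.append((period, lag))
        period += dt

    def kendall_s(a, ref):
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                s += np.sign(a[j] - a[i]) * np.sign(ref[j] - ref[i])
        return s

    best_p = np.inf
    for period, lag in combos:
        ref = np.round(np.cos(2 * np.pi * (t - lag) / period), 12)
        s_obs = kendall_s(y, ref)
        count = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if kendall_s(np.asarray(perm), ref) >= s_obs - 1e-9:
                count += 1
        best_p = min(best_p, count / total)
    return min(1.0, best_p * len(combos))


class TestFilter:
    def test_mean_count_boundary(self):
        m = pd.DataFrame(
            {f"CT{t}": [5.0, 6.0] for t in range(0, 25, 4)}, index=["low", "ok"]
        )
        out = rhythm.filter_expression(m, min_mean_count=6)
        assert list(out.matrix.index) == ["ok"]
        assert out.removed == ["low"]

    def test_all_zero_matrix_removes_everything_with_report(self):
        m = pd.DataFrame(np.zeros((3, 7)), index=list("abc"),
                         columns=[f"CT{t}" for t in range(0, 25, 4)])
        with pytest.warns(UserWarning, match="removed every gene"):
            out = rhythm.filter_expression(m, min_mean_count=6)
        assert len(out.matrix) == 0
        assert sorted(out.removed) == ["a", "b", "c"]


class TestCosinor:
    def test_pure_cosine_closed_form(self, time_grid):
        fit = rhythm.cosinor_fit(2 + np.cos(2 * np.pi * time_grid / 24), time_grid, 24)
        assert fit["mesor"] == pytest.approx(2.0)
        assert fit["amplitude"] == pytest.approx(1.0)
        assert fit["phase"] == pytest.approx(0.0, abs=1e-9)

    def test_sine_identity_gives_six_hour_phase(self, time_grid):
        fit = rhythm.cosinor_fit(3 + 0.5 * np.sin(2 * np.pi * time_grid / 24), time_grid, 24)
        assert fit["phase"] == pytest.approx(6.0)
        assert fit["amplitude"] == pytest.approx(0.5)

    def test_constant_series(self, time_grid):
        fit = rhythm.cosinor_fit(np.full(7, 3.0), time_grid, 24)
        assert fit["amplitude"] == 0.0
        assert fit["p"] == 1.0


class TestJTK:
    def test_pure_cosine_matches_enumeration_oracle(self, time_grid):
        y = np.cos(2 * np.pi * time_grid / 24)
        res = rhythm.jtk_cycle(y, time_grid)
        assert res["tau"] == pytest.approx(1.0)
        assert res["best_period"] == 24.0
        assert res["p"] == pytest.approx(jtk_oracle(y, time_grid))

    def test_noisy_series_match_enumeration_oracle(self, time_grid):
        rng = np.random.default_rng(17)
        for _ in range(3):
            y = rng.normal(size=7)
            assert rhythm.jtk_cycle(y, time_grid)["p"] == pytest.approx(
                jtk_oracle(y, time_grid)
            )

    def test_constant_series_p_one(self, time_grid):
        assert rhythm.jtk_cycle(np.full(7, 2.0), time_grid)["p"] == 1.0

    def test_reversed_cosine_shifts_best_lag_by_half_period(self, time_grid):
        # fixed 24 h grid so the check isolates the lag symmetry
        fwd = rhythm.jtk_cycle(np.cos(2 * np.pi * time_grid / 24), time_grid, 24, 24)
        rev = rhythm.jtk_cycle(-np.cos(2 * np.pi * time_grid / 24), time_grid, 24, 24)
        assert rev["best_period"] == fwd["best_period"] == 24.0
        assert abs(rev["best_lag"] - fwd["best_lag"]) == pytest.approx(12.0)
        assert rev["p"] == pytest.approx(fwd["p"])


class TestLombScargle:
    def test_noiseless_cosine_peaks_at_its_period(self, time_grid):
        res = rhythm.lomb_scargle(5 + np.cos(2 * np.pi * time_grid / 24), time_grid)
        assert res["peak_period"] == pytest.approx(24.0, abs=0.3)

    def test_constant_series(self, time_grid):
        res = rhythm.lomb_scargle(np.full(7, 1.0), time_grid)
        assert res["power"] == 0.0 and res["p"] == 1.0

    def test_null_type_one_error_within_binomial_margin(self, time_grid):
        """White noise: the rejection fraction at alpha=0.05 stays below the
        nominal level plus a 99% binomial margin (the p-value is allowed to
        be conservative, never anti-conservative)."""
        rng = np.random.default_rng(123)
        n = 1000
        ps = np.array([
            rhythm.lomb_scargle(rng.normal(size=7), time_grid)["p"] for _ in range(n)
        ])
        margin = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert (ps <= 0.05).mean() <= 0.05 + margin


class TestFisher:
    def test_all_ones(self):
        assert rhythm.integrate_pvalues([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_three_equal_pvalues_match_chi_square_oracle(self):
        x2 = -2 * 3 * np.log(0.05)
        assert x2 == pytest.approx(17.9744, abs=1e-4)
        expected = stats.chi2.sf(x2, 6)
        assert rhythm.integrate_pvalues([0.05] * 3) == pytest.approx(expected)

    def test_single_p_identity(self):
        assert rhythm.integrate_pvalues([0.2]) == pytest.approx(0.2)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = rhythm.integrate_pvalues([0.0, 0.5])
        assert 0 < p < 1e-100


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
def test_bh_adjustment_matches_brute_force(pvals):
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(pvals, method="fdr_bh")[1]
    np.testing.assert_allclose(adj, bh_oracle(pvals), rtol=1e-12)
    # monotone non-decreasing in p-rank
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDetect:
    def test_all_constant_matrix_has_no_rhythmic_genes(self):
        m = pd.DataFrame(np.ones((10, 7)) * 5, index=[f"g{i}" for i in range(10)],
                         columns=[f"CT{t}" for t in range(0, 25, 4)])
        table = rhythm.detect_rhythmic(m)
        assert table["rhythmic"].sum() == 0

    def test_recovers_planted_rhythms_on_small_study(self, small_study):
        matrix, truth = small_study
        table = rhythm.detect_rhythmic(matrix)
        detected = table.index[table["rhythmic"]]
        true_rhythmic = truth.index[truth["is_rhythmic"]]
        sens = len(set(detected) & set(true_rhythmic)) / len(true_rhythmic)
        assert sens >= 0.8
        assert (table["fdr"] >= table["p_integrated"] - 1e-12).all()

    def test_phase_recovery_noiseless(self):
        cfg = synthdata.SynthConfig(n_genes=40, frac_rhythmic=1.0, noise_cv=0.0,
                                    n_clock_genes=0, seed=21)
        matrix, truth = synthdata.generate_temporal_matrix(cfg)
        table = rhythm.detect_rhythmic(matrix)
        for g in table.index[table["rhythmic"]]:
            period = table.loc[g, "period_est"]
            d = abs(table.loc[g, "phase_est"] - truth.loc[g, "true_phase"]) % period
            assert min(d, period - d) <= 2.0

    def test_power_monotone_in_amplitude(self):
        """Detection count never decreases along an amplitude ladder."""
        detected = []
        for amp in (0.1, 0.4, 0.8):
            cfg = synthdata.SynthConfig(n_genes=80, frac_rhythmic=1.0, noise_cv=0.2,
                                        amplitude_range=(amp, amp), n_clock_genes=0,
                                        seed=33)
            matrix, _ = synthdata.generate_temporal_matrix(cfg)
            detected.append(int(rhythm.detect_rhythmic(matrix)["rhythmic"].sum()))
        assert detected == sorted(detected)


class TestDifferentialRhythmicity:
    @staticmethod
    def _table(genes, rhythmic):
        return pd.DataFrame(
            dict(p_integrated=0.5, fdr=0.5, rhythmic=[g in rhythmic for g in genes]),
            index=pd.Index(genes, name="gene"),
        )

    def test_identical_tables_have_empty_exclusive_sets(self):
        t = self._table(list("abcd"), {"a", "b"})
        out = rhythm.differential_rhythmicity({"A": t, "B": t.copy()})
        assert out.exclusive == {"A": set(), "B": set()}

    def test_gene_rhythmic_in_one_condition_only(self):
        ta = self._table(list("abc"), {"a"})
        tb = self._table(list("abc"), set())
        out = rhythm.differential_rhythmicity({"A": ta, "B": tb})
        assert out.exclusive["A"] == {"a"}

    def test_three_table_regions_match_brute_force(self):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(5)
        sets = {name: set(rng.choice(genes, size=12, replace=False))
                for name in ("A", "B", "C")}
        tables = {name: self._table(genes, s) for name, s in sets.items()}
        out = rhythm.differential_rhythmicity(tables)
        for combo in itertools.chain.from_iterable(
            itertools.combinations("ABC", r) for r in (1, 2, 3)
        ):
            inside = set.intersection(*(sets[c] for c in combo))
            rest = [sets[o] for o in "ABC" if o not in combo]
            expected = inside - set.union(*rest) if rest else inside
            assert out.regions["&".join(combo)] == len(expected)

    def test_disjoint_universes_rejected(self):
        ta = self._table(["a"], set())
        tb = self._table(["b"], set())
        with pytest.raises(ValueError, match="disjoint"):
            rhythm.differential_rhythmicity({"A": ta, "B": tb})
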