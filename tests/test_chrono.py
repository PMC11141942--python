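"""Dose-response fits, temporal efficacy statistics and target ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronotarget import chrono, synthdata
from chronotarget.synthdata import four_pl

DOSES = 10e-6 / 5.0 ** np.arange(7)[::-1]  # 16 nM .. 10 uM


class TestFourPL:
    def test_noiseless_parameters_recovered(self):
        v = four_pl(DOSES, 1.0, 0.0, 1e-6, 1.0)
        fit = chrono.fit_dose_response(DOSES, v)
        assert fit.converged
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50 == pytest.approx(1e-6, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)

    def test_constant_viability_gives_unit_auc(self):
        fit = chrono.fit_dose_response(DOSES, np.ones(7))
        assert fit.auc == pytest.approx(1.0, abs=1e-6)

    def test_ic50_is_half_viability_dose_by_bisection(self):
        v = four_pl(DOSES, 1.0, 0.2, 3e-7, 1.3)
        fit = chrono.fit_dose_response(DOSES, v)
        lo, hi = DOSES.min(), DOSES.max()
        half = (fit.top + fit.bottom) / 2
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if four_pl(np.array([mid]), fit.top, fit.bottom, fit.ic50, fit.hill)[0] > half:
                lo = mid
            else:
                hi = mid
        assert fit.ic50 == pytest.approx(np.sqrt(lo * hi), rel=1e-6)

    def test_auc_invariant_to_dose_unit_rescaling(self):
        v = four_pl(DOSES, 1.0, 0.1, 1e-6, 1.0)
        fit_molar = chrono.fit_dose_response(DOSES, v)
        fit_micromolar = chrono.fit_dose_response(DOSES * 1e6, v)
        assert fit_molar.auc == pytest.approx(fit_micromolar.auc, abs=1e-6)


class TestTemporalEfficacy:
    def test_identical_replicates_everywhere_give_f_zero(self):
        panel = synthdata.generate_dose_response_panel(
            ic50_rel_amp=0.0, noise_sd=0.0, n_replicates=3, seed=0)
        out = chrono.temporal_efficacy(panel)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_anova_matches_textbook_formula(self):
        """Constant-viability panels make AUC equal viability, so group AUCs
        are set directly; F compared with the hand-computed one-way ANOVA."""
        groups = {0.0: [0.1, 0.2, 0.3], 4.0: [0.4, 0.5, 0.6], 8.0: [0.1, 0.3, 0.5]}
        rows = []
        for t, vs in groups.items():
            for rep, v in enumerate(vs, 1):
                for d in DOSES:
                    rows.append(dict(time_h=t, dose=d, replicate=rep, viability=v))
        out = chrono.temporal_efficacy(pd.DataFrame(rows))
        data = list(groups.values())
        grand = np.mean([v for vs in data for v in vs])
        ssb = sum(len(vs) * (np.mean(vs) - grand) ** 2 for vs in data)
        ssw = sum((v - np.mean(vs)) ** 2 for vs in data for v in vs)
        f_expected = (ssb / 2) / (ssw / 6)
        assert out["F"] == pytest.approx(f_expected, rel=1e-6)
        assert out["p"] == pytest.approx(stats.f.sf(f_expected, 2, 6), rel=1e-6)
        assert out["tukey"] is not None

    def test_flat_panel_with_noise_is_not_significant(self):
        panel = synthdata.generate_dose_response_panel(
            ic50_rel_amp=0.0, noise_sd=0.02, n_replicates=3, seed=42)
        out = chrono.temporal_efficacy(panel)
        assert out["p"] > 0.05

    def test_single_replicate_skips_anova(self):
        panel = synthdata.generate_dose_response_panel(
            noise_sd=0.0, n_replicates=1, seed=0)
        with pytest.warns(UserWarning, match="ANOVA skipped"):
            out = chrono.temporal_efficacy(panel)
        assert np.isnan(out["F"]) and len(out["auc_series"]) == 7


class TestRhythmicityScore:
    @staticmethod
    def _matrix(rows):
        cols = [f"CT{t}" for t in range(0, 25, 4)]
        return pd.DataFrame(rows, index=cols).T

    def test_single_gene_score_is_its_normalized_series(self):
        t = np.arange(0, 25, 4)
        y = 2 + np.cos(2 * np.pi * t / 24)
        m = self._matrix({"g": y})
        score = chrono.rhythmicity_score(m, ["g"])
        np.testing.assert_allclose(score.to_numpy(), y / y.max())

    def test_antiphase_pair_gives_constant_half(self):
        t = np.arange(0, 25, 4)
        m = self._matrix({"a": 1 + np.cos(2 * np.pi * t / 24),
                          "b": 1 - np.cos(2 * np.pi * t / 24)})
        score = chrono.rhythmicity_score(m, ["a", "b"])
        np.testing.assert_allclose(score.to_numpy(), 0.5, atol=1e-12)

    def test_matches_two_line_oracle_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(2)
        rows = {f"g{i}": rng.random(7) + 0.1 for i in range(8)}
        m = self._matrix(rows)
        score = chrono.rhythmicity_score(m, list(rows))
        arr = m.to_numpy()
        expected = (arr / arr.max(axis=1, keepdims=True)).mean(axis=0)
        np.testing.assert_allclose(score.to_numpy(), expected)
        assert ((score > 0) & (score <= 1)).all()


class TestEfficacyCorrelation:
    def test_proportional_series_give_unit_r2(self):
        t = np.arange(0, 25, 4.0)
        score = pd.Series(1 + 0.3 * np.cos(2 * np.pi * t / 24), index=t)
        out = chrono.efficacy_expression_correlation(score, 2.0 * score)
        assert out["r2"] == pytest.approx(1.0)

    def test_independent_noise_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 25, 4.0)
        x = pd.Series(rng.random(7), index=t)
        y = pd.Series(rng.random(7), index=t)
        out = chrono.efficacy_expression_correlation(x, y)
        assert out["r"] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_phase_locked_panel_tracks_target_expression(self):
        """Noiseless end-to-end construction: viability AUC is maximal when
        the target gene peaks, so the two series correlate strongly."""
        t = np.arange(0, 25, 4.0)
        phase = 8.0
        target = pd.Series(10 * (1 + 0.5 * np.cos(2 * np.pi * (t - phase) / 24)), index=t)
        panel = synthdata.generate_dose_response_panel(
            ic50_phase=phase, ic50_rel_amp=0.4, noise_sd=0.0, n_replicates=1, seed=0)
        out_eff = chrono.temporal_efficacy(panel, anova=False)
        res = chrono.efficacy_expression_correlation(target, out_eff["auc_series"])
        assert res["r"] > 0 and res["r2"] >= 0.9


class TestTemporalAmplitude:
    def test_pure_cosine_both_estimators_equal_amplitude(self):
        t = np.arange(0, 24, 4.0)  # one full cycle without the repeated phase
        y = 3 + 0.7 * np.cos(2 * np.pi * t / 24)
        out = chrono.temporal_amplitude(y, t)
        assert out["amp_cosinor"] == pytest.approx(0.7)
        assert out["amp_peak_trough"] == pytest.approx(0.7, rel=0.1)

    def test_constant_series_has_zero_amplitude(self):
        t = np.arange(0, 25, 4.0)
        out = chrono.temporal_amplitude(np.full(7, 2.0), t)
        assert out["amp_cosinor"] == 0.0 and out["amp_peak_trough"] == 0.0

    def test_noisy_cosine_recovered_within_simulation_band(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 25, 4.0)
        amps = [chrono.temporal_amplitude(
            2 + 0.6 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.05, 7), t
        )["amp_cosinor"] for _ in range(200)]
        assert np.mean(amps) == pytest.approx(0.6, abs=3 * np.std(amps) / np.sqrt(200))


class TestPrioritizeTargets:
    @staticmethod
    def _rhythm(genes, rhythmic):
        return pd.DataFrame(dict(rhythmic=[g in rhythmic for g in genes]),
                            index=pd.Index(genes, name="gene"))

    @staticmethod
    def _cent(scores):
        return pd.DataFrame(dict(mcc=list(scores.values()),
                                 degree=[2.0] * len(scores)),
                            index=pd.Index(scores, name="node"))

    def test_single_druggable_candidate_ranks_first(self):
        rt = self._rhythm(["a", "b"], {"a"})
        cent = self._cent({"a": 10.0, "b": 5.0})
        coup = pd.DataFrame(dict(max_abs_r=[0.9]), index=["a"])
        drugs = pd.DataFrame(dict(gene=["a"], drug=["drugX"]))
        out = chrono.prioritize_targets(rt, ["a", "b"], cent, coup, drugs)
        assert list(out.index) == ["a"]
        assert out.loc["a", "rank"] == 1 and out.loc["a", "drugs"] == "drugX"

    def test_coupling_breaks_hub_ties(self):
        rt = self._rhythm(["a", "b"], {"a", "b"})
        cent = self._cent({"a": 10.0, "b": 10.0})
        coup = pd.DataFrame(dict(max_abs_r=[0.5, 0.9]), index=["a", "b"])
        out = chrono.prioritize_targets(rt, ["a", "b"], cent, coup, None)
        assert list(out.index) == ["b", "a"]

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        rt = self._rhythm(genes, set(genes[:6]))
        cent = self._cent({g: float(rng.integers(1, 50)) for g in genes})
        coup = pd.DataFrame(dict(max_abs_r=rng.random(10)), index=genes)
        out1 = chrono.prioritize_targets(rt, genes, cent, coup, None, shortlist_k=4)
        out2 = chrono.prioritize_targets(rt, genes[::-1], cent, coup, None, shortlist_k=4)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_rcdg_set_warns(self):
        rt = self._rhythm(["a"], set())
        with pytest.warns(UserWarning, match="no rhythmic"):
            out = chrono.prioritize_targets(rt, ["a"], self._cent({"a": 1.0}),
                                            pd.DataFrame(), None)
        assert out.empty
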