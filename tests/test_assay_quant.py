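import numpy as np
import pandas as pd
import pytest

from polyescan import (
    TitrationSpec,
    array_scores,
    fit_kd,
    fold_enrichment,
    gen_array_table,
    gen_titration,
    isotherm,
    percent_of_input,
)


class TestFoldEnrichment:
    def test_equal_cts_give_fold_one(self):
        assert fold_enrichment(21.3, 21.3).fold == 1.0

    def test_negative_delta_ct_doubles_per_cycle(self):
        fe = fold_enrichment(20.0, 23.0)
        assert fe.delta_ct == -3.0
        assert fe.fold == 8.0

    def test_antisymmetry(self):
        assert fold_enrichment(19.0, 24.0).fold * fold_enrichment(24.0, 19.0).fold == 1.0
        assert fold_enrichment(19.7, 24.2).fold * fold_enrichment(
            24.2, 19.7
        ).fold == pytest.approx(1.0, rel=1e-12)

    def test_fold_halves_per_added_cycle_exactly(self):
        for ct in (18.0, 22.5, 30.0):
            assert fold_enrichment(ct + 1.0, 20.0).fold == fold_enrichment(ct, 20.0).fold / 2.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(float("nan"), 20.0)
        with pytest.raises(ValueError):
            percent_of_input(float("inf"), 20.0)


class TestArrayScores:
    def _table(self):
        return pd.DataFrame(
            {
                "spot_id": ["s1", "s2", "s3"],
                "modification": ["m1", "m2", "neg"],
                "left_intensity": [4.0, 1.0, 2.0],
                "right_intensity": [6.0, 3.0, 2.0],
                "is_negative_control": [False, False, True],
            }
        )

    def test_hand_computed_ratios(self):
        scores = array_scores(self._table())
        assert scores.binding_score["m1"] == pytest.approx(5.0 / 2.0, abs=1e-12)
        assert scores.binding_score["m2"] == pytest.approx(2.0 / 2.0, abs=1e-12)

    def test_identical_duplicates_give_r2_one(self):
        df = self._table()
        df["right_intensity"] = df["left_intensity"]
        assert array_scores(df).duplicate_r2 == 1.0

    def test_r2_affine_invariant(self):
        table, _ = gen_array_table(60, binder_set=["mod001"], seed=3)
        base = array_scores(table).duplicate_r2
        scaled = table.copy()
        scaled["left_intensity"] = 3.5 * scaled["left_intensity"] + 100.0
        scaled["right_intensity"] = 3.5 * scaled["right_intensity"] + 100.0
        assert array_scores(scaled).duplicate_r2 == pytest.approx(base, abs=1e-12)

    def test_spots_equal_to_negatives_score_one(self):
        df = self._table()
        df["left_intensity"] = 2.0
        df["right_intensity"] = 2.0
        scores = array_scores(df)
        assert all(v == 1.0 for v in scores.binding_score.values())

    def test_unpaired_duplicate_names_spot(self):
        df = self._table()
        df.loc[1, "right_intensity"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            array_scores(df)

    def test_nonpositive_negative_mean_rejected(self):
        df = self._table()
        df.loc[2, ["left_intensity", "right_intensity"]] = 0.0
        with pytest.raises(ValueError, match="negative-control"):
            array_scores(df)


class TestFitKd:
    def test_noiseless_recovery_positive_and_negative_amplitude(self):
        for amp in (1.0, -0.75):
            table, _ = gen_titration(
                TitrationSpec(kd=2.4, amplitude=amp, baseline=0.3, noise_sd=0.0)
            )
            fit = fit_kd(table)
            assert fit.converged
            assert fit.kd == pytest.approx(2.4, rel=1e-6)
            assert fit.amplitude == pytest.approx(amp, rel=1e-6)
            assert fit.baseline == pytest.approx(0.3, abs=1e-8)

    def test_zero_amplitude_is_nd(self):
        table, _ = gen_titration(TitrationSpec(kd=5.0, amplitude=0.0, noise_sd=0.0))
        fit = fit_kd(table)
        assert not fit.converged
        assert np.isnan(fit.kd_ci[0])

    def test_pure_noise_is_usually_nd(self):
        nd = 0
        for seed in range(20):
            table, _ = gen_titration(
                TitrationSpec(kd=5.0, amplitude=0.0, noise_sd=0.05, seed=seed)
            )
            nd += not fit_kd(table).converged
        assert nd >= 16  # F-test at alpha=0.05

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"concentration": [1.0, 2.0, 4.0], "response": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="at least 4"):
            fit_kd(df)

    def test_first_order_optimality(self):
        table, _ = gen_titration(TitrationSpec(kd=10.0, noise_sd=0.05, seed=4))
        fit = fit_kd(table)
        c = table["concentration"].to_numpy()
        y = table["response"].to_numpy()
        resid = y - isotherm(c, fit.kd, fit.amplitude, fit.baseline)
        grad = np.column_stack([
            np.ones_like(c),
            c / (fit.kd + c),
            -fit.amplitude * c / (fit.kd + c) ** 2,
        ])
        assert np.all(np.abs(resid @ grad) < 1e-6 * max(1.0, float(np.abs(y).max())))

    def test_ci_brackets_truth_most_of_the_time(self):
        inside = 0
        for seed in range(20):
            table, _ = gen_titration(TitrationSpec(kd=2.4, noise_sd=0.03, seed=seed))
            fit = fit_kd(table)
            if fit.converged and fit.kd_ci[0] <= 2.4 <= fit.kd_ci[1]:
                inside += 1
        assert inside >= 14
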