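import numpy as np
import pytest

from polyescan import (
    ProteomeSpec,
    TitrationSpec,
    composition,
    fit_kd,
    fixed_sampler,
    gen_annotations,
    gen_array_table,
    gen_proteome,
    gen_titration,
    isotherm,
    max_run_length,
    uniform_int_sampler,
    write_fasta,
)
from polyescan.assay_quant import array_scores
from polyescan.synthetic import ALPHABET_ORDER, noise_sd_for_duplicate_r2


class TestComposition:
    def test_sums_to_one_and_respects_overrides(self):
        p = composition({"E": 0.07, "K": 0.1})
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[ALPHABET_ORDER.index("E")] == 0.07
        assert p[ALPHABET_ORDER.index("K")] == 0.1
        assert p[ALPHABET_ORDER.index("X")] == 0.0

    def test_overrides_above_one_rejected(self):
        with pytest.raises(ValueError):
            composition({"E": 0.9, "K": 0.2})


class TestGenProteome:
    def test_planted_carriers_and_only_them(self, planted_proteome):
        records, truth = planted_proteome
        carriers = set(truth["planted_runs"][0]["carrier_ids"])
        for rec in records:
            if rec.id in carriers:
                assert max_run_length(rec.sequence, "E") >= 9
            else:
                assert max_run_length(rec.sequence, "E") == 0

    def test_byte_identical_fasta_for_same_seed(self, tmp_path):
        spec = dict(
            n_sequences=20,
            length_sampler=fixed_sampler(60),
            composition=composition({"E": 0.07}),
            planted_runs=[("E", 9, 3)],
            seed=5,
        )
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(gen_proteome(ProteomeSpec(**spec))[0], a)
        write_fasta(gen_proteome(ProteomeSpec(**spec))[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_planted_run_longer_than_sequence_rejected(self):
        spec = ProteomeSpec(
            n_sequences=5,
            length_sampler=fixed_sampler(30),
            planted_runs=[("E", 31, 1)],
            seed=0,
        )
        with pytest.raises(ValueError, match="longer than sequence"):
            gen_proteome(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ProteomeSpec(n_sequences=5, planted_runs=[("E", 9, 6)])
        with pytest.raises(ValueError):
            ProteomeSpec(n_sequences=5, composition=np.ones(21))

    def test_background_max_run_distribution_matches_independent_sampler(self):
        """Max-run-length distribution of the generator equals that of an
        independent i.i.d. sampler (chi-squared on pooled categories)."""
        import random as pyrandom

        n, length, e_freq = 2000, 500, 0.07
        spec = ProteomeSpec(
            n_sequences=n,
            length_sampler=fixed_sampler(length),
            composition=composition({"E": e_freq}),
            seed=101,
        )
        records, _ = gen_proteome(spec)
        ours = np.array([max_run_length(r.sequence, "E") for r in records])

        pyrandom.seed(202)
        theirs = []
        for _ in range(n):
            seq = "".join(
                "E" if pyrandom.random() < e_freq else "A" for _ in range(length)
            )
            theirs.append(max_run_length(seq, "E"))
        theirs = np.array(theirs)

        from scipy.stats import chi2_contingency

        cats = np.arange(1, 8)
        table = np.array([
            [np.sum(ours == c) for c in cats] + [np.sum(ours >= 8)],
            [np.sum(theirs == c) for c in cats] + [np.sum(theirs >= 8)],
        ])
        keep = table.sum(axis=0) > 0
        _, p, _, _ = chi2_contingency(table[:, keep])
        assert p > 1e-3


class TestGenTitration:
    def test_half_saturation_identity(self):
        assert isotherm(2.4, kd=2.4, amplitude=0.8, baseline=0.1) == pytest.approx(0.5)

    def test_zero_amplitude_is_flat(self):
        table, _ = gen_titration(TitrationSpec(kd=5.0, amplitude=0.0, noise_sd=0.0))
        assert np.allclose(table["response"], 0.0)

    def test_noiseless_refit_recovers_kd(self):
        table, _ = gen_titration(TitrationSpec(kd=7.5, amplitude=-0.6,
                                               baseline=0.2, noise_sd=0.0))
        fit = fit_kd(table)
        assert fit.kd == pytest.approx(7.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(-0.6, rel=1e-6)

    def test_identifiability_guards(self):
        with pytest.raises(ValueError):
            TitrationSpec(kd=1.0, concentrations=np.geomspace(1, 10, 12))
        with pytest.raises(ValueError):
            TitrationSpec(kd=1.0, concentrations=np.geomspace(0.1, 100, 4))
        with pytest.raises(ValueError):
            TitrationSpec(kd=-1.0)

    def test_deterministic_given_seed(self):
        a, _ = gen_titration(TitrationSpec(kd=3.0, seed=8))
        b, _ = gen_titration(TitrationSpec(kd=3.0, seed=8))
        assert a.equals(b)


class TestGenAnnotations:
    def test_same_seed_reproducible(self):
        a, _ = gen_annotations(100, 10, uniform_int_sampler(5, 20), seed=3)
        b, _ = gen_annotations(100, 10, uniform_int_sampler(5, 20), seed=3)
        assert a == b

    def test_full_cover_planting_is_top_hit(self):
        from polyescan import enrich

        genes = [f"g{i:05d}" for i in range(30)]
        table, _ = gen_annotations(
            300, 10, uniform_int_sampler(30, 30), planted=("T_p", genes, 30), seed=2
        )
        rows = enrich(genes, table)
        assert rows[0].term == "T_p"
        assert rows[0].k == 30
        assert rows[0].p_hyper == min(r.p_hyper for r in rows)

    def test_oversized_planting_rejected(self):
        genes = [f"g{i:05d}" for i in range(5)]
        with pytest.raises(ValueError, match="excess"):
            gen_annotations(100, 5, uniform_int_sampler(10, 10),
                            planted=("T_p", genes, 6), seed=0)

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            gen_annotations(10, 2, uniform_int_sampler(2, 4),
                            planted=("T_p", ["nope"], 0), seed=0)


class TestGenArrayTable:
    def test_zero_noise_gives_perfect_duplicates(self):
        table, _ = gen_array_table(50, binder_set=["mod000"],
                                   duplicate_noise_sd=0.0, seed=6)
        scores = array_scores(table)
        assert scores.duplicate_r2 == 1.0
        assert scores.binding_score["mod000"] > 2.0

    def test_no_binders_scores_near_one(self):
        table, _ = gen_array_table(100, binder_set=[], duplicate_noise_sd=0.0, seed=7)
        scores = array_scores(table)
        values = np.array(list(scores.binding_score.values()))
        assert np.all(values > 0.4) and np.all(values < 1.9)
        assert values.mean() == pytest.approx(1.0, abs=0.1)

    def test_default_noise_lands_in_predicted_r2_band(self):
        """The derived noise level puts realized R^2 in the band predicted
        by an independent simulation of additive duplicate noise."""
        target = 0.927
        r2s = []
        for seed in range(30):
            table, truth = gen_array_table(384, binder_set=[], seed=seed,
                                           target_duplicate_r2=target)
            r2s.append(array_scores(table).duplicate_r2)

        # independent simulation of the same additive-noise model
        rng = np.random.default_rng(12345)
        sim = []
        for _ in range(200):
            m = rng.normal(1000.0, 150.0, size=392)
            s = noise_sd_for_duplicate_r2(m, target)
            left = m + rng.normal(0, s, 392)
            right = m + rng.normal(0, s, 392)
            sim.append(np.corrcoef(left, right)[0, 1] ** 2)
        lo, hi = np.quantile(sim, [0.005, 0.995])
        assert lo <= np.median(r2s) <= hi

    def test_binder_outside_modifications_rejected(self):
        with pytest.raises(ValueError):
            gen_array_table(5, binder_set=["mod999"], seed=0)
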