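"""Synthetic-data generators: determinism and generator/estimator closure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import mutscan as ms
from mutscan.enrichment import combine_synonymous, enrichment_scores
from mutscan.roc import DegenerateTruthError


class TestLibrary:
    def test_single_position_yields_63_variants(self, toy_reference):
        lib = ms.generate_library(toy_reference, [5])
        assert len(lib) == 63
        assert len(set(lib)) == 63

    def test_multi_position_no_duplicates(self, toy_reference):
        lib = ms.generate_library(toy_reference, [2, 3, 4])
        assert len(lib) == 63 * 3
        assert len(set(lib)) == len(lib)

    def test_synonymous_alleles_translate_to_wildtype(self, toy_reference):
        alleles = ms.synonymous_alleles(toy_reference, 25, seed=1)
        assert len(set(alleles)) == 25
        for a in alleles:
            assert a != toy_reference.dna
            cds = ms.CodingSequence("a", a)
            assert cds.protein == toy_reference.protein

    def test_library_sequences_call_back_correctly(self, toy_reference):
        from mutscan import call_variant

        for seq in ms.generate_library(toy_reference, [7]):
            call = call_variant(seq, toy_reference)
            if call.category == "single_codon":
                assert call.position == 7
            else:
                assert call.category == "wt_synonymous"


class TestScreen:
    def test_deterministic_given_seed(self, toy_reference, random_fitness):
        model = ms.ScreenModel(
            reference=toy_reference, true_fitness=random_fitness, depth=300, seed=42
        )
        u1, s1 = ms.simulate_screen(model)
        u2, s2 = ms.simulate_screen(model)
        assert u1.counts == u2.counts and s1.counts == s2.counts
        assert u1.wt_alleles == u2.wt_alleles and s1.wt_alleles == s2.wt_alleles

    def test_null_model_scores_near_zero(self, toy_reference):
        model = ms.ScreenModel(
            reference=toy_reference, positions=[2, 3, 4], true_fitness={},
            depth=20000, leak=None, n_wt_alleles=50, seed=0,
        )
        unsel, sel = ms.simulate_screen(model)
        m = combine_synonymous(enrichment_scores(sel, unsel))
        vals = m.values_flat(exclude_stop=True)
        assert np.abs(np.median(vals)) < 0.01
        assert np.abs(vals).max() < 0.1

    def test_planted_tenfold_variant_recovers_plus_one(self, toy_reference):
        fitness = {(5, "V"): 1.0}
        model = ms.ScreenModel(
            reference=toy_reference, positions=[4, 5, 6], true_fitness=fitness,
            depth=20000, leak=None, n_wt_alleles=50, seed=1,
        )
        unsel, sel = ms.simulate_screen(model)
        m = combine_synonymous(enrichment_scores(sel, unsel))
        assert m.scores.at["V", 5] == pytest.approx(1.0, abs=0.05)

    def test_stop_codons_carry_leak_fitness(self, toy_reference):
        model = ms.ScreenModel(
            reference=toy_reference, positions=[2, 3, 4], true_fitness={},
            depth=20000, leak=-1.0, n_wt_alleles=50, seed=2,
        )
        unsel, sel = ms.simulate_screen(model)
        m = combine_synonymous(enrichment_scores(sel, unsel))
        stops = m.scores.loc["*"].dropna()
        # relative to WT growth 1 + 0.1, stops grow at 0.1: about -1.04
        assert np.median(stops) == pytest.approx(np.log10(0.1 / 1.1), abs=0.1)

    def test_high_depth_parameter_recovery(self, toy_reference, random_fitness):
        """Spearman between recovered scores and planted fitness > 0.95
        at 10^4 reads per variant."""
        model = ms.ScreenModel(
            reference=toy_reference, true_fitness=random_fitness,
            depth=1e4, leak=None, n_wt_alleles=120, seed=5,
        )
        unsel, sel = ms.simulate_screen(model)
        m = combine_synonymous(enrichment_scores(sel, unsel))
        est = [m.scores.at[a, p] for (p, a) in random_fitness]
        tru = list(random_fitness.values())
        keep = ~np.isnan(est)
        rho = spearmanr(np.asarray(est)[keep], np.asarray(tru)[keep]).statistic
        assert rho > 0.95

    def test_positive_leak_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            ms.ScreenModel(reference=toy_reference, leak=0.5)


class TestCurveAndDecayGenerators:
    def test_zero_noise_curve_on_model_mean(self):
        curve = ms.simulate_unfolding_curve(
            25.0, 5.0, (-4.0, -0.1, -16.0, 0.3), (0.0, 0.0), assay="cd", n_points=11
        )
        u = curve.urea
        f = ms.fraction_folded(u, 25.0, 5.0)
        expected = -4.0 - 0.1 * u + (-16.0 + 0.3 * u) * f
        assert np.allclose(curve.signal, expected)

    def test_curve_generator_deterministic(self):
        a = ms.simulate_unfolding_curve(
            25.0, 5.0, (-4, -0.1, -16, 0.3), (0.3, 0.02), seed=9
        )
        b = ms.simulate_unfolding_curve(
            25.0, 5.0, (-4, -0.1, -16, 0.3), (0.3, 0.02), seed=9
        )
        assert np.array_equal(a.signal, b.signal)

    def test_zero_noise_decay_exact(self):
        t = np.linspace(0.5, 24, 12)
        series = ms.simulate_decay_series(10.0, 0.2, t)
        assert np.allclose(series.values, 10.0 * np.exp(-0.2 * t))

    def test_decay_deterministic(self):
        t = np.linspace(0.5, 24, 12)
        a = ms.simulate_decay_series(10.0, 0.2, t, 0.05, seed=3)
        b = ms.simulate_decay_series(10.0, 0.2, t, 0.05, seed=3)
        assert np.array_equal(a.values, b.values)


class TestVariantDatabases:
    def _truth(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        return {
            (int(p), "G", str(a)): float(rng.normal())
            for p, a in zip(rng.integers(2, 160, n), rng.choice(list("AVDELKTS"), n))
        }

    def test_clean_truth_yields_perfect_auc(self):
        truth_scores = self._truth(1)
        tp, tn = ms.simulate_variant_databases(truth_scores, threshold=0.8, seed=1)
        truth = ms.assemble_truth(tp, tn, min_count=1)
        curve = ms.roc_curve(truth_scores, truth)
        assert curve.auc == pytest.approx(1.0)

    def test_contamination_degrades_auc(self):
        truth_scores = self._truth(2)
        tp, tn = ms.simulate_variant_databases(
            truth_scores, threshold=0.8, contamination=0.5, seed=2
        )
        truth = ms.assemble_truth(tp, tn, min_count=1)
        auc = ms.roc_curve(truth_scores, truth).auc
        assert 0.3 < auc < 0.9

    def test_all_positives_below_cutoff_degenerates(self):
        truth_scores = self._truth(3)
        tp, tn = ms.simulate_variant_databases(truth_scores, threshold=0.8, seed=3)
        with pytest.raises(DegenerateTruthError):
            ms.assemble_truth(tp, tn, min_count=10**9)

    def test_databases_deterministic(self):
        truth_scores = self._truth(4)
        a = ms.simulate_variant_databases(truth_scores, threshold=0.5, seed=7)
        b = ms.simulate_variant_databases(truth_scores, threshold=0.5, seed=7)
        assert a[0].records == b[0].records and a[1].records == b[1].records


class TestAlignmentGenerator:
    def test_reference_row_gap_free_and_deterministic(self):
        a = ms.simulate_alignment(n_seqs=20, length=30, seed=11)
        b = ms.simulate_alignment(n_seqs=20, length=30, seed=11)
        assert a.sequences == b.sequences
        assert "-" not in a.sequences[0]
        assert len(a.column_map) == 30

    def test_conserved_columns_have_zero_entropy(self):
        aln = ms.simulate_alignment(
            n_seqs=40, length=30, variable_fraction=0.0, gap_fraction=0.0, seed=2
        )
        ents = ms.site_entropies(aln)
        assert all(v == 0.0 for v in ents.values())
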