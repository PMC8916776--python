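"""Enrichment scoring: normalization, baseline correction, post-processing."""

import math

import numpy as np
import pandas as pd
import pytest

from mutscan import (
    EnrichmentMatrix,
    baseline_correct,
    center_and_scale,
    combine_synonymous,
    enrichment_scores,
    estimate_mode,
    legacy_enrichment,
    position_means,
    wt_allele_scores,
    wt_normalizer,
    average_matrices,
)
from mutscan.enrichment import (
    CorrectionUnavailableError,
    MissingNormalizerError,
    ScalingError,
)

from conftest import make_tables


class TestWtNormalizer:
    def test_median_of_log_ratios(self):
        sel, unsel = make_tables(
            {}, {}, {"a": 100, "b": 200, "c": 400}, {"a": 100, "b": 100, "c": 100}
        )
        term = wt_normalizer(sel, unsel, pseudocount=0.0)
        assert term.median_log_ratio == pytest.approx(math.log10(2), abs=1e-12)
        assert term.n_wt_alleles == 3

    def test_unit_ratios_give_zero(self):
        sel, unsel = make_tables({}, {}, {"a": 7, "b": 9}, {"a": 7, "b": 9})
        assert wt_normalizer(sel, unsel, pseudocount=0.0).median_log_ratio == 0.0

    def test_even_count_median_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        sel_counts = {f"a{i}": float(rng.integers(50, 500)) for i in range(10)}
        unsel_counts = {f"a{i}": float(rng.integers(50, 500)) for i in range(10)}
        sel, unsel = make_tables({}, {}, sel_counts, unsel_counts)
        term = wt_normalizer(sel, unsel, pseudocount=0.0)
        logs = sorted(
            math.log10(sel_counts[k] / unsel_counts[k]) for k in sel_counts
        )
        oracle = (logs[4] + logs[5]) / 2
        assert term.median_log_ratio == pytest.approx(oracle, abs=1e-12)

    def test_no_alleles_raises(self):
        sel, unsel = make_tables({}, {}, {}, {})
        with pytest.raises(MissingNormalizerError):
            wt_normalizer(sel, unsel)


class TestEnrichmentScores:
    def test_tenfold_wt_median_ratio_scores_plus_one(self):
        sel, unsel = make_tables(
            {(12, "GTC"): 2000.0},
            {(12, "GTC"): 100.0},
            {"a": 100, "b": 200, "c": 400},
            {"a": 100, "b": 100, "c": 100},
        )
        df = enrichment_scores(sel, unsel, pseudocount=0.0)
        assert df.loc[0, "score"] == pytest.approx(1.0, abs=1e-12)

    def test_wt_median_ratio_scores_zero(self):
        sel, unsel = make_tables(
            {(12, "GTC"): 200.0},
            {(12, "GTC"): 100.0},
            {"a": 100, "b": 200, "c": 400},
            {"a": 100, "b": 100, "c": 100},
        )
        df = enrichment_scores(sel, unsel, pseudocount=0.0)
        assert df.loc[0, "score"] == pytest.approx(0.0, abs=1e-12)

    def test_variant_absent_from_unselected_is_missing_not_error(self):
        sel, unsel = make_tables(
            {(5, "AAA"): 10.0}, {}, {"a": 10, "b": 10, "c": 10}, {"a": 10, "b": 10, "c": 10}
        )
        df = enrichment_scores(sel, unsel)
        assert np.isnan(df.loc[0, "score"])

    def test_depth_invariance_without_pseudocount(self, toy_reference):
        """Scaling every selected count by a constant leaves scores unchanged."""
        import mutscan as ms

        model = ms.ScreenModel(
            reference=toy_reference, positions=[2, 3, 4], depth=500,
            leak=None, n_wt_alleles=20, seed=9,
        )
        unsel, sel = ms.simulate_screen(model)
        a = enrichment_scores(sel, unsel, pseudocount=0.0)
        b = enrichment_scores(sel.scaled(7.3), unsel, pseudocount=0.0)
        pd.testing.assert_frame_equal(a, b, atol=1e-10, rtol=0)


class TestLegacyEnrichment:
    def _tables(self):
        return make_tables(
            {(2, "AAA"): 300.0, (3, "CCC"): 50.0},
            {(2, "AAA"): 100.0, (3, "CCC"): 100.0},
            {"a": 120, "b": 200, "c": 390},
            {"a": 100, "b": 100, "c": 100},
        )

    def test_variant_at_reference_ratio_scores_zero(self):
        sel, unsel = self._tables()
        df = legacy_enrichment(sel, unsel, (301.0, 101.0), pseudocount=1.0)
        row = df[df.position == 2].iloc[0]
        assert row.score == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_reference_ratio_scores_plus_one(self):
        sel, unsel = make_tables(
            {(2, "AAA"): 1000.0}, {(2, "AAA"): 100.0}, {"a": 50}, {"a": 50}
        )
        df = legacy_enrichment(sel, unsel, (100.0, 100.0), pseudocount=0.0)
        assert df.loc[0, "score"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_reference_count_raises(self):
        sel, unsel = self._tables()
        with pytest.raises(ZeroDivisionError):
            legacy_enrichment(sel, unsel, (0.0, 100.0))

    def test_difference_to_median_scoring_is_constant(self):
        """Median-normalized and template-normalized scores differ by a
        single dataset constant across all variants."""
        sel, unsel = self._tables()
        new = enrichment_scores(sel, unsel, pseudocount=1.0)
        old = legacy_enrichment(sel, unsel, (250.0, 100.0), pseudocount=1.0)
        diff = new["score"] - old["score"]
        assert diff.std() == pytest.approx(0.0, abs=1e-12)


class TestBaselineCorrect:
    def test_hand_computed_correction(self):
        sel, unsel = make_tables(
            {
                (2, "TAA"): 10.0, (3, "TAG"): 20.0, (4, "TGA"): 30.0,
                (5, "AAA"): 50.0,
            },
            {
                (2, "TAA"): 100.0, (3, "TAG"): 100.0, (4, "TGA"): 100.0,
                (5, "AAA"): 100.0,
            },
            {"a": 10}, {"a": 10},
        )
        corrected = baseline_correct(sel, unsel)
        # median stop ratio 0.2: 50 - 100*0.2 = 30
        assert corrected.counts[(5, "AAA")] == pytest.approx(30.0)

    def test_zero_stop_ratio_leaves_counts_unchanged(self):
        sel, unsel = make_tables(
            {(2, "TAA"): 0.0, (5, "AAA"): 50.0},
            {(2, "TAA"): 100.0, (5, "AAA"): 100.0},
            {"a": 10}, {"a": 10},
        )
        corrected = baseline_correct(sel, unsel)
        assert corrected.counts[(5, "AAA")] == 50.0

    def test_count_at_baseline_is_floored(self):
        sel, unsel = make_tables(
            {(2, "TAA"): 20.0, (5, "AAA"): 20.0},
            {(2, "TAA"): 100.0, (5, "AAA"): 100.0},
            {"a": 10}, {"a": 10},
        )
        corrected = baseline_correct(sel, unsel, floor=1.0)
        assert corrected.counts[(5, "AAA")] == 1.0
        assert corrected.counts[(2, "TAA")] == 1.0

    def test_no_stop_codons_raises(self):
        sel, unsel = make_tables(
            {(5, "AAA"): 50.0}, {(5, "AAA"): 100.0}, {"a": 10}, {"a": 10}
        )
        with pytest.raises(CorrectionUnavailableError):
            baseline_correct(sel, unsel)

    def test_rank_preserved_at_equal_unselected_counts(self):
        rng = np.random.default_rng(1)
        sel_counts = {(2, "TAA"): 30.0}
        unsel_counts = {(2, "TAA"): 100.0}
        for i, c in enumerate(sorted(rng.uniform(31, 500, size=10))):
            sel_counts[(3 + i, "AAA")] = float(c)
            unsel_counts[(3 + i, "AAA")] = 100.0
        sel, unsel = make_tables(sel_counts, unsel_counts, {"a": 1}, {"a": 1})
        corrected = baseline_correct(sel, unsel)
        keys = [(3 + i, "AAA") for i in range(10)]
        before = [sel_counts[k] for k in keys]
        after = [corrected.counts[k] for k in keys]
        assert np.all(np.argsort(before) == np.argsort(after))


class TestPostProcessing:
    def test_combine_synonymous_mean_and_missing(self):
        df = pd.DataFrame(
            {
                "position": [2, 2, 2, 3, 3],
                "codon": ["GCT", "GCC", "TGT", "GCT", "GCC"],
                "amino_acid": ["A", "A", "C", "A", "A"],
                "score": [0.2, 0.4, 0.5, np.nan, np.nan],
            }
        )
        m = combine_synonymous(df)
        assert m.scores.at["A", 2] == pytest.approx(0.3)
        assert m.scores.at["C", 2] == pytest.approx(0.5)  # single codon identity
        assert np.isnan(m.scores.at["A", 3])  # all codons missing

    def test_mode_estimation_on_known_mode(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0.5, 0.05, 400), rng.uniform(-2, 3, 100)])
        assert estimate_mode(values) == pytest.approx(0.5, abs=0.05)

    def test_center_and_scale_shifts_by_mode_and_sets_sd(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(
            rng.normal(0.5, 0.4, size=(21, 6)),
            index=list("ACDEFGHIKLMNPQRSTVWY*"),
            columns=range(2, 8),
        )
        m = EnrichmentMatrix(wide.copy())
        wt = rng.normal(0.5, 0.05, 50)
        out = center_and_scale(m, wt, target_sd=1.0)
        assert out.sd(exclude_stop=True) == pytest.approx(1.0, abs=1e-9)
        assert out.normalization_record[-1]["step"] == "center_and_scale"
        # re-applying with current sd and centered WT scores is a no-op
        wt2 = (wt - out.normalization_record[-1]["mode"]) * out.normalization_record[-1]["scale_factor"]
        again = center_and_scale(out, wt2, target_sd=1.0)
        mode2 = again.normalization_record[-1]["mode"]
        assert abs(mode2) < 0.15
        assert again.normalization_record[-1]["scale_factor"] == pytest.approx(1.0, abs=1e-6)

    def test_center_and_scale_errors(self):
        wide = pd.DataFrame(
            np.zeros((21, 3)), index=list("ACDEFGHIKLMNPQRSTVWY*"), columns=range(2, 5)
        )
        m = EnrichmentMatrix(wide)
        with pytest.raises(ValueError):
            center_and_scale(m, [0.1, 0.2], target_sd=1.0)  # <3 WT scores
        with pytest.raises(ScalingError):
            center_and_scale(m, [0.0, 0.0, 0.0], target_sd=1.0)  # zero variance

    def test_position_means_matches_column_oracle(self):
        rng = np.random.default_rng(7)
        wide = pd.DataFrame(
            rng.normal(size=(21, 5)),
            index=list("ACDEFGHIKLMNPQRSTVWY*"),
            columns=range(2, 7),
        )
        wide.iloc[3, 2] = np.nan
        m = EnrichmentMatrix(wide.copy())
        means = position_means(m, exclude_stop=True)
        for pos in m.positions:
            col = wide.loc[list("ACDEFGHIKLMNPQRSTVWY"), pos].dropna()
            assert means[pos] == pytest.approx(col.mean())

    def test_position_mean_of_balanced_column_is_zero(self):
        wide = pd.DataFrame(
            np.nan, index=list("ACDEFGHIKLMNPQRSTVWY*"), columns=range(2, 4)
        )
        wide.at["A", 2], wide.at["C", 2] = 1.0, -1.0
        wide.at["A", 3] = 0.0
        m = EnrichmentMatrix(wide)
        means = position_means(m)
        assert means[2] == pytest.approx(0.0)
        assert means[3] == pytest.approx(0.0)

    def test_replicate_average(self):
        idx = list("ACDEFGHIKLMNPQRSTVWY*")
        a = EnrichmentMatrix(pd.DataFrame(1.0, index=idx, columns=range(2, 4)))
        b = EnrichmentMatrix(pd.DataFrame(3.0, index=idx, columns=range(2, 4)))
        avg = average_matrices([a, b])
        assert (avg.scores == 2.0).all().all()


def test_matrix_io_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    wide = pd.DataFrame(
        rng.normal(size=(21, 4)),
        index=list("ACDEFGHIKLMNPQRSTVWY*"),
        columns=range(5, 9),
    )
    wide.iloc[0, 0] = np.nan
    m = EnrichmentMatrix(wide, dataset_id="d1",
                         normalization_record=[{"step": "center_and_scale"}])
    path, sidecar = tmp_path / "scores.tsv", tmp_path / "scores.meta"
    m.write(path, sidecar)
    back = EnrichmentMatrix.read(path, dataset_id="d1")
    pd.testing.assert_frame_equal(back.scores, m.scores, check_names=False)
    assert "center_and_scale" in sidecar.read_text()


def test_matrix_requires_contiguous_positions():
    wide = pd.DataFrame(
        0.0, index=list("ACDEFGHIKLMNPQRSTVWY*"), columns=[2, 4]
    )
    with pytest.raises(ValueError):
        EnrichmentMatrix(wide)


def test_wt_allele_scores_center_on_median():
    sel, unsel = make_tables(
        {}, {}, {"a": 100, "b": 200, "c": 400}, {"a": 100, "b": 100, "c": 100}
    )
    scores = wt_allele_scores(sel, unsel, pseudocount=0.0)
    assert sorted(scores)[1] == pytest.approx(0.0, abs=1e-12)
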