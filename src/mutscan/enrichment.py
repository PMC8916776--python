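"""Relative enrichment scoring for selection screens.

The fitness of a variant is quantified as a relative enrichment score

    dE = log10(c_sel / c_unsel) - median(log10(C_wt_sel / C_wt_unsel))

where the second term is the median log ratio over the synonymous
wild-type alleles (library sequences that differ in DNA but translate to
the wild-type protein). A score of 0 means wild-type-like propagation;
+1/-1 mean tenfold faster/slower. Centering on the median of >100
internal null sequences makes the score robust to outliers, unlike the
legacy score that centers on the single template sequence.

For leaky selections (cells with non-functional variants still grow at a
basal rate) a baseline correction subtracts the null growth signal,
estimated from stop-codon variants, from the selected counts before
scoring. Post-processing combines synonymous codons by their mean,
re-centers on the mode of the wild-type allele score distribution, and
rescales to a common standard deviation so datasets are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .counts import VariantCountTable
from .genetics import AA_ORDER, STOP, translate_codon


class MissingNormalizerError(ValueError):
    """No synonymous wild-type alleles available to center the scores."""


class CorrectionUnavailableError(ValueError):
    """No stop-codon variants usable for the baseline correction."""


class ScalingError(ValueError):
    """Degenerate score distribution; cannot rescale."""


@dataclass(frozen=True)
class NormalizerTerm:
    """Median log10 selected/unselected ratio over synonymous WT alleles."""

    median_log_ratio: float
    n_wt_alleles: int

    def __post_init__(self) -> None:
        if self.n_wt_alleles < 1:
            raise MissingNormalizerError("need at least one wild-type allele")


@dataclass
class EnrichmentMatrix:
    """Amino-acid x position matrix of enrichment scores.

    Rows follow :data:`mutscan.genetics.AA_ORDER` (20 amino acids then
    ``'*'``); columns are a contiguous residue range. NaN marks variants
    not represented in the library, distinct from a genuine score of 0.
    ``normalization_record`` lists the post-processing steps applied, in
    order, with their parameters.
    """

    scores: pd.DataFrame
    dataset_id: str = ""
    normalization_record: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = list(self.scores.columns)
        if cols != list(range(min(cols), max(cols) + 1)):
            raise ValueError("positions must form a contiguous range")

    @property
    def positions(self) -> list[int]:
        return list(self.scores.columns)

    def values_flat(self, exclude_stop: bool = True) -> np.ndarray:
        """All non-missing scores as a 1-D array."""
        df = self.scores.drop(index=STOP) if exclude_stop else self.scores
        v = df.to_numpy(dtype=float).ravel()
        return v[~np.isnan(v)]

    def sd(self, exclude_stop: bool = True) -> float:
        return float(np.std(self.values_flat(exclude_stop)))

    # ------------------------------------------------------------------ IO
    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Long-form TSV (position, amino_acid, score) + key=value sidecar."""
        long = (
            self.scores.stack(future_stack=True)
            .rename("score")
            .rename_axis(["amino_acid", "position"])
            .reset_index()[["position", "amino_acid", "score"]]
        )
        long.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            lines = [f"dataset_id={self.dataset_id}"]
            for step in self.normalization_record:
                kv = ",".join(f"{k}:{v}" for k, v in step.items())
                lines.append(f"step={kv}")
            Path(sidecar).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path, dataset_id: str = "") -> "EnrichmentMatrix":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="amino_acid", columns="position", values="score")
        wide = wide.reindex(index=list(AA_ORDER))
        wide.columns = [int(c) for c in wide.columns]
        return cls(scores=wide, dataset_id=dataset_id)


# --------------------------------------------------------------------- scoring

def _paired_counts(
    table: VariantCountTable, keys: Iterable, pseudocount: float
) -> dict:
    return {k: table.counts.get(k, 0.0) + pseudocount for k in keys}


def wt_normalizer(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    pseudocount: float = 1.0,
) -> NormalizerTerm:
    """Median log10 ratio over synonymous wild-type alleles.

    Alleles are paired by identity across the two samples. With
    ``pseudocount=0`` alleles with a zero count in either sample are
    dropped; otherwise the pseudocount is added to every count.
    """
    alleles = sorted(set(selected.wt_alleles) | set(unselected.wt_alleles))
    ratios = []
    for a in alleles:
        s = selected.wt_alleles.get(a, 0.0) + pseudocount
        u = unselected.wt_alleles.get(a, 0.0) + pseudocount
        if s > 0 and u > 0:
            ratios.append(math.log10(s / u))
    if not ratios:
        raise MissingNormalizerError("no usable synonymous wild-type alleles")
    return NormalizerTerm(
        median_log_ratio=float(np.median(ratios)), n_wt_alleles=len(ratios)
    )


def wt_allele_scores(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    pseudocount: float = 1.0,
) -> list[float]:
    """Per-allele enrichment scores of the synonymous WT alleles themselves."""
    norm = wt_normalizer(selected, unselected, pseudocount)
    out = []
    for a in sorted(set(selected.wt_alleles) | set(unselected.wt_alleles)):
        s = selected.wt_alleles.get(a, 0.0) + pseudocount
        u = unselected.wt_alleles.get(a, 0.0) + pseudocount
        if s > 0 and u > 0:
            out.append(math.log10(s / u) - norm.median_log_ratio)
    return out


def enrichment_scores(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    baseline_correct_counts: bool = False,
    pseudocount: float = 1.0,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Codon-level relative enrichment scores.

    Returns a long DataFrame (position, codon, amino_acid, score). A
    variant absent from the unselected sample cannot be scored and is
    reported with a NaN score; a variant present in the unselected sample
    only gets the pseudocount in the selected numerator. When
    ``baseline_correct_counts`` is set, :func:`baseline_correct` is
    applied to the selected table first.
    """
    if baseline_correct_counts:
        selected = baseline_correct(selected, unselected, floor=floor)
    norm = wt_normalizer(selected, unselected, pseudocount)
    rows = []
    keys = sorted(set(selected.counts) | set(unselected.counts))
    for pos, codon in keys:
        in_unsel = (pos, codon) in unselected.counts
        s = selected.counts.get((pos, codon), 0.0) + pseudocount
        u = unselected.counts.get((pos, codon), 0.0) + pseudocount
        if not in_unsel or s <= 0 or u <= 0:
            score = np.nan
        else:
            score = math.log10(s / u) - norm.median_log_ratio
        rows.append(
            {
                "position": pos,
                "codon": codon,
                "amino_acid": translate_codon(codon),
                "score": score,
            }
        )
    return pd.DataFrame(rows, columns=["position", "codon", "amino_acid", "score"])


def legacy_enrichment(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    wt_reference_counts: tuple[float, float],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Legacy scoring centered on the single wild-type template sequence.

    ``wt_reference_counts`` is (selected, unselected) counts of the exact
    template DNA sequence. No pseudocount shields the reference: a zero
    reference count raises, which is precisely the fragility the
    median-of-alleles normalization removes.
    """
    ref_sel, ref_unsel = wt_reference_counts
    if ref_sel <= 0 or ref_unsel <= 0:
        raise ZeroDivisionError("wild-type reference count is zero")
    ref_term = math.log10(ref_sel / ref_unsel)
    df = enrichment_scores(selected, unselected, pseudocount=pseudocount)
    norm = wt_normalizer(selected, unselected, pseudocount)
    df["score"] = df["score"] + norm.median_log_ratio - ref_term
    return df


def baseline_correct(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    floor: float = 1.0,
) -> VariantCountTable:
    """Subtract the leaky null-growth signal estimated from stop codons.

    The stop-codon ratio ``x_f = median(c_sel/c_unsel over stop variants)``
    estimates how much selected signal a non-functional variant accrues
    per unselected count. Corrected selected counts are
    ``c_sel - c_unsel * x_f``, floored at ``floor`` when non-positive
    (the paper-silent case). Synonymous WT allele counts receive the same
    correction so the internal null stays consistent.
    """
    ratios = []
    for key, c_sel in selected.stop_counts.items():
        c_unsel = unselected.counts.get(key, 0.0)
        if c_unsel > 0:
            ratios.append(c_sel / c_unsel)
    if not ratios:
        raise CorrectionUnavailableError(
            "no stop-codon variants with nonzero unselected counts"
        )
    x_f = float(np.median(ratios))

    def corr(c_sel: float, c_unsel: float) -> float:
        c = c_sel - c_unsel * x_f
        return c if c > 0 else floor

    counts = {
        k: corr(v, unselected.counts.get(k, 0.0)) for k, v in selected.counts.items()
    }
    wt = {
        a: corr(v, unselected.wt_alleles.get(a, 0.0))
        for a, v in selected.wt_alleles.items()
    }
    return VariantCountTable(
        sample_id=selected.sample_id + "+baseline",
        counts=counts,
        wt_alleles=wt,
        total_reads=selected.total_reads,
    )


# ------------------------------------------------------------- post-processing

def combine_synonymous(codon_frame: pd.DataFrame, dataset_id: str = "") -> EnrichmentMatrix:
    """Collapse codon-level scores to amino-acid level by unweighted mean.

    Codons with missing scores are ignored; a cell is missing only when
    every codon for that amino acid at that position is missing.
    """
    agg = codon_frame.groupby(["amino_acid", "position"])["score"].mean()
    wide = agg.unstack("position")
    positions = range(int(min(wide.columns)), int(max(wide.columns)) + 1)
    wide = wide.reindex(index=list(AA_ORDER), columns=list(positions))
    return EnrichmentMatrix(scores=wide, dataset_id=dataset_id)


def estimate_mode(values: Sequence[float], grid_size: int = 512) -> float:
    """Mode of a sample by Gaussian KDE (plug-in bandwidth, 512-point grid)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise ValueError("need >=3 values for mode estimation")
    if np.ptp(v) == 0:
        return float(v[0])
    kde = gaussian_kde(v)
    pad = 3 * kde.factor * v.std()
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    return float(grid[np.argmax(kde(grid))])


def count_modes(
    values: Sequence[float], rel_height: float = 0.3, grid_size: int = 512
) -> int:
    """Number of substantive modes of a score distribution.

    A mode is a local maximum of the KDE whose density reaches at least
    ``rel_height`` of the principal peak; low-mass shoulders (e.g. the
    detection-limit pile-up of floored baseline-corrected counts) are not
    counted. Used to check the bimodal-to-unimodal effect of the baseline
    correction on leaky selections.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if np.ptp(v) == 0:
        return 1
    kde = gaussian_kde(v)
    pad = 3 * kde.factor * v.std()
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    d = kde(grid)
    peaks = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] >= rel_height * d.max())
    return int(peaks.sum())


def center_and_scale(
    matrix: EnrichmentMatrix,
    wt_scores: Sequence[float],
    target_sd: float = 1.0,
    exclude_stop: bool = True,
) -> EnrichmentMatrix:
    """Center on the mode of the WT-allele scores, rescale to ``target_sd``.

    The scale factor uses the standard deviation over all non-missing
    substitution scores (stop row excluded by default); the same shift and
    factor are applied to every cell, stop row included.
    """
    if len([s for s in wt_scores if not np.isnan(s)]) < 3:
        raise ValueError("need >=3 wild-type scores for mode estimation")
    mode = estimate_mode(wt_scores)
    centered = matrix.scores - mode
    shifted = EnrichmentMatrix(centered, matrix.dataset_id, list(matrix.normalization_record))
    sd = shifted.sd(exclude_stop=exclude_stop)
    if not np.isfinite(sd) or sd == 0:
        raise ScalingError("zero-variance score distribution")
    factor = target_sd / sd
    record = matrix.normalization_record + [
        {
            "step": "center_and_scale",
            "mode": round(mode, 6),
            "scale_factor": round(factor, 6),
            "target_sd": target_sd,
            "exclude_stop": exclude_stop,
        }
    ]
    return EnrichmentMatrix(centered * factor, matrix.dataset_id, record)


def position_means(matrix: EnrichmentMatrix, exclude_stop: bool = True) -> pd.Series:
    """Mean substitution score per position (the heatmap's bottom strip)."""
    df = matrix.scores.drop(index=STOP) if exclude_stop else matrix.scores
    return df.mean(axis=0, skipna=True)


def average_matrices(matrices: Sequence[EnrichmentMatrix]) -> EnrichmentMatrix:
    """Per-cell mean across biological replicates (NaN-aware)."""
    if not matrices:
        raise ValueError("no matrices to average")
    frames = [m.scores for m in matrices]
    stacked = pd.concat(frames, keys=range(len(frames)))
    avg = stacked.groupby(level=1, sort=False).mean()
    avg = avg.reindex(index=frames[0].index)
    rec = [{"step": "replicate_mean", "n": len(matrices)}]
    return EnrichmentMatrix(avg, matrices[0].dataset_id, rec)


def score_screen(
    selected: VariantCountTable,
    unselected: VariantCountTable,
    baseline: bool = True,
    pseudocount: float = 1.0,
    target_sd: float = 1.0,
    dataset_id: str = "",
) -> EnrichmentMatrix:
    """Full scoring pipeline for one selected/unselected pair.

    Baseline correction (optional) -> codon-level scores -> synonymous
    combination -> center on WT mode and rescale.
    """
    sel = baseline_correct(selected, unselected) if baseline else selected
    codon = enrichment_scores(sel, unselected, pseudocount=pseudocount)
    matrix = combine_synonymous(codon, dataset_id=dataset_id)
    if baseline:
        matrix.normalization_record.append({"step": "baseline_correct"})
    wt = wt_allele_scores(sel, unselected, pseudocount)
    return center_and_scale(matrix, wt, target_sd=target_sd)
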