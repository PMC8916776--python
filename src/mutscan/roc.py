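"""ROC benchmarking of fitness scores against variant truth sets.

Truth sets come either from cancer/population variant databases
(COSMIC-like counts as positives, gnomAD-like non-pathogenic variants as
negatives) or from a second saturation-mutagenesis dataset via the
1.5-standard-deviation activation rule. Higher score predicts
activating/pathogenic; AUC is the usual threshold-sweep trapezoid, which
for tied scores equals the pairwise rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .enrichment import EnrichmentMatrix
from .epistasis import activating_variants
from .genetics import STOP

#: Database variant identity: (position, wild-type aa, mutant aa).
Variant = tuple[int, str, str]


class DegenerateTruthError(ValueError):
    """A truth set ended up with an empty positive or negative class."""


@dataclass
class VariantDatabase:
    """Observation counts per variant per isoform, with pathogenic flags.

    ``records`` maps (isoform, position, wt_aa, mut_aa) to a count;
    ``pathogenic`` holds the isoform-free variant keys flagged pathogenic.
    """

    records: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    pathogenic: set[Variant] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.records.values()):
            raise ValueError("negative observation count")

    def variants(self) -> set[Variant]:
        return {(p, w, m) for (_, p, w, m) in self.records}

    def pooled_counts(self) -> dict[Variant, float]:
        out: dict[Variant, float] = {}
        for (_, p, w, m), c in self.records.items():
            out[(p, w, m)] = out.get((p, w, m), 0.0) + c
        return out

    # ------------------------------------------------------------------ IO
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isoform": iso,
                "position": pos,
                "wt_aa": w,
                "mut_aa": m,
                "count": c,
                "pathogenic": int((pos, w, m) in self.pathogenic),
            }
            for (iso, pos, w, m), c in sorted(self.records.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["isoform", "position", "wt_aa", "mut_aa", "count", "pathogenic"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "VariantDatabase":
        df = pd.read_csv(path, sep="\t")
        records, flagged = {}, set()
        for r in df.itertuples():
            key = (str(r.isoform), int(r.position), str(r.wt_aa), str(r.mut_aa))
            records[key] = records.get(key, 0.0) + float(r.count)
            if getattr(r, "pathogenic", 0):
                flagged.add(key[1:])
        return cls(records=records, pathogenic=flagged)


@dataclass
class VariantTruthSet:
    """Disjoint positive/negative variant labels for ROC analysis."""

    positives: set[Hashable]
    negatives: set[Hashable]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1), swept thresholds, and the AUC."""

    points: list[tuple[float, float]]
    auc: float
    threshold_grid: list[float]
    n_dropped: int = 0


def filter_by_count(
    db: VariantDatabase, min_count: float = 5, pooling: str = "pooled"
) -> set[Variant]:
    """Variants meeting the observation-count cutoff (default >= 5).

    ``pooling='pooled'`` sums counts across isoforms before applying the
    cutoff; ``'any_isoform'`` requires the cutoff within a single isoform.
    """
    if pooling == "pooled":
        return {v for v, c in db.pooled_counts().items() if c >= min_count}
    if pooling == "any_isoform":
        out = set()
        for (_, p, w, m), c in db.records.items():
            if c >= min_count:
                out.add((p, w, m))
        return out
    raise ValueError(f"unknown pooling mode {pooling!r}")


def assemble_truth(
    tp_db: VariantDatabase,
    tn_db: VariantDatabase,
    min_count: float = 5,
    pooling: str = "pooled",
) -> VariantTruthSet:
    """Build a truth set from a cancer-like and a population-like database.

    Positives are count-filtered cancer variants. Negatives are the
    population variants minus pathogenic-flagged ones and minus anything
    that is also a positive (an overlap variant is a true positive).
    Variants in neither set are unlabeled and never enter the ROC.
    """
    positives = filter_by_count(tp_db, min_count, pooling)
    negatives = tn_db.variants() - tn_db.pathogenic - positives
    if not positives or not negatives:
        raise DegenerateTruthError("empty positive or negative class")
    return VariantTruthSet(positives=positives, negatives=negatives)


def truth_from_scores(
    reference_matrix: EnrichmentMatrix, k: float = 1.5
) -> VariantTruthSet:
    """Truth set from a reference screen: activating variants (score above
    k standard deviations) are positives, every other scored variant a
    negative."""
    positives = activating_variants(reference_matrix, k)
    sub = reference_matrix.scores.drop(index=STOP)
    all_scored = {
        (int(pos), aa)
        for aa, row in sub.iterrows()
        for pos, v in row.items()
        if not np.isnan(v)
    }
    return VariantTruthSet(positives=positives, negatives=all_scored - positives)


def matrix_scores(
    matrix: EnrichmentMatrix, include_stop: bool = False
) -> dict[tuple[int, str], float]:
    """Non-missing matrix cells as a (position, amino_acid) -> score map."""
    df = matrix.scores if include_stop else matrix.scores.drop(index=STOP)
    return {
        (int(pos), aa): float(v)
        for aa, row in df.iterrows()
        for pos, v in row.items()
        if not np.isnan(v)
    }


def scores_as_variants(
    matrix: EnrichmentMatrix, reference_protein: str, first_residue_number: int = 1
) -> dict[Variant, float]:
    """Re-key matrix scores as (position, wt_aa, mut_aa) database variants."""
    out = {}
    for (pos, aa), v in matrix_scores(matrix).items():
        i = pos - first_residue_number
        if 0 <= i < len(reference_protein):
            out[(pos, reference_protein[i], aa)] = v
    return out


def roc_curve(scores: Mapping[Hashable, float], truth: VariantTruthSet) -> RocCurve:
    """ROC curve and AUC for a score map against a truth set.

    Truth variants without a score are dropped (their number reported in
    ``n_dropped``). Thresholds sweep every distinct score; the trapezoid
    AUC equals the tie-aware pairwise rank statistic.
    """
    labeled = [(v, 1) for v in truth.positives if v in scores] + [
        (v, 0) for v in truth.negatives if v in scores
    ]
    n_dropped = len(truth.positives) + len(truth.negatives) - len(labeled)
    y = np.array([lab for _, lab in labeled])
    s = np.array([scores[v] for v, _ in labeled], dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateTruthError("one truth class empty after score intersection")
    fpr, tpr, thresholds = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return RocCurve(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        threshold_grid=thresholds.tolist(),
        n_dropped=n_dropped,
    )
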