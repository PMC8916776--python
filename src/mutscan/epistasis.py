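"""Construct epistasis: comparing enrichment matrices between contexts.

Comparing the same substitution across Ras constructs of different
stability (e.g. a short 2-166 vs a long 2-180 construct, both with GAP)
isolates stability-dependent gain-of-function: sites whose mutations
activate only when the construct is stable enough to absorb the
destabilization. The per-cell pairwise difference

    ddE = dE(short) - dE(long)

is averaged over the defined substitutions at each position, and sites
are classified by the 1.5-standard-deviation activation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentMatrix
from .genetics import STOP


@dataclass
class EpistasisResult:
    """Pairwise difference matrix and its per-position means."""

    delta_matrix: pd.DataFrame
    position_means: pd.Series
    dataset_pair: tuple[str, str]


@dataclass
class SiteClassification:
    """Activating and stability-dependent gain-of-function sites."""

    activating_sites: set[int]
    stability_dependent_sites: set[int]
    per_variant_labels: dict[tuple[int, str], str] = field(default_factory=dict)


def pairwise_epistasis(
    short_matrix: EnrichmentMatrix, long_matrix: EnrichmentMatrix
) -> EpistasisResult:
    """Cellwise short-minus-long difference over the shared position range.

    Cells missing in either input are missing in the difference;
    positions with no defined substitution are dropped from the means.
    """
    shared = sorted(set(short_matrix.positions) & set(long_matrix.positions))
    if not shared:
        raise ValueError("matrices share no positions")
    s = short_matrix.scores[shared]
    l = long_matrix.scores[shared]
    delta = s - l
    means = delta.drop(index=STOP).mean(axis=0, skipna=True).dropna()
    return EpistasisResult(
        delta_matrix=delta,
        position_means=means,
        dataset_pair=(short_matrix.dataset_id, long_matrix.dataset_id),
    )


def activating_variants(
    matrix: EnrichmentMatrix, k: float = 1.5
) -> set[tuple[int, str]]:
    """Substitutions with score > k times the dataset standard deviation.

    The SD is taken over all non-missing substitution scores of the
    (centered) matrix, stop row excluded.
    """
    sd = matrix.sd(exclude_stop=True)
    cut = k * sd
    sub = matrix.scores.drop(index=STOP)
    out = set()
    for aa, row in sub.iterrows():
        for pos, v in row.items():
            if not np.isnan(v) and v > cut:
                out.add((int(pos), aa))
    return out


def classify_sites(
    short_matrix: EnrichmentMatrix,
    long_matrix: EnrichmentMatrix,
    k: float = 1.5,
) -> SiteClassification:
    """Label stability-dependent gain-of-function sites.

    A site is stability-dependent when at least one substitution is
    activating (k-rule) in the long construct but not in the short one.
    Variant labels: activating in both, long only, short only; otherwise
    deleterious (long score < -k*sd in the long dataset) or neutral.
    """
    act_long = activating_variants(long_matrix, k)
    act_short = activating_variants(short_matrix, k)
    sd_long = long_matrix.sd(exclude_stop=True)

    labels: dict[tuple[int, str], str] = {}
    sub = long_matrix.scores.drop(index=STOP)
    for aa, row in sub.iterrows():
        for pos, v in row.items():
            key = (int(pos), aa)
            if key in act_long and key in act_short:
                labels[key] = "activating_both"
            elif key in act_long:
                labels[key] = "activating_long"
            elif key in act_short:
                labels[key] = "activating_short"
            elif not np.isnan(v) and v < -k * sd_long:
                labels[key] = "deleterious"
            elif not np.isnan(v):
                labels[key] = "neutral"

    activating_sites = {pos for pos, _ in act_long}
    stability_dependent = {
        pos for pos, aa in act_long if (pos, aa) not in act_short
    }
    return SiteClassification(
        activating_sites=activating_sites,
        stability_dependent_sites=stability_dependent,
        per_variant_labels=labels,
    )
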