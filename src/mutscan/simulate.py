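"""Synthetic data generators for every pipeline input.

Screens are simulated forward from known truth: per-variant log10 growth
advantages, a library of all 63 codon substitutions per position plus a
panel of synonymous wild-type alleles (default 120, matching the
"more than a hundred" internal null sequences of real Ras libraries)
with log-normal abundances, leaky null growth applied uniformly (cells
without functional protein still propagate at 10^leak relative to
wild-type; stop-codon variants grow at the leak rate only), Poisson
sequencing sampling, and renormalization of the selected sample to a
target depth — sequencing reports frequencies, not absolute growth.

Also generated: two-state unfolding titrations with the exact
likelihoods the stability module fits, exponential decay series with
multiplicative normal noise, COSMIC/gnomAD-like variant databases with a
heavy-tailed count law, and toy alignments with a planted conservation
profile. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conservation import Alignment
from .counts import VariantCountTable
from .exchange import DecaySeries
from .genetics import AMINO_ACIDS, GENETIC_CODE, STOP, CodingSequence
from .roc import Variant, VariantDatabase
from .stability import DEFAULT_TEMPERATURE, UnfoldingCurve, fraction_folded


@dataclass
class ScreenModel:
    """Ground truth for one simulated selection screen.

    ``true_fitness`` maps (position, amino_acid) to log10 growth
    advantage (0 = wild-type-like; +1 = tenfold faster). ``leak`` is the
    log10 growth of null variants (<= 0; None disables leak entirely).
    ``depth`` is the expected unselected reads per library member.
    """

    reference: CodingSequence
    true_fitness: dict[tuple[int, str], float] = field(default_factory=dict)
    positions: Sequence[int] | None = None
    n_wt_alleles: int = 120
    wt_allele_sigma: float = 0.5
    abundance_sigma: float = 0.3
    leak: float | None = -2.0
    depth: float = 200.0
    selected_depth: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leak is not None and self.leak > 0:
            raise ValueError("leak must be <= 0 (relative to wild-type = 0)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.positions is None:
            self.positions = sorted({p for p, _ in self.true_fitness}) or list(
                self.reference.residue_numbers
            )


def leaky_screen_fitness(
    reference: CodingSequence,
    positions: Iterable[int],
    seed: int = 0,
    lethal_fraction: float = 0.04,
    deleterious_fraction: float = 0.36,
    neutral_sd: float = 0.15,
) -> dict[tuple[int, str], float]:
    """A realistic per-substitution fitness landscape for a leaky screen.

    Mixture per substitution: a small truly-lethal class (log10 fitness
    -4), a continuum of partial loss-of-function drawn uniformly from
    [-2, -0.3] decades, and a near-neutral bulk N(0, ``neutral_sd``).
    The continuous deleterious class is what makes real enrichment
    distributions unimodal after baseline correction, with the lethal
    class surviving only as a detection-limit shoulder.
    """
    rng = np.random.default_rng(seed)
    fitness: dict[tuple[int, str], float] = {}
    for pos in positions:
        wt_aa = reference.aa_at(pos)
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            r = rng.random()
            if r < lethal_fraction:
                fitness[(pos, aa)] = -4.0
            elif r < lethal_fraction + deleterious_fraction:
                fitness[(pos, aa)] = float(rng.uniform(-2.0, -0.3))
            else:
                fitness[(pos, aa)] = float(rng.normal(0.0, neutral_sd))
    return fitness


def generate_library(
    reference: CodingSequence,
    positions: Iterable[int],
    n_wt_alleles: int = 0,
    seed: int = 0,
) -> list[str]:
    """Variant DNA sequences: all 63 non-WT codons per position, plus
    ``n_wt_alleles`` distinct synonymous wild-type alleles."""
    seqs = []
    for pos in positions:
        wt_codon = reference.codon_at(pos)
        for codon in sorted(GENETIC_CODE):
            if codon != wt_codon:
                seqs.append(reference.with_codon(pos, codon))
    seqs.extend(synonymous_alleles(reference, n_wt_alleles, seed=seed))
    return seqs


def synonymous_alleles(
    reference: CodingSequence, n: int, seed: int = 0, max_changes: int = 3
) -> list[str]:
    """Distinct DNA sequences translating exactly to the WT protein."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    syn_options: dict[int, list[str]] = {}
    for res in reference.residue_numbers:
        wt = reference.codon_at(res)
        alts = [c for c in GENETIC_CODE if GENETIC_CODE[c] == GENETIC_CODE[wt] and c != wt]
        if alts:
            syn_options[res] = sorted(alts)
    out: set[str] = set()
    residues = sorted(syn_options)
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n:
            raise RuntimeError("cannot generate enough distinct synonymous alleles")
        k = int(rng.integers(1, max_changes + 1))
        picks = rng.choice(len(residues), size=min(k, len(residues)), replace=False)
        dna = reference.dna
        seq = CodingSequence("tmp", dna, reference.first_residue_number)
        for idx in picks:
            res = residues[idx]
            opts = syn_options[res]
            dna = seq.with_codon(res, opts[int(rng.integers(len(opts)))])
            seq = CodingSequence("tmp", dna, reference.first_residue_number)
        if dna != reference.dna:
            out.add(dna)
    return sorted(out)


def simulate_screen(
    model: ScreenModel,
) -> tuple[VariantCountTable, VariantCountTable]:
    """Simulate one unselected/selected count-table pair.

    Unselected counts are Poisson around depth-scaled log-normal
    abundances. Expected selected counts multiply the unselected
    expectation by the growth factor 10^fitness (+10^leak for the leaky
    floor; stop codons grow at the leak rate only), then are renormalized
    to the target selected depth and Poisson-sampled.
    """
    rng = np.random.default_rng(model.seed)
    ref = model.reference
    leak_lin = 0.0 if model.leak is None else 10.0 ** model.leak

    keys: list[tuple[int, str]] = []
    growth: list[float] = []
    for pos in model.positions:
        wt_codon = ref.codon_at(pos)
        for codon in sorted(GENETIC_CODE):
            if codon == wt_codon:
                continue
            aa = GENETIC_CODE[codon]
            keys.append((pos, codon))
            if aa == STOP:
                growth.append(leak_lin)
            else:
                f = model.true_fitness.get((pos, aa), 0.0)
                growth.append(10.0 ** f + leak_lin)
    wt_ids = [f"wt_{i:04d}" for i in range(model.n_wt_alleles)]
    growth_arr = np.concatenate(
        [np.array(growth), np.full(model.n_wt_alleles, 1.0 + leak_lin)]
    )

    n_total = len(keys) + model.n_wt_alleles
    abund = np.concatenate(
        [
            rng.lognormal(0.0, model.abundance_sigma, size=len(keys)),
            rng.lognormal(0.0, model.wt_allele_sigma, size=model.n_wt_alleles),
        ]
    )
    unsel_expected = model.depth * abund / abund.mean()
    unsel = rng.poisson(unsel_expected)

    sel_raw = unsel_expected * growth_arr
    target = model.selected_depth or model.depth
    sel_expected = sel_raw * (target * n_total) / sel_raw.sum()
    sel = rng.poisson(sel_expected)

    def table(sample_id: str, counts_arr: np.ndarray) -> VariantCountTable:
        counts = {k: float(c) for k, c in zip(keys, counts_arr[: len(keys)])}
        wt = {a: float(c) for a, c in zip(wt_ids, counts_arr[len(keys):])}
        return VariantCountTable(
            sample_id=sample_id,
            counts=counts,
            wt_alleles=wt,
            total_reads=int(counts_arr.sum()),
        )

    return table("unselected", unsel), table("selected", sel)


def simulate_unfolding_curve(
    dG: float,
    m: float,
    baselines: tuple[float, float, float, float],
    noise: tuple[float, ...],
    assay: str = "cd",
    n_points: int = 25,
    urea_max: float = 8.0,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
) -> UnfoldingCurve:
    """Forward-simulate a titration under the exact fitted noise law.

    ``noise`` is (sigma_constant, sigma_proportional) for CD and
    (sigma,) for proteolysis; all-zero noise returns the model mean.
    """
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, urea_max, n_points)
    s_u, b_u, s_f, b_f = baselines
    f = fraction_folded(u, dG, m, temperature)
    mean = s_u + b_u * u + (s_f + b_f * u) * f
    if assay == "cd":
        sig_c, sig_p = noise
        scale = sig_c + sig_p * u
    elif assay == "proteolysis":
        (sigma,) = noise
        scale = np.full_like(u, sigma)
    else:
        raise ValueError("assay must be 'cd' or 'proteolysis'")
    signal = mean + (rng.normal(0.0, 1.0, size=u.shape) * scale if np.any(scale) else 0.0)
    return UnfoldingCurve(urea=u, signal=signal, assay=assay, temperature=temperature)


def simulate_decay_series(
    amplitude: float,
    k: float,
    times: Sequence[float],
    noise_fraction: float = 0.0,
    seed: int | None = None,
    name: str = "probe",
) -> DecaySeries:
    """A*exp(-k*t) with multiplicative normal noise of the given fraction."""
    if k < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    values = amplitude * np.exp(-k * t)
    if noise_fraction:
        values = values * (1.0 + rng.normal(0.0, noise_fraction, size=t.shape))
    return DecaySeries(residue_or_probe=name, times=t, values=values)


def simulate_variant_databases(
    truth_scores: Mapping[Variant, float],
    threshold: float,
    contamination: float = 0.0,
    zipf_a: float = 1.6,
    seed: int = 0,
) -> tuple[VariantDatabase, VariantDatabase]:
    """COSMIC-like / gnomAD-like databases from planted variant scores.

    Variants scoring above ``threshold`` enter the cancer-like positive
    database with heavy-tailed (Zipf) observation counts — some fall
    below the five-count cutoff, like rare cancer variants. The rest
    enter the population-like negative database with small counts.
    ``contamination`` mislabels that fraction of variants (swapping
    databases), with mislabeled positives given counts passing the
    cutoff.
    """
    rng = np.random.default_rng(seed)
    isoforms = ("HRAS", "KRAS", "NRAS")
    tp = VariantDatabase()
    tn = VariantDatabase()
    for v in sorted(truth_scores):
        score = truth_scores[v]
        activating = score > threshold
        if contamination and rng.random() < contamination:
            activating = not activating
        iso = isoforms[int(rng.integers(len(isoforms)))]
        if activating:
            count = int(rng.zipf(zipf_a))
            tp.records[(iso, *v)] = float(count)
        else:
            tn.records[(iso, *v)] = float(1 + rng.poisson(2))
    return tp, tn


def simulate_alignment(
    n_seqs: int = 50,
    length: int = 40,
    variable_fraction: float = 0.5,
    n_column_symbols: int = 4,
    gap_fraction: float = 0.05,
    reference_id: str = "ref",
    first_residue_number: int = 1,
    seed: int = 0,
) -> Alignment:
    """Toy protein alignment with conserved and variable columns.

    A ``variable_fraction`` of columns draws uniformly from
    ``n_column_symbols`` residues; the rest are fully conserved. The
    (gap-free) reference row is the first sequence.
    """
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    columns = []
    for _ in range(length):
        if rng.random() < variable_fraction:
            pool = rng.choice(aas, size=n_column_symbols, replace=False)
            col = [str(pool[int(rng.integers(n_column_symbols))]) for _ in range(n_seqs)]
        else:
            col = [str(rng.choice(aas))] * n_seqs
        columns.append(col)
    rows = ["".join(columns[j][i] for j in range(length)) for i in range(n_seqs)]
    if gap_fraction:
        gapped = []
        for i, row in enumerate(rows):
            if i == 0:
                gapped.append(row)  # reference stays gap-free
                continue
            chars = [
                "-" if rng.random() < gap_fraction else c for c in row
            ]
            gapped.append("".join(chars))
        rows = gapped
    ids = [reference_id] + [f"seq_{i:03d}" for i in range(1, n_seqs)]
    return Alignment(
        sequences=rows,
        ids=ids,
        reference_id=reference_id,
        first_residue_number=first_residue_number,
    )
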