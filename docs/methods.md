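# Methods

## Enrichment scoring

The fitness of a substitution is the log10 selected/unselected count
ratio, centered by the median log ratio of the synonymous wild-type
alleles. The normalizer is deliberately a median over a large internal
null set (real Ras libraries carry over a hundred synonymous wild-type
alleles): a single reference sequence makes the legacy, template-centered
score fragile to counting noise and outliers, and the two scores differ
by exactly one additive constant per dataset, which the test suite
asserts algebraically.

Zero counts: by default a pseudocount of 1 is added to the selected and
unselected counts of every variant and wild-type allele before forming
ratios (the underlying studies do not state a policy). The pseudocount
is configurable, including 0, which drops zero-count alleles instead.
Note the exact depth-invariance of the score (rescaling one sample's
counts by a constant) holds only with pseudocount 0; with a pseudocount
it holds to O(1/count).

A variant present in the selected sample but absent from the unselected
one cannot be scored and is reported as missing (NaN), which is distinct
from a score of 0.

### Baseline correction

In leaky selections (e.g. leaky antibiotic-resistance expression in the
bacterial assay) every cell propagates at some floor rate, so
non-functional variants accrue selected counts proportional to their
unselected abundance. The stop-codon variants estimate that floor: with
x̃_f the median selected/unselected ratio over stop-codon variants,
corrected selected counts are c_sel − c_unsel·x̃_f. Non-positive
corrected counts are floored at 1 (configurable); they sit at the
detection limit of the screen. The correction is applied to synonymous
wild-type allele counts as well, keeping the internal null consistent
with the same leak model. It is refused (with a descriptive error) when
no stop-codon variant has a nonzero unselected count — the right
behavior for screens where stop codons grow like typical variants and
the floor is unidentifiable.

Effect on the score distribution: before correction, all variants below
the floor pile up at the leak level, giving a bimodal distribution;
after correction they spread into a left tail and the distribution is
unimodal with a detection-limit shoulder. The test suite checks this on
simulated leaky screens with a mode-count heuristic: kernel-density
local maxima count as modes only at ≥30% of the principal peak density,
so the low-mass floored shoulder is not a mode but the pre-correction
leak pile-up is. The 30% cut-off is a fixed package constant chosen to
separate "substantive second mode" from "shoulder"; it is deliberately
not exposed as a tuning knob of the correction itself.

### Post-processing

Codon-level scores are averaged (unweighted) into amino-acid cells;
all-codon-missing cells stay missing. Matrices are then centered on the
mode of the wild-type allele score distribution — estimated by a
Gaussian KDE (Scott plug-in bandwidth) argmax on a 512-point grid, which
is deterministic and robust to the left/right shoulders these
distributions develop — and rescaled so the SD over all non-missing
substitution scores equals a configurable target (default 1.0; the
constant used in the original datasets is unpublished). The stop-codon
row is excluded from the SD used for scaling and from per-position
means, which summarize amino-acid substitutions only. Replicates are
scored separately and averaged per cell.

## Epistasis and site classes

ΔΔE is the cellwise short-minus-long difference over the shared position
range, missing wherever either input is missing; per-position means
average the defined substitutions. A substitution is *activating* when
its score exceeds k·SD (default k = 1.5) of its own centered matrix; a
site is a *stability-dependent gain-of-function* site when some
substitution is activating in the long construct but not in the short
one. For the short-construct side the complement of the activating set
is used ("neutral or deleterious"); a separate lower threshold would be
an alternative reading, but the complement rule is the simpler and is
what the classification here implements. Because the k·SD rule is
relative to each matrix's own spread, adding a constant to both matrices
changes classifications only after re-centering is rerun.

## ROC benchmarking

Positives from a cancer-like database require ≥5 observations (counts
pooled across isoforms by default; a per-isoform mode is provided);
negatives are population-database variants minus pathogenic-flagged
entries minus anything also qualifying as positive. Variants in neither
set are unlabeled and excluded — absence from a cancer database is not
evidence of neutrality, both because activating variants can trigger
senescence and because some substitutions need multiple nucleotide
changes. Alternatively, a reference screen defines the truth set via the
1.5·SD rule with all other scored variants as negatives. The curve is a
full threshold sweep (higher score ⇒ predicted activating) with
trapezoidal AUC, which equals the tie-aware pairwise rank statistic;
the suite verifies this against a brute-force double loop.

## Two-state stability fits

Folded fraction: f(u) = logistic((ΔG − m·u)/RT), midpoint Cm = ΔG/m.
R = 8.314×10⁻³ kJ/(mol·K); default T = 298.15 K (assays at 25 °C).
The signal mean is (s_unf + b_unf·u) + (s_fold + b_fold·u)·f(u) — an
unfolded baseline plus a folded component modulated by the folded
fraction, exactly the parametrization the synthetic generator uses, so
fits and simulations share one forward model.

CD titrations are fit by maximum likelihood with normal noise whose
scale is linear in urea (σ_c + σ_p·u). The optimizer is staged:
multistart nonlinear least squares for the six mean parameters with
midpoint guesses on an even grid (initial m = 5 kJ/(mol·M), a typical
small-protein value; the original fitted m-values are unpublished), ML
estimation of the two noise parameters from residuals, one reweighted
mean pass, then a joint L-BFGS-B polish of all eight parameters under
positivity bounds. Standard errors for ΔG and m come from the
weighted-least-squares covariance at the fitted noise law with the
usual residual degrees-of-freedom correction (observed-information
Hessian as fallback). A fit is rejected — with a diagnostic error —
when the midpoint leaves the titration range, the folded amplitude at
the midpoint is under twice the noise, parameters pin at bounds, or
the model fails to beat a straight line by a likelihood ratio of 10:
all symptoms of a curve with no transition.

Pulse-proteolysis titrations use constant baselines, constant noise and
the m-value fixed to its CD estimate, making maximum likelihood
equivalent to nonlinear least squares in (ΔG, s_unf, s_fold); σ is
estimated from residuals and SEs from the covariance. Replicate-level
summaries (mean ± SD of ΔG and Cm across curves) are provided for
multi-curve experiments.

The ligand (GDP) contribution to apparent stability is implemented as
RT·ln((1 + [GDP]new/K_D)/(1 + [GDP]old/K_D)), with the K_D → 0 limit
RT·ln(new/old) supported exactly. The natural logarithm is used: the
reported ~2.53 kJ/mol for raising GDP from 36 to 100 µM at 298 K equals
RT·ln(100/36), not RT·log10(100/36) (≈1.10) — the log10 appearing in
some printed versions of the formula is inconsistent with its own worked
value, and this package follows the number.

### Recovery-study design

Calibration is assessed by simulating titrations at the reported
construct stabilities (CD ΔG = 29.9 kJ/mol with σ_c set to 2% of the
folded amplitude and a small proportional term; proteolysis
ΔG = 24.3 kJ/mol with σ = 3% of the amplitude) and checking that the
truth falls within ±2 estimated SE in ≥90% of 100 seeded runs. Both
studies use the generator's default 25-point 0–8 M urea grid: with ~9
residual degrees of freedom (a 12-point grid) the ±2·SE interval cannot
exceed ~92% coverage even for a perfectly calibrated estimator, whereas
the 25-point design is comfortably calibrated (~95% measured). Measured
bias of recovered ΔG is well under 0.5 kJ/mol in both assays.

## Exchange kinetics

Decays are fit to A·e^(−kt) (no offset by default — an optional additive
offset serves plateauing MS-style data) with log-linear initialization
followed by nonlinear least squares; R² is computed against the
mean-only model and fits are kept strictly when R² > 0.7. Degenerate
series (constant values, non-positive fitted rates) are flagged
not-kept rather than raising. Fold changes are k_mut/k_WT ratios,
defined only between kept fits, and binned at 1/3, 1/2, 2 and 3; the
exact 2× and 3× boundaries belong to the inner bin (the published bin
wording is ambiguous there, and its description of the extreme slow bin
is internally inconsistent — the monotone reading is implemented).

## Conservation entropy

Per-column Shannon entropy in bits (base 2; the base used in the
original analysis is unstated), with gaps excluded from the frequency
denominator by default (gap-as-21st-symbol selectable) and no
sequence-identity weighting or pseudocounts. Columns are mapped to
reference residue numbering via a designated gap-free-read reference
row; positions falling on reference gaps are reported missing.

## Synthetic-data generators

The screen generator draws library abundances log-normally (σ = 0.3 for
variants; 120 synonymous wild-type alleles at σ = 0.5), samples
unselected counts as Poisson at a configurable expected depth (default
200 reads/variant; real per-sub-library depths are unpublished, and the
depth is the knob every consistency test varies), applies growth factors
10^fitness + 10^leak (stop codons grow at the leak rate alone; leak
default −2 decades, None disables it), renormalizes the selected sample
to a target depth — sequencing reports frequencies, not absolute growth,
which is what makes depth-invariance testable — and Poisson-samples
again. `leaky_screen_fitness` provides a realistic landscape for
leak-regime studies: a small truly-lethal class (4%), a continuum of
partial loss-of-function (36%, uniform over −2..−0.3 decades), and a
near-neutral bulk; the continuous deleterious class is what real
enrichment distributions show and is required for the post-correction
distribution to be unimodal rather than floor-spiked.

What the generators do not emulate: PCR jackpots, position- or
sequence-dependent sequencing error, epistatic double mutants,
replicate-to-replicate selection-pressure drift, or real database
ascertainment biases. Passing tests therefore demonstrate correctness of
the estimators under the stated sampling models, not robustness to every
artifact of real screens.

All generators are deterministic given their seed (NumPy
`default_rng`).

## Numerical choices and degenerate inputs

* Overflow-safe logistic via `scipy.special.expit` everywhere the folded
  fraction is evaluated.
* Median and mode estimators are deterministic; KDE mode estimation
  needs ≥3 values and a nonzero spread.
* Empty read sets, missing wild-type alleles, missing stop codons,
  zero-variance score distributions, degenerate truth sets and
  transitionless titrations all raise typed, descriptive errors; read
  classification itself never raises (unreadable/multi-codon are
  categories, excluded from counting and tallied).
* Reads with two or more non-synonymously differing codons, or one
  non-synonymous change plus synonymous hitchhikers, are excluded from
  counting: a single-codon library cannot attribute them, and the
  conservative exclusion is a package decision where the original
  counting rule is unstated.

## Known limitations

* Refractive-index → urea conversion is not implemented; urea molarity
  is an input.
* The CD baseline parameters are weakly identified when the transition
  midpoint sits near the end of the titration range (they trade off
  against each other); ΔG remains identified, which is why results carry
  standard errors.
* Isoform handling in the variant databases is a plain text tag; no
  attempt is made to reconcile residue numbering across isoforms beyond
  the (position, wt, mut) key.
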