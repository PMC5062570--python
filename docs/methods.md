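# Methods notes

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## SILAC competition calling

Peptide observations are heavy/light ratios from a mixed heavy+light
proteome after competitor pretreatment of one channel. The working quantity
is the *competition ratio* (control channel over competed channel): raw H/L
for replicates with the competitor in the light culture, 1/(H/L) for
label-swap replicates. Ratios are strictly positive and multiplicative, so
background noise is modelled (and assumed) log-normal.

Aggregation reports the median over all pooled peptide observations of a
protein; per-replicate medians are retained separately and their sample
standard deviation (ddof = 1, ratio scale) drives the variability filter.
The headline median is taken over pooled peptides rather than over
replicate medians: the peptide-count filter ("at least five total
quantified peptides") refers to the pooled pool, and pooling is the reading
most robust to unbalanced replicates. Both values remain available in the
summary table.

Filter semantics are deliberately boundary-exact: 5 peptides pass ("less
than five" excluded), s.d. exactly 3.0 passes (">3" excluded), a protein
seen in one replicate has an undefined s.d. and fails. Target calls require
a median strictly greater than the 2.0 fold threshold. Even-count medians
use the mean of the two central values (numpy convention).

## Label-free PSM differential abundance

Spectral counts are treated as per-sample abundance proxies. QC order:

1. peptide ion-score filter (score < 20 removed, exactly 20 kept), then
   peptide rows are summed to protein counts;
2. contaminant removal by case-insensitive pattern match on accession +
   description (defaults: keratin, hemoglobin, histone; extendable);
3. pairwise-linearity sample QC: squared Pearson correlation of protein
   count vectors for every sample pair; a sample whose *median* pairwise r²
   is strictly below 0.8 is removed (worst first), recomputing after every
   removal until stable. The median-of-pairs form was chosen over
   correlation-to-a-reference because it needs no designated reference and
   is insensitive to a single bad partner. r² is computed on untransformed
   counts (a log-transform flag exists).

Eligibility: detected (count > 0) in ≥4 samples per condition and mean ≥5
PSM in both conditions. The test is Student's two-sample equal-variance
t-test (Welch by flag), two-tailed, on per-sample counts with technical
replicates treated as samples. Significance: eligible, max(fold, 1/fold)
strictly > 1.5, raw p < 0.01. Benjamini–Hochberg adjusted p-values are
reported as an extra column for modern reuse but do not affect the call,
which follows the raw-p convention of the assay this reimplements. A zero
vehicle mean with nonzero treated mean yields an infinite-fold sentinel;
eligibility and p remain evaluable.

## Densitometry, 4PL fits, shifts and windows

Percent inhibition = 100·(I_DMSO − I)/(I_DMSO − I_block), using each gel's
own anchors, which cancels scanner gain exactly (affine invariance is a
tested property). Values slightly outside [0, 100] are retained — clipping
would bias the fit.

The 4PL is fitted by least squares over (log₁₀ IC₅₀, hill, top, bottom)
with top/bottom box-bounded to [−20, 120]% (wide enough to be effectively
unconstrained for real curves, tight enough to stop the optimizer wandering
on degenerate data) and hill in [0.05, 10]. Initialization: the
concentration whose response is nearest the half-range, hill 1. Flat series
(<5 percentage points of dynamic range) and optimizer failures return
`converged=False` rather than raising. The IC₅₀ confidence interval is
asymptotic on the log scale from the Jacobian-based covariance. Replicates
are pooled after per-replicate normalization and fitted jointly;
per-replicate fits are a trivial loop for callers who want dispersion.

Censored potencies are `Bound` objects throughout: ">100 µM"/140 nM gives a
">714-fold" shift, never a point value; a point numerator over a
lower-bound denominator flips to an upper bound; '>'/'>' ratios raise
rather than guess a direction.

## Occupancy and separation

Occupancy% = 100·(r_p + r_m)/(1 + r_p + r_m) with r = C_u/IC₅₀ per species,
maximum 100%, reducing exactly to 100·r_p/(1 + r_p) when the metabolite
term is zero. All concentrations are molar internally; unbound
concentration is fu × total with fu = buffer/plasma from equilibrium
dialysis (clipped into [0, 1] with a warning). Average unbound
concentration over the dosing interval is an *input*; no PK modelling is
done here.

Separation between outcome classes is the exact order statistic: separable
iff max(negative occupancies) < min(positive occupancies), with the open
interval between them reported as the set of admissible thresholds. This is
equivalent to a brute-force scan over all candidate thresholds (tested as a
property) and makes "no separation" a first-class, reportable result — the
point of the negative controls (enzyme-scale IC₅₀s, BACE potencies).

## Fragment ions and site localization

Monoisotopic residue masses; proton 1.007276 Da, water 18.010565 Da.
b_k(1+) = Σ first k residue masses (+ modification deltas) + proton;
y_k adds water; higher charges via (neutral + z·proton)/z. Only b/y series,
charges 1–2; the conservation identity b_k + y_(n−k) = MH⁺ + proton holds
for every peptide and modification placement and is property-tested.

Peak matching is greedy within a strict ±0.8 Da window: candidate
(ion, nearest-peak) pairs are sorted by absolute error (ties to lower
ordinal) and accepted while both the ion and the peak are unused.
Localization intersects interval constraints — shifted b_k ⇒ site ≤ k,
unshifted b_k ⇒ site > k, shifted y_k ⇒ site ≥ n−k+1, unshifted
y_k ⇒ site ≤ n−k — and errors on an empty intersection, naming the
conflicting ions. When localizing against a spectrum, plain and
adduct-shifted candidate ions compete in a *single* matching pass so one
peak can never count as evidence for both series; near-isobaric b/y pairs
(e.g. b1 of Met vs y1 of Leu, 0.046 Da apart) otherwise create false
conflicts at a 0.8 Da tolerance.

## What the simulator emulates (and what it does not)

- **SILAC tables**: background proteins at true ratio 1 with log-normal
  peptide scatter, σ = 0.15 by default — chosen so that ≥95% of background
  protein medians fall in the 0.5–2.0 band that real background occupies;
  planted targets scatter around their true ratio; 4 replicates with one
  label swap. Peptide counts uniform 5–12 per protein per replicate.
- **PSM matrices**: Poisson counts around per-protein means (uniform
  5–80; planted-fold proteins at a defined base mean of 50 so a plant is a
  statement about fold, not abundance), 6 vs 6 layout (two technical
  replicates of three subjects), optional gamma overdispersion knob,
  named keratin/hemoglobin/histone contaminant rows, and an optional
  degraded sample whose counts are permuted across proteins — destroying
  pairwise linearity while preserving the count multiset.
- **Densitometry**: exact 4PL plus Gaussian intensity noise (default s.d.
  5% of the anchor span), 10 points spanning ±2 decades around the true
  IC₅₀, anchors included.
- **Cohorts**: four compounds with heterogeneous enzyme/cell shifts (86×,
  95×, 2×, 34×) and fixed unbound exposures; outcome positive iff cellular
  occupancy exceeds 80% (deterministic default; Bernoulli incidence
  optional). The 2×-shift compound dosed high is what makes the enzyme
  scale non-separable.
- **Peak lists**: every theoretical b/y ion of the (modified) peptide as a
  peak, optional decoys and intensity jitter.

Randomness flows from a single seed through per-table child streams
(`SeedSequence.spawn`), so regenerating one table type never perturbs the
others and fixture files are byte-identical across runs.

Not emulated: raw spectra and search-engine behaviour (identification FDR,
missed cleavages, ratio compression), inter-protein abundance correlation,
batch effects, PK time courses, dose–incidence stochasticity beyond the
simple Bernoulli option. Passing tests therefore demonstrate correctness of
the downstream statistics under clean generative assumptions, not
robustness to upstream search artefacts.

## Problem sizes and runtime

Defaults keep everything desk-scale: 100–200 proteins for SILAC recovery
runs (50 seeds in a few seconds), 4,000–10,000 proteins for null
calibration of the t-test, 10-point titrations, 7-study cohorts. These are
the package's test conditions; all thresholds are the assay defaults and
none were altered per dataset.

## Known limitations

- The t-test on counts is the faithful reimplementation of the original
  analysis; for new designs a count model (negative binomial) would be
  preferable, and the BH column is provided for that transition.
- Asymptotic IC₅₀ confidence intervals understate uncertainty for poorly
  constrained tops/bottoms; a profile-likelihood CI would be better there.
- Localization assumes a single adduct per peptide and noiseless charge
  assignment; doubly charged evidence is computed but localization
  constraints treat ion ordinals identically across charges.
- The separation analysis is deliberately threshold-based and
  non-parametric; it does not model incidence rates or dose within cohorts.
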