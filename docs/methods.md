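# Methods

## Mass arithmetic

All masses are neutral monoisotopic masses: the sum of most-abundant-isotope
masses over the elemental composition. Isotope masses come from the NIST
table distributed with pyteomics (`pyteomics.mass.nist_mass`); carbon is
exactly 12 by the definition of the unified atomic mass scale, and the
proton mass constant is the CODATA value 1.00727646677 Da. Average masses
are never used. Ionization is restricted to singly charged [M+H]+ and
[M−H]− adducts — the two modes of the emulated acquisition — and m/z values
are normalized to neutral mass on load. Formula addition is exact integer
arithmetic, so mass additivity holds to floating-point rounding (≤ 1e-9 Da,
property-tested).

## Transformation rules

A rule is a named elemental gain/loss with a phase label. The default set
covers the chemistry such a screen is built to detect on propranolol-like
parents:

| rule | phase | delta |
|---|---|---|
| hydroxylation | I | +O |
| desisopropylation | I | −C3H6 |
| desaturation | I | −H2 |
| reduction | I | +H2 |
| hydration | I | +H2O |
| o_dearylation | I | −C10H6 |
| glucuronidation | II | +C6H8O6 |
| sulfation | II | +SO3 |

Enumeration walks every feasible ordered rule chain up to a depth limit
(default 2), rejects applications that would drive an element count
negative, deduplicates products by formula while retaining every distinct
route, and suppresses the parent even when a chain nets to zero. The
pipeline default additionally allows at most one phase II step per chain and
requires it to be terminal: conjugates are excreted rather than further
functionalized, and the constraint curbs combinatorial blow-up. Both
constraints are parameters, not hard-coded; the plain enumerator imposes
neither. Rule sets are user-overridable via YAML.

One naming note: the doubly oxygenated product at 293.163 Da is modelled as
hydroxylation + hydration (+O +H2O → C16H23NO4), since +2O (C16H21NO4,
291.147 Da) is a different mass; reports carry the mass-consistent formula.

## The filters

* **Presence threshold.** "Signal" defaults to any explicit area > 0; a
  configurable noise floor can replace the 0. An absent (blank) cell is a
  non-detection — distinct from an explicit zero in table semantics, though
  both count as "no signal" in presence tests.
* **Filter 1** counts detections across all non-excluded control samples,
  positive and negative alike (neither receives the parent compound), and
  removes features detected in more than one.
* **Filter 2** uses the mean over non-excluded highest-dose replicates in
  the numerator and the mean over non-excluded negative controls in the
  denominator, with non-detects as zeros on both sides: for enrichment
  purposes a non-detect is a true zero abundance. Positive controls are
  excluded from the denominator — they received a different compound and
  their matrix could mask genuine enrichment. The boundary is strict:
  EF ≤ 10 is removed, EF exactly 10 fails. Replicates flagged for lethal or
  severe morphological endpoints are dropped before anything is counted.
* EF is a ratio of means, hence invariant under any global rescaling of
  areas (property-tested); per-sample internal-standard normalization, if
  used, should be applied before loading.

Filters 1 and 2 are independent predicates on a feature, so their
application order cannot change the surviving set (tested). Funnel counts
(raw → suspect → post-filter-1 → post-filter-2) are monotone by
construction.

## Rank statistics

Spearman's r_s is Pearson's correlation on midranks. The two-sided p-value
is exact — full enumeration of the n! pairings — for n ≤ 8, and a seeded
9999-draw Monte-Carlo permutation with the (b+1)/(m+1) correction above
that. scipy's `spearmanr` is used in the test suite as an independent
oracle (exhaustively for all pairings of n ≤ 6), never as the
implementation.

* **Dose gradient:** r_s of (dose, area) over all non-excluded dosed
  samples, non-detects as zero. The default pass threshold r_s ≥ 0.6 is a
  deliberate quantification of an inherently qualitative "increases with
  dose" judgement and is flagged as heuristic; a feature detected only in
  the top dose group still passes it when replicate counts are full.
* **Cross-dataset linking:** two features (one per dataset, paired by
  sample) are the same substance when r_s ≥ 0.83 and p ≤ 0.005. When r_s
  already fails, the permutation p cannot change the verdict and is skipped
  (reported NaN). At the design's 96 paired samples, independent features
  essentially never link (type-I rate bounded in the acceptance suite by a
  binomial envelope at α = 0.005).

## MS2 similarity

The scorer is a √intensity-weighted cosine: peaks of the two spectra are
matched greedily (smallest m/z difference first, each peak used once,
tolerance 0.01 Da default), and the score is Σ√(I_q·I_r) over matched pairs
divided by √(ΣI_q)·√(ΣI_r) over all peaks. This is symmetric, bounded in
[0, 1], equal to 1 on self-comparison, and invariant to uniform intensity
scaling (all property-tested); the √ weighting de-emphasizes dominant base
peaks, standard practice in spectral library matching. Spectra whose
retention times differ by more than the window (default 0.2 min) are
rejected outright — a rejection is not a score of 0. The scorer sits behind
a single function so alternative schemes can be swapped in. Similarity
≥ 0.90 against an authentic standard counts as a positive match, with the
boundary inclusive.

Fragment-annotation fractions (the FISh-style statistic) score how many
observed MS2 peaks fall within tolerance of a user-supplied candidate
fragment mass list; in-silico fragment generation itself is out of scope —
the arithmetic is ours, the candidate lists come from any external
predictor or curation.

## Confidence levels

Rules fire in order: standard match (similarity ≥ threshold and |ΔRT| ≤ 0.1
min) → CL 1; library/in-silico match at threshold → CL 2; MS2 present with
partial evidence → CL 3–4; no MS2 → CL 5. The standard RT window default of
0.1 min is chosen to stay below the ~0.075 min separation of close
positional isomers, so a standard cannot confirm its isomer. Detection in
the dosing medium or an in-source-fragment flag (co-elution with the parent
plus a fragment mass match) makes the assignment tentative without changing
the level. Strengthening evidence can only improve a level (tested), and
each assignment carries the ordered list of fired rules.

## Synthetic study design

The generator reproduces the statistical structure the screen assumes, with
defaults fixed at the emulated design:

* 6 doses (0.050, 0.49, 12, 62, 4550, 46540 μg/L), 12 replicates each,
  plus 12 positive- and 12 negative-control embryos; two datasets
  (HILIC_pos, C18_neg) sharing the same organisms.
* 2000 background features per dataset: i.i.d. log-normal areas (median
  5×10⁴, log-sd 1.0, per-cell CV 0.4), detected per cell with probability
  0.97, no dose structure.
* 8 spiked bioTPs with the rule chains of the products the workflow
  targets; mean area at the top dose 10⁶ scaling as dose^γ (γ = 1), with a
  shared biological log-normal factor (CV 0.3) and an independent
  per-dataset technical factor (CV 0.1); absent from every control; feature
  mass jittered by ≤ 1 ppm of truth.
* 20 control-only contaminants, 5 dosing-medium contaminants (dose-scaled,
  masses recorded in a medium-blank list), and per-replicate Bernoulli
  dropout with rates 3/12 and 4/12 at the two top doses (lethality).
* MS2 spectra for spikes contain the 8 candidate fragment masses plus 8
  low-intensity uniform noise peaks; authentic standards (intensity-jittered
  fragment spectra at matching RT) are emitted for 5 of the 8 spikes, one
  spike has no MS2 at all — so an end-to-end run exercises CL 1, CL 3–4 and
  CL 5 together.

Generation is bit-reproducible from the seed, and every feature's class and
true chain land in a truth table from which spike recall, chain correctness
and false-positive counts are computed.

What the generator does **not** emulate: retention-time drift and
alignment errors, adduct/isotope grouping artifacts, correlated background
(matrix) structure, censoring of low-abundance peaks by dynamic exclusion,
and in-source fragmentation. Passing the synthetic acceptance runs
therefore demonstrates the correctness of the filtering and scoring logic
under the assumed data model, not instrument-grade performance; on real
data the funnel's intermediate counts depend on the upstream peak picker.

## Problem sizes and numerics

The default synthetic study (2 × ~2030 features × 96 samples) screens in
about a second on one core; the parameter-recovery acceptance test repeats
it over 20 seeds. Permutation p-values are fully vectorized; exact
enumeration is used automatically for n ≤ 8. Ties use midranks everywhere.
ppm errors are computed relative to the theoretical (predicted) mass.
Degenerate inputs are explicit: zero-variance rank vectors return NaN,
features absent everywhere give EF = 0, empty spectra cannot be scored, and
groups losing all replicates to exclusion contribute nothing downstream
(with a logged warning).
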