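# Methods

This note records the models, conventions and numerical choices behind
`reflqc`, in the spirit of the model documentation that simulation and
statistics packages ship alongside their APIs.

## Scope and intent

The package operates strictly at the reflection level: its inputs are
unmerged intensity observations (h, k, l, batch, I, σ, d) and instrument
header text.  Spot integration, profile fitting, indexing, geometric
post-refinement, absorption/scale-factor refinement and everything
image-geometric are out of scope; headers are line-oriented ASCII
fixtures that carry the *semantics* of the real R-AXIS and Bruker binary
formats without reproducing their binary layout.

## Header dialects and pixel codecs

Fixture grammar conventions (documented here because the real formats
leave them implicit or undocumented):

* R-AXIS `a3fPhi a b c` = (start, offset, rotation-range-per-frame); only
  the range per frame is consumed downstream.  `a3fCircle` carries
  (ω, χ, swing θ).  `ImhCompression`'s numeric value is the overflow
  scale ratio R (default 8): a stored 16-bit value v ≥ 32768 decodes to
  (v − 32768)·R.  Values not on that grid encode to the nearest grid
  point and the encoder flags the result lossy.  No gain key exists in
  the native header; when absent the parser assumes 1.0 ADU/photon and
  records the default in the missing-fields ledger.
* Bruker `ANGLES` carries (2θ, ω, ϕ, χ); `AXIS: 3` selects ϕ (2 = ω).
  The gain is the first numeric field of `CCDPARM` and the baseline
  offset the second field of `NEXP`.  Stored bytes equal to 255 are
  sentinels consuming overflow-table entries in raster order; the
  baseline offset is subtracted after substitution.
* Optional records (`fGain`, `a4cAxes`, `a4cGonio`, `SENSE`) let a
  fixture be fully specified; the audit is defined so that its findings
  list is empty exactly when nothing needed downstream is missing, and
  removing a record can only grow the list.

## Symmetry

Only the two Laue classes relevant to pseudo-tetragonal protein crystals
are implemented: 4/mmm (16 operators) and mmm (8), generated from
{−I, m_x, 4_c} and {−I, m_x, m_y} and verified closed in the test suite
(with gemmi's symmorphic space-group operations as an independent
oracle).  The asymmetric-unit representative of an orbit is its
lexicographically greatest member — a total, convention-free choice.
Unique-reflection enumeration (the completeness denominator) is
Laue-level: space-group systematic absences are deliberately not
removed, because all merging statistics here are defined at the Laue
level.  Only orthogonal cells are supported (1/d² = h²/a² + k²/b² +
l²/c²); s = 1/(2d) is the sinθ/λ coordinate.

## Synthetic data generator

The generator emulates the statistical structure the downstream analysis
assumes — not images, profiles or geometry.

* **Intensities.** Per-unique true intensities are exponential
  (acentric Wilson) with mean C·exp(−2Bs²).  Centric reflections are not
  distinguished; this is adequate for exercising every downstream
  statistic and is noted as a simplification.
* **Symmetry breaking.** The unique set is generated under mmm.  For
  each 4/mmm-equivalent pair of mmm uniques, (h,k,l) with h > k is drawn
  freely and its partner (k,h,l) is set to τ·I_first + (1−τ)·I_indep.
  τ = 1 restores exact tetragonal equality; τ < 1 decorrelates the pair
  while preserving the marginal mean.
* **Noise.** Gaussian with variance K_true·(k₀ + I_true) +
  (g_true·I_true)², where k₀ = σ²_dark + σ²_read + σ²_bg.  Gaussian
  rather than literal Poisson counts: the analysis operates in the
  large-count regime where the variance decomposition, not discreteness,
  is the operative model.  The *delivered* sigma is √(k₀ + max(I,0)) —
  first two terms only, mirroring what integration programs report — so
  the (K, g) refinement has a real mismatch to recover.  Analytically
  the refinement should find K ≈ K_true and g ≈ g_true/√K_true: matching
  K·[(k₀+I) + (g I)²] against K_true·(k₀+I) + (g_true I)² term by term
  gives K = K_true and K·g² = g_true².
* **Sampling.** Each unique is included with probability p_observe
  (whole-reflection incompleteness, e.g. beam-stop shadowing and
  detector gaps); included uniques receive Poisson(target_redundancy)
  observations, so the empirical multiplicity of observed uniques is
  essentially the target.  A fully noiseless configuration would deliver
  σ = 0; such observations get unit sigmas so the output stays
  mergeable.
* **Ice.** Observations inside configured windows are multiplied by an
  excess factor with a contamination probability, with no sigma
  inflation, and the ground-truth flag is retained for recall tests.

**Defaults as study conditions.**  Cell 78.5/78.5/37.3 Å (tetragonal
lysozyme-like), d range 20–1.7 Å, B = 15 Å², C = 1000 ADU, redundancy 20
(laboratory datasets of this kind run roughly 12–31), σ_dark = σ_read =
3, σ_bg = 5 ADU, gain 1 ADU/photon, g_true = 0.03 and K_true = 1
(refined values typically fall in 0.02–0.04 and 0.7–1.5), τ = 1,
p_observe = 0.95, ice off.  Contamination studies use windows at
3.90/3.67/3.44 Å (standard hexagonal-ice spacings), half-width 0.05 Å,
excess ×10, fraction 0.3 — the excess and fraction are package
conventions chosen to represent visible but not pathological icing, not
measured values.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: batch-to-batch scale variation and
absorption, crystal slippage and orientation drift, detector
non-uniformity and its miscorrection, profile-truncation effects,
centric statistics, anomalous differences.

## Merging and statistics

Group means are inverse-variance weighted (w = 1/σ²), I_mean = Σw·I/Σw,
σ_mean = (Σw)^(−1/2); weighting follows the practice of the scaling
programs whose outputs these statistics mirror.  Groups with a single
observation are excluded from the R-factor sums but count toward
completeness and redundancy.  Merged intensities may be negative; ⟨I/σ⟩
uses signed values and averages per group.  Resolution shells are
equal-group-count (default 10), ordered by d; the last shell is the
"outer resolution shell" quoted in brackets in reports.  Per-shell
completeness bins the reference uniques by midpoint edges between
adjacent shells so each reference member lands in exactly one shell.

## Error model

χ² is the observation-count-weighted normalised deviation of equivalents
from their group means,

    χ² = Σ_h [n_h/(n_h−1)] Σ_i (I_i − ⟨I⟩_h)²/σ_i²  /  Σ_h n_h ,

which has expectation 1 under correctly scaled sigmas (the n/(n−1)
factor undoes the variance deflation of deviations measured about the
group's own mean).  The per-group terms are exposed separately.

Refinement minimises Σ_bins (χ²_bin − 1)² over (K, g) of
σ²_new = K·[σ² + (g⟨I⟩)²], with groups in 10 equal-count bins by ⟨I⟩.
Because χ²_bin(K, g) = f_bin(g)/K, the optimal K for fixed g is the
closed form K = Σf²/Σf, so the search reduces to a deterministic 1-D
bounded minimisation over g ∈ [0, 0.2] (coarse grid then Brent polish),
with K clipped to [0.1, 10].  ⟨I⟩ — both as the deviation reference and
inside (g⟨I⟩)² — is held at the delivered-sigma weighted mean during the
search; group means are recomputed with corrected weights when the model
is applied.  Robustness guard: observations deviating more than 10
delivered sigmas from their group mean are excluded from the refinement
sums (iteratively, means recomputed), so gross outliers such as ice
spikes calibrate nothing; without this, planted ice drives K and g to
their bounds and the subsequent 4σ rejection goes blind.  Degenerate
input (no scatter) falls back to K = 1, g = 0 with `converged = False`.
The reported χ²_before is computed on the untrimmed input.

Outlier rejection is two-sided at |I − ⟨I⟩|/σ > 4 (threshold and
iteration cap configurable; the canonical rule is one-sided, but a
measurement far below its equivalents is equally invalid).  The first
pass measures deviations from the group *lower quartile*: contaminants
only ever inflate intensities, and in heavily affected groups they drag
the weighted mean — and even the median — upward, which would flag the
healthy equivalents instead.  Subsequent passes use the weighted mean of
currently unflagged members and re-evaluate *all* members of groups with
≥ 2 survivors, so wrongly flagged observations are re-admitted; flags
freeze for groups reduced to a single member.  Iteration stops at a
fixed point or after 5 passes.

## Ice-ring detection

For each candidate centre the detector compares the median merged
intensity inside the window (half-width 0.05 Å) against the median of
the two flanking windows of equal total width, on the scale of the
standard error of the median (1.4826·MAD_flank·1.2533/√n_in); windows
with robust z above 4 are flagged.  The symmetric flanking baseline
cancels the smooth Wilson falloff to first order.  Window exclusion is a
separate path from 4σ rejection — regions versus individual
measurements — and the pipeline detects windows on the *pre-rejection*
merged data, because the 4σ pass already strips most contaminated
measurements and would hide the rings.  All constants are configurable;
the candidate spacings are standard hexagonal-ice values, not fitted.

## Wilson fit and Laue decision

The Wilson fit bins merged groups with d ≤ 4.5 Å (excluding the
low-resolution non-Wilson regime dominated by solvent and gross
structure) into 20 equal-count shells over s², drops shells with
non-positive mean intensity, and regresses ln(shell mean I) on shell
mean s² by ordinary least squares; B = −slope/2 with the standard error
propagated from the regression.  At least 3 usable shells are required.

The Laue decision merges the same observations independently under
4/mmm and mmm and compares R_meas — chosen over R_merge because the two
merge trees have different multiplicities and R_meas is
multiplicity-corrected.  mmm is chosen iff
R_meas(4/mmm) − R_meas(mmm) > 0.02; the threshold is a package
convention calibrated so that clearly split residual pairs (e.g.
0.180 vs 0.130) decide mmm while the sub-0.01 fluctuations seen on truly
tetragonal data do not.  Releasing the a = b cell constraint is
indexing/geometry work and out of scope; the decision here is
intensity-statistical only.

## Pipeline

`run_pipeline` fixes the stage order simulate → merge(mmm) →
refine-errors → 4σ reject → de-ice → statistics → Wilson → Laue-check,
writes every intermediate as TSV, logs one line per stage, and is fully
deterministic per seed.  Merging for the error model is done under mmm —
the safe subgroup — so that a possibly broken tetragonal symmetry cannot
masquerade as intensity error.

## Problem sizes

Statistical tests and the acceptance script size their simulations so
the quantity under test is well determined: ≥ 5000 uniques (2.6 Å cutoff
on the default cell, ≈ 7.5k) for error-model recovery, the full 1.7 Å
range (≈ 26k uniques) for Wilson-B recovery where the fit window's s²
leverage matters, and a 3.0 Å cutoff (≈ 4.4k uniques) for the 20-seed
Laue power study, where the symmetry-breaking signal is far above
threshold and per-seed size buys nothing.

## Known limitations

* Two Laue classes only; no general space-group machinery, no twinning
  tests, no absences.
* The (K, g) target function (least squares on binned χ²) is this
  package's operationalisation; production scaling programs do not
  publish theirs, so refined values are comparable in meaning but not
  guaranteed numerically identical to any particular program.
* Merged ⟨I/σ⟩ averages per group; programs that pool observations per
  shell will print slightly different values.
* The ice detector needs enough merged groups in and around a window
  (≥ 5 each side) and a genuine local excess; diffuse or very broad
  icing will not register.
* Header support is limited to the two fixture dialects; real binary
  headers require the vendor formats.
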