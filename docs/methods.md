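# Methods

## Problem setting

An applanation-tonometry pulse device records the radial-artery pressure
signal at three palpation positions (Chon, Gwan, Cheok) under five
increasing hold-down pressures (means 37, 73, 109, 143, 184 mmHg, each held
five seconds). The diagnostic target is binary: the deficient (forceless)
versus excess (forceful) pulse quality, with expert diagnoses as reference
labels. The working hypothesis throughout is that force-related pulse
quantities — amplitudes that stay large across hold-down pressures and
positions — carry the class signal.

## Waveform preprocessing

Each record is a uniformly sampled signal of a few seconds. The chain is:

* **Despiking.** First differences are scored in robust SD units
  (median absolute deviation / 0.6745); a sample is flagged when the
  difference into it exceeds `k` robust SDs (default `k = 6`; the sample
  after an isolated spike is unflagged when it rejoins the pre-spike
  level). Flagged samples take the value of their nearest unflagged
  neighbour. A record with more than half its samples flagged is rejected.
* **Baseline correction.** Beat feet are located as local minima between
  detected systolic peaks (plus edge minima when the regions before the
  first and after the last peak are long enough to contain a foot). A
  polynomial of order 5 (reduced when few anchors exist) is least-squares
  fitted **to the foot values** and subtracted, then a natural cubic spline
  through the residual feet is subtracted, pinning every anchored foot at
  exactly zero. Fitting the trend to the foot values rather than to all
  samples keeps the beat shape out of the baseline estimate and makes the
  correction idempotent: a record whose feet already sit at zero passes
  through unchanged (to machine precision on wander-free records). With
  fewer than 4 anchors the correction falls back to a full-record
  polynomial fit with a warning.
* **Segmentation and averaging.** Beats are delimited foot-to-foot
  (peak detection uses a 0.3 s refractory window, capping the admissible
  heart rate at 200 bpm), resampled to 100 samples, aligned at their
  systolic peak (a circular shift that only wraps flat foot-region
  samples), and averaged pointwise. The pulse amplitude is
  `H = max − min` of the ensemble-mean beat — translation invariant, and
  identical to max-from-zero after foot-anchored baseline correction. The
  alternative reading (per-beat amplitude, then averaged) differs only for
  noisy records; the averaged-beat form was adopted as the standard
  ensemble-averaging convention.

Measured on the shipped generator: noise-free records recover the true
amplitude to ≲0.5% across heart rates 60–100 bpm; at the default noise
level (2 arb wander at 0.25 Hz against beat amplitudes of 4–18 arb, one
motion spike per record in expectation) the median relative amplitude error
is below 1%, comfortably inside the 5% design target.

## Pulse quantities

From the 3×5 amplitude matrix: `PP_i = max_j H_ij` (pulse pressure,
proxy for systolic-minus-diastolic), `MPA_i = mean_j H_ij`, and the
over-position aggregates ⟨PP⟩, PP^max, ⟨MPA⟩, MPA^max. Max and mean are
exact. Cohort standardization uses the sample (n−1) SD, matching the
convention of the classical statistics packages.

## Factor analysis

Principal-component extraction on the correlation matrix of the 15
amplitudes; factors with eigenvalue strictly greater than 1 are retained
(Kaiser criterion); per-factor % variance is eigenvalue/15 × 100. The
retained loadings are varimax-rotated with Kaiser row normalization
(convergence 1e−8, up to 1000 sweeps); rotation preserves communalities
and the reproduced correlation structure by orthogonality. Adequacy
diagnostics: KMO = Σr²/(Σr² + Σq²) over off-diagonal entries with q the
anti-image partial correlations (exactly 0.5 for any correlated bivariate
data — the bivariate partial correlation equals the correlation), and
Bartlett's sphericity statistic −(n − 1 − (2p+5)/6)·ln|R| on p(p−1)/2
degrees of freedom (exactly 0 at the identity). Factor scores use the
regression method, Z R⁻¹ L. Both-class pooling is assumed for the factor
step, since it precedes discrimination.

## Fisher discriminant analysis

Two groups, one discriminant: coefficients a ∝ S_w⁻¹(μ_excess −
μ_deficient), scaled so the pooled within-group score variance is one and
oriented so excess scores higher. Standardized coefficients multiply each
raw coefficient by the pooled within-group SD of its variable.
The cutoff between the class centroids is, with the default
`priors="proportional"`, the centroid mean weighted by the *opposite*
group sizes (the classical two-group rule for unequal groups, 26/44 in the
reference design); `priors="equal"` gives the plain midpoint. Ties at the
cutoff classify as excess, consistent with the "≥" convention of the
threshold rules. Diagnostics: Wilks' Λ = |S_w|/|S_t| with Bartlett's χ²
approximation, and Box's M with its χ² approximation. Leave-one-out
cross-validation refits on each n−1 subset; a fold that loses a class is
excluded with a warning.

## Threshold classifiers

The single-variable rule on a standardized quantity z uses criteria
α ≥ β: excess when z ≥ α, deficient when z < β, intermediate otherwise
(total when α = β). The mixed-variable sequential model applies a
secondary quantity with criteria γ ≥ δ inside the primary's intermediate
band; γ = δ is enforced by default so every subject receives a label, and
γ > δ is allowed only with an explicit midpoint tie-break.

The fitting procedure is a design choice of this package (the reference
analysis reports fitted criteria without a selection procedure):
exhaustive search over candidate cuts at the midpoints of sorted unique z
values (±∞ included) for (α, β, γ=δ), maximizing training accuracy with
MCC as first tie-breaker and the narrowest band |α − β| as second, then
scan order. Because the α = β plane lies inside the search space, the
fitted mixed model never trains below the best single-cut rule or the
majority-class rate. The implementation reduces the O(n³) search to
prefix-sum algebra and evaluates the full grid in milliseconds at n = 70.

MCC uses the standard zero-denominator convention (return 0); the
deficient class is the bookkeeping positive, immaterial by the swap
symmetry of MCC.

## Synthetic cohorts

The generator emulates the study conditions rather than any public data
(none exists):

* n = 70 subjects, 44 excess / 26 deficient, mirroring the concordantly
  diagnosed cohort scale.
* Class-conditional mean surfaces: the deficient 3×5 profile peaks at a
  shallow depth at Chon, intermediate at Gwan, deep at Cheok (4–13 arb);
  the excess profile is the deficient one scaled by 1.05 **plus a focal
  boost of 60% applied to one uniformly chosen position's row per
  subject** — a forceful pulse is markedly strong at its optimal depth.
  The focal component is what makes PP^max informative beyond ⟨PP⟩ in the
  band where ⟨PP⟩ is equivocal, the phenomenon the sequential model
  exploits.
* Within-class noise: additive Gaussian (SD 4.5 arb), truncated at zero,
  with a five-block latent-factor structure (Cheok-heavy, light-pressure
  Gwan+Cheok, Chon-heavy, Gwan-heavy, Chon-light; loadings 0.75–0.85)
  so that factor analysis of large cohorts recovers five blocks.
* The (scale 1.05, tilt 0.6, SD 4.5) triple was calibrated once so the
  single-cut ⟨PP⟩ rule reaches ≈75% leave-one-out accuracy at n = 70 —
  the prescribed operating point — and then frozen.
* Waveform level: a two-lobe beat template (asymmetric Gaussian systolic
  peak + dicrotic wave at 62% of the period, 22% relative height),
  200 Hz sampling, 70 bpm, sinusoidal breathing wander and Poisson motion
  spikes, all recorded in ground-truth metadata.
* Reproducibility: one root seed; each subject draws from its own
  `[seed, counter]` stream, so subsetting a cohort never perturbs other
  subjects.

What the generator does **not** emulate: sensor-array geometry and
positioning search, hemodynamic (Windkessel-type) waveform realism,
beat-to-beat morphology variability, rater disagreement structure, and
demographic covariates. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical conditions, not clinical
performance on real cohorts.

## Numerical choices and degenerate inputs

* Spike threshold default k = 6 robust SDs; constant-signal records fall
  back to a tiny epsilon scale so they pass through unflagged.
* Peak-detection prominence: 25% of the 5–95 percentile signal range.
* Beat resampling length 100; refractory window 0.3 s.
* Varimax tolerance 1e−8, max 1000 sweeps; singular correlation or
  scatter matrices are rejected with collinearity diagnostics rather than
  regularized.
* The second baseline pass on a wander-bearing record may shift flat-foot
  anchors slightly and remove residual wander (bounded, in tests, by 5% of
  the signal range); on wander-free records the chain is exactly
  idempotent.
* Box's M is reported as NaN with a warning when a group covariance is
  singular (fewer subjects than variables in a class).

## Known limitations

* The sequential-threshold search optimizes training accuracy and can
  overfit small cohorts; the narrow-band tie-break mitigates but does not
  remove this. Out-of-sample, the mixed rule beats the single rule in a
  modest majority of default cohorts (≈57% of 200 seeds), consistent with
  a small true effect at n = 70.
* Confusion-table evaluation treats expert labels as ground truth; rater
  noise (≈70% inter-rater concordance in the motivating design) bounds
  achievable accuracy but is not modelled.
* The waveform simulator's beat template is stylized; absolute amplitude
  recovery figures on real device data will depend on morphology and
  artifact structure not represented here.
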