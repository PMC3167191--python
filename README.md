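# pulsedx

Classification of the **deficient** (Xu Mai, forceless) versus **excess**
(Shi Mai, forceful) pulse qualities from radial-artery pressure waveforms,
for researchers working on the quantification of traditional pulse
diagnosis with applanation-tonometry devices.

A pulse-taking device records the radial pressure signal at three adjacent
palpation positions (Chon, Gwan, Cheok; i = 1, 2, 3) while stepping the
hold-down pressure through five levels (P₁ ≈ 37 to P₅ ≈ 184 mmHg, each
held ~5 s). `pulsedx` implements the full analysis chain:

1. **Waveform preprocessing** — despiking by robust first-difference
   thresholding with nearest-neighbour replacement, baseline correction by
   a 5th-order polynomial plus natural cubic spline anchored on the beat
   feet, foot-to-foot period segmentation, and ensemble averaging. The
   pulse amplitude at position i, pressure step j is
   `H_ij = max − min` of the ensemble-mean beat.
2. **Pulse quantities** — per position, pulse pressure `PP_i = max_j H_ij`
   and mean pulse amplitude `MPA_i = (1/5) Σ_j H_ij`; over positions, the
   aggregates ⟨PP⟩, PP^max, ⟨MPA⟩, MPA^max.
3. **Multivariate analysis** — principal-component factor analysis of the
   15 amplitudes (Kaiser criterion, varimax rotation, KMO and Bartlett
   sphericity diagnostics) and two-group Fisher discriminant analysis with
   standardized canonical coefficients, Wilks' Λ, Box's M, and
   leave-one-out cross-validation.
4. **Threshold classifiers** — the banded single-variable rule on a
   standardized quantity z (excess if z ≥ α, deficient if z < β, with
   α ≥ β leaving an intermediate band), and the **mixed-variable sequential
   model** in which a secondary quantity with criteria γ = δ resolves the
   primary's intermediate band. Thresholds are fitted by exhaustive grid
   search (accuracy objective, MCC tie-break, narrowest band preferred).
5. **Evaluation** — 2×2 confusion tables against expert labels, accuracy,
   and the Matthews correlation coefficient
   `MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`.

No public subject-level cohort exists for this problem, so the package
ships a first-class synthetic-data module: two-class cohorts of 3×5
amplitude surfaces with a five-block latent-factor correlation structure,
and raw waveform records with known beat amplitude, baseline wander and
motion spikes, all reproducible from a single seed.

## Worked example

```python
import pulsedx as px
from pulsedx.discriminant import FisherDiscriminant

labels, matrices = px.simulate_amplitude_cohort(px.CohortSpec(seed=1))
cohort = px.feature_table(matrices, labels)

lda = FisherDiscriminant.from_dataframe(cohort, ["PP1", "PP2", "PP3"]).fit()
print(lda.summary())

mixed = px.MixedThreshold.from_dataframe(cohort, primary="PP_avg",
                                         secondary="PP_max").fit()
print(mixed.summary())
```

prints

```
Fisher discriminant analysis (deficient vs excess)
====================================================
n = 70  (deficient 26, excess 44); priors = proportional
Wilks' Lambda = 0.586 (P = 0.000)
Box's M = 22.09 (P = 0.002)

variable        raw coef    std coef
PP1               0.1766      0.7648
PP2               0.1129      0.4971
PP3               0.1364      0.6312
cutoff            6.7037

training accuracy = 85.7%   MCC = 0.70

Mixed-variable sequential threshold model
=============================================
primary   : PP_avg  alpha=-0.3083  beta=-0.9906
secondary : PP_max  gamma=delta=-0.2881
n=70  training accuracy=91.4%  MCC=0.82
```

The discriminant summary shows the three per-position pulse pressures
contributing on the same order of magnitude (standardized coefficients
0.76/0.50/0.63), a significant discriminant function (Wilks' Λ = 0.586),
and the training concordance with the simulated expert labels. The mixed
model reads: classify as excess when standardized ⟨PP⟩ ≥ −0.31, deficient
when < −0.99, and otherwise let PP^max decide at its own cut −0.29; on this
cohort the second stage lifts training accuracy from the single-variable
rule's level to 91.4%.

A command-line interface mirrors the library
(`pulsedx simulate | preprocess | extract | fit | fit-mixed | classify |
evaluate | run`); `pulsedx run --config run.json` executes the whole
simulate→evaluate pipeline and writes a report grid comparing every
candidate decision variable with entire-data and cross-validated
accuracy/MCC.

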