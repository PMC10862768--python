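# Methods

## Model and procedure

`macpolar` quantifies macrophage polarization in bulk log-expression data
in four stages.

**1. StepMiner thresholds.** Each gene's values are sorted ascending and
fit with a one-step function: every split s ∈ {1..n−1} partitions the
values into a low and a high segment, each summarised by its mean, and the
split minimising the total within-segment sum of squared errors is chosen
exhaustively. The threshold SThr is the midpoint of the two segment means.
Conventions fixed here because they are not forced by the idea itself:

- among splits whose SSE ties within 1e−12 relative, the smallest split
  index wins (determinism);
- SThr sits at the midpoint of the segment means, not at a fitted crossing
  point;
- the dispersion σ is the population (ddof = 0) SD of all of the gene's
  values;
- genes with σ < 1e−12 are excluded as constant; genes missing ≥ 20% of
  samples are excluded as too missing; remaining NAs are dropped pairwise.
  Exclusions are reported, never silent.

The fit is verified in the test suite against an exhaustive brute-force
scan coded independently.

**2. Modified Z-score.** z = (x − SThr − 0.5)/(3σ). The −0.5 offset and
the 3σ denominator are applied exactly as written, on the expression
scale; the expression is read as division by (3σ), the only reading that
is a Z-score. A consequence worth knowing: normalized values are invariant
to shifting a gene's row (SThr absorbs the shift) but *not* to rescaling
it — the −0.5 does not rescale. The threshold itself is shift- and
scale-equivariant.

**3. Boolean-path composite score.** The three signature clusters form an
ordered path C13 → C14 → C3 with strictly monotone weights (−1, 1, 2);
partial paths C13 (weight −1) and C14–3 (weights 1, 2) are induced from
the same triple. The score is the weighted sum of per-cluster means of
normalized values; samples are ranked ascending (rank 1 = most reactive),
ties broken by sample id. Cluster genes are matched case-insensitively
after trimming; a cluster with no genes present is an error, not an empty
mean.

**4. Marker-gene abundance normalization.** Macrophage content varies
between bulk samples and shifts every macrophage-programme gene, hence the
score. With x the marker expression (default FCER1G) and y the composite
score, each sample-type group has bounding-box statistics S1 (score
range), S2 (marker range), S3 (mean score), S4 (mean marker), and each
sample is shifted to

    x′ = x − S3·(S2 + 1)/(S1 + 1),   y′ = y + S4·(S1 + 1)/(S2 + 1)

(the +1 guards keep the ratios finite for zero-range groups). One OLS
trend y′ = m·x′ + c is fit pooled over all samples and the final score is
the residual y′ − (m·x′ + c); samples are re-ranked.

*Whose statistics shift each sample* was a genuinely open design point and
the package's central design decision. Two modes are implemented:

- `stats_mode="reference"` (default): one bounding box — the reference
  group's (lexicographically first label unless specified) — is applied to
  every sample. The shifts are then global constants, so the final scores
  equal the plain OLS residuals of score on marker. By the algebra of
  least squares this removes abundance-mediated group differences exactly
  and leaves marker-independent differences intact. On simulated cohorts
  with a pure abundance confound (no planted polarization difference,
  groups' log macrophage fraction shifted by 1.5), the spurious group
  ROC-AUC of ≈ 0.93 falls to ≈ 0.49 after normalization, while a pure
  planted polarization difference (AUC 1.00) is untouched.
- `stats_mode="own"`: each sample is shifted by its own group's
  statistics. Because the y-shift is proportional to the group's mean
  marker expression, group-level abundance differences are *re-injected*
  into y′; measured on the same simulations this mode amplifies the
  confound (AUC 0.93 → 1.00) and erodes real signal (1.00 → 0.78). It is
  retained for comparison, not recommended.

In every mode the final scores are OLS residuals, so their mean and their
sample covariance with x′ are zero to floating-point precision, and
re-normalizing the residuals yields a slope of ~0 — both asserted in the
tests. An optional `prescale` flag min–max scales x and y to [0, 1] before
the transform (an alternative reading of the procedure's scaling step);
it is off by default because the transform is stated on the raw values.

**Statistics.** Welch's unequal-variance two-sample t-test (two-sided;
scipy), Benjamini–Hochberg step-up adjustment (statsmodels) across the
family of contrasts emitted by one `compare_groups` call, and ROC-AUC as
the Mann–Whitney probability with ties counted ½ (scikit-learn). Each is
cross-checked in the tests against a hand-coded oracle: the textbook Welch
formula with Welch–Satterthwaite degrees of freedom, a step-up BH
implementation, and O(n²) pair counting. The AUC's positive class and
orientation are explicit; an orientation-free mode reports
max(AUC, 1 − AUC).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, on
an additive Gaussian log-expression scale:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 30 reactive / 30 tolerant | samples per group |
| `cluster_sizes` | (20, 20, 20) | genes in C13 / C14 / C3 |
| `n_background` | 100 | unstructured genes |
| `polarization_effect` δ | 1.0 log-units | planted state shift (= 2·noise_sd) |
| `macrophage_fraction` | log-uniform on [0.05, 0.5] | per-sample fraction f |
| `marker_coupling` κ | 1.0 | slope of log f into programme genes |
| `noise_sd` | 0.5 log-units | per-cell Gaussian noise |
| `marker_noise_sd` | 0.05 | marker gene's (low) noise |
| `baseline_mean` | 6.0 | background log-expression level |

C13 genes gain δ in reactive samples; C14 gains δ and C3 gains 1.5·δ in
tolerant samples (the ×1.5 encodes the path ordering so planted
monotonicity along C13 → C14 → C3 is meaningful; any distinct positive
scaling would do, this one is fixed for determinism). All macrophage-
programme genes and the marker gene FCER1G gain κ·log f, making f a shared
nuisance the marker tracks. `simulate_confounded_cohort` additionally
shifts the second group's log f by a stated strength (1.5 log-units in the
package's evaluation experiments — roughly "the confounded group has ~4×
the macrophage content"), creating a spurious score–group association.
Values are chosen to be realistic for processed bulk log₂ expression:
baseline ~6, noise SD 0.5, effects of 0.5–1.5 log-units.

Everything is deterministic under the config seed (numpy PCG64 /
`default_rng`). What the generator does **not** emulate: count-level
sampling noise, gene–gene correlation beyond the shared abundance factor,
batch effects, cluster-specific marker coupling, or single-cell structure.
Passing tests therefore demonstrate the pipeline's algebra and its
behaviour under the planted-effect model, not performance on real cohorts.

## Evaluation experiment sizes

The packaged experiments use cohorts of 60 samples × 161 genes, 10–20
seeds per condition, 2,000 replicates for the type-I-error check, and
1,000 random vectors (n ∈ [2, 200]) for the step-fit oracle sweep — sizes
at which every numeric claim is checked in seconds while the multi-seed
statistics are stable.

One caveat is worth stating explicitly: with 30 + 30 samples, a null
ROC-AUC has sampling SD ≈ 0.075, so single-seed null AUCs regularly fall
outside [0.4, 0.6]; only multi-seed averages are tight at this n.

## Degenerate inputs and numerical conventions

- Floats are serialized with `repr`, so every write→read round trip is
  bit-exact; score ranks are a deterministic function of (scores, ids).
- Duplicate gene symbols (case-insensitive) are a parse error, never
  collapsed.
- Singleton groups are rejected in the bounding-box statistics; a constant
  transformed marker (x′) makes the trend undefined and raises with
  guidance.
- Welch's test requires ≥ 2 values per group and rejects two zero-
  variance groups; ROC-AUC requires both classes present.
- Plots always write a JSON sidecar of the plotted data; tests assert on
  the sidecar, never on pixels. Reports contain no timestamps so reruns
  are byte-identical.

## Known limitations

- The three cluster gene lists shipped with the package are a synthetic
  stand-in matching the generator's gene vocabulary; for real analyses
  supply the published signature clusters as a JSON file.
- The marker normalization uses a single marker gene; no multi-marker
  composite or deconvolution.
- Expression is assumed already log-transformed and normalized; no
  quantification, no GEO series-matrix parsing in the required path.
- Bulk samples only; the score is not applied per cell.
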