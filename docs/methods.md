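# Methods

## Data model

Each omics layer is a feature × sample matrix on an analysis scale —
log₂ label-free (LFQ) intensity for proteome/secretome, log₂ SILAC ratio
for the phosphoproteome, variance-stabilized (VST) levels for
transcripts. Samples span stimulation condition (CTRL, TNF, IFN,
TNF_IFN) × time (hours; 2 min is encoded as 0.0333 h) × replicate, with
headers `CONDITION_T<hours>h_R<rep>`. The sample grid must be complete;
missingness is allowed only at the value level. Per-time summaries are
replicate **medians** (replicate-level values are retained for the
differential stage). Gene symbols are upper-cased on read; phosphosites
are keyed `GENE|SITE`.

## Differential calling

For each (stimulus, timepoint) the contrast is stimulus vs control at
the matched time: log₂FC is the mean difference, s² the pooled
within-arm variance on df = n₁+n₂−2 degrees of freedom. Features with
fewer than two observed replicates in either arm are flagged untestable
and excluded from that contrast.

The empirical-Bayes prior (d₀, s₀²) is fitted once per layer across all
contrasts by moment matching on z = log s²: with
e = z − ψ(df/2) + log(df/2), the excess of Var(e) over the sampling term
ψ′(df/2) identifies d₀ through the trigamma inverse (solved by bisection
to 1e−8), and the mean of e then identifies s₀². Non-positive excess, or
d₀ above 10⁶, is reported as d₀ = ∞ (posterior variance pinned at s₀²,
normal reference distribution). Degenerate input in which every variance
is exactly equal is returned as d₀ = ∞ with s₀² equal to that common
value — the only answer consistent with a zero-spread sample. Fitting
requires at least 10 positive variances; below that the error message
advises an ordinary t-test.

BH adjustment is applied within each (layer, condition, timepoint)
family — the per-contrast convention of moderated testing; the family
definition is recorded in the output metadata. Significance requires
adjusted p < α and |log₂FC| > 1, with α = 0.05 generally and 0.01 for
the secretome. Transcript calling uses the same moderated-t machinery on
VST values; count-model dispersion estimation is deliberately out of
scope, keeping the pipeline scale-agnostic and self-contained.

SILAC ratios, which are within-sample stimulus/control contrasts
already, use a no-intercept linear model `ratio ~ 0 + condition` on
non-imputed observations only: each condition effect is the mean of its
observed ratios, tested against zero with the pooled residual variance
on n_obs − k df. The pipeline default tests per timepoint; a joint time
model is intentionally not imposed.

## Imputation

Two procedures with disjoint scopes:

- **Downshifted normal** (label-free layers, before statistics): missing
  entries in sample column j are drawn from
  N(μⱼ − shift·σⱼ, (width·σⱼ)²) with width 0.3 and shift 1.8, where μⱼ,
  σⱼ are over the column's observed values — the Perseus-style per-column
  convention (a global variant is not offered; per-column adapts to
  per-sample depth differences). Columns need ≥ 3 observed values.
  Observed cells are never altered.
- **Linear interpolation** (time-course reconstruction only): missing
  replicate medians are interpolated linearly against time; leading and
  trailing gaps take the nearest observed value. Never applied before
  the differential tests.

A per-group complete-case filter (`complete_case_filter`, fraction
configurable, default 1.0) is available for presence filtering before
imputation.

## Response classification

Only features significant in the combined arm (any timepoint) enter
classification. Courses are replicate-median **deflections from the
matched control course** (default; `baseline="t0"` subtracts the arm's
own t=0 median instead — exposed because either convention is
defensible; the control-course default removes any shared drift).
Correlations and AUCs are computed on these median deflections.

- Shape: S1 iff r_TNF > 0.7 and r_IFN < 0.7; S2 mirrored; S3 iff both
  > 0.7; S4 iff both < 0.3; otherwise NONE. Boundary values are excluded
  (strict inequalities). An undefined correlation (zero-variance course)
  falls through to NONE.
- Effect: ratios |AUC_comb| / max(|AUC_single|, ε) with
  ε = 1e−6·|AUC_comb|; a single-stimulus AUC whose sign opposes the
  combined AUC gets ratio +∞ (that stimulus cannot explain the combined
  direction). E1 iff ratio_TNF < 2 < ratio_IFN; E2 mirrored; E3 iff both
  > 2; zero combined AUC gives NONE.
- Final: SYNERGY if S4 or E3 (highest precedence), then TNF (S1, or
  S3∧E1), IFN (S2, or S3∧E2), COMMON (S3), else NOT_CLASSIFIED. The
  rule table resolves an internal tension in the written scheme — a
  combined class triggered by S3 would contradict "common when S3 but
  not E3" and leave S4 unused — so the combined-specific shape S4 is the
  shape route to SYNERGY; the other reading is selectable
  (`synergy_rule="s3_or_e3"`).
- E-classes are evaluated regardless of the S-class; precedence handles
  features lacking a shape class.

Because only correlations and AUC *ratios* enter the rules, the
classification is invariant to rescaling the time axis (verified by a
property test). The synergy decomposition is pure arithmetic:
frac_TNF = AUC_TNF/AUC_comb, frac_IFN likewise,
frac_excess = 1 − frac_TNF − frac_IFN; negative fractions (antagonism)
are reported as-is.

## Temporal events

An event is a feature's **first attainment of significance** under a
stimulus; cumulative curves count onsets ≤ t on the grid, so they are
monotone and their final value equals the number of ever-significant
features. A per-timepoint recounting mode is provided for comparison.
Layers are ranked by median onset with mean-onset then layer-name
tie-breaks; layers with zero events are excluded with a warning.

## Network summaries

Edge filtering is strict (score > cutoff) with symmetric duplicates
collapsed to the maximum score and self-edges dropped. The default
cutoff is 0.95 (an override to 0.9 or any other value is one config
field away, since both conventions appear in practice). Hub membership
is a user-supplied gene → label map, mirroring manual curation;
compositions are exact fractions over
{TNF, IFN, SYNERGY, COMMON, NOT_CLASSIFIED}. Feature-to-gene collapsing
keeps per-layer classes as separate columns and selects the primary
class by the fixed priority transcript > protein > phospho > secretome.
Receptors are genes with "extracellular"/"GPI-anchor" annotations;
ligands additionally require an edge (score > 0.4) to a receptor plus a
"secreted"/"signal"/"extracellular space"/"extracellular region"
annotation. Cross-layer same-gene linking is not performed
automatically. The cytokine-registry overlay reports, per registry gene
detected in the secretome, the stimuli with significant induction at
24 h and a constitutive flag for genes never significant.

## Synthetic data

The generator encodes the study conditions: 4 arms × grid
{0, 0.0333, 0.5, 4, 8, 12, 24} h × 3 replicates; noise i.i.d.
N(0, 0.2²) on the log scale. Response shapes are smooth parametric
stand-ins for the observed kinetics: a log-normal-in-time bump for
transient transcript peaks (maximal at t_peak), a saturating exponential
for sustained rises (time constant 6 h for transcripts), the same form
delayed by a 6 h lag for protein accumulation, and a fast exponential
relaxation (time constant 0.01 h) for immediate (de)phosphorylation.
All shapes are zero at t = 0.

The combined arm adds `multiplier × (TNF + IFN deflection)`. Defaults
per ground-truth class: single-stimulus classes 1.0, SYNERGY 3.0, and
COMMON **0.8**. The COMMON value is deliberately sub-additive: with an
exactly additive combined arm and equal single amplitudes, both AUC
ratios sit exactly on the effect threshold of 2, so any noise makes the
E-class (and hence the final call) a coin flip — a measure-zero boundary
of the classification scheme, not a resolvable signal. A mildly
saturating shared response (both cytokines driving a common target
toward a ceiling) is the realistic regime the scheme is meant to
separate, and gives ratios of 1.6 per stimulus. NULL features are flat
in all arms.

Intensity-dependent missingness (probability 1/(1+exp(slope·(x−mid))),
midpoint 4 log₂ units below the layer baseline, slope 1 — about 2%
dropout at baseline, rising steeply below it) is applied to the
LFQ-intensity layers (proteome/secretome), where the detection-limit
mechanism operates on abundance; SILAC ratio values are not censored by
the generator since a ratio is not an intensity. Amplitudes are drawn
uniformly in [1, 1.4]× the base amplitude (default 2.5 log₂ units) and
are predominantly positive, matching the predominantly upregulated
responses these stimuli induce; alternate phosphosites are downregulated
(dephosphorylation). One RNG stream seeded from the config drives noise
then missingness in feature-major order, so identical config + seed is
bit-identical.

What the generator does **not** emulate: peptide-level artifacts,
count overdispersion or library-size effects (values are produced
directly on the analysis scale), batch structure, donor-to-donor
variability, and per-layer sampling grids (one shared grid is used;
the real phosphoproteome is sampled at minutes, the proteome at hours).
Passing tests therefore demonstrate correctness of the statistical
machinery and decision rules under the stated noise model — not
robustness to these unmodeled features of real data.

## Problem sizes and numerical choices

Benchmark runs (tests and `scripts/acceptance.py`) use 500 features
(100 per class) for classifier recovery, 5000 features for the
moderated-t null calibration and hyperparameter recovery, 1000 random
vectors of length ≤ 8 for the BH oracle, 10⁴ missing cells for the
imputation moments, and a 40-features-per-layer demo for end-to-end
determinism — sizes at which every reported quantity is stable across
seeds. Trigamma-inverse bisection tolerance is 1e−8; d₀ ≥ 10⁶ is
infinite; AUC uses the composite trapezoid rule (exact for
piecewise-linear courses); undefined correlations and zero combined
AUCs fall through to non-classification rather than raising.

## Known limitations

- The moderated-t framework on VST transcript values ignores
  count-level mean-variance structure; with few replicates and strong
  heteroskedasticity a count model would be preferable.
- The BH adjusted-p transform is not idempotent (no step-up adjustment
  is); significance calls should always be made from the raw p values
  of one family, not re-adjusted values.
- Classification near the decision boundaries (r ≈ 0.7/0.3, AUC ratio
  ≈ 2) is inherently unstable under noise; the generator's class
  geometry keeps ground-truth classes away from those boundaries, real
  data will not.
- Hub assignment is consumed, not inferred; no graph clustering or
  layout is provided.
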