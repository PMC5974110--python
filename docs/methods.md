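# Methods

## Model and procedure

`qgdemar` treats each microarray probe as the analysis unit. For any
contrast of interest a per-probe scalar discrimination variable is
formed from condition means (replicates averaged, unweighted), and
differential probes are those in the tails of that variable's
distribution relative to an empirical Gaussian null.

The central assumption is a contamination model: the variable is a
mixture of a dominant Gaussian component (probes whose expression
fluctuates only stochastically) and a small fraction of displaced
probes (truly differential, or artifactual). Because the contaminating
mass sits in the tails, the central region of the empirical
distribution is essentially uncontaminated, and the null's location
and scale can be read off it.

**Null estimation (deconvolution).** The sorted finite values receive
plotting positions p_k = (k − ½)/n. Order statistics with p_k inside
the window [q_lo, q_hi] are regressed by ordinary least squares on
Φ⁻¹(p_k). The intercept estimates μ̂, the slope σ̂, and the regression
R² is reported as a linearity (i.e. Gaussianity-of-the-window)
diagnostic. This probit-window estimator was chosen over alternatives
(trimmed moments, half-sample modes, interquartile rescaling) because
it has a testable closed form, degrades gracefully when the window
edges touch contamination, and reports its own goodness of fit. Its
price is a small, predictable bias under one-sided contamination: with
5% of mass displaced to +5σ, the fitted μ̂ is biased by ≈ +0.07 and σ̂
by ≈ +0.06 (both well inside a ±0.1 band, and negligible next to the
≈ +0.46 inflation the full-sample standard deviation suffers on the
same data). A comparator, `fit_full_sample_null`, implements the
classical control-chart limits (whole-sample mean and SD) and is what
`control_chart_detect` uses.

**Tail detection.** For threshold t in the upper tail the estimated
FDR% is 100 · N · P(X > t | μ̂, σ̂) / #{xᵢ > t}, capped at 100, with N
the count of finite values — the denominator of the FDR covers the
whole probe universe, not only annotated probes. Candidate thresholds
are placed at the observed values beyond μ̂, scanned moving outward;
the least extreme candidate meeting the target is selected
(maximizing detections subject to the bound). Values exactly equal to
a threshold are *not* detected: strict inequality gives deterministic
tie-breaking. If no candidate qualifies the tail is NDAS; an NDAS tail
carries no threshold and an empty set. One Gaussian is fitted jointly
for both tails, since up- and down-regulation are the two tails of a
single ratio distribution. Non-finite values are excluded from
fitting, detection and N, and logged.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| q_lo, q_hi | 0.25, 0.75 | quantile fractions | central half of the data; wide enough for a stable regression, narrow enough that ≤ 25% one-sided contamination cannot reach the window |
| fdr_target | 5 | % | the conventional discovery cut-off used throughout the analyses |
| MIN_FINITE_VALUES | 50 | count | below this, order-statistic regression is meaningless |
| MIN_WINDOW_POINTS | 10 | count | a regression on fewer points has no diagnostic value |

## Discrimination variables

- `log_ratio(num, den)` = mean(num) − mean(den): log2 of the intensity
  ratio; positive ⇒ numerator up-regulated.
- `super_ratio(M, WT, c1, c2)` = [(M−WT)@c1] − [(M−WT)@c2]: the 2×2
  interaction between strain and condition. It is exactly the
  difference of the two within-condition log-ratios (compositionality)
  and antisymmetric under swapping c1/c2; both identities are tested to
  floating point.
- `difference(a, b)` = mean(a) − mean(b): used with a = WT, b = ΔN (a
  cloning control carrying the unmodified gene at the same ectopic
  locus as the mutants). Values ≪ 0 flag probes spuriously *induced*
  by the insertion, values ≫ 0 spuriously attenuated ones.
- `log2_quotient(num, den)` = mean(num)/mean(den): a literal division
  of log2 means (the ordinate of the control-chart scatter, clustering
  at 1). It is deliberately kept distinct from the log-ratio and never
  silently substituted, because the two readings of "ratio of log2
  intensities" are both legitimate and give different distributions;
  the quotient is the default for the non-deconvolved comparator path.

Probes missing in all replicates of a required condition are excluded
from that variable and logged with counts; probes missing in some
replicates use the mean of the available ones. Replicates are averaged
unweighted even when conditions have different replicate numbers —
per-condition summaries are single values and nothing in the detection
machinery uses within-condition variance.

## Spurious-transcription corrections

`build_spurious_lists` runs detection on WT − ΔN per phase: lower-tail
detections form the false-positive list, upper-tail the false-negative
list. `cross_exclude` removes a spurious list from a detected list —
at probe granularity as a plain set difference, or at gene granularity
(the default reading for published gene lists) by collapsing probes to
symbols and removing every probe of a flagged gene; mixed identifier
spaces raise an error rather than silently matching. The operation is
idempotent and can only shrink the list. `operon_exclude` is the
lighter alternative: only genes of the operon hosting the insertion
(shipped default: paaA…paaK) are removed.

The self-comparison `wt == dn` returns empty lists without fitting:
the difference variable is identically zero there, and a zero-variance
input is otherwise a `DegenerateNullError` everywhere in the package
(constant data admit no positive-scale null; reporting NDAS would
disguise a degenerate input as a negative result).

## Synthetic data: what it emulates and what it does not

`simulate_factorial` emulates the structure of a two-series bacterial
Affymetrix study: 10,207 probes with 8,662 gene-annotated (defaults),
strains × phases factorial layout with 2–3 replicates, a per-probe
baseline log2 intensity ~ N(7, 1) shared across conditions, additive
log2 condition offsets for spiked probes, and i.i.d. Gaussian
replicate noise. Defaults for the positional artifact mirror the
asymmetric pattern of a real insertion control (≈ 1.9% of probes
spuriously induced in exponential phase versus ≈ 0.2% in stationary
phase, with smaller attenuated fractions). Neither source study
reports a replicate variance, so the noise scale is an explicit
parameter, `replicate_sigma`, defaulting to 0.25 log2 units — a
typical within-condition SD for replicate bacterial arrays — rather
than a value inferred from data.

Design choices worth recording:

- **Named RNG streams.** Every draw comes from a generator keyed by
  (seed, role label), so adding a spike specification leaves the
  baseline and noise draws bit-identical. This is what makes
  before/after artifact comparisons exact in tests.
- **Interaction-only spikes** use a balanced mutant-only pattern
  (+e/2 in one phase, −e/2 in the other): the super-ratio sees the
  full effect e, each within-phase ratio only e/2, and wild-type cells
  stay untouched. A strictly interaction-only additive pattern that
  leaves the wild type untouched does not exist; this is the closest
  realizable one.
- **Positional artifacts** accept a list of affected strains. The
  designated ΔN-like control is the default, but the biology the
  artifact emulates — an insertion shared by control and mutants —
  requires listing the mutants too, and the correction-efficacy tests
  do so.
- Replicate noise is i.i.d. Gaussian on top of a per-probe condition
  mean, chosen for analytic tractability of the oracles (the log-ratio
  null is then exactly Gaussian with sd = replicate_sigma·√(2/r)).

What the simulator does **not** model: probe-sequence
cross-hybridization, intensity-dependent variance (the real
mean–variance relationship of hybridization data), scanner saturation,
correlated replicates, or pre-log raw intensities. Passing tests
therefore demonstrate the statistical machinery under its own
assumptions — Gaussian bulk plus displaced contamination — not
robustness to every artifact of real arrays.

## Problem sizes used in tests and the acceptance script

Calibration and recovery runs use 10,000-probe simulations (100 seeds
for null calibration and dominance, 50 for mixture recovery and
correction efficacy, 20 for spike recovery) and 8,000 probes for the
correction pipeline; these sizes give binomial/sampling error far
smaller than the asserted margins while keeping any single suite run
in well under a minute. The mixture-recovery summaries report medians
over seeds: the probit-window fit on a 5%-contaminated mixture has a
small positive bias (≈ +0.07 in μ̂), and the median over seeds is the
stable seed-aggregate of that estimator.

## Known limitations

- The estimated FDR is a tail-area ratio against a *fitted* Gaussian
  null; it is accurate to the extent the stochastic bulk is Gaussian.
  Heavy-tailed nulls would make it anti-conservative. The window R²
  diagnostic flags gross departures but is not a formal test.
- Thresholds are data values, so the selected threshold is a step
  function of the sample; two near-identical datasets can differ in
  one detection at the boundary.
- `read_geo_series_matrix` parses locally stored series-matrix text
  only; sample titles are free text, so strain/phase metadata must be
  supplied by the user, and no log2 auto-detection is attempted (an
  explicit flag controls transformation).
- Probe-to-gene summarization is deliberately absent; gene-level
  outputs are collapses of probe-level sets, not re-estimated
  statistics.
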