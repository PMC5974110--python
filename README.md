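# qgdemar

Quantile-Gaussian deconvolution analysis of factorial probe-level
microarray data.

## The problem

In bulk microarray experiments comparing bacterial strains across
culture conditions — e.g. *E. coli* deletion mutants of the protein
acetylation machinery (ΔcobB, ΔpatZ) or CRP acetylation variants grown
in batch and glucose-limited chemostat cultures — only a small number
of genes respond to any one contrast, while thousands of probes
fluctuate stochastically. Classical control-chart limits (sample mean
± z·SD of the whole distribution) are inflated by the very outliers one
wants to find, costing sensitivity. `qgdemar` implements the
quantile-Gaussian deconvolution approach (Q-GDEMAR): the null
distribution of a per-probe discrimination variable is estimated from
the **central quantile window** of its empirical distribution, and
probes are called per tail at a target false discovery rate. Analysis
stays at probe level throughout; gene symbols are carried as
annotation.

## The method

For a discrimination variable *x* (one scalar per probe), the order
statistics with plotting positions (k − ½)/n inside a quantile window
[q_lo, q_hi] (default 0.25–0.75) are regressed by OLS on standard
normal quantiles; the intercept and slope estimate μ̂ and σ̂ of the
stochastic bulk. For a candidate threshold *t* in the upper tail the
estimated FDR is

    FDR%(t) = 100 · N · P(X > t | μ̂, σ̂) / #{x_i > t}

(and symmetrically for the lower tail). The least extreme threshold
with FDR% ≤ target is selected per tail — maximizing detections subject
to the FDR bound — or the tail is declared **NDAS** ("not detectable as
significant"). Discrimination variables over a 2×2 factorial design:

- **log-ratio** mean(num) − mean(den) — up-regulation of the numerator;
- **super-ratio** [(M − WT)@c₁] − [(M − WT)@c₂] — the growth-rate ×
  mutation interaction;
- **difference** mean(a) − mean(b) — the WT − ΔN positional control;
- **log2-quotient** mean(num)/mean(den) — the control-chart ordinate.

Detected lists can be corrected for spurious transcription caused by
ectopic cloning (crossing against the WT − ΔN lists, or excluding the
host paa operon) and partitioned with two-set Venn algebra.

## Worked example

```python
import qgdemar as q

params = q.SimulationParams(
    n_probes=10_000, n_annotated=8_662,
    strains=("WT", "M"), phases=("exponential", "chemostat"),
    replicates_per_condition=3,
    spike_specs=(q.SpikeSpec("M", "chemostat", frac_up=0.01, frac_down=0.0,
                             effect_size=4.0),),
    seed=3,
)
matrix, truth = q.simulate_factorial(params)
var = q.log_ratio(matrix, q.ConditionKey("M", "chemostat"),
                  q.ConditionKey("WT", "chemostat"))
result = q.detect(var, fdr_target=5.0)
report = q.evaluate_detection(result, truth, "M:chemostat")
print(result.null.mu_hat, result.null.sigma_hat)
print(result.upper.threshold, result.upper.n_detected, result.upper.fdr_percent)
print(report.sensitivity_upper, report.fdp_upper)
```

prints

```
0.0058122474454361155 0.20414596079210479
0.6966815285299539 101 3.5340528413641707
1.0 0.009900990099009901
```

The fitted null has σ̂ ≈ 0.20 — the replicate-noise scale of a
three-replicate log-ratio (0.25·√(2/3)), untouched by the spikes. The
upper threshold ≈ 0.70 sits between the bulk and the +4 log2 spike
mode; all 100 spiked probes are recovered (sensitivity 1.0) with one
false positive among 101 detections and an estimated per-tail FDR of
3.5%, under the 5% target.

The same pipeline is available from the shell:

```sh
qgdemar simulate --seed 3 --spike M:chemostat:0.01:0.0:4.0 --out-dir sim
qgdemar detect --matrix sim/matrix.tsv --metadata sim/metadata.tsv \
    --numerator M:chemostat --denominator WT:chemostat --out-dir det
qgdemar report            # arithmetic summary of the shipped printed counts
```

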