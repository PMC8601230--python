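# caosc — calcium oscillation analysis for egg activation

Mammalian eggs respond to fertilization (or to parthenogenetic agents such
as strontium) with hours of repetitive cytoplasmic calcium transients.
These oscillations drive egg activation, and their pattern — when the first
transient starts, how long it lasts, how often transients recur, how long
they persist — is a sensitive readout of egg quality, used for example to
compare eggs from superovulated versus naturally cycling females.

`caosc` is a reproducible pipeline for that readout. It takes per-egg
ratiometric Fura-2 traces (dimensionless F340/F380 sampled every 7.5 s over
roughly two hours), detects calcium transients, computes the standard
per-egg metric panel, and compares two groups of eggs with the
nonparametric tests this field uses:

- **detection** — per-trace baseline `b` and noise `σ` (pre-stimulus
  median/MAD when pre-stimulus frames exist, otherwise a rolling 10th
  percentile), events as maximal runs above `b + max(k·σ, A_min)` with a
  hysteresis offset at a fraction (default 0.25) of peak height, gap-based
  merging and a minimum-duration filter;
- **features** — time to first transient, first-transient duration, numbers
  of oscillations within 60 and 120 min of the first onset, oscillations
  per 10 min (`n60/6`), area under the curve above baseline over the first
  60 min (trapezoidal, ratio·s), and the cessation time with right
  censoring for eggs still oscillating at the analysis horizon
  (110 min for strontium, 120 min for IVF);
- **stats** — two-sided Mann–Whitney U per scalar metric (exact by full
  enumeration for small tie-free samples, tie-corrected normal
  approximation otherwise; reported `U = min(U_x, U_y)`), and the log-rank
  (Mantel–Cox) test for oscillation persistence;
- **synthetic** — a seeded generator producing trace sets with a known
  ground-truth event table (latency, a first larger/longer transient,
  recurring transients with slowly stretching intervals, per-egg cessation,
  drift, noise, per-egg amplitude scale), so every stage is testable
  against truth without any experimental data.

## Worked example

Simulate the strontium contrast (group B with 1.15× latency and 1.5× first
transient duration, n = 75/78 eggs), run the full pipeline, and print the
six-panel comparison:

```
caosc run --scenario sr_paper --seed 1 --out results/sr_paper
```

```
          metric  n_a  n_b   median_a   median_b   statistic          test      p_value  significant_at_alpha
 time_to_first_s   75   78 322.500000 337.500000 2279.500000 mw_asymptotic 1.848232e-02                  True
first_duration_s   75   78  52.500000  71.250000 1284.500000 mw_asymptotic 1.616754e-09                  True
  freq_per_10min   75   78   1.833333   1.833333 2903.500000 mw_asymptotic 9.381458e-01                 False
          auc_60   75   78 128.681562 133.168938 2765.000000 mw_asymptotic 5.604854e-01                 False
       n_osc_120   75   78  14.000000  14.000000 2888.000000 mw_asymptotic 8.936878e-01                 False
     persistence   75   78  71.625000  68.687500    0.103187       logrank 7.480385e-01                 False
```

Reading the table: group B's median onset is 15 s later and its median
first transient 19 s (~36%) longer than group A's, both flagged by the
Mann–Whitney test (`p_value` column; `statistic` is `U = min(U_x, U_y)`).

The two manipulated metrics come out significant; frequency, total calcium
signal (AUC), oscillation counts and persistence do not — the same
two-of-six pattern the strontium experiment this scenario emulates reported
(and `--scenario ivf_null` reproduces the all-non-significant IVF outcome).
`results/sr_paper/` holds the traces, detected transients, per-egg feature
table, persistence curves, comparison table and a JSON run report with the
config hash; rerunning with the same seed reproduces every file
byte-identically.

The same stages are importable as a library (`caosc.simulate_experiment`,
`caosc.detect_transients`, `caosc.extract_features`, `caosc.compare_groups`,
`caosc.run_pipeline`) and as separate subcommands
(`caosc simulate/detect/features/compare`) for real exported trace tables
(long or wide TSV; see `docs/methods.md` for the format).

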