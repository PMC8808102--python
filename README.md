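# actirhythm

Non-parametric rest–activity rhythm analysis for wrist actigraphy.

Actigraphy studies record gross motor activity as integer counts per
1-minute epoch, continuously over one to two weeks per subject.
`actirhythm` compares two groups of such recordings — e.g. healthy
controls against acute-insomnia subjects — without fitting any parametric
rhythm model (no cosinor, no distributional assumption on the counts).
It is aimed at chronobiology and sleep researchers who want model-free
group comparisons of circadian timing and ultradian spectral structure.

## Method

Each recording is shifted to start at midnight and partitioned into whole
24 h segments of l = 1440 epochs. Three complementary analyses follow:

**Motion probability densities.** Each day y_{s,k}(t) is normalized by its
total count C_{s,k} = Σ_t y_{s,k}(t) to give a per-day motion PDF
P_{s,k}(t) = y_{s,k}(t)/C_{s,k} — the probability that a movement count
falls at minute t. Days average into subject profiles (÷D_s), subjects
into group profiles (÷N), so every subject counts once regardless of how
many days they wore the device.

**Delayed Jaccard shift estimation.** For group PDFs P and Q on the
circular day,

    J(τ) = 1 − Σ_t min(P(t), Q(t+τ)) / Σ_t max(P(t), Q(t+τ)),  τ = 0 … l−1,

is the Jaccard distance between P and the cyclically advanced Q: 0 for
identical densities, 1 for disjoint supports. Its minimizer τ_min
estimates the temporal offset between the two activity profiles (how much
one group's day lags the other's), and the plateau of shifts within a
tolerance of the minimum quantifies how sharply the offset is determined.

**Spectral ensembles and KS tests.** Every day-segment is decomposed with
the plain DFT, ŷ(ω_k) = Σ_t x(t)·e^(−i2πtk/l); amplitude A_k = |ŷ(ω_k)|
and quadrant-aware phase φ_k ∈ (−π, π] are collected per component
k = 1 … l/2 across all days of all subjects of each group. k = 1 is the
circadian (24 h) mode; k = 17, 19, 20 sit in the ≈85/75/72-minute
basic-rest-activity-cycle band. Per component, amplitude and phase samples
are compared between groups with the two-sided two-sample
Kolmogorov–Smirnov test (exact null for small samples), and p-values are
labelled significant (p < 0.01) or marginal (0.01 ≤ p < 0.1). Phase
differences convert to minutes via Δφ · lP/(2πk): 20° at k = 1 is 80 min.

A seeded synthetic cohort generator produces study-like data — two-level
diurnal profiles with abrupt (control) or slow (insomniac) evening
transitions, a configurable built-in group delay Δ, weak ultradian cosine
components, and point-mass/Poisson/negative-binomial count noise — so the
whole pipeline is testable without any recordings.

## Worked example

Simulate a cohort of 21 controls and 18 insomniacs (7–14 days each,
negative-binomial count noise) in which the insomnia group's intensity is
the control intensity delayed by 90 minutes, then run the full analysis:

```python
from actirhythm import RunConfig, SyntheticConfig, NoiseSpec, run_pipeline

config = RunConfig(
    synthetic=SyntheticConfig(shift_only=True, noise=NoiseSpec("nbinom", 10.0)),
    output_dir="demo", K=20, seed=1,
)
report = run_pipeline(config)
print(report.summary["n_day_segments"])          # {'control': 227, 'insomnia': 174}
print(report.summary["tau_min_minutes"])         # 90
print(report.summary["plateau_width_minutes"])   # 1
print(report.summary["jaccard_at_min"])          # 0.026990504881315713
```

The delayed-Jaccard minimizer recovers the built-in 90-minute delay
exactly: after averaging ~200 noisy days per group, the group PDFs are
near-perfect shifted copies, so the plateau collapses to a single epoch
and the residual distance at the minimum (≈0.027) reflects only count
noise. The KS table (`demo/ks_table.tsv`) shows what a pure time shift
looks like spectrally — amplitude samples indistinguishable at every
component, phase samples separated wherever the wrapped offset 2πkΔ/l is
large:

```
k  n_a  n_b  D_amp   p_amp   label_amp        D_phase  p_phase  label_phase
1  227  174  0.1032  0.2314  not_significant  1.0      2.2e-308 significant
2  227  174  0.0772  0.5756  not_significant  1.0      2.2e-308 significant
3  227  174  0.0536  0.9261  not_significant  0.0802   0.5280   not_significant
```

The same analysis is available from the shell:

```sh
actirhythm simulate --seed 1 --out cohort.csv
actirhythm run --cohort cohort.csv --out-dir demo
actirhythm validate cohort.csv        # per-subject whole-day counts
```

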