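# microstatekit

EEG microstate analysis with automatic selection of the number of
microstates, for researchers studying the spatiotemporal dynamics of
multichannel EEG — in particular emotional EEG, where the usual convention
of fixing four canonical resting-state microstates is too restrictive.

## What it computes

An EEG *microstate* is a short period (~80–120 ms) during which the scalp
potential topography stays quasi-stable before switching abruptly to a new
configuration. The package turns a multichannel recording `v ∈ ℝ^{C×N}`
into microstate templates, label sequences and feature tables:

1. **Global field power (GFP).** `GFP_n = sqrt(Σ_i (v_in − v̄_n)² / C)`,
   the spatial standard deviation of the average-referenced map. Maps at
   local GFP maxima (high SNR, stable topography) form the clustering bank.
2. **Polarity-invariant modified K-means.** Maps are clustered by the
   orthogonal squared distance `d²_kn = xₙᵀxₙ − (xₙᵀa_k)²` to unit-norm
   templates `a_k`, so a map and its sign-flip share a class; centres are
   sign-aligned means, best of several seeded restarts by global explained
   variance (GEV):
   `GEV = Σ_n Corr(x_n, a_{l_n})² · GFP_n² / Σ_n GFP_n²`.
3. **Model-order selection (KL-GEV criterion).** With
   `g(K) = K^{2/C}·GEV_K`, the interval-2 increments
   `DIFF_K = g(K) − g(K−2)` and ratios `KL_K = DIFF_K / DIFF_{K+2}` locate
   the elbow of the GEV curve; the largest interior local peak of the KL
   series is the selected number of microstates `K_optimal`.
4. **Backfitting and smoothing.** Every sample is labelled with the
   template of highest |spatial correlation|; a windowed smoother (fit cost
   minus λ × label agreement within ±b samples) or a minimum-duration rule
   removes noise-driven micro-segments.
5. **Features and statistics.** Per analysis window and class: occurrence,
   mean duration, coverage, per-class GEV, transition probabilities, mean
   GFP and mean spatial correlation (`4K + K²` temporal + `2K` spatial
   features), plus Welch band power in the δ/θ/α/β/γ bands; trials are
   grouped by emotion labels or per-subject valence/arousal thresholds and
   compared feature-wise with the two-sided Wilcoxon rank-sum test.

A synthetic generator plants known templates, a semi-Markov label sequence
and calibrated noise, so the whole chain is testable against ground truth.

## Worked example

```python
import numpy as np
import microstatekit as mk

cfg = mk.SynthConfig(K_true=4, C=32, fs=200.0, duration_s=120.0,
                     mean_duration_ms=100.0, snr=4.0, seed=7)
rec, truth, segs, tpl = mk.simulate_recording(cfg)

bank = mk.extract_peak_maps(rec, cap_per_recording=1000, seed=7)
scan, fit = mk.scan_and_select(bank, 1, 10,
                               mk.ClusterConfig(restarts=5, max_iter=50, seed=7))
print("k_optimal:", scan.k_optimal, "GEV:", round(scan.gev_by_k[scan.k_optimal], 3))

seq = mk.smooth_window(mk.backfit(rec, fit), fit,
                       mk.SmoothingParams(b=3, lam=0.2))
p = mk.class_parameters(seq, mk.segmentize(seq), K=4)
print("coverage:", p.coverage.round(3))
print("mean duration (ms):", p.duration_ms.round(1))
```

prints

```
k_optimal: 4 GEV: 0.971
coverage: [0.232 0.269 0.258 0.241]
mean duration (ms): [100.1 109.9 109.7 104.4]
```

The criterion recovers the 4 planted templates from the 1000 pooled
GFP-peak maps (pairwise template match |corr| ≥ 0.9999 here), the four
classes cover the recording roughly evenly, and the recovered mean segment
durations sit within 10 % of the planted 100 ms.

On a real multi-subject study the same calls run per dataset: pool peak
maps across subjects, scan a K grid (e.g. 2–17), backfit the selected
templates to every trial, then cut 15 s windows into feature tables for
classification or group statistics.

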