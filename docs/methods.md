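# Methods

## Model

The microstate model treats multichannel EEG as a concatenation of short
epochs during which the scalp potential topography is quasi-stable up to
amplitude modulation and polarity. Formally, the average-referenced map
`x_n ∈ ℝ^C` at sample `n` is approximated by `x_n ≈ s_n · a_{l_n}` with
unit-norm, zero-mean templates `a_k`, a per-sample amplitude `s_n` of
either sign, and a label sequence `l_n` that is piecewise constant on the
80–120 ms scale. All fitting is therefore polarity invariant: assignment
maximises squared spatial correlation, and only `|corr|` enters goodness
of fit.

### Clustering and GEV

Clustering operates on maps sampled at local maxima of the global field
power, where topographies are stable and SNR is highest. The modified
K-means alternates (a) assignment by minimal orthogonal squared distance
`d²_kn = xₙᵀxₙ − (xₙᵀa_k)²` and (b) centre recalculation. The centre is
the mathematical average of the member maps; because assignment is
polarity invariant, members of one class can carry opposite polarity and a
literal average can cancel. The default therefore sign-aligns each member
with the current centre before averaging (`align_mode="sign_aligned_mean"`;
`"literal_mean"` is available). Centres are re-centred and re-normalised
after every update; an emptied cluster is re-seeded from the worst-fitting
map. The best of `restarts` seeded initialisations by total GEV is kept.

Fit quality is global explained variance,
`GEV = Σ_n Corr(x_n, a_{l_n})² GFP_n² / Σ GFP_n²`, the GFP²-weighted share
of topographic variance explained by the assigned templates.

### Model-order selection

GEV increases monotonically with K, so the number of microstates is chosen
at the elbow of the GEV curve. With `g(K) = K^{2/C} · GEV_K` (the `K^{2/C}`
factor mirrors the dimensionality correction of the classical
Krzanowski–Lai cluster-number criterion), define

    DIFF_K = g(K) − g(K−2)          (interval-2 increment)
    KL_K   = DIFF_K / DIFF_{K+2}

The interval of 2 suppresses local jitter of the scan. Before the true
order both increments are large; after it both are small; exactly at it a
large increment is followed by a small one, so `KL` peaks. The selector
returns the interior local maximum of the KL series with the largest
value (ties to the smallest K); endpoints of the defined series are never
eligible, and a peak-free series raises `NoPeakError` rather than
guessing.

Because `DIFF_K` needs `GEV_{K−2}` and `KL_K` additionally needs
`DIFF_{K+2}`, a scan over `k_min..k_max` defines KL only on
`k_min+2 .. k_max−2`, and eligible peaks only on `k_min+3 .. k_max−3`.
The scan therefore accepts `k_min = 1` (a single-template fit has a
perfectly well-defined GEV): recovery experiments with a small true K
(e.g. 4) scan 1..10 so the true order sits interior to the KL series. For
dense-electrode studies the default grid is 2..17, which defines KL on
4..15.

### Backfitting and smoothing

Templates are backfit to every sample by maximal `|corr|` (absolute mode;
signed mode is a config option). Two smoothers are provided:

* **Windowed relabelling** (default): iteratively assign each sample the
  label minimising `(1 − corr²_nk) − λ · #{same label within ±b samples}`.
  Sweeps stop when labels are stable or when the global objective — total
  misfit minus λ times the number of agreeing sample pairs within distance
  b, each pair counted once — stops decreasing, which bounds the iteration
  and keeps the objective monotone. Defaults `b = 3` samples, `λ = 5`
  (strongly smoothing; at 200 Hz this suppresses essentially all
  sub-window blips), `max_smooth_iter = 1000`.
* **Minimum-duration rejection**: segments shorter than a threshold
  (default 30 ms) are dissolved into their neighbours, shortest first,
  choosing per sample the neighbour template with the higher |corr| but
  enforcing a single left/right crossing so the segment count can only
  decrease.

For quantitative recovery experiments on the synthetic generator the
smoothing strength is chosen from the misfit scale rather than taken from
the default: with planted templates at pairwise |corr| < 0.3, the misfit
contrast `1 − corr²` between the correct and a wrong template is ≈ 0.9,
so `λ = 0.2` with `b = 3` (maximum agreement differential ≈ 6·λ = 1.2)
corrects isolated noise-driven errors while leaving genuine short segments
— common under geometric durations — largely intact. Heavier smoothing
biases the recovered mean duration upward by absorbing real segments.

### Features

Per analysis window (default 15 s, non-overlapping, incomplete trailing
window dropped) and class k: occurrence (segments/s), mean duration (ms),
coverage (fraction of samples), per-class GEV, the K×K transition matrix
between consecutive distinct segments (zero diagonal, rows normalised;
kept at full K² length including the zero diagonal so the temporal feature
count is `4K + K²`), mean GFP (µV) and mean |spatial correlation| (the
`2K` spatial features). Occurrence counts window-truncated edge segments,
which preserves the identity `coverage = occurrence × duration / 1000`
exactly on every window. Band power uses Welch's method (2 s segments,
50 % overlap — conventional values, configurable) integrated over
δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–45 Hz, giving `5C` columns.

### Grouping and statistics

Continuous 1–9 valence/arousal ratings are dichotomised per subject
(rating ranges differ strongly between individuals): threshold rules are
subject mean (default), subject median, or a fixed value (default 5.0,
also the fallback for constant raters); a rating exactly at threshold
counts as low. The quadrant labels are HAHV/HALV/LAHV/LALV. Feature-wise
comparisons use the two-sided Wilcoxon rank-sum test (exact null
distribution when both groups have n ≤ 12 without ties, otherwise the
tie-corrected normal approximation) at α = 0.05 with no multiplicity
correction by default; Benjamini–Hochberg FDR is available.

## Preprocessing

Band-pass 1–45 Hz and notch 48–52 Hz as 4th-order zero-phase
forward-backward Butterworth filters (no phase distortion, so topography
timing is preserved), then common average reference, then polyphase
resampling (default 200 Hz). Filter family and order are configurable;
ICA-based artifact removal is deliberately out of scope — the pipeline
expects cleaned data.

## Synthetic generator

`simulate_recording` draws a semi-Markov label sequence (geometric segment
durations with 100 ms mean by default, matching the typical 80–120 ms
microstate time scale; a truncated-Gaussian option yields more realistic
duration histograms), multiplies the active template by a rectified 10 Hz
sinusoid (two GFP peaks per cycle, as alpha activity produces) scaled to
10 µV, adds white sensor noise at a configured signal/noise RMS ratio
(default 4), and average-references the result. Templates are random
mixtures of low-order spatial harmonics on a channel ring — smooth,
zero-mean, unit-norm, pairwise |corr| < 0.3 (or exactly orthogonal on
request).

What it does **not** emulate: volume-conducted 1/f background, spatially
correlated noise, artifacts, electrode geometry beyond a ring, or
non-stationary amplitude dynamics. Passing recovery tests on this
generator therefore demonstrates correctness of the algorithms under the
microstate model's own assumptions, not robustness to every property of
real EEG.

## Numerical choices

* Ties in assignment, backfitting and peak selection break to the smallest
  index; plateaus in the GFP curve count once, at their first sample.
* Template polarity is a gauge freedom; templates are stored at whatever
  sign the centre update produced.
* All randomness (restart initialisations, peak subsampling, simulation)
  flows from explicit integer seeds via `numpy` `SeedSequence` spawning,
  so every result is bit-reproducible from config + seed.
* GFP-peak banks are capped at 1000 maps per recording by seeded uniform
  subsampling to keep pooled clustering tractable without biasing the
  topography distribution; the cap is configurable or can be disabled.
* Degenerate inputs fail loudly (`ValidationError`) rather than silently:
  zero-norm maps, all-zero GFP, K > bank size, bands at or above Nyquist.
  A zero map inside a recording inherits the previous sample's label.

## Problem sizes used in the test suite

Recovery experiments simulate 120 s at 200 Hz with 32 channels and SNR 4
(≈ 1200 planted segments, ≈ 2400 GFP peaks capped to 1000), cluster with
5 restarts × ≤ 50 iterations, and scan K = 1..10; the model-order
recovery experiment repeats this over 20 seeds. These sizes give stable
statistics (duration and transition estimates to a few percent) at
desk-scale runtimes.

## Known limitations

* The criterion needs a GEV curve with a discernible elbow; on very flat
  or noisy scans it reports failure instead of a K.
* Windowed smoothing optimises a local objective by coordinate descent;
  it is not guaranteed to find the global optimum (the test suite checks
  it does on a small exhaustive instance).
* Group-level clustering pools GFP-peak maps without per-subject
  normalisation; strongly unequal subject amplitudes would weight subjects
  unequally in the bank.
* The classification stage of a full emotion-recognition study (an AutoML
  ensemble in the literature) is out of scope; the feature tables are
  classifier-ready and a generic cross-validated model can be attached
  downstream.
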