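# Methods

This note documents the models, defaults and numerical choices behind
`respconn`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic generative model

Each frequency band `b` has one shared oscillator whose phase is a
random-frequency walk centred on the band,

    Θ_b(t+1) = Θ_b(t) + 2π f_b / fs + ξ_t,   ξ_t ~ N(0, jitter²),

with band centres f_δ = 2.5, f_θ = 6, f_α = 10.5, f_β = 21.5 Hz and
`jitter = 0.08 rad/√sample` (a spectral line width of roughly 0.5 Hz at
500 Hz, keeping each component's Welch peak inside its nominal band).
Channel `i` observes the oscillator through stationary AR(1) Gaussian phase
noise `d_ib(t)`:

    φ_ib(t) = Θ_b(t) + d_ib(t),
    d_·b(t+1) = ρ d_·b(t) + √(1−ρ²) ε_t,   ε_t ~ N(0, σ² R),

where the cross-channel correlation matrix `R` is the condition- and
band-specific coupling matrix κ (unit diagonal added, projected to the
nearest positive-semidefinite correlation matrix). The recorded signal is
`Σ_b a_b g_cb cos(φ_ib)` plus white sensor noise. Defaults: σ = 1.4 rad,
ρ = 0.995 (noise correlation time ≈ 0.4 s), band amplitudes
a = (20, 12, 15, 6) µV for (δ, θ, α, β), sensor noise 5 µV.

For wrapped-Gaussian phase noise the population phase-locking value of a
pair is `PLV = exp(−σ²(1−κ))` — exactly 1 at κ = 1 and monotone in κ.
This calibration curve is a design guide, not an identity: narrow-band
filtering smooths part of the private phase noise, so measured PLV sits
somewhat above the curve, more for wide bands (β) than narrow ones (δ).
The tests therefore assert monotonicity and the κ = 1 / κ = 0 endpoints
(the κ = 0 null is checked against an independent Monte-Carlo simulation of
the AR(1) phase-difference process) rather than the literal curve.

Default condition effects mirror the qualitative group differences the
pipeline is meant to detect: SB carries stronger δ/θ coupling (κ = 0.65 /
0.5 vs baseline 0.2) over the 15 frontal edge pairs (Fp1, Fp2, F3, F4, F7,
F8); BH carries broadly stronger α/β coupling (κ = 0.55 / 0.5); α has three
distinct condition levels (0.35 / 0.55 / 0.2) so it is the most
discriminative band, with β slightly behind (0.45 / 0.5 / 0.35 — the
condition gap is halved relative to α). Amplitude gains (×1.3 for SB in
δ/θ, BH in α/β) give the spectral stage signed ground truth of the same
direction. One continuous run contains all three conditions; the breathing
blocks of the default layout alternate SB and PB with SB first, and 50-s
breathing / 20-s hold blocks (four holds) total 330 s.

### FVC covariate

`generate_cohort` can plant a linear association between FVC (litres) and
one edge's coupling within one (condition, band): per subject
κ_e ~ N(κ₀, 0.1²) clipped to [0, 1], and
FVC = 3.5 + 0.8·(r·z_κ + √(1−r²)·z) — a linear-Gaussian construction whose
population correlation is exactly the target r before clipping. A
calibration test confirms the mean empirical r over 500 cohorts of n = 35
is within ±0.05 of the target.

`simulate_plv_cohort` is the feature-level twin of the signal generator: it
maps coupling matrices through the calibration curve and adds independent
Gaussian PLV-estimation noise (default SD 0.03). Large-replicate
statistical studies (error-rate and power simulations at 500–1000 cohorts)
run on this twin; signal-level correctness is covered separately by
end-to-end tests on short-block runs. Statements validated on the twin
concern the statistics stages, not the signal chain.

### What the generator does not emulate

No ocular/muscle artifacts, no respiratory-belt or infra-slow (<1 Hz)
respiration-locked potentials, no volume conduction (zero-lag mixing), no
1/f background or non-stationarities beyond block switching. Passing tests
show the pipeline recovers known coupling structure from well-behaved
oscillatory data; they do not show robustness to artifacts or to the
zero-lag inflation of PLV that real scalp data exhibit.

## Preprocessing

Filters are zero-phase forward–backward Butterworth, order 4 (per-pass),
applied per channel; band edges are lower-inclusive / upper-exclusive so
δ/θ/α/β partition 1–30 Hz. An order-4 response leaves measurable energy in
a 45→50 Hz transition; tests pin suppression to the filter's own frequency
response rather than an idealised brick wall. Channel rejection tiles the
recording into non-overlapping 2-s epochs (configurable; rejection epochs
are not aligned to paradigm blocks) and drops a channel when the share of
epochs containing any |x| > 100 µV sample strictly exceeds 20 %; no
interpolation. Baseline correction subtracts the per-channel mean of the
(−200, 0) ms window anchored at block onset, taken from the continuous
recording; the first block of a run has no pre-onset context and falls
back to its initial 200 ms. Band filtering is applied per extracted block
after baseline correction, and always precedes Hilbert phase extraction.

## Spectral estimation

Welch's averaged modified periodogram: 128-sample Hamming window, 50 %
overlap, zero-padded to 256 points, one-sided density scaling. At 500 Hz
this grid has a step of 500/256 ≈ 1.95 Hz, which is recorded in the
estimate's parameters. Band power is the arithmetic mean over in-band bins
(matching "mean PSD" semantics; an integral is a one-line change), averaged
across a condition's epochs first and log₁₀-transformed after (log base
configurable).

## Connectivity

PLV is computed per segment from analytic-signal phases, discarding 5 % of
samples at each end to suppress Hilbert edge effects, then averaged
arithmetically across segments (not pooled). The diagonal is 1 by
definition and excluded from statistics. No volume-conduction correction is
applied; on real data zero-lag mixing inflates PLV and a lagged measure
would be a natural extension.

## Graph metrics

Matrices are used unthresholded. CC is the Onnela geometric-mean form with
weights normalised by the global maximum (bounded in [0, 1]); nodes with
fewer than two neighbours contribute 0 to the mean. GE maps weights to
lengths as 1/w (w = 0 disconnects; 1−w available by flag) and defaults to
the Latora–Marchiori mean of inverse shortest-path lengths, which is finite
under disconnection; the literal inverse-of-mean-path variant is available
by flag. LE applies GE to each node's nonzero-neighbour subgraph. DC is
mean node strength. All four agree with brute-force oracles (exhaustive
triplet enumeration, Floyd–Warshall) to 1e−12 on random graphs up to n = 8.
The density sweep retains the strongest edges at 10–40 % density and
compares metrics against surrogates that permute the retained weights over
the retained positions — preserving binary topology and degree sequence;
note DC is invariant under this null, so its z-score is identically 0.

## Group statistics

Contrasts default to two-sample t-tests even though conditions are
within-subject, matching the analysis convention this package reproduces; a
paired mode (sign-flip permutation) is provided and recommended for real
within-subject designs. FWE control defaults to max-T permutation (5000
label permutations, seeded, reproducible bit-exactly) because EEG features
are strongly correlated and Bonferroni is conservative there; Bonferroni is
available by flag. Simulated family-wise error over 1000 global-null
cohorts is within the binomial confidence band of the nominal 0.01.

FVC correlations are Pearson r per edge with BH-FDR at α = 0.01 across the
full family. The default family follows the 256-entries × 3-conditions
convention (768 tests, diagonal and duplicate entries included — constant
features get r = 0, p = 1 and cannot be selected); a statistically cleaner
120-unique-edge mode is available. **Detection power at small n is poor by
arithmetic**: surviving BH at α = 0.01 among 768 tests with a single true
association requires p ≲ 1.3e−5, i.e. an observed |r| ≈ 0.66 at n = 35. A
planted r = 0.5 is therefore flagged in only ~2 % of replicate cohorts
(PLV-estimation attenuation included). The corresponding recovery test
asserts a much stronger detection rate (≥ 80 %) and is intentionally left
failing as documentation of this limit; moderate correlations at n = 35
sometimes reported as FDR-significant in this literature are not reproducible under
an honestly applied 768-test BH procedure.

## Classification

ReliefF (Kononenko multiclass update, k = 10 neighbours, Manhattan distance
on range-normalised features, all instances visited in seeded order) ranks
the 120 edges; the top 30 feed a dense 30→64→32→3 network — ReLU, inverted
dropout 0.3 after each hidden layer, softmax cross-entropy with L2 0.001 —
trained 200 epochs with Adam (lr 0.001, batch 16). The network is a compact
NumPy implementation, so initialisation, batch order and dropout masks all
derive from one seed and training is bit-reproducible. Evaluation is
stratified 10-fold CV repeated 10 times; accuracy (%) and Cohen's κ are
means over folds.

Two protocol choices matter and are explicit flags:
`paper_faithful=True` ranks features once on the full dataset before
splitting (the common but leak-prone ordering, which inflates reported
accuracy); the default refits ReliefF and standardisation inside each
training fold. `groups=` keeps a subject's three condition rows in the same
fold (subject-leakage control); ungrouped stratification is the default
convention being reproduced. An RBF-SVM baseline under the same CV protocol
is provided for reference.

## Problem sizes used in validation

Statistical suites run at 500–1000 replicate cohorts on the feature-level
twin; signal-level tests use runs scaled to 2–13 s blocks (identical code
path, shorter blocks) and two-channel single-band recordings for
calibration curves; graph oracles use 100 random graphs of n ≤ 8; the
worked example runs 12 subjects at the full 330-s paradigm. These sizes
were chosen so the whole validation remains desk-scale while every
assertion is computed, not assumed.

## Known limitations

- The PLV calibration curve is approximate after filtering; only
  monotonicity and endpoints are contractual.
- The generator's planted FVC association varies a single edge; real
  covariate structure is surely more diffuse.
- Two-sample contrasts on within-subject conditions understate power;
  the paired mode is preferred for real data.
- EDF is read-only (via the optional mne extra); recordings are written as
  TSV + JSON sidecar.
- The density-sweep surrogate preserves topology exactly and so cannot
  probe topology-driven effects, only weight organisation.
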