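# Methods

`emergeeg` analyzes single-channel frontal EEG around the two behaviorally
verified anesthetic state transitions — loss of responsiveness (LOR) during
induction and return of responsiveness (ROR) during emergence — and compares
emergence dynamics between anesthetic maintenance regimens (propofol,
sevoflurane, isoflurane). Because the clinical recordings this kind of study
rests on are not publicly downloadable, the package ships a synthetic cohort
generator that reproduces the relevant statistical structure, so that every
analysis stage is exercised and tested end-to-end.

## Signal model of the synthetic generator

Each subject's EEG is a sum of three spectrally shaped Gaussian-noise
components, built in the frequency domain and band-limited to the recorder's
6–42 Hz pass band (raised-cosine edges, 1 Hz wide), sampled at 100 Hz:

* **background**: 1/f^γ noise, γ = 1.5 by default, total in-band power
  100 µV²;
* **alpha**: a narrowband component centered at 10 Hz (Gaussian profile,
  2 Hz FWHM), full-amplitude power 150 µV² — the strong frontal alpha
  rhythm of anesthetic-induced unconsciousness;
* **fast band**: flat-spectrum noise over 13–42 Hz, full-amplitude power
  60 µV² — the beta-and-above activation seen when the cortex reactivates.
  The band deliberately extends to the recorder's 42 Hz edge: the
  high-frequency (30–42 Hz) energy is the numerator of both depth-index
  sub-parameters, and emergence activation (fast beta, EMG) is not confined
  below 30 Hz in practice.

Slow amplitude envelopes define the states. During **induction** (LOR at the
record midpoint) the fast band falls from its awake amplitude to 5% and the
alpha rises from 20% to full, both over a ~60 s logistic transition. During
**emergence** the alpha wanes linearly from full amplitude to 60% at ROR, and
the fast band ramps up logistically (60 s rise) starting a subject-specific
*onset lead* before ROR. The lead is Gamma-distributed (shape 4, producing
right-skewed durations) with a group-specific mean: 60 s for the
propofol-like group, 270 s for both volatile-like groups, emulating the early
"wake-like" fast activation under volatile anesthetics. With probability 0.2
a subject additionally shows burst-suppression epochs early in emergence
(amplitude reduced to 5% for 2–10 s stretches within the first 30% of the
emergence window). Between-subject variability is log-normal per component
(σ = 0.1). With these defaults the RMS amplitude is 10–30 µV, typical of
frontal adult EEG.

Per-subject random substreams are derived from
`SeedSequence([seed, phase, group, subject])`, so cohorts are pure functions
of their configuration and subjects do not change when the cohort grows.

What the generator does **not** emulate: physiological waveform shape
(no neural-mass dynamics), EMG as a separate source, electrode artifacts,
delta/theta activity (the modeled recorder high-passes at ~6 Hz), and any
pharmacokinetics — state timing is imposed, not simulated.  Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
pipeline under realistic spectral structure, not clinical validity on real
EEG.

## Spectral pipeline

PSDs are Welch estimates over 10 s episodes advanced in 1 s steps (the
density-spectral-array grid). Within an episode: 2 s Hamming sub-windows,
50% overlap, per-window mean removal — 0.5 Hz resolution, enough to separate
alpha from beta while averaging 9 sub-windows per episode. A window
[t, t+10 s) is indexed by its start t; "the value 15 s before LOR" is the
window starting at LOR−15 s and therefore contains only pre-event EEG.
Band powers are trapezoidal integrals; reporting is confined to 6–30 Hz
(band edges: alpha 8–12, beta 13–30 — conventional choices). Normalized
spectrograms divide each row by its own 6–30 Hz integral.

## Permutation entropy

Ordinal patterns of length m = 3 at lag τ = 1, after a single zero-phase
4th-order Butterworth low-pass at 30 Hz per recording (per-window filtering
would re-introduce edge transients). Entropy is Shannon entropy of the
pattern frequencies in **bits** — anesthesia-range values of 2.2–2.5 exceed
the nats ceiling ln 6 ≈ 1.79 and are only consistent with log₂. Ties are
broken by temporal order (stable sort), the original ordinal-pattern
convention; it matters only for quantized or synthetic data.

## Depth index

The transparent 0–100 index uses the published sub-parameter family of
spectral log-energy ratios, with in-package band choices (the commercial
bands are proprietary): α-ratio = ln(E₃₀₋₄₂/E₆₋₁₂),
β-ratio = ln(E₃₀₋₄₂/E₁₁₋₂₁), and their difference (the log of the ratio
quotient — stored as a difference to avoid dividing signed logs), plus the
burst-suppression ratio (moving-RMS envelope over 0.2 s; suppressed =
envelope < 5 µV for ≥ 0.5 s contiguously). Band energies are floored at
10⁻⁶ µV² so suppressed windows keep finite ratios.

The composite is `100·sigmoid(4.5 + 1.4·αr + 1.4·βr + 0.2·βα)·(1 − BS%/100)`:
monotone nondecreasing in each ratio, non-increasing in BS%, 0 under full
suppression. The weights were calibrated **once** on the generator's
stationary states (awake-like median ≈ 97 ≥ 85; deep-anesthesia-like median
≈ 22 ≤ 50) and are frozen constants; they are never refit during analysis.
No claim of numerical equivalence to any commercial index is made; an
optional trailing moving average (off by default) can emulate monitor
display smoothing and its delay.

## Transition statistics

Parameter values are compared between event−15 s and event+30 s (the post
offset absorbs index-calculation delay). The Wilcoxon signed-rank test drops
zero differences (classic convention, logged); with ≤ 15 nonzero differences
the null is enumerated exactly over all sign assignments with midranks,
above that a tie- and continuity-corrected normal approximation is used.
Hedges' g for dependent data is J·mean(d)/sd(d) with d = pre − post, the
n−1 denominator and J = 1 − 3/(4(n−1) − 1); its 95% CI is a bias-corrected
(BC) percentile bootstrap over subjects. The sign convention makes a
parameter *decrease* yield positive g. The AUC is the Mann–Whitney
probability, computed by the rank formula, oriented as P(responsive-state
value > unresponsive-state value) — pre at LOR, post at ROR — and equipped
with a subject-resampling percentile bootstrap CI (default 10 000
resamples); a comparison is significant when the 95% CI excludes 0.5, with
closed-interval containment (an endpoint touching 0.5 counts as containing).

## Group comparisons and multiplicity

Per-frequency-bin and per-pixel group comparisons use the same
subject-level bootstrap AUC. Two false-positive guards apply:

* **PSD bins**: findings are retained only where ≥ 2 adjacent bins are
  jointly significant. Note a structural property, verified empirically in
  the test suite: with a 5% per-bin rate on 49 bins, at least one adjacent
  false-positive pair occurs in ≳ 11% of null datasets even under
  independence, and in ~30% with the correlation Welch estimation induces
  between neighboring bins — the rule suppresses isolated bins, it does not
  deliver a 5% family-wise rate.
* **2-D maps**: pixels are retained only inside 4-connected significant
  components of ≥ `cluster_min` pixels. `cluster_min` was calibrated once on
  24 null cohorts (identical group parameters, n = 15/group, full 591×49
  ROR-aligned grid, the default generator): the largest null component had
  median 36, 90th percentile ≈ 58 and maximum 174 pixels — overlapping 10 s
  windows and between-subject amplitude variability make chance patches of
  tens of pixels routine. The frozen default is 200 (observed null
  exceedance 0/24, family-wise false-cluster rate comfortably ≤ 10%), while
  genuine volatile-vs-propofol clusters measure thousands of pixels.

Kruskal–Wallis (tie-corrected, via SciPy) with Dunn's pairwise z tests and
Holm step-down adjustment handles the three-group duration comparison. The
Freeman–Halton test enumerates every r×c table with the observed margins
and sums multivariate hypergeometric probabilities of tables no more
probable than the observed one (probability-ordering two-sided convention;
reduces to Fisher's exact test for 2×2, agrees with R's `fisher.test` for
r×c). A seeded conditional Monte-Carlo fallback covers tables beyond the
enumeration budget.

The duration a subject's index stayed ≥ 80 before ROR is the length of the
maximal contiguous run of ≥ 80 windows ending at the last window before ROR,
measured from that run's first window start to ROR; a subject below 80 at
ROR enters as 0 s. The alternative "total time ≥ 80" reading is available
behind `mode="total"`.

## Numerical and scale choices

Bootstraps: 10 000 resamples for scalar statistics; 1 000 for maps and
per-bin comparisons (each pixel needs a full bootstrap; quantiles from
1 000 resamples are accurate to ~0.01 at the CI edges). Null-calibration
checks in the test suite run at 500 replicates for per-bin rates (n_boot =
500) and 60 replicates on 120 s-span maps for the cluster rule — sizes
chosen for desk-scale replication; the cluster_min calibration itself was
done on the full 600 s grid. All stochastic stages accept explicit seeds
and the pipeline derives per-stage generators from one master seed, making
every output table bit-reproducible.

Degenerate inputs: all-zero differences give Wilcoxon p = 1 with a warning;
zero-variance differences make Hedges' g an error (not NaN); constant
bootstrap statistics collapse the CI with a warning; spectrogram rows with
non-finite samples get a false quality flag and NaN index values, and are
excluded from paired sets with a logged reason per subject.

## Known limitations

* The depth-index proxy shares only its *inputs* with commercial monitors;
  absolute values are not comparable to any vendor index.
* The generator's emergence is stationary-in-distribution given its
  envelopes; real emergence EEG drifts continuously, so change-point
  behavior on real data will be noisier than the recovery tests suggest.
* EDF export writes a minimal single-channel EDF+C file (validated against
  the `mne` reader); it is not a general-purpose EDF library.
* Exact Freeman–Halton enumeration is practical for the demographic-scale
  tables it is meant for; larger tables need the Monte-Carlo path.
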