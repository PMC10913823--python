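# Methods

## Signal model and processing chain

The pipeline treats each channel's dual-wavelength intensity as

    I_λ(t) = g_λ · exp(−ΔOD_λ(t)),
    ΔOD_λ(t) = d · DPF_λ · (ε_HbO₂,λ ΔHbO₂(t) + ε_HHb,λ ΔHHb(t)) + drift + motion + noise,

with d the source–detector distance (2.5 cm long channels, 1.0 cm
short-separation), DPF = (5.4, 4.6) at (763, 841) nm, and ε the molar
extinction coefficients bundled in `data/extinction_coefficients.tsv`
(1/(mM·cm), interpolated at the instrument wavelengths from the standard
haemoglobin compilation). The analysis inverts exactly this model stage by
stage; the synthetic generator runs it forwards, so concentration recovery is
an exact round trip (tested to 1e-10 relative).

Processing order is fixed and tagged on the records: OD conversion → wavelet
motion correction → SCI/PSP channel pruning → 0.009–0.08 Hz band-pass →
Beer–Lambert inversion → nuisance regression → ROI averaging → connectivity.

### Wavelet motion correction

Discrete db2 decomposition with symmetric padding; within each detail level,
coefficients outside [Q1 − k·IQR, Q3 + k·IQR] (k = 0.8) are zeroed and the
series reconstructed. The decomposition depth is chosen automatically so the
approximation band keeps everything below `protect_hz` (default 0.09 Hz, just
above the analysis band edge; level 7 at 25 Hz). The rationale: motion spikes
and baseline steps are broadband and land in the detail levels, while the
quartile criterion fires on ~8% of coefficients even for clean
Gaussian-distributed signal — applying it to the levels that carry the
0.009–0.08 Hz band would systematically attenuate connectivity (measured:
recovery of an injected r = 0.6 drops from ≈0.57 to ≈0.48 with full-depth
decomposition). With the protected depth, a 10× motion spike is suppressed by
≈87% while a low-frequency sinusoid changes by <1% RMS. Gaussian in-band
signal still changes ~17% RMS through the band-edge leakage of the short db2
filters; this is a property of the published correction method, not of the
implementation, and it perturbs correlation estimates only mildly (the
parameter-recovery experiments quantify the net effect).

### Channel quality (SCI/PSP)

Both wavelengths are band-passed to the cardiac band (0.5–2.5 Hz, bracketing
child heart rates; configurable) and z-normalised within non-overlapping 3-s
windows. SCI is their Pearson correlation; PSP is the peak of
|FFT(cross-correlation)|²/n² restricted to the cardiac band, normalised so a
perfectly coupled cardiac sinusoid scores ≈0.25 and uncorrelated noise stays
well below the 0.06 threshold. Windows with zero variance score (0, 0). A
channel is dropped when both measures fall below threshold in strictly more
than 60% of windows. Note the null level of |SCI| in such short band-limited
windows is ≈0.23 (effective dof ≈ 2BT ≈ 12), far below the 0.60 keep
threshold; separation comes from coupled channels scoring ≈1. The exact
internal normalisations of the original QC tool are not published; these
definitions are explicit substitutes validated by their own property suite.
Manual visual inspection is replaced by an optional automated saturation flag
(intensity at a configured ceiling in >5% of samples), off by default.

### Band-pass

Third-order Butterworth in second-order sections, applied forward–backward
(zero phase). Measured gains: ≥0.99 at the geometric mid-band, <1e-4 at
0.5 Hz.

### Nuisance regression

Per condition segment and chromophore, every surviving channel is
OLS-residualised on an intercept, both short-separation channels
(chromophore-matched) and the band-passed 3-axis accelerometer. Collinear
columns are dropped greedily; residual orthogonality to the design is
asserted on every call (1e-8 relative). Fitting per segment (default) rather
than over the whole recording prevents condition differences from leaking
into the nuisance fit; the whole-recording variant sits behind a flag.

### Connectivity and group statistics

Surviving channels are averaged (unweighted) into 10 ROIs from the bundled
channel→ROI table; an ROI with no surviving channel is explicitly absent
(NaN rows, flagged mask) and its participants are dropped pairwise from group
tests. Pearson r over each condition's samples (windows shorter than 120 s
are refused — connectivity estimates stabilise after about two minutes in
this population), Fisher z = atanh(r) with clipping at ±(1−1e-12). Group
inference: one-sample t per condition, paired t preferred−assigned, both
two-sided; Benjamini–Hochberg FDR at q = 0.05 within the family of the
24 frontal×temporoparietal pairs per chromophore per test (the family
membership is listed in every run report). Chi-square tests on 2×2
behavioural tables use the Pearson statistic without continuity correction
(the convention consistent with the published worked values; Yates correction
is available behind a flag). Percentages are reported rounded half-up.

## Registration path

The bundled channel→ROI table is the pipeline default. The geometric path
that produces such a table is implemented and tested on synthetic labelled
sphere meshes (stand-ins for segmented template surfaces): a 12-dof
least-squares affine on the five cranial landmarks (exact whenever the
correspondence is affine), nearest-vertex snapping to the scalp then to the
cortex mesh (ties to the lowest index), and labelling by the dominant label
among cortex vertices within a 12.5 mm sphere, requiring ≥25% overlap by
vertex-count fraction (ties by larger fraction, then lexicographic). Overlap
by vertex count rather than surface area, and nearest-vertex snapping, are
deliberate simplest-verifiable choices — both are brute-forced in tests.

## Synthetic cohorts

`GroundTruthSpec` fixes, per condition: the 10×10 target correlation of
latent neural series (validated symmetric/unit-diagonal/PSD); neural band
0.009–0.08 Hz and amplitude 0.5 µM; ΔHHb = −0.4·ΔHbO₂ + noise; systemic
oscillations shared by all channels (cardiac 1.1 Hz / 0.4 µM, Mayer 0.1 Hz /
0.2 µM, respiration 0.3 Hz / 0.15 µM, each with phase jitter) with the
short-separation channels receiving systemic content only; per-channel white
concentration noise (0.1 µM) and OD measurement noise (3e-4); linear drift
(±2e-5 OD/s); Poisson motion events (2 spikes/min of 1–3 s, 0.5 shifts/min)
added in OD space with matched accelerometer transients; lognormal optical
gain. Condition blocks are 180 s (the study's 3 minutes), cohorts default to
n = 32, and the amplitudes are free parameters chosen to be physiologically
plausible — the study reports no SNR figures, so they are not estimates of
its data.

Latent series are synthesised in the frequency domain: independent complex
Gaussian Fourier coefficients shaped by a third-order Butterworth band-pass
magnitude and mixed across ROIs by a matrix square root of the target
correlation. This holds the target cross-correlation exactly at every
frequency and produces circularly stationary series. (Time-domain filtering
of white noise was rejected: at a 0.0007–0.0064 normalised band the
reflection-padded zero-phase filter's edge response dominates the output and
induces spurious inter-series correlations of ~0.5.) Per-participant seeds
derive from the master seed by `SeedSequence` spawning; identical seeds give
bit-identical recordings.

What the generator does not emulate: real photon-transport physics, spatially
heterogeneous systemic effects, vascular delay/dispersion between HbO₂ and
HHb, non-stationary artifact statistics, and inter-individual anatomy.
Passing tests therefore demonstrate internal consistency of the chain and
correct calibration of its statistics under the stated model — not
performance on human data.

## Validation experiments (problem sizes)

- Parameter recovery: target r = 0.6 on lMPFC–rTPJ, 50 participants through
  the full optical pipeline with all nuisance at default amplitude, compared
  with the same generator at zero nuisance (the oracle); the means are
  compared by a two-sample 95% criterion. Typical values ≈0.57 vs ≈0.58 —
  both sit slightly below the target because correlation estimated from
  ~25 effective degrees of freedom (2BT at 3 min) is noisy and the wavelet
  stage shrinks a little in-band energy.
- Null calibration: 200 replicate no-effect cohorts (n = 32) on the
  ROI-level fast path (latent series → correlation → paired t → BH-FDR),
  which exercises the connectivity and statistics layers at scale while the
  optical layers are covered by the recovery experiment; per-pair rejection
  is checked against the binomial 95% band around 0.05 and the family FDP
  against q.
- Power: rejection rate on the affected pair for Δr ∈ {0, 0.15, 0.3} with
  cohort seeds shared across effect sizes (a paired comparison, hence
  monotone up to Monte-Carlo noise).

## Known limitations

- The SCI/PSP normalisations and the wavelet "auto" depth are explicit,
  documented substitutes for unpublished tool internals.
- The channel→optode wiring in the default montage is schematic (only S-D
  distances matter downstream).
- The per-gender avatar-choice probabilities of the behavioural simulator are
  reconstructed from printed margins; cell-level counts are not all published
  and one consistent completion was chosen.
- The pipeline assumes both short-separation channels survive QC; if pruned,
  regression proceeds with the remaining regressors and logs the reduction.
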