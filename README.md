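# nirsfc

Functional-connectivity analysis for wearable fNIRS recordings from
naturalistic preschool social-interaction experiments, together with a
synthetic-cohort generator that makes the whole chain verifiable without any
participant data.

## The problem

A dual-wavelength (763/841 nm) continuous-wave fNIRS cap with 48 channels
(two 10 mm short-separation channels, the rest at 25 mm) records spontaneous
cortical haemodynamics at 25 Hz while 3-to-5-year-olds play with a preferred
and an assigned virtual partner for ~3 minutes each. The scientific question
is whether fronto-temporoparietal functional connectivity — Pearson
correlation of slow (0.009–0.08 Hz) fluctuations between 10 regions of
interest (bilateral MPFC, DLPFC, TPJ, M/STG, IPL) — differs between the two
social conditions. Freely-moving preschoolers produce heavy motion and
systemic contamination, so most of the work is in the signal chain:

1. intensity → optical density, OD(t) = −ln(I(t)/Ī);
2. wavelet motion correction: detail coefficients outside
   [Q1 − 0.8·IQR, Q3 + 0.8·IQR] per level are zeroed;
3. channel pruning by scalp-coupling index (SCI) and peak spectral power
   (PSP) over 3-s windows — drop when both fall below (0.60, 0.06) in more
   than 60% of windows;
4. zero-phase Butterworth band-pass, 0.009–0.08 Hz;
5. modified Beer–Lambert law (DPF 5.4/4.6) to ΔHbO₂/ΔHHb in µM:
   ΔOD_λ = d·DPF_λ·(ε_HbO₂,λ·ΔHbO₂ + ε_HHb,λ·ΔHHb);
6. OLS regression of the two short-separation channels
   (chromophore-matched) and the band-passed 3-axis accelerometer out of all
   long channels, per condition segment;
7. averaging surviving channels into the 10 ROIs (bundled channel→ROI table,
   recomputable geometrically from landmark-affine registration + cortical
   sphere labelling);
8. per-condition 10×10 Pearson matrices, Fisher z = atanh(r), one-sample and
   paired t-tests, Benjamini–Hochberg FDR over the 24 frontal×temporoparietal
   pairs per chromophore; behavioural chi-square and paired-t analyses.

Since no recordings are deposited, the package ships a forward model
(`nirsfc.simulate`) that generates raw intensities from band-limited latent
ROI series with a prescribed correlation structure plus cardiac/Mayer/
respiratory systemic oscillations, drift, accelerometer-coupled motion
artifacts and optical noise — through the same Beer–Lambert system the
analysis inverts — so recovery, calibration and power are all testable.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # 4 participants -> results/data/
python analysis/02_preprocess_qc.py        # channel QC
python analysis/03_connectivity.py         # per-participant FC matrices
python analysis/04_group_stats.py          # group tests + FDR
python analysis/05_behaviour_stats.py      # behavioural chi-squares
python analysis/06_validation.py           # recovery / calibration / power
```

A run of script 05 prints:

```
chi-square tests recomputed from the printed counts:
  gender_vs_avatar_age: X2(1, N=37) = 4.20, p = 0.040
  gender_vs_avatar_gender: X2(1, N=37) = 3.41, p = 0.065
  agegroup_vs_avatar_age: X2(1, N=37) = 0.67, p = 0.414
  agegroup_vs_avatar_gender: X2(1, N=37) = 1.51, p = 0.219
imaging inclusion rate: 86%
```

i.e. the association between participant gender and avatar age is significant
(preschool girls overwhelmingly chose toddler avatars), the gender–gender
association is a trend, and the age-group splits are null. Script 06 prints,
for a target inter-ROI correlation of 0.6 injected on lMPFC–rTPJ:

```
recovery: mean r = 0.631 (oracle 0.644, band 0.579..0.710) -> within the oracle band
null calibration: per-pair rejection 0.049 (nominal 0.05), family FDP 0.0000 (bound 0.05)
power over condition effects: {0.0: 0.033, 0.15: 0.9, 0.3: 1.0}
```

meaning the full optical pipeline recovers injected connectivity to within
its own nuisance-free Monte-Carlo band, the paired tests are correctly sized
on null cohorts, and a Δr of 0.3 at n = 32 is detected essentially always.

There is also a CLI (`nirsfc simulate|preprocess|connectivity|stats|run-all|
qc-report`) wrapping the same library functions.

## Layout

- `src/nirsfc/` — the library: montage/registration, simulator, signal chain,
  connectivity, statistics, SNIRF I/O, pipeline runner, CLI.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `docs/methods.md` — model, parameter and design documentation.
- `tests/` — pytest suite with independent oracles for every operation.
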