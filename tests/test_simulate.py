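import numpy as np
import pytest

from nirsfc.connectivity import fc_from_series
from nirsfc.montage import ROI_LABELS
from nirsfc.preprocess import bandpass, intensity_to_od, mbll
from nirsfc.simulate import (
    DEFAULT_CHOICE_PROBS,
    GroundTruthSpec,
    apply_effect,
    correlation_with_pairs,
    default_condition_specs,
    latent_roi_series,
    participant_seeds,
    simulate_behaviour,
    simulate_cohort,
    simulate_participant,
    simulate_roi_cohort,
    validate_correlation,
)

IDX = {r: i for i, r in enumerate(ROI_LABELS)}


class TestGroundTruthSpec:
    def test_default_is_identity_correlation(self):
        spec = GroundTruthSpec()
        assert np.allclose(spec.roi_correlation, np.eye(10))

    def test_non_psd_correlation_named_in_error(self):
        C = np.eye(10)
        C[0, 1] = C[1, 0] = 1.5  # breaks PSD
        with pytest.raises(ValueError, match="roi_correlation.*positive semi-definite"):
            GroundTruthSpec(roi_correlation=C)

    def test_asymmetric_correlation_rejected(self):
        C = np.eye(10)
        C[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            validate_correlation(C)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(channel_noise_sd_um=-1.0)

    def test_noise_free_zeroes_every_nuisance(self):
        clean = GroundTruthSpec().noise_free()
        assert all(s.amplitude_um == 0 for s in clean.systemic)
        assert clean.channel_noise_sd_um == 0
        assert clean.motion.spike_rate_per_min == 0
        assert clean.od_noise_sd == 0


class TestLatentSeries:
    fs = 25.0

    def test_identity_target_gives_near_zero_offdiagonals(self):
        rng = np.random.default_rng(0)
        x = latent_roi_series(np.eye(10), 4500, self.fs, (0.009, 0.08), rng)
        r = np.corrcoef(x)
        off = r[~np.eye(10, dtype=bool)]
        # ~2BT ~ 25 effective dof at 3 min: E[r^2] ~ 1/25
        assert np.mean(off**2) < 0.08
        assert x.shape == (10, 4500)

    def test_target_correlation_recovered_on_average(self):
        C = correlation_with_pairs({("lMPFC", "rTPJ"): 0.6})
        rs = [
            np.corrcoef(latent_roi_series(C, 4500, self.fs, (0.009, 0.08),
                                          np.random.default_rng(s)))[IDX["lMPFC"], IDX["rTPJ"]]
            for s in range(30)
        ]
        assert 0.5 < np.mean(rs) < 0.7

    def test_correlation_converges_with_duration(self):
        def mean_abs_off(n):
            rng = np.random.default_rng(42)
            r = np.corrcoef(latent_roi_series(np.eye(10), n, self.fs, (0.009, 0.08), rng))
            return np.abs(r[~np.eye(10, dtype=bool)]).mean()

        assert mean_abs_off(45000) < mean_abs_off(4500)  # 30 min vs 3 min

    def test_band_limited_spectrum(self):
        rng = np.random.default_rng(3)
        x = latent_roi_series(np.eye(10), 45000, self.fs, (0.009, 0.08), rng)[0]
        freqs = np.fft.rfftfreq(x.size, 1 / self.fs)
        power = np.abs(np.fft.rfft(x)) ** 2
        in_band = power[(freqs >= 0.005) & (freqs <= 0.12)].sum()
        assert in_band / power.sum() > 0.95


class TestSimulateParticipant:
    def test_same_seed_bit_identical(self):
        a, _ = simulate_participant(default_condition_specs(), seed=9)
        b, _ = simulate_participant(default_condition_specs(), seed=9)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.accelerometer, b.accelerometer)
        assert a.annotations == b.annotations

    def test_intensity_strictly_positive_and_annotations_valid(self, realistic_participant):
        raw, _ = realistic_participant
        assert np.all(raw.intensity > 0)
        labels = [a.label for a in raw.annotations]
        assert labels == ["preferred", "assigned"]
        assert all(a.duration_s >= 120 for a in raw.annotations)

    def test_clean_identity_empirical_fc_near_identity(self, clean_participant):
        raw, truth = clean_participant
        sl = raw.condition_slice("preferred")
        r = np.corrcoef(truth.latents[:, sl])
        off = r[~np.eye(10, dtype=bool)]
        assert np.mean(off**2) < 0.08

    def test_clean_mbll_round_trip_recovers_latents(self, clean_participant, roi_map):
        # analysis-side OD->conc inverts the generator's conc->OD: the recovered
        # HbO2 of any long channel equals its ROI latent up to scale and mean
        raw, truth = clean_participant
        conc = mbll(intensity_to_od(raw))
        sl = raw.condition_slice("preferred")
        cid = roi_map.channels_in_roi("lMPFC")[0]
        got = conc.conc[cid - 1, 0, sl]
        want = 0.5 * truth.latents[IDX["lMPFC"], sl]  # neural_amplitude_um = 0.5
        got = got - got.mean()
        want = want - want.mean()
        scale = np.abs(want).max()
        assert np.allclose(got, want, atol=1e-6 * scale)

    def test_ssc_channels_carry_no_neural_content(self, montage):
        # after analysis band-pass, SSC stays decorrelated from every latent
        rs = []
        for seed in (0, 1, 2):
            raw, truth = simulate_participant(default_condition_specs(), seed=seed)
            od = bandpass(intensity_to_od(raw))
            sl = raw.condition_slice("preferred")
            for cid in montage.ssc_ids:
                ssc = od.od[cid - 1, 0, sl]
                for k in range(10):
                    rs.append(abs(np.corrcoef(ssc, truth.latents[k, sl])[0, 1]))
        # individual estimates sit at the null level (sd ~ 1/sqrt(2BT) ~ 0.2 at
        # 3 min); the mean over 60 SSC-latent pairs must stay there
        assert np.mean(rs) < 0.2


class TestSimulateCohort:
    def test_minimal_cohort_distinct_seeds(self):
        cohort = simulate_cohort(n_participants=2, seed=5)
        assert len(cohort.recordings) == 2
        assert cohort.truths[0].seed != cohort.truths[1].seed
        assert not np.array_equal(cohort.recordings[0].intensity,
                                  cohort.recordings[1].intensity)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(n_participants=1)

    def test_effect_shifts_preferred_condition_only(self):
        cohort = simulate_cohort(
            n_participants=2, effect=[(("lMPFC", "rTPJ"), 0.3)], seed=0)
        spec_pref = cohort.truths[0].spec_per_condition["preferred"]
        spec_assn = cohort.truths[0].spec_per_condition["assigned"]
        assert spec_pref.roi_correlation[IDX["lMPFC"], IDX["rTPJ"]] == pytest.approx(0.3)
        assert spec_assn.roi_correlation[IDX["lMPFC"], IDX["rTPJ"]] == 0.0

    def test_effect_mean_delta_z_matches_closed_form(self):
        # fast path: mean Fisher-z difference vs atanh(r0 + dr) - atanh(r0)
        dr, n = 0.3, 32
        C0 = np.eye(10)
        C1 = apply_effect(C0, [(("lMPFC", "rTPJ"), dr)])
        dzs = []
        for rep in range(6):
            parts = simulate_roi_cohort(n, {"preferred": C1, "assigned": C0}, seed=rep)
            for p in parts:
                z1 = fc_from_series(p["preferred"])[1][IDX["lMPFC"], IDX["rTPJ"]]
                z0 = fc_from_series(p["assigned"])[1][IDX["lMPFC"], IDX["rTPJ"]]
                dzs.append(z1 - z0)
        want = np.arctanh(dr) - np.arctanh(0.0)
        se = np.std(dzs) / np.sqrt(len(dzs))
        assert abs(np.mean(dzs) - want) < 3 * se + 0.02

    def test_participant_seed_derivation_below_2_31(self):
        seeds = participant_seeds(123, 64)
        assert len(set(seeds)) == 64
        assert all(0 <= s < 2**31 for s in seeds)


class TestSimulateBehaviour:
    def test_degenerate_probs_all_choose_girl(self):
        probs = {g: {"girl": 1.0, "boy": 0.0, "woman": 0.0, "man": 0.0}
                 for g in ("female", "male")}
        df = simulate_behaviour(n=10, choice_probs=probs, seed=0)
        assert (df["chosen_avatar"] == "girl").all()

    def test_invalid_probs_rejected(self):
        probs = {g: {"girl": 0.6, "boy": 0.6, "woman": 0.0, "man": 0.0}
                 for g in ("female", "male")}
        with pytest.raises(ValueError, match="sum"):
            simulate_behaviour(n=5, choice_probs=probs)

    def test_reproducible(self):
        a = simulate_behaviour(n=20, seed=3)
        b = simulate_behaviour(n=20, seed=3)
        assert a.equals(b)

    def test_female_same_gender_rate_matches_configured_margin(self):
        # the default female probabilities encode 12/15 same-gender choices
        p_same = (DEFAULT_CHOICE_PROBS["female"]["girl"]
                  + DEFAULT_CHOICE_PROBS["female"]["woman"])
        assert p_same == pytest.approx(12 / 15)
        rng_counts = []
        for seed in range(40):
            df = simulate_behaviour(n=15, female_fraction=1.0, seed=seed)
            same = df["chosen_avatar"].isin(["girl", "woman"]).sum()
            rng_counts.append(same)
        mean = np.mean(rng_counts)
        se = np.sqrt(15 * p_same * (1 - p_same)) / np.sqrt(len(rng_counts))
        assert abs(mean - 12.0) < 4 * se + 0.5

    def test_equal_bubble_rates_give_null_paired_t(self):
        from nirsfc.stats import paired_t
        nonsig = 0
        reps = 100
        for seed in range(reps):
            df = simulate_behaviour(n=37, seed=seed)
            res = paired_t(df["bubbles_preferred"], df["bubbles_assigned"])
            nonsig += res.p_value >= 0.05
        assert nonsig / reps >= 0.90
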