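import numpy as np
import pytest
from scipy.stats import spearmanr

from thalcortex.connectivity import psi_static, surrogate_psi
from thalcortex.epochs import (extract_rest_epochs, merge_tic_sequences,
                               select_isolated_tics)
from thalcortex.io_formats import Modality
from thalcortex.spectral import decompose
from thalcortex.synth import (EEG_CHANNELS_63, FRONTAL_PRESET, GroundTruth,
                              expected_plv, generate_cohort,
                              generate_recording, ground_truth_report,
                              kappa_for_plv)


class TestExpectedPLV:
    def test_zero_coupling(self):
        assert expected_plv(0.0) == 0.0

    def test_bessel_ratio_at_two(self):
        # I1(2)/I0(2)
        assert expected_plv(2.0) == pytest.approx(0.69777, abs=1e-4)

    def test_limit_to_one(self):
        assert expected_plv(1000.0) > 0.999

    def test_monotone_and_invertible(self):
        ks = [0.5, 2.0, 10.0, 50.0]
        plvs = [expected_plv(k) for k in ks]
        assert np.all(np.diff(plvs) > 0)
        for k, p in zip(ks, plvs):
            assert kappa_for_plv(p) == pytest.approx(k, rel=1e-5)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            expected_plv(-1.0)


class TestGenerateRecording:
    def test_seed_reproducibility(self):
        truth = GroundTruth(kappa={"Fz": 5.0}, seed=11)
        a = generate_recording(30.0, truth, eeg_rate=250.0, eeg_channels=["Fz"])
        b = generate_recording(30.0, truth, eeg_rate=250.0, eeg_channels=["Fz"])
        assert np.array_equal(a.lfp.data, b.lfp.data)
        assert np.array_equal(a.eeg.data, b.eeg.data)
        assert a.events == b.events

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(5.0, GroundTruth())

    def test_shapes_rates_and_sync_markers(self):
        truth = GroundTruth(kappa={}, lfp_clock_offset=2.0, seed=0)
        sess = generate_recording(20.0, truth, eeg_channels=["Fz", "Pz"])
        assert sess.lfp.rate == 250.0 and sess.lfp.n_samples == 5000
        assert sess.eeg.rate == 5000.0 and sess.eeg.n_samples == 100000
        assert sess.lfp.modality is Modality.LFP
        assert sess.lfp.start_offset == 2.0
        syncs = sess.events.of_kind("artifact_sync")
        assert len(syncs) == 2

    def test_tics_obey_isolation_after_own_merging(self):
        for seed in range(5):
            sess = generate_recording(120.0, GroundTruth(seed=seed),
                                      eeg_rate=250.0, eeg_channels=["Fz"])
            tics = sess.events.tics().df
            assert tics["onset"].is_monotonic_increasing
            cleaned = select_isolated_tics(merge_tic_sequences(sess.events))
            assert len(cleaned.tics()) == len(tics)

    def test_source_channels_emitted(self):
        truth = GroundTruth(kappa={"M1": 10.0}, seed=1)
        sess = generate_recording(20.0, truth, eeg_rate=250.0,
                                  eeg_channels=["Fz"],
                                  source_channels=["M1", "S1"])
        assert sess.source is not None
        assert sess.source.modality is Modality.SOURCE
        assert sess.source.rate == 250.0
        assert sess.source.channel_labels == ["M1", "S1"]


def _alpha_center_psi(truth, duration, channels, seed=1):
    """Measured PSI at the oscillator center frequency for each channel."""
    sess = generate_recording(duration, truth, eeg_rate=250.0,
                              eeg_channels=channels, with_tics=False,
                              seed=seed)
    ep_l = extract_rest_epochs(sess.lfp, sess.events, 4.0)
    ep_e = extract_rest_epochs(sess.eeg, sess.events, 4.0)
    freqs = np.arange(8.0, 13.0)
    tf_l = decompose(ep_l, freqs=freqs)
    tf_e = decompose(ep_e, freqs=freqs)
    psi = psi_static(tf_l, tf_e,
                     pairs=[("lfp_left", ch) for ch in channels])
    return psi.values[:, psi.freqs == 10.0][:, 0], ep_l.n_trials, (tf_l, tf_e)


class TestCouplingOracle:
    def test_plv_matches_bessel_ratio(self):
        """200 epochs, four replicate channels per kappa, tolerance 0.03."""
        for kap in (2.0, 10.0, 50.0):
            chans = ["Fz", "F1", "F2", "FC1"]
            truth = GroundTruth(kappa={c: kap for c in chans}, seed=42)
            vals, n, _ = _alpha_center_psi(truth, 860.0, chans)
            assert n >= 200
            assert np.mean(vals) == pytest.approx(expected_plv(kap), abs=0.03)

    def test_psi_monotone_in_kappa(self):
        chans = ["Fz", "F1", "F2", "FC1"]
        means = []
        for kap in (0.0, 2.0, 10.0, 50.0):
            truth = GroundTruth(kappa={c: kap for c in chans}, seed=7)
            vals, _, _ = _alpha_center_psi(truth, 420.0, chans)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_strong_coupling_is_high_and_maximal(self):
        truth = GroundTruth(kappa={"Fz": 50.0}, seed=3)
        vals, _, _ = _alpha_center_psi(truth, 420.0, ["Fz", "Pz", "Oz"])
        assert vals[0] > 0.8
        assert vals[0] == vals.max()

    def test_uncoupled_channel_matches_surrogate_level(self):
        truth = GroundTruth(kappa={"Fz": 0.0}, seed=5)
        vals, n, (tf_l, tf_e) = _alpha_center_psi(truth, 420.0, ["Fz"])
        sur = surrogate_psi(tf_l, tf_e, pairs=[("lfp_left", "Fz")],
                            n_iter=100, seed=0)
        ens = sur.values[:, 0, sur.freqs == 10.0][:, 0]
        # original PSI indistinguishable from the surrogate ensemble
        lo, hi = np.quantile(ens, [0.005, 0.995])
        assert lo - 0.02 <= vals[0] <= hi + 0.02


class TestRamp:
    def test_pre_tic_decoupling_lowers_sliding_psi(self):
        from thalcortex.connectivity import psi_sliding
        from thalcortex.epochs import (extract_epochs_at, extract_tic_epochs,
                                       merge_tic_sequences,
                                       select_isolated_tics)

        truth = GroundTruth(kappa={"Fz": 20.0}, ramp_start=-0.5,
                            ramp_depth=1.0, seed=9)
        sess = generate_recording(400.0, truth, eeg_rate=250.0,
                                  eeg_channels=["Fz"])
        events = select_isolated_tics(merge_tic_sequences(sess.events))
        ep_e = extract_tic_epochs(sess.eeg, events, (-2.1, 0.9))
        ep_l = extract_epochs_at(sess.lfp, ep_e.trial_meta["onset"].to_numpy(),
                                 (-2.1, 0.9), anchor="tic_onset")
        freqs = np.arange(8.0, 13.0)
        tf_l = decompose(ep_l, freqs=freqs)
        tf_e = decompose(ep_e, freqs=freqs)
        from thalcortex.spectral import ALPHA
        s = psi_sliding(tf_l, tf_e, ALPHA, pairs=[("lfp_left", "Fz")])
        t = s.times
        ramp = s.values[0][(t >= -0.5) & (t <= 0.0)]
        baseline = s.values[0][(t >= -1.8) & (t <= -1.0)]
        assert ramp.mean() < baseline.mean()
        # the decoupling deepens toward onset
        assert s.values[0][np.argmin(np.abs(t))] < baseline.mean() - 0.15


class TestCohort:
    def test_reproducible_and_monotone_link(self):
        a = generate_cohort(4, seed=5, durations={"tic_freely": 0.0})
        b = generate_cohort(4, seed=5, durations={"tic_freely": 0.0})
        assert [p.clinical for p in a.patients] == [p.clinical for p in b.patients]
        assert all(not p.sessions for p in a.patients)

    def test_zero_noise_gives_perfect_negative_rank_link(self):
        coh = generate_cohort(6, seed=0, clinical_noise_sd=0.0,
                              durations={"tic_freely": 0.0})
        plv = [expected_plv(p.truth.kappa["Fz"]) for p in coh.patients]
        tts = [p.clinical.ygtss_tts for p in coh.patients]
        puts = [p.clinical.puts for p in coh.patients]
        assert spearmanr(plv, tts).statistic == pytest.approx(-1.0)
        assert spearmanr(plv, puts).statistic == pytest.approx(-1.0)

    def test_large_noise_weakens_link(self):
        rhos = []
        for seed in range(10):
            coh = generate_cohort(6, seed=seed, clinical_noise_sd=40.0,
                                  durations={"tic_freely": 0.0})
            plv = [expected_plv(p.truth.kappa["Fz"]) for p in coh.patients]
            tts = [p.clinical.ygtss_tts for p in coh.patients]
            rhos.append(spearmanr(plv, tts).statistic)
        assert np.mean(np.abs(rhos)) < 0.75

    def test_degenerate_kappa_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_cohort(4, kappa_range=(5.0, 5.0),
                            durations={"tic_freely": 0.0})

    def test_fz_holds_the_maximal_kappa(self):
        coh = generate_cohort(3, seed=2, durations={"tic_freely": 0.0})
        for p in coh.patients:
            kmax = max(p.truth.kappa, key=p.truth.kappa.get)
            assert kmax == "Fz"
            assert set(p.truth.kappa) == set(FRONTAL_PRESET)

    def test_scores_respect_clinical_invariants(self):
        coh = generate_cohort(8, seed=4, clinical_noise_sd=10.0,
                              durations={"tic_freely": 0.0})
        for p in coh.patients:
            assert p.clinical.ygtss_tts >= 0
            assert p.clinical.ygtss_tts <= p.clinical.ygtss_global


class TestGroundTruthReport:
    def test_expected_plv_column(self):
        coh = generate_cohort(3, seed=1, durations={"tic_freely": 0.0})
        rep = ground_truth_report(coh)
        assert set(rep["patient"]) == {p.patient_id for p in coh.patients}
        row = rep[(rep["patient"] == coh.patients[0].patient_id)
                  & (rep["channel"] == "Fz")].iloc[0]
        assert row["expected_plv"] == pytest.approx(
            expected_plv(coh.patients[0].truth.kappa["Fz"]))

    def test_limits(self):
        assert expected_plv(0.0) == 0.0
        assert expected_plv(2.0) == pytest.approx(0.698, abs=1e-3)


class TestMontage:
    def test_63_channels_unique(self):
        assert len(EEG_CHANNELS_63) == 63
        assert len(set(EEG_CHANNELS_63)) == 63
        assert set(FRONTAL_PRESET) <= set(EEG_CHANNELS_63)
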