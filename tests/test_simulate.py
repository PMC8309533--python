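"""Waveform physics, fixture fidelity and determinism of the simulator."""

import numpy as np
import pytest

from breathmss import (
    ChannelModel,
    GasState,
    InjectionSequence,
    SimStudyConfig,
    simulate_alcohol_experiment,
    simulate_study,
    simulate_waveform,
)

ONE_CYCLE = InjectionSequence(sampling_rate=100.0, blocks=((10.0, 1),))


def clean_channel(**kw):
    base = dict(tau_sorb=1.0, tau_desorb=1.0, h=0.01, noise_sd=0.0, drift_rate=0.0)
    base.update(kw)
    return ChannelModel(**base)


class TestWaveformPhysics:
    def test_zero_amplitude_gives_zero_signal(self):
        ch = clean_channel()
        sig = simulate_waveform(ch, GasState(rh=40.0), GasState(rh=40.0), ONE_CYCLE)
        np.testing.assert_array_equal(sig, np.zeros(ONE_CYCLE.n_ticks))

    def test_first_sample_half_matches_closed_form(self):
        ch = clean_channel(tau_sorb=1.0)
        sig = simulate_waveform(ch, GasState(rh=73.0), GasState(rh=33.0), ONE_CYCLE)
        t = np.arange(1000) / 100.0
        expected = 0.4 * (1.0 - np.exp(-t / 1.0))
        np.testing.assert_allclose(sig[:1000], expected, rtol=1e-12, atol=1e-15)

    def test_value_at_half_cycle_end(self):
        # A = 0.01 * (73 - 33) = 0.4; at t = 10 s with tau = 1 s the response
        # is 0.4 * (1 - e^-10) ~= 0.39998 (read at the first purge tick,
        # which continues from the sample-half endpoint)
        ch = clean_channel(tau_sorb=1.0)
        sig = simulate_waveform(ch, GasState(rh=73.0), GasState(rh=33.0), ONE_CYCLE)
        assert sig[1000] == pytest.approx(0.4 * (1.0 - np.exp(-10.0)), abs=1e-12)
        assert sig[1000] == pytest.approx(0.39998, abs=1e-5)

    def test_purge_half_decays_exponentially(self):
        ch = clean_channel(tau_sorb=1.0, tau_desorb=2.0)
        sig = simulate_waveform(ch, GasState(rh=73.0), GasState(rh=33.0), ONE_CYCLE)
        v0 = 0.4 * (1.0 - np.exp(-10.0))
        t = np.arange(1000) / 100.0
        np.testing.assert_allclose(sig[1000:], v0 * np.exp(-t / 2.0), rtol=1e-12)

    def test_voc_superposition_raises_amplitude_exactly(self):
        # 100 ppm at 0.002 /ppm adds 0.2 to the steady-state amplitude
        long_cycle = InjectionSequence(blocks=((100.0, 1),))
        ch = clean_channel(vocsens={"ethanol": 0.002})
        base = simulate_waveform(ch, GasState(rh=73.0), GasState(rh=33.0), long_cycle)
        spiked = simulate_waveform(
            ch,
            GasState(rh=73.0, voc_conc={"ethanol": 100.0}),
            GasState(rh=33.0),
            long_cycle,
        )
        assert spiked[9999] - base[9999] == pytest.approx(0.2, abs=1e-12)

    def test_amplitude_monotone_in_rh_difference(self):
        ch = clean_channel()
        ends = []
        for rh_purge in (50.0, 40.0, 30.0, 20.0):
            sig = simulate_waveform(ch, GasState(rh=73.0), GasState(rh=rh_purge), ONE_CYCLE)
            ends.append(sig[999])
        assert np.all(np.diff(ends) > 0)

    def test_doubling_concentration_doubles_amplitude(self):
        ch = clean_channel(h=0.0, vocsens={"v": 0.01})
        one = simulate_waveform(
            ch, GasState(rh=40.0, voc_conc={"v": 5.0}), GasState(rh=40.0), ONE_CYCLE
        )
        two = simulate_waveform(
            ch, GasState(rh=40.0, voc_conc={"v": 10.0}), GasState(rh=40.0), ONE_CYCLE
        )
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12, atol=1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            clean_channel(tau_sorb=-1.0)
        with pytest.raises(ValueError):
            clean_channel(h=np.nan)
        with pytest.raises(ValueError):
            GasState(rh=120.0)
        with pytest.raises(ValueError):
            GasState(rh=40.0, voc_conc={"v": -1.0})


class TestStudyFixture:
    def test_record_counts(self, study_records):
        by_type = {}
        for r in study_records:
            by_type[r.sample_type] = by_type.get(r.sample_type, 0) + 1
        assert by_type == {"breath": 83, "reference": 33}

    def test_reference_records_are_humidified_gas_only(self, study_records):
        # metadata carries RH for every record; breath ids are distinct
        ids = [r.measurement_id for r in study_records]
        assert len(set(ids)) == len(ids)
        for r in study_records:
            assert 20.0 <= r.metadata["rh_purge"] <= 50.0
            assert 70.3 <= r.metadata["rh_sample"] <= 75.3

    def test_same_seed_reproduces_records_exactly(self, short_sequence):
        cfg = SimStudyConfig(
            n_breath=3,
            n_reference=2,
            rh_purge_breath=(22.0, 33.0, 44.0),
            rh_purge_reference=(25.0, 45.0),
            sequence=short_sequence,
            seed=7,
        )
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.signals, rb.signals)
            assert ra.metadata == rb.metadata

    def test_pair_structure_validation(self, short_sequence):
        with pytest.raises(ValueError, match="out of range"):
            SimStudyConfig(
                n_breath=3,
                n_reference=2,
                rh_purge_breath=(22.0, 33.0, 44.0),
                rh_purge_reference=(25.0, 45.0),
                sequence=short_sequence,
                pair_structure=((0, 5),),
            )

    def test_rh_list_length_must_match_counts(self):
        with pytest.raises(ValueError, match="rh_purge_breath"):
            SimStudyConfig(n_breath=5, rh_purge_breath=(30.0,) * 4)


class TestAlcoholExperiment:
    def test_paired_design_counts(self, short_sequence):
        cfg = SimStudyConfig(seed=3, sequence=short_sequence)
        recs = simulate_alcohol_experiment(cfg, n_subjects=3, n_days=3)
        pre = [r for r in recs if r.metadata["condition"] == "pre_alcohol"]
        post = [r for r in recs if r.metadata["condition"] == "post_alcohol"]
        assert (len(pre), len(post)) == (9, 9)
        assert {r.metadata["subject"] for r in recs} == {"S1", "S2", "S3"}

    def test_pre_records_carry_no_ethanol(self, short_sequence):
        cfg = SimStudyConfig(seed=3, sequence=short_sequence)
        recs = simulate_alcohol_experiment(cfg)
        for r in recs:
            if r.metadata["condition"] == "pre_alcohol":
                assert r.metadata["ethanol_ppm"] == 0.0
            else:
                assert 60.0 <= r.metadata["ethanol_ppm"] <= 120.0

    def test_degenerate_range_is_a_point_distribution(self, short_sequence):
        cfg = SimStudyConfig(seed=3, sequence=short_sequence)
        recs = simulate_alcohol_experiment(cfg, ethanol_ppm_range=(100.0, 100.0))
        post = [r for r in recs if r.metadata["condition"] == "post_alcohol"]
        assert all(r.metadata["ethanol_ppm"] == 100.0 for r in post)

    def test_invalid_designs_rejected(self, short_sequence):
        cfg = SimStudyConfig(seed=3, sequence=short_sequence)
        with pytest.raises(ValueError):
            simulate_alcohol_experiment(cfg, n_subjects=0)
        with pytest.raises(ValueError):
            simulate_alcohol_experiment(cfg, ethanol_ppm_range=(120.0, 60.0))
        with pytest.raises(ValueError):
            simulate_alcohol_experiment(cfg, ethanol_ppm_range=(60.0, 400.0))
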