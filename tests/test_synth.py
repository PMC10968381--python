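import numpy as np
import pytest

from alphanet import connectivity, preprocess, spectral, synth


def small_design(**kw):
    labels = [f"C{i + 1}" for i in range(4)]
    defaults = dict(montage=synth.make_simple_montage(labels), n_per_group=2,
                    fs=200.0, duration=10.0, noise_amplitude=1.0,
                    nonscalp_noise_amplitude=0.0, seed=3)
    defaults.update(kw)
    return synth.GroupDesign(**defaults)


class TestDeterminism:
    def test_identical_seeds_bit_identical(self):
        a = synth.generate_recording(small_design(), 0, "athlete")
        b = synth.generate_recording(small_design(), 0, "athlete")
        np.testing.assert_array_equal(a.data, b.data)

    def test_subjects_and_groups_differ(self):
        d = small_design()
        a = synth.generate_recording(d, 0, "athlete")
        b = synth.generate_recording(d, 1, "athlete")
        c = synth.generate_recording(d, 0, "control")
        assert not np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_study_bit_identical(self):
        s1 = synth.generate_group_study(small_design())
        s2 = synth.generate_group_study(small_design())
        for r1, r2 in zip(s1.recordings, s2.recordings):
            np.testing.assert_array_equal(r1.data, r2.data)


class TestSpectralGroundTruth:
    def test_psd_peak_at_oscillator_frequency(self):
        d = small_design(noise_amplitude=0.0)
        rec = synth.generate_recording(d, 0, "athlete")
        ep = preprocess.segment_epochs(rec, 2.0)
        res = spectral.psd_epochs(ep)
        for ch in range(4):
            assert res.freqs[np.argmax(res.psd[ch])] == pytest.approx(10.0, abs=0.5)

    def test_noiseless_power_matches_amplitude(self):
        """With zero noise, per-channel variance is A^2/2 within 1%."""
        d = small_design(noise_amplitude=0.0,
                         oscillator=synth.OscillatorSpec(10.0, 6.0, 0.05))
        rec = synth.generate_recording(d, 0, "athlete")
        expected = 6.0**2 / 2
        for ch in range(4):
            assert rec.data[ch].var() == pytest.approx(expected, rel=0.01)

    def test_planted_amplitude_raises_alpha_power(self):
        osc = synth.OscillatorSpec(10.0, 10.0, 0.05)
        d = small_design(
            duration=20.0, n_per_group=4, noise_amplitude=3.0, oscillator=osc,
            group_oscillator={"athlete": synth.OscillatorSpec(10.0, 15.0, 0.05)})
        study = synth.generate_group_study(d)
        powers = {}
        for g in d.group_labels:
            vals = []
            for rec in study.by_group(g):
                ep = preprocess.segment_epochs(rec, 2.0)
                vals.append(spectral.band_power(spectral.psd_epochs(ep),
                                                spectral.ALPHA).mean())
            powers[g] = np.mean(vals)
        assert powers["athlete"] > powers["control"]


class TestCoupling:
    def test_full_coupling_gives_unit_wpli(self, pair_design):
        rec = synth.generate_recording(pair_design, 0, "athlete")
        ep = preprocess.segment_epochs(rec, 2.0)
        cm = connectivity.subject_wpli(ep, spectral.ALPHA)
        assert cm.values[0, 1] > 0.99

    def test_unknown_coupling_label_names_it(self):
        d = small_design()
        d.couplings = [synth.CouplingSpec(("C1", "NOPE"))]
        with pytest.raises(KeyError, match="NOPE"):
            synth.generate_recording(d, 0, "athlete")

    def test_coupling_strength_bounds_validated(self):
        with pytest.raises(ValueError):
            synth.CouplingSpec(("a", "b"), coupling_strength=1.5)


class TestModuleSpec:
    def test_all_module_pairs_phase_locked(self):
        labels = [f"C{i + 1}" for i in range(6)]
        mont = synth.make_simple_montage(labels)
        mod = synth.ModuleSpec(channels=tuple(labels[:4]),
                               coupling_strength=0.9, lag_spacing=0.3)
        d = synth.GroupDesign(montage=mont, n_per_group=2, fs=250.0,
                              duration=60.0, noise_amplitude=0.5,
                              nonscalp_noise_amplitude=0.0,
                              group_modules={"athlete": [mod]}, seed=21)
        rec = synth.generate_recording(d, 0, "athlete")
        ep = preprocess.segment_epochs(rec, 2.0)
        cm = connectivity.subject_wpli(ep, spectral.ALPHA)
        for i in range(4):
            for j in range(i + 1, 4):
                assert cm.values[i, j] > 0.5, (i, j)
        assert cm.values[4, 5] < 0.3  # outside the module

    def test_module_validation(self):
        with pytest.raises(ValueError, match="2 channels"):
            synth.ModuleSpec(channels=("a",))
        with pytest.raises(ValueError):
            synth.ModuleSpec(channels=("a", "b"), coupling_strength=2.0)

    def test_unknown_module_channel_names_it(self):
        labels = ["C1", "C2"]
        d = synth.GroupDesign(montage=synth.make_simple_montage(labels),
                              n_per_group=2, fs=200.0, duration=4.0,
                              modules=[synth.ModuleSpec(channels=("C1", "BAD"))],
                              seed=0)
        with pytest.raises(KeyError, match="BAD"):
            synth.generate_recording(d, 0, "athlete")


class TestGroupStudy:
    def test_study_size(self):
        d = small_design(n_per_group=24, duration=2.0)
        study = synth.generate_group_study(d)
        assert len(study.recordings) == 48
        assert study.groups.count("athlete") == 24
        assert study.groups.count("control") == 24

    def test_null_design_draws_groups_identically_configured(self):
        d = small_design()
        assert d.oscillator_for("athlete") == d.oscillator_for("control")
        assert d.couplings_for("athlete") == d.couplings_for("control")

    def test_n_per_group_minimum(self):
        with pytest.raises(ValueError, match="n_per_group"):
            small_design(n_per_group=1)

    def test_non_integral_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            small_design(fs=3.0, duration=10.1)


class TestMixingModel:
    def test_rows_stochastic(self, montage64):
        m = synth.MixingModel.from_montage(montage64, spread=0.3)
        np.testing.assert_allclose(m.mixing_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert m.mixing_matrix.shape == (60, 60)
        # diagonal dominant: self-weight is the largest in each row
        assert np.all(np.argmax(m.mixing_matrix, axis=1) == np.arange(60))

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            synth.MixingModel(mixing_matrix=np.ones((3, 3)))


class TestOneOverFNoise:
    def test_spectrum_slopes_downward(self, rng):
        x = synth._one_over_f_noise(rng, 2**14, 1.0, 1.0)
        f = np.fft.rfftfreq(len(x))
        p = np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        assert lo > 10 * hi
        assert x.std() == pytest.approx(1.0, rel=1e-6)


class TestMatrixSampler:
    def test_symmetry_bounds_zero_diagonal(self, rng):
        mats = synth.sample_wpli_matrices(rng, 5, [f"n{i}" for i in range(8)])
        assert mats.shape == (5, 8, 8)
        np.testing.assert_array_equal(mats, np.transpose(mats, (0, 2, 1)))
        assert np.all((mats >= 0) & (mats <= 1))
        assert np.all(np.diagonal(mats, axis1=1, axis2=2) == 0)

    def test_planted_delta_shifts_group_a_only(self, rng):
        labels = [f"n{i}" for i in range(10)]
        a, b = synth.sample_study_wpli(rng, 30, labels,
                                       planted=[([("n0", "n1")], 0.3)])
        da = a[:, 0, 1].mean() - b[:, 0, 1].mean()
        dother = a[:, 2, 3].mean() - b[:, 2, 3].mean()
        assert da == pytest.approx(0.3, abs=0.08)
        assert abs(dother) < 0.08


def test_write_study_layout(tmp_path):
    d = small_design(duration=4.0)
    study = synth.generate_group_study(d)
    out = synth.write_study(study, tmp_path / "study")
    assert (out / "manifest.json").exists()
    assert (out / "montage.tsv").exists()
    assert len(list(out.glob("*.tsv"))) == 5  # 4 subjects + montage
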