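import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hearkit.gammatone import atom_waveform, build_filterbank
from hearkit.sparse import (
    GammatoneAtom,
    SparseCode,
    load_code,
    matching_pursuit,
    privacy_report,
    rasterize,
    rasterize_with_shape,
    reconstruct,
    save_code,
)

from conftest import brute_force_mp


class TestMatchingPursuit:
    def test_zero_signal_early_stops_with_no_atoms(self, toy_bank):
        code = matching_pursuit(np.zeros(300), toy_bank, K=10)
        assert len(code) == 0
        assert code.residual_energy == 0.0

    def test_recovers_a_planted_single_atom(self, toy_bank):
        x = 0.5 * atom_waveform(toy_bank, 2, 100, 400)
        code = matching_pursuit(x, toy_bank, K=4)
        first = code.atoms[0]
        assert (first.filter_index, first.time_offset) == (2, 100)
        assert first.amplitude == pytest.approx(0.5, abs=1e-6)
        assert code.residual_energy <= 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_selections_match_exhaustive_oracle(self, toy_bank, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        oracle, oracle_residual = brute_force_mp(x, toy_bank, 5)
        code = matching_pursuit(x, toy_bank, 5)
        for (m, t, a), atom in zip(oracle, code.atoms):
            assert (m, t) == (atom.filter_index, atom.time_offset)
            assert a == pytest.approx(atom.amplitude, rel=1e-9, abs=1e-12)
        assert code.residual_energy == pytest.approx(
            float(oracle_residual @ oracle_residual), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_energy_conservation_and_monotone_residual(self, toy_bank, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal(400)
        energies = []
        for K in (1, 5, 20, 60):
            code = matching_pursuit(x, toy_bank, K)
            total = sum(a.amplitude**2 for a in code.atoms) + code.residual_energy
            assert total == pytest.approx(code.initial_energy, rel=1e-6)
            energies.append(code.residual_energy)
        # residual energy is non-increasing in K
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(energies, energies[1:]))

    def test_binaural_input_is_downmixed(self, toy_bank):
        rng = np.random.default_rng(5)
        left = rng.standard_normal(300)
        right = rng.standard_normal(300)
        stereo = np.stack([left, right], axis=1)
        code_stereo = matching_pursuit(stereo, toy_bank, 3)
        code_mono = matching_pursuit((left + right) / 2, toy_bank, 3)
        assert [(a.filter_index, a.time_offset) for a in code_stereo.atoms] == [
            (a.filter_index, a.time_offset) for a in code_mono.atoms
        ]

    def test_invalid_inputs_rejected(self, toy_bank):
        with pytest.raises(ValueError):
            matching_pursuit(np.array([]), toy_bank, 3)
        with pytest.raises(ValueError):
            matching_pursuit(np.array([1.0, np.nan]), toy_bank, 3)
        with pytest.raises(ValueError):
            matching_pursuit(np.ones(10), toy_bank, 0)


class TestMatchingPursuitProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        x=arrays(
            np.float64,
            st.integers(64, 320),
            elements=st.floats(-4, 4, allow_nan=False, width=64),
        ),
        K=st.integers(1, 12),
    )
    def test_energy_identity_and_monotone_residual_hold_for_any_input(self, x, K):
        bank = build_filterbank(M=4, fmin=100, fmax=1500, sample_rate=4000)
        code = matching_pursuit(x, bank, K)
        if code.initial_energy == 0.0:
            assert len(code) == 0
            return
        total = sum(a.amplitude**2 for a in code.atoms) + code.residual_energy
        assert total == pytest.approx(code.initial_energy, rel=1e-6)
        assert code.residual_energy <= code.initial_energy * (1 + 1e-12)
        # every atom references a valid filter and in-signal offset
        for atom in code.atoms:
            assert 0 <= atom.filter_index < 4
            assert 0 <= atom.time_offset < code.signal_length


class TestReconstruct:
    def test_empty_code_gives_silence(self, toy_bank):
        code = SparseCode([], 128, toy_bank.sample_rate, 0.0, 0.0)
        assert np.array_equal(reconstruct(code, toy_bank), np.zeros(128))

    def test_single_atom_code_is_scaled_waveform(self, toy_bank):
        code = SparseCode(
            [GammatoneAtom(1, 10, 0.5)], 400, toy_bank.sample_rate, 0.0, 1.0
        )
        expected = 0.5 * atom_waveform(toy_bank, 1, 10, 400)
        assert np.allclose(reconstruct(code, toy_bank), expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_residual_identity_for_mp_codes(self, toy_bank, seed):
        x = np.random.default_rng(200 + seed).standard_normal(350)
        code = matching_pursuit(x, toy_bank, 25)
        xhat = reconstruct(code, toy_bank)
        assert float(np.sum((x - xhat) ** 2)) == pytest.approx(
            code.residual_energy, rel=1e-6
        )

    def test_sample_rate_mismatch_rejected(self, toy_bank):
        other = build_filterbank(M=4, fmin=100, fmax=1500, sample_rate=8000)
        x = np.random.default_rng(0).standard_normal(200)
        code = matching_pursuit(x, toy_bank, 3)
        with pytest.raises(ValueError):
            reconstruct(code, other)


class TestRasterize:
    def test_empty_code_gives_zero_grid(self, toy_bank):
        code = SparseCode([], 100, toy_bank.sample_rate, 0.0, 0.0)
        feat = rasterize_with_shape(code, bin_width=10, n_filters=4)
        assert feat.grid.shape == (4, 10)
        assert not feat.grid.any()

    def test_single_atom_lands_in_one_cell_with_magnitude(self):
        code = SparseCode([GammatoneAtom(3, 2 * 16 + 1, -2.0)], 160, 1000.0, 0.0, 4.0)
        feat = rasterize_with_shape(code, bin_width=16, transform="linear", n_filters=5)
        assert feat.grid[3, 2] == pytest.approx(2.0)
        assert np.count_nonzero(feat.grid) == 1

    def test_linear_grid_total_equals_sum_of_magnitudes(self, toy_bank):
        x = np.random.default_rng(3).standard_normal(300)
        code = matching_pursuit(x, toy_bank, 30)
        feat = rasterize_with_shape(code, bin_width=25, transform="linear", n_filters=4)
        assert feat.grid.sum() == pytest.approx(
            sum(abs(a.amplitude) for a in code.atoms), rel=1e-12
        )

    def test_invariant_to_atom_order(self, toy_bank):
        x = np.random.default_rng(4).standard_normal(300)
        code = matching_pursuit(x, toy_bank, 20)
        shuffled = SparseCode(
            list(reversed(code.atoms)),
            code.signal_length,
            code.sample_rate,
            code.residual_energy,
            code.initial_energy,
        )
        a = rasterize_with_shape(code, 25, "log1p", n_filters=4).grid
        b = rasterize_with_shape(shuffled, 25, "log1p", n_filters=4).grid
        assert np.allclose(a, b)

    def test_grid_dimensions_cover_the_signal(self, toy_bank):
        code = SparseCode([], 257, toy_bank.sample_rate, 0.0, 0.0)
        feat = rasterize_with_shape(code, bin_width=16, n_filters=4)
        assert feat.grid.shape[1] == int(np.ceil(257 / 16))

    def test_bad_parameters_rejected(self, toy_bank):
        code = SparseCode([], 100, toy_bank.sample_rate, 0.0, 0.0)
        with pytest.raises(ValueError):
            rasterize(code, bin_width=0)
        with pytest.raises(ValueError):
            rasterize(code, bin_width=10, transform="sqrt")


class TestPrivacyReport:
    def test_zero_signal_retained_fraction_is_zero(self, toy_bank):
        code = matching_pursuit(np.zeros(100), toy_bank, 3)
        rep = privacy_report(code, np.zeros(100), toy_bank)
        assert rep["retained_energy_fraction"] == 0.0

    def test_exact_single_atom_signal_fully_retained(self, toy_bank):
        x = 0.7 * atom_waveform(toy_bank, 1, 50, 400)
        code = matching_pursuit(x, toy_bank, 2)
        rep = privacy_report(code, x, toy_bank)
        assert rep["retained_energy_fraction"] == pytest.approx(1.0, abs=1e-9)

    def test_retained_fraction_matches_direct_recomputation(self, toy_bank):
        x = np.random.default_rng(11).standard_normal(4000)
        code = matching_pursuit(x, toy_bank, 16)
        rep = privacy_report(code, x, toy_bank)
        xhat = reconstruct(code, toy_bank)
        direct = 1.0 - np.sum((x - xhat) ** 2) / np.sum(x**2)
        assert rep["retained_energy_fraction"] == pytest.approx(direct, rel=1e-6)

    def test_length_mismatch_rejected(self, toy_bank):
        code = matching_pursuit(np.ones(100), toy_bank, 2)
        with pytest.raises(ValueError):
            privacy_report(code, np.ones(101), toy_bank)


class TestSerialization:
    def test_code_round_trip(self, toy_bank, tmp_path):
        x = np.random.default_rng(21).standard_normal(300)
        code = matching_pursuit(x, toy_bank, 15)
        save_code(code, tmp_path / "c.csv")
        code2 = load_code(tmp_path / "c.csv")
        assert code2.atoms == code.atoms
        assert code2.signal_length == code.signal_length
        assert code2.residual_energy == pytest.approx(code.residual_energy)

    def test_serialized_form_holds_no_raw_samples(self, toy_bank, tmp_path):
        """Privacy contract: the files store only atom triples and scalars."""
        x = np.random.default_rng(22).standard_normal(500)
        code = matching_pursuit(x, toy_bank, 10)
        save_code(code, tmp_path / "c.csv")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "c.csv")
        assert list(df.columns) == [
            "atom_rank",
            "filter_index",
            "time_offset_samples",
            "amplitude",
        ]
        assert len(df) == 10 < code.signal_length
        meta = json.loads((tmp_path / "c.json").read_text())
        assert all(np.isscalar(v) for v in meta.values())
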