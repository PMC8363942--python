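"""B-tensor construction, waveform integration and protocol plumbing."""

import numpy as np
import pytest

from somamap.protocol import (
    GYROMAGNETIC_RATIO,
    BTensor,
    GradientWaveform,
    Shell,
    btensor_from_waveform,
    default_protocol,
    fibonacci_directions,
    load_protocol,
    make_btensor,
    read_scheme,
    save_protocol,
    shape_of,
    split_directions,
    write_scheme,
)


class TestMakeBTensor:
    def test_ste_is_isotropic(self):
        bt = make_btensor(1000.0, 0.0, [0.0, 1.0, 0.0])
        assert np.allclose(bt.matrix, np.eye(3) * 1000.0 / 3.0)

    def test_lte_is_rank_one(self):
        bt = make_btensor(1000.0, 1.0, [1.0, 0.0, 0.0])
        expected = np.zeros((3, 3))
        expected[0, 0] = 1000.0
        assert np.allclose(bt.matrix, expected)
        assert np.linalg.matrix_rank(bt.matrix, tol=1e-6) == 1

    def test_planar_shape(self):
        bt = make_btensor(3000.0, -0.5, [0.0, 0.0, 1.0])
        assert np.allclose(bt.matrix, np.diag([1500.0, 1500.0, 0.0]))
        assert np.isclose(bt.b, 3000.0)

    @pytest.mark.parametrize("b,bdelta", [(500.0, 1.0), (2000.0, 0.0),
                                          (3500.0, -0.5), (1234.5, 0.3)])
    def test_trace_equals_b(self, b, bdelta, rng):
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        assert np.isclose(make_btensor(b, bdelta, n).b, b, rtol=1e-12)

    def test_ste_direction_invariant(self, rng):
        mats = [make_btensor(800.0, 0.0, v / np.linalg.norm(v)).matrix
                for v in rng.standard_normal((5, 3))]
        for m in mats[1:]:
            assert np.allclose(m, mats[0])

    def test_rejects_non_unit_direction(self):
        with pytest.raises(ValueError, match="unit"):
            make_btensor(1000.0, 1.0, [2.0, 0.0, 0.0])

    def test_rejects_out_of_range_shape(self):
        with pytest.raises(ValueError, match="b_delta"):
            make_btensor(1000.0, 1.5, [1.0, 0.0, 0.0])


def _pgse_waveform(g_mT_m, delta, big_delta, dt):
    """Rectangular pulse pair along x, refocusing pulse mid-gap."""
    n_pulse = int(round(delta / dt))
    n_gap = int(round((big_delta - delta) / dt))
    gx = np.concatenate([
        np.full(n_pulse, g_mT_m), np.zeros(n_gap), np.full(n_pulse, g_mT_m),
    ])
    samples = np.zeros((3, gx.size))
    samples[0] = gx
    return GradientWaveform(samples, dt, rf_flip_index=n_pulse + n_gap // 2)


class TestWaveformIntegration:
    def test_stejskal_tanner_closed_form(self):
        g, delta, big_delta, dt = 40.0, 0.020, 0.040, 1e-5
        w = _pgse_waveform(g, delta, big_delta, dt)
        bt = btensor_from_waveform(w)
        b_expected = (GYROMAGNETIC_RATIO * g * 1e-3 * delta) ** 2 \
            * (big_delta - delta / 3.0) * 1e-6  # s/mm^2
        assert abs(bt.matrix[0, 0] - b_expected) < 1e-3 * b_expected
        assert np.allclose(bt.matrix[1:], 0.0)

    def test_zero_waveform(self):
        w = GradientWaveform(np.zeros((3, 100)), 1e-5, rf_flip_index=50)
        assert np.allclose(btensor_from_waveform(w).matrix, 0.0)

    def test_rotation_equivariance(self, rng):
        w = _pgse_waveform(30.0, 0.01, 0.03, 1e-5)
        # random rotation via QR decomposition
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = GradientWaveform(q @ w.samples, w.dt, w.rf_flip_index)
        b_rot = btensor_from_waveform(rotated).matrix
        b_ref = btensor_from_waveform(w).matrix
        assert np.allclose(b_rot, q @ b_ref @ q.T, atol=1e-9 * b_ref.max())

    def test_non_rephased_waveform_rejected(self):
        samples = np.zeros((3, 100))
        samples[0] = 10.0  # constant gradient, never refocused
        w = GradientWaveform(samples, 1e-5, rf_flip_index=100)
        with pytest.raises(ValueError, match="rephase"):
            btensor_from_waveform(w)


class TestShapeOf:
    @pytest.mark.parametrize("b,bdelta", [(2000.0, 0.0), (5000.0, 1.0),
                                          (1500.0, 0.6), (900.0, -0.4)])
    def test_round_trip(self, b, bdelta):
        bt = make_btensor(b, bdelta, [0.0, 1.0, 0.0])
        b_out, bd_out = shape_of(bt)
        assert np.isclose(b_out, b) and np.isclose(bd_out, bdelta)

    def test_planar_eigenvalues(self):
        b, bd = shape_of(BTensor(np.diag([1500.0, 1500.0, 0.0])))
        assert np.isclose(b, 3000.0) and np.isclose(bd, -0.5)

    def test_rejects_non_axially_symmetric(self):
        with pytest.raises(ValueError, match="axially symmetric"):
            shape_of(BTensor(np.diag([100.0, 700.0, 1500.0])))


class TestProtocol:
    def test_default_shells(self, protocol):
        ste = [s for s in protocol.shells if s.b_delta == 0.0]
        lte = [s for s in protocol.shells if s.b_delta == 1.0]
        assert [s.b for s in ste] == [0.5, 1.0, 1.5, 2.0]
        assert [s.b for s in lte] == [1.0, 2.0, 3.5, 5.0]
        assert sum(s.n_dirs for s in ste) == 128
        assert sum(s.n_dirs for s in lte) == 128
        assert protocol.te == 0.094 and protocol.n_b0 == 12

    def test_fingerprint_sensitive_to_shells(self, protocol):
        other = default_protocol(n_dirs_per_encoding=64)
        assert protocol.fingerprint() != other.fingerprint()
        assert protocol.fingerprint() == default_protocol().fingerprint()

    def test_split_directions(self):
        assert split_directions(128, 4) == [32, 32, 32, 32]
        assert split_directions(30, 4) == [7, 7, 8, 8]

    def test_shell_validation(self):
        with pytest.raises(ValueError):
            Shell(-1.0, 0.0, 32)
        with pytest.raises(ValueError):
            Shell(1.0, 1.2, 32)
        with pytest.raises(ValueError):
            Shell(1.0, 0.0, 0)

    def test_json_round_trip(self, protocol, tmp_path):
        path = tmp_path / "protocol.json"
        save_protocol(protocol, path)
        loaded = load_protocol(path)
        assert loaded.fingerprint() == protocol.fingerprint()

    def test_scheme_round_trip(self, protocol, tmp_path):
        path = tmp_path / "scheme.txt"
        table = write_scheme(protocol, path)
        loaded = read_scheme(path)
        assert loaded.shape == (protocol.n_b0 + int(protocol.n_dirs.sum()), 5)
        assert np.allclose(loaded, table, atol=1e-6)
        # direction rows are unit vectors
        dirs = loaded[protocol.n_b0:, 2:]
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-5)


class TestDirections:
    def test_unit_norm_and_balance(self):
        d = fibonacci_directions(128)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert np.linalg.norm(d.mean(axis=0)) < 0.05

    def test_deterministic(self):
        assert np.array_equal(fibonacci_directions(32, seed=3),
                              fibonacci_directions(32, seed=3))
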