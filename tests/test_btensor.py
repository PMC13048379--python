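"""b-tensor algebra: waveform integration, shapes, schemes, file I/O."""

import numpy as np
import pytest

from cortiq.btensor import (
    GAMMA_PROTON,
    BTensor,
    BTensorScheme,
    GradientWaveform,
    ProtocolConfig,
    build_protocol_scheme,
    electrostatic_directions,
    make_shape_btensor,
    mat_to_voigt,
    split_ste_axes,
    ste_waveform,
    voigt_to_mat,
    waveform_to_btensor,
)

from conftest import random_rotation


def pgse_waveform(G=50.0, delta=10.0, Delta=20.0, dt=0.01, axis=2):
    """Rectangular bipolar (Stejskal-Tanner) pulse pair.

    The lobes sit strictly inside the sampled window with identical
    sample patterns, so trapezoidal integration rephases exactly.
    """
    n = int(round((Delta + delta) / dt)) + 3
    t = np.arange(n) * dt
    g = np.zeros((n, 3))
    g[(t >= dt) & (t < delta + dt), axis] = G
    g[(t >= Delta + dt) & (t < Delta + delta + dt), axis] = -G
    return GradientWaveform(g, dt)


def stejskal_tanner_b(G, delta, Delta):
    return (GAMMA_PROTON * G * delta) ** 2 * (Delta - delta / 3.0) * 1e-9


class TestWaveformToBTensor:
    def test_matches_stejskal_tanner_closed_form(self):
        w = pgse_waveform(G=50.0, delta=10.0, Delta=20.0, dt=0.001)
        b = waveform_to_btensor(w)
        expected = stejskal_tanner_b(50.0, 10.0, 20.0)
        assert b.b == pytest.approx(expected, rel=1e-3)
        assert b.classify() == "linear"
        # all encoding on the z axis
        assert b.matrix[2, 2] == pytest.approx(b.b, rel=1e-6)

    def test_convergence_under_dt_halving(self):
        expected = stejskal_tanner_b(40.0, 8.0, 16.0)
        errs = []
        for dt in (0.02, 0.01, 0.005, 0.0025):
            b = waveform_to_btensor(pgse_waveform(40.0, 8.0, 16.0, dt))
            errs.append(abs(b.b - expected) / expected)
        assert errs[-1] < 1e-3  # < 0.1% as dt -> 0
        assert errs == sorted(errs, reverse=True)

    def test_zero_waveform_gives_zero_tensor(self):
        w = GradientWaveform(np.zeros((100, 3)), 0.01)
        b = waveform_to_btensor(w)
        assert b.b == 0.0
        assert np.allclose(b.matrix, 0.0)

    def test_non_rephasing_waveform_raises_with_residual(self):
        g = np.zeros((200, 3))
        g[:, 2] = 30.0  # never refocused
        with pytest.raises(ValueError, match="residual"):
            waveform_to_btensor(GradientWaveform(g, 0.01))

    def test_protocol_ste_recovers_trace_2000(self):
        b = waveform_to_btensor(ste_waveform(b=2000.0))
        assert b.b == pytest.approx(2000.0, rel=0.01)
        assert b.classify() == "spherical"


class TestSplitSteAxes:
    def test_lte_is_rank_one(self):
        lte, _ = split_ste_axes(ste_waveform(b=1400.0))
        ev = waveform_to_btensor(lte).eigenvalues
        assert ev[1] / ev[0] < 0.05

    def test_pte_has_two_equal_eigenvalues(self):
        _, pte = split_ste_axes(ste_waveform(b=1400.0))
        ev = waveform_to_btensor(pte).eigenvalues
        assert ev[0] == pytest.approx(ev[1], rel=0.05)
        assert ev[2] / ev[0] < 0.05

    def test_split_sums_to_parent(self):
        w = ste_waveform(b=700.0)
        b = waveform_to_btensor(w).matrix
        lte, pte = split_ste_axes(w)
        total = waveform_to_btensor(lte).matrix + waveform_to_btensor(pte).matrix
        assert np.allclose(total, b, atol=1e-3 * np.trace(b))

    def test_degenerate_axis_raises(self):
        w = ste_waveform(b=700.0)
        g = w.samples.copy()
        g[:, 2] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            split_ste_axes(GradientWaveform(g, w.dt))


class TestMakeShapeBTensor:
    @pytest.mark.parametrize(
        "shape,b,orientation,expected",
        [
            ("spherical", 2000.0, None, np.eye(3) * 2000.0 / 3.0),
            ("linear", 1400.0, (0, 0, 1), np.diag([0.0, 0.0, 1400.0])),
            ("planar", 700.0, (0, 0, 1), np.diag([350.0, 350.0, 0.0])),
        ],
    )
    def test_analytic_shapes(self, shape, b, orientation, expected):
        bt = make_shape_btensor(shape, b, orientation)
        assert np.allclose(bt.matrix, expected)
        assert bt.b == pytest.approx(b)

    def test_unknown_shape_and_bad_orientation(self):
        with pytest.raises(ValueError, match="unknown shape"):
            make_shape_btensor("oblate", 1000.0, (0, 0, 1))
        with pytest.raises(ValueError, match="unit vector"):
            make_shape_btensor("linear", 1000.0, (0, 0, 2))

    def test_rotation_leaves_trace_invariant(self, rng):
        for _ in range(100):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            for shape in ("linear", "planar"):
                bt = make_shape_btensor(shape, 1234.5, n)
                assert bt.b == pytest.approx(1234.5, rel=1e-9)


class TestBTensorValidation:
    def test_rejects_negative_eigenvalues(self):
        m = np.diag([100.0, 50.0, -10.0])
        with pytest.raises(ValueError, match="negative eigenvalue"):
            BTensor(m)

    def test_rejects_inconsistent_shape_label(self):
        with pytest.raises(ValueError, match="inconsistent"):
            BTensor(np.diag([1000.0, 0.0, 0.0]), shape="spherical")


class TestVoigt:
    def test_round_trip(self, rng):
        a = rng.standard_normal((5, 3, 3))
        a = a + np.swapaxes(a, 1, 2)
        assert np.allclose(voigt_to_mat(mat_to_voigt(a)), a)

    def test_inner_product_preserved(self, rng):
        a = rng.standard_normal((3, 3))
        a = a + a.T
        b = rng.standard_normal((3, 3))
        b = b + b.T
        assert mat_to_voigt(a) @ mat_to_voigt(b) == pytest.approx(
            np.sum(a * b)
        )


class TestProtocolScheme:
    def test_default_has_four_shells(self, protocol_scheme):
        assert np.allclose(
            protocol_scheme.shells(), [200.0, 700.0, 1400.0, 2000.0]
        )

    def test_ten_spherical_per_shell(self, protocol_scheme):
        bvals = protocol_scheme.bvals
        shapes = np.array(protocol_scheme.shapes)
        for b in (200.0, 700.0, 1400.0, 2000.0):
            n = np.sum((np.abs(bvals - b) < 1.0) & (shapes == "spherical"))
            assert n == 10

    def test_single_shell_single_shape_rejected(self):
        cfg = ProtocolConfig(
            shells=(1000.0,), ste_per_shell=0, lte_per_shell=40,
            pte_per_shell=0, n_b0=0,
        )
        with pytest.raises(ValueError):
            build_protocol_scheme(cfg)

    def test_too_few_measurements_rejected(self):
        cfg = ProtocolConfig(
            shells=(700.0, 1400.0), ste_per_shell=2, lte_per_shell=2,
            pte_per_shell=2, n_b0=1,
        )
        with pytest.raises(ValueError, match="28"):
            build_protocol_scheme(cfg)

    def test_deterministic_rebuild(self):
        s1 = build_protocol_scheme()
        s2 = build_protocol_scheme()
        assert np.array_equal(s1.matrices, s2.matrices)

    def test_file_round_trip(self, protocol_scheme, tmp_path):
        path = tmp_path / "scheme.txt"
        protocol_scheme.save(path)
        loaded = BTensorScheme.load(path)
        assert np.allclose(loaded.matrices, protocol_scheme.matrices)
        assert loaded.shapes == protocol_scheme.shapes

    def test_matrix_dialect_reader(self, tmp_path):
        path = tmp_path / "scheme9.txt"
        rows = []
        for b, shape, ori in [
            (1000.0, "linear", (0.0, 0.0, 1.0)),
            (900.0, "spherical", None),
        ] * 20:
            m = make_shape_btensor(shape, b, ori).matrix
            rows.append(" ".join(f"{x:.8g}" for x in m.ravel()))
        path.write_text("\n".join(rows) + "\n")
        scheme = BTensorScheme.load(path)
        assert len(scheme) == 40
        assert scheme.btensors[0].classify() == "linear"
        assert scheme.btensors[1].classify() == "spherical"


def test_electrostatic_directions_are_unit_and_spread():
    x = electrostatic_directions(10, seed=1234)
    assert np.allclose(np.linalg.norm(x, axis=1), 1.0)
    # antipodally-aware minimum angle should be well above random
    cos = np.abs(x @ x.T)
    np.fill_diagonal(cos, 0.0)
    assert np.max(cos) < 0.95
    assert np.array_equal(x, electrostatic_directions(10, seed=1234))


def test_waveform_file_round_trip(tmp_path):
    from cortiq.btensor import load_waveform, save_waveform

    w = ste_waveform(b=700.0)
    save_waveform(w, tmp_path / "w.txt")
    loaded = load_waveform(tmp_path / "w.txt")
    assert loaded.dt == pytest.approx(w.dt, rel=1e-6)
    assert np.allclose(loaded.samples, w.samples, atol=1e-6)
    b1 = waveform_to_btensor(w)
    b2 = waveform_to_btensor(loaded)
    assert np.allclose(b1.matrix, b2.matrix, rtol=1e-5, atol=1e-4 * b1.b)


def test_waveform_file_rejects_nonuniform_time(tmp_path):
    from cortiq.btensor import load_waveform

    (tmp_path / "bad.txt").write_text("0 0 0 0\n0.1 1 0 0\n0.35 0 0 0\n")
    with pytest.raises(ValueError, match="uniform"):
        load_waveform(tmp_path / "bad.txt")
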