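import numpy as np
import pandas as pd
import pytest

from bypassflow import metrics as mx
from bypassflow.fields import WallMesh, WSSField, make_wall_mesh
from bypassflow.geometry import default_windows
from bypassflow.synthwss import RegimeSpec, generate_field


def single_node_field(fn, n_steps=1000, period=1.0):
    """Build a 1-node field from tau(t) given as a (n_steps, 3) array."""
    t = np.arange(n_steps) / n_steps * period
    vals = np.asarray(fn(t), dtype=float).reshape(1, n_steps, 3)
    return WSSField(vals, period=period)


def axial(series):
    def fn(t):
        out = np.zeros((len(t), 3))
        out[:, 0] = series(t)
        return out
    return fn


class TestTawss:
    def test_constant(self):
        f = single_node_field(axial(lambda t: np.ones_like(t)))
        assert mx.tawss(f, 0) == pytest.approx(1.0, rel=1e-12)

    def test_rectified_sinusoid_mean(self):
        a = 2.3
        f = single_node_field(axial(lambda t: a * np.sin(2 * np.pi * t)))
        assert mx.tawss(f, 0) == pytest.approx(2 * a / np.pi, rel=5e-3)

    def test_zero_field(self):
        f = single_node_field(lambda t: np.zeros((len(t), 3)))
        assert mx.tawss(f, 0) == 0.0

    def test_rejects_nonfinite(self):
        vals = np.zeros((1, 16, 3))
        vals[0, 3, 0] = np.nan
        with pytest.raises(ValueError):
            WSSField(vals)

    def test_too_few_steps(self):
        with pytest.raises(ValueError):
            mx.tawss(WSSField(np.zeros((1, 4, 3))))


class TestOsi:
    def test_unidirectional_is_zero(self):
        f = single_node_field(axial(lambda t: 1.0 + 0.4 * np.sin(
            2 * np.pi * t)))
        assert mx.osi(f, 0) == pytest.approx(0.0, abs=1e-12)

    def test_pure_sinusoid_is_half(self):
        f = single_node_field(axial(lambda t: np.sin(2 * np.pi * t)))
        assert mx.osi(f, 0) == pytest.approx(0.5, abs=1e-3)

    def test_biased_sinusoid_analytic(self):
        f = single_node_field(axial(lambda t: 0.5 + np.sin(2 * np.pi * t)))
        assert mx.osi(f, 0) == pytest.approx(0.1518, abs=0.002)


class TestRrt:
    def test_unit_case(self):
        val, capped = mx.rrt(1.0, 0.0)
        assert val == 1.0 and not capped

    def test_arithmetic(self):
        val, _ = mx.rrt(0.05, 0.25)
        assert val == pytest.approx(40.0, rel=1e-12)

    def test_singular_limit_capped_and_flagged(self):
        val, capped = mx.rrt(1.0, 0.5)
        assert capped and val == mx.RRT_CEILING

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mx.rrt(-1.0, 0.1)


class TestTransWss:
    def test_planar_unidirectional_is_zero(self):
        f = single_node_field(axial(lambda t: 1.0 + 0.3 * np.sin(
            2 * np.pi * t)))
        tw, undef = mx.transwss(f, 0, normals=np.array([0.0, 0.0, 1.0]))
        assert tw == pytest.approx(0.0, abs=1e-9)
        assert not undef

    def test_transverse_sinusoid_mean(self):
        def fn(t):
            out = np.zeros((len(t), 3))
            out[:, 0] = 1.0
            out[:, 1] = np.sin(2 * np.pi * t)
            return out
        f = single_node_field(fn)
        tw, _ = mx.transwss(f, 0, normals=np.array([0.0, 0.0, 1.0]))
        assert tw == pytest.approx(2 / np.pi, rel=5e-3)

    def test_zero_field_flagged(self):
        f = single_node_field(lambda t: np.zeros((len(t), 3)))
        tw, undef = mx.transwss(f, 0, normals=np.array([0.0, 0.0, 1.0]))
        assert tw == 0.0 and undef

    def test_non_unit_normal_rejected(self):
        f = single_node_field(axial(lambda t: np.ones_like(t)))
        with pytest.raises(ValueError):
            mx.transwss(f, 0, normals=np.array([0.0, 0.0, 2.0]))


class TestComputeAll:
    def test_pf_only_field_low_osi(self, windows):
        mesh = make_wall_mesh(windows, nodes_per_mm=4, n_circ=4)
        specs = {"PF": RegimeSpec("PF", 0.32, 0.06, 0.02)}
        field = generate_field(mesh, windows, specs,
                               transition_halfwidth=50.0)
        df = mx.compute_all(field, mesh)
        assert (df["osi"] <= 0.1).all()

    def test_zero_field_all_flagged(self, windows):
        mesh = make_wall_mesh(windows, nodes_per_mm=2, n_circ=2)
        field = WSSField(np.zeros((mesh.n_nodes, 16, 3)))
        df = mx.compute_all(field, mesh)
        assert (df["tawss"] == 0).all()
        assert df["flag_rrt_capped"].all()
        assert df["flag_mean_dir_undefined"].all()

    def test_phase_shift_invariance(self, default_field):
        mesh, field = default_field
        shifted = WSSField(np.roll(field.values, 37, axis=1), field.period)
        a = mx.compute_all(field, mesh)
        b = mx.compute_all(shifted, mesh)
        for col in ("tawss", "osi", "transwss"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-6,
                                       atol=1e-12)

    def test_rrt_pointwise_identity(self, default_field):
        mesh, field = default_field
        df = mx.compute_all(field, mesh)
        ok = ~df["flag_rrt_capped"]
        expected = 1.0 / ((1 - 2 * df["osi"][ok])
                          * (df["tawss"][ok] / 10.0))
        np.testing.assert_allclose(df["rrt"][ok], expected, rtol=1e-12)

    def test_quadrature_convergence(self, windows):
        # halving the time step changes smooth-waveform metrics < 0.1%
        mesh = make_wall_mesh(windows, nodes_per_mm=2, n_circ=2)
        specs = {"DS": RegimeSpec("DS", 0.11, 0.2, 0.04)}
        coarse = generate_field(mesh, windows, specs, n_steps=100,
                                transition_halfwidth=50.0)
        fine = generate_field(mesh, windows, specs, n_steps=200,
                              transition_halfwidth=50.0)
        for f in (mx.tawss, mx.osi):
            np.testing.assert_allclose(f(coarse), f(fine), rtol=1e-3)

    def test_invariants_on_random_waveforms(self):
        rng = np.random.default_rng(0)
        n = 1000
        t = np.arange(64) / 64
        vals = np.zeros((n, 64, 3))
        for k in range(3):
            amp = rng.uniform(0, 2, (n, 1))
            phase = rng.uniform(0, 2 * np.pi, (n, 1))
            bias = rng.uniform(-1, 1, (n, 1))
            vals[:, :, k] = amp * (bias + np.sin(2 * np.pi * t + phase))
        field = WSSField(vals)
        normals = np.tile([0.0, 0.0, 1.0], (n, 1))
        # make normals orthogonal-ish irrelevant: use z normal, tau has z
        vals[:, :, 2] = 0.0
        field = WSSField(vals)
        ta = mx.tawss(field)
        os_ = mx.osi(field)
        tw, _ = mx.transwss(field, normals=normals)
        assert np.all((os_ >= 0) & (os_ <= 0.5))
        assert np.all(tw <= ta + 1e-9)


class TestSummaries:
    def test_single_node_regions(self):
        df = pd.DataFrame({
            "axial_mm": [-13.0, -1.0, 1.0, 11.0],
            "tawss": [0.0, 0.1, 0.4, 0.3], "osi": [0.4, 0.2, 0.05, 0.06],
            "rrt": [1e9, 40, 5, 10], "log10_rrt": [9, 1.6, 0.7, 1],
            "transwss": [0, 0.04, 0.1, 0.02]})
        s = mx.summarize_regions(df, default_windows())
        assert (s["min"] == s["mean"]).all() and (s["max"] == s["mean"]).all()

    def test_empty_region_named_in_error(self):
        df = pd.DataFrame({
            "axial_mm": [-1.0], "tawss": [0.1], "osi": [0.2],
            "rrt": [40.0], "log10_rrt": [1.6], "transwss": [0.04]})
        with pytest.raises(ValueError, match="ST"):
            mx.summarize_regions(df, default_windows())

    def test_min_mean_max_invariant_on_random_fields(self, default_field,
                                                     windows):
        mesh, field = default_field
        s = mx.summarize_regions(mx.compute_all(field, mesh), windows)
        assert (s["min"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["max"] + 1e-12).all()

    def test_osi_region_ordering(self, default_field, windows):
        mesh, field = default_field
        s = mx.summarize_regions(mx.compute_all(field, mesh), windows)
        osi_means = s[s["metric"] == "osi"].set_index("region")["mean"]
        assert osi_means["ST"] > osi_means["DS"] > osi_means["HS"]
        assert abs(osi_means["HS"] - osi_means["PF"]) < 0.05


class TestClassify:
    def test_example_nodes(self):
        df = pd.DataFrame({
            "tawss": [1.5e-6, 0.32, 0.11, 0.35],
            "osi": [0.42, 0.06, 0.20, 0.08],
            "transwss": [0.0, 0.02, 0.04, 0.10]})
        labels = mx.classify_regimes(df)
        assert list(labels) == ["ST", "PF", "DS", "HS"]

    def test_ground_truth_recovery(self, default_field):
        mesh, field = default_field
        assert mesh.n_nodes >= 2000
        df = mx.compute_all(field, mesh)
        labels = mx.classify_regimes(df)
        acc = (labels.to_numpy() == mesh.region).mean()
        assert acc >= 0.95

    def test_malformed_thresholds(self):
        with pytest.raises(ValueError):
            mx.RegimeThresholds(high_shear_percentile=120.0)
        with pytest.raises(ValueError):
            mx.RegimeThresholds(disturbed_osi=0.7)
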