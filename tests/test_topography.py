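"""Gradient fits, IQR heterogeneity statistics, nearest neighbors, areas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tonopipe.topography import (
    FieldOfView,
    assign_area,
    field_iqr,
    fit_gradient,
    local_iqr,
    nn_delta_frequency,
    project_to_axis,
)


def _neurons(xy, bf_oct, cls=None):
    n = len(xy)
    return pd.DataFrame(
        {
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "cls": cls or ["tuned"] * n,
            "bf_oct": bf_oct,
        }
    )


class TestProjection:
    ORIGIN = np.array([100.0, 200.0])
    UNIT = np.array([0.0, 1.0])

    def test_origin_maps_to_zero(self):
        assert project_to_axis(self.ORIGIN, self.ORIGIN, self.UNIT)[0] == 0.0

    def test_displacement_along_axis(self):
        p = self.ORIGIN + 500.0 * self.UNIT
        assert project_to_axis(p, self.ORIGIN, self.UNIT)[0] == pytest.approx(0.5)

    def test_reversed_axis_negates(self):
        pts = np.array([[150.0, 700.0], [80.0, -40.0]])
        a = project_to_axis(pts, self.ORIGIN, self.UNIT)
        b = project_to_axis(pts, self.ORIGIN, -self.UNIT)
        assert np.allclose(a, -b)


class TestGradientFit:
    def test_exact_line(self):
        x = np.linspace(0, 1.2, 30)
        bf = 2.0 * 2 ** (1.0 + 2.0 * x)
        fit = fit_gradient(x, bf)
        assert fit.slope_oct_per_mm == pytest.approx(2.0)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.significant

    def test_constant_bf_degenerate(self):
        fit = fit_gradient(np.array([0.0, 0.5, 1.0]), np.array([8.0, 8.0, 8.0]))
        assert fit.slope_oct_per_mm == 0.0
        assert fit.pearson_r == 0.0
        assert fit.degenerate

    def test_zero_position_variance_errors(self):
        with pytest.raises(ValueError):
            fit_gradient(np.array([0.3, 0.3, 0.3]), np.array([2.0, 4.0, 8.0]))

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_two_point_closed_form(self, data):
        """With three collinear-x points (two distinct), the fitted slope
        equals the two-point closed form through the group means."""
        x0 = data.draw(st.floats(0, 1))
        x1 = data.draw(st.floats(1.2, 2.5))
        b0 = data.draw(st.floats(0.1, 4))
        b1 = data.draw(st.floats(0.1, 4))
        x = np.array([x0, x0, x1, x1])
        y_oct = np.array([b0, b0, b1, b1])
        fit = fit_gradient(x, 2.0 * 2**y_oct)
        if b0 != b1:
            assert fit.slope_oct_per_mm == pytest.approx((b1 - b0) / (x1 - x0), rel=1e-6)


class TestFieldIqr:
    def test_percentile_arithmetic(self):
        """BFs {0, 0.43, 0.86, 1.29, 1.72} octaves -> IQR 0.86."""
        xy = [(100 + i, 100) for i in range(5)]
        fov = FieldOfView("m", 0, 100, 100, 0.0, _neurons(xy, [0, 0.43, 0.86, 1.29, 1.72]))
        assert field_iqr(fov) == pytest.approx(0.86)

    def test_too_few_central_neurons_gives_missing(self):
        xy = [(100 + i, 100) for i in range(4)]
        fov = FieldOfView("m", 0, 100, 100, 0.0, _neurons(xy, [0.0, 0.4, 0.9, 1.3]))
        assert field_iqr(fov) is None

    def test_identical_bfs_give_zero(self):
        xy = [(95 + i, 100) for i in range(6)]
        fov = FieldOfView("m", 0, 100, 100, 0.0, _neurons(xy, [1.0] * 6))
        assert field_iqr(fov) == 0.0

    def test_agrees_with_sorted_percentile_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            bf = rng.uniform(0, 4.3, n)
            xy = [(100 + rng.uniform(-50, 50), 100 + rng.uniform(-50, 50)) for _ in range(n)]
            fov = FieldOfView("m", 0, 100, 100, 0.0, _neurons(xy, bf))
            got = field_iqr(fov)
            v = np.sort(bf)
            oracle = np.percentile(v, 75) - np.percentile(v, 25)
            assert got == pytest.approx(oracle)


class TestLocalIqr:
    def test_isolated_neuron_not_retained(self):
        df = _neurons([(0, 0), (500, 500), (900, 100)], [0.5, 1.0, 2.0])
        out = local_iqr(df, radius_um=25, seed=0)
        assert out.empty

    def test_homogeneous_cluster_gives_zero(self):
        df = _neurons([(10, 10), (15, 10), (10, 15), (12, 12)], [1.5] * 4)
        out = local_iqr(df, radius_um=25, seed=0)
        assert (out["iqr_oct"] == 0.0).all() and len(out) == 4


def test_nn_delta_trivial_pairs():
    df = _neurons([(0, 0), (10, 0)], [1.0, 1.0])
    assert np.allclose(nn_delta_frequency(df), [0.0, 0.0])
    df2 = _neurons([(0, 0), (10, 0)], [1.0, 2.0])  # 4 vs 8 kHz
    assert np.allclose(nn_delta_frequency(df2), [1.0, 1.0])


def test_nn_matches_brute_force_oracle(rng):
    """All-pairs python-loop oracle on 50 random neurons."""
    n = 50
    xy = rng.uniform(0, 200, (n, 2))
    bf = rng.uniform(0, 4.3, n)
    df = _neurons([tuple(p) for p in xy], bf)
    got = nn_delta_frequency(df)
    oracle = []
    for i in range(n):
        best_j, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = np.hypot(*(xy[i] - xy[j]))
            if d < best_d - 1e-15:
                best_d, best_j = d, j
        oracle.append(abs(bf[i] - bf[best_j]))
    assert np.allclose(got, oracle)


def test_nn_requires_two_tuned():
    df = _neurons([(0, 0)], [1.0])
    assert nn_delta_frequency(df).size == 0


class TestAssignArea:
    def setup_method(self):
        self.lf = np.zeros((10, 10), bool)
        self.hf = np.zeros((10, 10), bool)
        self.lf[2:5, 2:5] = True
        self.hf[6:9, 6:9] = True

    def test_membership(self):
        assert assign_area((3, 3), self.lf, self.hf) == "LF"
        assert assign_area((7, 7), self.lf, self.hf) == "HF"
        assert assign_area((0, 9), self.lf, self.hf) == "other"

    def test_boundary_inclusive(self):
        assert assign_area((2, 2), self.lf, self.hf) == "LF"
        assert assign_area((4, 4), self.lf, self.hf) == "LF"

    def test_frame_mismatch(self):
        with pytest.raises(ValueError):
            assign_area((0, 0), self.lf, np.zeros((5, 5), bool))


def test_heterogeneity_ordering_ct_above_tr(tr_preset, ct_preset):
    """CT populations are more locally heterogeneous than TR: median local
    IQR and nearest-neighbor delta-frequency are larger for CT in nearly all
    seeds (generator scatter ordering)."""
    from tonopipe.synthetic import sample_planes

    per_plane = {"TR": 45, "CT": 68}  # study densities
    wins_iqr = wins_nn = trials = 0
    for seed in range(20):
        vals = {}
        for preset in (tr_preset, ct_preset):
            planes = sample_planes(preset, 30, per_plane[preset.name], seed=100 + seed)
            iqrs, nns = [], []
            for pl in planes:
                df = pd.DataFrame(
                    {
                        "x_um": [n.x_um for n in pl],
                        "y_um": [n.y_um for n in pl],
                        "cls": [n.cls for n in pl],
                        "bf_oct": [n.bf_oct if n.cls == "tuned" else np.nan for n in pl],
                    }
                )
                out = local_iqr(df, seed=seed)
                iqrs.extend(out["iqr_oct"].tolist())
                nns.extend(nn_delta_frequency(df).tolist())
            vals[preset.name] = (np.median(iqrs) if iqrs else 0.0, np.median(nns))
        trials += 1
        wins_iqr += vals["CT"][0] > vals["TR"][0]
        wins_nn += vals["CT"][1] > vals["TR"][1]
    assert wins_iqr >= 19
    assert wins_nn >= 19
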