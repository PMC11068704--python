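"""Wavelet-frame construction: spline identities, enumeration, combinatorics,
and design-matrix contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavenetid.frame import (
    FrameSpec,
    build_design_matrix,
    count_wavelons,
    enumerate_frame,
    eval_displaced_scaling,
    eval_mother_wavelet,
    eval_scaling,
    eval_wavelet,
    get_family,
    normalization_from_data,
)

QUAD = get_family("quadratic_spline")
CUBIC = get_family("bicubic_spline")


class TestScalingFunctions:
    def test_interscale_coefficients_sum_to_two(self):
        for fam in (QUAD, CUBIC):
            assert fam.p.sum() == pytest.approx(2.0)
            # alternating sum vanishes -> mother wavelet has zero mean
            assert np.sum([(-1) ** n * p for n, p in enumerate(fam.p)]) == 0.0

    def test_quadratic_middle_piece_value(self):
        # natural argument 1.5 maps to x = 0.5 after [0,3] -> [0,1] rescaling:
        # -x^2 + 3x - 3/2 at 1.5 gives 0.75
        assert eval_scaling(QUAD, np.array([0.5]))[0] == pytest.approx(0.75)

    def test_quadratic_partition_of_unity_on_lattice(self):
        # phi(0.5) + phi(1.5) + phi(2.5) = 0.125 + 0.75 + 0.125 = 1
        vals = QUAD.phi_natural(np.array([0.5, 1.5, 2.5]))
        assert vals == pytest.approx([0.125, 0.75, 0.125])
        assert vals.sum() == pytest.approx(1.0)

    def test_zero_outside_unit_interval(self):
        x = np.array([-0.3, -1e-9, 1.0 + 1e-9, 2.0])
        assert np.all(eval_scaling(QUAD, x) == 0.0)
        assert np.all(eval_displaced_scaling(CUBIC, 1, 5, x) == 0.0)
        assert np.all(eval_wavelet(QUAD, 0, 1, 1, 3, x) == 0.0)

    @pytest.mark.parametrize("family", [QUAD, CUBIC])
    def test_refinement_identity(self, family):
        """phi(x) = sum_n p_n phi(2x - n) to near machine precision."""
        x = np.linspace(-1.0, family.support_length + 1.0, 20011)
        lhs = family.phi_natural(x)
        rhs = sum(p * family.phi_natural(2 * x - n) for n, p in enumerate(family.p))
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_displaced_centres(self):
        """Numeric argmax of phi_k sits at 1 - k/(N_S-1) within a grid step."""
        grid = np.linspace(0.0, 1.0, 20001)
        for fam in (QUAD, CUBIC):
            for n_s in (3, 5):
                for k in range(n_s):
                    vals = eval_displaced_scaling(fam, k, n_s, grid)
                    centre = 1.0 - k / (n_s - 1)
                    assert grid[np.argmax(vals)] == pytest.approx(
                        centre, abs=2.0 / 20000
                    )

    def test_displacement_index_out_of_range(self):
        with pytest.raises(ValueError):
            eval_displaced_scaling(QUAD, 3, 3, np.array([0.5]))

    def test_mother_wavelet_zero_integral(self):
        # interior displacement (full support inside [0,1]) integrates to 0
        x = np.linspace(0.0, 1.0, 400001)
        for fam in (QUAD, CUBIC):
            w = eval_mother_wavelet(fam, 1, 3, x)
            assert abs(np.trapezoid(w, x)) < 1e-8

    def test_wavelet_dilation_relations(self):
        x = np.linspace(0.0, 1.0, 501)
        # r=0, n=0 equals the mother wavelet
        np.testing.assert_allclose(
            eval_wavelet(QUAD, 1, 0, 0, 3, x), eval_mother_wavelet(QUAD, 1, 3, x)
        )
        # r=1, n=0 equals sqrt(2) psi_k(2x)
        np.testing.assert_allclose(
            eval_wavelet(QUAD, 1, 1, 0, 3, x),
            np.sqrt(2.0) * eval_mother_wavelet(QUAD, 1, 3, 2 * x),
        )

    def test_invalid_wavelet_indices(self):
        with pytest.raises(ValueError):
            eval_wavelet(QUAD, 0, -1, 0, 3, np.array([0.5]))
        with pytest.raises(ValueError):
            eval_wavelet(QUAD, 0, 1, 2, 3, np.array([0.5]))

    def test_scaling_level_reproduces_constants_in_interior(self):
        """Least-squares combination of the N_S=5 displaced scalings is ~1
        away from the domain edges (frame richness)."""
        x = np.linspace(0.0, 1.0, 2001)
        for fam in (QUAD, CUBIC):
            cols = np.column_stack(
                [eval_displaced_scaling(fam, k, 5, x) for k in range(5)]
            )
            coef, *_ = np.linalg.lstsq(cols, np.ones_like(x), rcond=None)
            interior = (x > 0.2) & (x < 0.8)
            err = np.abs(cols @ coef - 1.0)[interior].max()
            assert err < 0.05


class TestCombinatorics:
    @pytest.mark.parametrize(
        "ni,ns,nr,ids,expected",
        [
            # printed frame sizes for the studied configurations
            (3, 5, 1, 2, 1002),
            (3, 4, 2, 2, 2178),
            (3, 5, 2, 2, 4252),
            (4, 4, 2, 3, 24579),
            (5, 3, 1, 4, 7780),
            (5, 4, 1, 4, 32772),
            (5, 3, 2, 4, 66586),
        ],
    )
    def test_printed_wavelon_counts(self, ni, ns, nr, ids, expected):
        spec = FrameSpec(ni, ns, nr, identity_inputs=tuple(range(ids)))
        assert count_wavelons(spec) == expected

    def test_level_function_counts_three_inputs(self):
        """27 scaling-level products, 189 at r=0, 702 at r=1 for N_I=N_S=3."""
        spec0 = FrameSpec(3, 3, 0)
        spec1 = FrameSpec(3, 3, 1)
        spec2 = FrameSpec(3, 3, 2)
        assert count_wavelons(spec0) == 27
        assert count_wavelons(spec1) - count_wavelons(spec0) == 189
        assert count_wavelons(spec2) - count_wavelons(spec1) == 702

    def test_smallest_frame(self):
        spec = FrameSpec(1, 1, 1, identity_inputs=(0,))
        wavelons = enumerate_frame(spec)
        assert len(wavelons) == 3  # identity, phi, psi
        kinds = [w.kind for w in wavelons]
        assert kinds == ["identity", "product", "product"]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        ni=st.integers(1, 4),
        ns=st.integers(1, 5),
        nr=st.integers(0, 2),
        data=st.data(),
    )
    def test_enumeration_matches_closed_form(self, ni, ns, nr, data):
        ids = data.draw(
            st.lists(st.integers(0, ni - 1), unique=True, max_size=ni)
        )
        spec = FrameSpec(ni, ns, nr, identity_inputs=tuple(ids))
        wavelons = enumerate_frame(spec)
        assert len(wavelons) == count_wavelons(spec)
        assert len(set(map(repr, wavelons))) == len(wavelons)


class TestDesignMatrix:
    def test_shape_and_identity_columns(self, unit_frame, rng):
        X = rng.random((64, 3))
        G = build_design_matrix(unit_frame, X)
        assert G.shape == (64, count_wavelons(unit_frame))
        np.testing.assert_array_equal(G[:, 0], X[:, 0])
        np.testing.assert_array_equal(G[:, 1], X[:, 1])

    def test_chunked_equals_monolithic(self, unit_frame, rng):
        X = rng.random((1003, 3))
        G = build_design_matrix(unit_frame, X)
        parts = [
            build_design_matrix(unit_frame, X, rows=slice(i, i + 100))
            for i in range(0, 1003, 100)
        ]
        np.testing.assert_array_equal(G, np.vstack(parts))

    def test_input_dimension_mismatch(self, unit_frame, rng):
        with pytest.raises(ValueError):
            build_design_matrix(unit_frame, rng.random((8, 4)))

    def test_out_of_box_rows_vanish_except_identity(self, unit_frame):
        X = np.array([[0.5, 0.5, 1.7]])  # third channel outside [0,1]
        with pytest.warns(UserWarning):
            G = build_design_matrix(unit_frame, X)
        assert np.all(G[0, 2:] == 0.0)
        assert G[0, 0] == 0.5

    def test_normalization_applied(self, rng):
        spec = FrameSpec(
            2, 3, 0, identity_inputs=(0,), normalization=((-10.0, 10.0), (0.0, 4.0))
        )
        X = np.array([[0.0, 2.0]])
        G = build_design_matrix(spec, X)
        assert G[0, 0] == pytest.approx(0.5)  # identity of normalized channel

    def test_normalization_from_data_margins(self):
        X = np.array([[0.0, -1.0], [1.0, 3.0]])
        bounds = normalization_from_data(X)
        assert bounds[0] == pytest.approx((-0.05, 1.05))
        assert bounds[1] == pytest.approx((-1.2, 3.2))

    def test_tensor_products_match_explicit_evaluation(self, unit_frame, rng):
        """Columns agree with direct per-wavelon evaluation of the products."""
        X = rng.random((16, 3))
        G = build_design_matrix(unit_frame, X)
        fam = get_family(unit_frame.family)
        wavelons = enumerate_frame(unit_frame)
        for j in [2, 10, 40, 120, len(wavelons) - 1]:
            w = wavelons[j]
            col = np.ones(16)
            for i, s in enumerate(w.selectors):
                if s[0] == "scaling":
                    col *= eval_displaced_scaling(fam, s[1], 3, X[:, i])
                else:
                    _, k, r, n = s
                    col *= eval_wavelet(fam, k, r, n, 3, X[:, i])
            np.testing.assert_allclose(G[:, j], col, atol=1e-14)


class TestFrameSpecValidation:
    def test_serialization_roundtrip(self, unit_frame):
        again = FrameSpec.from_json(unit_frame.to_json())
        assert again == unit_frame

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_inputs=0, n_superpositions=3, n_levels=0),
            dict(n_inputs=2, n_superpositions=0, n_levels=0),
            dict(n_inputs=2, n_superpositions=3, n_levels=0, identity_inputs=(2,)),
            dict(
                n_inputs=2,
                n_superpositions=3,
                n_levels=0,
                normalization=((0.0, 1.0), (1.0, 1.0)),
            ),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FrameSpec(**kwargs)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            FrameSpec(2, 3, 0, family="haar")
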