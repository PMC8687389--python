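import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aemglucose import model
from aemglucose.model import (
    NOMINAL_PATIENT,
    TABLE_RANGES,
    PatientParams,
    StateBox,
    build_matrices,
    delta_bound,
    from_deviated,
    lipschitz_constant,
    phi,
    rhs,
    to_deviated,
)


class TestPatientParams:
    def test_nominal_values(self):
        p = NOMINAL_PATIENT
        assert (p.c1, p.c2, p.c3, p.c4, p.c5) == (0.0, 0.015, 2e-6, 0.2, 0.05)
        assert (p.Gb, p.Ib) == (80.0, 7.0)

    @pytest.mark.parametrize("bad", [dict(c2=0.0), dict(c4=-0.1), dict(Gb=0.0), dict(c1=-1.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            NOMINAL_PATIENT.replace(**bad)

    def test_ranges_bracket_nominal(self):
        TABLE_RANGES.validate_nominal(NOMINAL_PATIENT)
        with pytest.raises(ValueError):
            TABLE_RANGES.validate_nominal(NOMINAL_PATIENT.replace(c2=0.05))


class TestMatrices:
    def test_augmented_structure(self, mats):
        A, B, C = mats.A, mats.B, mats.C
        assert A.shape == (4, 4)
        np.testing.assert_array_equal(B, [0, 0, 1, 0])
        np.testing.assert_array_equal(C, [1, 0, 0, 0])
        # meal state feeds glucose with unit coefficient and self-decays
        assert A[0, 3] == 1.0
        assert A[3, 3] == -NOMINAL_PATIENT.c5

    def test_nominal_entries(self, mats):
        A = mats.A
        assert A[1, 1] == -0.015
        assert A[1, 2] == 2e-6
        assert A[2, 2] == -0.2
        assert A[3, 3] == -0.05
        assert A[0, 0] == 0.0  # c1 = 0 for the T1D nominal subject
        assert A[0, 1] == -80.0  # linearised bilinear term carries -Gb

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            build_matrices(NOMINAL_PATIENT.replace(c4=-1.0))


class TestRhs:
    def test_equilibrium_is_stationary(self):
        x = np.array([80.0, 0.0, 7.0, 0.0])
        np.testing.assert_allclose(rhs(0.0, x, 0.0, NOMINAL_PATIENT), 0.0, atol=1e-15)

    def test_hyperglycemic_derivatives(self):
        x = np.array([200.0, 0.001, 7.0, 0.0])
        d = rhs(0.0, x, 0.0, NOMINAL_PATIENT)
        np.testing.assert_allclose(d, [-0.2, -1.5e-5, 0.0, 0.0], rtol=1e-12)

    def test_glucose_nonnegative_at_boundary(self):
        x = np.array([0.0, 0.02, 30.0, 4.0])
        d = rhs(0.0, x, 1.0, NOMINAL_PATIENT)
        assert d[0] == pytest.approx(4.0)  # only the meal term remains
        assert d[0] >= 0

    def test_negative_insulin_is_contract_violation(self):
        with pytest.raises(ValueError):
            rhs(0.0, np.zeros(4), -1.0, NOMINAL_PATIENT)

    @given(
        x=st.lists(st.floats(0.0, 400.0), min_size=4, max_size=4),
        u=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nonnegative_orthant_is_invariant_on_faces(self, x, u):
        """On each zero face the corresponding derivative points inward."""
        x = np.asarray(x)
        for i in range(4):
            y = x.copy()
            y[i] = 0.0
            d = rhs(0.0, y, u, NOMINAL_PATIENT)
            if i == 1:  # remote action: -c2*0 + c3*(x3 - Ib) can be negative
                if y[2] >= NOMINAL_PATIENT.Ib:
                    assert d[1] >= 0
            elif i == 2:  # plasma insulin at 0: -c4*(0 - Ib) + u > 0
                assert d[2] > 0
            else:
                assert d[i] >= 0


class TestDeviated:
    def test_equilibrium_maps_to_origin(self):
        np.testing.assert_array_equal(
            to_deviated(np.array([80.0, 0.0, 7.0, 0.0])), np.zeros(4)
        )

    def test_example(self):
        np.testing.assert_allclose(
            to_deviated(np.array([200.0, 0.001, 7.0, 0.0])), [120.0, 0.001, 0.0, 0.0]
        )

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip(self, x):
        x = np.asarray(x)
        np.testing.assert_allclose(from_deviated(to_deviated(x)), x, atol=1e-9)

    def test_deviated_and_absolute_integration_agree(self):
        """Same trajectory whether integrated in absolute or deviated form."""
        from scipy.integrate import solve_ivp

        p = NOMINAL_PATIENT
        A = build_matrices(p).A
        x0 = np.array([150.0, 0.002, 12.0, 3.0])
        u = 0.5
        f_abs = lambda t, x: rhs(t, x, u, p)
        f_dev = lambda t, z: A @ z + build_matrices(p).B * u + phi(z)
        sa = solve_ivp(f_abs, (0, 200), x0, rtol=1e-10, atol=1e-12)
        sd = solve_ivp(f_dev, (0, 200), to_deviated(x0), rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            sa.y[:, -1], from_deviated(sd.y[:, -1]), rtol=1e-6, atol=1e-8
        )


class TestLipschitz:
    def test_default_box_constant(self):
        box = StateBox(x1d=(-80.0, 320.0), x2d=(0.0, 0.05), x3d=(-7.0, 93.0), d=(0.0, 10.0))
        assert lipschitz_constant(box) == pytest.approx(np.hypot(320.0, 0.05))

    def test_degenerate_box(self):
        box = StateBox(x1d=(0.0, 0.0), x2d=(0.0, 0.0), x3d=(0.0, 0.0), d=(0.0, 0.0))
        assert lipschitz_constant(box) == 0.0

    def test_unbounded_box_rejected(self):
        with pytest.raises(ValueError):
            StateBox(x1d=(-np.inf, 320.0))

    def test_sampling_oracle(self):
        """|phi(x) - phi(y)| <= L * |x - y| over random pairs, and the
        corner value is attained within 1% by the sampled supremum."""
        box = StateBox()
        L = lipschitz_constant(box)
        rng = np.random.default_rng(42)
        lows = np.array([iv[0] for iv in box.intervals])
        highs = np.array([iv[1] for iv in box.intervals])
        X = rng.uniform(lows, highs, size=(10_000, 4))
        Y = rng.uniform(lows, highs, size=(10_000, 4))
        dphi = np.abs(X[:, 0] * X[:, 1] - Y[:, 0] * Y[:, 1])
        dxy = np.linalg.norm(X - Y, axis=1)
        assert np.all(dphi <= L * dxy + 1e-9)
        # supremum of the local Jacobian norm sampled on the box
        jac = np.hypot(X[:, 0], X[:, 1]).max()
        assert jac <= L
        assert jac >= 0.99 * L


class TestDeltaBound:
    def test_table_ranges_value(self):
        # dominated by the +/-30% swing of the insulin degradation rate
        d = delta_bound(TABLE_RANGES)
        assert d == pytest.approx(0.06, rel=1e-3)

    def test_degenerate_ranges(self):
        r = model.ParamRanges(
            c2=(0.015, 0.015), c3=(2e-6, 2e-6), c4=(0.2, 0.2), c5=(0.05, 0.05)
        )
        assert delta_bound(r) == 0.0

    def test_widening_never_decreases(self):
        base = model.ParamRanges(
            c2=(0.014, 0.016), c3=(1.9e-6, 2.1e-6), c4=(0.19, 0.21), c5=(0.049, 0.051)
        )
        d0 = delta_bound(base)
        for wide in (
            base.__class__(**{**base.as_dict(), "c2": (0.012, 0.018), "c1": (0.0, 0.0)}),
            base.__class__(**{**base.as_dict(), "c4": (0.15, 0.25), "c1": (0.0, 0.0)}),
        ):
            assert delta_bound(wide) >= d0 - 1e-15


def test_default_bounds_assembly():
    b = model.default_bounds()
    assert b.X_plus == pytest.approx(
        np.sqrt(320.0**2 + 0.05**2 + 93.0**2 + 10.0**2)
    )
    assert b.D_plus == 10.0
    assert b.delta == pytest.approx(0.06, rel=1e-3)
    assert b.L_phi == pytest.approx(320.0, rel=1e-4)
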