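import logging

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sdcm.model_core import (
    BasisSet,
    DCMSpec,
    HemodynamicParams,
    NeuralConnectivity,
    SpecificationError,
    attach_basis,
    bold_gradient,
    bold_observation,
    hemodynamic_flow,
    hemodynamic_jacobian,
    make_basis_values,
    neural_flow,
    neural_jacobian,
    pack_parameters,
    unpack_parameters,
)


def random_connectivity(seed, n=2, m=1, with_gating=True):
    rng = np.random.default_rng(seed)
    conn = NeuralConnectivity(
        A=rng.standard_normal((n, n)),
        B=[rng.standard_normal((n, n)) for _ in range(m)],
        C=rng.standard_normal((n, m)),
        D=[rng.standard_normal((n, n)) for _ in range(n)] if with_gating else [],
        A_mask=np.ones((n, n), dtype=int),
        C_mask=np.ones((n, m), dtype=int),
    )
    return conn


class TestNeuralFlow:
    def test_vanishes_at_origin_without_drive(self):
        conn = random_connectivity(0)
        conn.C[:] = 0.0
        assert np.allclose(neural_flow(np.zeros(2), np.zeros(1), conn), 0.0)

    def test_single_region_product(self):
        conn = NeuralConnectivity(A=np.array([[-0.5]]), C=np.zeros((1, 1)))
        out = neural_flow(np.array([2.0]), np.array([0.0]), conn)
        assert out == pytest.approx([-1.0])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_termwise_loop_oracle(self, seed):
        """The vectorised flow equals a naive per-term summation."""
        rng = np.random.default_rng(seed)
        conn = random_connectivity(seed, n=3, m=2)
        x = rng.standard_normal(3)
        u = rng.standard_normal(2)
        expected = np.zeros(3)
        for r in range(3):
            for c in range(3):
                expected[r] += conn.A[r, c] * x[c]
                for i in range(2):
                    expected[r] += u[i] * conn.B[i][r, c] * x[c]
                for j in range(3):
                    expected[r] += x[j] * conn.D[j][r, c] * x[c]
            for i in range(2):
                expected[r] += conn.C[r, i] * u[i]
        assert np.allclose(neural_flow(x, u, conn), expected, rtol=1e-14)

    def test_linearity_without_gating(self):
        conn = random_connectivity(4, with_gating=False)
        conn.C[:] = 0.0
        rng = np.random.default_rng(5)
        x1, x2 = rng.standard_normal((2, 2))
        u = rng.standard_normal(1)
        lhs = neural_flow(2.0 * x1 + 3.0 * x2, u, conn)
        rhs = 2.0 * neural_flow(x1, u, conn) + 3.0 * neural_flow(x2, u, conn)
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_dimension_mismatch(self):
        conn = random_connectivity(0)
        with pytest.raises(SpecificationError):
            neural_flow(np.zeros(3), np.zeros(1), conn)


class TestNeuralJacobian:
    def test_constant_without_gating(self):
        conn = random_connectivity(0, with_gating=False)
        u = np.array([0.7])
        J1 = neural_jacobian(np.zeros(2), u, conn)
        J2 = neural_jacobian(np.array([3.0, -1.0]), u, conn)
        assert np.allclose(J1, J2)
        assert np.allclose(J1, conn.A + u[0] * conn.B[0])

    def test_one_region_linear(self):
        conn = NeuralConnectivity(A=np.array([[-1.0]]), C=np.zeros((1, 1)))
        for x in ([0.0], [5.0]):
            J = neural_jacobian(np.array(x), np.zeros(1), conn)
            assert np.allclose(J, [[-1.0]])

    @pytest.mark.parametrize("seed", [7, 8])
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        conn = random_connectivity(seed, n=3, m=2)
        x = rng.standard_normal(3)
        u = rng.standard_normal(2)
        J = neural_jacobian(x, u, conn)
        h = 1e-6
        for c in range(3):
            e = np.zeros(3)
            e[c] = h
            fd = (neural_flow(x + e, u, conn) - neural_flow(x - e, u, conn)) / (2 * h)
            assert np.allclose(J[:, c], fd, rtol=1e-6, atol=1e-8)


class TestHemodynamics:
    def test_origin_is_equilibrium(self):
        hp = HemodynamicParams()
        assert np.allclose(hemodynamic_flow(np.zeros(4), 0.0, hp), 0.0)

    def test_origin_locally_stable(self):
        hp = HemodynamicParams()
        J = hemodynamic_jacobian(np.zeros(4), hp)
        assert np.all(np.linalg.eigvals(J).real < 0)

    def test_jacobian_matches_finite_differences(self):
        hp = HemodynamicParams()
        rng = np.random.default_rng(0)
        x = 0.3 * rng.standard_normal(4)
        J = hemodynamic_jacobian(x, hp)
        h = 1e-6
        for c in range(4):
            e = np.zeros(4)
            e[c] = h
            fd = (hemodynamic_flow(x + e, 0.0, hp) - hemodynamic_flow(x - e, 0.0, hp)) / (2 * h)
            assert np.allclose(J[:, c], fd, rtol=1e-5, atol=1e-7)

    def test_step_response_has_main_lobe_then_undershoot(self):
        """A sustained neural drive yields a positive BOLD lobe; removing
        it produces the post-stimulus undershoot."""
        hp = HemodynamicParams()

        def rhs(t, x):
            return hemodynamic_flow(x, 1.0 if t < 10.0 else 0.0, hp)

        t_eval = np.linspace(0, 30, 601)
        sol = solve_ivp(rhs, (0, 30), np.zeros(4), t_eval=t_eval,
                        rtol=1e-9, atol=1e-11)
        y = np.array([bold_observation(sol.y[:, k], hp)
                      for k in range(sol.y.shape[1])])
        assert y.max() > 0.5
        assert y[t_eval > 15].min() < -1e-3  # undershoot after offset


class TestBoldObservation:
    def test_zero_at_rest(self):
        assert bold_observation(np.zeros(4), HemodynamicParams()) == 0.0

    def test_gradient_matches_finite_differences(self):
        hp = HemodynamicParams()
        rng = np.random.default_rng(1)
        x = 0.2 * rng.standard_normal(4)
        g = bold_gradient(x, hp)
        h = 1e-7
        for c in range(4):
            e = np.zeros(4)
            e[c] = h
            fd = (bold_observation(x + e, hp) - bold_observation(x - e, hp)) / (2 * h)
            assert g[c] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_deoxyhemoglobin_increase_lowers_signal(self):
        hp = HemodynamicParams()
        x = np.zeros(4)
        x[3] = 0.1   # more deoxyhemoglobin -> signal drop
        assert bold_observation(x, hp) < 0.0


class TestBasis:
    def test_k_zero_leaves_spec_unchanged(self):
        conn = random_connectivity(0)
        spec = DCMSpec(connectivity=conn)
        out = attach_basis(spec, "none", 0, 600.0, 1.0)
        assert out.basis.K == 0
        v0, _ = pack_parameters(spec)
        v1, _ = pack_parameters(out)
        assert v0.size == v1.size

    @pytest.mark.parametrize("kind", ["fourier", "rbf"])
    def test_32_functions_add_64_parameters(self, kind):
        conn = random_connectivity(0)
        spec = DCMSpec(connectivity=conn)
        n0 = pack_parameters(spec)[0].size
        out = attach_basis(spec, kind, 32, 600.0, 1.0)
        n1 = pack_parameters(out)[0].size
        assert n1 - n0 == 64

    def test_odd_fourier_order_rounds_down(self, caplog):
        with caplog.at_level(logging.WARNING):
            _, vals = make_basis_values("fourier", 33, 600.0, 1.0)
        assert vals.shape[0] == 32
        assert any("rounding" in r.message for r in caplog.records)

    def test_fourier_orthogonality(self):
        _, vals = make_basis_values("fourier", 8, 600.0, 1.0)
        G = vals @ vals.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_projection_r2_improves_with_k(self):
        """A smooth sinusoid mixture is reconstructed far better by 32
        Fourier functions than by 4 (least-squares projection)."""
        t = np.arange(0.0, 600.0, 1.0)
        rng = np.random.default_rng(3)
        signal = sum(a * np.sin(2 * np.pi * f * t + p)
                     for a, f, p in zip(rng.uniform(0.5, 1, 5),
                                        rng.uniform(0.003, 0.02, 5),
                                        rng.uniform(0, 2 * np.pi, 5)))

        def r2(K):
            _, vals = make_basis_values("fourier", K, 600.0, 1.0)
            coef, *_ = np.linalg.lstsq(vals.T, signal, rcond=None)
            resid = signal - vals.T @ coef
            return 1.0 - np.sum(resid**2) / np.sum((signal - signal.mean())**2)

        assert r2(32) > r2(4)
        assert r2(32) > 0.9


class TestPacking:
    def test_round_trip_identity(self):
        conn = random_connectivity(0, n=3, m=2)
        spec = DCMSpec(connectivity=conn)
        vec, imap = pack_parameters(spec)
        spec2 = unpack_parameters(vec, imap, spec)
        vec2, _ = pack_parameters(spec2)
        assert np.array_equal(vec, vec2)   # bit-exact

    def test_masked_entries_never_packed(self):
        A = np.array([[-1.0, 0.0], [0.5, -1.0]])
        conn = NeuralConnectivity(A=A, C=np.array([[1.0], [0.0]]),
                                  A_mask=np.array([[1, 0], [1, 1]]),
                                  C_mask=np.array([[1], [0]]))
        vec, imap = pack_parameters(DCMSpec(connectivity=conn))
        assert len(vec) == 4
        assert ("A", (0, 1)) not in imap.entries

    def test_vector_length_matches_combinatorial_count(self):
        conn = random_connectivity(1, n=3, m=2)
        spec = DCMSpec(connectivity=conn)
        spec = attach_basis(spec, "rbf", 10, 300.0, 1.0)
        vec, imap = pack_parameters(spec)
        expected = (int(conn.A_mask.sum()) + sum(int(np.sum(m)) for m in conn.B_masks)
                    + int(conn.C_mask.sum()) + sum(int(np.sum(m)) for m in conn.D_masks)
                    + 3 * 10)
        assert len(vec) == expected
        assert imap.n_hemo == 0

    def test_free_hemo_parameters_appended(self):
        conn = random_connectivity(2)
        spec = DCMSpec(connectivity=conn)
        spec.priors.hemodynamic_variance = 1e-2
        vec, imap = pack_parameters(spec)
        assert imap.n_hemo == 10
        spec2 = unpack_parameters(vec, imap, spec)
        assert spec2.hemo.tau_0 == pytest.approx(spec.hemo.tau_0)


class TestValidation:
    def test_table_defaults(self):
        hp = HemodynamicParams()
        assert (hp.kappa_s, hp.kappa_f, hp.tau_0, hp.alpha, hp.E_0) == \
            (0.65, 0.41, 2.0, 0.32, 0.34)
        assert (hp.V_0, hp.nu_0, hp.TE, hp.r_0, hp.epsilon_0) == \
            (4.0, 40.3, 0.04, 25.0, 1.0)

    def test_nonpositive_hemo_parameter_rejected(self):
        with pytest.raises(SpecificationError):
            HemodynamicParams(tau_0=-1.0)

    def test_basis_consistency(self):
        with pytest.raises(SpecificationError):
            BasisSet(kind="fourier", K=0)


class TestPackingProperties:
    from hypothesis import given, settings as hsettings, strategies as hst

    @hsettings(deadline=None, derandomize=True, max_examples=30)
    @given(hst.integers(min_value=0, max_value=10**6))
    def test_round_trip_with_random_masks(self, seed):
        """pack/unpack is the identity for arbitrary mask patterns, and the
        vector length always equals the number of set mask bits."""
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 4)), int(rng.integers(1, 3))
        def masked(shape):
            mask = rng.integers(0, 2, shape)
            vals = rng.standard_normal(shape) * mask
            return vals, mask
        A, A_mask = masked((n, n))
        C, C_mask = masked((n, m))
        Bs = [masked((n, n)) for _ in range(m)] if rng.random() < 0.5 else []
        Ds = [masked((n, n)) for _ in range(n)] if rng.random() < 0.5 else []
        conn = NeuralConnectivity(
            A=A, C=C, A_mask=A_mask, C_mask=C_mask,
            B=[b for b, _ in Bs], B_masks=[mk for _, mk in Bs] or None,
            D=[d for d, _ in Ds], D_masks=[mk for _, mk in Ds] or None)
        spec = DCMSpec(connectivity=conn)
        vec, imap = pack_parameters(spec)
        expected = int(A_mask.sum() + C_mask.sum()
                       + sum(mk.sum() for _, mk in Bs)
                       + sum(mk.sum() for _, mk in Ds))
        assert len(vec) == expected
        back, _ = pack_parameters(unpack_parameters(vec, imap, spec))
        assert np.array_equal(vec, back)
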