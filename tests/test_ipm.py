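"""Kernel discretisation and the demographic quantities lambda, R0, T."""

import numpy as np
import pytest
from scipy.special import logit

import medaka_ipm as m
from medaka_ipm.ipm import IPMKernels
from medaka_ipm.vitals import FecundityModel, LogisticCurve


def flat_vitals(
    s=0.5,
    fp=1.0,
    fn=1.5,
    f_g=1.0,
    rho=1.0,
    growth=m.VBParams(30.0, 0.02, 0.0),
    sd_g=0.05,
    juv_mean=2.5,
    juv_sd=0.1,
):
    """Size-independent vital rates (flat logistic curves, b = 0)."""
    return m.VitalRates(
        survival=LogisticCurve(float(logit(np.clip(s, 1e-12, 1 - 1e-12))), 0.0),
        growth_params=growth,
        growth_sd_log=sd_g,
        reproduction=LogisticCurve(float(logit(np.clip(fp, 1e-12, 1 - 1e-12))), 0.0),
        fecundity=FecundityModel(float(np.log(fn)), 0.0),
        recruits=m.RecruitParams(f_g, juv_mean, juv_sd),
        female_fraction=rho,
    )


GRID = m.build_grid(2.0, 3.6, 100)


class TestGrid:
    def test_default_mesh_count(self):
        assert m.build_grid(2.0, 3.6).n_mesh == 400

    def test_midpoint_arithmetic(self):
        g = m.build_grid(0.0, 4.0, 4)
        assert g.h == pytest.approx(1.0)
        assert g.midpoints == pytest.approx([0.5, 1.5, 2.5, 3.5])

    def test_partition_property(self):
        g = m.build_grid(1.3, 2.9, 37)
        assert g.n_mesh * g.h == pytest.approx(g.U - g.L)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            m.build_grid(3.0, 2.0, 10)
        with pytest.raises(ValueError):
            m.build_grid(0.0, 1.0, 1)


class TestGrowthKernel:
    P = m.VBParams(30.0, 0.02, 0.0)

    def test_point_mass_when_sd_zero(self):
        G = m.growth_kernel(GRID, self.P, 0.0)
        assert G.sum(axis=0) == pytest.approx(np.ones(GRID.n_mesh))
        assert ((G == 0) | (G == 1)).all()

    def test_columns_renormalised(self):
        G = m.growth_kernel(GRID, self.P, 0.05)
        assert G.sum(axis=0) == pytest.approx(np.ones(GRID.n_mesh), abs=1e-12)

    def test_truncate_loses_boundary_mass(self):
        G = m.growth_kernel(GRID, self.P, 0.05, eviction="truncate")
        assert G.sum(axis=0).max() <= 1.0 + 1e-12
        assert G.sum(axis=0).min() < 0.999  # some eviction at the top

    def test_column_mean_matches_deterministic_step(self):
        G = m.growth_kernel(GRID, self.P, 0.05)
        z = GRID.midpoints
        mu = np.log(m.vb_step(self.P, np.exp(z)))
        col_mean = (z[:, None] * G).sum(axis=0)
        interior = (mu > GRID.L + 0.3) & (mu < GRID.U - 0.3)
        assert np.abs(col_mean - mu)[interior].max() < GRID.h

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            m.growth_kernel(GRID, self.P, -0.1)


class TestAssemble:
    def test_no_survival_limit(self):
        kern = m.assemble_kernels(GRID, flat_vitals(s=1e-15))
        assert kern.P == pytest.approx(np.zeros_like(kern.P), abs=1e-12)
        assert kern.K == pytest.approx(kern.F)

    def test_no_reproduction_limit(self):
        vit = flat_vitals(fp=1e-15, s=0.5)
        kern = m.assemble_kernels(GRID, vit)
        assert kern.F == pytest.approx(np.zeros_like(kern.F), abs=1e-12)
        lam = m.asymptotic_lambda(kern).lam
        assert lam <= 0.5 + 1e-9

    def test_p_columns_sum_to_survival(self, demography):
        """Conservation after eviction renormalisation: column j of P
        carries exactly the survival probability s(z_j)."""
        for d in demography.values():
            kern = m.assemble_kernels(d.grid, d.vitals)
            s = np.asarray(d.vitals.survival(d.grid.midpoints))
            assert kern.P.sum(axis=0) == pytest.approx(s, abs=1e-10)

    def test_missing_component_rejected(self):
        vit = flat_vitals()
        vit.fecundity = None
        with pytest.raises(ValueError):
            m.assemble_kernels(GRID, vit)


class TestLambda:
    def test_identity_kernel(self):
        g = m.build_grid(0.0, 1.0, 5)
        kern = IPMKernels(grid=g, P=np.eye(5), F=np.zeros((5, 5)))
        est = m.asymptotic_lambda(kern)
        assert est.lam == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_kernel(self):
        g = m.build_grid(0.0, 1.0, 2)
        kern = IPMKernels(grid=g, P=np.diag([0.5, 0.2]), F=np.zeros((2, 2)))
        assert m.asymptotic_lambda(kern).lam == pytest.approx(0.5, abs=1e-10)

    def test_rank_one_kernel(self):
        # K = outer(b, a) * h with a = (1, 1), b = (2, 0), h = 0.5:
        # lambda = h * a.b = 1
        g = m.build_grid(0.0, 1.0, 2)
        K = np.outer([2.0, 0.0], [1.0, 1.0]) * 0.5
        kern = IPMKernels(grid=g, P=np.zeros((2, 2)), F=K)
        est = m.asymptotic_lambda(kern)
        assert est.lam == pytest.approx(1.0, abs=1e-10)
        assert est.w == pytest.approx([1.0, 0.0])

    def test_negative_kernel_rejected(self):
        g = m.build_grid(0.0, 1.0, 2)
        kern = IPMKernels(grid=g, P=np.array([[0.1, -0.2], [0.0, 0.1]]), F=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            m.asymptotic_lambda(kern)

    def test_size_independent_limit(self):
        """With flat rates the IPM collapses to the scalar model
        lambda = s + fp * fn * f_g * rho."""
        vit = flat_vitals(s=0.6, fp=0.4, fn=2.0, f_g=0.5, rho=0.5)
        kern = m.assemble_kernels(GRID, vit)
        expected = 0.6 + 0.4 * 2.0 * 0.5 * 0.5
        assert m.asymptotic_lambda(kern).lam == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_fertility_and_survival(self):
        """Perron-Frobenius: elementwise increases of F or s never
        decrease lambda."""
        rng = np.random.default_rng(0)
        vit = flat_vitals(s=0.7, fp=0.3, fn=1.2, f_g=0.4, rho=0.5)
        kern = m.assemble_kernels(GRID, vit)
        lam0 = m.asymptotic_lambda(kern).lam
        for _ in range(5):
            bump = rng.random(kern.F.shape) * 1e-3
            kern_up = IPMKernels(grid=GRID, P=kern.P, F=kern.F + bump)
            assert m.asymptotic_lambda(kern_up).lam >= lam0 - 1e-12


class TestGenerationTime:
    def test_one_step_life_cycle(self):
        """P = 0 (reproduce once, then die): R0 = lambda and T = 1."""
        vit = flat_vitals(s=1e-15, fp=0.5, fn=3.0, f_g=0.5, rho=1.0)
        kern = m.assemble_kernels(GRID, vit)
        est = m.generation_time(kern)
        assert est.R0 == pytest.approx(est.lam, rel=1e-9)
        assert est.T == pytest.approx(1.0, abs=1e-9)

    def test_scalar_leslie_oracle(self):
        """s = 0.5 and per-step recruitment 0.75: lambda = 1.25,
        R0 = 0.75 / (1 - 0.5) = 1.5, T = log 1.5 / log 1.25."""
        vit = flat_vitals(s=0.5, fp=1 - 1e-12, fn=0.75, f_g=1.0, rho=1.0)
        kern = m.assemble_kernels(GRID, vit)
        est = m.generation_time(kern)
        assert est.lam == pytest.approx(1.25, abs=1e-6)
        assert est.R0 == pytest.approx(1.5, abs=1e-6)
        assert est.T == pytest.approx(np.log(1.5) / np.log(1.25), abs=1e-4)

    def test_doubling_f_doubles_r0(self):
        vit = flat_vitals(s=0.5, fp=0.5, fn=1.0, f_g=0.5, rho=0.5)
        kern = m.assemble_kernels(GRID, vit)
        r0 = m.generation_time(kern).R0
        kern2 = IPMKernels(grid=GRID, P=kern.P, F=2.0 * kern.F)
        assert m.generation_time(kern2).R0 == pytest.approx(2.0 * r0, rel=1e-9)

    def test_immortal_population_rejected(self):
        g = m.build_grid(0.0, 1.0, 2)
        kern = IPMKernels(grid=g, P=np.eye(2), F=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            m.generation_time(kern)

    def test_lambda_one_fallback_finite(self):
        """Exactly at lambda = 1 the stabilised fallback returns a finite
        generation time near log R0 / log lambda's limit R0-side."""
        # scalar model tuned to lambda = 1: s + m = 1
        vit = flat_vitals(s=0.5, fp=1 - 1e-12, fn=0.5, f_g=1.0, rho=1.0)
        kern = m.assemble_kernels(GRID, vit)
        est = m.generation_time(kern)
        assert est.lam == pytest.approx(1.0, abs=1e-9)
        assert est.T is not None and np.isfinite(est.T)
        # analytic limit: T -> log(R0)/log(lam) ~ R0' ; sanity bounds
        assert 0.0 < est.T < 1e4


class TestIteratePopulation:
    def test_ratio_converges_to_lambda(self):
        vit = flat_vitals(s=0.6, fp=0.4, fn=2.0, f_g=0.5, rho=0.5)
        kern = m.assemble_kernels(GRID, vit)
        est = m.asymptotic_lambda(kern)
        traj = m.iterate_population(kern, np.ones(GRID.n_mesh), 400)
        totals = traj.sum(axis=1)
        assert totals[-1] / totals[-2] == pytest.approx(est.lam, abs=1e-8)
        assert (traj >= 0).all()

    def test_eigenvector_start_gives_lambda_immediately(self):
        vit = flat_vitals(s=0.6, fp=0.4, fn=2.0, f_g=0.5, rho=0.5)
        kern = m.assemble_kernels(GRID, vit)
        est = m.asymptotic_lambda(kern)
        traj = m.iterate_population(kern, est.w, 1)
        assert traj[1].sum() / traj[0].sum() == pytest.approx(est.lam, abs=1e-8)

    def test_zero_start_rejected(self):
        vit = flat_vitals()
        kern = m.assemble_kernels(GRID, vit)
        with pytest.raises(ValueError):
            m.iterate_population(kern, np.zeros(GRID.n_mesh), 5)
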