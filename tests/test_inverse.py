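"""Contrast-update QP assembly/solution and the Born iterative loop."""

import numpy as np
import pytest

from mwtomo.forward import (
    AntennaArray,
    ScatteringDataset,
    green_data,
    green_domain,
    incident_fields,
    scattered_at_receivers,
    simulate_dataset,
)
from mwtomo.grids import build_grid
from mwtomo.inverse import (
    BIMConfig,
    ContrastBounds,
    assemble_qp,
    bim_reconstruct,
    gradient_penalty_matrix,
    initial_guess,
    solve_qp,
)
from mwtomo.medium import BackgroundMedium
from mwtomo.metrics import relative_error
from mwtomo.phantoms import PhantomMap, contrast_map

WIDE = ContrastBounds(-10.0, 10.0, -10.0, 10.0)


def _true_field_system(grid, arr, medium, chi_true, lam=0.0, bounds=WIDE):
    """Noiseless data and the QP assembled with the *true* total field."""
    ei = incident_fields(arr, grid, medium)
    gs = [green_data(grid, arr, kb) for kb in medium.k_b]
    et = np.empty_like(ei)
    data = np.empty((medium.n_freq, arr.n_sources, arr.n_receivers), complex)
    for f, kb in enumerate(medium.k_b):
        from mwtomo.forward import solve_total_field

        et[f] = solve_total_field(ei[f], green_domain(grid, kb), chi_true)
        data[f] = scattered_at_receivers(gs[f], chi_true, et[f])
    ds = ScatteringDataset(data, arr, medium)
    return ds, assemble_qp(ds, et, gs, lam, bounds, grid), et, gs


class TestAssembly:
    def test_dimension_bookkeeping(self):
        """F=2, L=3, Nr=18, N=16 gives 216 equality rows and 248 unknowns."""
        grid = build_grid(0.18, 4)
        medium = BackgroundMedium(10.0, frequencies=[3e8, 6e8])
        arr = AntennaArray(3, 18, 0.10)
        ei = incident_fields(arr, grid, medium)
        gs = [green_data(grid, arr, kb) for kb in medium.k_b]
        ds = ScatteringDataset(np.zeros((2, 3, 18), complex), arr, medium)
        system = assemble_qp(ds, ei, gs, 0.1, WIDE, grid)
        assert system.n_equality_rows == 216
        assert system.n_unknowns == 216 + 32

    def test_objective_equals_misfit_without_regularizer(self, medium4):
        """With lambda=0 the eliminated objective equals the explicit
        per-row misfit sum at any contrast."""
        grid = build_grid(0.18, 4)
        arr = AntennaArray(3, 6, 0.10)
        rng = np.random.default_rng(0)
        chi_true = 0.3 * rng.random(16) + 0j
        ds, system, et, gs = _true_field_system(grid, arr, medium4, chi_true)
        chi_probe = 0.2 * rng.standard_normal(16) + 0.05j * rng.standard_normal(16)
        explicit = sum(
            np.sum(np.abs(meas - b @ chi_probe) ** 2)
            for b, meas in system.blocks
        )
        assert system.objective(chi_probe) == pytest.approx(explicit, rel=1e-10)

    def test_constant_contrast_has_zero_gradient_penalty(self):
        grid = build_grid(0.18, 6)
        reg = gradient_penalty_matrix(grid)
        const = np.full(grid.n_pixels, 1.7)
        assert const @ (reg @ const) == pytest.approx(0.0, abs=1e-12)


class TestQPSolve:
    def test_matches_least_squares_oracle_at_full_rank(self, medium4):
        """Frozen true field, lambda=0, inactive bounds: the QP equals the
        dense least-squares solution (and the true contrast) to 1e-6."""
        grid = build_grid(0.18, 8)  # N = 64
        arr = AntennaArray(8, 12, 0.10)
        rng = np.random.default_rng(5)
        chi_true = 0.05 * rng.standard_normal(64) - 0.02j * np.abs(
            rng.standard_normal(64)
        )
        ds, system, et, gs = _true_field_system(grid, arr, medium4, chi_true)
        chi_qp = solve_qp(system)
        a = np.vstack([b for b, _ in system.blocks])
        rhs = np.concatenate([m for _, m in system.blocks])
        assert np.linalg.matrix_rank(a) == 64
        chi_ls = np.linalg.lstsq(a, rhs, rcond=None)[0]
        assert np.linalg.norm(chi_qp - chi_ls) <= 1e-6 * np.linalg.norm(chi_ls)
        assert np.linalg.norm(chi_qp - chi_true) <= 1e-6 * np.linalg.norm(chi_true)
        assert system.kkt_residual(chi_qp) <= 1e-6

    def test_zero_data_returns_zero_contrast(self, medium4):
        grid = build_grid(0.18, 8)
        arr = AntennaArray(4, 8, 0.10)
        ei = incident_fields(arr, grid, medium4)
        gs = [green_data(grid, arr, kb) for kb in medium4.k_b]
        ds = ScatteringDataset(np.zeros((4, 4, 8), complex), arr, medium4)
        for lam in (0.0, 0.5):
            system = assemble_qp(ds, ei, gs, lam, ContrastBounds(-1, 5, -1, 0), grid)
            chi = solve_qp(system)
            assert np.abs(chi).max() == pytest.approx(0.0, abs=1e-12)
            assert system.objective(chi) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_box_pins_solution(self, medium4):
        grid = build_grid(0.18, 4)
        arr = AntennaArray(3, 6, 0.10)
        rng = np.random.default_rng(1)
        chi_true = 0.5 * rng.random(16) + 0j
        _, system, _, _ = _true_field_system(
            grid, arr, medium4, chi_true,
            bounds=ContrastBounds(0.3, 0.3, -0.1, -0.1),
        )
        chi = solve_qp(system)
        assert np.allclose(chi, 0.3 - 0.1j)

    def test_kkt_holds_with_active_bounds(self, medium4):
        grid = build_grid(0.18, 8)
        arr = AntennaArray(8, 12, 0.10)
        rng = np.random.default_rng(7)
        chi_true = 0.4 * rng.random(64) + 0j
        bounds = ContrastBounds(0.0, 0.2, -0.05, 0.0)
        _, system, _, _ = _true_field_system(
            grid, arr, medium4, chi_true, lam=1e-6, bounds=bounds
        )
        chi = solve_qp(system)
        assert chi.real.max() <= 0.2 + 1e-10
        assert chi.real.min() >= -1e-10
        assert system.kkt_residual(chi) <= 1e-6

    def test_regularization_monotonicity(self, medium4):
        """Raising lambda never increases the gradient-penalty term."""
        grid = build_grid(0.18, 8)
        arr = AntennaArray(8, 12, 0.10)
        rng = np.random.default_rng(9)
        chi_true = 0.3 * rng.random(64) + 0j
        reg = gradient_penalty_matrix(grid)
        pens = []
        for lam in (0.0, 1e-4, 1e-2, 1.0):
            _, system, _, _ = _true_field_system(
                grid, arr, medium4, chi_true, lam=lam
            )
            chi = solve_qp(system)
            pens.append(
                chi.real @ (reg @ chi.real) + chi.imag @ (reg @ chi.imag)
            )
        assert np.all(np.diff(pens) <= 1e-9 * max(pens))


class TestInitialGuess:
    def test_constant_min_value(self, weak_dataset, grid16):
        chi = initial_guess(weak_dataset, grid16, "constant_min")
        assert np.allclose(chi, (2.5 - 10.0) / 10.0)

    def test_zero_dataset_gives_zero_guess(self, grid8, array8x12, medium4):
        ds = ScatteringDataset(np.zeros((4, 8, 12), complex), array8x12, medium4)
        chi = initial_guess(ds, grid8, "born_zero")
        assert np.abs(chi).max() == pytest.approx(0.0, abs=1e-12)

    def test_born_guess_recovers_weak_scatterer(self, medium4):
        """First-order linearisation at lambda=0 recovers a weak contrast
        within 5% on an overdetermined small grid."""
        grid = build_grid(0.18, 4)  # small well-conditioned instance
        arr = AntennaArray(8, 12, 0.10)
        rng = np.random.default_rng(11)
        eps = 10.0 * (1 + 0.01 * rng.random(grid.n_pixels))
        ph = PhantomMap(grid, eps, np.zeros(grid.n_pixels))
        ds = simulate_dataset(ph, arr, medium4)
        chi_true = contrast_map(ph, medium4, 0)
        cfg = BIMConfig(iterations=1, lambda_reg=0.0, init_mode="multi_freq_source")
        chi = initial_guess(ds, grid, "multi_freq_source", cfg)
        assert np.linalg.norm(chi - chi_true) <= 0.05 * np.linalg.norm(chi_true)

    def test_unknown_mode_rejected(self, weak_dataset, grid16):
        with pytest.raises(ValueError):
            initial_guess(weak_dataset, grid16, "gradient_descent")


class TestBIM:
    def test_weak_scatterer_inverse_crime_recovery(
        self, weak_dataset, weak_phantom, grid16
    ):
        """Born-regime, noiseless, same-grid reconstruction reaches
        relative error < 1e-2 within 3 iterations, residuals bounded."""
        cfg = BIMConfig(iterations=3, init_mode="born_zero", lambda_reg=0.0)
        res = bim_reconstruct(weak_dataset, grid16, cfg)
        rep = relative_error([weak_phantom.eps_image()], [res.eps_image()])
        assert rep.relative_error < 1e-2
        assert res.residuals[-1] <= res.initial_residual + 1e-12
        assert len(res.chi_per_iteration) == len(res.residuals) == 3

    def test_zero_contrast_is_fixed_point(self, grid8, array8x12, medium4):
        ds = ScatteringDataset(np.zeros((4, 8, 12), complex), array8x12, medium4)
        res = bim_reconstruct(ds, grid8, BIMConfig(iterations=2, init_mode="born_zero"))
        for chi in res.chi_per_iteration:
            assert np.abs(chi).max() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.eps_r, 10.0)

    def test_final_permittivity_respects_bounds(self, weak_dataset, grid16):
        cfg = BIMConfig(iterations=2, eps_range=(2.5, 67.0))
        res = bim_reconstruct(weak_dataset, grid16, cfg)
        assert res.eps_r.min() >= 2.5
        assert res.eps_r.max() <= 67.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BIMConfig(init_mode="nonsense")
        with pytest.raises(ValueError):
            BIMConfig(iterations=0)
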