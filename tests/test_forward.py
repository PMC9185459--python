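"""Forward-solver correctness: Green operators, state/data equations,
dataset simulation, and the scattering invariants."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.special import hankel2

from mwtomo.forward import (
    AntennaArray,
    ToeplitzGreenOperator,
    green_data,
    green_domain,
    incident_fields,
    scattered_at_receivers,
    simulate_dataset,
    solve_total_field,
)
from mwtomo.grids import build_grid
from mwtomo.medium import BackgroundMedium
from mwtomo.phantoms import PhantomMap, circular_phantom, contrast_map


class TestGreenDomain:
    def test_symmetry(self, grid8, medium4):
        g = green_domain(grid8, medium4.k_b[-1])
        assert np.abs(g - g.T).max() == 0.0

    def test_magnitude_decays_with_distance(self, medium4):
        grid = build_grid(0.18, 6)
        g = green_domain(grid, medium4.k_b[-1])
        row = np.abs(g[0])
        dist = np.hypot(grid.x - grid.x[0], grid.y - grid.y[0])
        order = np.argsort(dist)[1:]  # skip the self term
        assert np.all(np.diff(row[order]) < 1e-18)

    def test_offdiagonal_matches_cell_quadrature(self):
        """Each coefficient approximates kb^2 * integral of the continuous
        2D Green function over the source cell (<= 1% relative).

        The equal-area-circle coefficient is a small-cell approximation,
        so the 2x2 grid spans a domain of a few millimetres where cells
        are electrically small at 1 GHz."""
        grid = build_grid(0.008, 2)
        medium = BackgroundMedium(10.0, frequencies=[1e9])
        kb = medium.k_b[0]
        g = green_domain(grid, kb)
        half = grid.dx / 2
        for m, n in [(0, 1), (0, 3)]:
            xm, ym = grid.centers[m]
            xn, yn = grid.centers[n]

            def integrand(part):
                def f(y, x):
                    val = hankel2(0, kb * np.hypot(xm - x, ym - y))
                    return part(-0.25j * val)
                return f

            re, _ = dblquad(integrand(np.real), xn - half, xn + half,
                            yn - half, yn + half)
            im, _ = dblquad(integrand(np.imag), xn - half, xn + half,
                            yn - half, yn + half)
            oracle = kb**2 * (re + 1j * im)
            assert abs(g[m, n] - oracle) / abs(oracle) < 0.01

    def test_self_term_matches_equivalent_circle_quadrature(self):
        """The diagonal equals kb^2 times the Green integral over the
        equal-area circular cell (polar quadrature, singularity removed)."""
        grid = build_grid(0.008, 2)
        medium = BackgroundMedium(10.0, frequencies=[1e9])
        kb = medium.k_b[0]
        g = green_domain(grid, kb)
        from scipy.integrate import quad

        # int_0^a H0^(2)(kb r) r dr, split into real/imag 1D quadratures
        re, _ = quad(lambda r: np.real(hankel2(0, kb * r)) * r, 0, grid.a_eq)
        im, _ = quad(lambda r: np.imag(hankel2(0, kb * r)) * r, 0, grid.a_eq)
        oracle = kb**2 * (-0.25j) * 2 * np.pi * (re + 1j * im)
        assert abs(g[0, 0] - oracle) / abs(oracle) < 0.01

    def test_fft_operator_matches_dense(self, medium4):
        grid = build_grid(0.18, 12)
        kb = medium4.k_b[-1]
        dense = green_domain(grid, kb)
        op = ToeplitzGreenOperator(grid, kb)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(grid.n_pixels) + 1j * rng.standard_normal(grid.n_pixels)
        assert np.abs(op.matvec(x) - dense @ x).max() < 1e-12 * np.abs(dense @ x).max()


class TestGreenData:
    def test_entries_shrink_with_receiver_distance(self, grid8, medium4):
        near = AntennaArray(4, 8, 0.13)
        far = AntennaArray(4, 8, 0.20)
        kb = medium4.k_b[-1]
        g_near = np.abs(green_data(grid8, near, kb))
        g_far = np.abs(green_data(grid8, far, kb))
        assert np.all(g_far < g_near)

    def test_mirror_symmetric_receivers_give_mirror_rows(self, medium4):
        grid = build_grid(0.18, 8)
        kb = medium4.k_b[-1]
        arr = AntennaArray(4, 8, 0.15)  # receivers include +-45 deg pairs
        g = green_data(grid, arr, kb)
        # receivers q=1 (45 deg) and q=7 (315 deg) are mirrors about x-axis;
        # pixel reflection about x-axis flips the y-index
        refl = np.arange(grid.n_pixels).reshape(8, 8)[::-1].ravel()
        assert np.allclose(g[1], g[7][refl])


class TestIncidentFields:
    def test_radial_symmetry(self, medium4):
        grid = build_grid(0.18, 8)
        arr = AntennaArray(1, 4, 0.2)
        e = incident_fields(arr, grid, medium4)
        d = np.hypot(grid.x - 0.2, grid.y)
        i, j = 1, np.argmin(np.abs(d - d[1]) + (np.arange(64) == 1) * 1e9)
        if abs(d[i] - d[j]) < 1e-12:
            assert e[0, 0, i] == pytest.approx(e[0, 0, j])

    def test_far_zone_amplitude_decay(self):
        """Doubling the distance reduces |H0| by ~1/sqrt(2) in the far zone."""
        medium = BackgroundMedium(10.0, frequencies=[1e9])
        kb = medium.k_b[0]
        d0 = 1.0  # k*d ~ 66: comfortably far zone
        ratio = abs(hankel2(0, kb * 2 * d0)) / abs(hankel2(0, kb * d0))
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_zero_amplitude_gives_zero_fields(self, grid8, array8x12, medium4):
        e = incident_fields(array8x12, grid8, medium4, amplitude=0.0)
        assert np.all(e == 0)


class TestStateEquation:
    def test_zero_contrast_returns_incident(self, grid8, array8x12, medium4):
        kb = medium4.k_b[0]
        gd = green_domain(grid8, kb)
        ei = incident_fields(array8x12, grid8, medium4)[0]
        et = solve_total_field(ei, gd, np.zeros(grid8.n_pixels))
        assert np.allclose(et, ei)

    def test_weak_contrast_matches_neumann_series(self, grid8, array8x12, medium4):
        kb = medium4.k_b[-1]
        gd = green_domain(grid8, kb)
        ei = incident_fields(array8x12, grid8, medium4)[-1]
        rng = np.random.default_rng(1)
        chi = 1e-3 * rng.random(grid8.n_pixels)
        et = solve_total_field(ei, gd, chi)
        series = ei + (chi * ei) @ gd.T
        rel = np.linalg.norm(et - series) / np.linalg.norm(et)
        assert rel < 1e-5  # O(|chi|^2)

    def test_small_system_matches_dense_inversion(self, medium4):
        grid = build_grid(0.05, 2)
        kb = medium4.k_b[2]
        gd = green_domain(grid, kb)
        rng = np.random.default_rng(2)
        chi = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        ei = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        et = solve_total_field(ei, gd, chi)
        brute = np.linalg.inv(np.eye(4) - gd @ np.diag(chi)) @ ei
        assert np.allclose(et, brute)


class TestDataEquation:
    def test_zero_contrast_zero_scattering(self, grid8, array8x12, medium4):
        gs = green_data(grid8, array8x12, medium4.k_b[0])
        ei = incident_fields(array8x12, grid8, medium4)[0]
        es = scattered_at_receivers(gs, np.zeros(grid8.n_pixels), ei)
        assert np.all(es == 0)

    def test_linearity_in_contrast_at_fixed_field(self, grid8, array8x12, medium4):
        gs = green_data(grid8, array8x12, medium4.k_b[1])
        rng = np.random.default_rng(3)
        chi = rng.random(grid8.n_pixels)
        et = rng.standard_normal((8, grid8.n_pixels)) * (1 + 0j)
        es1 = scattered_at_receivers(gs, chi, et)
        es3 = scattered_at_receivers(gs, 3.0 * chi, et)
        assert np.allclose(es3, 3.0 * es1)

    def test_reciprocity_through_full_solver(self, medium4):
        """Swapping a source and a co-located receiver leaves the sampled
        scattered field unchanged (<= 1e-6 relative)."""
        grid = build_grid(0.18, 24)
        arr = AntennaArray(8, 8, 0.10)
        ph = circular_phantom(grid)
        ds = simulate_dataset(ph, arr, medium4)
        for f in range(medium4.n_freq):
            d = ds.data[f]
            assert np.abs(d - d.T).max() <= 1e-6 * np.abs(d).max()


class TestSimulateDataset:
    def test_noiseless_determinism(self, weak_phantom, array8x12, medium4):
        a = simulate_dataset(weak_phantom, array8x12, medium4)
        b = simulate_dataset(weak_phantom, array8x12, medium4)
        assert np.array_equal(a.data, b.data)

    def test_background_phantom_scatters_nothing(self, grid16, array8x12, medium4):
        ph = PhantomMap(grid16, np.full(grid16.n_pixels, 10.0),
                        np.zeros(grid16.n_pixels))
        ds = simulate_dataset(ph, array8x12, medium4)
        assert np.all(ds.data == 0)

    def test_circular_configuration_dimensions(self):
        """The published circular setup yields an F x L x Nr = 15 x 18 x 30
        dataset."""
        medium = BackgroundMedium(10.0)  # default 15-frequency sweep
        arr = AntennaArray(18, 30, 0.10)
        ph = circular_phantom(build_grid(0.18, 48))
        ds = simulate_dataset(ph, arr, medium)
        assert ds.data.shape == (15, 18, 30)

    def test_inverse_crime_warning(self, weak_phantom, array8x12, medium4):
        with pytest.warns(UserWarning, match="inverse-crime"):
            simulate_dataset(weak_phantom, array8x12, medium4,
                             inversion_pixels=16)

    def test_noise_reproducible_and_at_requested_level(
        self, weak_phantom, array8x12, medium4
    ):
        clean = simulate_dataset(weak_phantom, array8x12, medium4)
        a = simulate_dataset(weak_phantom, array8x12, medium4,
                             noise_snr_db=20.0, seed=5)
        b = simulate_dataset(weak_phantom, array8x12, medium4,
                             noise_snr_db=20.0, seed=5)
        assert np.array_equal(a.data, b.data)
        snr = 10 * np.log10(
            np.mean(np.abs(clean.data) ** 2)
            / np.mean(np.abs(a.data - clean.data) ** 2)
        )
        assert snr == pytest.approx(20.0, abs=1.5)


class TestScatteringInvariants:
    def test_born_limit(self, grid16, array8x12, medium4):
        """Full forward and first-Born data agree to 0.1% for |chi|<=1e-3."""
        eps = np.full(grid16.n_pixels, 10.0)
        mask = np.hypot(grid16.x, grid16.y) < 0.03
        eps[mask] = 10.0 * (1 + 1e-3)
        ph = PhantomMap(grid16, eps, np.zeros(grid16.n_pixels))
        ds = simulate_dataset(ph, array8x12, medium4)
        ei = incident_fields(array8x12, grid16, medium4)
        for f, kb in enumerate(medium4.k_b):
            chi = contrast_map(ph, medium4, f)
            gs = green_data(grid16, array8x12, kb)
            born = scattered_at_receivers(gs, chi, ei[f])
            rel = np.linalg.norm(ds.data[f] - born) / np.linalg.norm(ds.data[f])
            assert rel < 1e-3

    def test_grid_refinement_convergence(self, medium4):
        """Scattered fields converge as the simulation grid refines."""
        arr = AntennaArray(4, 8, 0.10)

        def fields(m):
            g = build_grid(0.18, m)
            eps = np.full(g.n_pixels, 10.0)
            eps[np.hypot(g.x, g.y) < 0.04] = 10.5
            ph = PhantomMap(g, eps, np.zeros(g.n_pixels))
            return simulate_dataset(ph, arr, medium4).data

        d16, d32, d64 = fields(16), fields(32), fields(64)
        e1 = np.linalg.norm(d32 - d16) / np.linalg.norm(d32)
        e2 = np.linalg.norm(d64 - d32) / np.linalg.norm(d64)
        assert e2 < e1
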