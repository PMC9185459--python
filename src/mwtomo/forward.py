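"""Discretised EFIE forward solver for 2D TM scattering.

Pulse-basis / point-matching method of moments on a square grid: each
cell is replaced by an equivalent circular cell of the same area, giving
closed-form Green coefficients

    g_mn = -(j/2) pi k_b a J1(k_b a) H0^(2)(k_b |r_m - r_n|)   (m != n)
    g_nn = -(j/2) [pi k_b a H1^(2)(k_b a) - 2j]                (self term)

with the e^{j omega t} time convention (outgoing waves carry Hankel
functions of the second kind).  The state equation

    (I - G_D diag(chi)) E_t = E_i

is solved densely on small grids and by an FFT-accelerated Krylov method
on fine simulation grids, where G_D is block-Toeplitz.  The data equation
samples E_s = G_S diag(chi) E_t at external receivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sp_fft
from scipy import linalg as sla
from scipy.sparse.linalg import LinearOperator, bicgstab, gmres
from scipy.special import hankel2, j1

from .grids import ImagingGrid, build_grid
from .medium import BackgroundMedium
from .phantoms import PhantomMap, box_resample, contrast_map

__all__ = [
    "AntennaArray",
    "GreenOperators",
    "FieldSet",
    "ScatteringDataset",
    "SolverError",
    "green_domain",
    "green_data",
    "incident_fields",
    "solve_total_field",
    "scattered_at_receivers",
    "simulate_dataset",
]


class SolverError(RuntimeError):
    """Linear solve failed or did not reach the requested tolerance."""


@dataclass(frozen=True)
class AntennaArray:
    """Circular array of line sources and field-sampling positions.

    Sources and receivers are equispaced on a circle of given radius
    centred at the origin; the receiver ring may be offset in angle.
    """

    n_sources: int
    n_receivers: int
    radius: float
    receiver_angle_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_receivers < 1:
            raise ValueError("need at least one source and one receiver")
        if self.radius <= 0:
            raise ValueError("array radius must be positive")

    @property
    def source_positions(self) -> np.ndarray:
        ang = 2.0 * np.pi * np.arange(self.n_sources) / self.n_sources
        return self.radius * np.column_stack([np.cos(ang), np.sin(ang)])

    @property
    def receiver_positions(self) -> np.ndarray:
        ang = (
            2.0 * np.pi * np.arange(self.n_receivers) / self.n_receivers
            + self.receiver_angle_offset
        )
        return self.radius * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass
class GreenOperators:
    """Domain and data Green matrices at one sweep frequency."""

    G_D: np.ndarray
    G_S: np.ndarray
    frequency_index: int


@dataclass
class FieldSet:
    """Incident/total fields and contrast currents, indexed (freq, source, pixel)."""

    E_i: np.ndarray
    E_t: np.ndarray
    chi: np.ndarray

    @property
    def J(self) -> np.ndarray:
        """Contrast current density J = chi * E_t (zero off the support)."""
        return self.chi * self.E_t


@dataclass
class ScatteringDataset:
    """Scattered-field samples indexed (frequency, source, receiver)."""

    data: np.ndarray  # complex, (F, L, Nr)
    array: AntennaArray
    medium: BackgroundMedium
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        expected = (self.medium.n_freq, self.array.n_sources, self.array.n_receivers)
        if self.data.shape != expected:
            raise ValueError(
                f"dataset shape {self.data.shape} != (F, L, Nr) = {expected}"
            )

    @property
    def n_freq(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    @property
    def n_receivers(self) -> int:
        return self.data.shape[2]


def _offdiag_coeff(k_b: float, a: float) -> complex:
    return -0.5j * np.pi * k_b * a * j1(k_b * a)


def _self_coeff(k_b: float, a: float) -> complex:
    return -0.5j * (np.pi * k_b * a * hankel2(1, k_b * a) - 2.0j)


def green_domain(grid: ImagingGrid, k_b: float) -> np.ndarray:
    """Dense domain-to-domain Green matrix G_D (N x N, complex, symmetric)."""
    if k_b <= 0:
        raise ValueError("wavenumber must be positive")
    c = grid.centers
    dist = np.hypot(
        c[:, 0][:, None] - c[:, 0][None, :], c[:, 1][:, None] - c[:, 1][None, :]
    )
    if np.any((dist == 0) & ~np.eye(grid.n_pixels, dtype=bool)):
        raise RuntimeError("coincident distinct pixel centres: invalid grid")
    np.fill_diagonal(dist, 1.0)  # placeholder, overwritten below
    g = _offdiag_coeff(k_b, grid.a_eq) * hankel2(0, k_b * dist)
    np.fill_diagonal(g, _self_coeff(k_b, grid.a_eq))
    return g


def green_data(grid: ImagingGrid, array: AntennaArray, k_b: float) -> np.ndarray:
    """Data Green matrix G_S (Nr x N): domain cells to receiver samples."""
    if k_b <= 0:
        raise ValueError("wavenumber must be positive")
    rq = array.receiver_positions
    c = grid.centers
    dist = np.hypot(rq[:, 0][:, None] - c[:, 0][None, :],
                    rq[:, 1][:, None] - c[:, 1][None, :])
    # Receivers may sit inside the square domain (a measurement ring often
    # crosses the domain corners) provided the cells they overlap carry no
    # contrast; only an exact coincidence with a cell centre is singular.
    if np.any(dist < 1e-12):
        raise ValueError("receiver coincides with a pixel centre")
    return _offdiag_coeff(k_b, grid.a_eq) * hankel2(0, k_b * dist)


def incident_fields(
    array: AntennaArray,
    grid: ImagingGrid,
    medium: BackgroundMedium,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Line-source incident fields, shape (F, Ni, N).

    E_i(r_n; r_p) = A * H0^(2)(k_b |r_n - r_p|), unit amplitude by default.
    """
    rp = array.source_positions
    c = grid.centers
    dist = np.hypot(rp[:, 0][:, None] - c[:, 0][None, :],
                    rp[:, 1][:, None] - c[:, 1][None, :])
    if np.any(dist < 1e-12):
        raise ValueError("source coincides with a pixel centre")
    if amplitude == 0.0:
        return np.zeros((medium.n_freq, array.n_sources, grid.n_pixels), complex)
    out = np.empty((medium.n_freq, array.n_sources, grid.n_pixels), complex)
    for fi, kb in enumerate(medium.k_b):
        out[fi] = amplitude * hankel2(0, kb * dist)
    return out


def solve_total_field(
    E_i: np.ndarray,
    G_D: np.ndarray,
    chi: np.ndarray,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Solve (I - G_D diag(chi)) E_t = E_i for one frequency.

    ``E_i`` may be (N,) or (L, N); the solution has the same shape.
    Raises :class:`SolverError` on singular/ill-conditioned systems, with
    the estimated condition number in the message.
    """
    chi = np.asarray(chi, dtype=complex).ravel()
    n = chi.size
    A = np.eye(n, dtype=complex) - G_D * chi[None, :]
    rhs = np.atleast_2d(np.asarray(E_i, dtype=complex))
    try:
        lu, piv = sla.lu_factor(A)
        sol = sla.lu_solve((lu, piv), rhs.T).T
    except (sla.LinAlgError, ValueError) as exc:
        raise SolverError(f"state-equation solve failed: {exc}") from exc
    resid = np.linalg.norm(A @ sol.T - rhs.T) / max(np.linalg.norm(rhs), 1e-300)
    if not np.isfinite(resid) or resid > max(rtol, 1e-8):
        cond = np.linalg.cond(A)
        raise SolverError(
            f"state equation near-singular: relative residual {resid:.2e}, "
            f"condition number {cond:.2e}"
        )
    return sol if np.asarray(E_i).ndim > 1 else sol[0]


class ToeplitzGreenOperator:
    """Matrix-free G_D matvec via 2D FFT (the kernel depends on r_m - r_n)."""

    def __init__(self, grid: ImagingGrid, k_b: float):
        m = grid.pixels
        self.m = m
        off = np.arange(-(m - 1), m)
        dxs = off * grid.dx
        dist = np.hypot(dxs[None, :], dxs[:, None])
        kern = np.empty((2 * m - 1, 2 * m - 1), complex)
        nz = dist > 0
        kern[nz] = _offdiag_coeff(k_b, grid.a_eq) * hankel2(0, k_b * dist[nz])
        kern[m - 1, m - 1] = _self_coeff(k_b, grid.a_eq)
        # embed the Toeplitz kernel circularly in a 2m x 2m array
        circ = np.zeros((2 * m, 2 * m), complex)
        idx = np.r_[np.arange(0, m), np.arange(-(m - 1), 0)]
        circ[np.ix_(idx % (2 * m), idx % (2 * m))] = kern[
            np.ix_(idx + m - 1, idx + m - 1)
        ]
        self._kern_hat = sp_fft.fft2(circ)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        m = self.m
        xp = np.zeros((2 * m, 2 * m), complex)
        xp[:m, :m] = x.reshape(m, m)
        y = sp_fft.ifft2(self._kern_hat * sp_fft.fft2(xp))[:m, :m]
        return y.ravel()


def _solve_total_field_fft(
    E_i: np.ndarray,
    op: ToeplitzGreenOperator,
    chi: np.ndarray,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Krylov solve of the state equation using the FFT Green operator."""
    n = chi.size

    def mv(x):
        return x - op.matvec(chi * x)

    A = LinearOperator((n, n), matvec=mv, dtype=complex)
    rhs = np.atleast_2d(E_i)
    out = np.empty_like(rhs)
    for i, b in enumerate(rhs):
        x, info = bicgstab(A, b, rtol=rtol, atol=0.0, maxiter=2000, x0=b)
        if info != 0:  # fall back to GMRES on breakdown/stagnation
            x, info = gmres(A, b, rtol=rtol, atol=0.0, restart=80, maxiter=50, x0=x)
        if info != 0:
            raise SolverError(f"iterative state-equation solve stalled (info={info})")
        out[i] = x
    return out if np.asarray(E_i).ndim > 1 else out[0]


def scattered_at_receivers(
    G_S: np.ndarray, chi: np.ndarray, E_t: np.ndarray
) -> np.ndarray:
    """Data equation: E_s = G_S diag(chi) E_t, per source if E_t is stacked."""
    chi = np.asarray(chi, dtype=complex).ravel()
    Et = np.atleast_2d(np.asarray(E_t, dtype=complex))
    es = (chi[None, :] * Et) @ G_S.T
    return es if np.asarray(E_t).ndim > 1 else es[0]


# Dense state-equation solves are used up to this many cells; beyond it the
# FFT-accelerated Krylov path takes over.
_DENSE_SOLVE_MAX_N = 1200


def simulate_dataset(
    phantom: PhantomMap,
    array: AntennaArray,
    medium: BackgroundMedium,
    fine_pixels: Optional[int] = None,
    noise_snr_db: Optional[float] = None,
    seed: Optional[int] = None,
    inversion_pixels: Optional[int] = None,
) -> ScatteringDataset:
    """Simulate a multi-source multi-frequency scattered-field dataset.

    The forward problem is solved on the phantom's own grid (expected to be
    the fine simulation grid).  If ``fine_pixels`` is given and differs from
    the phantom grid it must coarsen it, in which case the dielectric maps
    are box-averaged first.  Optional complex white Gaussian noise is added
    per frequency at the given SNR (dB on the per-frequency sample power).

    Passing ``inversion_pixels`` equal to the simulation grid size warns
    about the inverse crime (same discretisation for data generation and
    inversion) but does not fail.
    """
    grid = phantom.grid
    if fine_pixels is not None and fine_pixels != grid.pixels:
        if fine_pixels > grid.pixels:
            raise ValueError(
                "fine_pixels exceeds the phantom grid; render the phantom "
                "on the fine grid instead of upsampling"
            )
        coarse = build_grid(grid.extent, fine_pixels)
        eps = box_resample(phantom.eps_image(), fine_pixels).ravel()
        sig = box_resample(phantom.sigma_image(), fine_pixels).ravel()
        phantom = PhantomMap(coarse, eps, sig, None, meta=dict(phantom.meta))
        grid = coarse
    if inversion_pixels is not None and inversion_pixels >= grid.pixels:
        warnings.warn(
            "simulation grid is not finer than the inversion grid: "
            "inverse-crime conditions",
            stacklevel=2,
        )

    E_i = incident_fields(array, grid, medium)
    data = np.zeros((medium.n_freq, array.n_sources, array.n_receivers), complex)
    dense = grid.n_pixels <= _DENSE_SOLVE_MAX_N
    for fi, kb in enumerate(medium.k_b):
        chi = contrast_map(phantom, medium, fi)
        G_S = green_data(grid, array, kb)
        if not np.any(chi):
            continue
        if dense:
            G_D = green_domain(grid, kb)
            E_t = solve_total_field(E_i[fi], G_D, chi)
        else:
            op = ToeplitzGreenOperator(grid, kb)
            E_t = _solve_total_field_fft(E_i[fi], op, chi)
        data[fi] = scattered_at_receivers(G_S, chi, E_t)

    noise_rec: dict = {}
    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        for fi in range(medium.n_freq):
            p_sig = np.mean(np.abs(data[fi]) ** 2)
            std = np.sqrt(p_sig * 10.0 ** (-noise_snr_db / 10.0) / 2.0)
            data[fi] += std * (
                rng.standard_normal(data[fi].shape)
                + 1j * rng.standard_normal(data[fi].shape)
            )
        noise_rec = {"type": "awgn", "snr_db": float(noise_snr_db), "seed": seed}
    return ScatteringDataset(data=data, array=array, medium=medium, noise=noise_rec)
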