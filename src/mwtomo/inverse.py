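"""Born iterative method with quadratic-programming contrast updates.

Each iteration alternates (a) a total-field solve with the current
contrast estimate and (b) a contrast update posed as the convex program

    min_{d, chi}  sum_m |d_m|^2  +  lambda ||grad chi||^2
    s.t.          d_m + sum_n g_mn chi_n E^t_n = E~^s_m      (all m)
                  chi within box bounds,

stacked over all sources and frequencies with a single shared contrast
vector.  Eliminating the slack d_m analytically (the constraints fix
d = residual) leaves a box-constrained quadratic in the real vector
z = [Re chi; Im chi], whose unique global minimum is found by a
projected-Newton active-set iteration on the dense Hessian and verified
by a KKT residual check.

Because all procedures operate on real quantities, the complex misfit is
rearranged into its real and imaginary parts: the Hermitian data Gram
H = sum B^H B maps to the symmetric real block form
[[Re H, -Im H], [Im H, Re H]], which represents the same quadratic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import sparse

from .forward import (
    ScatteringDataset,
    SolverError,
    green_data,
    green_domain,
    incident_fields,
    scattered_at_receivers,
    solve_total_field,
)
from .grids import ImagingGrid
from .medium import BackgroundMedium
from .phantoms import EPS_R_RANGE, permittivity_from_contrast

__all__ = [
    "ContrastBounds",
    "QPSystem",
    "BIMConfig",
    "ReconstructionResult",
    "gradient_penalty_matrix",
    "assemble_qp",
    "solve_qp",
    "initial_guess",
    "bim_reconstruct",
]

INIT_MODES = ("born_zero", "multi_freq_source", "constant_min")


@dataclass(frozen=True)
class ContrastBounds:
    """Box bounds on the real and imaginary parts of the contrast."""

    re_lo: float
    re_hi: float
    im_lo: float
    im_hi: float

    @staticmethod
    def from_physical(
        medium: BackgroundMedium,
        eps_range: tuple[float, float] = EPS_R_RANGE,
        sigma_max: float = 4.0,
        ref_frequency_index: Optional[int] = None,
    ) -> "ContrastBounds":
        """Bounds from a permittivity range and a conductivity cap.

        Re chi in [(eps_lo - eps_rb)/eps_rb, (eps_hi - eps_rb)/eps_rb];
        Im chi in [-(sigma_max - sigma_b)/(omega_ref eps_b), 0] using the
        mid-band frequency as the reference for the conductivity scaling.
        """
        if ref_frequency_index is None:
            ref_frequency_index = medium.n_freq // 2
        w = medium.omega[ref_frequency_index]
        lo = (eps_range[0] - medium.eps_rb) / medium.eps_rb
        hi = (eps_range[1] - medium.eps_rb) / medium.eps_rb
        im_lo = -max(sigma_max - medium.sigma_b, 0.0) / (w * medium.eps_b)
        return ContrastBounds(lo, hi, im_lo, 0.0)


def gradient_penalty_matrix(grid: ImagingGrid) -> sparse.csr_matrix:
    """Gram matrix D^T D of forward first differences on the grid.

    Zero-flux (replicate) boundary: differences across the domain edge are
    dropped, so spatially constant maps incur zero penalty.
    """
    m = grid.pixels
    eye = sparse.identity(m, format="csr")
    d1 = sparse.diags([-np.ones(m - 1), np.ones(m - 1)], [0, 1],
                      shape=(m - 1, m), format="csr")
    dx = sparse.kron(eye, d1, format="csr")   # along x (fast axis)
    dy = sparse.kron(d1, eye, format="csr")   # along y
    return (dx.T @ dx + dy.T @ dy).tocsr()


@dataclass
class QPSystem:
    """One stacked contrast-update quadratic program.

    The objective over the feasible set equals
    sum_m |d_m|^2 + lambda ||grad chi||^2 with d eliminated; ``H``/``c``
    carry the complex data Gram and correlation, ``reg`` the (real)
    gradient-penalty Gram applied to Re and Im parts separately.
    """

    H: np.ndarray               # (N, N) complex Hermitian, sum of B^H B
    c: np.ndarray               # (N,) complex, sum of B^H e~
    const: float                # sum |e~|^2
    reg: sparse.spmatrix        # (N, N) real, D^T D
    lam: float
    bounds: ContrastBounds
    n_equality_rows: int        # 2 * F * L * Nr
    n_unknowns: int             # 2 * F * L * Nr (slack) + 2 N (contrast)
    blocks: Optional[list] = None  # [(B, e~)] per incidence, small systems only

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def real_hessian(self) -> np.ndarray:
        """Dense symmetric Hessian P of f(z) = z^T P z - 2 q^T z + const."""
        hr, hi = self.H.real, self.H.imag
        n = self.n
        p = np.empty((2 * n, 2 * n))
        p[:n, :n] = hr
        p[n:, n:] = hr
        p[:n, n:] = -hi
        p[n:, :n] = hi
        r = (self.lam * self.reg).toarray()
        p[:n, :n] += r
        p[n:, n:] += r
        return p

    def real_rhs(self) -> np.ndarray:
        return np.concatenate([self.c.real, self.c.imag])

    def bound_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        lo = np.concatenate([np.full(n, self.bounds.re_lo),
                             np.full(n, self.bounds.im_lo)])
        hi = np.concatenate([np.full(n, self.bounds.re_hi),
                             np.full(n, self.bounds.im_hi)])
        return lo, hi

    def objective(self, chi: np.ndarray, d: Optional[np.ndarray] = None) -> float:
        """Objective at a point; with d omitted, slacks take their
        constraint-implied values (the misfit residuals)."""
        chi = np.asarray(chi, dtype=complex).ravel()
        if d is not None:
            misfit = float(np.sum(np.abs(np.asarray(d)) ** 2))
        else:
            misfit = float(
                np.real(chi.conj() @ (self.H @ chi))
                - 2.0 * np.real(self.c.conj() @ chi) + self.const
            )
        pen = float(chi.real @ (self.reg @ chi.real)
                    + chi.imag @ (self.reg @ chi.imag))
        return misfit + self.lam * pen

    def kkt_residual(self, chi: np.ndarray) -> float:
        """Max KKT violation of a candidate solution, scaled by the
        gradient magnitude (0 at the exact constrained minimum)."""
        z = np.concatenate([np.real(chi).ravel(), np.imag(chi).ravel()])
        p, q = self.real_hessian(), self.real_rhs()
        g = 2.0 * (p @ z - q)
        lo, hi = self.bound_vectors()
        span = np.maximum(hi - lo, 1e-30)
        tol_b = 1e-9 * span
        at_lo = z <= lo + tol_b
        at_hi = z >= hi - tol_b
        viol = np.abs(g.copy())
        viol[at_lo] = np.maximum(-g[at_lo], 0.0)
        viol[at_hi & ~at_lo] = np.maximum(g[at_hi & ~at_lo], 0.0)
        viol[(hi - lo) <= 1e-30] = 0.0  # pinned variables carry no condition
        scale = max(np.linalg.norm(g), 2.0 * np.linalg.norm(q), 1e-30)
        return float(viol.max() / scale)


def default_lambda(H: np.ndarray, reg: sparse.spmatrix) -> float:
    """Scale-free Tikhonov weight: 1e-2 x (data trace / penalty trace)."""
    tr_data = float(np.real(np.trace(H)))
    tr_pen = float(reg.diagonal().sum())
    if tr_pen <= 0:
        return 0.0
    return 1e-2 * tr_data / tr_pen


# Keep per-incidence blocks for oracle checks only while they stay small.
_BLOCK_KEEP_MAX = 1 << 20


def assemble_qp(
    dataset: ScatteringDataset,
    E_t_current: np.ndarray,
    G_S: Sequence[np.ndarray],
    lambda_reg: Optional[float],
    bounds: ContrastBounds,
    grid: ImagingGrid,
    gram_cache: Optional[Sequence[np.ndarray]] = None,
) -> QPSystem:
    """Stack all (frequency, source) incidences into one QPSystem.

    ``E_t_current`` has shape (F, L, N); ``G_S[f]`` is the (Nr, N) data
    Green matrix at frequency f.  ``lambda_reg=None`` selects the
    trace-ratio default weight.
    """
    F, L, nr = dataset.data.shape
    n = E_t_current.shape[-1]
    if E_t_current.shape != (F, L, n):
        raise ValueError("E_t_current must be (F, L, N)")
    if len(G_S) != F or any(g.shape != (nr, n) for g in G_S):
        raise ValueError("G_S must hold one (Nr, N) matrix per frequency")

    H = np.zeros((n, n), complex)
    c = np.zeros(n, complex)
    const = 0.0
    keep_blocks = F * L * nr * n <= _BLOCK_KEEP_MAX
    blocks = [] if keep_blocks else None
    for f in range(F):
        K = gram_cache[f] if gram_cache is not None else G_S[f].conj().T @ G_S[f]
        for l in range(L):
            e = E_t_current[f, l]
            meas = dataset.data[f, l]
            H += K * (e.conj()[:, None] * e[None, :])
            c += e.conj() * (G_S[f].conj().T @ meas)
            const += float(np.sum(np.abs(meas) ** 2))
            if keep_blocks:
                blocks.append((G_S[f] * e[None, :], meas))
    reg = gradient_penalty_matrix(grid)
    lam = default_lambda(H, reg) if lambda_reg is None else float(lambda_reg)
    return QPSystem(
        H=H, c=c, const=const, reg=reg, lam=lam, bounds=bounds,
        n_equality_rows=2 * F * L * nr,
        n_unknowns=2 * F * L * nr + 2 * n,
        blocks=blocks,
    )


def _chol_solve(p: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the PSD system p x = rhs.

    Cholesky with a tiny ridge in the common positive-definite case; if the
    system is singular (e.g. an underdetermined lambda=0 update) the result
    is checked and a pseudo-inverse solve takes over, which returns the
    minimum-norm minimiser.
    """
    scale_p = np.trace(p) / p.shape[0]
    ridge = 1e-13 * scale_p if scale_p > 0 else 1e-30
    x = None
    for _ in range(3):
        try:
            cf = sla.cho_factor(p + ridge * np.eye(p.shape[0]), lower=True,
                                check_finite=False)
            x = sla.cho_solve(cf, rhs, check_finite=False)
            x += sla.cho_solve(cf, rhs - p @ x, check_finite=False)
            break
        except sla.LinAlgError:
            ridge *= 1e4
    scale = max(np.linalg.norm(rhs), 1e-30)
    if x is not None and np.linalg.norm(p @ x - rhs) <= 1e-9 * scale:
        return x
    x, *_ = sla.lstsq(p, rhs, check_finite=False)
    dx, *_ = sla.lstsq(p, rhs - p @ x, check_finite=False)  # one refinement
    return x + dx


def solve_qp(system: QPSystem, tol: float = 1e-6, max_newton: int = 30) -> np.ndarray:
    """Solve the contrast-update QP to global optimality.

    Returns the complex contrast reassembled from [Re chi; Im chi].
    Strategy: the unconstrained Newton solution is accepted when it is
    feasible; otherwise a bound-constrained quasi-Newton descent
    identifies the active set, followed by exact Newton polish steps on
    the free variables.  Stopped on the KKT residual; raises
    :class:`SolverError` (carrying the last iterate in ``.iterate``) if
    the tolerance is not reached.
    """
    from scipy.optimize import minimize

    p = system.real_hessian()
    q = system.real_rhs()
    lo, hi = system.bound_vectors()

    z = _chol_solve(p, q)
    if np.all(z >= lo - 1e-12) and np.all(z <= hi + 1e-12):
        z = np.clip(z, lo, hi)
        return z[: system.n] + 1j * z[system.n:]

    def fval(zz):
        return float(zz @ (p @ zz) - 2.0 * q @ zz)

    def kkt(zz):
        g = 2.0 * (p @ zz - q)
        span = np.maximum(hi - lo, 1e-30)
        at_lo = zz <= lo + 1e-9 * span
        at_hi = zz >= hi - 1e-9 * span
        viol = np.abs(g.copy())
        viol[at_lo] = np.maximum(-g[at_lo], 0.0)
        viol[at_hi & ~at_lo] = np.maximum(g[at_hi & ~at_lo], 0.0)
        viol[(hi - lo) <= 1e-30] = 0.0  # pinned variables carry no condition
        scale = max(np.linalg.norm(g), 2.0 * np.linalg.norm(q), 1e-30)
        return float(viol.max() / scale)

    def fval_grad(zz):
        pz = p @ zz
        return float(zz @ pz - 2.0 * q @ zz), 2.0 * (pz - q)

    # global phase: compiled bound-constrained quasi-Newton descent; the
    # Newton polish below supplies the final accuracy
    res = minimize(
        fval_grad, np.clip(z, lo, hi), jac=True,
        method="L-BFGS-B", bounds=list(zip(lo, hi)),
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10},
    )
    z = np.clip(res.x, lo, hi)

    # polish phase: exact Newton on the free set of the identified bounds
    span = np.maximum(hi - lo, 1e-30)
    for _ in range(max_newton):
        if kkt(z) <= tol:
            break
        g = 2.0 * (p @ z - q)
        at_lo = z <= lo + 1e-9 * span
        at_hi = z >= hi - 1e-9 * span
        active = (at_lo & (g > 0)) | (at_hi & (g < 0))
        z_trial = z.copy()
        z_trial[at_lo & active] = lo[at_lo & active]
        z_trial[at_hi & active] = hi[at_hi & active]
        idx = np.flatnonzero(~active)
        if idx.size:
            rhs = q[idx] - p[np.ix_(idx, np.flatnonzero(active))] @ z_trial[active]
            z_trial[idx] = _chol_solve(p[np.ix_(idx, idx)], rhs)
        z_trial = np.clip(z_trial, lo, hi)
        if fval(z_trial) > fval(z) + 1e-14 * abs(fval(z)):
            break  # active set misidentified; keep the descent iterate
        z = z_trial
    if kkt(z) > tol * 10:
        err = SolverError(
            f"QP solve did not reach KKT tolerance: residual {kkt(z):.2e}"
        )
        err.iterate = z[: system.n] + 1j * z[system.n:]
        raise err
    return z[: system.n] + 1j * z[system.n:]


@dataclass
class BIMConfig:
    """Settings for one reconstruction run."""

    iterations: int = 10
    lambda_reg: Optional[float] = None          # None -> trace-ratio default
    init_mode: str = "multi_freq_source"
    eps_range: tuple[float, float] = EPS_R_RANGE
    sigma_max: float = 4.0
    qp_tol: float = 1e-6
    ref_frequency_index: Optional[int] = None   # None -> mid-band

    def __post_init__(self) -> None:
        if self.init_mode not in INIT_MODES:
            raise ValueError(
                f"unknown init mode {self.init_mode!r}; choose from {INIT_MODES}"
            )
        if self.iterations < 1:
            raise ValueError("at least one iteration is required")

    def as_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "lambda_reg": self.lambda_reg,
            "init_mode": self.init_mode,
            "eps_range": list(self.eps_range),
            "sigma_max": self.sigma_max,
            "qp_tol": self.qp_tol,
            "ref_frequency_index": self.ref_frequency_index,
        }


@dataclass
class ReconstructionResult:
    """Per-iteration contrast history and the recovered dielectric maps."""

    grid: ImagingGrid
    chi_per_iteration: list
    residuals: list
    initial_residual: float
    eps_r: np.ndarray
    sigma: np.ndarray
    config: dict

    @property
    def chi(self) -> np.ndarray:
        return self.chi_per_iteration[-1]

    @property
    def iterations(self) -> int:
        return len(self.chi_per_iteration)

    def eps_image(self) -> np.ndarray:
        return self.grid.reshape(self.eps_r)


class _Operators:
    """Per-frequency Green matrices and incident fields on one grid."""

    def __init__(self, grid: ImagingGrid, dataset: ScatteringDataset):
        medium = dataset.medium
        self.grid = grid
        self.medium = medium
        self.E_i = incident_fields(dataset.array, grid, medium)
        self.G_S = [green_data(grid, dataset.array, kb) for kb in medium.k_b]
        self.G_D = [green_domain(grid, kb) for kb in medium.k_b]
        self.gram = [g.conj().T @ g for g in self.G_S]

    def total_fields(self, chi: np.ndarray) -> np.ndarray:
        if not np.any(chi):
            return self.E_i.copy()
        out = np.empty_like(self.E_i)
        for f in range(self.medium.n_freq):
            out[f] = solve_total_field(self.E_i[f], self.G_D[f], chi)
        return out

    def predict(self, chi: np.ndarray, E_t: np.ndarray) -> np.ndarray:
        data = np.empty(
            (self.medium.n_freq, E_t.shape[1], self.G_S[0].shape[0]), complex
        )
        for f in range(self.medium.n_freq):
            data[f] = scattered_at_receivers(self.G_S[f], chi, E_t[f])
        return data


def _residual(dataset: ScatteringDataset, predicted: np.ndarray) -> float:
    denom = np.linalg.norm(dataset.data)
    if denom == 0:
        return float(np.linalg.norm(predicted))
    return float(np.linalg.norm(dataset.data - predicted) / denom)


def initial_guess(
    dataset: ScatteringDataset,
    grid: ImagingGrid,
    mode: str = "multi_freq_source",
    config: Optional[BIMConfig] = None,
    operators: Optional[_Operators] = None,
) -> np.ndarray:
    """Initial contrast estimate.

    ``born_zero``: first-order Born update (E_t = E_i) from the sources of
    the highest frequency only; ``multi_freq_source``: the same linearised
    update jointly over all sources and all frequencies;
    ``constant_min``: uniform contrast of the minimum permittivity.
    """
    if mode not in INIT_MODES:
        raise ValueError(f"unknown init mode {mode!r}; choose from {INIT_MODES}")
    cfg = config or BIMConfig(init_mode=mode)
    medium = dataset.medium
    if mode == "constant_min":
        chi0 = (cfg.eps_range[0] - medium.eps_rb) / medium.eps_rb
        return np.full(grid.n_pixels, chi0, dtype=complex)
    ops = operators or _Operators(grid, dataset)
    bounds = ContrastBounds.from_physical(
        medium, cfg.eps_range, cfg.sigma_max, cfg.ref_frequency_index
    )
    if mode == "born_zero":
        f_sel = medium.n_freq - 1
        sub = ScatteringDataset(
            data=dataset.data[f_sel:f_sel + 1],
            array=dataset.array,
            medium=medium.replace_frequencies(medium.frequencies[f_sel:f_sel + 1]),
            noise=dataset.noise,
        )
        system = assemble_qp(
            sub, ops.E_i[f_sel:f_sel + 1], ops.G_S[f_sel:f_sel + 1],
            cfg.lambda_reg, bounds, grid, gram_cache=ops.gram[f_sel:f_sel + 1],
        )
    else:  # multi_freq_source
        system = assemble_qp(
            dataset, ops.E_i, ops.G_S, cfg.lambda_reg, bounds, grid,
            gram_cache=ops.gram,
        )
    return solve_qp(system, tol=cfg.qp_tol)


def bim_reconstruct(
    dataset: ScatteringDataset,
    grid: ImagingGrid,
    config: Optional[BIMConfig] = None,
) -> ReconstructionResult:
    """Full Born-iterative reconstruction on the inversion grid.

    Alternates total-field solves and QP contrast updates for the fixed
    iteration budget, recording the contrast and the data residual
    ||E~s - Es(chi_k)|| / ||E~s|| after every update.  The final
    permittivity map inverts the contrast definition at the reference
    (mid-band) frequency and is clipped to the configured range.
    """
    cfg = config or BIMConfig()
    medium = dataset.medium
    ops = _Operators(grid, dataset)
    bounds = ContrastBounds.from_physical(
        medium, cfg.eps_range, cfg.sigma_max, cfg.ref_frequency_index
    )

    chi = initial_guess(dataset, grid, cfg.init_mode, cfg, operators=ops)
    try:
        E_t = ops.total_fields(chi)
    except SolverError as exc:
        raise SolverError(f"initial forward solve failed: {exc}") from exc
    initial_residual = _residual(dataset, ops.predict(chi, E_t))

    chis: list[np.ndarray] = []
    residuals: list[float] = []
    for it in range(cfg.iterations):
        system = assemble_qp(
            dataset, E_t, ops.G_S, cfg.lambda_reg, bounds, grid,
            gram_cache=ops.gram,
        )
        try:
            chi = solve_qp(system, tol=cfg.qp_tol)
        except SolverError as exc:
            chi = getattr(exc, "iterate", chi)
            chis.append(chi)
            residuals.append(float("nan"))
            break
        try:
            E_t = ops.total_fields(chi)
        except SolverError as exc:
            raise SolverError(
                f"forward solve became singular at iteration {it + 1}: {exc}"
            ) from exc
        chis.append(chi.copy())
        residuals.append(_residual(dataset, ops.predict(chi, E_t)))

    ref = cfg.ref_frequency_index if cfg.ref_frequency_index is not None \
        else medium.n_freq // 2
    eps_r, sigma = permittivity_from_contrast(chis[-1], medium, ref)
    eps_r = np.clip(eps_r, cfg.eps_range[0], cfg.eps_range[1])
    sigma = np.clip(sigma, 0.0, cfg.sigma_max)
    return ReconstructionResult(
        grid=grid,
        chi_per_iteration=chis,
        residuals=residuals,
        initial_residual=initial_residual,
        eps_r=eps_r,
        sigma=sigma,
        config=cfg.as_dict(),
    )
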