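"""Multifractal Fokker-Planck release model.

The states density of the drug dynamics obeys an Ornstein-Uhlenbeck-type
Fokker-Planck equation

    drho/dt + d/dx(-eta x rho) - D d2rho/dx2 = 0,

whose transition density from a point start at x0 is a Gaussian with mean
``x0 exp(-eta t)`` and variance ``(D/eta)(1 - exp(-2 eta t))`` (saturating
at D/eta).  D is the diffusion-type coefficient, tied to the multifractal
scale-transition coefficient lambda by ``D = 2 lambda (dt)^(2/f(alpha)-1)``;
eta is the relaxation rate.

The cumulative release law adopted here is the standard-deviation growth of
that density,

    M(t) = sqrt((D/eta)(1 - exp(-2 eta t)))   (release units, e.g. %),

which grows as sqrt(2 D t) at early times (power-law exponent 0.5, the
Fickian signature) and saturates at the plateau sqrt(D/eta).  The
"fractalization degree" of a release curve is the fitted D, extracted
independently on an early (< breakpoint) and a late (> breakpoint) time
segment.

A seeded Euler-Maruyama particle ensemble (``dx = -eta x dtau +
sqrt(2 D) dW``) serves as an independent stochastic oracle for the closed
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .release_data import ReleaseCurve

__all__ = [
    "ScaleParameters",
    "OUParameters",
    "HydrodynamicField",
    "FractalFitResult",
    "OUEnsemble",
    "scale_amplitude",
    "ou_density",
    "ou_cdf",
    "ou_moments",
    "fokker_planck_residual",
    "hydrodynamic_diagnostics",
    "lambda_from_D",
    "D_from_lambda",
    "simulate_ou_ensemble",
    "release_from_ou",
    "fit_multifractal_release",
]


class DegenerateDensityError(ValueError):
    """Transition density requested at t <= 0 (point mass, not evaluable)."""


@dataclass(frozen=True)
class ScaleParameters:
    """Multifractal scale bookkeeping.

    lam : coefficient of the multifractal/non-multifractal scale transition
    dt_res : scale resolution (> 0)
    f_alpha : singularity-spectrum value f(alpha) (> 0); f_alpha = 2 is the
        monofractal, fractal-dimension-2 case in which the scale exponent
        2/f(alpha) - 1 vanishes
    alpha_idx : singularity index (metadata)
    D_f : fractal dimension (metadata)
    """

    lam: float = 0.5
    dt_res: float = 1.0
    f_alpha: float = 2.0
    alpha_idx: float | None = None
    D_f: float | None = None

    def __post_init__(self):
        if self.dt_res <= 0:
            raise ValueError("dt_res must be > 0")
        if self.f_alpha <= 0:
            raise ValueError("f_alpha must be > 0")


def scale_amplitude(sp: ScaleParameters) -> float:
    """lambda * (dt)^(2/f(alpha) - 1): prefactor of the fractal velocity."""
    return sp.lam * sp.dt_res ** (2.0 / sp.f_alpha - 1.0)


@dataclass(frozen=True)
class OUParameters:
    """Parameters of the Fokker-Planck release equation.

    D : diffusion-type coefficient, (release units)^2 per hour, >= 0
    eta : relaxation rate, 1/h, > 0  (eta = g*B/2 for coupling g, field B)
    x0 : initial position in release units
    g_coupling, B_field : optional decomposition of eta (eta = g*B/2)
    """

    D: float
    eta: float
    x0: float = 0.0
    g_coupling: float | None = None
    B_field: float | None = None

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")


@dataclass
class HydrodynamicField:
    """Hydrodynamic (Madelung) diagnostics of a states density on a grid."""

    x_grid: np.ndarray
    rho: np.ndarray
    s_phase: np.ndarray
    V_D: np.ndarray
    V_F: np.ndarray
    Q: np.ndarray


@dataclass
class FractalFitResult:
    """Two-timescale fractal fit of one release curve.

    The early segment covers t <= breakpoint_h, the late segment
    t > breakpoint_h; each is fit independently with the OU release law and
    the fitted D of each segment is its fractalization degree.
    ``early_mass_fraction`` is released(breakpoint)/released(end).
    """

    breakpoint_h: float
    D_early: float
    eta_early: float
    r_squared_early: float
    D_late: float
    eta_late: float
    r_squared_late: float
    early_mass_fraction: float
    n_points_early: int = 0
    n_points_late: int = 0

    @property
    def fractalization_degree_early(self) -> float:
        return self.D_early

    @property
    def fractalization_degree_late(self) -> float:
        return self.D_late


# ---------------------------------------------------------------------------
# closed forms

def ou_moments(t, p: OUParameters):
    """Mean and variance of the transition density at time(s) t >= 0.

    mean = x0 exp(-eta t); variance = (D/eta)(1 - exp(-2 eta t)).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    mean = p.x0 * np.exp(-p.eta * t_arr)
    var = (p.D / p.eta) * (1.0 - np.exp(-2.0 * p.eta * t_arr))
    if t_arr.ndim:
        return mean, var
    return float(mean), float(var)


def ou_density(x, t: float, p: OUParameters):
    """Closed-form Gaussian transition density rho(x, t), t > 0.

    At t <= 0 the density degenerates to a point mass at x0 and is not
    evaluable; a DegenerateDensityError is raised.
    """
    if t <= 0:
        raise DegenerateDensityError("density is a point mass at t <= 0")
    if p.D == 0:
        raise DegenerateDensityError("density is a moving point mass when D = 0")
    mean, var = ou_moments(float(t), p)
    x_arr = np.asarray(x, dtype=float)
    out = np.exp(-((x_arr - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)
    return out if out.ndim else float(out)


def ou_cdf(x, t: float, p: OUParameters):
    """CDF of the transition density (Gaussian with the closed-form moments)."""
    from scipy.stats import norm

    if t <= 0 or p.D == 0:
        raise DegenerateDensityError("CDF degenerate at t <= 0 or D = 0")
    mean, var = ou_moments(float(t), p)
    return norm.cdf(np.asarray(x, dtype=float), loc=mean, scale=np.sqrt(var))


# ---------------------------------------------------------------------------
# PDE residual

def fokker_planck_residual(
    p: OUParameters,
    x_grid: np.ndarray,
    t_grid: np.ndarray,
    density=None,
) -> float:
    """Max-norm residual of the Fokker-Planck operator on a density.

    Evaluates ``d_t rho + d_x(-eta x rho) - D d_xx rho`` with centered
    second-order differences on a uniform (x, t) mesh and returns the
    max norm over interior nodes.  On the exact transition density the
    residual is pure discretization error, O(dx^2 + dt^2): halving both
    spacings divides it by about 4.

    ``density`` defaults to :func:`ou_density`; pass a different callable
    (x, t, p) -> rho for negative controls.
    """
    x = np.asarray(x_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if x.size < 3 or t.size < 3:
        raise ValueError("mesh too coarse for centered stencils")
    dx = np.diff(x)
    dt = np.diff(t)
    if not (np.allclose(dx, dx[0]) and np.allclose(dt, dt[0])):
        raise ValueError("mesh must be uniform in x and t")
    if np.any(t <= 0):
        raise ValueError("all t values must be > 0")
    dens = density if density is not None else ou_density
    dx0, dt0 = dx[0], dt[0]
    rho = np.array([dens(x, ti, p) for ti in t])  # shape (nt, nx)
    flux = -p.eta * x[None, :] * rho
    d_t = (rho[2:, 1:-1] - rho[:-2, 1:-1]) / (2.0 * dt0)
    d_x_flux = (flux[1:-1, 2:] - flux[1:-1, :-2]) / (2.0 * dx0)
    d_xx = (rho[1:-1, 2:] - 2.0 * rho[1:-1, 1:-1] + rho[1:-1, :-2]) / dx0**2
    resid = d_t + d_x_flux - p.D * d_xx
    return float(np.max(np.abs(resid)))


# ---------------------------------------------------------------------------
# hydrodynamic diagnostics

def hydrodynamic_diagnostics(
    x_grid: np.ndarray,
    rho: np.ndarray,
    sp: ScaleParameters,
    s_phase: np.ndarray | None = None,
) -> HydrodynamicField:
    """Fractal-hydrodynamic fields of a states density.

    V_F = a * d/dx ln(rho)     (non-differentiable velocity)
    Q   = -2 a^2 * (d2/dx2 sqrt(rho)) / sqrt(rho)   (specific potential)
    V_D = 2 a * d/dx s         (differentiable velocity; zero phase -> 0)

    with a = lambda*(dt)^(2/f(alpha)-1).  Derivatives are second-order
    centered differences (one-sided at the ends via numpy.gradient).
    """
    x = np.asarray(x_grid, dtype=float)
    r = np.asarray(rho, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rho must be strictly positive on the grid")
    a = scale_amplitude(sp)
    v_f = a * np.gradient(np.log(r), x, edge_order=2)
    sqrt_r = np.sqrt(r)
    d2 = np.gradient(np.gradient(sqrt_r, x, edge_order=2), x, edge_order=2)
    q = -2.0 * a**2 * d2 / sqrt_r
    if s_phase is None:
        s_phase = np.zeros_like(x)
        v_d = np.zeros_like(x)
    else:
        s_phase = np.asarray(s_phase, dtype=float)
        v_d = 2.0 * a * np.gradient(s_phase, x, edge_order=2)
    return HydrodynamicField(x_grid=x, rho=r, s_phase=s_phase, V_D=v_d,
                             V_F=v_f, Q=q)


def lambda_from_D(D: float, sp: ScaleParameters) -> float:
    """Scale-transition coefficient from the diffusion coefficient.

    D = 2 lambda (dt)^(2/f(alpha)-1)  =>  lambda = D / (2 (dt)^(...)).
    """
    return D / (2.0 * sp.dt_res ** (2.0 / sp.f_alpha - 1.0))


def D_from_lambda(lam: float, sp: ScaleParameters) -> float:
    """Inverse of :func:`lambda_from_D`."""
    return 2.0 * lam * sp.dt_res ** (2.0 / sp.f_alpha - 1.0)


# ---------------------------------------------------------------------------
# particle-level oracle

@dataclass
class OUEnsemble:
    """Euler-Maruyama ensemble: positions[i, j] = particle i at t_grid[j]."""

    t_grid: np.ndarray
    positions: np.ndarray
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def variance(self) -> np.ndarray:
        return self.positions.var(axis=0, ddof=1)


def simulate_ou_ensemble(
    p: OUParameters,
    n_particles: int,
    t_grid: np.ndarray,
    step: float | None = None,
    seed: int = 0,
) -> OUEnsemble:
    """Integrate dx = -eta x dtau + sqrt(2 D) dW for an ensemble.

    Euler-Maruyama from x0 at tau=0, recording positions at the (sorted,
    positive) times in t_grid.  The step defaults to 0.1/eta and must stay
    below the stability bound 1/(2 eta).
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be sorted, distinct, >= 0")
    if step is None:
        step = 0.1 / p.eta
    if step >= 0.5 / p.eta:
        raise ValueError("step too large: need step < 1/(2 eta) for stability")
    rng = np.random.default_rng(seed)
    x = np.full(n_particles, float(p.x0))
    sig = np.sqrt(2.0 * p.D)
    out = np.empty((n_particles, t.size))
    tau = 0.0
    for j, tj in enumerate(t):
        span = tj - tau
        if span > 0:
            nsub = max(1, int(np.ceil(span / step)))
            h = span / nsub
            sqh = np.sqrt(h)
            for _ in range(nsub):
                x += -p.eta * x * h + sig * sqh * rng.standard_normal(n_particles)
            tau = tj
        out[:, j] = x
    return OUEnsemble(t_grid=t, positions=out, seed=seed)


# ---------------------------------------------------------------------------
# release law and the two-timescale fractal fit

def release_from_ou(t, p: OUParameters):
    """Cumulative release M(t) = sqrt((D/eta)(1 - exp(-2 eta t))).

    Release units follow D (for D in %^2/h the output is %).  Early times
    grow as sqrt(2 D t); the plateau is sqrt(D/eta).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    val = np.sqrt((p.D / p.eta) * (1.0 - np.exp(-2.0 * p.eta * t_arr)))
    return val if val.ndim else float(val)


def _fit_ou_segment(t: np.ndarray, m: np.ndarray,
                    residual_mode: str = "increments"
                    ) -> tuple[float, float, float]:
    """Fit (D, eta) of the OU release law to one segment.

    Multi-start nonlinear least squares in (log D, log eta); eta starts on a
    log grid, D from plateau^2 * eta (plateau ~ max observed release).

    ``residual_mode="increments"`` (default) fits the log-ratio of observed
    to model release *increments* within the segment.  Spectrophotometric
    sampling contributes an independent proportional error to each
    withdrawn aliquot, so increment residuals are approximately i.i.d.
    while cumulative residuals are strongly autocorrelated; whitening this
    way keeps the diffusion degree D well conditioned even on segments deep
    in the sqrt(2 D t) regime where eta is weakly identified.
    ``residual_mode="cumulative"`` fits the cumulative values directly.

    Returns (D, eta, r_squared); r_squared is always reported against the
    cumulative values.
    """
    plateau = float(m.max())
    if plateau <= 0:
        raise ValueError("segment has no release; cannot fit")

    def model(q):
        d, eta = np.exp(q)
        return np.sqrt((d / eta) * (1.0 - np.exp(-2.0 * eta * t)))

    if residual_mode == "increments":
        # prepending the zero release at t=0 makes the first "increment"
        # the cumulative level at the segment start, anchoring the scale
        obs_incr = np.diff(np.concatenate([[0.0], m]))
        good = obs_incr > 0

        def resid(q):
            pred = np.maximum(np.diff(np.concatenate([[0.0], model(q)])),
                              1e-300)
            out = np.zeros_like(obs_incr)
            out[good] = np.log(obs_incr[good] / pred[good])
            return out
    elif residual_mode == "cumulative":
        def resid(q):
            return model(q) - m
    else:
        raise ValueError(f"unknown residual_mode {residual_mode!r}")

    best = None
    for eta0 in np.logspace(-4, 1, 12):
        d0 = max(plateau**2 * eta0, 1e-12)
        try:
            sol = least_squares(resid, x0=[np.log(d0), np.log(eta0)],
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("OU segment fit failed to converge from all starts")
    d_hat, eta_hat = np.exp(best.x)
    fitted = model(best.x)
    ss_res = float(np.sum((fitted - m) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(d_hat), float(eta_hat), float(np.clip(r2, 0.0, 1.0))


def fit_multifractal_release(
    curve: ReleaseCurve,
    breakpoint_h: float = 50.0,
    residual_mode: str = "increments",
) -> FractalFitResult:
    """Two-timescale fractal fit of a release curve.

    Fits the OU release law independently on the early (t <= breakpoint_h)
    and late (t > breakpoint_h) segments; each segment needs >= 3 points
    with t > 0.  The fitted D of each segment is its fractalization degree.
    No continuity is enforced across the breakpoint: the two segments are
    treated as dynamics at two different temporal scale resolutions.
    """
    t, m = curve.times, curve.released
    pos = t > 0
    early = pos & (t <= breakpoint_h)
    late = t > breakpoint_h
    if early.sum() < 3:
        raise ValueError(f"fewer than 3 points at 0 < t <= {breakpoint_h} h")
    if late.sum() < 3:
        raise ValueError(f"fewer than 3 points at t > {breakpoint_h} h")
    d_e, eta_e, r2_e = _fit_ou_segment(t[early], m[early], residual_mode)
    d_l, eta_l, r2_l = _fit_ou_segment(t[late], m[late], residual_mode)
    m_bp = float(np.interp(breakpoint_h, t, m))
    early_frac = m_bp / float(m[-1]) if m[-1] > 0 else np.nan
    return FractalFitResult(
        breakpoint_h=float(breakpoint_h),
        D_early=d_e, eta_early=eta_e, r_squared_early=r2_e,
        D_late=d_l, eta_late=eta_l, r_squared_late=r2_l,
        early_mass_fraction=early_frac,
        n_points_early=int(early.sum()),
        n_points_late=int(late.sum()),
    )


def solve_eta_for_early_fraction(
    D: float, target_release: float, breakpoint_h: float
) -> float | None:
    """eta such that the OU release law reaches target_release at breakpoint.

    The release at the breakpoint decreases monotonically in eta with
    supremum sqrt(2 D breakpoint) (eta -> 0); if the target exceeds that
    bound no eta exists and None is returned.
    """
    sup = np.sqrt(2.0 * D * breakpoint_h)
    if target_release >= sup * (1.0 - 1e-9):
        return None

    def f(log_eta):
        eta = np.exp(log_eta)
        return (np.sqrt((D / eta) * (1.0 - np.exp(-2.0 * eta * breakpoint_h)))
                - target_release)

    return float(np.exp(brentq(f, np.log(1e-10), np.log(1e4), xtol=1e-14)))
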