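"""Harmonic-map pattern fields of the polymer-drug dynamics.

The stationary harmonic map into the hyperbolic plane admits the
closed-form solution

    h(Phi, alpha) = (cosh(Phi/2) - sinh(Phi/2) e^{-i alpha})
                    / (cosh(Phi/2) + sinh(Phi/2) e^{-i alpha}),

valid whenever Phi/2 is harmonic (Laplace) in the spatial variables and
alpha is a real constant.  Substituting the time-dependent phase
alpha = 2 Omega t yields the pattern field

    h(Omega, t) = i [e^{2 Phi} sin(2 Omega t) - sin(2 Omega t) - 2 i e^{Phi}]
                  / [e^{2 Phi} (cos(2 Omega t) + 1) - cos(2 Omega t) + 1],

periodic in t with period pi/Omega and free of singularities for real Phi
(the denominator is >= 2 when Phi >= 0).  The field is viewed at three
scale resolutions: |h| (global), Re h (differentiable) and Im h
(non-differentiable); Im h vanishes at t = 0 where h = e^{-Phi}.

The solution maps into the right half-plane (Re h > 0); its hyperbolic
conjugate field is -conj(h), so the Euler-Lagrange residual implemented in
:func:`euler_residual` is ``(h + conj h) lap(h) - 2 (grad h)^2``
(equivalently, i*h solves the upper-half-plane equation
(w - conj w) lap(w) = 2 (grad w)^2 verbatim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonicField",
    "EulerResidual",
    "harmonic_h",
    "harmonic_h_time",
    "field_denominator",
    "harmonic_field",
    "euler_residual",
    "export_pattern",
]

VIEWS = {"modulus": np.abs, "real": np.real, "imaginary": np.imag}


@dataclass
class HarmonicField:
    """Complex pattern field h(Omega, t) on a rectangular grid.

    Omega and t are dimensionless; ``h_values[i, j]`` is h at
    (omega_grid[i], t_grid[j]).
    """

    Phi: float
    omega_grid: np.ndarray
    t_grid: np.ndarray
    h_values: np.ndarray
    resolution_view: str = "modulus"

    def view(self, which: str | None = None) -> np.ndarray:
        which = which or self.resolution_view
        try:
            return VIEWS[which](self.h_values)
        except KeyError:
            raise ValueError(f"unknown view {which!r}; choose from {sorted(VIEWS)}")

    def period(self, omega: float) -> float:
        """Temporal period pi/Omega of the field at fixed Omega."""
        if omega == 0:
            return np.inf
        return np.pi / omega


def harmonic_h(Phi, alpha):
    """Closed-form harmonic-map solution h(Phi, alpha) (vectorized).

    At alpha = 0 this is e^{-Phi}; at Phi = 0 it is identically 1.
    """
    Phi = np.asarray(Phi, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    c, s = np.cosh(Phi / 2.0), np.sinh(Phi / 2.0)
    z = np.exp(-1j * alpha)
    out = (c - s * z) / (c + s * z)
    return out if out.ndim else complex(out)


def field_denominator(Phi, omega, t):
    """Denominator e^{2 Phi}(cos 2 Omega t + 1) - cos 2 Omega t + 1.

    For Phi >= 0 it is bounded below by 2 (write it as
    (cos+1)(e^{2 Phi} - 1) + 2), so the field has no poles.
    """
    a = 2.0 * np.asarray(omega, dtype=float) * np.asarray(t, dtype=float)
    e2 = np.exp(2.0 * np.asarray(Phi, dtype=float))
    return e2 * (np.cos(a) + 1.0) - np.cos(a) + 1.0


def harmonic_h_time(Phi, omega, t):
    """Pattern field via the explicit (Omega, t) expression (vectorized).

    Independent code path from :func:`harmonic_h`; the two agree to
    rounding with alpha = 2 Omega t.
    """
    omega = np.asarray(omega, dtype=float)
    t = np.asarray(t, dtype=float)
    a = 2.0 * omega * t
    e1 = np.exp(np.asarray(Phi, dtype=float))
    num = 1j * (e1**2 * np.sin(a) - np.sin(a) - 2j * e1)
    out = num / field_denominator(Phi, omega, t)
    return out if out.ndim else complex(out)


def harmonic_field(
    Phi: float,
    omega_range: tuple = (0.0, 20.0),
    t_range: tuple = (0.0, 20.0),
    grid_size: int = 512,
    resolution_view: str = "modulus",
) -> HarmonicField:
    """Evaluate the pattern field on a grid_size x grid_size (Omega, t) grid."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2 per axis")
    if omega_range[1] <= omega_range[0] or t_range[1] <= t_range[0]:
        raise ValueError("empty range")
    om = np.linspace(*omega_range, grid_size)
    tt = np.linspace(*t_range, grid_size)
    h = harmonic_h_time(Phi, om[:, None], tt[None, :])
    return HarmonicField(Phi=float(Phi), omega_grid=om, t_grid=tt,
                         h_values=h, resolution_view=resolution_view)


@dataclass
class EulerResidual:
    """Residual of the harmonic-map Euler equation on a grid."""

    norm: float
    phi_harmonic: bool
    dx: float
    dy: float


def euler_residual(
    phi: np.ndarray,
    alpha: float,
    dx: float,
    dy: float,
    harmonic_tol: float = 1e-8,
) -> EulerResidual:
    """Centered-difference residual of (h + conj h) lap h = 2 (grad h)^2.

    ``phi`` is Phi sampled on a uniform 2-D spatial grid with spacings
    (dx, dy); h is built pointwise from the closed form at fixed alpha.
    On a harmonic Phi (e.g. affine) the residual is pure discretization
    error and halves twice (ratio ~4) when the grid is refined by 2.  A
    non-harmonic Phi is reported with ``phi_harmonic=False``: the residual
    is still returned but does not converge to zero.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or min(phi.shape) < 3:
        raise ValueError("phi must be a 2-D grid with >= 3 nodes per axis")
    lap_phi = (
        (phi[2:, 1:-1] - 2 * phi[1:-1, 1:-1] + phi[:-2, 1:-1]) / dx**2
        + (phi[1:-1, 2:] - 2 * phi[1:-1, 1:-1] + phi[1:-1, :-2]) / dy**2
    )
    scale = max(1.0, float(np.max(np.abs(phi))))
    harmonic = bool(np.max(np.abs(lap_phi)) <= harmonic_tol * scale / min(dx, dy) ** 2)

    h = harmonic_h(phi, alpha)
    hx = (h[2:, 1:-1] - h[:-2, 1:-1]) / (2 * dx)
    hy = (h[1:-1, 2:] - h[1:-1, :-2]) / (2 * dy)
    lap_h = (
        (h[2:, 1:-1] - 2 * h[1:-1, 1:-1] + h[:-2, 1:-1]) / dx**2
        + (h[1:-1, 2:] - 2 * h[1:-1, 1:-1] + h[1:-1, :-2]) / dy**2
    )
    hc = h[1:-1, 1:-1]
    resid = (hc + np.conj(hc)) * lap_h - 2.0 * (hx**2 + hy**2)
    return EulerResidual(norm=float(np.max(np.abs(resid))),
                         phi_harmonic=harmonic, dx=dx, dy=dy)


def export_pattern(field: HarmonicField, view: str, path,
                   image_path=None) -> None:
    """Write one view of the field as a CSV grid with axis headers.

    Rows are Omega values (index column "omega"), columns are t values.
    If ``image_path`` is given, a rendering is also saved (requires
    matplotlib; purely cosmetic).
    """
    data = field.view(view)
    df = pd.DataFrame(data, index=field.omega_grid, columns=field.t_grid)
    df.index.name = "omega"
    df.columns.name = "t"
    df.to_csv(path, float_format="%.10g")
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        ext = (field.t_grid[0], field.t_grid[-1],
               field.omega_grid[0], field.omega_grid[-1])
        im = ax.imshow(data, origin="lower", aspect="auto", extent=ext,
                       cmap="viridis")
        ax.set_xlabel("t (dimensionless)")
        ax.set_ylabel("Omega (dimensionless)")
        ax.set_title(f"{view} of h, Phi={field.Phi}")
        fig.colorbar(im, ax=ax)
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
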