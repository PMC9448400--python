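"""Ritger-Peppas power-law release kinetics: prediction and fitting.

The empirical power law ``Mt/Minf = k * t^n`` describes the early fraction
of drug released from a polymeric matrix; n near 0.5 indicates Fickian
diffusion, n near 1 case-II (relaxation-controlled) transport.  Fitting is
done by ordinary least squares of ln(Mt/Minf) on ln(t) (the linearized
form), with a direct nonlinear mode available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .release_data import ReleaseCurve

__all__ = ["RitgerPeppasFit", "rp_predict", "fit_ritger_peppas"]


@dataclass
class RitgerPeppasFit:
    """Fitted power-law parameters for one release curve.

    k has units h^-n; n is dimensionless.  ``window`` is the (t_min, t_max)
    interval actually used; ``normalization`` records whether fractions were
    formed against the observed plateau (Minf = final release) or the total
    encapsulated load (Minf = 100 %).  n outside (0, 1) is flagged in
    ``warnings_``, not rejected.
    """

    k: float
    n: float
    r_squared: float
    window: tuple
    normalization: str
    n_points_used: int = 0
    n_points_excluded: int = 0
    warnings_: list = field(default_factory=list)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def rp_predict(k: float, n: float, t):
    """Predicted released fraction k*t^n, capped at 1 (with a warning).

    t may be a scalar or array of hours; negative t is an error.
    """
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative time")
    frac = k * np.power(t_arr, n)
    if np.any(frac > 1.0):
        warnings.warn("predicted fraction exceeds 1; capping", RuntimeWarning,
                      stacklevel=2)
        frac = np.minimum(frac, 1.0)
    return frac if frac.ndim else float(frac)


def fit_ritger_peppas(
    curve: ReleaseCurve,
    window: tuple | None = None,
    normalization: str = "plateau",
    method: str = "loglog",
) -> RitgerPeppasFit:
    """Fit Mt/Minf = k * t^n to a release curve.

    Parameters
    ----------
    curve : ReleaseCurve
    window : (t_min, t_max) or None
        Time window in hours; defaults to the full curve.  The classical
        "first 60 % of release" restriction is not applied automatically --
        pass a window to impose it.
    normalization : "plateau" or "total_load"
        Minf = final observed release, or 100 % of the encapsulated load.
    method : "loglog" or "direct"
        OLS on (ln t, ln fraction), or nonlinear least squares on the raw
        fractions (initialized from the log-log solution).

    Points with t <= 0 or Mt <= 0 cannot enter the log-log regression; they
    are excluded and counted in ``n_points_excluded``.
    """
    if normalization not in ("plateau", "total_load"):
        raise ValueError(f"unknown normalization {normalization!r}")
    minf = curve.plateau if normalization == "plateau" else 100.0
    if minf <= 0:
        raise ValueError("non-positive plateau; cannot normalize")
    t = curve.times
    frac = curve.released / minf

    mask = np.ones(t.size, dtype=bool)
    if window is not None:
        lo, hi = window
        mask &= (t >= lo) & (t <= hi)
    usable = mask & (t > 0) & (frac > 0)
    n_excluded = int(mask.sum() - usable.sum())
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable points (t>0, Mt>0) in window")
    tt, ff = t[usable], frac[usable]
    if np.all(tt == tt[0]):
        raise ValueError("all usable times equal; cannot fit")

    lt, lf = np.log(tt), np.log(ff)
    flags: list[str] = []
    # OLS slope/intercept
    slope, intercept = np.polyfit(lt, lf, 1)
    resid = lf - (slope * lt + intercept)
    ss_tot = float(np.sum((lf - lf.mean()) ** 2))
    if ss_tot == 0.0:
        # constant release values: slope 0, perfect "fit" of a constant
        slope = 0.0
        r2 = 1.0
    else:
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot
    n_hat, k_hat = float(slope), float(np.exp(intercept))

    if method == "direct":
        def model(p):
            return np.exp(p[0]) * np.power(tt, p[1]) - ff

        sol = least_squares(model, x0=[np.log(k_hat), n_hat], xtol=1e-14,
                            ftol=1e-14, gtol=1e-14)
        k_hat, n_hat = float(np.exp(sol.x[0])), float(sol.x[1])
        pred = np.exp(sol.x[0]) * np.power(tt, sol.x[1])
        ss_tot_d = float(np.sum((ff - ff.mean()) ** 2))
        r2 = 1.0 - float(np.sum((ff - pred) ** 2)) / ss_tot_d if ss_tot_d else 1.0
    elif method != "loglog":
        raise ValueError(f"unknown method {method!r}")

    if not (0.0 < n_hat < 1.0):
        flags.append(f"exponent n={n_hat:.4g} outside (0, 1)")
        warnings.warn(flags[-1], RuntimeWarning, stacklevel=2)

    return RitgerPeppasFit(
        k=k_hat if k_hat > 0 else np.finfo(float).tiny,
        n=n_hat,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        window=(float(tt.min()), float(tt.max())),
        normalization=normalization,
        n_points_used=int(usable.sum()),
        n_points_excluded=n_excluded,
        warnings_=flags,
    )
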