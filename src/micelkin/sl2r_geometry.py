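"""Cubic parameterization, SL(2,R) group action and hyperbolic metric.

A nondegenerate real cubic ``a0 X^3 + 3 a1 X^2 + 3 a2 X + a3`` is
parameterized by the roots (h, hbar) of its Hessian covariant together with
a unit-type parameter k:

    X_l = (h + eps^(l-1) hbar k) / (1 + eps^(l-1) k),   eps = (-1+i sqrt3)/2.

Homographies X -> (aX+b)/(cX+d) act on the roots and induce the simply
transitive action h -> (ah+b)/(ch+d), hbar likewise, k -> k (c hbar + d)/(c h + d),
whose infinitesimal generators close on the sl(2,R) bracket relations

    [B1,B2] = B1,  [B2,B3] = B3,  [B3,B1] = -2 B2.

Writing h = u + iv, k = exp(i theta), the invariant 1-forms reduce the
group metric to ``-(dtheta + du/v)^2 + (du^2 + dv^2)/v^2``; imposing the
angle-of-parallelism constraint dtheta = -du/v leaves the Poincare
upper-half-plane metric (du^2 + dv^2)/v^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sym

__all__ = [
    "EPS_CUBE_ROOT",
    "CubicParameterization",
    "HyperbolicPoint",
    "SL2RGenerators",
    "parameterize_cubic",
    "reconstruct_roots",
    "act_on_roots",
    "act_on_hk",
    "sl2r_generators",
    "verify_sl2r_structure",
    "one_forms_hk",
    "one_forms_real",
    "metric_ds2",
    "metric_ds2_hk",
]

#: primitive cube root of unity used in the root parameterization
EPS_CUBE_ROOT = (-1.0 + 1j * np.sqrt(3.0)) / 2.0


class DegenerateCubicError(ValueError):
    """Repeated roots (vanishing discriminant) or a0 = 0."""


@dataclass
class CubicParameterization:
    """Roots and Hessian-root parameterization of one nondegenerate cubic.

    Coefficients follow the weighted convention a0 X^3 + 3 a1 X^2 +
    3 a2 X + a3.  ``k_g`` is the group variable (named to avoid clashing
    with the release-rate k); for real cubics with three real roots it has
    unit modulus.
    """

    a0: float
    a1: float
    a2: float
    a3: float
    roots: np.ndarray        # X1, X2, X3 ordered by (Re, Im)
    h: complex
    h_bar: complex
    k_g: complex
    eps: complex = EPS_CUBE_ROOT
    reconstruction_residual: float = 0.0


@dataclass(frozen=True)
class HyperbolicPoint:
    """Upper-half-plane point (u, v>0) with connection angle theta."""

    u: float
    v: float
    theta: float = 0.0

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("v must be positive (upper half-plane)")


def _hessian_roots(a0: float, a1: float, a2: float, a3: float) -> np.ndarray:
    # Hessian covariant of the weighted cubic: H(X) proportional to
    # (a0 a2 - a1^2) X^2 + (a0 a3 - a1 a2) X + (a1 a3 - a2^2)
    A = a0 * a2 - a1**2
    B = a0 * a3 - a1 * a2
    C = a1 * a3 - a2**2
    if A == 0:
        # one Hessian root escapes to infinity; the (h, hbar, k)
        # parameterization does not apply to this measure-zero family
        raise DegenerateCubicError("degenerate Hessian (root at infinity)")
    return np.roots([A, B, C])


def _sorted_roots(r: np.ndarray) -> np.ndarray:
    order = np.lexsort((r.imag.round(12), r.real.round(12)))
    return r[order]


def reconstruct_roots(h: complex, h_bar: complex, k_g: complex) -> np.ndarray:
    """Evaluate the three roots from (h, hbar, k) via the eps-parameterization."""
    eps = EPS_CUBE_ROOT
    return np.array([
        (h + h_bar * k_g) / (1.0 + k_g),
        (h + eps * h_bar * k_g) / (1.0 + eps * k_g),
        (h + eps**2 * h_bar * k_g) / (1.0 + eps**2 * k_g),
    ])


def parameterize_cubic(coeffs) -> CubicParameterization:
    """Parameterize a cubic by its Hessian roots and the group variable.

    Parameters
    ----------
    coeffs : sequence of 4 reals
        Plain polynomial coefficients (c3, c2, c1, c0) of
        c3 X^3 + c2 X^2 + c1 X + c0 (numpy.roots order).  Internally the
        weighted convention a1 = c2/3, a2 = c1/3 is stored.

    The cubic must have three distinct roots; ``k_g`` is solved from X1
    (k = (h - X1)/(X1 - hbar)) and the remaining two roots are matched
    against the eps-parameterization (swapping the eps branches if needed).
    The max mismatch is stored as ``reconstruction_residual``.
    """
    c3, c2, c1, c0 = (float(c) for c in coeffs)
    if c3 == 0:
        raise DegenerateCubicError("a0 = 0: not a cubic")
    a0, a1, a2, a3 = c3, c2 / 3.0, c1 / 3.0, c0
    scale = max(abs(c3), abs(c2), abs(c1), abs(c0))
    # discriminant of c3 x^3 + c2 x^2 + c1 x + c0
    disc = (18 * c3 * c2 * c1 * c0 - 4 * c2**3 * c0 + c2**2 * c1**2
            - 4 * c3 * c1**3 - 27 * c3**2 * c0**2)
    if abs(disc) < 1e-12 * scale**4:
        raise DegenerateCubicError("repeated roots (discriminant ~ 0)")

    roots = _sorted_roots(np.roots([c3, c2, c1, c0]))
    hr = _hessian_roots(a0, a1, a2, a3)
    if hr.size != 2:
        raise DegenerateCubicError("Hessian is not a proper quadratic")
    # h: positive imaginary part when complex (upper half-plane), else the
    # larger real root
    if abs(hr[0].imag) > 1e-14 * max(1.0, abs(hr[0])):
        h = hr[0] if hr[0].imag > 0 else hr[1]
        h_bar = hr[1] if hr[0].imag > 0 else hr[0]
    else:
        hr = hr[np.argsort(hr.real)]
        h, h_bar = hr[1], hr[0]

    x1 = roots[0]
    k_g = (h - x1) / (x1 - h_bar)
    rec = reconstruct_roots(h, h_bar, k_g)
    # rec[0] == X1 by construction; match rec[1:] to roots[1:], allowing the
    # eps <-> eps^2 branch swap
    direct = max(abs(rec[1] - roots[1]), abs(rec[2] - roots[2]))
    swapped = max(abs(rec[1] - roots[2]), abs(rec[2] - roots[1]))
    roots_out = roots.copy()
    if swapped < direct:
        roots_out[1], roots_out[2] = roots[2], roots[1]
        residual = swapped
    else:
        residual = direct
    residual = max(residual, abs(rec[0] - roots[0]))
    return CubicParameterization(
        a0=a0, a1=a1, a2=a2, a3=a3, roots=roots_out,
        h=complex(h), h_bar=complex(h_bar), k_g=complex(k_g),
        reconstruction_residual=float(residual),
    )


# ---------------------------------------------------------------------------
# group action

def act_on_roots(roots, mat) -> np.ndarray:
    """Homographic action X -> (aX + b)/(cX + d) on each root."""
    a, b, c, d = mat
    if a * d - b * c == 0:
        raise ValueError("singular transformation (ad - bc = 0)")
    r = np.asarray(roots, dtype=complex)
    den = c * r + d
    if np.any(np.abs(den) < 1e-300):
        raise ZeroDivisionError("homography pole hit (cX + d = 0)")
    return (a * r + b) / den


def act_on_hk(triple, mat) -> tuple[complex, complex, complex]:
    """Induced action on (h, hbar, k): homography on h, hbar; k picks up
    the multiplier (c hbar + d)/(c h + d)."""
    a, b, c, d = mat
    if a * d - b * c == 0:
        raise ValueError("singular transformation (ad - bc = 0)")
    h, h_bar, k_g = triple
    den_h, den_hb = c * h + d, c * h_bar + d
    if min(abs(den_h), abs(den_hb)) < 1e-300:
        raise ZeroDivisionError("homography pole hit")
    return (
        (a * h + b) / den_h,
        (a * h_bar + b) / den_hb,
        k_g * den_hb / den_h,
    )


# ---------------------------------------------------------------------------
# generators and brackets

@dataclass
class SL2RGenerators:
    """Vector fields on (h, hbar, k) as sympy coefficient triples."""

    B1: tuple
    B2: tuple
    B3: tuple
    symbols: tuple


def sl2r_generators() -> SL2RGenerators:
    """The infinitesimal generators of the induced group action:

    B1 = d_h + d_hbar
    B2 = h d_h + hbar d_hbar
    B3 = h^2 d_h + hbar^2 d_hbar + (h - hbar) k d_k
    """
    h, hb, k = sym.symbols("h hbar k")
    return SL2RGenerators(
        B1=(sym.Integer(1), sym.Integer(1), sym.Integer(0)),
        B2=(h, hb, sym.Integer(0)),
        B3=(h**2, hb**2, (h - hb) * k),
        symbols=(h, hb, k),
    )


def _lie_bracket(X, Y, syms):
    """[X, Y]^i = X^j d_j Y^i - Y^j d_j X^i for polynomial vector fields."""
    return tuple(
        sym.expand(
            sum(X[j] * sym.diff(Y[i], syms[j]) for j in range(3))
            - sum(Y[j] * sym.diff(X[i], syms[j]) for j in range(3))
        )
        for i in range(3)
    )


def verify_sl2r_structure(
    g: SL2RGenerators | None = None,
    n_points: int = 25,
    seed: int = 0,
) -> float:
    """Max defect of the bracket relations [B1,B2]=B1, [B2,B3]=B3,
    [B3,B1]=-2B2.

    Brackets are computed exactly as polynomial vector fields; the defect
    (difference of coefficient functions) is evaluated at random complex
    points and its max modulus returned.  Zero (to rounding) for the
    canonical generators; O(1) for perturbed ones.
    """
    if g is None:
        g = sl2r_generators()
    syms = g.symbols
    defects = []
    for X, Y, expect, sign in (
        (g.B1, g.B2, g.B1, 1),
        (g.B2, g.B3, g.B3, 1),
        (g.B3, g.B1, g.B2, -2),
    ):
        br = _lie_bracket(X, Y, syms)
        defects.extend(sym.expand(br[i] - sign * expect[i]) for i in range(3))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-2, 2, size=(n_points, 6))
    worst = 0.0
    fns = [sym.lambdify(syms, d, "numpy") for d in defects]
    for p in pts:
        vals = (complex(p[0], p[1]), complex(p[2], p[3]), complex(p[4], p[5]))
        for f in fns:
            worst = max(worst, abs(complex(f(*vals))))
    return worst


# ---------------------------------------------------------------------------
# differential forms and metric

def one_forms_hk(h: complex, h_bar: complex, k_g: complex,
                 dh: complex, dh_bar: complex, dk: complex):
    """The invariant 1-forms in (h, hbar, k) coordinates:

    omega1 = dh / ((h - hbar) k)
    omega2 = -i (dk/k - (dh + dhbar)/(h - hbar))
    omega3 = -k dhbar / (h - hbar)
    """
    if h == h_bar:
        raise ZeroDivisionError("h = hbar: degenerate point")
    diff = h - h_bar
    w1 = dh / (diff * k_g)
    w2 = -1j * (dk / k_g - (dh + dh_bar) / diff)
    w3 = -k_g * dh_bar / diff
    return w1, w2, w3


def one_forms_real(point: HyperbolicPoint, du: float, dv: float, dtheta: float):
    """The real 1-forms at (u, v, theta):

    Omega1 = dtheta + du/v
    Omega2 = cos(theta) du/v + sin(theta) dv/v
    Omega3 = -sin(theta) du/v + cos(theta) dv/v
    """
    v, th = point.v, point.theta
    o1 = dtheta + du / v
    o2 = (np.cos(th) * du + np.sin(th) * dv) / v
    o3 = (-np.sin(th) * du + np.cos(th) * dv) / v
    return o1, o2, o3


def metric_ds2(point: HyperbolicPoint, du: float, dv: float,
               dtheta: float | None = None, constrained: bool = False) -> float:
    """Squared line element at (u, v, theta).

    Unconstrained: ds^2 = -(dtheta + du/v)^2 + (du^2 + dv^2)/v^2
    (equal to -(Omega1)^2 + (Omega2)^2 + (Omega3)^2).

    Constrained (angle of parallelism, dtheta = -du/v): the first term
    vanishes and ds^2 = (du^2 + dv^2)/v^2, the Poincare half-plane metric;
    any supplied dtheta is ignored in this mode.
    """
    v = point.v
    poincare = (du**2 + dv**2) / v**2
    if constrained:
        return poincare
    if dtheta is None:
        raise ValueError("dtheta required in unconstrained mode")
    return -((dtheta + du / v) ** 2) + poincare


def metric_ds2_hk(h: complex, h_bar: complex, k_g: complex,
                  dh: complex, dh_bar: complex, dk: complex) -> complex:
    """Group metric in complex coordinates:

    ds^2 = (dk/k - (dh + dhbar)/(h - hbar))^2 - 4 dh dhbar / (h - hbar)^2.

    With h = u+iv, hbar = u-iv, k = e^{i theta} this equals the real form
    of :func:`metric_ds2` (the -4/(h-hbar)^2 factor carries the 1/v^2).
    """
    if h == h_bar:
        raise ZeroDivisionError("h = hbar: degenerate point")
    diff = h - h_bar
    return (dk / k_g - (dh + dh_bar) / diff) ** 2 - 4.0 * dh * dh_bar / diff**2
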