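"""Synthetic release-curve panels with the statistical structure the
analysis assumes.

The reference study panel covers 3 copolymer samples (A, B, C; increasing
molecular weight) released in 3 media (pH 2, 6.8, 7.4) over up to 300 h.
Per condition the panel carries a final release efficiency (plateau, % of
the encapsulated drug), a duration and a power-law exponent n near 0.5;
these are the generator defaults (REFERENCE_PANEL below).

Three generating laws are available:

* ``ritger_peppas`` -- released(t) = 100 k t^n, with k derived so the
  plateau is reached exactly at the curve's duration (so the whole curve is
  a pure power law and the generating (k, n) are recoverable);
* ``ou_release``    -- the saturating law sqrt((D/eta)(1 - e^{-2 eta t}))
  with eta matched so the plateau equals the configured value;
* ``two_regime``    -- an early (t <= breakpoint) and a late (t > breakpoint)
  regime with distinct diffusion degrees D_early < D_late, emulating the
  two temporal scale resolutions: the late regime plateaus at the
  configured value, the early one aims to place ~30 % of the total release
  mass before the breakpoint (when the early degree allows; otherwise it
  falls back to the late relaxation rate).

Measurement noise is multiplicative Gaussian on the release *increments*
(relative s.d. ``noise_rel``, default 2 %), which keeps every generated
curve non-decreasing while producing %-scale scatter.  All randomness is
threaded from a single mandatory root seed (numpy SeedSequence), so equal
seeds give byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loading_efficiency import Formulation
from .multifractal_kinetics import (
    OUParameters,
    release_from_ou,
    solve_eta_for_early_fraction,
)
from .release_data import ReleaseCurve

__all__ = [
    "REFERENCE_PANEL",
    "REFERENCE_FORMULATIONS",
    "CurveSpec",
    "PanelConfig",
    "generate_panel",
    "generate_formulations",
    "default_times",
]

#: Per-(sample, pH) reference conditions: plateau Ef (%), duration (h),
#: power-law exponent n.
REFERENCE_PANEL: dict[tuple[str, float], tuple[float, float, float]] = {
    ("A", 2.0): (95.2, 300.0, 0.548),
    ("B", 2.0): (94.3, 300.0, 0.445),
    ("C", 2.0): (94.1, 300.0, 0.527),
    ("A", 6.8): (63.0, 264.0, 0.417),
    ("B", 6.8): (58.2, 264.0, 0.428),
    ("C", 6.8): (46.8, 264.0, 0.519),
    ("A", 7.4): (80.8, 218.0, 0.544),
    ("B", 7.4): (61.6, 264.0, 0.410),
    ("C", 7.4): (58.8, 218.0, 0.566),
}

#: Feed: 250 mg copolymer + 25 mg curcumin; measured drug contents (mg per
#: g of micelle powder) for samples A, B, C.
REFERENCE_FORMULATIONS = (
    ("A", 250.0, 25.0, 65.30),
    ("B", 250.0, 25.0, 63.95),
    ("C", 250.0, 25.0, 51.26),
)


def default_times(duration_h: float = 300.0, n_points: int = 25,
                  dense_until: float = 50.0) -> np.ndarray:
    """Sampling grid: denser before ``dense_until`` (early kinetics), then
    evenly spread to the end; no t = 0 row."""
    n_early = max(3, int(round(n_points * 0.4)))
    n_late = n_points - n_early
    early = np.linspace(dense_until / n_early, dense_until, n_early)
    late = np.linspace(dense_until, duration_h, n_late + 1)[1:]
    return np.concatenate([early, late])


@dataclass(frozen=True)
class CurveSpec:
    """Generator truth for one (sample, pH) curve."""

    sample_id: str
    pH: float
    plateau_pct: float
    duration_h: float
    # ritger_peppas truth
    n_exponent: float = 0.5
    k_rate: float | None = None      # derived from plateau/duration if None
    # ou_release / two_regime truth (generator units: %^2/h)
    D: float | None = None
    D_early: float | None = None
    D_late: float | None = None
    eta: float | None = None


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic panel.

    ``generator`` is one of {"ritger_peppas", "ou_release", "two_regime"};
    ``curves`` defaults to the reference panel conditions; ``seed`` is
    mandatory (all noise is reproducible).
    """

    seed: int
    generator: str = "ritger_peppas"
    curves: tuple = ()
    noise_rel: float = 0.02
    n_points: int = 25
    breakpoint_h: float = 50.0
    early_mass_target: float = 0.30

    def __post_init__(self):
        if self.generator not in ("ritger_peppas", "ou_release", "two_regime"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.curves:
            object.__setattr__(self, "curves", tuple(
                CurveSpec(sample_id=s, pH=ph, plateau_pct=ef,
                          duration_h=dur, n_exponent=n)
                for (s, ph), (ef, dur, n) in REFERENCE_PANEL.items()
            ))
        for c in self.curves:
            if not (0.0 < c.plateau_pct <= 100.0):
                raise ValueError("plateau_pct must lie in (0, 100]")


def _noiseless_curve(spec: CurveSpec, cfg: PanelConfig,
                     times: np.ndarray) -> np.ndarray:
    if cfg.generator == "ritger_peppas":
        k = spec.k_rate
        if k is None:
            k = (spec.plateau_pct / 100.0) / spec.duration_h**spec.n_exponent
        return np.minimum(100.0 * k * times**spec.n_exponent, spec.plateau_pct)

    plateau = spec.plateau_pct
    if cfg.generator == "ou_release":
        d = spec.D if spec.D is not None else 5.0
        eta = spec.eta if spec.eta is not None else d / plateau**2
        return release_from_ou(times, OUParameters(D=d, eta=eta))

    # two_regime
    d_late = spec.D_late if spec.D_late is not None else 9.0
    d_early = spec.D_early if spec.D_early is not None else d_late / 4.0
    eta_late = spec.eta if spec.eta is not None else d_late / plateau**2
    # "early mass" targets the fraction of the release actually reached by
    # the end of the experiment, not the (possibly unattained) asymptote
    final_release = release_from_ou(spec.duration_h,
                                    OUParameters(D=d_late, eta=eta_late))
    eta_early = solve_eta_for_early_fraction(
        d_early, cfg.early_mass_target * final_release, cfg.breakpoint_h)
    if eta_early is None:
        eta_early = eta_late
    bp = cfg.breakpoint_h
    early = release_from_ou(times, OUParameters(D=d_early, eta=eta_early))
    late = release_from_ou(times, OUParameters(D=d_late, eta=eta_late))
    vals = np.where(times <= bp, early, late)
    # the late branch generally sits above the early one at the junction;
    # guard monotonicity in the rare reversed case
    return np.maximum.accumulate(vals)


def generate_panel(cfg: PanelConfig) -> list[ReleaseCurve]:
    """Generate one synthetic panel of release curves.

    Curves are non-decreasing, reach their configured plateau within the
    time range, and are reproducible: equal configs (including seed) yield
    identical curves.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(cfg.curves))
    out = []
    for spec, ss in zip(cfg.curves, children):
        times = default_times(spec.duration_h, cfg.n_points, cfg.breakpoint_h)
        clean = _noiseless_curve(spec, cfg, times)
        if cfg.noise_rel > 0:
            rng = np.random.default_rng(ss)
            incr = np.diff(np.concatenate([[0.0], clean]))
            factors = np.maximum(
                0.0, 1.0 + cfg.noise_rel * rng.standard_normal(incr.size))
            noisy = np.cumsum(incr * factors)
        else:
            noisy = clean
        out.append(ReleaseCurve(
            sample_id=spec.sample_id, pH=spec.pH, times=times,
            released=np.minimum(noisy, 110.0),
            medium=f"synthetic ({cfg.generator})",
        ))
    return out


def generate_formulations(n_random: int = 0, seed: int | None = None
                          ) -> list[Formulation]:
    """The three reference formulations, plus optional randomized variants
    (drug content uniform in [5, 90] mg/g) for fuzzing."""
    out = [Formulation(polymer_mass_mg=p, drug_added_mg=d,
                       drug_in_micelles_mg_per_g=c, sample_id=s)
           for s, p, d, c in REFERENCE_FORMULATIONS]
    if n_random:
        if seed is None:
            raise ValueError("seed required for randomized formulations")
        rng = np.random.default_rng(seed)
        for i in range(n_random):
            out.append(Formulation(
                polymer_mass_mg=250.0, drug_added_mg=25.0,
                drug_in_micelles_mg_per_g=float(rng.uniform(5.0, 90.0)),
                sample_id=f"R{i+1}",
            ))
    return out
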