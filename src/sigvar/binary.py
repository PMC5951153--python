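"""Binary (threshold) population signaling on top of the five-step pathway.

A cell switches into the active state when its steady-state output exceeds
a threshold (default 10, chosen well above the basal output of 1).  The
population-level observable is the fraction of activated cells as a
function of the fold-input R; its steepness is summarized by an apparent
Hill coefficient (aHC) fitted to the dose-response curve.

Analytically, the aHC scales inversely with the total pathway log-noise:

    aHC ≈ beta / (CV * sqrt(N)),   beta ≈ 1.4

and together with the analog detection limit fIDL = exp(alpha*CV*sqrt(N))
yields a CV- and N-independent co-dependency product

    log2(fIDL) * aHC = alpha * beta / ln 2

quantifying the trade-off between analog single-cell accuracy and binary
population controllability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .analog import calibration_alpha, fidl_analytic
from .pathway import NoiseSpec, simulate_population

__all__ = [
    "BinaryModelSpec",
    "DoseResponse",
    "HillFit",
    "TradeoffSpec",
    "default_r_grid",
    "fraction_activated",
    "dose_response",
    "hill_curve",
    "fit_hill",
    "ahc_analytic",
    "effective_cv",
    "tradeoff_curve",
]


def default_r_grid(r_min: float = 1.0, r_max: float = 100.0, n: int = 30) -> np.ndarray:
    """Log-spaced fold-input grid bracketing the default threshold of 10."""
    return np.logspace(np.log10(r_min), np.log10(r_max), n)


@dataclass
class BinaryModelSpec:
    threshold: float = 10.0
    r_grid: np.ndarray = field(default_factory=default_r_grid)
    n_cells: int = 5000
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        if self.threshold <= 1:
            raise ValueError("threshold must exceed the basal output of 1")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")


@dataclass
class DoseResponse:
    r: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.r.shape != self.fraction.shape:
            raise ValueError("r and fraction must have the same length")


@dataclass
class HillFit:
    h: float
    k_half: float
    residual: float
    step_like: bool = False  # fit hit the steepness bound (near-step data)


@dataclass
class TradeoffSpec:
    cv: float
    n_components: int = 10
    n_cov: int = 0
    beta: float = 1.4
    accuracy: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.n_cov <= self.n_components:
            raise ValueError("n_cov must be between 0 and n_components")

    @property
    def alpha(self) -> float:
        return calibration_alpha(self.accuracy)


def fraction_activated(
    spec: BinaryModelSpec, R: float, rng: Optional[np.random.Generator] = None
) -> float:
    """Fraction of simulated cells whose steady-state output exceeds threshold."""
    pop = simulate_population(R=R, spec=spec.noise, n_cells=spec.n_cells, rng=rng)
    return float(np.mean(pop.outputs > spec.threshold))


def dose_response(
    spec: BinaryModelSpec, rng: Optional[np.random.Generator] = None
) -> DoseResponse:
    """Percent-activated curve over the fold-input grid."""
    if rng is None:
        rng = spec.noise.rng()
    frac = np.array([fraction_activated(spec, r, rng) for r in spec.r_grid])
    return DoseResponse(r=spec.r_grid, fraction=frac)


def hill_curve(r: np.ndarray, h: float, k: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return r**h / (k**h + r**h)


def fit_hill(curve: DoseResponse, h_max: float = 100.0) -> HillFit:
    """Nonlinear least-squares Hill fit f(R) = R^h / (k^h + R^h).

    Saturated points (fraction exactly 0 or 1) are retained — they carry
    steepness information.  Initial guesses: k at the grid point nearest
    half-activation, h = 2.  If the least-squares fit fails (step-like
    data), h is recovered by a profile grid search instead.
    """
    r, f = curve.r, curve.fraction
    interior = (f > 0) & (f < 1)
    if interior.sum() < 1 and not (np.any(f == 0) and np.any(f == 1)):
        raise ValueError("curve never crosses the transition; nothing to fit")
    k0 = r[np.argmin(np.abs(f - 0.5))]
    try:
        popt, _ = curve_fit(
            hill_curve, r, f, p0=(2.0, k0),
            bounds=([1e-3, r.min() / 10], [h_max, r.max() * 10]),
            maxfev=20_000,
        )
        h, k = float(popt[0]), float(popt[1])
        resid = float(np.sum((hill_curve(r, h, k) - f) ** 2))
        return HillFit(h=h, k_half=k, residual=resid, step_like=h >= 0.99 * h_max)
    except RuntimeError:
        # profile search: best k for each h on a log grid
        hs = np.logspace(-2, np.log10(h_max), 400)
        best = (np.inf, np.nan, np.nan)
        for h in hs:
            ks = np.logspace(np.log10(r.min() / 3), np.log10(r.max() * 3), 200)
            sse = [np.sum((hill_curve(r, h, k) - f) ** 2) for k in ks]
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (sse[i], h, ks[i])
        return HillFit(
            h=float(best[1]), k_half=float(best[2]), residual=float(best[0]),
            step_like=best[1] >= 0.99 * h_max,
        )


def ahc_analytic(spec: TradeoffSpec) -> float:
    """Apparent Hill coefficient beta / (cv * sqrt(N)); unbounded at cv=0."""
    cv_tot = effective_cv(spec.cv, spec.n_components, spec.n_cov)
    if cv_tot == 0:
        raise ValueError("aHC is unbounded at zero CV (step response)")
    return spec.beta / cv_tot


def effective_cv(cv: float, n: int, n_cov: int = 0) -> float:
    """Total output CV with ``n_cov`` perfectly covarying components.

    Error propagation over n log-additive terms of which ``n_cov`` share one
    draw: the shared terms add linearly (variance n_cov^2 * cv^2), the rest
    in quadrature, giving cv * sqrt(n - n_cov + n_cov^2).  Reduces to
    cv*sqrt(n) at n_cov in {0, 1} and to cv*n when all components covary.
    """
    if not 0 <= n_cov <= n:
        raise ValueError("n_cov must be between 0 and n")
    return cv * np.sqrt(n - n_cov + n_cov**2)


def tradeoff_curve(
    cvs: Sequence[float],
    n_components: int = 10,
    n_cov: int = 0,
    beta: float = 1.4,
    accuracy: float = 0.95,
) -> list[tuple[float, float]]:
    """(log2 fIDL, aHC) points along a CV grid.

    The product log2(fIDL) * aHC is the same at every point:
    alpha * beta / ln 2.
    """
    points = []
    for cv in cvs:
        spec = TradeoffSpec(
            cv=cv, n_components=n_components, n_cov=n_cov, beta=beta, accuracy=accuracy
        )
        cv_tot = effective_cv(cv, n_components, n_cov)
        fidl = fidl_analytic(cv_tot, n_components=1, accuracy=accuracy)
        points.append((float(np.log2(fidl)), ahc_analytic(spec)))
    return points
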