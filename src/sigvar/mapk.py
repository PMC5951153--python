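"""Noisy MAPK/ERK cascade producing bimodal pERK activation.

A Sturm-type ERK signaling network: RasGTP (the input, standing in for
extracellular EGF) activates Raf; active Raf doubly phosphorylates MEK;
doubly phosphorylated MEK (ppMEK) doubly phosphorylates ERK; four
phosphatases reverse the four cycles; doubly phosphorylated ERK (ppERK,
the output, a proxy for ERK activity) feeds back negatively on Raf
activation.  The packaged rate set (``data/mapk_rates.yaml``) is a
package-authored parameterization of this architecture: the upstream tiers
respond gradedly to dose while the ERK tier operates with near-saturated
phosphatases, so terminal ppERK switches sharply between an OFF state near
zero and an ON plateau.  With lognormal cell-to-cell noise on the MEK and
ERK totals (default CV 15%) and on the input (default CV 10%), terminal
ppERK at intermediate doses is bimodal and a threshold (default 17)
classifies cells as active or inactive.

Strong feedback combined with deep zero-order ultrasensitivity makes this
architecture a relaxation oscillator; the packaged feedback is therefore
first-order with a large inhibition constant, which keeps terminal ppERK a
monotone function of dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .binary import DoseResponse, HillFit, fit_hill

__all__ = [
    "MapkConfig",
    "MapkNoiseSpec",
    "MapkCellResult",
    "load_default_config",
    "simulate_mapk_cell",
    "mapk_population",
    "mapk_dose_response",
    "fold_error_at_fraction",
    "stratify_by_activity",
    "default_dose_grid",
]

_STATE_NAMES = ("raf", "araf", "mek", "pmek", "ppmek", "erk", "perk", "pperk")


@dataclass
class MapkConfig:
    species: dict
    rates: dict
    t_end: float = 240.0
    perk_threshold: float = 17.0

    def __post_init__(self) -> None:
        for name, v in {**self.species, **self.rates}.items():
            if v < 0:
                raise ValueError(f"parameter {name} must be non-negative")


@dataclass
class MapkNoiseSpec:
    cv_mek_erk: float = 0.15
    cv_input: float = 0.10
    covary: bool = False

    def __post_init__(self) -> None:
        if self.cv_mek_erk < 0 or self.cv_input < 0:
            raise ValueError("CVs must be non-negative")


@dataclass
class MapkCellResult:
    t: np.ndarray
    perk_trace: np.ndarray
    active: bool
    mek_level: float
    erk_level: float
    dose: float
    trajectory: Optional[np.ndarray] = None  # (n_t, 8) full state if kept


def load_default_config() -> MapkConfig:
    """Load the packaged cascade parameterization."""
    text = resources.files("sigvar").joinpath("data/mapk_rates.yaml").read_text()
    raw = yaml.safe_load(text)
    return MapkConfig(
        species=raw["species"],
        rates=raw["rates"],
        t_end=raw["simulation"]["t_end"],
        perk_threshold=raw["simulation"]["perk_threshold"],
    )


def default_dose_grid(
    log2_min: float = 9.0, log2_max: float = 13.0, n: int = 24
) -> np.ndarray:
    """Log2-spaced RasGTP dose grid bracketing the activation window."""
    return 2.0 ** np.linspace(log2_min, log2_max, n)


def _rhs(t, y, ras, s, r):
    raf, araf, mek, pmek, ppmek, erk, perk, pperk = y
    fb = 1.0 / (1.0 + (pperk / r["ki"]) ** r["nfb"])
    v_ra = r["k1"] * ras * fb * raf / (r["km1"] + raf)
    v_rd = r["k2"] * s["p1"] * araf / (r["km2"] + araf)
    v1 = r["k3"] * araf * mek / (r["km3"] + mek)
    v2 = r["k3b"] * araf * pmek / (r["km3"] + pmek)
    v3 = r["k4"] * s["p2"] * ppmek / (r["km4"] + ppmek)
    v4 = r["k4"] * s["p2"] * pmek / (r["km4"] + pmek)
    v5 = r["k5"] * ppmek * erk / (r["km5"] + erk)
    v6 = r["k5b"] * ppmek * perk / (r["km5"] + perk)
    v7 = r["k6"] * s["p3"] * pperk / (r["km6"] + pperk)
    v8 = r["k7"] * s["p4"] * perk / (r["km7"] + perk)
    return (
        -v_ra + v_rd, v_ra - v_rd,
        -v1 + v4, v1 - v2 + v3 - v4, v2 - v3,
        -v5 + v8, v5 - v6 + v7 - v8, v6 - v7,
    )


def simulate_mapk_cell(
    dose: float,
    noise: MapkNoiseSpec | None = None,
    rng: Optional[np.random.Generator] = None,
    config: Optional[MapkConfig] = None,
    n_points: int = 61,
    keep_trajectory: bool = False,
) -> MapkCellResult:
    """Integrate one cell's cascade with noise-scaled MEK/ERK/input levels.

    Classification is by terminal ppERK against the configured threshold.
    """
    if config is None:
        config = load_default_config()
    if noise is None:
        noise = MapkNoiseSpec()
    if rng is None:
        rng = np.random.default_rng()
    if noise.covary:
        mek_f = erk_f = float(np.exp(rng.standard_normal() * noise.cv_mek_erk))
    else:
        mek_f, erk_f = np.exp(rng.standard_normal(2) * noise.cv_mek_erk)
    ras = dose * float(np.exp(rng.standard_normal() * noise.cv_input))
    s = config.species
    y0 = [s["raf_total"], 0.0, s["mek_total"] * mek_f, 0.0, 0.0,
          s["erk_total"] * erk_f, 0.0, 0.0]
    t_eval = np.linspace(0.0, config.t_end, n_points)
    sol = solve_ivp(
        _rhs, (0.0, config.t_end), y0, args=(ras, s, config.rates),
        method="LSODA", rtol=1e-6, atol=1e-8, t_eval=t_eval,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"MAPK integration failed: {sol.message}")
    perk = sol.y[7]
    return MapkCellResult(
        t=sol.t,
        perk_trace=perk,
        active=bool(perk[-1] > config.perk_threshold),
        mek_level=s["mek_total"] * mek_f,
        erk_level=s["erk_total"] * erk_f,
        dose=dose,
        trajectory=sol.y.T if keep_trajectory else None,
    )


def mapk_population(
    dose: float,
    n_cells: int,
    noise: MapkNoiseSpec | None = None,
    rng: Optional[np.random.Generator] = None,
    config: Optional[MapkConfig] = None,
) -> list[MapkCellResult]:
    if config is None:
        config = load_default_config()
    return [
        simulate_mapk_cell(dose, noise=noise, rng=rng, config=config, n_points=2)
        for _ in range(n_cells)
    ]


def mapk_dose_response(
    dose_grid: Sequence[float] | None = None,
    n_cells: int = 200,
    noise: MapkNoiseSpec | None = None,
    rng: Optional[np.random.Generator] = None,
    config: Optional[MapkConfig] = None,
) -> DoseResponse:
    """Fraction of active cells per dose over an increasing dose grid."""
    if dose_grid is None:
        dose_grid = default_dose_grid()
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(np.diff(dose_grid) <= 0):
        raise ValueError("dose_grid must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng()
    frac = np.array([
        np.mean([c.active for c in mapk_population(d, n_cells, noise, rng, config)])
        for d in dose_grid
    ])
    return DoseResponse(r=dose_grid, fraction=frac)


def fold_error_at_fraction(
    curve: DoseResponse, target_fraction: float = 0.01, input_error: float = 0.10
) -> float:
    """Fold-change in activated fraction caused by a relative input error.

    Interpolates the dose R* at which the curve crosses ``target_fraction``
    (monotone piecewise-linear in (log2 dose, log10 fraction)) and returns
    fraction(R* * (1 + input_error)) / fraction(R*).  A perfectly flat
    curve gives 1; for an exact Hill curve at small fractions the result
    approaches (1 + input_error)^h.
    """
    pos = curve.fraction > 0
    x = np.log2(curve.r[pos])
    y = np.log10(curve.fraction[pos])
    y = np.maximum.accumulate(y)  # enforce monotonicity against MC jitter
    if target_fraction < 10 ** y[0] or target_fraction > 10 ** y[-1]:
        raise ValueError("target fraction outside the positive range of the curve")
    lt = np.log10(target_fraction)
    x_star = float(np.interp(lt, y, x))
    x_pert = x_star + np.log2(1.0 + input_error)
    f_star = 10 ** float(np.interp(x_star, x, y))
    f_pert = 10 ** float(np.interp(min(x_pert, x[-1]), x, y))
    return f_pert / f_star


def stratify_by_activity(results: Sequence[MapkCellResult]) -> dict:
    """Median/quartile MEK and ERK levels in active vs inactive cells."""
    groups = {
        "active": [c for c in results if c.active],
        "inactive": [c for c in results if not c.active],
    }
    out: dict = {}
    for name, cells in groups.items():
        if not cells:
            out[name] = None
            continue
        mek = np.array([c.mek_level for c in cells])
        erk = np.array([c.erk_level for c in cells])
        out[name] = {
            "n": len(cells),
            "mek": dict(zip(("q1", "median", "q3"), np.quantile(mek, (0.25, 0.5, 0.75)))),
            "erk": dict(zip(("q1", "median", "q3"), np.quantile(erk, (0.25, 0.5, 0.75)))),
        }
    out["comparable"] = out["active"] is not None and out["inactive"] is not None
    return out


def fit_mapk_hill(curve: DoseResponse, dose_scale: float = 2048.0) -> HillFit:
    """Hill fit of a MAPK dose-response with doses rescaled near unity."""
    fit = fit_hill(DoseResponse(r=curve.r / dose_scale, fraction=curve.fraction))
    fit.k_half *= dose_scale
    return fit
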