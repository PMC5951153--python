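"""Analog single-cell transmission accuracy metrics.

Two complementary metrics for how well a noisy pathway transmits a graded
(fold-change) input:

* the fold-Input Detection Limit (fIDL) — the minimal fold-stimulus whose
  output distribution can be distinguished from the unstimulated one with a
  given accuracy (default 95%).  For N independent lognormal regulators the
  total output log-noise is ``CV * sqrt(N)`` and the closed form is

      fIDL = exp(2 * Phi^-1(accuracy) * CV * sqrt(N)) = exp(alpha * CV * sqrt(N))

  with alpha = 2 * Phi^-1(0.95) ≈ 3.3 at 95% accuracy;

* the plug-in mutual information of the (input, output) channel from a 2-D
  histogram in log2 units.  Unlike the fIDL, MI depends strongly on the
  fold-output range, which is why a saturating output transform is provided
  for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.stats import norm

from .pathway import NoiseSpec, simulate_population

__all__ = [
    "FidlSpec",
    "MISpec",
    "calibration_alpha",
    "fidl_analytic",
    "fidl_simulated",
    "fidl_from_outputs",
    "mutual_information",
    "saturating_output",
]


@dataclass
class FidlSpec:
    cv: float = 0.10
    n_components: int = 10
    accuracy: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.accuracy < 1:
            raise ValueError("accuracy must be in (0, 1)")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    @property
    def alpha(self) -> float:
        return calibration_alpha(self.accuracy)

    @property
    def cv_total(self) -> float:
        return self.cv * np.sqrt(self.n_components)


@dataclass
class MISpec:
    n_samples: int = 10_000
    bin_width: float = 0.05  # log2 units
    saturation_ceiling: Optional[float] = None  # e.g. 10
    saturation_half_term: float = 9.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")


def calibration_alpha(accuracy: float = 0.95) -> float:
    """The constant alpha = 2 * Phi^-1(accuracy) (≈ 3.29 at 95%)."""
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must be in (0, 1)")
    return 2.0 * norm.ppf(accuracy)


def fidl_analytic(
    cv: float, n_components: int = 10, accuracy: float = 0.95
) -> float:
    """Closed-form fold-input detection limit exp(alpha * cv * sqrt(N))."""
    spec = FidlSpec(cv=cv, n_components=n_components, accuracy=accuracy)
    return float(np.exp(spec.alpha * spec.cv_total))


def fidl_from_outputs(outputs: np.ndarray, accuracy: float = 0.95) -> float:
    """fIDL from a basal (R=1) output sample of a scale-equivariant model.

    The detection criterion matches the ``accuracy`` quantile of the basal
    log-output distribution with the ``1-accuracy`` quantile of the
    stimulated one.  For a model whose output scales linearly with R the
    stimulated distribution is the basal one shifted by ln R, so the limit
    is simply the quantile ratio of the basal sample.
    """
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must be in (0, 1)")
    outputs = np.asarray(outputs, dtype=float)
    if np.any(outputs <= 0):
        raise ValueError("outputs must be positive")
    log_out = np.log(outputs)
    hi = np.quantile(log_out, accuracy)
    lo = np.quantile(log_out, 1.0 - accuracy)
    if hi <= lo:  # degenerate (zero-variance) distribution
        return 1.0
    return float(np.exp(hi - lo))


def fidl_simulated(
    spec: NoiseSpec,
    accuracy: float = 0.95,
    n_cells: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    model: Optional[Callable[[float, int], np.ndarray]] = None,
    r_max: float = 1e6,
    tol: float = 1e-4,
) -> float:
    """Monte-Carlo fold-input detection limit.

    Without ``model`` the linear five-step pathway is simulated once at R=1
    and the scale-equivariant quantile-ratio shortcut is used.  With a
    ``model(R, n_cells) -> outputs`` callable (e.g. one with output
    saturation, which breaks scale equivariance) the limit is found by
    bisection on ln R for the smallest R whose output distribution clears
    the basal one at the matched quantiles.
    """
    if rng is None:
        rng = spec.rng()
    if model is None:
        out = simulate_population(R=1.0, spec=spec, n_cells=n_cells, rng=rng).outputs
        return fidl_from_outputs(out, accuracy=accuracy)

    basal = np.log(model(1.0, n_cells))
    hi_basal = np.quantile(basal, accuracy)

    def clears(log_r: float) -> bool:
        stim = np.log(model(float(np.exp(log_r)), n_cells))
        return np.quantile(stim, 1.0 - accuracy) >= hi_basal

    lo, hi = 0.0, np.log(r_max)
    if clears(lo):
        return 1.0
    if not clears(hi):
        raise ValueError("no detectable fold-input below r_max; increase r_max")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if clears(mid):
            hi = mid
        else:
            lo = mid
    return float(np.exp(0.5 * (lo + hi)))


def saturating_output(
    y4_drive: np.ndarray | float, ceiling: float = 10.0, half_term: float = 9.0
) -> np.ndarray | float:
    """Saturating transform ceiling * y / (y + half_term) of the y4 drive.

    Equals 1 at y=1 and approaches ``ceiling`` as y grows, imposing a
    bounded fold-output range on the otherwise unbounded linear model.
    """
    y = np.asarray(y4_drive, dtype=float)
    if np.any(y < 0):
        raise ValueError("drive must be non-negative")
    out = ceiling * y / (y + half_term)
    return float(out) if np.isscalar(y4_drive) else out


def mutual_information(
    r_samples: np.ndarray, outputs: np.ndarray, spec: MISpec | None = None
) -> float:
    """Plug-in mutual information (bits) of the input/output channel.

    Histogram both variables in log2 units with the spec's bin width and
    apply the naive plug-in estimator; empty bins contribute zero by the
    0*log(0) = 0 convention.  No bias correction is applied.
    """
    if spec is None:
        spec = MISpec()
    r = np.asarray(r_samples, dtype=float)
    a = np.asarray(outputs, dtype=float)
    if r.shape != a.shape:
        raise ValueError("r_samples and outputs must have the same length")
    if np.any(r <= 0) or np.any(a <= 0):
        raise ValueError("inputs and outputs must be positive")
    lr, la = np.log2(r), np.log2(a)
    w = spec.bin_width

    def edges(x: np.ndarray) -> np.ndarray:
        lo = np.floor(x.min() / w) * w
        hi = np.ceil(x.max() / w) * w
        n = max(int(round((hi - lo) / w)), 1)
        return lo + w * np.arange(n + 1)

    joint, _, _ = np.histogram2d(lr, la, bins=(edges(lr), edges(la)))
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))
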