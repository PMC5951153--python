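"""Named end-to-end experiments tying the simulators and statistics together.

Each experiment takes a seed and optional parameter overrides, runs the
relevant modules, and returns a JSON-serializable summary holding every
headline statistic it produced.  ``run_experiment`` also writes the
summary (plus a manifest with the config hash and seed) when given an
output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import __version__
from .analog import MISpec, calibration_alpha, fidl_analytic, fidl_simulated, \
    mutual_information, saturating_output
from .binary import (BinaryModelSpec, TradeoffSpec, ahc_analytic, default_r_grid,
                     dose_response, fit_hill, tradeoff_curve)
from .expression import batch_cv, bootstrap_cv, correction_factors, \
    pairwise_correlations
from .mapk import MapkNoiseSpec, default_dose_grid, fit_mapk_hill, \
    load_default_config, mapk_dose_response, mapk_population, stratify_by_activity
from .pathway import NoiseSpec
from .synthetic import egg120_config, generate_egg_dataset

__all__ = ["ExperimentSpec", "run_experiment", "EXPERIMENTS"]


@dataclass
class ExperimentSpec:
    name: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)
    out_dir: Optional[Path] = None


def _fig1_fidl(seed: int, params: dict) -> dict:
    cvs = params.get("cvs", (0.05, 0.10, 0.25))
    n_cells = int(params.get("n_cells", 200_000))
    accuracy = float(params.get("accuracy", 0.95))
    rng = np.random.default_rng(seed)
    out = {"alpha": calibration_alpha(accuracy), "cv": list(cvs),
           "fidl_analytic": [], "fidl_simulated": []}
    for cv in cvs:
        spec = NoiseSpec(cv=cv, mode="independent")
        out["fidl_analytic"].append(fidl_analytic(cv, 10, accuracy))
        out["fidl_simulated"].append(
            fidl_simulated(spec, accuracy=accuracy, n_cells=n_cells, rng=rng)
        )
    return out


def _figev1_mi(seed: int, params: dict) -> dict:
    cv = float(params.get("cv", 0.10))
    n = int(params.get("n_samples", 10_000))
    log2_r_range = params.get("log2_r_range", (0.0, 6.0))
    rng = np.random.default_rng(seed)
    spec = NoiseSpec(cv=cv, mode="independent")
    from .pathway import draw_noise, _ODD, _EVEN  # noqa: internal reuse

    r = 2.0 ** rng.uniform(*log2_r_range, n)
    eps = draw_noise(spec, n, rng)
    gain = np.prod(eps[:, _ODD], axis=1) / np.prod(eps[:, _EVEN], axis=1)
    linear = r * gain
    # saturating variant: the y4 drive is capped before the last step
    drive = r * np.prod(eps[:, _ODD[:4]], axis=1) / np.prod(eps[:, _EVEN[:4]], axis=1)
    capped = saturating_output(drive) * eps[:, 8] / eps[:, 9]
    mi_spec = MISpec(n_samples=n)
    return {
        "cv": cv,
        "mi_linear_bits": mutual_information(r, linear, mi_spec),
        "mi_saturated_bits": mutual_information(r, capped, mi_spec),
        "fidl_analytic": fidl_analytic(cv, 10),
    }


def _fig5_hill(seed: int, params: dict) -> dict:
    cvs = params.get("cvs", (0.05, 0.10, 0.20, 0.40))
    n_cells = int(params.get("n_cells", 5000))
    rng = np.random.default_rng(seed)
    results = {"cv": list(cvs), "hill": [], "k_half": []}
    for cv in cvs:
        spec = BinaryModelSpec(noise=NoiseSpec(cv=cv), n_cells=n_cells)
        fit = fit_hill(dose_response(spec, rng))
        results["hill"].append(fit.h)
        results["k_half"].append(fit.k_half)
    return results


def _fig7_covariation(seed: int, params: dict) -> dict:
    cv = float(params.get("cv", 0.10))
    n_cells = int(params.get("n_cells", 5000))
    rng = np.random.default_rng(seed)
    out = {}
    for mode in ("independent", "sign_grouped"):
        spec = BinaryModelSpec(noise=NoiseSpec(cv=cv, mode=mode), n_cells=n_cells)
        out[mode] = fit_hill(dose_response(spec, rng)).h
    return {"cv": cv, "ahc": out, "covary_shallower": out["sign_grouped"] < out["independent"]}


def _fig8_tradeoff(seed: int, params: dict) -> dict:
    cvs = params.get("cvs", (0.05, 0.10, 0.25, 0.40))
    n = int(params.get("n_components", 10))
    pts = tradeoff_curve(cvs, n_components=n)
    prods = [p[0] * p[1] for p in pts]
    return {"cv": list(cvs), "log2_fidl": [p[0] for p in pts],
            "ahc": [p[1] for p in pts], "product": prods,
            "gamma": float(np.mean(prods))}


def _egg_pipeline(seed: int, params: dict) -> dict:
    rng = np.random.default_rng(seed)
    config = egg120_config(**params.get("generator", {}))
    table, truth = generate_egg_dataset(config, rng)
    factors, corrected = correction_factors(table)
    cvs = batch_cv(corrected)
    mek_erk = pairwise_correlations(corrected).query(
        "protein_a == 'MEK_like' and protein_b == 'ERK_like'"
    ).iloc[0]
    point, lo, hi = bootstrap_cv(
        corrected.values["MEK_like"].to_numpy(), n_boot=2000, rng=rng
    )
    return {
        "n_samples": len(table.values),
        "median_cv": float(cvs["cv"].median()),
        "mek_erk_r": float(mek_erk["r"]),
        "mek_erk_p_adjusted": float(mek_erk["p_adjusted"]),
        "mek_cv_ci": [point, lo, hi],
        "calibration_factor_range": [float(factors.min()), float(factors.max())],
    }


def _mapk_bimodal(seed: int, params: dict) -> dict:
    rng = np.random.default_rng(seed)
    config = load_default_config()
    dose = float(params.get("dose", 2.0 ** 10.9))
    n_cells = int(params.get("n_cells", 400))
    cells = mapk_population(dose, n_cells, MapkNoiseSpec(), rng, config)
    strata = stratify_by_activity(cells)
    grid = default_dose_grid(n=int(params.get("n_doses", 12)))
    n_dr = int(params.get("n_cells_per_dose", 150))
    curves = {}
    for covary in (False, True):
        dr = mapk_dose_response(grid, n_dr, MapkNoiseSpec(covary=covary), rng, config)
        curves["covary" if covary else "independent"] = fit_mapk_hill(dr).h
    return {
        "dose": dose,
        "fraction_active": float(np.mean([c.active for c in cells])),
        "strata": {
            k: v for k, v in strata.items() if k in ("active", "inactive")
        },
        "ahc": curves,
        "covary_shallower": curves["covary"] < curves["independent"],
    }


EXPERIMENTS: dict[str, Callable[[int, dict], dict]] = {
    "fig1_fidl": _fig1_fidl,
    "figEV1_mi": _figev1_mi,
    "fig5_hill": _fig5_hill,
    "fig7_covariation": _fig7_covariation,
    "fig8_tradeoff": _fig8_tradeoff,
    "egg_pipeline": _egg_pipeline,
    "mapk_bimodal": _mapk_bimodal,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run a registered experiment and return (and optionally write) its summary."""
    if spec.name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {spec.name!r}; choose from {sorted(EXPERIMENTS)}"
        )
    start = time.time()
    summary = EXPERIMENTS[spec.name](spec.seed, dict(spec.parameters))
    config_blob = json.dumps(
        {"name": spec.name, "seed": spec.seed, "parameters": spec.parameters},
        sort_keys=True, default=str,
    )
    manifest = {
        "experiment": spec.name,
        "seed": spec.seed,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "package_version": __version__,
        "runtime_s": round(time.time() - start, 3),
    }
    bundle = {"manifest": manifest, "summary": summary}
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{spec.name}.json").write_text(
            json.dumps(bundle, indent=2, default=_jsonify)
        )
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return str(obj)
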