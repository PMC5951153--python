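"""Synthetic data generators for the measurement-statistics pipeline.

Everything the statistics arm consumes can be generated here with fully
specified ground truth: single-egg relative-abundance tables (lognormal
biological variation with a planted correlation structure, cell-cycle
profiles for cyclin-like proteins, per-sample multiplicative calibration
error, per-measurement technical noise), per-cell imaging tables (mass
stain, 2N/4N DNA mixture, correlated target concentrations, an activation
model driven by pathway-protein levels) and FRET activity timecourses.

The default configurations mirror the study designs the pipeline is meant
for: 5 eggs x 5 timepoints; 2 timepoints x 6 batches x 10 eggs; a
30-replicate technical-variation design with biological variance collapsed;
and imaging fields of a few thousand cells.  Generators never aim at the
absolute abundances of any real protein panel — only the variance and
covariation structure is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import AbundanceTable

__all__ = [
    "EggGeneratorConfig",
    "CellGeneratorConfig",
    "FretKinetics",
    "generate_egg_dataset",
    "generate_cell_dataset",
    "generate_fret_trace",
    "egg25_config",
    "egg120_config",
    "tech30_config",
    "PRESETS",
]

_DEFAULT_N_PROTEINS = 26
_DEFAULT_CYCLING = ("CyclinA_like", "CyclinB_like", "Cdc6_like", "Emi1_like")


def _cycling_profile(t_minutes: np.ndarray) -> np.ndarray:
    """Qualitative cyclin-like trajectory: mid-cycle peak, late degradation."""
    knots_t = np.array([0.0, 20.0, 40.0, 60.0, 80.0])
    knots_v = np.array([0.7, 1.0, 1.4, 1.1, 0.5])
    return np.interp(t_minutes, knots_t, knots_v)


@dataclass
class EggGeneratorConfig:
    """Design and noise structure of a synthetic single-egg SRM dataset."""

    n_proteins: int = _DEFAULT_N_PROTEINS
    timepoints: tuple = (0, 20, 40, 60, 80)     # minutes after activation
    eggs_per_timepoint: int = 5
    batches_per_timepoint: int = 1              # eggs split into batches
    biological_cv: float | np.ndarray = 0.07
    calibration_cv: float = 0.05
    technical_cv: float = 0.02
    correlated_pairs: dict = field(
        default_factory=lambda: {("MEK_like", "ERK_like"): 0.7,
                                 ("MCM5_like", "MCM7_like"): 0.7}
    )
    cycling_proteins: tuple = _DEFAULT_CYCLING
    seed: Optional[int] = None

    def protein_names(self) -> list[str]:
        named = ["MEK_like", "ERK_like", "MCM5_like", "MCM7_like",
                 *self.cycling_proteins]
        fillers = [f"protein_{i:02d}" for i in range(self.n_proteins - len(named))]
        return named + fillers

    def correlation_matrix(self) -> np.ndarray:
        names = self.protein_names()
        c = np.eye(self.n_proteins)
        for (a, b), r in self.correlated_pairs.items():
            i, j = names.index(a), names.index(b)
            c[i, j] = c[j, i] = r
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("planted correlation matrix is not positive semidefinite")
        return c


def generate_egg_dataset(
    config: EggGeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[AbundanceTable, dict]:
    """Synthesize an abundance table and return it with its ground truth.

    value[s, p] = mean_p * profile_p(t_s) * exp(b[s, p]) * calib_s
                  * exp(tech[s, p])

    with ``b`` rows drawn from the planted correlated normal (per-protein
    log-sd equal to the biological CV), ``calib_s`` a per-sample lognormal
    calibration factor and ``tech`` independent technical noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = config.protein_names()
    n_p = config.n_proteins
    cv = np.broadcast_to(np.asarray(config.biological_cv, dtype=float), (n_p,))
    corr = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))

    rows, meta_rows = [], []
    truth_b = []
    calib_all = []
    means = np.exp(rng.uniform(np.log(0.2), np.log(5.0), n_p))  # arbitrary scales
    for t in config.timepoints:
        for batch in range(config.batches_per_timepoint):
            for _ in range(config.eggs_per_timepoint):
                profile = np.ones(n_p)
                for cyc in config.cycling_proteins:
                    profile[names.index(cyc)] = _cycling_profile(np.array([t]))[0]
                b = (chol @ rng.standard_normal(n_p)) * cv
                calib = float(np.exp(rng.standard_normal() * config.calibration_cv))
                tech = rng.standard_normal(n_p) * config.technical_cv
                rows.append(means * profile * np.exp(b) * calib * np.exp(tech))
                meta_rows.append({"timepoint": t,
                                  "batch": f"t{t}_b{batch}"})
                truth_b.append(b)
                calib_all.append(calib)

    values = pd.DataFrame(rows, columns=names)
    sample_meta = pd.DataFrame(meta_rows, index=values.index)
    protein_meta = pd.DataFrame(
        {
            "is_reference": [n not in config.cycling_proteins for n in names],
            "is_cell_cycle_regulated": [n in config.cycling_proteins for n in names],
        },
        index=names,
    )
    table = AbundanceTable(values=values, sample_meta=sample_meta,
                           protein_meta=protein_meta)
    truth = {
        "means": dict(zip(names, means)),
        "biological_cv": dict(zip(names, cv)),
        "calibration_factors": np.array(calib_all),
        "latent_log_deviations": np.array(truth_b),
        "correlation": corr,
        "protein_names": names,
    }
    return table, truth


def egg25_config(seed: Optional[int] = None, **kw) -> EggGeneratorConfig:
    """5 eggs at each of 5 timepoints (25 samples)."""
    return EggGeneratorConfig(seed=seed, **kw)


def egg120_config(seed: Optional[int] = None, **kw) -> EggGeneratorConfig:
    """60 eggs at each of 2 timepoints, in 6 batches of 10."""
    kw.setdefault("timepoints", (60, 80))
    kw.setdefault("eggs_per_timepoint", 10)
    kw.setdefault("batches_per_timepoint", 6)
    return EggGeneratorConfig(seed=seed, **kw)


def tech30_config(seed: Optional[int] = None, **kw) -> EggGeneratorConfig:
    """Technical-replicate design: biological variance collapsed (mixed
    lysate split into 30 aliquots), so only calibration + technical noise
    remain."""
    kw.setdefault("timepoints", (60,))
    kw.setdefault("eggs_per_timepoint", 30)
    kw.setdefault("biological_cv", 0.0)
    kw.setdefault("calibration_cv", 0.03)
    kw.setdefault("technical_cv", 0.04)
    return EggGeneratorConfig(seed=seed, **kw)


@dataclass
class FretKinetics:
    baseline: float = 1.0
    plateau_active: float = 0.8      # added on top of baseline for responders
    plateau_inactive: float = 0.05
    rise_time: float = 6.0           # minutes
    noise_sd: float = 0.02
    sample_interval: float = 2.0     # minutes between frames
    duration: float = 60.0
    stim_time: float = 10.0


def generate_fret_trace(
    responder: bool,
    kinetics: FretKinetics | None = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One FRET/CFP ratio timecourse sampled every ``sample_interval`` min.

    Responders rise saturatingly to baseline+plateau after the stimulus;
    non-responders stay at baseline (with a small residual plateau).
    """
    k = kinetics or FretKinetics()
    if rng is None:
        rng = np.random.default_rng()
    t = np.arange(0.0, k.duration + 1e-9, k.sample_interval)
    plateau = k.plateau_active if responder else k.plateau_inactive
    rise = np.where(
        t >= k.stim_time,
        plateau * (1.0 - np.exp(-(t - k.stim_time) / k.rise_time)),
        0.0,
    )
    trace = k.baseline + rise + rng.standard_normal(len(t)) * k.noise_sd
    return t, trace


@dataclass
class CellGeneratorConfig:
    """Synthetic imaging field: cells x (antibody, mass, DNA, position)."""

    n_cells: int = 3000
    mass_cv: float = 0.25
    dna_modes: tuple = (2.0, 4.0)
    dna_weights: tuple = (0.6, 0.4)
    dna_cv: float = 0.05
    target_means: dict = field(
        default_factory=lambda: {"MEK": 1.0, "ERK": 1.0, "GAPDH": 1.0}
    )
    target_cvs: dict = field(
        default_factory=lambda: {"MEK": 0.12, "ERK": 0.12, "GAPDH": 0.10}
    )
    target_correlations: dict = field(
        default_factory=lambda: {("MEK", "ERK"): 0.7}
    )
    measurement_cv: float = 0.03
    activation_gain: float = 6.0     # logistic slope on ln(MEK*ERK)
    activation_bias: float = 0.0     # ln-units offset of the switch point
    field_size: float = 1080.0
    fret: FretKinetics = field(default_factory=FretKinetics)
    seed: Optional[int] = None

    def correlation_matrix(self) -> np.ndarray:
        names = list(self.target_means)
        c = np.eye(len(names))
        for (a, b), r in self.target_correlations.items():
            i, j = names.index(a), names.index(b)
            c[i, j] = c[j, i] = r
        return c


def generate_cell_dataset(
    config: CellGeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, list, dict]:
    """Synthesize a per-cell table, FRET traces and the ground truth.

    Antibody intensity = mass * concentration * measurement noise, so
    dividing by the mass stain recovers concentration up to technical
    noise.  The probability that a cell responds to stimulation is a
    logistic function of ln(MEK*ERK concentration product), making
    responders enriched for high pathway-protein levels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    names = list(config.target_means)
    cvs = np.array([config.target_cvs[t] for t in names])
    try:
        chol = np.linalg.cholesky(config.correlation_matrix())
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(config.correlation_matrix())
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    conc = np.array([config.target_means[t] for t in names]) * np.exp(z * cvs)

    mass = np.exp(rng.standard_normal(n) * config.mass_cv)
    mode_idx = rng.choice(len(config.dna_modes), size=n, p=config.dna_weights)
    dna = np.array(config.dna_modes)[mode_idx] * np.exp(
        rng.standard_normal(n) * config.dna_cv
    )
    pos = rng.uniform(0, config.field_size, size=(n, 2))

    ln_drive = np.zeros(n)
    for t in ("MEK", "ERK"):
        if t in names:
            ln_drive += np.log(conc[:, names.index(t)])
    p_active = 1.0 / (1.0 + np.exp(-config.activation_gain * (ln_drive - config.activation_bias)))
    responder = rng.random(n) < p_active

    table = pd.DataFrame({"mass_stain": mass, "dna": dna,
                          "x": pos[:, 0], "y": pos[:, 1]})
    noise = np.exp(rng.standard_normal((n, len(names))) * config.measurement_cv)
    for j, t in enumerate(names):
        table[t] = mass * conc[:, j] * noise[:, j]

    traces = [generate_fret_trace(bool(r), config.fret, rng) for r in responder]
    truth = {
        "concentrations": pd.DataFrame(conc, columns=names),
        "responder": responder,
        "is_2n": mode_idx == 0,
        "p_active": p_active,
        "mass": mass,
    }
    return table, traces, truth


PRESETS = {
    "egg25": egg25_config,
    "egg120": egg120_config,
    "tech30": tech30_config,
    "ifcells": lambda seed=None: CellGeneratorConfig(seed=seed),
    "fret": lambda seed=None: CellGeneratorConfig(seed=seed, n_cells=800),
}
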