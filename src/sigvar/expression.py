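"""Single-cell measurement statistics: variation and covariation estimation.

Two experimental arms share this module:

* targeted proteomics of single cells (light/heavy peptide ratios as
  relative abundances): per-sample correction factors from a reference
  peptide set, per-batch CVs with bootstrap confidence intervals, pairwise
  Pearson covariation with Benjamini-Hochberg adjustment, and a
  technical-vs-biological variation comparison;

* per-cell imaging (antibody intensities, a total-protein mass stain, a
  DNA stain, FRET activity timecourses): G0/G1 gating on the 2N DNA mode,
  mass-stain normalization to relative concentration, integrated activity
  (area under the FRET curve after stimulation) with bimodal threshold
  classification, and a top-vs-bottom activity-extremes comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "correction_factors",
    "batch_cv",
    "bootstrap_cv",
    "pairwise_correlations",
    "technical_vs_biological",
    "gate_g1",
    "normalize_by_mass",
    "integrated_activity",
    "bimodal_threshold",
    "classify_by_threshold",
    "compare_extremes",
]


@dataclass
class AbundanceTable:
    """Samples x proteins relative-abundance matrix with annotations.

    ``values`` rows are samples (e.g. single eggs), columns proteins.
    ``sample_meta`` carries batch/timepoint labels indexed like the rows;
    ``protein_meta`` carries ``is_reference`` (member of the correction
    set) and ``is_cell_cycle_regulated`` flags indexed like the columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    protein_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("relative abundances must be positive")
        if self.protein_meta.empty:
            self.protein_meta = pd.DataFrame(
                {"is_reference": True, "is_cell_cycle_regulated": False},
                index=self.values.columns,
            )

    @property
    def reference_proteins(self) -> pd.Index:
        return self.protein_meta.index[self.protein_meta["is_reference"]]


def correction_factors(
    table: AbundanceTable, tol: float = 1e-13, max_iter: int = 500
) -> tuple[pd.Series, AbundanceTable]:
    """Per-sample calibration factors from the reference-peptide medians.

    Each reference peptide is normalized by its median across samples; a
    sample's factor is the median of its normalized reference values
    (typically 0.9-1.1 for real calibration error), and all abundances of
    the sample are divided by it.  Because dividing shifts the column
    medians slightly, a single pass leaves residual factors of up to a few
    percent; the pass is therefore iterated to its fixed point (where all
    factors are 1 to within ``tol``), making the correction idempotent.
    The returned factors are the per-sample products over iterations and
    differ from the familiar single-pass values only in the third decimal.
    """
    if len(table.values) < 2:
        raise ValueError("need at least 2 samples to derive correction factors")
    ref = table.reference_proteins
    if len(ref) == 0:
        raise ValueError("reference protein set is empty")
    corrected = table.values.copy()
    total = pd.Series(1.0, index=corrected.index)
    for _ in range(max_iter):
        ref_vals = corrected[ref]
        normalized = ref_vals / ref_vals.median(axis=0)
        factors = normalized.median(axis=1)
        total *= factors
        corrected = corrected.div(factors, axis=0)
        if (factors - 1.0).abs().max() < tol:
            break
    return total, AbundanceTable(
        values=corrected,
        sample_meta=table.sample_meta.copy(),
        protein_meta=table.protein_meta.copy(),
    )


def _cv(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.mean(x))


def batch_cv(
    table: AbundanceTable, grouping: Optional[Sequence] = None
) -> pd.DataFrame:
    """Per-protein, per-group coefficient of variation (sd/mean, ddof=1).

    ``grouping`` defaults to the ``batch`` column of ``sample_meta`` (one
    group of all samples if absent).  Groups with fewer than 2 samples are
    excluded.
    """
    if grouping is None:
        if "batch" in table.sample_meta.columns:
            grouping = table.sample_meta["batch"]
        else:
            grouping = pd.Series("all", index=table.values.index)
    grouping = pd.Series(np.asarray(grouping), index=table.values.index)
    rows = []
    for batch, idx in table.values.groupby(grouping).groups.items():
        sub = table.values.loc[idx]
        if len(sub) < 2:
            continue
        for protein in sub.columns:
            rows.append({
                "protein": protein, "batch": batch, "n": len(sub),
                "cv": _cv(sub[protein].to_numpy()),
            })
    return pd.DataFrame(rows)


def bootstrap_cv(
    column: np.ndarray,
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float, float]:
    """Point CV and percentile bootstrap CI from resampling with replacement."""
    x = np.asarray(column, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations to bootstrap a CV")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    samples = x[idx]
    cvs = samples.std(axis=1, ddof=1) / samples.mean(axis=1)
    lo, hi = np.percentile(cvs, ci)
    return _cv(x), float(lo), float(hi)


def pairwise_correlations(table: AbundanceTable, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlations with Benjamini-Hochberg adjustment.

    Two-sided p-values from the t-distribution with n-2 degrees of
    freedom; BH step-up over the P(P-1)/2 unique unordered pairs.
    Zero-variance columns yield undefined pairs, which are reported with
    NaN and excluded from the multiplicity count.
    """
    vals = table.values
    if len(vals) < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    proteins = list(vals.columns)
    rows = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            x, y = vals[a].to_numpy(), vals[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"protein_a": a, "protein_b": b,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"protein_a": a, "protein_b": b, "r": r, "p": p})
    report = pd.DataFrame(rows)
    defined = report["p"].notna()
    adj = np.full(len(report), np.nan)
    if defined.any():
        adj[defined] = multipletests(report.loc[defined, "p"], method="fdr_bh")[1]
    report["p_adjusted"] = adj
    report["significant"] = report["p_adjusted"] < alpha
    return report


def technical_vs_biological(
    tech_cvs: pd.DataFrame, bio_cvs: pd.DataFrame
) -> pd.DataFrame:
    """Pair technical and biological CVs per protein and flag floor-limited ones.

    Expects frames with ``protein``, ``cv`` and optional ``ci_low``/
    ``ci_high`` columns (one row per protein).  A protein is flagged when
    its biological CI overlaps the technical CI — its biological variation
    is indistinguishable from the measurement floor.
    """
    t = tech_cvs.set_index("protein")
    b = bio_cvs.set_index("protein")
    if set(t.index) != set(b.index):
        raise ValueError("technical and biological reports cover different proteins")
    b = b.loc[t.index]
    out = pd.DataFrame({
        "protein": t.index,
        "technical_cv": t["cv"].to_numpy(),
        "biological_cv": b["cv"].to_numpy(),
    })
    out["ratio"] = out["biological_cv"] / out["technical_cv"]
    if {"ci_low", "ci_high"} <= set(t.columns) and {"ci_low", "ci_high"} <= set(b.columns):
        out["floor_limited"] = (
            (b["ci_low"].to_numpy() <= t["ci_high"].to_numpy())
            & (t["ci_low"].to_numpy() <= b["ci_high"].to_numpy())
        )
    else:
        out["floor_limited"] = out["ratio"] <= 1.0
    return out


def gate_g1(
    cells: pd.DataFrame,
    width: float = 0.25,
    center: Optional[tuple[float, float]] = None,
    max_radius: Optional[float] = 350.0,
) -> pd.DataFrame:
    """Keep cells in the 2N (G0/G1) DNA mode and inside the central region.

    The 2N mode is the lowest substantial peak of a Gaussian KDE of the
    integrated DNA stain; the gate is mode * [1-width, 1+width].  Cells
    farther than ``max_radius`` from ``center`` (default: mean position)
    are dropped regardless of DNA content.
    """
    if "dna" not in cells.columns:
        raise ValueError("cell table lacks a 'dna' column")
    dna = cells["dna"].to_numpy(dtype=float)
    if dna.std() == 0:
        mode = float(dna[0])
    else:
        kde = stats.gaussian_kde(dna)
        grid = np.linspace(dna.min(), dna.max(), 512)
        dens = kde(grid)
        peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(dens))])
        # lowest-DNA peak that carries at least 10% of the max density
        substantial = peaks[dens[peaks] >= 0.10 * dens.max()]
        if len(substantial) == 0:
            raise ValueError("no discernible 2N peak in the DNA histogram")
        mode = float(grid[substantial[0]])
    keep = (dna >= mode * (1 - width)) & (dna <= mode * (1 + width))
    if max_radius is not None and {"x", "y"} <= set(cells.columns):
        cx, cy = center if center is not None else (cells["x"].mean(), cells["y"].mean())
        r = np.hypot(cells["x"] - cx, cells["y"] - cy)
        keep &= (r <= max_radius).to_numpy()
    return cells.loc[keep].copy()


def normalize_by_mass(cells: pd.DataFrame, target: str) -> pd.Series:
    """Relative concentration: antibody intensity over the total-mass stain."""
    if (cells["mass_stain"] <= 0).any():
        raise ValueError("mass_stain must be positive")
    return cells[target] / cells["mass_stain"]


def integrated_activity(
    t: np.ndarray, trace: np.ndarray, stim_time: float
) -> float:
    """Area under the activity ratio curve from the stimulus to trace end."""
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if t.shape != trace.shape:
        raise ValueError("time and trace must have equal length")
    if stim_time >= t[-1]:
        raise ValueError("trace does not extend past the stimulation time")
    mask = t >= stim_time
    tt, yy = t[mask], trace[mask]
    if not mask[0] and t[mask][0] > stim_time:
        # interpolate the value exactly at the stimulus time
        y0 = float(np.interp(stim_time, t, trace))
        tt = np.concatenate(([stim_time], tt))
        yy = np.concatenate(([y0], yy))
    return float(np.trapezoid(yy, tt))


def bimodal_threshold(values: np.ndarray) -> float:
    """Threshold at the density minimum between the two largest modes.

    Gaussian KDE with Silverman bandwidth; raises if the smoothed
    distribution is unimodal.
    """
    x = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
    if len(peaks) < 2:
        raise ValueError("activity distribution is unimodal; no threshold to place")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(grid[top2])
    between = (grid > lo) & (grid < hi)
    return float(grid[between][np.argmin(dens[between])])


def classify_by_threshold(values: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
    """Boolean active flags; threshold placed automatically if not given."""
    x = np.asarray(values, dtype=float)
    if threshold is None:
        threshold = bimodal_threshold(x)
    return x > threshold


def compare_extremes(
    activity: np.ndarray,
    concentration: np.ndarray,
    fraction: float = 0.15,
) -> dict:
    """Compare a concentration between top- and bottom-activity cells.

    Takes the top and bottom ``fraction`` of cells ranked by activity and
    reports medians, quartiles, notch half-widths 1.58*IQR/sqrt(n) (an
    approximate 95% CI of the median) and a two-sided Wilcoxon rank-sum
    p-value for the concentration difference.
    """
    act = np.asarray(activity, dtype=float)
    conc = np.asarray(concentration, dtype=float)
    if act.shape != conc.shape:
        raise ValueError("activity and concentration must align")
    n_group = int(np.floor(len(act) * fraction))
    if n_group < 1 or len(act) < 2 * n_group:
        raise ValueError("too few cells for the requested extreme fraction")
    order = np.argsort(act, kind="stable")
    bottom, top = conc[order[:n_group]], conc[order[-n_group:]]

    def summary(x: np.ndarray) -> dict:
        q1, med, q3 = np.quantile(x, (0.25, 0.5, 0.75))
        return {
            "n": len(x), "median": float(med), "q1": float(q1), "q3": float(q3),
            "notch": float(1.58 * (q3 - q1) / np.sqrt(len(x))),
        }

    stat, p = stats.mannwhitneyu(top, bottom, alternative="two-sided")
    return {"top": summary(top), "bottom": summary(bottom),
            "rank_sum_p": float(p), "statistic": float(stat)}
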