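"""Figure rendering for the analytics outputs (SVG/PNG via matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparative import AgeComparison, RREstimate
from .refmodel import ConsultReport, predict_centiles
from .survival import SurvivalCurve
from .tables import ResultTable


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_frequency(table: ResultTable, path: str | Path) -> Path:
    """Horizontal bar chart of a frequency table (top item first)."""
    rendered = table.rendered()
    labels = rendered["label"].tolist()
    pcts = [float(p) if not p.startswith("<") else 0.0 for p in rendered["percent"]]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(labels), 4) + 1))
    y = np.arange(len(labels))[::-1]
    ax.barh(y, pcts, color="#47a")
    ax.set_yticks(y, labels)
    ax.set_xlabel("% of cohort members with >= 1 event")
    ax.set_xlim(0, 100)
    ax.set_title(table.title)
    return _save(fig, path)


def plot_rr_forest(estimates: list[RREstimate], path: str | Path) -> Path:
    """Forest-style plot of a relative-risk scan (log scale)."""
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(len(estimates), 4) + 1))
    y = np.arange(len(estimates))[::-1]
    for yi, e in zip(y, estimates):
        ax.plot([e.ci_low, e.ci_high], [yi, yi], color="#555")
        ax.plot(e.rr, yi, "s", color="#a33")
    ax.axvline(1.0, color="#999", ls="--")
    ax.set_yticks(y, [f"{e.code} {e.display[:40]}" for e in estimates])
    ax.set_xscale("log")
    ax.set_xlabel("relative risk (log scale)")
    return _save(fig, path)


def plot_age_densities(cmp: AgeComparison, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, dens in cmp.densities.items():
        ax.plot(cmp.density_grid, dens, label=name)
    ax.set_xlabel("age at cohort entry (years)")
    ax.set_ylabel("density")
    ax.legend()
    if cmp.kw is not None:
        ax.set_title(f"Age at entry (Kruskal-Wallis p = {cmp.kw.p:.3g})")
    return _save(fig, path)


def plot_survival(curve: SurvivalCurve, path: str | Path, as_incidence: bool = True) -> Path:
    """Step plot of the product-limit curve (or 1-S cumulative incidence)."""
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.survival])
    y = 1.0 - s if as_incidence else s
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.step(t, y, where="post", color="#47a")
    ax.set_xlabel("days since index")
    ax.set_ylabel("cumulative incidence" if as_incidence else "S(t)")
    ax.set_ylim(0, 1.02)
    return _save(fig, path)


def plot_consult(report: ConsultReport, path: str | Path,
                 centiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> Path:
    """Two-panel consult figure: raw values + fitted curves above, the
    patient's z-scores against the reference model below."""
    lo, hi = report.reference.t_domain
    grid = np.linspace(lo, hi, 200)
    curves = predict_centiles(report.reference, grid, centiles)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 8), sharex=True,
                                   height_ratios=[2, 1])
    for cohort, sub in report.overlay.groupby("cohort"):
        is_patient = len(sub["patient_id"].unique()) == 1
        ax1.plot(sub["time"], sub["value"], "o",
                 ms=5 if is_patient else 2.5,
                 alpha=1.0 if is_patient else 0.25,
                 label=cohort, zorder=3 if is_patient else 1)
    for c in centiles:
        ax1.plot(grid, curves[f"c{c:g}"], color="#a33",
                 lw=1.8 if c == 0.5 else 0.8,
                 alpha=0.9 if c == 0.5 else 0.6)
    if report.patient_model is not None:
        plo, phi = report.patient_model.t_domain
        pgrid = np.linspace(plo, phi, 100)
        ax1.plot(pgrid, report.patient_model.quantile(0.5, pgrid),
                 color="#36a", lw=1.5, label="patient fit (median)")
    ax1.set_ylabel(report.observation_code)
    ax1.legend(fontsize=8)
    ax2.axhline(0.0, color="#999", ls="--")
    for level in (-1.96, 1.96):
        ax2.axhline(level, color="#c99", ls=":")
    ax2.plot(report.patient_scores["time"], report.patient_scores["z"], "o-",
             color="#36a", ms=4)
    ax2.set_xlabel("days since index")
    ax2.set_ylabel("z-score vs reference")
    return _save(fig, path)


__all__ = [
    "plot_frequency",
    "plot_rr_forest",
    "plot_age_densities",
    "plot_survival",
    "plot_consult",
]
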