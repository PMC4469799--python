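"""Diagnostic plots: the association scatter plot and the funnel plot.

Both plots draw their coordinates and reference lines directly from values
computed by :mod:`mregger.estimators`; nothing is re-estimated here.

The funnel plot follows the Mendelian-randomization convention of putting the
per-variant ratio estimate on the horizontal axis and instrument strength
(optionally allele-frequency corrected) on the vertical axis — note classic
meta-analysis funnels put precision on the vertical axis as well, but plot
the study estimate, not an instrument, horizontally.  Asymmetry of weak
variants about the pooled estimate indicates directional pleiotropy, the
analogue of small-study bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .data import MRDataset
from .estimators import MREstimate, maf_corrected_strength, ratio_estimates

__all__ = ["PlotSpec", "scatter_plot", "funnel_plot"]

IVW_COLOR = "red"
EGGER_COLOR = "blue"
TRUTH_COLOR = "black"


@dataclass(frozen=True)
class PlotSpec:
    """Options shared by the two plot kinds."""

    kind: str = "scatter"  # "scatter" or "funnel"
    show_ivw: bool = True
    show_egger: bool = True
    true_slope: float | None = None
    maf_correction: bool = False
    output_path: str | Path | None = None
    ivw_color: str = IVW_COLOR
    egger_color: str = EGGER_COLOR

    def __post_init__(self) -> None:
        if self.kind not in ("scatter", "funnel"):
            raise ValueError("plot kind must be 'scatter' or 'funnel'")


def _save(fig, spec: PlotSpec):
    if spec.output_path is not None:
        fig.savefig(spec.output_path, dpi=150, bbox_inches="tight")
    return fig


def scatter_plot(
    dataset: MRDataset,
    estimates: Mapping[str, MREstimate],
    spec: PlotSpec = PlotSpec(kind="scatter"),
):
    """Scatter of outcome associations against exposure associations.

    The IVW fit is drawn as a red line through the origin, the MR-Egger fit
    as a blue line with its intercept, and the true slope (if given) dotted.
    ``estimates`` maps "IVW"/"MR-Egger" to fitted :class:`MREstimate` objects;
    line slopes are taken from these, never re-fitted.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if spec.show_egger and "MR-Egger" in estimates and not dataset.oriented:
        raise ValueError("orient the dataset before plotting an MR-Egger line")
    x = dataset.beta_exposure
    y = dataset.beta_outcome
    fig, ax = plt.subplots()
    ax.errorbar(
        x,
        y,
        xerr=dataset.se_exposure,
        yerr=dataset.se_outcome,
        fmt="o",
        color="0.3",
        ecolor="0.7",
        ms=4,
        lw=1,
        label="variants",
    )
    grid = [0.0, float(max(x.max(), 0.0)) * 1.05] if x.max() > 0 else [x.min(), 0.0]
    if spec.true_slope is not None:
        ax.plot(
            grid,
            [spec.true_slope * g for g in grid],
            ls=":",
            color=TRUTH_COLOR,
            label="true slope",
        )
    if spec.show_ivw and "IVW" in estimates:
        b = estimates["IVW"].slope
        ax.plot(grid, [b * g for g in grid], color=spec.ivw_color, label="IVW")
    if spec.show_egger and "MR-Egger" in estimates:
        est = estimates["MR-Egger"]
        b0 = est.intercept or 0.0
        ax.plot(
            grid,
            [b0 + est.slope * g for g in grid],
            color=spec.egger_color,
            label="MR-Egger",
        )
    ax.axhline(0.0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(0.0, color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel("association with exposure (per allele)")
    ax.set_ylabel("association with outcome (per allele)")
    ax.legend(frameon=False)
    return _save(fig, spec)


def funnel_plot(
    dataset: MRDataset,
    estimates: Mapping[str, MREstimate],
    spec: PlotSpec = PlotSpec(kind="funnel"),
):
    """Funnel plot of instrument strength against per-variant causal estimates.

    Horizontal axis: ratio estimates; vertical axis: gene-exposure
    association, allele-frequency corrected when ``spec.maf_correction`` is
    set (requires ``eaf``).  Vertical reference lines mark the IVW (red) and
    MR-Egger (blue) slope estimates.
    """
    ratios = ratio_estimates(dataset)  # raises on zero beta_exposure
    b = [r.estimate for r in ratios]
    if spec.maf_correction:
        strength = maf_corrected_strength(dataset)
        ylabel = "MAF-corrected association with exposure"
    else:
        strength = dataset.beta_exposure
        ylabel = "association with exposure (per allele)"
    fig, ax = plt.subplots()
    ax.plot(b, strength, "o", color="0.3", ms=4, label="variants")
    if spec.show_ivw and "IVW" in estimates:
        ax.axvline(estimates["IVW"].slope, color=spec.ivw_color, label="IVW")
    if spec.show_egger and "MR-Egger" in estimates:
        ax.axvline(
            estimates["MR-Egger"].slope, color=spec.egger_color, label="MR-Egger"
        )
    if spec.true_slope is not None:
        ax.axvline(spec.true_slope, ls=":", color=TRUTH_COLOR, label="true slope")
    ax.set_xlabel("per-variant causal estimate (ratio)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return _save(fig, spec)
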