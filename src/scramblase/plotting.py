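"""Publication-grade figures: aligned spectral traces and PPR plots.

Two figure types cover the visual analysis of a scramblase assay data
set: the raw traces (one panel per experimental series, aligned to the
dithionite-addition time, colored by adjusted PPR) and the PPR plot at
the heart of the analysis — occupancy probability P>=1 against adjusted
PPR with the fitted saturation curve per group.

Axis trimming options remove points from *display* only; fits always use
the full data. The curves drawn are evaluated through the very model
functions the fits report, so figure and statistics cannot drift apart.
Output format (PNG/PDF/SVG) follows the output file extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import cm, colors

from .detection import align_traces, detect_addition_time, manual_addition_call
from .errors import DetectionError, ValidationError
from .io import AssayRecord, read_spectrum
from .models import FitResult, SizeDistribution, analyze_records, model_gen1, model_gen2
from .reduction import DEFAULT_PPR_SCALE_FACTOR, compute_ppr

__all__ = ["PlotOptions", "plot_traces", "plot_ppr"]


@dataclass
class PlotOptions:
    """Display options shared by the trace and PPR plots."""

    adjust: bool = True  # align traces to the addition time
    time_min_sec: float | None = None
    time_max_sec: float | None = None
    ppr_axis_max: float | None = None
    split_by_experiment: bool = False
    output_path: str | Path | None = None

    def __post_init__(self) -> None:
        if (
            self.time_min_sec is not None
            and self.time_max_sec is not None
            and not self.time_min_sec < self.time_max_sec
        ):
            raise ValidationError(
                f"time_min_sec ({self.time_min_sec}) must be < "
                f"time_max_sec ({self.time_max_sec})"
            )


def _panel_grid(n: int) -> tuple[int, int]:
    ncols = min(n, 2)
    return math.ceil(n / ncols), ncols


def _save(fig, output_path) -> None:
    if output_path is not None:
        fig.savefig(output_path, dpi=300, bbox_inches="tight")


def plot_traces(
    records: list[AssayRecord],
    options: PlotOptions | None = None,
    ppr_scale_factor: float | None = DEFAULT_PPR_SCALE_FACTOR,
):
    """Plot all spectra, one panel per series, colored by adjusted PPR.

    Returns the matplotlib figure; writes ``options.output_path`` when
    given. Detection failures are collected and reported together with
    the offending file paths.
    """
    if not records:
        raise ValidationError("no assay records to plot")
    options = options or PlotOptions()

    loaded = []
    failures = []
    for rec in records:
        trace = read_spectrum(rec.spectrum_path)
        try:
            if rec.addition_time_s is not None:
                call = manual_addition_call(trace, rec.addition_time_s)
            else:
                call = detect_addition_time(trace)
        except DetectionError as err:
            failures.append(str(err))
            continue
        loaded.append((rec, trace, call))
    if failures:
        raise DetectionError(
            "addition detection failed for:\n" + "\n".join(failures)
        )

    aligned = align_traces([(t, c) for _, t, c in loaded], adjust=options.adjust)
    series_labels = sorted({rec.series for rec, _, _ in loaded})
    pprs = [
        compute_ppr(rec.protein_mg, rec.lipid_mmol, ppr_scale_factor)
        for rec, _, _ in loaded
    ]
    norm = colors.Normalize(vmin=min(pprs), vmax=max(pprs) or 1.0)
    cmap = cm.viridis

    nrows, ncols = _panel_grid(len(series_labels))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5.0 * ncols, 3.2 * nrows), squeeze=False, sharex=True
    )
    axmap = {s: axes.flat[i] for i, s in enumerate(series_labels)}
    for ax in axes.flat[len(series_labels) :]:
        ax.set_visible(False)
    for (rec, _, _), trace, ppr in zip(loaded, aligned, pprs):
        t, f = trace.time_s, trace.intensity
        mask = np.ones(t.size, dtype=bool)
        if options.time_min_sec is not None:
            mask &= t >= options.time_min_sec
        if options.time_max_sec is not None:
            mask &= t <= options.time_max_sec
        axmap[rec.series].plot(t[mask], f[mask], color=cmap(norm(ppr)), lw=1.0)
    for s, ax in axmap.items():
        ax.set_title(s or "(unlabeled series)")
        ax.set_xlabel("time after dithionite addition (s)" if options.adjust else "acquisition time (s)")
        ax.set_ylabel("fluorescence (a.u.)")
    label = "adj. PPR (mg/mmol)" if ppr_scale_factor is not None else "PPR (mg/mmol)"
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=axes, label=label)
    _save(fig, options.output_path)
    return fig


def _curve(fit: FitResult, grid: np.ndarray) -> np.ndarray:
    if fit.generation == 1:
        return model_gen1(
            grid, fit.alpha, fit.b, fit.c, fit.force_through_origin
        )
    return model_gen2(
        grid,
        fit.alpha,
        fit.size_dist or SizeDistribution(),
        fit.b,
        fit.c,
        fit.force_through_origin,
    )


def plot_ppr(
    records: list[AssayRecord],
    options: PlotOptions | None = None,
    **fit_options,
):
    """The PPR plot: P>=1 vs adjusted PPR with fitted saturation curves.

    One panel per series; with ``split_by_experiment`` each experiment
    gets its own fit and color within the panel, otherwise all
    experiments pool into a single fit. ``fit_options`` are forwarded to
    :func:`scramblase.models.analyze_records`. Returns ``(figure, fits)``.
    """
    options = options or PlotOptions()
    fit_options.setdefault("split_by_experiment", options.split_by_experiment)
    scale_factor = fit_options.get("ppr_scale_factor", DEFAULT_PPR_SCALE_FACTOR)
    points, fits = analyze_records(records, **fit_options)

    fitted_series = sorted({f.series for f in fits})
    nrows, ncols = _panel_grid(len(fitted_series))
    fig, axes = plt.subplots(
        nrows,
        ncols,
        figsize=(4.2 * ncols, 3.4 * nrows),
        squeeze=False,
        sharex=True,
        sharey=True,
    )
    axmap = {s: axes.flat[i] for i, s in enumerate(fitted_series)}
    for ax in axes.flat[len(fitted_series) :]:
        ax.set_visible(False)

    palette = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    experiments = sorted({p.record.experiment for p in points})
    color_of = {e: palette[i % len(palette)] for i, e in enumerate(experiments)}

    xmax_data = max(p.ppr_adj for p in points)
    xmax = options.ppr_axis_max if options.ppr_axis_max is not None else xmax_data
    grid = np.linspace(0.0, xmax, 200)

    for fit in fits:
        ax = axmap[fit.series]
        group = [
            p
            for p in points
            if p.record.series == fit.series
            and (fit.experiment is None or p.record.experiment == fit.experiment)
            and not math.isnan(p.p_ge1)
        ]
        color = color_of[fit.experiment] if fit.experiment is not None else palette[0]
        xs = np.array([p.ppr_adj for p in group])
        ys = np.array([p.p_ge1 for p in group])
        shown = xs <= xmax
        ax.scatter(xs[shown], ys[shown], s=18, color=color,
                   label=fit.experiment, zorder=3)
        ax.plot(grid, _curve(fit, grid), color=color, lw=1.2)
    for s, ax in axmap.items():
        ax.set_title(s or "(unlabeled series)")
        ax.set_xlabel(
            "adj. PPR (mg/mmol)" if scale_factor is not None else "PPR (mg/mmol)"
        )
        ax.set_ylabel(r"$P_{\geq 1}$")
        ax.set_xlim(0.0 if options.ppr_axis_max is None else None, xmax)
        if any(f.experiment is not None for f in fits):
            ax.legend(fontsize=7, title="experiment", title_fontsize=7)
    fig.tight_layout()
    _save(fig, options.output_path)
    return fig, fits
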