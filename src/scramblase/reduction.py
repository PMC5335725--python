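"""Per-measurement fluorescence statistics of the dithionite assay.

For each spectrum the pre-addition baseline ``F_baseline`` and the
post-reduction level ``F_min`` are ten-point medians; ``F_min`` is
volume-corrected for the dilution caused by the dithionite aliquot, and
the fractional fluorescence reduction is

    y_raw = 1 - F_min / F_baseline .

Protein-free liposomes with a symmetric transbilayer label distribution
give y_raw ~= 0.5 (only the outer-leaflet fluorophores are reduced);
scramblase-containing vesicles approach complete reduction. Scaling y
between the protein-free control ``y0`` and the saturation plateau
``y_max`` yields the per-liposome occupancy probability

    P>=1 = (y - y0) / (y_max - y0) ,

the probability that a vesicle carries at least one scramblase. Values
outside [0, 1] arise from noise and are flagged, never clipped: silent
clipping would bias the downstream saturation fits.

The protein-to-phospholipid ratio is reported as adjusted PPR,
``protein_mg / (lipid_mmol * ppr_scale_factor)`` with the default scale
factor 0.65: only about 65% of the vesicle pool is competent for
scramblase reconstitution, so the protein distributes over a
correspondingly smaller lipid pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .detection import AdditionCall, detect_addition_time, manual_addition_call
from .errors import FitError, ValidationError
from .io import AssayRecord, Trace, read_spectrum

__all__ = [
    "ProcessedPoint",
    "compute_baseline",
    "compute_fmin",
    "volume_correct",
    "compute_yraw",
    "compute_ppr",
    "determine_ymax",
    "compute_pge1",
    "process_record",
    "process_records",
    "points_table",
]

#: Number of samples in the baseline / F_min median windows.
MEDIAN_WINDOW = 10

#: Default usable-pool fraction for PPR adjustment.
DEFAULT_PPR_SCALE_FACTOR = 0.65


@dataclass
class ProcessedPoint:
    """Derived per-measurement quantities, one per assay record."""

    record: AssayRecord
    t_add_s: float
    f_baseline: float
    f_min_raw: float
    f_min_corrected: float
    y_raw: float
    ppr_adj: float
    #: relative reduction; equals y_raw here, kept as its own field for the
    #: control (y0) and plateau (y_max) roles in the scaling step
    y: float = 0.0
    p_ge1: float = float("nan")
    addition_method: str = "cwt"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = self.y_raw


def _median_window(values: np.ndarray, what: str, where: str, flags: list[str] | None) -> float:
    if values.size == 0:
        raise ValidationError(f"{where}: no samples available for {what}")
    if values.size < MEDIAN_WINDOW:
        warnings.warn(
            f"{where}: only {values.size} samples available for {what} "
            f"({MEDIAN_WINDOW} wanted)",
            stacklevel=3,
        )
        if flags is not None:
            flags.append(f"short_{what}_window")
    return float(np.median(values[-MEDIAN_WINDOW:]))


def compute_baseline(
    trace: Trace, call: AdditionCall, flags: list[str] | None = None
) -> float:
    """Median of the ten samples strictly preceding the addition index."""
    pre = trace.intensity[max(0, call.index - MEDIAN_WINDOW) : call.index]
    return _median_window(pre, "baseline", trace.source_path, flags)


def compute_fmin(
    trace: Trace,
    call: AdditionCall,
    timepoint_s: float,
    flags: list[str] | None = None,
) -> float:
    """Median of the last ten samples up to ``timepoint_s`` after addition.

    Times are taken relative to the addition call; samples in
    ``(0, timepoint_s]`` qualify. A trace that ends before the requested
    time point is used up to its end, with a warning.
    """
    rel = trace.time_s - call.time_s
    in_window = (rel > 0) & (rel <= timepoint_s)
    if rel[-1] < timepoint_s and flags is not None:
        warnings.warn(
            f"{trace.source_path}: acquisition ends at {rel[-1]:g} s after "
            f"addition, before the requested {timepoint_s:g} s time point",
            stacklevel=2,
        )
        flags.append("truncated_acquisition")
    return _median_window(
        trace.intensity[in_window], "f_min", trace.source_path, flags
    )


def volume_correct(
    f_min_raw: float, volume_before_ul: float, volume_after_ul: float
) -> float:
    """Undo the dilution caused by the dithionite aliquot.

    Adding the reductant increases the assay volume and dilutes the
    fluorophore; multiplying by ``V_after / V_before`` removes that purely
    volumetric drop so y_raw reflects chemical reduction only.
    """
    if volume_before_ul <= 0:
        raise ValidationError(f"volume_before_ul must be > 0 (got {volume_before_ul})")
    if volume_after_ul < volume_before_ul:
        raise ValidationError(
            f"volume_after_ul ({volume_after_ul}) must be >= "
            f"volume_before_ul ({volume_before_ul})"
        )
    return f_min_raw * (volume_after_ul / volume_before_ul)


def compute_yraw(f_baseline: float, f_min_corrected: float) -> float:
    """Fractional fluorescence reduction, 1 - F_min/F_baseline."""
    if f_baseline <= 0:
        raise ValidationError(f"f_baseline must be > 0 (got {f_baseline})")
    return 1.0 - f_min_corrected / f_baseline


def compute_ppr(
    protein_mg: float,
    lipid_mmol: float,
    ppr_scale_factor: float | None = DEFAULT_PPR_SCALE_FACTOR,
) -> float:
    """Adjusted protein-to-phospholipid ratio (mg/mmol).

    The scale factor is the reconstitution-competent fraction of the
    vesicle pool; the lipid amount is multiplied by it, so the adjusted
    PPR exceeds the nominal one. ``ppr_scale_factor=None`` disables the
    adjustment.
    """
    if lipid_mmol <= 0:
        raise ValidationError(f"lipid_mmol must be > 0 (got {lipid_mmol})")
    if ppr_scale_factor is None:
        return protein_mg / lipid_mmol
    if not 0 < ppr_scale_factor <= 1:
        raise ValidationError(
            f"ppr_scale_factor must be in (0, 1] or None (got {ppr_scale_factor})"
        )
    return protein_mg / (lipid_mmol * ppr_scale_factor)


def determine_ymax(
    ppr: np.ndarray,
    y: np.ndarray,
    scale_to: str = "model",
    y0: float | None = None,
) -> float:
    """Saturation level y_max of a titration.

    ``scale_to="data"`` returns the maximal measured y.
    ``scale_to="model"`` (default) fits the monoexponential
    ``y(PPR) = y0 + (b - y0) * (1 - exp(-PPR/tau))`` and returns the
    plateau ``b`` — the safeguard for titrations that stop short of
    saturation. A non-converging fit falls back to the data maximum with
    a warning.
    """
    ppr = np.asarray(ppr, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("determine_ymax: empty point list")
    if scale_to == "data":
        return float(np.max(y))
    if scale_to != "model":
        raise ValidationError(f"scale_to must be 'data' or 'model' (got {scale_to!r})")
    if np.unique(ppr).size < 3:
        raise ValidationError(
            "determine_ymax(scale_to='model') needs at least 3 distinct PPR values"
        )
    y0_fit = float(np.min(y)) if y0 is None else float(y0)

    def mono(x: np.ndarray, b: float, tau: float) -> np.ndarray:
        return y0_fit + (b - y0_fit) * (1.0 - np.exp(-x / tau))

    span = float(np.max(ppr[ppr > 0])) if np.any(ppr > 0) else 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                mono,
                ppr,
                y,
                p0=(float(np.max(y)), span / 3.0),
                maxfev=2000,
            )
        b = float(popt[0])
        if not np.isfinite(b) or b <= y0_fit:
            raise RuntimeError("degenerate plateau")
        return b
    except RuntimeError:
        warnings.warn(
            "monoexponential y_max fit did not converge; "
            "falling back to the data maximum",
            stacklevel=2,
        )
        return float(np.max(y))


def compute_pge1(y: float, y0: float, y_max: float) -> float:
    """Probability of at least one scramblase per liposome.

    Invariant under any affine rescaling applied to all of (y, y0, y_max).
    Out-of-range values (noise) are returned as-is.
    """
    if y_max <= y0:
        raise FitError(
            f"degenerate scaling: y_max ({y_max}) must exceed y0 ({y0})"
        )
    return (y - y0) / (y_max - y0)


# ---------------------------------------------------------------------------
# record-level pipeline
# ---------------------------------------------------------------------------


def process_record(
    record: AssayRecord,
    ppr_scale_factor: float | None = DEFAULT_PPR_SCALE_FACTOR,
    trace: Trace | None = None,
) -> ProcessedPoint:
    """Run detection and reduction statistics for one assay record.

    ``trace`` may be supplied to avoid re-reading the spectrum. P>=1 is
    left unset; it requires the control/plateau scaling context of the
    whole group (see :func:`scramblase.models.assay_stats`).
    """
    if trace is None:
        trace = read_spectrum(record.spectrum_path)
    flags: list[str] = []
    if record.addition_time_s is not None:
        call = manual_addition_call(trace, record.addition_time_s)
    else:
        call = detect_addition_time(trace)
    f_baseline = compute_baseline(trace, call, flags)
    f_min_raw = compute_fmin(trace, call, record.timepoint_s, flags)
    f_min_corrected = volume_correct(
        f_min_raw, record.volume_before_ul, record.volume_after_ul
    )
    y_raw = compute_yraw(f_baseline, f_min_corrected)
    if not 0.0 <= y_raw <= 1.0:
        flags.append("y_raw_out_of_range")
    ppr_adj = compute_ppr(record.protein_mg, record.lipid_mmol, ppr_scale_factor)
    return ProcessedPoint(
        record=record,
        t_add_s=call.time_s,
        f_baseline=f_baseline,
        f_min_raw=f_min_raw,
        f_min_corrected=f_min_corrected,
        y_raw=y_raw,
        ppr_adj=ppr_adj,
        addition_method=call.method,
    )


def process_records(
    records: list[AssayRecord],
    ppr_scale_factor: float | None = DEFAULT_PPR_SCALE_FACTOR,
) -> list[ProcessedPoint]:
    """Apply :func:`process_record` to every record."""
    return [process_record(r, ppr_scale_factor) for r in records]


def points_table(points: list[ProcessedPoint]):
    """Audit table of all per-record quantities (one row per record)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "path": [p.record.spectrum_path for p in points],
            "series": [p.record.series for p in points],
            "experiment": [p.record.experiment for p in points],
            "protein_mg": [p.record.protein_mg for p in points],
            "lipid_mmol": [p.record.lipid_mmol for p in points],
            "t_add_s": [p.t_add_s for p in points],
            "addition_method": [p.addition_method for p in points],
            "f_baseline": [p.f_baseline for p in points],
            "f_min_raw": [p.f_min_raw for p in points],
            "f_min_corrected": [p.f_min_corrected for p in points],
            "y_raw": [p.y_raw for p in points],
            "ppr_adj": [p.ppr_adj for p in points],
            "p_ge1": [p.p_ge1 for p in points],
            "flags": [";".join(p.flags) for p in points],
        }
    )
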