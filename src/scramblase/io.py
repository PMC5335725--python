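"""Reading and writing of fluorimeter spectra and the assay parameter spreadsheet.

Three spectrum dialects are supported, all plain text with time in seconds
and fluorescence intensity (arbitrary units) as columns:

``generic_tsv``
    Two tab/whitespace-delimited numeric columns, optionally preceded by a
    single header line; ``#`` comment lines are ignored.
``felix_gx``
    A FelixGX-style export: a free-form metadata preamble terminated by the
    sentinel column-designation line ``X<TAB>Y``, then the numeric block.
``felix_32``
    A Felix32-style export: a fixed three-line header (a first line starting
    with ``Felix32``, a trace-name line, an integer point count), then the
    numeric block.

The exact grammar of the proprietary exports varies between instrument
software versions; the grammars above are the tolerant, frozen contract of
this package (see ``docs/formats.md``) and file-type determination uses
header content only, never the file extension.
"""

from __future__ import annotations

import io as _io
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpectrumParseError, UnsupportedFormatError, ValidationError

__all__ = [
    "Trace",
    "AssayRecord",
    "detect_format",
    "read_spectrum",
    "read_assay_table",
    "generate_template",
    "write_generic_spectrum",
]

#: Minimum number of samples a trace must have for downstream processing
#: (ten-point medians on either side of the addition point).
MIN_SAMPLES = 20

#: Sentinel line terminating the FelixGX metadata preamble.
FELIX_GX_SENTINEL = "X\tY"

#: Magic prefix of the Felix32 dialect.
FELIX_32_MAGIC = "Felix32"

DEFAULT_TIMEPOINT_S = 400.0


@dataclass(frozen=True)
class Trace:
    """One fluorescence spectrum: sampled time (s) and intensity (a.u.)."""

    time_s: np.ndarray
    intensity: np.ndarray
    dialect: str = "generic_tsv"
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", f)
        where = self.source_path
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise ValidationError(
                f"{where}: time and intensity must be 1-d arrays of equal length"
            )
        if t.size < MIN_SAMPLES:
            raise ValidationError(
                f"{where}: trace too short ({t.size} samples; "
                f"at least {MIN_SAMPLES} required)"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValidationError(f"{where}: non-finite values in trace")
        if np.any(np.diff(t) <= 0):
            raise SpectrumParseError(
                f"{where}: malformed spectrum, time values not strictly increasing"
            )
        if np.any(f < 0):
            raise ValidationError(f"{where}: negative fluorescence intensities")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class AssayRecord:
    """One parameter-spreadsheet row describing a single assay measurement.

    ``protein_mg == 0`` denotes the required liposome-only (no protein)
    control. Volumes are the assay volumes without/with the dithionite
    aliquot and give the dilution correction factor. ``addition_time_s``
    optionally bypasses algorithmic addition detection.
    """

    spectrum_path: str
    protein_mg: float
    lipid_mmol: float
    volume_before_ul: float
    volume_after_ul: float
    timepoint_s: float = DEFAULT_TIMEPOINT_S
    experiment: str = "Experiment 1"
    series: str = ""
    addition_time_s: float | None = None

    def validate(self, where: str = "record") -> None:
        def _bad(msg: str) -> ValidationError:
            return ValidationError(f"{where}: {msg}")

        for name in (
            "protein_mg",
            "lipid_mmol",
            "volume_before_ul",
            "volume_after_ul",
            "timepoint_s",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise _bad(f"{name} must be a finite number (got {v!r})")
        if self.protein_mg < 0:
            raise _bad(f"protein_mg must be >= 0 (got {self.protein_mg})")
        if self.lipid_mmol <= 0:
            raise _bad(f"lipid_mmol must be > 0 (got {self.lipid_mmol})")
        if self.volume_before_ul <= 0:
            raise _bad(
                f"volume_before_ul must be > 0 (got {self.volume_before_ul})"
            )
        if self.volume_after_ul < self.volume_before_ul:
            raise _bad(
                "volume_after_ul must be >= volume_before_ul "
                f"(got {self.volume_after_ul} < {self.volume_before_ul})"
            )
        if self.timepoint_s <= 0:
            raise _bad(f"timepoint_s must be > 0 (got {self.timepoint_s})")


# ---------------------------------------------------------------------------
# dialect detection and spectrum parsing
# ---------------------------------------------------------------------------


def _is_numeric_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def _read_lines(path: str | Path) -> list[str]:
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        return [line.rstrip("\r\n") for line in fh]


def detect_format(path: str | Path) -> str:
    """Classify a spectrum file as one of the supported dialects.

    The decision is a pure function of the file's content; the file name
    and extension are never consulted.
    """
    lines = _read_lines(path)
    stripped = [ln.strip() for ln in lines]
    nonblank = [ln for ln in stripped if ln]
    if not nonblank:
        raise UnsupportedFormatError(f"{path}: empty file")
    if nonblank[0].startswith(FELIX_32_MAGIC):
        return "felix_32"
    for ln in lines[:100]:
        if ln.strip() == FELIX_GX_SENTINEL.strip() or ln == FELIX_GX_SENTINEL:
            return "felix_gx"
    candidates = [ln for ln in nonblank if not ln.startswith("#")]
    if candidates:
        if _is_numeric_pair(candidates[0]):
            return "generic_tsv"
        # a single non-numeric header line followed by numeric rows
        if len(candidates) > 1 and _is_numeric_pair(candidates[1]):
            return "generic_tsv"
    offending = candidates[0] if candidates else nonblank[0]
    raise UnsupportedFormatError(
        f"{path}: no supported spectrum dialect matches; "
        f"first non-matching line: {offending!r}"
    )


def _parse_numeric_block(
    lines: list[str], start_lineno: int, path: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    """Parse two-column numeric rows; blanks and '#'-comments are skipped."""
    times: list[float] = []
    values: list[float] = []
    for offset, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) != 2:
                raise ValueError
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(
                f"{path}, line {start_lineno + offset}: "
                f"expected two numeric columns, got {raw!r}"
            ) from None
    if len(times) < MIN_SAMPLES:
        raise SpectrumParseError(
            f"{path}: too few data rows ({len(times)}; "
            f"at least {MIN_SAMPLES} required)"
        )
    return np.asarray(times), np.asarray(values)


def read_spectrum(path: str | Path) -> Trace:
    """Read a fluorimeter spectrum in any supported dialect."""
    dialect = detect_format(path)
    lines = _read_lines(path)
    if dialect == "felix_gx":
        sentinel_at = next(
            i for i, ln in enumerate(lines) if ln.strip() == FELIX_GX_SENTINEL.strip()
        )
        data_lines, first_lineno = lines[sentinel_at + 1 :], sentinel_at + 2
    elif dialect == "felix_32":
        nonblank_idx = [i for i, ln in enumerate(lines) if ln.strip()]
        if len(nonblank_idx) < 3:
            raise SpectrumParseError(
                f"{path}: Felix32 header truncated (three header lines expected)"
            )
        count_idx = nonblank_idx[2]
        try:
            declared = int(lines[count_idx].strip())
        except ValueError:
            raise SpectrumParseError(
                f"{path}, line {count_idx + 1}: Felix32 point count expected, "
                f"got {lines[count_idx]!r}"
            ) from None
        data_lines, first_lineno = lines[count_idx + 1 :], count_idx + 2
        n_rows = sum(1 for ln in data_lines if ln.strip())
        if declared != n_rows:
            raise SpectrumParseError(
                f"{path}: Felix32 header declares {declared} points "
                f"but {n_rows} data rows found"
            )
    else:
        data_lines, first_lineno = list(lines), 1
        # drop the optional single header line
        for i, ln in enumerate(data_lines):
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            if not _is_numeric_pair(s):
                data_lines = data_lines[i + 1 :]
                first_lineno = i + 2
            break
    time_s, intensity = _parse_numeric_block(data_lines, first_lineno, path)
    return Trace(time_s, intensity, dialect=dialect, source_path=str(path))


def write_generic_spectrum(trace: Trace, path: str | Path) -> None:
    """Write a trace as a generic two-column tab-delimited spectrum.

    ``read_spectrum(write_generic_spectrum(t))`` is the identity on the
    (time, intensity) payload.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Time (s)\tIntensity\n")
        for t, f in zip(trace.time_s, trace.intensity):
            fh.write(f"{t:.17g}\t{f:.17g}\n")


# ---------------------------------------------------------------------------
# parameter spreadsheet
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "path": "spectrum_path",
    "protein reconstituted (mg)": "protein_mg",
    "lipid in reconstitution (mmol)": "lipid_mmol",
    "fluorescence assay vol. w/o dt (ul)": "volume_before_ul",
    "fluorescence assay vol. with dt (ul)": "volume_after_ul",
}
_OPTIONAL_COLUMNS = {
    "timepoint of measurement (s)": "timepoint_s",
    "experiment": "experiment",
    "experimental series": "series",
    "addition time (s)": "addition_time_s",
}
_NUMERIC_FIELDS = {
    "protein_mg",
    "lipid_mmol",
    "volume_before_ul",
    "volume_after_ul",
    "timepoint_s",
    "addition_time_s",
}


def _canonical(name: str) -> str:
    return " ".join(name.strip().lower().split())


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read and validate the tab-delimited parameter spreadsheet.

    Column matching is case-insensitive after whitespace trimming; '#'
    lines are comments. Relative spectrum paths are resolved against the
    spreadsheet's directory and must point to existing files. Omitted
    optional cells receive documented defaults (e.g. a 400 s measurement
    time point).
    """
    path = Path(path)
    lines = [
        ln
        for ln in _read_lines(path)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValidationError(f"{path}: no header row found")
    header = [_canonical(c) for c in lines[0].split("\t")]
    seen: set[str] = set()
    for col in header:
        if col in seen and col:
            raise ValidationError(f"{path}: duplicated column {col!r} in header")
        seen.add(col)
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): " + ", ".join(sorted(missing))
        )
    known = {**_REQUIRED_COLUMNS, **_OPTIONAL_COLUMNS}
    frame = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    frame.columns = [_canonical(c) for c in frame.columns]

    records: list[AssayRecord] = []
    for i, row in frame.iterrows():
        where = f"{path}, data row {i + 1}"
        kwargs: dict[str, object] = {}
        for col, fieldname in known.items():
            if col not in frame.columns:
                continue
            cell = str(row[col]).strip()
            if not cell:
                continue  # default injected by the dataclass
            if fieldname in _NUMERIC_FIELDS:
                try:
                    kwargs[fieldname] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{where}, column {col!r}: numeric value expected, "
                        f"got {cell!r}"
                    ) from None
            else:
                kwargs[fieldname] = cell
        if "spectrum_path" not in kwargs:
            raise ValidationError(f"{where}: 'Path' cell is empty")
        spec_path = Path(str(kwargs["spectrum_path"]))
        if not spec_path.is_absolute():
            spec_path = path.parent / spec_path
        if not spec_path.is_file():
            raise ValidationError(
                f"{where}: spectrum file not found: {spec_path}"
            )
        kwargs["spectrum_path"] = str(spec_path)
        record = AssayRecord(**kwargs)  # type: ignore[arg-type]
        record.validate(where)
        records.append(record)
    return records


_TEMPLATE = """\
# Dithionite scramblase assay - parameter spreadsheet template
#
# One row per assay measurement. Keep the file tab-delimited plain text.
# Lines starting with '#' are comments and are ignored by the reader.
#
# Column                               Type     Default            Meaning
# Path                                 text     (required)         spectrum file; relative paths resolve against this spreadsheet
# Protein Reconstituted (mg)           number   (required)         0 denotes the liposome-only control
# Lipid in Reconstitution (mmol)       number   (required)         phospholipid amount, > 0
# Fluorescence Assay Vol. w/o DT (ul)  number   (required)         assay volume before dithionite addition
# Fluorescence Assay Vol. with DT (ul) number   (required)         assay volume after dithionite addition
# Timepoint of Measurement (s)         number   400                time at which post-reduction fluorescence is read
# Experiment                           text     Experiment 1       label grouping measurements from one experiment
# Experimental Series                  text     (empty)            label for an experimental series, e.g. a protein variant
# Addition Time (s)                    number   (auto-detected)    manual dithionite-addition time, bypasses detection
#
Path\tProtein Reconstituted (mg)\tLipid in Reconstitution (mmol)\tFluorescence Assay Vol. w/o DT (ul)\tFluorescence Assay Vol. with DT (ul)\tTimepoint of Measurement (s)\tExperiment\tExperimental Series\tAddition Time (s)
# example: spectra/wildtype_ppr0p5.txt\t0.0025\t0.005\t2000\t2040\t400\tExperiment 1\twildtype\t
"""


def generate_template(path: str | Path | None) -> str:
    """Write the parameter-spreadsheet template; return its content.

    ``path=None`` writes to standard output. The uncommented header row is
    accepted verbatim by :func:`read_assay_table`.
    """
    if path is None:
        sys.stdout.write(_TEMPLATE)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_TEMPLATE)
    return _TEMPLATE
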