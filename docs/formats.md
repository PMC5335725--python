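# File formats

All inputs are plain text. Time is always in seconds; no unit sniffing is
performed. File-type determination is algorithmic and uses header content
only — never the file name or extension.

## Spectrum dialects

A spectrum is a time series of fluorescence intensity (arbitrary units).
Three dialects are read; `detect_format` classifies them as follows.

### `generic_tsv`

Two tab- (or whitespace-) delimited numeric columns: time (s), intensity.
An optional single non-numeric header line is allowed and skipped; lines
starting with `#` are comments. This format is trivially produced from
any spreadsheet program and is what `write_generic_spectrum` emits:

```
Time (s)	Intensity
0	10000
1	10001.3
...
```

### `felix_gx` (FelixGX-style export)

A free-form metadata preamble terminated by the sentinel
column-designation line `X<TAB>Y`, then the numeric block:

```
1
Session: <anything>
600
X	Y
0	10000
...
```

Classification rule: the sentinel `X<TAB>Y` occurs within the first 100
lines.

### `felix_32` (Felix32-style export)

A fixed three-line header — a first line starting with `Felix32`, a
trace-name line, and an integer point count (validated against the data
block) — then the numeric block:

```
Felix32 v1.20 export
Trace: <anything>
600
0	10000
...
```

Classification rule: the first non-blank line starts with `Felix32`.

The exact grammars of real QuantaMaster exports vary between instrument
software versions; the two proprietary grammars above are this package's
frozen, documented stand-ins and should be reconciled against real
exports where available. Parsing is strict inside the data block: any
non-numeric row is reported with its line number, at least 20 samples
are required, and time must be strictly increasing.

## Parameter spreadsheet

Tab-delimited, `#` comments, one row per assay measurement. Column
matching is exact after whitespace trimming and case folding. Relative
spectrum paths are resolved against the spreadsheet's own directory.

| Column | Type | Default | Meaning |
| --- | --- | --- | --- |
| `Path` | text | required | spectrum file |
| `Protein Reconstituted (mg)` | number | required | 0 = liposome-only control |
| `Lipid in Reconstitution (mmol)` | number | required | > 0 |
| `Fluorescence Assay Vol. w/o DT (ul)` | number | required | volume before dithionite |
| `Fluorescence Assay Vol. with DT (ul)` | number | required | volume after dithionite |
| `Timepoint of Measurement (s)` | number | 400 | F_min readout time |
| `Experiment` | text | `Experiment 1` | grouping label |
| `Experimental Series` | text | empty | e.g. protein variant |
| `Addition Time (s)` | number | auto-detected | manual override |

`scramblase template out.tsv` writes a commented template documenting
all of the above.

## Stats output

`scramblase stats` writes a tab-delimited table with columns `series`,
`experiment` (only when splitting by experiment), `alpha_x1e4`,
`alpha_se_x1e4`, `n_points`, `converged`, `generation`, `scale_to`.

## Synthetic-experiment manifest

`simulate_experiment` writes `manifest.txt`, plain `key=value` lines
recording every generative parameter (`alpha_true`, radius distribution,
refractory fraction, seed, ...) for parameter-recovery tests.
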