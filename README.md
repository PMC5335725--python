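# scramblase

Automated analysis of fluorescence-based (dithionite) scramblase assays:
from raw fluorimeter spectra and a tab-delimited parameter spreadsheet to
the scramblase-characterizing fit constant α, with publication-grade
trace and PPR plots.

## Who this is for

Membrane biochemists running dithionite scramblase (or compatible
back-extraction) assays: reconstitute a candidate scramblase into
NBD-lipid-doped liposomes, add dithionite, record the fluorescence
decay, and titrate the protein-to-phospholipid ratio (PPR). Protein-free
liposomes lose ~50% of their fluorescence (only outer-leaflet
fluorophores are reduced); vesicles containing at least one active
scramblase lose essentially all of it. This package replaces the long
chain of manual spreadsheet steps between the fluorimeter export and the
fitted activity constant.

## The model

Per spectrum, the pre-addition baseline and post-reduction minimum are
ten-point medians; after volume correction the fluorescence reduction is

```
y_raw = 1 − F_min / F_baseline
```

and, scaled between the protein-free control y₀ and the saturation
plateau y_max, the probability that a vesicle holds ≥ 1 scramblase:

```
P≥1 = (y − y₀) / (y_max − y₀)
```

Reconstitution is Poisson, so P≥1 saturates with PPR. Two model
generations are fitted by Levenberg–Marquardt least squares:
generation 1, `P≥1 = 1 − exp(−PPR/α)`; and generation 2 (default), which
averages Poisson occupancy with membrane-area-scaled means over the
liposome radius distribution (truncated normal, `r_bar = 88 nm`,
`sigma_r_bar = 28 nm` by default):

```
P≥1(PPR) = ∫ r² (1 − e^(−α·PPR·r²)) φ(r) dr / ∫ r² φ(r) dr
```

α (per (mg/mmol)·nm², reported ×10⁴) is the headline number: larger α,
steeper saturation, higher specific scramblase activity. PPR is adjusted
by the usable-pool factor 0.65 because roughly a third of the vesicle
pool is refractory to reconstitution. See `docs/methods.md` for the full
statistical treatment and `docs/formats.md` for the file formats.

## Worked example

The package ships a forward simulator, so a complete worked example
needs no instrument data (see `examples/`):

```python
from scramblase import ExperimentSpec, assay_stats, read_assay_table, simulate_experiment

sheet = simulate_experiment(
    ExperimentSpec(seed=7, output_dir="scratch/example_experiment", n_experiments=2)
)
records = read_assay_table(sheet)
print(assay_stats(records).to_string(index=False))
```

prints

```
   series  alpha_x1e4  alpha_se_x1e4  n_points  converged  generation scale_to
synthetic       15.19            0.7        16       True           2    model
```

The titration was generated with α × 10⁴ = 15: the full pipeline —
wavelet detection of the addition time, median baselines, volume
correction, occupancy scaling, generation-2 fit pooled over both
experiments — recovers 15.19 ± 0.70 from 16 noisy spectra. Per-trace
statistics for a noiseless protein-free control
(`examples/02_trace_statistics.py`):

```
addition detected at t = 49 s (sample 49, method cwt)
F_baseline          = 10000.0 a.u.
F_min (raw)         = 4900.0 a.u.
F_min (vol.-corr.)  = 5000.0 a.u.
fluorescence reduction y_raw = 50.00%
```

— the 2% dilution caused by the dithionite aliquot is undone by the
volume correction, leaving exactly the 50% reduction expected when only
the outer leaflet is accessible.

## Command line

The same four workflows are available from a shell:

```
scramblase template assays.tsv          # commented spreadsheet template
scramblase traces assays.tsv -o traces.png --time-max-sec 300
scramblase ppr assays.tsv -o ppr.png --ppr-axis-max 3
scramblase stats assays.tsv             # TSV of fit constants to stdout
```

All fitting options (`--generation`, `--scale-to`, `--ppr-scale-factor`,
`--force-through-origin`, `--split-by-experiment`, `--r-bar`,
`--sigma-r-bar`, `--manual-addition-time`) mirror the library defaults.
Exit codes: 0 success, 1 usage, 2 data/validation, 3 numeric failure.

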