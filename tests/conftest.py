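"""Shared fixtures: synthetic traces, dialect fixture writers, a small
titration experiment on disk."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from scramblase.io import Trace
from scramblase.synthetic import ExperimentSpec, TraceParams, simulate_experiment, simulate_trace


def write_felix_gx(trace: Trace, path: Path) -> None:
    """Serialize a trace in the frozen FelixGX-style fixture grammar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("1\n")
        fh.write("Session: synthetic fixture\n")
        fh.write(f"{len(trace)}\n")
        fh.write("X\tY\n")
        for t, f in zip(trace.time_s, trace.intensity):
            fh.write(f"{t:.17g}\t{f:.17g}\n")


def write_felix_32(trace: Trace, path: Path) -> None:
    """Serialize a trace in the frozen Felix32-style fixture grammar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Felix32 v1.20 export\n")
        fh.write("Trace: synthetic fixture\n")
        fh.write(f"{len(trace)}\n")
        for t, f in zip(trace.time_s, trace.intensity):
            fh.write(f"{t:.17g}\t{f:.17g}\n")


@pytest.fixture
def step_trace() -> Trace:
    """Noiseless plateau -> dilution step -> exponential reduction trace."""
    return simulate_trace(TraceParams(noise_sd=0.0))


@pytest.fixture
def trace_factory():
    """Factory for simulated traces with overridable parameters."""

    def make(**kwargs) -> Trace:
        return simulate_trace(TraceParams(**kwargs))

    return make


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory) -> Path:
    """A quick two-experiment titration on disk; returns the spreadsheet path."""
    out = tmp_path_factory.mktemp("experiment")
    return simulate_experiment(
        ExperimentSpec(seed=7, output_dir=out, n_experiments=2, n_vesicles=20_000)
    )
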