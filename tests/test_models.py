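"""Saturation models, their analytic relations, and the alpha fits."""

from __future__ import annotations

import numpy as np
import pytest

import scramblase.models
from scramblase.errors import FitError, ValidationError
from scramblase.models import (
    SizeDistribution,
    fit_ppr,
    model_gen1,
    model_gen2,
)
from scramblase.synthetic import simulate_vesicle_population

ALPHA2 = 1.5e-3  # generative fit constant, per (mg/mmol) nm^2
SIZE = SizeDistribution(88.0, 28.0)
PPR_GRID = np.array([0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.0])


class TestGen1:
    def test_closed_form_anchors(self):
        assert model_gen1(0.0, 0.1) == 0.0
        assert model_gen1(1e9, 0.1) == pytest.approx(1.0)
        assert model_gen1(0.1, 0.1) == pytest.approx(1.0 - np.exp(-1.0))

    def test_free_intercept_composition(self):
        # c at the origin, plateau b at saturation
        assert model_gen1(0.0, 0.1, b=0.9, c=0.07, force_through_origin=False) == pytest.approx(0.07)
        assert model_gen1(1e9, 0.1, b=0.9, c=0.07, force_through_origin=False) == pytest.approx(0.9)

    def test_positive_alpha_required(self):
        with pytest.raises(ValidationError):
            model_gen1(1.0, 0.0)


class TestGen2:
    def test_origin(self):
        assert model_gen2(0.0, ALPHA2, SIZE)[0] == 0.0

    def test_sigma_to_zero_matches_gen1(self):
        """Point-sized radius distribution: gen-2 collapses onto gen-1 with
        alpha_1 = 1/(alpha_2 * r_bar^2)."""
        narrow = SizeDistribution(88.0, 1e-6)
        g2 = model_gen2(PPR_GRID, ALPHA2, narrow)
        g1 = model_gen1(PPR_GRID, 1.0 / (ALPHA2 * 88.0**2))
        np.testing.assert_allclose(g2, g1, atol=1e-6)

    def test_continuous_in_sigma_at_zero(self):
        exact = model_gen2(PPR_GRID, ALPHA2, SizeDistribution(88.0, 0.0))
        near = model_gen2(PPR_GRID, ALPHA2, SizeDistribution(88.0, 1e-4))
        np.testing.assert_allclose(near, exact, atol=1e-6)

    def test_monotone_in_ppr_and_alpha_bounded_by_plateau(self):
        for alpha in (ALPHA2 / 10, ALPHA2, ALPHA2 * 10):
            vals = model_gen2(PPR_GRID, alpha, SIZE, b=0.97)
            assert np.all(np.diff(vals) > 0)
            assert np.all(vals <= 0.97 + 1e-12)
        ladder = [
            float(model_gen2(0.4, a, SIZE)[0])
            for a in (ALPHA2 / 4, ALPHA2, 4 * ALPHA2)
        ]
        assert ladder == sorted(ladder)

    def test_quadrature_order_converged(self, monkeypatch):
        """Doubling the Gauss-Legendre order moves predictions by < 1e-8."""
        base = model_gen2(PPR_GRID, ALPHA2, SIZE)
        monkeypatch.setattr(scramblase.models, "QUADRATURE_ORDER", 128)
        dense = model_gen2(PPR_GRID, ALPHA2, SIZE)
        assert np.max(np.abs(dense - base)) < 1e-8

    def test_monte_carlo_oracle_agrees(self):
        """Brute-force vesicle population (no refractory pool) vs quadrature."""
        for ppr in (0.05, 0.2, 0.8):
            frac, se = simulate_vesicle_population(
                ppr,
                ALPHA2,
                SIZE,
                refractory_fraction=0.0,
                n_vesicles=200_000,
                seed=int(ppr * 1000),
                return_se=True,
            )
            mc_pge1 = (frac - 0.5) / 0.5
            closed = float(model_gen2(ppr, ALPHA2, SIZE)[0])
            assert abs(mc_pge1 - closed) < 3 * (se / 0.5) + 1e-9


class TestFit:
    def test_noiseless_self_consistency(self):
        """Points on the exact generation-2 curve return alpha to < 0.1%."""
        pge1 = model_gen2(PPR_GRID, ALPHA2, SIZE)
        fit = fit_ppr(PPR_GRID, pge1, generation=2, size_dist=SIZE)
        assert fit.converged
        assert abs(fit.alpha - ALPHA2) / ALPHA2 < 1e-3
        assert fit.alpha_se < 0.01 * fit.alpha

    def test_noiseless_gen1_self_consistency(self):
        alpha1 = 0.35
        pge1 = model_gen1(PPR_GRID, alpha1)
        fit = fit_ppr(PPR_GRID, pge1, generation=1)
        assert abs(fit.alpha - alpha1) / alpha1 < 1e-3

    def test_free_plateau_fit_recovers_all_parameters(self):
        truth = dict(b=0.92, c=0.04)
        pge1 = model_gen2(PPR_GRID, ALPHA2, SIZE, force_through_origin=False, **truth)
        fit = fit_ppr(
            PPR_GRID, pge1, generation=2, size_dist=SIZE, force_through_origin=False
        )
        assert abs(fit.alpha - ALPHA2) / ALPHA2 < 1e-3
        assert fit.b == pytest.approx(truth["b"], abs=1e-4)
        assert fit.c == pytest.approx(truth["c"], abs=1e-4)

    def test_noisy_recovery_median_error(self):
        """0.05 noise on P>=1, 8 points, 200 seeds: median |rel err| <= 10%."""
        clean = model_gen2(PPR_GRID, ALPHA2, SIZE)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0.0, 0.05, clean.size)
            fit = fit_ppr(PPR_GRID, noisy, generation=2, size_dist=SIZE)
            errs.append(abs(fit.alpha - ALPHA2) / ALPHA2)
        assert np.median(errs) <= 0.10

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        noisy = model_gen2(PPR_GRID, ALPHA2, SIZE) + rng.normal(0, 0.03, PPR_GRID.size)
        a = fit_ppr(PPR_GRID, noisy, generation=2, size_dist=SIZE)
        b = fit_ppr(PPR_GRID, noisy, generation=2, size_dist=SIZE)
        assert a.alpha == b.alpha and a.alpha_se == b.alpha_se

    def test_under_determined_group_is_named(self):
        with pytest.raises(FitError, match="F45L"):
            fit_ppr(np.array([0.4, 0.4]), np.array([0.5, 0.6]), series="F45L")

    def test_size_distribution_invariants(self):
        with pytest.raises(ValidationError):
            SizeDistribution(-1.0, 0.0)
        with pytest.raises(ValidationError):
            SizeDistribution(50.0, 60.0)


class TestGroupAssembly:
    def _records(self, small_experiment):
        from scramblase.io import read_assay_table

        return read_assay_table(small_experiment)

    def test_identical_experiments_give_identical_fits(self, small_experiment, tmp_path):
        """Two experiments referencing the same spectra yield two identical
        per-experiment fits under split_by_experiment."""
        import shutil

        from scramblase.io import read_assay_table
        from scramblase.models import analyze_records

        src = small_experiment.read_text().splitlines()
        header, rows = src[0], [r for r in src[1:] if "Experiment 1" in r]
        twin_rows = [r.replace("Experiment 1", "Experiment 2") for r in rows]
        for name in {r.split("\t")[0] for r in rows}:
            shutil.copy(small_experiment.parent / name, tmp_path / name)
        sheet = tmp_path / "twin.tsv"
        sheet.write_text("\n".join([header, *rows, *twin_rows]) + "\n")
        _, fits = analyze_records(
            read_assay_table(sheet), split_by_experiment=True
        )
        assert len(fits) == 2
        assert fits[0].alpha == fits[1].alpha
        assert fits[0].alpha_se == fits[1].alpha_se

    def test_liposome_only_records_cannot_be_fit(self, small_experiment):
        from scramblase.io import read_assay_table
        from scramblase.models import analyze_records

        controls = [
            r for r in self._records(small_experiment) if r.protein_mg == 0
        ]
        with pytest.raises(FitError, match="liposome-only"):
            analyze_records(controls)

    def test_missing_control_is_an_error(self, small_experiment):
        from scramblase.models import analyze_records

        no_controls = [
            r for r in self._records(small_experiment) if r.protein_mg > 0
        ]
        with pytest.raises(ValidationError, match="control"):
            analyze_records(no_controls)

    def test_points_table_exports_audit_columns(self, small_experiment):
        from scramblase.models import analyze_records
        from scramblase.reduction import points_table

        points, _ = analyze_records(self._records(small_experiment))
        table = points_table(points)
        assert len(table) == 16
        for col in ("f_baseline", "y_raw", "ppr_adj", "p_ge1", "flags"):
            assert col in table.columns
        assert table["p_ge1"].notna().all()
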