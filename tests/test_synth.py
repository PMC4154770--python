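"""Synthetic-data generator: simulation fidelity and round trips."""

import warnings

import numpy as np
import pandas as pd
import pytest

from grasslandsem.metrics import SpeciesTrait, OccurrenceRecord, plot_guild_metrics
from grasslandsem.ram import build_ram, implied_covariance
from grasslandsem.semspec import SEMModelSpec
from grasslandsem.synth import (
    SyntheticTruth,
    default_pool,
    default_truth,
    recovery_report,
    simulate_plot_table,
    simulate_species_records,
)


def toy_truth(beta=0.8, resid_y=0.6):
    spec = SEMModelSpec(name="toy", observed=("x", "y"), paths=(("x", "y"),))
    return SyntheticTruth(
        spec=spec,
        coefficients={"x->y": beta},
        residual_sds={"x": 1.0, "y": resid_y},
    )


class TestSimulatePlotTable:
    def test_same_seed_is_identical(self, rh_truth):
        a = simulate_plot_table(rh_truth, 50, seed=3)
        b = simulate_plot_table(rh_truth, 50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_residuals_reduce_to_structural_equations(self):
        truth = toy_truth(beta=0.8, resid_y=0.0)
        table = simulate_plot_table(truth, 200, seed=1)
        np.testing.assert_allclose(table["y"], 0.8 * table["x"], atol=1e-12)

    def test_sample_covariance_matches_implied(self, rh_truth):
        table = simulate_plot_table(rh_truth, 10_000, seed=5)
        ram = build_ram(rh_truth.spec)
        implied = implied_covariance(ram, rh_truth.theta())
        sample = np.cov(table.to_numpy(), rowvar=False, ddof=1)
        np.testing.assert_allclose(sample, implied, atol=0.05)

    def test_unit_variance_construction(self, ra_truth):
        ram = build_ram(ra_truth.spec)
        implied = implied_covariance(ram, ra_truth.theta())
        np.testing.assert_allclose(np.diag(implied), 1.0, atol=1e-10)


def _traits_from_pool(pool):
    return {
        r["species"]: SpeciesTrait(r["species"], r["guild"], r["mean_length_mm"])
        for _, r in pool.table.iterrows()
    }


def _plot_row(**kw):
    base = dict(
        plot="P1", year=2008,
        herbivore_diversity=0, herbivore_abundance=0, herbivore_biomass=0.0,
        predator_diversity=0, predator_abundance=0, predator_biomass=0.0,
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestSpeciesRecords:
    def test_minimal_single_species_plot(self):
        pool = default_pool(seed=0)
        table = _plot_row(herbivore_diversity=1, herbivore_abundance=5, herbivore_biomass=0.05)
        records = simulate_species_records(table, pool, seed=0, juvenile_fraction=0.0, decomposer_rate=0.0)
        assert records["species"].nunique() == 1
        assert records["count"].sum() == 5

    def test_round_trip_recovers_richness_and_abundance_exactly(self):
        pool = default_pool(seed=1)
        truth = default_truth("ra", plots_per_region=100, seed=1)
        from grasslandsem.synth import to_measurement_scale

        rng = np.random.default_rng(2)
        table = to_measurement_scale(simulate_plot_table(truth, 100, seed=2), rng)
        table.insert(0, "plot", [f"P{i}" for i in range(len(table))])
        table.insert(1, "year", 2008)
        records = simulate_species_records(table, pool, seed=3)
        traits = _traits_from_pool(pool)
        recs_by_plot = {}
        for r in records.itertuples():
            recs_by_plot.setdefault(r.plot, []).append(
                OccurrenceRecord(r.plot, r.year, r.month, r.species, r.life_stage, r.count)
            )
        for _, row in table.iterrows():
            rich, abund, bio, _ = plot_guild_metrics(recs_by_plot.get(row["plot"], []), traits)
            for guild in ("herbivore", "predator"):
                assert rich[guild] == row[f"{guild}_diversity"]
                assert abund[guild] == row[f"{guild}_abundance"]
                if row[f"{guild}_biomass"] > 0.01:
                    assert bio[guild] == pytest.approx(row[f"{guild}_biomass"], rel=0.10)

    def test_all_juvenile_mode_yields_zero_abundance(self):
        pool = default_pool(seed=0)
        table = _plot_row(herbivore_diversity=3, herbivore_abundance=30, herbivore_biomass=0.5)
        records = simulate_species_records(table, pool, seed=0, juvenile_fraction=1.0)
        traits = _traits_from_pool(pool)
        recs = [
            OccurrenceRecord(r.plot, r.year, r.month, r.species, r.life_stage, r.count)
            for r in records.itertuples()
        ]
        rich, abund, bio, _ = plot_guild_metrics(recs, traits)
        assert sum(abund.values()) == 0

    def test_richness_beyond_pool_rejected(self):
        pool = default_pool(n_herbivores=3, seed=0)
        table = _plot_row(herbivore_diversity=5, herbivore_abundance=9, herbivore_biomass=0.1)
        with pytest.raises(ValueError, match="pool"):
            simulate_species_records(table, pool, seed=0)


class TestRecoveryReport:
    def test_small_run_reports_every_parameter(self, rh_truth):
        report = recovery_report(rh_truth, n_reps=5, n_plots=400, seed=2)
        ram = build_ram(rh_truth.spec)
        assert len(report) == ram.n_free
        assert report["rmse_std"].notna().all()
        assert report.attrs["n_reps"] == 5

    def test_degenerate_two_rep_run_warns(self, rh_truth):
        with pytest.warns(UserWarning, match="noisy"):
            recovery_report(rh_truth, n_reps=2, n_plots=400, seed=0)

    def test_too_few_reps_rejected(self, rh_truth):
        with pytest.raises(ValueError):
            recovery_report(rh_truth, n_reps=1)
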