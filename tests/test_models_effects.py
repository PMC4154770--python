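"""Path enumeration, total effects and stepwise pruning.

Oracles: a recursive depth-first search written here (independent of
networkx), the matrix identity total = ((I - A_std)^-1 - I)[target, source],
and simulation from a known truth for the pruning behavior.
"""

import numpy as np
import pytest

from grasslandsem.fit import SampleMoments, fit_ml
from grasslandsem.models import (
    default_rh_model,
    enumerate_paths,
    round_half_away,
    stepwise_prune,
    total_effect,
    total_effect_from_coefficients,
)
from grasslandsem.synth import default_truth, simulate_plot_table

import networkx as nx


def dfs_paths(edges, source, target):
    """Brute-force simple-path enumeration, independent of the library."""
    adj = {}
    for s, t in edges:
        adj.setdefault(s, []).append(t)
    out = []

    def walk(node, trail):
        if node == target:
            out.append(tuple(trail))
            return
        for nxt in adj.get(node, []):
            if nxt not in trail:
                walk(nxt, trail + [nxt])

    if source in adj or any(t == source for _, t in edges):
        walk(source, [source])
    return sorted(out)


class TestEnumeratePaths:
    def test_no_connection_is_empty(self, rh_spec):
        assert enumerate_paths(rh_spec, "predator_diversity", "mowing") == []

    def test_plant_to_predator_has_two_routes(self, rh_spec):
        paths = enumerate_paths(rh_spec, "plant_diversity", "predator_diversity")
        assert paths == [
            ("plant_diversity", "herbivore_diversity", "predator_diversity"),
            ("plant_diversity", "predator_diversity"),
        ]

    def test_latent_reaches_arthropods_only_via_plants(self, rh_spec):
        for target in ("herbivore_diversity", "predator_diversity"):
            for path in enumerate_paths(rh_spec, "land_use", target):
                assert "plant_diversity" in path or "plant_biomass" in path

    def test_unknown_node_rejected(self, rh_spec):
        with pytest.raises(KeyError):
            enumerate_paths(rh_spec, "land_use", "unicorns")

    def test_agrees_with_dfs_on_random_dags(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            nodes = [f"v{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            assert enumerate_paths(g, nodes[0], nodes[-1]) == dfs_paths(
                edges, nodes[0], nodes[-1]
            )


class TestTotalEffects:
    def test_worked_example_from_reported_coefficients(self):
        coeffs = {
            ("plant_diversity", "herbivore_diversity"): 0.13,
            ("herbivore_diversity", "predator_diversity"): 0.64,
            ("plant_diversity", "predator_diversity"): -0.25,
        }
        dec = total_effect_from_coefficients(coeffs, "plant_diversity", "predator_diversity")
        assert dec.n_paths == 2
        assert round_half_away(dec.total, 2) == -0.17

    def test_single_path_total_is_direct_coefficient(self):
        dec = total_effect_from_coefficients({("a", "b"): 0.42}, "a", "b")
        assert dec.total == pytest.approx(0.42)

    def test_source_equals_target_rejected(self):
        with pytest.raises(ValueError):
            total_effect_from_coefficients({("a", "b"): 1.0}, "a", "a")

    def test_total_is_sum_of_products(self, rh_truth, rh_moments):
        fit = fit_ml(rh_truth.spec, rh_moments, seed=0)
        dec = total_effect(fit, "land_use", "predator_diversity")
        assert dec.total == pytest.approx(sum(p for _, p in dec.paths))
        assert all(len(set(nodes)) == len(nodes) for nodes, _ in dec.paths)

    def test_matches_matrix_inverse_on_fitted_model(self, rh_truth, rh_moments):
        fit = fit_ml(rh_truth.spec, rh_moments, seed=0)
        variables = fit.spec.variables
        idx = {v: i for i, v in enumerate(variables)}
        A = np.zeros((len(variables), len(variables)))
        for _, row in fit.params.iterrows():
            if row["kind"] in ("path", "loading"):
                A[idx[row["target"]], idx[row["source"]]] = row["std_estimate"]
        totals = np.linalg.inv(np.eye(len(variables)) - A) - np.eye(len(variables))
        for source in ("land_use", "plant_diversity", "mowing"):
            for target in ("plant_biomass", "herbivore_diversity", "predator_diversity"):
                dec = total_effect(fit, source, target)
                assert dec.total == pytest.approx(
                    totals[idx[target], idx[source]], abs=1e-10
                )

    def test_matches_matrix_inverse_on_random_dags(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            nodes = [f"v{i}" for i in range(n)]
            coeffs = {
                (nodes[i], nodes[j]): float(rng.normal(scale=0.5))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.5
            }
            incident = {v for edge in coeffs for v in edge}
            if nodes[0] not in incident or nodes[-1] not in incident:
                continue
            A = np.zeros((n, n))
            for (s, t), v in coeffs.items():
                A[nodes.index(t), nodes.index(s)] = v
            totals = np.linalg.inv(np.eye(n) - A) - np.eye(n)
            dec = total_effect_from_coefficients(coeffs, nodes[0], nodes[-1])
            assert dec.total == pytest.approx(totals[n - 1, 0], abs=1e-10)


class TestStepwisePrune:
    def test_well_fitting_model_is_untouched(self, rh_truth):
        table = simulate_plot_table(rh_truth, 500, seed=31)
        moments = SampleMoments(
            rh_truth.spec.observed, np.cov(table.to_numpy(), rowvar=False, ddof=1), 500
        )
        fit, trace = stepwise_prune(rh_truth.spec, moments, seed=0)
        assert trace.status == "fit_adequate"
        assert trace.steps == []

    def test_aicc_trigger_deletes_the_spurious_path_first(self):
        truth = default_truth("rh")
        reduced_spec = truth.spec.without_path("grazing", "plant_biomass")
        reduced = default_truth("rh")
        reduced.coefficients["grazing->plant_biomass"] = 0.0
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            table = simulate_plot_table(reduced, 500, seed=1000 + rep)
            moments = SampleMoments(
                truth.spec.observed, np.cov(table.to_numpy(), rowvar=False, ddof=1), 500
            )
            fit, trace = stepwise_prune(
                truth.spec, moments, seed=0, trigger="aicc", max_steps=1
            )
            if trace.steps and trace.steps[0].deleted == ("grazing", "plant_biomass"):
                hits += 1
        assert hits >= n_rep // 2
        assert reduced_spec.paths == tuple(
            p for p in truth.spec.paths if p != ("grazing", "plant_biomass")
        )

    def test_trace_aicc_strictly_decreasing(self, ra_truth):
        # force pruning on a misspecified model: fit RH-shaped data with RA spec
        rh = default_truth("rh")
        table = simulate_plot_table(ra_truth, 200, seed=4)
        moments = SampleMoments(
            ra_truth.spec.observed, np.cov(table.to_numpy(), rowvar=False, ddof=1), 200
        )
        fit, trace = stepwise_prune(ra_truth.spec, moments, seed=0, trigger="aicc")
        aiccs = [s.aicc_before for s in trace.steps] + (
            [trace.steps[-1].aicc_after] if trace.steps else []
        )
        assert all(b > a for b, a in zip(aiccs, aiccs[1:]))

    def test_terminates_and_labels_status(self, rh_truth):
        table = simulate_plot_table(rh_truth, 100, seed=8)
        moments = SampleMoments(
            rh_truth.spec.observed, np.cov(table.to_numpy(), rowvar=False, ddof=1), 100
        )
        fit, trace = stepwise_prune(rh_truth.spec, moments, seed=0, max_steps=5)
        assert trace.status in ("fit_adequate", "gof_rescue", "failed")

    def test_bad_trigger_rejected(self, rh_truth, rh_moments):
        with pytest.raises(ValueError):
            stepwise_prune(rh_truth.spec, rh_moments, trigger="magic")


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.1668, -0.17), (0.125, 0.13), (-0.125, -0.13), (0.1249, 0.12), (0.0, 0.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 2) == expected
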