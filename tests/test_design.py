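"""Experiment drivers: panel evaluation, greedy selection, clustering, families."""

import numpy as np
import pytest

from protdeconv import (
    FamilyAssignment,
    KineticMatrix,
    ShapeError,
    SimConfig,
    SingleAssay,
    Timecourse,
    cluster_proteases,
    evaluate_panel,
    family_deconvolution_experiment,
    greedy_substrate_reduction,
    lambda_difficulty_sweep,
    sample_family_panel,
    sample_kinetic_matrix,
    simulate_single_assays,
)
from protdeconv.design import SelectionStep, SelectionTrace

TINY = dict(P=2, seed=17)


class TestEvaluatePanel:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(M=3, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        a = evaluate_panel(km, km.substrates, cfg)
        b = evaluate_panel(km, km.substrates, cfg)
        np.testing.assert_array_equal(a.per_protease, b.per_protease)

    def test_single_protease_single_substrate_recovery(self):
        cfg = SimConfig(M=1, N=1, P=4, seed=23)
        km = sample_kinetic_matrix(cfg)
        rep = evaluate_panel(km, km.substrates, cfg)
        assert rep.overall < 0.05

    def test_empty_subset_rejected(self):
        cfg = SimConfig(M=3, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        with pytest.raises(ShapeError):
            evaluate_panel(km, [], cfg)


class TestGreedyReduction:
    def test_trace_structure(self):
        cfg = SimConfig(M=4, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        trace = greedy_substrate_reduction(km, cfg)
        sizes = [len(s.substrate_set) for s in trace.steps]
        assert sizes == [4, 3, 2]
        assert trace.steps[0].removed is None
        assert trace.terminal_size == 2
        # nesting: each set is the previous minus the removed substrate
        for prev, cur in zip(trace.steps, trace.steps[1:]):
            assert set(cur.substrate_set) == set(prev.substrate_set) - {cur.removed}

    def test_seed_determinism(self):
        cfg = SimConfig(M=4, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        t1 = greedy_substrate_reduction(km, cfg)
        t2 = greedy_substrate_reduction(km, cfg)
        assert t1 == t2

    def test_duplicate_substrate_removed_first(self):
        # 3 proteases need 3 informative substrates; with 3 distinct rows
        # plus an exact duplicate, only the duplicate is redundant, so
        # greedy must drop it first.
        cfg = SimConfig(M=3, N=3, P=3, seed=31)
        km = sample_kinetic_matrix(cfg)
        km_dup = KineticMatrix(
            km.substrates + ("S1dup",),
            km.proteases,
            np.vstack([km.V, km.V[0]]),
            np.vstack([km.K, km.K[0]]),
            np.vstack([km.n, km.n[0]]),
            np.vstack([km.beta, km.beta[0]]),
        )
        trace = greedy_substrate_reduction(km_dup, cfg)
        assert trace.steps[1].removed in ("S1", "S1dup")
        assert trace.steps[1].rmse <= trace.steps[0].rmse + 1e-6

    def test_invalid_trace_construction_rejected(self):
        s0 = SelectionStep(("S1", "S2", "S3"), None, 0.1)
        bad = SelectionStep(("S1",), "S2", 0.2)  # skips a size
        with pytest.raises(ShapeError):
            SelectionTrace((s0, bad))

    def test_requires_three_substrates(self):
        cfg = SimConfig(M=2, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        with pytest.raises(ShapeError):
            greedy_substrate_reduction(km, cfg)


class TestLambdaSweep:
    def test_tidy_output_structure(self):
        cfg = SimConfig(M=3, **TINY)
        tab = lambda_difficulty_sweep(cfg, lambdas=[0.0, 0.9], substrate_counts=[2, 3])
        assert list(tab.columns) == ["lam", "n_substrates", "rmse"]
        assert len(tab) == 4
        assert (tab["rmse"] >= 0).all()

    def test_counts_validated(self):
        cfg = SimConfig(M=3, **TINY)
        with pytest.raises(ShapeError):
            lambda_difficulty_sweep(cfg, lambdas=[0.5], substrate_counts=[5])


class TestClustering:
    @staticmethod
    def _assay(prot, sub, values, times=(10.0, 60.0)):
        return SingleAssay(prot, sub, Timecourse(np.asarray(times), np.asarray(values)))

    def test_identical_proteases_always_co_cluster(self):
        assays = [
            self._assay("A", "S1", [0.9, 0.5]),
            self._assay("B", "S1", [0.9, 0.5]),
            self._assay("C", "S1", [0.4, 0.1]),
        ]
        fa = cluster_proteases(assays, cutoff=1e-6)
        assert fa.labels["A"] == fa.labels["B"] != fa.labels["C"]

    def test_small_cutoff_gives_singletons(self):
        assays = [
            self._assay("A", "S1", [0.9, 0.5]),
            self._assay("B", "S1", [0.8, 0.4]),
            self._assay("C", "S1", [0.4, 0.1]),
        ]
        fa = cluster_proteases(assays, cutoff=1e-9)
        assert fa.n_families == 3

    def test_partition_invariant_to_input_order(self):
        assays = [
            self._assay("A", "S1", [0.9, 0.5]),
            self._assay("B", "S1", [0.88, 0.48]),
            self._assay("C", "S1", [0.4, 0.1]),
        ]
        fa1 = cluster_proteases(assays, cutoff=0.2)
        fa2 = cluster_proteases(assays[::-1], cutoff=0.2)
        for x in "ABC":
            for y in "ABC":
                same1 = fa1.labels[x] == fa1.labels[y]
                same2 = fa2.labels[x] == fa2.labels[y]
                assert same1 == same2

    def test_incomplete_grid_rejected(self):
        assays = [
            self._assay("A", "S1", [0.9, 0.5]),
            self._assay("A", "S2", [0.9, 0.5]),
            self._assay("B", "S1", [0.4, 0.1]),
        ]
        with pytest.raises(ShapeError):
            cluster_proteases(assays)

    def test_recovers_simulated_family_structure(self):
        cfg = SimConfig(M=7, seed=41, lam=0.9)
        km, truth = sample_family_panel(cfg, cfg.rng())
        assays = simulate_single_assays(km, cfg.calibration_times)
        fa = cluster_proteases(assays, cutoff=0.6)
        assert fa.n_families == 3
        for fam, members in fa.families.items():
            assert len({truth[m] for m in members}) == 1


class TestFamilyDeconvolution:
    def test_singleton_families_match_protease_level(self):
        cfg = SimConfig(M=4, N=2, P=3, seed=19)
        km = sample_kinetic_matrix(cfg)
        singleton = {p: f"F{j}" for j, p in enumerate(km.proteases)}
        res = family_deconvolution_experiment(km, singleton, cfg)
        assert res.family_report.overall == pytest.approx(
            res.protease_report.overall, abs=0.02
        )

    def test_uncovered_protease_rejected(self):
        cfg = SimConfig(M=3, N=2, **TINY)
        km = sample_kinetic_matrix(cfg)
        with pytest.raises(ShapeError):
            family_deconvolution_experiment(km, {"E1": "F1"}, cfg)

    def test_assignment_dataclass_properties(self):
        fa = FamilyAssignment(
            labels={"A": "F1", "B": "F1", "C": "F2"},
            cutoff=0.6,
            linkage_heights=np.array([0.1, 0.9]),
        )
        assert fa.n_families == 2
        assert sorted(fa.families["F1"]) == ["A", "B"]
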