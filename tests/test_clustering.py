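"""Distance kernels vs brute-force oracles, clustering and consensus behavior."""

import numpy as np
import pandas as pd
import pytest

from sleepstrat import (
    EmbeddingMatrix,
    cluster_k,
    consensus_analysis,
    cross_solution_flow,
    earth_mover_distance_1d,
    embedding_pair_distance,
    energy_distance,
    label_risk_groups,
    project_samples,
    silhouette_by_k,
)
from sleepstrat.containers import ClusterSolution
from tests.conftest import make_regime_embeddings


def energy_brute(x, y):
    """Independent oracle: literal double sums over all ordered pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return (
        2 * np.abs(x[:, None] - y[None, :]).mean()
        - np.abs(x[:, None] - x[None, :]).mean()
        - np.abs(y[:, None] - y[None, :]).mean()
    )


def emd_brute(x, y):
    """Independent oracle: L1 distance between quantile functions."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    grid = np.linspace(0, 1, 20000, endpoint=False) + 0.5 / 20000
    qx = x[np.minimum((grid * len(x)).astype(int), len(x) - 1)]
    qy = y[np.minimum((grid * len(y)).astype(int), len(y) - 1)]
    return np.abs(qx - qy).mean()


class TestDistanceKernels:
    def test_energy_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 40, 2)
            x = rng.normal(size=n) * rng.uniform(0.1, 5)
            y = rng.normal(size=m) + rng.uniform(-2, 2)
            assert abs(energy_distance(x, y) - energy_brute(x, y)) < 1e-12

    def test_emd_matches_quantile_oracle(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 40, 2)
            x = rng.normal(size=n) * rng.uniform(0.1, 5)
            y = rng.normal(size=m) + rng.uniform(-2, 2)
            assert abs(earth_mover_distance_1d(x, y) - emd_brute(x, y)) < 1e-3

    @pytest.mark.parametrize(
        "x,y,expected",
        [([0, 1], [0, 1], 0.0), ([0], [1], 2.0), ([0, 1], [1, 2], 1.0)],
    )
    def test_energy_hand_examples(self, x, y, expected):
        assert energy_distance(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y,expected", [([3, 1], [1, 3], 0.0), ([0], [1], 1.0), ([0, 2], [1], 1.0)]
    )
    def test_emd_hand_examples(self, x, y, expected):
        assert earth_mover_distance_1d(x, y) == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            energy_distance([], [1.0])
        with pytest.raises(ValueError):
            earth_mover_distance_1d([1.0], [])

    def test_scale_equivariance(self, rng):
        """Multiplying both samples by c > 0 scales both metrics by c."""
        x, y = rng.normal(size=20), rng.normal(size=31)
        for c in (0.5, 3.0):
            assert energy_distance(c * x, c * y) == pytest.approx(
                c * energy_distance(x, y), rel=1e-10
            )
            assert earth_mover_distance_1d(c * x, c * y) == pytest.approx(
                c * earth_mover_distance_1d(x, y), rel=1e-10
            )


class TestEmbeddingPairDistance:
    def test_identity_and_hand_example(self):
        a = EmbeddingMatrix(np.array([[0.0, 0.0], [1.0, 1.0]]))
        b = EmbeddingMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert embedding_pair_distance(a, a) == 0.0
        # row 0: energy({0,0},{1,1}) = 2; row 1: identical -> 0; mean = 1
        assert embedding_pair_distance(a, b, "energy") == pytest.approx(1.0)

    def test_symmetry_and_unequal_lengths(self, rng):
        for _ in range(20):
            a = EmbeddingMatrix(rng.normal(size=(5, int(rng.integers(3, 30)))))
            b = EmbeddingMatrix(rng.normal(size=(5, int(rng.integers(3, 30)))))
            for metric in ("energy", "earth_mover"):
                d_ab = embedding_pair_distance(a, b, metric)
                d_ba = embedding_pair_distance(b, a, metric)
                assert d_ab == pytest.approx(d_ba, rel=1e-10)
                assert d_ab >= 0

    def test_dim_mismatch_rejected(self):
        a = EmbeddingMatrix(np.zeros((3, 4)))
        b = EmbeddingMatrix(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="dimension mismatch"):
            embedding_pair_distance(a, b)

    def test_matches_per_row_public_kernels(self, rng):
        """Pair distance equals the mean of per-dimension kernel calls."""
        a = EmbeddingMatrix(rng.normal(size=(4, 17)))
        b = EmbeddingMatrix(rng.normal(size=(4, 23)))
        for metric, kernel in (("energy", energy_distance),
                               ("earth_mover", earth_mover_distance_1d)):
            expected = np.mean(
                [kernel(a.values[j], b.values[j]) for j in range(4)]
            )
            assert embedding_pair_distance(a, b, metric) == pytest.approx(
                expected, rel=1e-9
            )


class TestProjection:
    def test_singleton_micro_example(self):
        embs = [EmbeddingMatrix(np.array([[v]]), f"s{i}")
                for i, v in enumerate([0.0, 1.0, 3.0])]
        proj = project_samples(embs, "energy")
        np.testing.assert_allclose(
            proj.matrix, [[0, 2, 6], [2, 0, 4], [6, 4, 0]], atol=1e-12
        )

    def test_identical_embeddings_zero_entry(self):
        vals = np.arange(6.0).reshape(2, 3)
        embs = [EmbeddingMatrix(vals.copy(), "a"), EmbeddingMatrix(vals.copy(), "b"),
                EmbeddingMatrix(vals + 1, "c")]
        proj = project_samples(embs)
        assert proj.matrix[0, 1] == 0.0

    def test_symmetric_hollow_nonnegative(self, rng):
        _, embs = make_regime_embeddings(10, centers=[np.zeros(6), np.ones(6)],
                                         embed_dim=6, seed=1)
        proj = project_samples(embs)
        np.testing.assert_allclose(proj.matrix, proj.matrix.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(proj.matrix), 0.0, atol=1e-12)
        assert (proj.matrix >= 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            project_samples([EmbeddingMatrix(np.zeros((2, 3)))])

    def test_projection_scale_equivariance(self, rng):
        _, embs = make_regime_embeddings(4, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=2)
        scaled = [EmbeddingMatrix(3.0 * e.values, e.recording_id) for e in embs]
        p1 = project_samples(embs).matrix
        p2 = project_samples(scaled).matrix
        np.testing.assert_allclose(p2, 3.0 * p1, rtol=1e-9)


class TestKMeansAndSilhouette:
    def test_separated_regimes_perfect_ari(self):
        from sklearn.metrics import adjusted_rand_score

        labels, embs = make_regime_embeddings(
            15, centers=[np.zeros(6), 10 * np.ones(6)], embed_dim=6, seed=3
        )
        proj = project_samples(embs)
        sol = cluster_k(proj, k=2, seed=0)
        assign = [sol.assignment[e.recording_id] for e in embs]
        assert adjusted_rand_score(labels, assign) == 1.0

    def test_same_seed_identical_assignment(self):
        _, embs = make_regime_embeddings(8, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=4)
        proj = project_samples(embs)
        assert cluster_k(proj, 2, seed=5).assignment == cluster_k(
            proj, 2, seed=5
        ).assignment

    def test_invalid_k_rejected(self):
        _, embs = make_regime_embeddings(3, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=4)
        proj = project_samples(embs)
        with pytest.raises(ValueError, match="k must"):
            cluster_k(proj, k=6, seed=0)

    def test_silhouette_hand_example(self):
        """1-D points {0, 0.1, 10, 10.1} at k=2: mean silhouette = 0.99."""
        from sklearn.metrics import silhouette_score

        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        # hand: each point has a in {0.1}, b in {9.95, 10.05}; mean s = 0.99
        assert silhouette_score(X, labels) == pytest.approx(0.99, abs=1e-3)

    def test_silhouette_by_k_peaks_at_planted_k(self):
        _, embs = make_regime_embeddings(
            8, centers=[np.zeros(5), 8 * np.ones(5), -8 * np.ones(5)],
            embed_dim=5, seed=6,
        )
        proj = project_samples(embs)
        table = silhouette_by_k(proj, range(2, 7), seed=0)
        best_k = int(table.loc[table["silhouette"].idxmax(), "k"])
        assert best_k == 3

    def test_empty_k_range_rejected(self):
        _, embs = make_regime_embeddings(4, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=4)
        with pytest.raises(ValueError, match="empty"):
            silhouette_by_k(project_samples(embs), [], seed=0)


class TestConsensus:
    def test_separated_regimes_block_zero_one(self):
        labels, embs = make_regime_embeddings(
            12, centers=[np.zeros(6), 10 * np.ones(6)], embed_dim=6, seed=7
        )
        proj = project_samples(embs)
        cm = consensus_analysis(proj, k=2, n_iterations=50, seed=0)
        same = labels[:, None] == labels[None, :]
        defined = ~cm.undefined_mask
        np.testing.assert_allclose(cm.values[same & defined], 1.0)
        np.testing.assert_allclose(cm.values[~same & defined], 0.0)

    def test_values_in_unit_interval_and_symmetric(self):
        _, embs = make_regime_embeddings(10, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=8)
        cm = consensus_analysis(project_samples(embs), k=2, n_iterations=30, seed=1)
        assert ((cm.values >= 0) & (cm.values <= 1)).all()
        np.testing.assert_allclose(cm.values, cm.values.T)
        assert len(cm.ward_order) == 20

    def test_bad_fraction_rejected(self):
        _, embs = make_regime_embeddings(5, centers=[np.zeros(4), np.ones(4)],
                                         embed_dim=4, seed=8)
        with pytest.raises(ValueError, match="subsample_fraction"):
            consensus_analysis(project_samples(embs), 2, subsample_fraction=1.5)


class TestRiskLabeling:
    def _subjects(self, rows):
        return pd.DataFrame(rows).set_index("id")

    def test_sorts_by_crude_mortality(self):
        sol = ClusterSolution(
            k=3, assignment={"a": 0, "b": 1, "c": 2}, silhouette=0.5, seed=0
        )
        subjects = self._subjects([
            {"id": "a", "time_years": 10.0, "event": 1},   # rate 0.10
            {"id": "b", "time_years": 100.0, "event": 1},  # rate 0.01
            {"id": "c", "time_years": 50.0, "event": 1},   # rate 0.02
        ])
        labeled = label_risk_groups(sol, subjects)
        assert labeled.risk_labels == {1: "RG1", 2: "RG2", 0: "RG3"}
        assert labeled.risk_label_of("a") == "RG3"

    def test_ties_break_by_cluster_id(self):
        sol = ClusterSolution(
            k=2, assignment={"a": 1, "b": 0}, silhouette=0.0, seed=0
        )
        subjects = self._subjects([
            {"id": "a", "time_years": 10.0, "event": 0},
            {"id": "b", "time_years": 10.0, "event": 0},
        ])
        assert label_risk_groups(sol, subjects).risk_labels == {0: "RG1", 1: "RG2"}

    def test_missing_outcomes_listed(self):
        sol = ClusterSolution(k=2, assignment={"a": 0, "b": 1}, silhouette=0, seed=0)
        subjects = self._subjects([{"id": "a", "time_years": 1.0, "event": 0}])
        with pytest.raises(ValueError, match="b"):
            label_risk_groups(sol, subjects)

    def test_planted_hazard_gradient_recovered(self):
        """Risk labels reproduce a planted 3-group hazard ordering."""
        from sleepstrat import CohortSpec, generate_cohort

        hits = 0
        for seed in range(100):
            spec = CohortSpec(
                n_subjects=600, group_proportions=(1 / 3, 1 / 3, 1 / 3),
                group_log_hazard_ratios=(0.0, np.log(2.5), np.log(6.0)),
                baseline_hazard=0.02, censoring_rate=0.01,
                followup_horizon=15.0, seed=seed,
            )
            df = generate_cohort(spec).set_index("id")
            sol = ClusterSolution(
                k=3,
                assignment={i: int(g) for i, g in df["group"].items()},
                silhouette=0.0, seed=0,
            )
            labels = label_risk_groups(sol, df).risk_labels
            hits += labels == {0: "RG1", 1: "RG2", 2: "RG3"}
        assert hits >= 95


class TestCrossSolutionFlow:
    def test_identical_partitions_diagonal(self):
        assign = {f"s{i}": i % 2 for i in range(10)}
        sols = [ClusterSolution(2, dict(assign), 0.0, 0) for _ in range(2)]
        flow = cross_solution_flow(sols)
        assert set(zip(flow.cluster_from, flow.cluster_to)) == {(0, 0), (1, 1)}

    def test_outflow_conservation_under_refinement(self):
        coarse = {f"s{i}": i % 2 for i in range(20)}
        fine = {f"s{i}": i % 4 for i in range(20)}  # refines i%2
        flow = cross_solution_flow([
            ClusterSolution(2, coarse, 0.0, 0), ClusterSolution(4, fine, 0.0, 0)
        ])
        for c in (0, 1):
            out = flow[flow.cluster_from == c]["count"].sum()
            assert out == sum(1 for v in coarse.values() if v == c)

    def test_sample_set_mismatch_rejected(self):
        a = ClusterSolution(2, {"x": 0, "y": 1}, 0.0, 0)
        b = ClusterSolution(2, {"x": 0, "z": 1}, 0.0, 0)
        with pytest.raises(ValueError, match="sample set"):
            cross_solution_flow([a, b])

    def test_high_risk_regime_concentrates_at_coarse_k(self):
        """The extreme regime's members stay together in the k=2 partition."""
        labels, embs = make_regime_embeddings(
            10,
            centers=[np.zeros(5), 0.8 * np.ones(5), 1.6 * np.ones(5),
                     2.4 * np.ones(5), 12 * np.ones(5)],
            embed_dim=5, spread=0.25, seed=9,
        )
        proj = project_samples(embs)
        sol2 = cluster_k(proj, 2, seed=0)
        extreme_ids = [e.recording_id for e, l in zip(embs, labels) if l == 4]
        counts = pd.Series([sol2.assignment[i] for i in extreme_ids]).value_counts()
        assert counts.iloc[0] >= 0.8 * len(extreme_ids)
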