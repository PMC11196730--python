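"""PageRank (teleport-on-d form), hemisphere ranking, prediction scoring."""

import networkx as nx
import numpy as np
import pytest

from resectsim.centrality import (
    centrality_report,
    pagerank_scores,
    pr_prediction_rates,
    rank_per_hemisphere,
)
from resectsim.connectome_io import Connectome
from resectsim.percolation_engine import percolation_sweep
from resectsim.resection_enumerator import enumerate_resections
from resectsim.synthetic_cohort import CohortConfig, generate_cohort

from conftest import connectome_from_edges


def power_iteration_oracle(weights, d, weighted=False, iters=5000):
    """Dense-matrix fixed point of PR = d/n + (1-d) M^T PR."""
    n = weights.shape[0]
    trans = weights.copy() if weighted else (weights > 0).astype(float)
    out = trans.sum(axis=1)
    m = np.zeros((n, n))
    for i in range(n):
        if out[i] == 0:
            m[i, :] = 1.0 / n  # dangling: uniform
        else:
            m[i, :] = trans[i, :] / out[i]
    x = np.full(n, 1.0 / n)
    for _ in range(iters):
        x = d / n + (1 - d) * m.T @ x
    return x


def ring_connectome(n):
    edges = {(f"p{i}", f"p{(i + 1) % n}"): 1 for i in range(n)}
    return connectome_from_edges([f"p{i}" for i in range(n)], edges)


class TestPagerankScores:
    @pytest.mark.parametrize("d", [0.05, 0.15, 0.5])
    def test_ring_is_uniform(self, d):
        scores = pagerank_scores(ring_connectome(7), d=d)
        assert all(v == pytest.approx(1 / 7, abs=1e-12) for v in scores.values())

    def test_teleport_only_limit_uniform(self):
        c = connectome_from_edges("abcd", {("a", "b"): 3, ("a", "c"): 1})
        scores = pagerank_scores(c, d=1.0)
        assert all(v == pytest.approx(1 / 4) for v in scores.values())

    def test_star_matches_power_iteration_oracle(self):
        edges = {("hub", leaf): 1 for leaf in ("l1", "l2", "l3")}
        c = connectome_from_edges(["hub", "l1", "l2", "l3"], edges)
        scores = pagerank_scores(c, d=0.15)
        expected = power_iteration_oracle(c.weights, 0.15)
        for p, e in zip(c.parcels, expected):
            assert scores[p] == pytest.approx(e, abs=1e-10)
        assert scores["hub"] > scores["l1"]

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_graphs_match_oracle(self, seed, weighted):
        """Oracle equivalence on random graphs up to 50 nodes, 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        w = np.triu(rng.poisson(0.8, (n, n)) * rng.integers(1, 9, (n, n)), 1).astype(float)
        w = w + w.T
        c = Connectome("r", tuple(f"p{i:02d}" for i in range(n)), w)
        scores = pagerank_scores(c, d=0.15, weighted=weighted)
        expected = power_iteration_oracle(w, 0.15, weighted=weighted)
        np.testing.assert_allclose(
            [scores[p] for p in c.parcels], expected, atol=1e-10
        )

    def test_matches_standard_pagerank_with_transposed_damping(self):
        """d = 0.15 in the teleport-on-d form equals alpha = 0.85 standard PR."""
        rng = np.random.default_rng(3)
        w = np.triu(rng.poisson(1.0, (12, 12)), 1).astype(float)
        w = w + w.T
        w[0, :] = w[:, 0] = 0  # keep a dangling node in play
        c = Connectome("r", tuple(f"p{i:02d}" for i in range(12)), w)
        scores = pagerank_scores(c, d=0.15)
        g = nx.from_numpy_array(w)
        nx_scores = nx.pagerank(g, alpha=0.85, tol=1e-14, max_iter=500, weight=None)
        for i, p in enumerate(c.parcels):
            assert scores[p] == pytest.approx(nx_scores[i], abs=1e-8)

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(9)
        w = np.triu(rng.poisson(1.0, (20, 20)), 1).astype(float)
        w = w + w.T
        c = Connectome("r", tuple(f"p{i:02d}" for i in range(20)), w)
        assert sum(pagerank_scores(c).values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_damping_rejected(self, triangle_connectome):
        with pytest.raises(ValueError):
            pagerank_scores(triangle_connectome, d=1.5)


class TestRankPerHemisphere:
    def test_two_parcels_ranked_by_score(self, grid_atlas):
        scores = {p: 1.0 for p in grid_atlas.parcels}
        scores["L_frontal_00"] = 5.0
        ranks = rank_per_hemisphere(scores, grid_atlas)
        assert ranks["L_frontal_00"] == 1

    def test_ranks_are_hemisphere_permutations(self, grid_atlas):
        rng = np.random.default_rng(1)
        scores = {p: float(rng.random()) for p in grid_atlas.parcels}
        ranks = rank_per_hemisphere(scores, grid_atlas)
        for hemi in ("left", "right"):
            members = [p for p in grid_atlas.parcels if grid_atlas.hemisphere[p] == hemi]
            assert sorted(ranks[p] for p in members) == list(range(1, len(members) + 1))

    def test_exact_tie_broken_lexicographically(self, grid_atlas):
        scores = {p: 1.0 for p in grid_atlas.parcels}
        ranks = rank_per_hemisphere(scores, grid_atlas)
        left = sorted(p for p in grid_atlas.parcels if grid_atlas.hemisphere[p] == "left")
        assert ranks[left[0]] == 1

    def test_input_order_irrelevant(self, grid_atlas):
        rng = np.random.default_rng(2)
        scores = {p: float(rng.random()) for p in grid_atlas.parcels}
        shuffled = dict(sorted(scores.items(), key=lambda kv: kv[1]))
        assert rank_per_hemisphere(scores, grid_atlas) == rank_per_hemisphere(
            shuffled, grid_atlas
        )

    def test_full_scale_global_ranks_span_379(self):
        from resectsim.synthetic_cohort import generate_atlas

        atlas = generate_atlas("full-scale")
        (c,), _ = generate_cohort(CohortConfig(n_subjects=1, atlas_spec="full-scale", seed=4), atlas=atlas)
        report = centrality_report(c, atlas)
        assert sorted(report.global_rank.values()) == list(range(1, 380))


@pytest.fixture(scope="module")
def cohort_rates(grid_atlas):
    lobe = "frontal/left"
    cfg = CohortConfig(
        n_subjects=8,
        connectotype_mix={lobe: (("L_frontal_11", 1.0),)},
        seed=17,
    )
    subjects, _ = generate_cohort(cfg, atlas=grid_atlas)
    sets = enumerate_resections(grid_atlas, lobe, 2)
    sweeps = [percolation_sweep(c, sets) for c in subjects]
    reports = {c.subject_id: centrality_report(c, grid_atlas) for c in subjects}
    return pr_prediction_rates(sweeps, reports, grid_atlas, lobe)


class TestPredictionRates:
    def test_criteria_nested(self, cohort_rates):
        assert cohort_rates.rate_worst <= cohort_rates.rate_worst_or_neighbor
        assert cohort_rates.rate_worst <= cohort_rates.rate_top3
        assert 0 <= cohort_rates.rate_worst <= 1
        assert 0 <= cohort_rates.rate_top3 <= 1

    def test_report_row_format(self, cohort_rates):
        row = cohort_rates.as_row()
        n = cohort_rates.n_subjects
        assert row["worst"].startswith(f"{cohort_rates.worst}/{n};")

    def test_perfect_predictor_scores_all_criteria(self, grid_atlas):
        """If top PR always equals the worst deletion, all rates are 100%."""
        lobe = "frontal/left"
        cfg = CohortConfig(
            n_subjects=5,
            connectotype_mix={lobe: (("L_frontal_11", 1.0),)},
            hub_boost=8.0,
            noise_sd=0.0,
            seed=23,
        )
        subjects, _ = generate_cohort(cfg, atlas=grid_atlas)
        sets = enumerate_resections(grid_atlas, lobe, 1)
        sweeps = [percolation_sweep(c, sets) for c in subjects]
        reports = {c.subject_id: centrality_report(c, grid_atlas) for c in subjects}
        rates = pr_prediction_rates(sweeps, reports, grid_atlas, lobe)
        if rates.worst == rates.n_subjects:  # strong boost: expected path
            assert rates.worst_or_neighbor == rates.n_subjects
            assert rates.top3 == rates.n_subjects

    def test_missing_report_rejected(self, grid_atlas):
        lobe = "frontal/left"
        (c,), _ = generate_cohort(CohortConfig(n_subjects=1, seed=1), atlas=grid_atlas)
        sets = enumerate_resections(grid_atlas, lobe, 1)
        sweeps = [percolation_sweep(c, sets)]
        with pytest.raises(ValueError, match="no centrality report"):
            pr_prediction_rates(sweeps, {}, grid_atlas, lobe)

    def test_format_cell_example(self):
        from resectsim.formatting import format_percent

        assert format_percent(53, 80) == "53/80; 66%"
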