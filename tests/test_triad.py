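import numpy as np
import pytest

from gdparent import (
    ConfigurationError,
    GapResult,
    SimConfig,
    TriadScores,
    declare_triads,
    encode,
    enumerate_triads,
    expected_progeny,
    find_gap,
    gower_dissimilarity,
    run_triad_analysis,
    score_triads,
    simulate_population,
)

from conftest import random_states
from gdparent.genotype import GenotypeMatrix


class TestEnumerateTriads:
    def test_all_coded_population_count_formula(self):
        ids = [f"i{x}" for x in range(3)]
        space = enumerate_triads(ids, ["All"] * 3)
        assert len(space) == 9  # n^2 (n-1) / 2 for n = 3
        assert len(space.pairs) == 3
        assert len(space.triads()) == 9

    def test_fully_specified_roster_gives_single_triad(self):
        space = enumerate_triads(["A", "B", "C"], ["Mo", "Fa", "Off"])
        assert space.triads() == [("A", "B", "C")]

    def test_pairs_deduplicated_but_oriented(self):
        space = enumerate_triads(["A", "B", "C"], ["Mo", "All", "Off"])
        # A can only mother; B can do anything; pair {A,B} appears once
        assert space.pairs == [("A", "B")]
        assert space.offspring_ids == ["B", "C"]

    def test_offspring_includes_parents_when_all(self):
        space = enumerate_triads(["A", "B"], ["All", "All"])
        assert space.offspring_ids == ["A", "B"]
        assert len(space) == 2  # (A,B) x {A, B}

    @pytest.mark.parametrize(
        "keys, missing",
        [
            (["Fa", "Fa", "Off"], "mother"),
            (["Mo", "Mo", "Off"], "father"),
            (["Mo", "Fa", "Pa"], "offspring"),
        ],
    )
    def test_empty_candidate_set_is_fatal(self, keys, missing):
        with pytest.raises(ConfigurationError, match=missing):
            enumerate_triads(["A", "B", "C"], keys)


def test_score_triads_matches_per_triad_recomputation():
    rng = np.random.default_rng(31)
    n, L = 8, 40
    gm = GenotypeMatrix(
        ids=[f"i{x}" for x in range(n)],
        class_keys=["All"] * n,
        states=random_states(rng, (n, L)),
        alleles=[("A", "C")] * L,
        locus_names=[f"L{j}" for j in range(L)],
    )
    space = enumerate_triads(gm.ids, gm.class_keys)
    scores = score_triads(gm, space)
    for p, (m, f) in enumerate(space.pairs):
        ep = expected_progeny(gm, m, f)
        for k, off in enumerate(space.offspring_ids):
            gd, usable = gower_dissimilarity(ep.states, gm.row(off))
            assert scores.usable[p, k] == usable
            if usable:
                assert scores.gd[p, k] == pytest.approx(gd)
            else:
                assert np.isnan(scores.gd[p, k])
            assert scores.self_overlap[p, k] == (off in (m, f))


class TestFindGap:
    def test_midpoint_of_widest_gap(self):
        gap = find_gap(np.array([0.001, 0.002, 0.050, 0.051]), 0.1, seed=1)
        assert gap.determinable
        assert gap.threshold == pytest.approx(0.026)
        assert gap.gap_size == pytest.approx(0.048)
        assert gap.n_below == 2

    def test_search_restricted_to_region_below_ceiling(self):
        gds = np.array([0.001, 0.002, 0.050, 0.051, 0.5, 0.9])
        gap = find_gap(gds, 0.1, seed=1)
        assert gap.threshold == pytest.approx(0.026)
        assert gap.n_in_region == 4

    def test_fewer_than_three_values_undeterminable(self):
        gap = find_gap(np.array([0.01, 0.02, 0.5, 0.6]), 0.1, seed=1)
        assert not gap.determinable

    def test_all_values_above_ceiling_undeterminable(self):
        gap = find_gap(np.array([0.2, 0.3, 0.4, 0.5]), 0.1, seed=1)
        assert not gap.determinable

    def test_uniformly_spaced_values_not_significant(self):
        gap = find_gap(np.linspace(0.0, 0.09, 30), 0.1, seed=1)
        assert gap.determinable
        assert gap.gap_p == 1.0  # all adjacent gaps identical

    def test_jittered_uniform_values_not_significant(self):
        rng = np.random.default_rng(8)
        gds = np.sort(rng.uniform(0.0, 0.099, 40))
        gap = find_gap(gds, 0.1, seed=1)
        assert gap.gap_p > 0.01

    def test_equal_maximal_gaps_resolve_to_lower(self):
        gap = find_gap(np.array([0.00, 0.04, 0.05, 0.09]), 0.1, seed=1)
        assert gap.threshold == pytest.approx(0.02)


def _toy_scores(gds, overlap=None):
    """One parent pair per GD value, a single shared offspring column."""
    gds = np.asarray(gds, dtype=float).reshape(-1, 1)
    return TriadScores(
        pairs=[(f"m{i}", f"f{i}") for i in range(gds.shape[0])],
        offspring_ids=["k"],
        gd=gds,
        usable=np.full_like(gds, 200, dtype=np.int64),
        self_overlap=(
            np.zeros_like(gds, dtype=bool) if overlap is None
            else np.asarray(overlap, dtype=bool).reshape(-1, 1)
        ),
    )


class TestDeclareTriads:
    def _scores_and_gap(self, overlap=None):
        rng = np.random.default_rng(12)
        spurious = np.sort(rng.uniform(0.05, 0.095, 40))
        gds = np.concatenate([[0.001, 0.002], spurious])
        scores = _toy_scores(gds, overlap)
        gap = find_gap(gds, 0.1, seed=4)
        return scores, gap

    def test_clear_outliers_declared(self):
        scores, gap = self._scores_and_gap()
        declared = declare_triads(scores, gap, alpha=0.01, seed=4)
        assert {r.gd for r in declared} == {0.001, 0.002}
        assert all(r.p_value <= 0.01 for r in declared)

    def test_insignificant_gap_gates_everything(self):
        scores, gap = self._scores_and_gap()
        forced = GapResult(
            determinable=True, threshold=gap.threshold, gap_size=gap.gap_size,
            gap_p=0.5, n_below=gap.n_below, n_in_region=gap.n_in_region,
            search_ceiling=0.1,
        )
        assert declare_triads(scores, forced, alpha=0.01, seed=4) == []
        assert not scores.declared.any()

    def test_borderline_value_not_declared(self):
        # below the threshold but nearly touching the above-gap cluster
        gds = np.concatenate([[0.0485], np.linspace(0.05, 0.095, 40)])
        scores = _toy_scores(gds)
        gap = GapResult(
            determinable=True, threshold=0.04925, gap_size=0.0015, gap_p=0.001,
            n_below=1, n_in_region=41, search_ceiling=0.1,
        )
        declared = declare_triads(scores, gap, alpha=0.01, seed=4)
        assert declared == []

    def test_self_overlap_never_declared(self):
        overlap = np.zeros(42, dtype=bool)
        overlap[0] = True  # the lowest GD belongs to a parent-as-offspring triad
        scores, gap = self._scores_and_gap(overlap)
        declared = declare_triads(scores, gap, alpha=0.01, seed=4)
        assert {r.gd for r in declared} == {0.002}

    def test_small_above_gap_pool_used_with_warning(self, caplog):
        gds = np.concatenate([[0.001], np.linspace(0.06, 0.09, 8)])
        scores = _toy_scores(gds)
        gap = find_gap(gds, 0.1, seed=4)
        with caplog.at_level("WARNING"):
            declared = declare_triads(
                scores, gap, alpha=0.01, comparison_sample_size=30, seed=4
            )
        assert "using all" in caplog.text
        assert [r.gd for r in declared] == [0.001]


class TestOnSimulatedPopulations:
    def test_true_trios_recovered_exactly(self, default_sim, default_triad_result):
        _, truth = default_sim
        declared = {
            (frozenset((r.mother_id, r.father_id)), r.offspring_id)
            for r in default_triad_result.declared
        }
        assert declared == truth.truth_triad_set()

    def test_no_full_sib_declared_as_parent(self, default_sim, default_triad_result):
        _, truth = default_sim
        offspring = {k for _, _, k in truth.trios}
        for r in default_triad_result.declared:
            assert r.mother_id not in offspring
            assert r.father_id not in offspring

    def test_declared_subset_of_below_threshold(self, default_triad_result):
        res = default_triad_result
        for r in res.declared:
            assert r.gd < res.gap.threshold < res.gap.search_ceiling

    def test_deterministic_given_seed(self, default_gm):
        a = run_triad_analysis(default_gm, seed=5)
        b = run_triad_analysis(default_gm, seed=5)
        assert np.array_equal(a.scores.gd, b.scores.gd, equal_nan=True)
        assert a.gap.threshold == b.gap.threshold
        assert a.gap.gap_p == b.gap.gap_p
        assert [(r.mother_id, r.father_id, r.offspring_id, r.p_value)
                for r in a.declared] == [
            (r.mother_id, r.father_id, r.offspring_id, r.p_value)
            for r in b.declared
        ]

    def test_true_trio_gd_small_but_positive_with_errors(
        self, default_sim, default_gm, default_triad_result
    ):
        """Genotyping error lifts true-trio GDs off zero, yet they stay far
        below the spurious mass."""
        _, truth = default_sim
        scores = default_triad_result.scores
        pair_index = {frozenset(p): i for i, p in enumerate(scores.pairs)}
        off_index = {k: i for i, k in enumerate(scores.offspring_ids)}
        true_gds = [
            scores.gd[pair_index[frozenset((m, f))], off_index[k]]
            for m, f, k in truth.trios
        ]
        assert all(0 <= g < 0.05 for g in true_gds)
        assert max(true_gds) > 0  # the 1% error rate lifts most trios off zero
        finite = scores.flat_gd[np.isfinite(scores.flat_gd)]
        background = np.median(finite)
        assert max(true_gds) < background / 4
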