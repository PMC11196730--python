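"""Stepwise classification, worst-by-size extraction, and frequency tables."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resectsim.cohort_patterns import (
    CATEGORIES,
    classify_stepwise,
    worst_by_size,
    worst_frequency_table,
    worst_membership_table,
)
from resectsim.percolation_engine import PercolationRecord, ResectionSweep
from resectsim.resection_enumerator import ResectionSet


def sweep_from_strata(strata, subject_id="s", lobe="x/left", k_parcels=None):
    """Build a sweep whose stratum n has the given GE values.

    ``strata``: {size -> list of GE values}.  Parcel tuples are generated so
    each set of size n is connected-agnostic filler (patterns only need GE).
    """
    records = []
    for n, ges in strata.items():
        for i, ge in enumerate(ges):
            parcels = tuple(f"p{n}_{i}_{j}" for j in range(n))
            records.append(PercolationRecord(ResectionSet(lobe, parcels), ge))
    records.sort(key=lambda r: (-r.ge, r.resection.size, r.resection.parcels))
    baseline = max((r.ge for r in records), default=1.0) + 1.0
    return ResectionSweep(subject_id, lobe, "inverse-weight", baseline, tuple(records))


class TestClassifyStepwise:
    def test_strictly_separated_strata_perfect(self):
        sweep = sweep_from_strata({n: [10.0 - n, 10.4 - n] for n in range(1, 6)})
        cls = classify_stepwise(sweep)
        assert cls.category == "perfect"
        assert all(cls.flags.values())

    def test_late_interleaving_partial(self):
        strata = {n: [10.0 - n, 10.4 - n] for n in range(1, 7)}
        strata[7] = [2.95]  # overlaps stratum 6's range
        strata[6] = [3.0, 2.9]
        cls = classify_stepwise(sweep_from_strata(strata))
        assert cls.flags[1] and cls.flags[2] and cls.flags[3]
        assert not cls.flags[6]
        assert cls.category == "partial"

    def test_everything_interleaved_non_step(self):
        sweep = sweep_from_strata({n: [5.0, 1.0] for n in range(1, 5)})
        cls = classify_stepwise(sweep)
        assert cls.category == "non-step"
        assert not any(cls.flags.values())

    def test_early_interleaving_without_partial_prefix_mixed(self):
        strata = {n: [10.0 - n, 10.4 - n] for n in range(1, 6)}
        strata[2] = [9.1, 8.3]  # dips into stratum 3's range
        strata[3] = [8.4, 7.6]
        cls = classify_stepwise(sweep_from_strata(strata))
        assert cls.category == "mixed"

    def test_equal_boundary_values_count_as_mixed_in(self):
        sweep = sweep_from_strata({1: [5.0, 4.0], 2: [4.0, 3.0], 3: [2.0], 4: [1.0]})
        cls = classify_stepwise(sweep)
        assert cls.flags[1] is False  # min S_1 == max S_2 is not stepwise

    def test_small_k_restricted_with_warning(self, caplog):
        sweep = sweep_from_strata({1: [3.0], 2: [2.0], 3: [1.0]})
        with caplog.at_level("WARNING"):
            cls = classify_stepwise(sweep)
        assert "partial" in caplog.text
        assert cls.category == "perfect"

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.booleans(), min_size=3, max_size=9))
    def test_categories_exhaustive_and_exclusive(self, flags):
        """Every flag pattern lands in exactly one category."""
        # construct strata realizing the flag pattern
        strata, level = {}, 100.0
        sizes = range(1, len(flags) + 2)
        values = {n: [level - 2 * n, level - 2 * n - 1] for n in sizes}
        for n, flag in enumerate(flags, start=1):
            if not flag:  # make max of S_{n+1} exceed min of S_n
                values[n + 1][0] = values[n][1] + 0.5
        cls = classify_stepwise(sweep_from_strata(values))
        assert cls.category in CATEGORIES
        matches = [
            all(cls.flags.values()),
            all(cls.flags.get(n, False) for n in (1, 2, 3))
            and not all(cls.flags.get(n, False) for n in range(4, max(sizes))),
            not any(cls.flags.values()),
        ]
        expected = (
            "perfect"
            if matches[0]
            else "non-step"
            if matches[2]
            else "partial"
            if matches[1]
            else "mixed"
        )
        assert cls.category == expected


class TestWorstBySize:
    def test_dominant_parcel_yields_full_nesting(self):
        records = []
        for n in (1, 2, 3):
            # sets containing "x" always have lower GE
            with_x = tuple(["x"] + [f"f{j}" for j in range(n - 1)])
            without = tuple(f"g{j}" for j in range(n))
            records += [
                PercolationRecord(ResectionSet("L", with_x), 1.0 - 0.1 * n),
                PercolationRecord(ResectionSet("L", without), 2.0 - 0.1 * n),
            ]
        sweep = ResectionSweep("s", "L", "inverse-weight", 3.0, tuple(records))
        wbs = worst_by_size(sweep)
        assert all(wbs.contains_previous.values())
        assert wbs.nesting_fraction() == 1.0

    def test_tie_broken_by_lexicographic_tuple(self):
        records = [
            PercolationRecord(ResectionSet("L", ("b", "c")), 1.0),
            PercolationRecord(ResectionSet("L", ("a", "d")), 1.0),
            PercolationRecord(ResectionSet("L", ("a",)), 2.0),
        ]
        sweep = ResectionSweep("s", "L", "inverse-weight", 3.0, tuple(records))
        assert worst_by_size(sweep).worst[2].resection.parcels == ("a", "d")

    def test_worst_ge_non_increasing_in_size(self, grid_atlas):
        """Follows from monotonicity on real sweeps of nested enumerations."""
        from resectsim.percolation_engine import percolation_sweep
        from resectsim.resection_enumerator import enumerate_resections
        from resectsim.synthetic_cohort import CohortConfig, generate_cohort

        (subject,), _ = generate_cohort(CohortConfig(n_subjects=1, seed=2), atlas=grid_atlas)
        sets = enumerate_resections(grid_atlas, "frontal/left", 4)
        wbs = worst_by_size(percolation_sweep(subject, sets))
        ges = [wbs.worst[n].ge for n in sorted(wbs.worst)]
        assert all(a >= b for a, b in itertools.pairwise(ges))


def make_wbs(subject_id, lobe, worst_parcel, extra_sizes=()):
    worst = {1: PercolationRecord(ResectionSet(lobe, (worst_parcel,)), 1.0)}
    for n, parcels in extra_sizes:
        worst[n] = PercolationRecord(ResectionSet(lobe, parcels), 1.0 - 0.1 * n)
    from resectsim.cohort_patterns import WorstBySize

    return WorstBySize(subject_id, lobe, worst, {})


class TestFrequencyTable:
    def test_counts_and_percent_cells(self):
        # 14 subjects share worst parcel "p"; the rest split between q0/q1
        cohort = [make_wbs(f"s{i}", "L", "p" if i < 14 else f"q{i % 2}") for i in range(80)]
        table = worst_frequency_table(cohort, "L", min_fraction=0.05)
        assert table.set_index("parcel").loc["p", "display"] == "14/80; 18%"
        assert table["count"].sum() == 80
        counts = list(table["count"])
        assert counts == sorted(counts, reverse=True)

    def test_single_shared_worst_parcel(self):
        cohort = [make_wbs(f"s{i}", "L", "p") for i in range(5)]
        table = worst_frequency_table(cohort, "L")
        assert len(table) == 1
        assert table.iloc[0]["display"] == "5/5; 100%"

    def test_empty_lobe_gives_empty_table(self):
        assert worst_frequency_table([], "L").empty

    def test_rare_parcels_collapse_into_other(self):
        cohort = [make_wbs(f"s{i}", "L", "p" if i < 18 else f"rare{i}") for i in range(20)]
        table = worst_frequency_table(cohort, "L", min_fraction=0.1)
        assert list(table["parcel"]) == ["p", "other"]
        assert int(table.set_index("parcel").loc["other", "count"]) == 2
        assert table["count"].sum() == 20

    def test_membership_table_counts_sequence_appearances(self):
        cohort = [
            make_wbs("s0", "L", "p", extra_sizes=[(2, ("p", "q"))]),
            make_wbs("s1", "L", "q", extra_sizes=[(2, ("q", "r"))]),
        ]
        table = worst_membership_table(cohort, "L").set_index("parcel")
        assert int(table.loc["q", "count"]) == 2  # in both subjects' sequences
        assert int(table.loc["p", "count"]) == 1
        assert int(table.loc["r", "count"]) == 1
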