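"""Froh, length-class binning, per-animal/chromosome summaries, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st


from rohpipe.summaries import (
    MODEL_SCHEME,
    TABLE_SCHEME,
    LengthClassScheme,
    bin_by_length,
    compute_froh,
    group_identical_roh,
    per_animal_summary,
    per_chromosome_summary,
)

from conftest import make_map, make_rohset


class TestFroh:
    def test_single_roh_fraction(self):
        mm = make_map([1, 2_500_000_001])  # covered span 2.5 Gb
        rs = make_rohset([("a1", 1, 1_000_000, 26_000_000)], animal_ids=["a1", "a2"])
        t = compute_froh(rs, mm)
        froh = t.froh()
        assert froh["a1"] == pytest.approx(0.01)
        assert froh["a2"] == 0.0
        assert t.table["l_aut_bp"].unique().tolist() == [2_500_000_000]

    def test_random_set_matches_recount(self, rng):
        mm = make_map(
            np.concatenate([np.sort(rng.choice(10**8, 50, replace=False)) + 1 for _ in range(3)]),
            chrom=np.repeat([1, 2, 3], 50),
        )
        animals = [f"a{k}" for k in range(8)]
        entries = []
        for k in range(60):
            a = animals[rng.integers(0, 8)]
            c = int(rng.integers(1, 4))
            s = int(rng.integers(1, 9 * 10**7))
            entries.append((a, c, s, s + int(rng.integers(10**6, 10**7))))
        rs = make_rohset(entries, animal_ids=animals)
        froh = compute_froh(rs, mm).froh()
        l_aut = mm.l_aut_bp()
        for a in animals:
            expected = sum(e[3] - e[2] for e in entries if e[0] == a) / l_aut
            assert froh[a] == pytest.approx(expected)

    def test_empty_map_errors(self):
        mm = make_map([])
        with pytest.raises(ValueError, match="empty"):
            compute_froh(make_rohset([], animal_ids=["a1"]), mm)


class TestBinning:
    @pytest.mark.parametrize(
        "mb,scheme,label",
        [
            (1.35, TABLE_SCHEME, "1-2"),
            (23.29, TABLE_SCHEME, ">16"),
            (2.0, TABLE_SCHEME, "2-4"),  # left-closed bins
            (8.0, MODEL_SCHEME, "8-16"),
            (16.0, MODEL_SCHEME, ">16"),
        ],
    )
    def test_assignment(self, mb, scheme, label):
        rs = make_rohset([("a1", 1, 10**6, 10**6 + int(mb * 1e6))])
        df = bin_by_length(rs, scheme)
        assert df.loc[df["count"] == 1, "length_class"].tolist() == [label]
        assert df.loc[df["count"] == 1, "mean_length_mb"].iloc[0] == pytest.approx(mb)

    def test_too_short_roh_errors(self):
        rs = make_rohset([("a1", 1, 10**6, 16 * 10**5)])  # 0.6 Mb
        with pytest.raises(ValueError, match="first class edge"):
            bin_by_length(rs, TABLE_SCHEME)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            LengthClassScheme(())
        with pytest.raises(ValueError):
            LengthClassScheme((1, 1))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1.0, max_value=120.0,
                              allow_nan=False), min_size=0, max_size=60))
    def test_partition_property(self, lengths_mb):
        """Every ROH lands in exactly one class under both schemes."""
        entries = [("a1", 1, 10**6, 10**6 + int(mb * 1e6)) for mb in lengths_mb]
        entries = [e for e in entries if e[3] > e[2]]
        rs = make_rohset(entries, animal_ids=["a1"])
        for scheme in (TABLE_SCHEME, MODEL_SCHEME):
            df = bin_by_length(rs, scheme)
            assert df["count"].sum() == len(entries)
            if len(entries):
                assert df["percentage"].sum() == pytest.approx(100.0, abs=1e-9)


class TestPerAnimal:
    def test_example_and_zero_roh_animals(self):
        rs = make_rohset(
            [("a1", 1, 0, 2_000_000), ("a1", 2, 0, 4_000_000)],
            animal_ids=["a1", "a2"],
        )
        df, pop = per_animal_summary(rs)
        row = df.set_index("animal_id").loc["a1"]
        assert row["n_roh"] == 2 and row["mean_length_mb"] == pytest.approx(3.0)
        a2 = df.set_index("animal_id").loc["a2"]
        assert a2["n_roh"] == 0 and np.isnan(a2["mean_length_mb"])
        assert pop["n_animals_with_roh"] == 1

    def test_empty_set(self):
        df, pop = per_animal_summary(make_rohset([], animal_ids=[]))
        assert pop["n_animals_with_roh"] == 0 and pop["mean_roh_per_animal"] == 0.0

    def test_population_sd_matches_two_pass(self, rng):
        animals = [f"a{k}" for k in range(10)]
        entries = [
            (animals[rng.integers(0, 10)], 1, s := int(rng.integers(1, 10**7)),
             s + int(rng.integers(10**6, 5 * 10**6)))
            for _ in range(40)
        ]
        rs = make_rohset(entries, animal_ids=animals)
        df, pop = per_animal_summary(rs)
        counts = df["n_roh"].to_numpy(float)
        mean = counts.sum() / len(counts)
        sd = np.sqrt(((counts - mean) ** 2).sum() / (len(counts) - 1))
        assert pop["mean_roh_per_animal"] == pytest.approx(mean)
        assert pop["sd_roh_per_animal"] == pytest.approx(sd)


class TestPerChromosome:
    def test_coverage_examples(self):
        mm = make_map([1, 100_000_001])  # 100 Mb span
        one = make_rohset([("a1", 1, 10_000_000, 20_000_000)], animal_ids=["a1"])
        df = per_chromosome_summary(one, mm)
        assert df["pct_covered"].iloc[0] == pytest.approx(10.0)
        # second animal without the ROH halves the population mean
        two = make_rohset([("a1", 1, 10_000_000, 20_000_000)], animal_ids=["a1", "a2"])
        df2 = per_chromosome_summary(two, mm)
        assert df2["pct_covered"].iloc[0] == pytest.approx(5.0)

    def test_union_oracle_on_overlapping_runs(self):
        mm = make_map([1, 100_000_001])
        rs = make_rohset(
            [("a1", 1, 10_000_000, 20_000_000), ("a1", 1, 15_000_000, 30_000_000)],
            animal_ids=["a1"],
        )
        df = per_chromosome_summary(rs, mm)
        assert df["pct_covered"].iloc[0] == pytest.approx(20.0)  # union, not sum
        assert df["n_roh"].iloc[0] == 2 and df["pct_of_total"].iloc[0] == 100.0

    def test_unknown_chromosome_errors(self):
        mm = make_map([1, 10**7])
        rs = make_rohset([("a1", 2, 1, 2_000_000)])
        with pytest.raises(ValueError, match="absent from map"):
            per_chromosome_summary(rs, mm)

    def test_bounds_on_random_sets(self, rng):
        mm = make_map(np.concatenate([[1, 10**8], [1, 5 * 10**7]]),
                      chrom=np.array([1, 1, 2, 2]))
        animals = [f"a{k}" for k in range(5)]
        entries = []
        for _ in range(30):
            c = int(rng.integers(1, 3))
            lim = 10**8 if c == 1 else 5 * 10**7
            s = int(rng.integers(1, lim - 10**6))
            entries.append((animals[rng.integers(0, 5)], c, s,
                            min(lim, s + int(rng.integers(10**6, 2 * 10**7)))))
        df = per_chromosome_summary(make_rohset(entries, animal_ids=animals), mm)
        assert ((df["pct_covered"] >= 0) & (df["pct_covered"] <= 100)).all()
        assert df["pct_of_total"].sum() == pytest.approx(100.0)


class TestGrouping:
    def test_shared_and_unique(self):
        rs = make_rohset(
            [
                ("a1", 1, 10**6, 3 * 10**6, 5, 20),
                ("a2", 1, 10**6, 3 * 10**6, 5, 20),
                ("a3", 2, 10**6, 3 * 10**6, 5, 20),
            ]
        )
        distinct, counts = group_identical_roh(rs)
        assert len(distinct) == 2
        shared = [d for d in distinct if d.carrier_count == 2][0]
        assert set(shared.carrier_ids) == {"a1", "a2"}
        assert counts == {"n_unique": 1, "n_repeated": 2}

    def test_all_distinct(self):
        rs = make_rohset([("a1", 1, 10**6, 2 * 10**6, 1, 9),
                          ("a2", 1, 10**6, 2 * 10**6, 2, 9)])
        _, counts = group_identical_roh(rs)
        assert counts == {"n_unique": 2, "n_repeated": 0}

    def test_partition_property(self, rng):
        animals = [f"a{k}" for k in range(12)]
        entries = []
        for _ in range(80):
            a = animals[rng.integers(0, 12)]
            si = int(rng.integers(0, 6))
            ei = si + int(rng.integers(5, 15))
            if any(e[0] == a and e[4] == si and e[5] == ei for e in entries):
                continue
            entries.append((a, 1, (si + 1) * 10**6, (ei + 1) * 10**6, si, ei))
        rs = make_rohset(entries, animal_ids=animals)
        distinct, counts = group_identical_roh(rs)
        assert sum(d.carrier_count for d in distinct) == len(rs)
        assert counts["n_unique"] + counts["n_repeated"] == len(rs)
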