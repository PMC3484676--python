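"""Ortholog projection, family binding rule, Venn partitions, enrichment."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from regulonkit.conserve import (
    OrthologMap,
    category_enrichment,
    family_bound_in_both,
    map_fly_to_human,
    overlap_table,
    venn_partition,
)


def make_map(links):
    return OrthologMap(links=[(f, h, None) for f, h in links])


class TestMapFlyToHuman:
    def test_empty_fly_set(self):
        omap = make_map([("f1", "h1")])
        assert map_fly_to_human([], omap).human_genes == set()

    def test_fanout_counts(self):
        omap = make_map([("f1", "h1"), ("f1", "h2"), ("f1", "h3")])
        proj = map_fly_to_human(["f1"], omap)
        assert proj.human_genes == {"h1", "h2", "h3"}
        assert proj.multiplicity == {"f1": 3}

    def test_union_over_targets_with_known_fanout(self):
        rng = np.random.default_rng(1)
        links, expected = [], {}
        for i in range(40):
            fly = f"f{i}"
            humans = {f"h{i}_{j}" for j in range(int(rng.integers(0, 4)))}
            links += [(fly, h) for h in humans]
            expected[fly] = humans
        omap = make_map(links)
        targets = [f"f{i}" for i in range(0, 40, 2)]
        proj = map_fly_to_human(targets, omap)
        union = set().union(*(expected[t] for t in targets))
        assert proj.human_genes == union
        assert set(proj.no_ortholog) == {t for t in targets if not expected[t]}


class TestFamilyRule:
    def test_fly_only_binding_excluded(self):
        omap = make_map([("f1", "h1")])
        assert family_bound_in_both({"f1"}, set(), omap) == set()

    def test_one_member_per_species_suffices(self):
        # family of 3 fly and 2 human genes; one bound on each side qualifies
        omap = make_map(
            [("f1", "h1"), ("f2", "h1"), ("f3", "h1"), ("f1", "h2")]
        )
        fams = family_bound_in_both({"f2"}, {"h2"}, omap)
        assert len(fams) == 1

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            links = [
                (f"f{int(rng.integers(12))}", f"h{int(rng.integers(12))}")
                for _ in range(int(rng.integers(1, 25)))
            ]
            omap = make_map(links)
            fly_bound = {f"f{i}" for i in rng.choice(12, 4, replace=False)}
            human_bound = {f"h{i}" for i in rng.choice(12, 4, replace=False)}
            got = family_bound_in_both(fly_bound, human_bound, omap)
            expected = set()
            for fam, (flies, humans) in omap.family_members().items():
                if any(f in fly_bound for f in flies) and any(h in human_bound for h in humans):
                    expected.add(fam)
            assert got == expected

    def test_monotone_under_added_binding(self):
        rng = np.random.default_rng(3)
        links = [(f"f{int(rng.integers(10))}", f"h{int(rng.integers(10))}") for _ in range(20)]
        omap = make_map(links)
        small = family_bound_in_both({"f1"}, {"h1"}, omap)
        big = family_bound_in_both({"f1", "f2", "f3"}, {"h1", "h2"}, omap)
        assert small <= big

    def test_inconsistent_explicit_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            OrthologMap(links=[("f1", "h1", "famA"), ("f1", "h2", "famB")])


class TestVenn:
    def test_disjoint_sets(self):
        table = overlap_table({"a", "b"}, {"c1": {"x"}, "c2": {"y"}})
        assert table.per_condition == {"c1": 0, "c2": 0}

    def test_subset_overlap_is_full(self):
        table = overlap_table({"a", "b"}, {"c1": {"a", "b", "z"}})
        assert table.per_condition["c1"] == 2

    def test_partition_matches_bitvector_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            names = ["s1", "s2", "s3"]
            pool = [f"g{i}" for i in range(100)]
            sets = {
                nm: set(rng.choice(pool, size=int(rng.integers(0, 60)), replace=False))
                for nm in names
            }
            got = venn_partition(sets)
            # independent oracle: set algebra per membership pattern
            expected = {}
            for r in range(1, 4):
                for inside in itertools.combinations(names, r):
                    outside = [nm for nm in names if nm not in inside]
                    region = set.intersection(*(sets[nm] for nm in inside))
                    for nm in outside:
                        region = region - sets[nm]
                    if region:
                        expected[frozenset(inside)] = len(region)
            assert got == expected
            assert sum(got.values()) == len(set().union(*sets.values()))

    def test_guard_refuses_more_than_five_sets(self):
        sets = {f"s{i}": {"g"} for i in range(6)}
        with pytest.raises(ValueError, match="5"):
            venn_partition(sets)

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_table(set(), {"c": {"x"}})


class TestCategoryEnrichment:
    def test_subset_equal_universe_gives_unit_folds(self):
        universe = {f"g{i}" for i in range(30)}
        cats = {g: ["A" if i % 2 else "B"] for i, g in enumerate(sorted(universe))}
        df = category_enrichment(universe, universe, cats)
        assert np.allclose(df["fold"], 1.0)

    def test_closed_form_hypergeometric_tail(self):
        # N=20 genes, K=4 in the category, n=10 drawn, all k=4 in the subset:
        # P(X >= 4) = C(4,4) C(16,6) / C(20,10)
        universe = [f"g{i}" for i in range(20)]
        subset = universe[:10]
        cats = {g: ["cat"] for g in universe[:4]}
        df = category_enrichment(subset, universe, cats).set_index("category")
        expected_p = comb(16, 6) / comb(20, 10)
        assert df.loc["cat", "p_hyper"] == pytest.approx(expected_p, rel=1e-12)
        assert df.loc["cat", "fold"] == pytest.approx(2.0)
        assert not df.loc["cat", "depleted"]

    def test_hypergeom_matches_exact_tail_summation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            big_n = int(rng.integers(20, 500))
            big_k = int(rng.integers(1, big_n))
            n = int(rng.integers(1, big_n))
            universe = [f"g{i}" for i in range(big_n)]
            subset = list(rng.choice(universe, size=n, replace=False))
            cat_genes = set(rng.choice(universe, size=big_k, replace=False))
            cats = {g: ["c"] for g in cat_genes}
            df = category_enrichment(subset, universe, cats).set_index("category")
            k = len(cat_genes & set(subset))
            exact = sum(
                comb(big_k, j, exact=True) * comb(big_n - big_k, n - j, exact=True)
                for j in range(k, min(big_k, n) + 1)
            ) / comb(big_n, n, exact=True)
            assert df.loc["c", "p_hyper"] == pytest.approx(exact, rel=1e-9)

    def test_shuffled_labels_rarely_significant(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(200)]
        subset = universe[:50]
        n_sig = n_tot = 0
        for _ in range(30):
            shuffled = rng.permutation(universe)
            cats = {}
            for i, g in enumerate(shuffled):
                cats.setdefault(g, []).append(f"cat{i % 8}")
            df = category_enrichment(subset, universe, cats)
            n_sig += int((df["q_bh"] < 0.05).sum())
            n_tot += len(df)
        assert n_sig / n_tot < 0.05

    def test_subset_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            category_enrichment({"x"}, {"y"}, {})


def test_explicit_family_ids_respected():
    omap = OrthologMap(links=[("f1", "h1", "famA"), ("f2", "h2", "famB")])
    assert omap.family_of_fly("f1") == "famA"
    assert family_bound_in_both({"f1"}, {"h2"}, omap) == set()
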