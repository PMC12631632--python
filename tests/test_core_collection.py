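import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ssrcore.core_collection import (
    LdssConfig,
    build_ladder,
    ldss_reduce,
    retention_rate,
    select_core,
    validate_core,
)
from ssrcore.datasets import reference_core_ladder
from ssrcore.genotype_io import to_binary_matrix
from ssrcore.synthetic_data import SimConfig, simulate_dataset
from ssrcore.tree_ordination import genetic_distance
from conftest import make_ds


# ---------------------------------------------------------------------------
# independent brute-force oracle of the greedy rule
# ---------------------------------------------------------------------------


def oracle_reduce(ds, distance, target_size):
    """Straight-line re-implementation of the stepwise rule, working directly
    on band sets with nested loops (no shared code with the package path)."""
    kept = sorted(ds.accession_ids)
    D = distance

    def unique_count(acc, members):
        count = 0
        for locus in ds.locus_ids:
            for allele in ds.band(acc, locus):
                carried_elsewhere = any(
                    allele in ds.band(other, locus)
                    for other in members
                    if other != acc
                )
                if not carried_elsewhere:
                    count += 1
        return count

    while len(kept) > target_size:
        best_pair, best_d = None, math.inf
        for x, y in itertools.combinations(kept, 2):
            d = D.loc[x, y]
            if d < best_d - 1e-12 or (
                abs(d - best_d) <= 1e-12 and (best_pair is None or (x, y) < best_pair)
            ):
                best_pair, best_d = (x, y), min(d, best_d)
        a, b = best_pair
        ua, ub = unique_count(a, kept), unique_count(b, kept)
        if ua < ub:
            victim = a
        elif ub < ua:
            victim = b
        else:
            rest = [z for z in kept if z not in (a, b)]
            ma = np.mean([D.loc[a, z] for z in rest]) if rest else 0.0
            mb = np.mean([D.loc[b, z] for z in rest]) if rest else 0.0
            if abs(ma - mb) > 1e-12:
                victim = a if ma < mb else b
            else:
                victim = max(a, b)
        kept.remove(victim)
    return [x for x in ds.accession_ids if x in set(kept)]


def random_small_ds(rng, n_acc, n_loci=4):
    cells = {}
    for i in range(n_acc):
        cells[f"x{i:02d}"] = {
            f"L{j}": set(
                rng.choice([100, 102, 104, 106], size=rng.integers(1, 3), replace=False)
            )
            for j in range(n_loci)
        }
    return make_ds(cells)


class TestLdssReduce:
    def test_duplicate_removed_distinct_kept(self):
        ds = make_ds(
            {
                "a1": {"S1": {100}},
                "a2": {"S1": {100}},
                "zz": {"S1": {104}},
            }
        )
        d = genetic_distance(to_binary_matrix(ds))
        kept = ldss_reduce(ds, d, 2)
        assert "zz" in kept and len(kept) == 2

    def test_target_equals_n_is_identity(self, small_sim):
        ds, _ = small_sim
        d = genetic_distance(to_binary_matrix(ds))
        assert ldss_reduce(ds, d, ds.n_accessions) == ds.accession_ids

    def test_deterministic_across_runs(self, rng):
        ds = random_small_ds(rng, 12)
        d = genetic_distance(to_binary_matrix(ds))
        assert ldss_reduce(ds, d, 5) == ldss_reduce(ds, d, 5)

    def test_matches_brute_force_oracle_small_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            ds = random_small_ds(rng, n)
            d = genetic_distance(to_binary_matrix(ds))
            target = int(rng.integers(2, n))
            assert ldss_reduce(ds, d, target) == oracle_reduce(ds, d, target)

    def test_beats_random_subsets_on_allele_retention(self):
        rng = np.random.default_rng(5)
        ds = random_small_ds(rng, 10, n_loci=5)
        d = genetic_distance(to_binary_matrix(ds))
        kept = ldss_reduce(ds, d, 5)

        def allele_count(members):
            return sum(
                len(set().union(*(ds.band(a, l) for a in members)))
                for l in ds.locus_ids
            )

        ldss_count = allele_count(kept)
        ids = ds.accession_ids
        for _ in range(200):
            subset = list(rng.choice(ids, size=5, replace=False))
            assert ldss_count >= allele_count(subset)

    def test_degenerate_all_equal_distances_terminates(self):
        ds = make_ds({f"a{i}": {"S1": {100 + 2 * i}} for i in range(5)})
        labels = ds.accession_ids
        d = pd.DataFrame(1.0 - np.eye(5), index=labels, columns=labels)
        kept = ldss_reduce(ds, d, 2)
        assert len(kept) == 2

    def test_bad_target_size_rejected(self, small_sim):
        ds, _ = small_sim
        d = genetic_distance(to_binary_matrix(ds))
        with pytest.raises(ValueError):
            ldss_reduce(ds, d, 1)


@pytest.fixture(scope="module")
def ladder():
    cfg = SimConfig(n_species=2, pops_per_species=3, accessions_per_pop=7,
                    n_loci=10, inbreeding_f=1.0, missing_rate=0.05, seed=13)
    ds, _ = simulate_dataset(cfg)
    return build_ladder(ds, LdssConfig(target_ratios=(0.6, 0.4, 0.2)))


class TestLadder:
    def test_nested_membership(self, ladder):
        prev = set(ladder.original.members)
        for step in ladder.steps:
            assert set(step.members) <= prev
            prev = set(step.members)

    def test_ra_monotone_non_increasing(self, ladder):
        ras = [ladder.original.ra] + [s.ra for s in ladder.steps]
        assert all(a >= b for a, b in zip(ras, ras[1:]))
        assert ladder.original.ra == 100.0

    def test_sizes_follow_rounding_rule(self, ladder):
        n = ladder.original.size
        expected = [int(math.floor(r * n + 0.5)) for r in (0.6, 0.4, 0.2)]
        assert [s.size for s in ladder.steps] == expected

    def test_explicit_size_override(self):
        cfg = LdssConfig(target_ratios=(0.59, 0.45), sizes=(103, 78))
        assert cfg.resolved_sizes(175) == [103, 78]
        default = LdssConfig(target_ratios=(0.59, 0.45, 0.35, 0.24, 0.13))
        assert default.resolved_sizes(175) == [103, 79, 61, 42, 23]

    def test_single_full_ratio_is_whole_collection(self, small_sim):
        ds, _ = small_sim
        ladder = build_ladder(ds, LdssConfig(target_ratios=(1.0,)))
        step = ladder.steps[0]
        assert step.members == ds.accession_ids
        assert step.ra == 100.0

    def test_frame_layout(self, ladder):
        frame = ladder.to_frame()
        assert list(frame.columns) == ["size", "ratio", "N", "Na", "Ne", "I", "Ho", "He", "Ra"]
        assert frame.index[0] == "Original"


class TestRetention:
    @pytest.mark.parametrize(
        "core_na, orig_na, expected",
        [(4.347, 5.139, 84.59), (5.139, 5.139, 100.00), (2.375, 5.139, 46.22)],
    )
    def test_percentage_arithmetic(self, core_na, orig_na, expected):
        assert retention_rate(core_na, orig_na) == expected

    def test_zero_original_is_an_error(self):
        with pytest.raises(ValueError):
            retention_rate(1.0, 0.0)


class TestSelection:
    def test_dominating_step_selected(self):
        ladder = reference_core_ladder()
        chosen = select_core(ladder)
        assert chosen.size == 78  # the 45% rung maximizes He, I and Ne

    def test_monotone_decreasing_diversity_keeps_largest(self):
        ladder = reference_core_ladder()
        for k, step in enumerate(ladder.steps):
            step.summary = step.summary.copy()
            step.summary["He"] = 0.9 - 0.1 * k
            step.summary["I"] = 1.0 - 0.1 * k
            step.summary["Ne"] = 3.0 - 0.1 * k
        assert select_core(ladder) is ladder.steps[0]


class TestValidation:
    def test_core_equal_to_collection_is_indistinguishable(self, small_sim):
        ds, _ = small_sim
        v = validate_core(ds, ds.accession_ids)
        assert (v.tests["t"] == 0.0).all()
        assert (v.tests["p"] == 1.0).all()
        assert v.membership.all()

    def test_removing_exact_duplicates_is_non_significant(self):
        rng = np.random.default_rng(2)
        base = random_small_ds(rng, 12, n_loci=6)
        # append exact duplicates of the first three accessions
        cells = {a: {l: set(base.band(a, l)) for l in base.locus_ids}
                 for a in base.accession_ids}
        for i in range(3):
            cells[f"dup{i}"] = dict(cells[f"x{i:02d}"])
        ds = make_ds(cells)
        core = [a for a in ds.accession_ids if not a.startswith("dup")]
        v = validate_core(ds, core)
        assert (v.tests["p"] > 0.05).all()

    def test_single_locus_dataset_rejected(self):
        ds = make_ds({"a1": {"S1": {100}}, "a2": {"S1": {102}}, "a3": {"S1": {104}}})
        with pytest.raises(ValueError, match="loci"):
            validate_core(ds, ["a1", "a2"])

    def test_core_tree_is_valid_newick(self, small_sim):
        from ssrcore.tree_ordination import read_newick

        ds, _ = small_sim
        core = ds.accession_ids[: ds.n_accessions // 2]
        v = validate_core(ds, core)
        tree = read_newick(v.core_tree_newick)
        assert {t.name for t in tree.tips()} == set(core)
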