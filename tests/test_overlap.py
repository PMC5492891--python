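"""Symbol harmonisation, Venn partitioning, Fisher and permutation tests."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rbptargets.overlap import (
    GeneSet,
    GeneUniverse,
    IdMappingTable,
    VennPartition,
    build_common_background,
    expected_overlaps,
    fisher_overlap,
    permutation_overlap,
    resolve_ids,
    restrict_to_background,
    venn_partition,
)


# ---------------------------------------------------------------------------
# universes, sets, backgrounds
# ---------------------------------------------------------------------------

def test_common_background_case_folds_and_intersects():
    bg = build_common_background(["Map1b", "Actb"], ["MAP1B", "GAPDH"])
    assert bg.symbols == {"MAP1B"}


def test_common_background_identical_universes():
    bg = build_common_background(["A", "B", "C"], ["a", "b", "c"])
    assert bg.symbols == {"A", "B", "C"}


def test_common_background_excludes_case_fold_collisions():
    # "ABC" and "Abc" collide after folding within the first universe
    bg = build_common_background(["ABC", "Abc", "XYZ"], ["abc", "xyz"])
    assert bg.symbols == {"XYZ"}


def test_restrict_to_background():
    universe = GeneUniverse(["A", "B", "C", "D"])
    assert restrict_to_background(GeneSet("s", ["x", "y"]), universe).size == 0
    assert restrict_to_background(GeneSet("s", ["a", "b"]), universe).symbols == {"A", "B"}
    ten = GeneSet("s", ["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"])
    assert restrict_to_background(ten, universe).size == 4


# ---------------------------------------------------------------------------
# identifier resolution
# ---------------------------------------------------------------------------

@pytest.fixture
def mapping_table():
    rows = [
        # ens, entrez, symbol, refseq, type
        ("ENS1", "101", "GENEA", "NM_001", "mRNA"),      # clean 1:1
        ("ENS2", "102", "GENEB", "NM_002", "mRNA"),      # ENS2 -> two entrez:
        ("ENS2", "103", "MIR102", "NR_003", "miRNA"),    #   one mRNA + one miRNA
        ("ENS3", "104", "GENEC", "NM_004", "mRNA"),      # ENS3 -> two mRNAs
        ("ENS3", "105", "GENED", "NM_005", "mRNA"),
        ("", "106", "GENEE", "NM_006", "mRNA"),          # symbol-only route
    ]
    return IdMappingTable(
        pd.DataFrame(rows, columns=["ensembl", "entrez", "symbol", "refseq", "gene_type"])
    )


def test_resolve_one_to_one_ensembl(mapping_table):
    frame, audit = resolve_ids([{"ensembl": "ENS1"}], mapping_table)
    assert list(frame["entrez"]) == ["101"]
    assert audit["ensembl_1to1"] == 1


def test_resolve_multi_match_keeps_single_mrna(mapping_table):
    frame, audit = resolve_ids([{"ensembl": "ENS2"}], mapping_table)
    assert list(frame["entrez"]) == ["102"]
    assert audit["mrna_filter"] == 1


def test_resolve_falls_back_to_symbol_then_refseq(mapping_table):
    frame, audit = resolve_ids(
        [{"symbol": "GENEE"}, {"refseq": "NM_006"}], mapping_table
    )
    assert audit["symbol_unique"] == 1 and audit["refseq_unique"] == 1
    assert audit["duplicate_entrez_dropped"] == 1  # both resolve to 106


def test_resolve_ambiguous_two_gene_record_dropped(mapping_table):
    # ENS3 maps to two mRNA genes and carries no disambiguating keys
    frame, audit = resolve_ids([{"ensembl": "ENS3"}], mapping_table)
    assert frame.empty and audit["unresolved"] == 1


def test_resolve_unknown_record_dropped(mapping_table):
    frame, audit = resolve_ids([{"ensembl": "ENS99"}], mapping_table)
    assert frame.empty and audit["unresolved"] == 1


def test_empty_mapping_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        IdMappingTable(pd.DataFrame(columns=list(IdMappingTable.COLUMNS)))


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

def test_venn_partition_hand_case():
    part = venn_partition(
        GeneSet("a", ["x", "y", "z"]), GeneSet("b", ["y", "z", "w"]), GeneSet("c", ["z"])
    )
    assert part.region_counts() == {
        "a_only": 1, "b_only": 1, "c_only": 0,
        "ab_only": 1, "ac_only": 0, "bc_only": 0, "abc": 1,
    }
    assert (part.ab, part.ac, part.bc) == (2, 1, 1)
    assert part.union_size == 4


def test_venn_partition_disjoint_sets():
    part = venn_partition(
        GeneSet("a", ["p"]), GeneSet("b", ["q"]), GeneSet("c", ["r"])
    )
    assert part.ab == part.ac == part.bc == part.abc == 0
    assert part.union_size == 3


def test_venn_pairwise_totals_consistent_on_random_sets(rng):
    universe = [f"G{i}" for i in range(200)]
    for _ in range(50):
        sets = [
            GeneSet(label, rng.choice(universe, size=int(rng.integers(0, 80)),
                                      replace=False))
            for label in "abc"
        ]
        part = venn_partition(*sets)
        assert part.ab == part.ab_only + part.abc
        assert part.ac == part.ac_only + part.abc
        assert part.bc == part.bc_only + part.abc
        assert part.union_size == len(sets[0].symbols | sets[1].symbols | sets[2].symbols)
        assert (part.size_a, part.size_b, part.size_c) == tuple(len(s) for s in sets)


def test_negative_region_counts_rejected():
    with pytest.raises(ValueError):
        VennPartition(-1, 0, 0, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _exact_tail(N, K, n, k):
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def test_fisher_small_case_exact_fraction():
    res = fisher_overlap(10, 4, 5, 3)
    assert res.p_value == pytest.approx(66 / 252, rel=1e-12)
    assert res.expected == pytest.approx(2.0)


def test_fisher_zero_overlap_gives_one():
    assert fisher_overlap(100, 10, 20, 0).p_value == 1.0


def test_fisher_minimal_achievable_overlap_gives_one():
    # K + n > N forces an overlap of at least K + n - N
    assert fisher_overlap(10, 7, 8, 5).p_value == 1.0


def test_fisher_extreme_tail_is_representable():
    res = fisher_overlap(16760, 821, 3130, 821)
    assert 0 < res.p_value or res.log10_p < -300


def test_fisher_argument_validation():
    with pytest.raises(ValueError):
        fisher_overlap(10, 12, 5, 3)
    with pytest.raises(ValueError):
        fisher_overlap(10, 4, 5, 5)


def test_fisher_monotone_nonincreasing_in_k(rng):
    for _ in range(20):
        N = int(rng.integers(10, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        last = 1.0
        for k in range(max(0, K + n - N), min(K, n) + 1):
            p = fisher_overlap(N, K, n, k).p_value
            assert p <= last + 1e-12
            last = p


def test_fisher_matches_exact_enumeration_sampled_grid(rng):
    for _ in range(300):
        N = int(rng.integers(1, 41))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        expected = float(_exact_tail(N, K, n, k))
        assert fisher_overlap(N, K, n, k).p_value == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_permutation_reproducible_and_audited():
    obs = VennPartition(0, 0, 0, 2, 0, 0, 0)
    a = permutation_overlap(50, (10, 10, 10), obs, n_perm=500, seed=42)
    b = permutation_overlap(50, (10, 10, 10), obs, n_perm=500, seed=42)
    assert a.empirical_p == b.empirical_p
    assert a.null_exceed_counts == b.null_exceed_counts
    for region, r in a.null_exceed_counts.items():
        assert a.empirical_p[region] == r / 500


def test_permutation_observed_zero_gives_one_with_ties():
    obs = VennPartition(0, 0, 0, 0, 0, 0, 0)
    res = permutation_overlap(30, (5, 5, 5), obs, n_perm=200, seed=0,
                              include_ties=True)
    assert all(p == 1.0 for p in res.empirical_p.values())


def test_permutation_add_one_convention():
    obs = VennPartition(0, 0, 0, 50, 0, 0, 0)  # unreachable: r = 0
    res = permutation_overlap(60, (10, 10, 10), obs, n_perm=100, seed=3, add_one=True)
    assert res.empirical_p["ab_only"] == pytest.approx(1 / 101)


def test_permutation_size_validation():
    with pytest.raises(ValueError):
        permutation_overlap(10, (12, 3, 3), VennPartition(0, 0, 0, 0, 0, 0, 0), 10, 0)


def _enumerate_exact_tails(N, sizes, observed):
    """Exhaustive tail probabilities over every (A, B, C) subset triple."""
    universe = range(N)
    ka, kb, kc = sizes
    totals = {key: 0 for key in ("ab_only", "ac_only", "bc_only", "abc")}
    n_outcomes = 0
    for a in itertools.combinations(universe, ka):
        sa = set(a)
        for b in itertools.combinations(universe, kb):
            sb = set(b)
            ab = sa & sb
            for c in itertools.combinations(universe, kc):
                sc = set(c)
                abc = len(ab & sc)
                counts = {
                    "ab_only": len(ab) - abc,
                    "ac_only": len(sa & sc) - abc,
                    "bc_only": len(sb & sc) - abc,
                    "abc": abc,
                }
                n_outcomes += 1
                for key, obs in observed.items():
                    if counts[key] > obs:
                        totals[key] += 1
    return {key: totals[key] / n_outcomes for key in totals}, n_outcomes


def test_permutation_matches_exhaustive_enumeration_tiny_universe():
    """N=8, sizes (3,3,2): empirical tails vs full enumeration of all
    C(8,3)^2 * C(8,2) outcome triples, within 3 Monte-Carlo SDs."""
    observed = {"ab_only": 1, "ac_only": 1, "bc_only": 1, "abc": 1}
    exact, n_outcomes = _enumerate_exact_tails(8, (3, 3, 2), observed)
    assert n_outcomes == comb(8, 3) ** 2 * comb(8, 2)
    obs_part = VennPartition(0, 0, 0, 1, 1, 1, 1)
    n_perm = 200_000
    res = permutation_overlap(8, (3, 3, 2), obs_part, n_perm=n_perm, seed=11)
    for region, p_exact in exact.items():
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.empirical_p[region] - p_exact) <= 3 * mc_sd, region


def test_null_moments_match_analytic_expectations():
    N, sizes = 400, (40, 60, 30)
    res = permutation_overlap(
        N, sizes, VennPartition(0, 0, 0, 0, 0, 0, 0), n_perm=20_000, seed=5
    )
    expect = expected_overlaps(N, sizes)
    for region in ("ab_only", "ac_only", "bc_only", "abc"):
        se = res.null_sd[region] / np.sqrt(res.n_perm)
        assert abs(res.null_mean[region] - expect[region]) <= 3 * se, region


def test_expected_overlaps_formulas():
    expect = expected_overlaps(100, (10, 10, 10))
    assert expect["ab"] == pytest.approx(1.0)
    # E[triple] = 10*10*10 / 100^2 under independent uniform draws
    assert expect["abc"] == pytest.approx(0.1)
    assert expect["ab_only"] == pytest.approx(0.9)
    zero = expected_overlaps(100, (0, 10, 10))
    assert zero["ab"] == 0 and zero["abc"] == 0
    with pytest.raises(ValueError):
        expected_overlaps(10, (20, 1, 1))
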