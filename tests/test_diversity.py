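"""Diversity statistics: H_S, PL, rarefied richness against brute-force oracles."""

import itertools

import numpy as np
import pytest

from popgen.diversity import (
    DiversityError,
    allelic_richness,
    diversity_table,
    gene_diversity,
    nucleotide_diversity,
    polymorphic_fraction,
    private_allelic_richness,
)
from popgen.io import MISSING

from conftest import make_matrix


# ---------------------------------------------------------------------------
# brute-force rarefaction oracles (exhaustive subsample enumeration)


def oracle_richness(alleles: list[int], g_size: int) -> float:
    """Mean number of distinct alleles over all subsamples of size g_size."""
    counts = [len(set(sub)) for sub in itertools.combinations(alleles, g_size)]
    return float(np.mean(counts))


def oracle_private(unit_alleles: dict[str, list[int]], focal: str, g_size: int) -> float:
    """Mean count of alleles present in the focal subsample and absent from
    every other unit's subsample, over all joint subsample combinations."""
    names = list(unit_alleles)
    pools = [list(itertools.combinations(unit_alleles[u], g_size)) for u in names]
    f = names.index(focal)
    total, n_comb = 0.0, 0
    for combo in itertools.product(*pools):
        others = set(itertools.chain.from_iterable(c for i, c in enumerate(combo) if i != f))
        total += len(set(combo[f]) - others)
        n_comb += 1
    return total / n_comb


class TestGeneDiversity:
    def test_monomorphic_locus_is_zero(self):
        g = make_matrix([[0], [0], [0]])
        mean, se, per = gene_diversity(g)
        assert mean == 0.0 and per.tolist() == [0.0]

    def test_two_sample_half_and_unbiased(self):
        g = make_matrix([[0], [1]])
        plain, _, _ = gene_diversity(g, estimator="plain")
        unbiased, _, _ = gene_diversity(g, estimator="unbiased")
        assert plain == pytest.approx(0.5)
        assert unbiased == pytest.approx(1.0)

    def test_plain_never_exceeds_unbiased(self, rng):
        calls = rng.integers(0, 2, size=(8, 20)).astype(np.int8)
        g = make_matrix(calls.tolist())
        p, _, _ = gene_diversity(g, estimator="plain")
        u, _, _ = gene_diversity(g, estimator="unbiased")
        assert p <= u + 1e-12

    def test_single_sample_unit_rejected(self):
        g = make_matrix([[0], [1]])
        with pytest.raises(DiversityError):
            gene_diversity(g, unit=["s1"])


class TestPolymorphicFraction:
    def test_polymorphism_scored_within_unit(self):
        # L2 is polymorphic overall but monomorphic within {s2, s3}
        g = make_matrix([[0, 0], [0, 1], [1, 1]])
        assert polymorphic_fraction(g, unit=["s2", "s3"]) == pytest.approx(50.0)
        assert polymorphic_fraction(g) == pytest.approx(100.0)

    def test_fixed_population_zero(self):
        g = make_matrix([[0, 1]] * 4, pops=["p"] * 4)
        assert polymorphic_fraction(g) == 0.0


class TestRarefaction:
    @pytest.mark.parametrize("n1,n,g_size", [(2, 4, 2), (1, 5, 3), (3, 8, 4), (0, 6, 2)])
    def test_richness_matches_enumeration(self, n1, n, g_size):
        alleles = [1] * n1 + [0] * (n - n1)
        g = make_matrix([[a] for a in alleles])
        units = {"u": [f"s{i + 1}" for i in range(n)]}
        got, _ = allelic_richness(g, units, g_size)["u"]
        assert got == pytest.approx(oracle_richness(alleles, g_size), abs=1e-12)

    def test_richness_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 9))
            alleles = rng.integers(0, 2, size=n).tolist()
            g_size = int(rng.integers(1, n + 1))
            g = make_matrix([[a] for a in alleles])
            got, _ = allelic_richness(g, {"u": [f"s{i + 1}" for i in range(n)]}, g_size)["u"]
            assert got == pytest.approx(oracle_richness(alleles, g_size), abs=1e-12)

    def test_richness_at_full_size_counts_observed_alleles(self):
        g = make_matrix([[0], [1], [1], [1]])
        got, _ = allelic_richness(g, {"u": ["s1", "s2", "s3", "s4"]}, g_size=4)["u"]
        assert got == pytest.approx(2.0)

    def test_monomorphic_locus_rarefies_to_one(self):
        g = make_matrix([[1], [1], [1]])
        got, _ = allelic_richness(g, {"u": ["s1", "s2", "s3"]}, g_size=2)["u"]
        assert got == pytest.approx(1.0)

    def test_private_two_units_with_exclusive_allele(self):
        # unit A carries the only copies of allele 1
        unit_alleles = {"A": [1, 1, 0], "B": [0, 0, 0]}
        g = make_matrix([[a] for a in unit_alleles["A"] + unit_alleles["B"]])
        units = {"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]}
        rp = private_allelic_richness(g, units, g_size=2)
        assert rp["A"][0] == pytest.approx(oracle_private(unit_alleles, "A", 2), abs=1e-12)
        assert rp["B"][0] == pytest.approx(oracle_private(unit_alleles, "B", 2), abs=1e-12)

    def test_private_random_instances_match_oracle(self, rng):
        for _ in range(10):
            ua = {
                "A": rng.integers(0, 2, size=int(rng.integers(2, 6))).tolist(),
                "B": rng.integers(0, 2, size=int(rng.integers(2, 6))).tolist(),
            }
            g_size = int(min(len(ua["A"]), len(ua["B"])))
            g_size = int(rng.integers(1, g_size + 1))
            g = make_matrix([[a] for a in ua["A"] + ua["B"]])
            units = {
                "A": [f"s{i + 1}" for i in range(len(ua["A"]))],
                "B": [f"s{i + 1 + len(ua['A'])}" for i in range(len(ua["B"]))],
            }
            rp = private_allelic_richness(g, units, g_size)
            for u in ("A", "B"):
                assert rp[u][0] == pytest.approx(oracle_private(ua, u, g_size), abs=1e-12)

    def test_shared_fixed_allele_contributes_nothing(self):
        g = make_matrix([[1]] * 6)
        units = {"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]}
        rp = private_allelic_richness(g, units, g_size=2)
        assert rp["A"][0] == pytest.approx(0.0)

    def test_identical_allele_sets_have_zero_private(self, rng):
        calls = rng.integers(0, 2, size=(4, 10)).astype(np.int8)
        calls = np.vstack([calls, calls])  # two units with identical compositions
        g = make_matrix(calls.tolist())
        units = {"A": [f"s{i + 1}" for i in range(4)], "B": [f"s{i + 5}" for i in range(4)]}
        rp = private_allelic_richness(g, units, g_size=4)
        # equal allele sets in both units: privacy only via rarefaction loss
        got_a = rp["A"][0]
        per_locus_priv = []
        for j in range(10):
            ua = {"A": calls[:4, j].tolist(), "B": calls[4:, j].tolist()}
            per_locus_priv.append(oracle_private(ua, "A", 4))
        assert got_a == pytest.approx(np.mean(per_locus_priv), abs=1e-12)

    def test_private_needs_two_units(self):
        g = make_matrix([[0], [1]])
        with pytest.raises(DiversityError):
            private_allelic_richness(g, {"A": ["s1", "s2"]}, 1)


class TestDiversityTable:
    def test_small_unit_gets_placeholder_row(self):
        g = make_matrix([[0, 1], [1, 0], [0, 0]], pops=["p1", "p1", "p2"])
        recs = diversity_table(g, {"p1": ["s1", "s2"], "p2": ["s3"]})
        by_unit = {r.unit: r for r in recs}
        assert by_unit["p2"].H_S is None  # '-' entry for N=1 units
        assert by_unit["p1"].N_H == 2
        assert 0 <= by_unit["p1"].PL <= 100


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        res = nucleotide_diversity(["ACGT" * 25] * 3)
        assert res.pi_all == 0.0
        assert res.n_polymorphisms == 0

    def test_single_difference_over_100_sites(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        res = nucleotide_diversity([a, b])
        assert res.pi_all == pytest.approx(0.01)
        assert res.n_polymorphisms == 1

    def test_gaps_excluded_pairwise(self):
        # the gap column is skipped for pairs involving seq b only
        res = nucleotide_diversity(["AAAA", "AAA-", "CAAA"])
        # pairs: (a,b): 0/3; (a,c): 1/4; (b,c): 1/3
        assert res.pi_all == pytest.approx((0 + 0.25 + 1 / 3) / 3)

    def test_silent_site_restriction(self):
        a = "AAAA"
        b = "CAAC"
        classes = ["silent", "silent", "nonsilent", "nonsilent"]
        res = nucleotide_diversity([a, b], site_classes=classes)
        assert res.pi_silent == pytest.approx(0.5)  # 1 diff over 2 silent sites

    def test_no_comparable_sites_raises(self):
        with pytest.raises(DiversityError):
            nucleotide_diversity(["----", "AAAA"])
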