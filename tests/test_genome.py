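import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revenant.genome import (
    FamilyRates,
    GeneCopy,
    Genome,
    RateConfig,
    apply_duplication,
    apply_inversion,
    apply_inversion_intergenic,
    apply_loss,
    apply_origination,
    apply_transfer,
    apply_transposition,
    apply_transposition_intergenic,
    choose_recipient,
    init_root_genome,
    locate_intergenic,
    sample_extension,
    total_intergene_length,
    total_rate,
)
from revenant.species_tree import load_user_tree


def mk(spec: str, lineage="x") -> Genome:
    """'+a -b +c' -> genome of single-copy families a=1, b=2 ..."""
    genes = []
    for i, tok in enumerate(spec.split()):
        genes.append(GeneCopy(ord(tok[1]) - ord("a") + 1, 1, 1 if tok[0] == "+" else -1))
    return Genome(lineage, genes)


def sig(g: Genome) -> list[tuple[int, int]]:
    return [(c.family_id, c.orientation) for c in g.genes]


class TestInit:
    def test_families_are_distinct_single_copies(self):
        g = init_root_genome(5, seed=0)
        assert len(g) == 5
        assert sorted(c.family_id for c in g.genes) == [1, 2, 3, 4, 5]
        assert all(c.copy_id == 1 for c in g.genes)

    def test_single_gene_genome_valid(self):
        g = init_root_genome(1, seed=0)
        assert g.segment_indices(0, 1) == [0]

    def test_deterministic_under_seed(self):
        assert init_root_genome(20, seed=3).genes == init_root_genome(20, seed=3).genes

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            init_root_genome(0)

    def test_orientations_are_random(self):
        g = init_root_genome(200, seed=1)
        plus = sum(1 for c in g.genes if c.orientation > 0)
        assert 60 < plus < 140  # both signs occur, roughly balanced


class TestRates:
    def test_total_rate_arithmetic(self):
        g = init_root_genome(10, seed=0)
        rates = RateConfig(duplication=0.1, loss=0.1, inversion=0.1,
                           transposition=0.1, transfer=0.1, origination=0.0)
        assert total_rate(g, rates) == pytest.approx(5.0)

    def test_empty_genome_rate_is_origination(self):
        g = Genome("x", [])
        assert total_rate(g, RateConfig(duplication=1.0, origination=0.7)) == 0.7

    def test_linearity_in_genome_size(self):
        rates = RateConfig(duplication=0.2, loss=0.1)
        r10 = total_rate(init_root_genome(10, seed=0), rates)
        r20 = total_rate(init_root_genome(20, seed=0), rates)
        assert r20 == pytest.approx(2 * r10)

    def test_family_override_changes_per_gene_rate(self):
        rates = RateConfig(duplication=0.1, family_overrides={2: FamilyRates(duplication=0.5)})
        g = mk("+a +b +c")
        assert total_rate(g, rates) == pytest.approx(0.1 + 0.5 + 0.1)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RateConfig(duplication=-0.1)
        with pytest.raises(ValueError):
            RateConfig(duplication_extension=0.5)


class TestExtension:
    def test_mean_one_is_degenerate(self, rng):
        assert all(sample_extension(1.0, rng) == 1 for _ in range(100))

    def test_mean_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_extension(0.5, rng)

    def test_sample_mean_matches_parameter(self, rng):
        draws = np.array([sample_extension(3.0, rng) for _ in range(20000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se


class TestDuplication:
    def test_single_gene_tandem(self):
        g = mk("+a")
        apply_duplication(g, 0, 1, [2])
        assert sig(g) == [(1, 1), (1, 1)]
        assert g.genes[0].copy_id != g.genes[1].copy_id

    def test_tandem_placement(self):
        g = mk("+a +b +c")
        apply_duplication(g, 1, 2, [7, 8])
        assert sig(g) == [(1, 1), (2, 1), (3, 1), (2, 1), (3, 1)]
        assert [c.copy_id for c in g.genes] == [1, 1, 1, 7, 8]

    def test_family_sizes_grow_by_segment_membership(self):
        g = mk("+a +b +a")
        g.genes[2] = GeneCopy(1, 2, 1)  # second copy of family a
        before = g.family_sizes()
        apply_duplication(g, 1, 2, [9, 9])
        after = g.family_sizes()
        assert after[1] == before[1] + 1 and after[2] == before[2] + 1

    def test_extension_beyond_size_rejected(self):
        with pytest.raises(ValueError):
            apply_duplication(mk("+a"), 0, 2, [2, 3])


class TestLoss:
    def test_lose_everything(self):
        g = mk("+a +b")
        apply_loss(g, 0, 2)
        assert len(g) == 0

    def test_wrapping_loss(self):
        g = mk("+a +b +c +d")
        apply_loss(g, 3, 2)  # removes d then wraps to a
        assert sig(g) == [(2, 1), (3, 1)]


class TestInversion:
    def test_reverses_and_flips(self):
        g = mk("+a +b +c +d +e")
        apply_inversion(g, 1, 2)
        assert sig(g) == [(1, 1), (3, -1), (2, -1), (4, 1), (5, 1)]

    def test_single_gene_flips_in_place(self):
        g = mk("+a +b")
        apply_inversion(g, 1, 1)
        assert sig(g) == [(1, 1), (2, -1)]

    @given(st.integers(2, 8), st.integers(0, 7), st.integers(1, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_involution(self, n, start, k, seed):
        start, k = start % n, 1 + (k - 1) % n
        g = init_root_genome(n, seed=seed)
        before = sig(g)
        apply_inversion(g, start, k)
        apply_inversion(g, start, k)
        assert sig(g) == before


class TestTransposition:
    def test_simple_move(self):
        g = mk("+a +b +c")
        apply_transposition(g, 0, 1, insert_after=1)
        assert sig(g) == [(2, 1), (1, 1), (3, 1)]

    def test_move_to_own_flank_is_identity(self):
        g = mk("+a +b +c")
        apply_transposition(g, 1, 1, insert_after=0)
        assert sig(g) == [(1, 1), (2, 1), (3, 1)]

    def test_content_conserved(self, rng):
        g = init_root_genome(9, seed=2)
        before = sorted(sig(g))
        apply_transposition(g, 2, 4, insert_after=7)
        assert sorted(sig(g)) == before

    def test_insertion_inside_segment_rejected(self):
        with pytest.raises(ValueError):
            apply_transposition(mk("+a +b +c +d"), 0, 2, insert_after=1)


class TestOrigination:
    def test_into_empty_genome(self):
        g = Genome("x", [])
        apply_origination(g, 0, 99, 1)
        assert sig(g) == [(99, 1)]

    def test_duplicate_family_id_rejected(self):
        g = mk("+a")
        with pytest.raises(ValueError):
            apply_origination(g, 0, 1, 1, existing_families={1})


class TestTransfer:
    def test_additive_into_empty_recipient(self):
        donor, rec = mk("+a", "d"), Genome("r", [])
        apply_transfer(donor, 0, 1, rec, 0, [5])
        assert sig(donor) == [(1, 1)]
        assert sig(rec) == [(1, 1)]
        assert rec.genes[0].copy_id == 5

    def test_family_now_spans_two_lineages(self):
        donor, rec = mk("+a +b", "d"), mk("+c", "r")
        apply_transfer(donor, 0, 2, rec, 1, [5, 6])
        assert {c.family_id for c in rec.genes} == {1, 2, 3}


class TestIntergenic:
    def geno(self, n, rng, total=1.0):
        return init_root_genome(n, rng=rng, with_intergenes=True, total_intergene_length=total)

    def test_locate_maps_coordinates(self, rng):
        g = Genome("x", mk("+a +b").genes, [0.25, 0.75])
        assert locate_intergenic(g, 0.1) == (0, pytest.approx(0.1))
        idx, off = locate_intergenic(g, 0.5)
        assert idx == 1 and off == pytest.approx(0.25)

    @given(st.integers(3, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_inversion_conserves_total_intergene_length(self, n, seed):
        rng = np.random.default_rng(seed)
        g = self.geno(n, rng)
        tot = total_intergene_length(g)
        i, a = locate_intergenic(g, rng.random() * tot)
        j, b = locate_intergenic(g, rng.random() * tot)
        content = sorted((c.family_id for c in g.genes))
        apply_inversion_intergenic(g, i, a, j, b)
        assert total_intergene_length(g) == pytest.approx(tot)
        assert sorted(c.family_id for c in g.genes) == content
        assert len(g.intergenes) == len(g.genes)

    @given(st.integers(3, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_transposition_conserves_total_intergene_length(self, n, seed):
        rng = np.random.default_rng(seed)
        g = self.geno(n, rng)
        tot = total_intergene_length(g)
        while True:
            i, a = locate_intergenic(g, rng.random() * tot)
            j, b = locate_intergenic(g, rng.random() * tot)
            if i != j:
                break
        k = (j - i) % n
        excised = (g.intergenes[i] - a) + b + sum(
            g.intergenes[(i + 1 + t) % n] for t in range(k - 1)
        )
        u3 = rng.random() * (tot - excised)
        content = sorted(c.family_id for c in g.genes)
        apply_transposition_intergenic(g, i, a, j, b, u3)
        assert total_intergene_length(g) == pytest.approx(tot)
        assert sorted(c.family_id for c in g.genes) == content
        assert len(g.intergenes) == len(g.genes)


class TestRecipientChoice:
    def test_two_alive_picks_the_other(self, rng):
        tree = load_user_tree("(A:1,B:1);")
        assert choose_recipient({"A", "B"}, "A", tree, 0.0, 0.5, rng) == "B"

    def test_sole_survivor_returns_none(self, rng):
        tree = load_user_tree("(A:1,B:1);")
        assert choose_recipient({"A"}, "A", tree, 0.0, 0.5, rng) is None

    def test_uniform_when_unbiased(self, rng):
        tree = load_user_tree("((A:1,B:1):1,(C:1,D:1):1);")
        draws = [choose_recipient({"A", "B", "C", "D"}, "A", tree, 0.0, 1.5, rng)
                 for _ in range(30000)]
        freqs = {x: draws.count(x) / len(draws) for x in "BCD"}
        se = np.sqrt((1 / 3) * (2 / 3) / len(draws))
        for f in freqs.values():
            assert abs(f - 1 / 3) < 4 * se

    def test_large_bias_prefers_closest_relative(self, rng):
        # caterpillar: B is A's sister, C and D progressively farther
        tree = load_user_tree("(((A:1,B:1):1,C:2):1,D:3);")
        draws = [choose_recipient({"A", "B", "C", "D"}, "A", tree, 50.0, 3.0, rng)
                 for _ in range(300)]
        assert draws.count("B") / len(draws) > 0.99
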