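import numpy as np
import pytest

from oligofish.barcode import (
    BarcodeScheme,
    PatternBlock,
    PrimerPair,
    amplify_in_silico,
    assemble_pool,
    assemble_probe,
    assign_scheme,
    validate_primer_set,
    verify_scheme,
)
from oligofish.genome import Interval, reverse_complement
from oligofish.selection import Sublibrary
from oligofish.simulate import (
    make_primer_set,
    table1_fixture,
    table1_scheme,
    table1_sublibraries,
)


@pytest.fixture(scope="module")
def primers():
    return make_primer_set(5)


@pytest.fixture(scope="module")
def by_id(primers):
    return {p.id: p for p in primers}


def random_inserts(rng, n):
    return ["".join("ACGT"[b] for b in rng.integers(0, 4, 50)) for _ in range(n)]


class TestPrimerPairs:
    def test_validation(self):
        with pytest.raises(ValueError):
            PrimerPair("x", "ACGT", "ACGTACGTACGTACGTACGT")  # too short
        with pytest.raises(ValueError):
            PrimerPair("x", "A" * 20, "A" * 20)  # forward == reverse

    def test_substring_rejected(self):
        a = PrimerPair("a", "ACGTACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG")
        b = PrimerPair("b", "ACGTACGTACGTACGTACGT", "GGCCGGCCGGCCGGCCGG")
        with pytest.raises(ValueError, match="substring"):
            validate_primer_set([a, b])


class TestVerifyScheme:
    def test_published_colors_without_positions_collide(self):
        scheme = table1_scheme(with_positions=False)
        ok, collisions = verify_scheme(scheme)
        assert not ok
        assert ("Chr_1", "Chr_8") in collisions
        assert ("Chr_5", "Chr_7") in collisions
        # chromosomes with unique color sequences never collide
        flat = {c for pair in collisions for c in pair}
        assert "Chr_6" not in flat  # (W2, W1) is unique among patterns

    def test_published_colors_with_arm_layout_unique(self):
        ok, collisions = verify_scheme(table1_scheme(with_positions=True))
        assert ok and collisions == []

    def test_single_chromosome_trivially_unique(self):
        scheme = BarcodeScheme(
            assignments={},
            per_chromosome_pattern={"c": [PatternBlock(0.5, "short", "W1")]},
        )
        assert verify_scheme(scheme) == (True, [])

    def test_position_tolerance_matters(self):
        mk = lambda f: [PatternBlock(f, "unknown", "W1")]
        scheme = BarcodeScheme(
            assignments={},
            per_chromosome_pattern={"a": mk(0.30), "b": mk(0.40)},
        )
        assert verify_scheme(scheme, position_tolerance=0.15)[0] is False
        assert verify_scheme(scheme, position_tolerance=0.05)[0] is True


class TestAssignScheme:
    def make_subs(self, placements):
        """placements: chrom -> list of region (start, end)."""
        subs = []
        for k, (chrom, spans) in enumerate(placements.items(), start=1):
            for j, (s, e) in enumerate(spans, start=1):
                subs.append(
                    Sublibrary(
                        id=f"{chrom}_r{j}", chrom=chrom,
                        region=Interval(chrom, s, e),
                        internal_primer=f"P{k}",
                    )
                )
        return subs

    def test_two_chromosomes_one_region_each(self, primers):
        subs = self.make_subs({"c1": [(0, 100)], "c2": [(0, 100)]})
        scheme = assign_scheme(
            subs, primers, chrom_lengths={"c1": 1000, "c2": 1000}
        )
        colors = [scheme.external_of(s.id) for s in subs]
        assert sorted(colors) == ["W1", "W2"]
        assert verify_scheme(scheme)[0]

    def test_eight_single_regions_no_positions_impossible(self, primers):
        subs = self.make_subs({f"c{i}": [(0, 100)] for i in range(8)})
        with pytest.raises(ValueError, match="colliding"):
            assign_scheme(subs, primers)  # no lengths -> no positions

    def test_published_vector_passes_on_layout_fixture(self):
        scheme = table1_scheme(with_positions=True)
        assert verify_scheme(scheme)[0]
        w = [scheme.external_of(r.contig) for r in table1_fixture()]
        assert w.count("W1") == 8 and w.count("W2") == 6

    def test_internal_is_function_of_chromosome(self, primers):
        subs = self.make_subs(
            {"c1": [(0, 100), (500, 600)], "c2": [(0, 100)]}
        )
        scheme = assign_scheme(
            subs, primers, chrom_lengths={"c1": 1000, "c2": 1000}
        )
        assert scheme.internal_of("c1_r1") == scheme.internal_of("c1_r2") == "P1"
        assert scheme.internal_of("c2_r1") == "P2"


class TestAssembly:
    def test_layout_and_length(self, by_id):
        p = assemble_probe("A" * 50, by_id["P1"], by_id["W1"])
        assert len(p) == 50 + 4 * 20
        assert p.startswith(by_id["W1"].forward)
        assert p.endswith(reverse_complement(by_id["W1"].reverse))
        i = len(by_id["W1"].forward)
        assert p[i : i + 20] == by_id["P1"].forward

    def test_insert_with_n_rejected(self, by_id):
        with pytest.raises(ValueError):
            assemble_probe("A" * 20 + "N" + "A" * 29, by_id["P1"], by_id["W1"])

    def test_own_pairs_amplify_wrong_internal_does_not(self, by_id):
        probe = assemble_probe("ACGT" * 12 + "GT", by_id["P3"], by_id["W2"])
        from oligofish.barcode import Probe

        pool = [Probe("x", probe)]
        assert amplify_in_silico(pool, by_id["W2"]) == pool
        assert amplify_in_silico(pool, by_id["P3"]) == pool
        assert amplify_in_silico(pool, by_id["P4"]) == []
        assert amplify_in_silico(pool, by_id["W1"]) == []

    def test_empty_pool(self, by_id):
        assert amplify_in_silico([], by_id["P1"]) == []


@pytest.fixture(scope="module")
def pool(primers):
    rng = np.random.default_rng(2)
    subs = table1_sublibraries()
    scheme = table1_scheme(with_positions=True)
    inserts = {s.id: random_inserts(rng, 15) for s in subs}
    return subs, scheme, assemble_pool(subs, scheme, primers, inserts)


class TestPoolPartitions:

    def test_internal_primers_partition_by_chromosome(self, pool, by_id):
        subs, scheme, probes = pool
        seen = 0
        for k in range(1, 9):
            prod = amplify_in_silico(probes, by_id[f"P{k}"])
            chroms = {
                next(s.chrom for s in subs if s.id == p.name.rsplit(":", 1)[0])
                for p in prod
            }
            assert chroms == {f"Chr_{k}"}
            seen += len(prod)
        assert seen == len(probes)

    def test_external_primers_partition_by_class(self, pool, by_id):
        subs, scheme, probes = pool
        w1 = amplify_in_silico(probes, by_id["W1"])
        w2 = amplify_in_silico(probes, by_id["W2"])
        assert len(w1) + len(w2) == len(probes)
        assert len(w1) == 8 * 15 and len(w2) == 6 * 15  # 8 vs 6 sublibraries

    def test_amplification_is_identity_on_own_probes(self, pool, by_id):
        subs, scheme, probes = pool
        for s in subs[:3]:
            internal, external = scheme.assignments[s.id]
            own = [p for p in probes if p.name.startswith(s.id + ":")]
            twice = amplify_in_silico(
                amplify_in_silico(own, by_id[external]), by_id[internal]
            )
            assert twice == own
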