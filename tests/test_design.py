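import numpy as np
import pytest

from _oracle import (
    oracle_best_matches,
    oracle_best_matches_slow,
    oracle_decisions,
)
from conftest import random_genome
from oligofish.design import (
    DesignParams,
    Oligo,
    filter_unique,
    max_offtarget_identity,
    offtarget_match_counts,
    tile_candidates,
)
from oligofish.genome import Genome, Interval, reverse_complement
from oligofish.simulate import DuplicationSpec, ToyGenomeSpec, make_toy_genome


def planted_genome(seed, identities, length=6000):
    """Random record with one 50-nt near-duplicate per identity value,
    both endpoints stride-5 aligned."""
    dups = [
        DuplicationSpec(0, 500 + 200 * i, 50, ident, 0, 3000 + 200 * i)
        for i, ident in enumerate(identities)
    ]
    spec = ToyGenomeSpec(1, [length], seed=seed, duplications=dups)
    return make_toy_genome(spec)


class TestTiling:
    def test_enumerates_stride_windows(self):
        g = Genome([("x", "ACGT" * 25)])  # 100 bp
        c = tile_candidates(g, [], DesignParams())
        assert [o.start for o in c] == list(range(0, 55, 5))
        assert all(o.sequence == g["x"][o.start : o.end] for o in c)

    def test_short_record_yields_nothing(self):
        assert tile_candidates(Genome([("x", "ACGT" * 12)]), []) == []

    def test_fully_masked_record_yields_nothing(self):
        g = random_genome(1, [200])
        mask = [Interval(g.ids[0], 0, 200)]
        assert tile_candidates(g, mask) == []

    def test_n_windows_excluded(self):
        g = Genome([("x", "A" * 60 + "N" + "C" * 60)])
        starts = {o.start for o in tile_candidates(g, [])}
        assert all(s + 50 <= 60 or s >= 61 for s in starts)

    def test_partial_mask_respected(self):
        g = random_genome(2, [300])
        mask = [Interval(g.ids[0], 100, 150)]
        starts = {o.start for o in tile_candidates(g, mask)}
        assert all(s + 50 <= 100 or s >= 150 for s in starts)


class TestMaxOfftargetIdentity:
    def test_exact_duplicate_scores_one(self):
        g, _ = planted_genome(17, [1.0])
        o = Oligo("Chr_1", 500, 550, g["Chr_1"][500:550])
        assert max_offtarget_identity(o, g) == 1.0

    @pytest.mark.parametrize("ident,expected", [(0.76, 0.76), (0.74, 0.74)])
    def test_planted_near_duplicates(self, ident, expected):
        g, _ = planted_genome(19, [ident])
        o = Oligo("Chr_1", 500, 550, g["Chr_1"][500:550])
        assert max_offtarget_identity(o, g) == pytest.approx(expected)

    def test_random_oligo_background_low(self, small_genome):
        rid = small_genome.ids[0]
        o = Oligo(rid, 1000, 1050, small_genome[rid][1000:1050])
        got = max_offtarget_identity(o, small_genome)
        (oracle,) = oracle_best_matches_slow(small_genome, [o])
        assert got == oracle / 50
        assert got <= 0.74  # no spurious near-duplicate in random 2 kb


class TestOracleSelfConsistency:
    def test_matrix_oracle_matches_pure_python(self):
        g = random_genome(23, [300])
        cands = tile_candidates(g, [])
        fast = oracle_best_matches(g, cands)
        slow = oracle_best_matches_slow(g, cands)
        assert list(fast) == list(slow)


class TestFilterUnique:
    def test_boundary_38_removed_37_retained(self):
        g, truth = planted_genome(29, [0.76, 0.74])
        params = DesignParams()
        kept = {o.start for o in filter_unique(
            tile_candidates(g, [], params), g, params, engine="exact")}
        src_76 = truth["duplications"][0].start
        src_74 = truth["duplications"][2].start
        assert src_76 not in kept   # 38/50 matches -> removed
        assert src_74 in kept       # 37/50 matches -> survives
        dst_76 = truth["duplications"][1].start
        assert dst_76 not in kept   # the planted copy is removed too

    def test_all_unique_random_genome_fully_retained(self):
        g = random_genome(31, [4000])
        params = DesignParams()
        cands = tile_candidates(g, [], params)
        assert oracle_decisions(g, cands) == [True] * len(cands)  # verified
        assert len(filter_unique(cands, g, params, engine="exact")) == len(cands)

    @pytest.mark.parametrize("engine", ["exact", "seeded"])
    def test_exact_duplicates_removed_by_both_engines(self, engine):
        spec = ToyGenomeSpec(
            2, [4000, 4000], seed=37,
            duplications=[DuplicationSpec(0, 1000, 300, 1.0, 1, 2000)],
        )
        g, _ = make_toy_genome(spec)
        params = DesignParams()
        kept = filter_unique(tile_candidates(g, [], params), g, params,
                             engine=engine)
        starts1 = {o.start for o in kept if o.chrom == "Chr_1"}
        # every window fully inside the duplicated segment must be gone
        assert all(not (1000 <= s and s + 50 <= 1300) for s in starts1)

    def test_oracle_equivalence_on_seeded_genomes(self):
        """Implementation decisions match the brute-force oracle exactly,
        including annotated statistics, on genomes with straddling
        duplications."""
        params = DesignParams()
        for seed in (41, 43, 45):
            g, _ = planted_genome(seed, [0.70, 0.74, 0.76, 0.80, 1.0])
            cands = tile_candidates(g, [], params)
            kept = filter_unique(cands, g, params, engine="exact")
            kept_set = {(o.chrom, o.start) for o in kept}
            dec = oracle_decisions(g, cands)
            assert [(c.chrom, c.start) in kept_set for c in cands] == dec
            best = oracle_best_matches(g, cands)
            by_pos = {(c.chrom, c.start): b for c, b in zip(cands, best)}
            for o in kept:
                assert o.max_offtarget_identity == by_pos[(o.chrom, o.start)] / 50

    def test_self_exclusion(self):
        # a unique oligo is never discarded because of its own window
        g = random_genome(47, [1000])
        params = DesignParams()
        cands = tile_candidates(g, [], params)
        kept = filter_unique(cands, g, params, engine="exact")
        assert len(kept) == len(cands)

    def test_strand_symmetry(self):
        g, _ = planted_genome(53, [0.76, 0.80])
        params = DesignParams()
        kept_fwd = filter_unique(tile_candidates(g, [], params), g, params,
                                 engine="exact")
        g_rc = Genome([("Chr_1", reverse_complement(g["Chr_1"]))])
        kept_rev = filter_unique(tile_candidates(g_rc, [], params), g_rc,
                                 params, engine="exact")

        def canon(oligos):
            return {
                min(o.sequence, reverse_complement(o.sequence))
                for o in oligos
            }

        assert canon(kept_fwd) == canon(kept_rev)

    def test_threshold_monotonicity(self):
        g, _ = planted_genome(59, [0.72, 0.76, 0.84])
        cands = tile_candidates(g, [])
        kept_by_thr = {}
        for thr in (0.70, 0.75, 0.85):
            params = DesignParams(similarity_threshold=thr)
            kept_by_thr[thr] = {
                o.start
                for o in filter_unique(cands, g, params, engine="exact")
            }
        assert kept_by_thr[0.70] <= kept_by_thr[0.75] <= kept_by_thr[0.85]

    def test_engines_agree_above_threshold_flags(self):
        spec = ToyGenomeSpec(
            2, [6000, 6000], seed=61,
            duplications=[
                DuplicationSpec(0, 1000, 200, 0.90, 1, 2500),
                DuplicationSpec(0, 3000, 200, 1.00, 1, 4500),
            ],
        )
        g, _ = make_toy_genome(spec)
        params = DesignParams()
        ce = offtarget_match_counts(g, params, engine="exact")
        cs = offtarget_match_counts(g, params, engine="seeded")
        for chrom in ce:
            assert np.array_equal(ce[chrom] >= 38, cs[chrom] >= 38)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DesignParams(step=0)
        with pytest.raises(ValueError):
            DesignParams(similarity_threshold=1.0)
        with pytest.raises(ValueError):
            DesignParams(min_density=1.0)  # below the soft floor

    def test_boundary_match_count(self):
        assert DesignParams().max_matches_kept == 37
        assert DesignParams(similarity_threshold=0.76).max_matches_kept == 38
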