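import numpy as np
import pytest

from oligofish.barcode import BarcodeScheme
from oligofish.genome import Genome
from oligofish.karyotype import (
    KaryotypeMeasure,
    RdnaSite,
    RdnaSitePattern,
    arm_ratio,
    expected_signal_pairs,
    load_rdna_patterns,
    overlay_rdna,
    pattern_signature,
    predicted_ideogram,
    relative_lengths,
)
from oligofish.simulate import table1_scheme


@pytest.fixture(scope="module")
def nominal_genome():
    return Genome([(f"Chr_{i}", "A" * 30_000_000) for i in range(1, 9)])


@pytest.fixture(scope="module")
def patterns():
    return load_rdna_patterns()


class TestPredictedIdeogram:
    def test_published_fixture_has_14_blocks(self, nominal_genome):
        ideo = predicted_ideogram(
            table1_scheme(with_positions=True), nominal_genome,
            {f"Chr_{i}": 14_000_000 for i in range(1, 9)},
        )
        assert ideo.n_blocks == 14
        assert len(ideo.chromosomes) == 8

    def test_whole_record_block(self):
        g = Genome([("c", "A" * 1000)])
        scheme = BarcodeScheme(
            assignments={"s": ("P1", "W1")}, regions={"s": ("c", 0, 1000)}
        )
        ideo = predicted_ideogram(scheme, g)
        (block,) = ideo.chromosomes["c"].blocks
        assert (block.start, block.end) == (0.0, 1.0)

    def test_empty_scheme(self, nominal_genome):
        ideo = predicted_ideogram(BarcodeScheme(assignments={}), nominal_genome)
        assert ideo.n_blocks == 0

    def test_unknown_chromosome_errors(self):
        g = Genome([("c", "A" * 1000)])
        scheme = BarcodeScheme(
            assignments={"s": ("P1", "W1")}, regions={"s": ("zzz", 0, 100)}
        )
        with pytest.raises(KeyError):
            predicted_ideogram(scheme, g)


class TestOverlay:
    def test_pseudocerasus_adds_five_blocks(self, nominal_genome, patterns):
        ideo = predicted_ideogram(
            table1_scheme(with_positions=True), nominal_genome,
            {f"Chr_{i}": 14_000_000 for i in range(1, 9)},
        )
        over = overlay_rdna(ideo, patterns["P. pseudocerasus"])
        assert over.n_blocks == ideo.n_blocks + 5

    def test_existing_blocks_untouched(self, nominal_genome, patterns):
        ideo = predicted_ideogram(
            table1_scheme(with_positions=True), nominal_genome,
            {f"Chr_{i}": 14_000_000 for i in range(1, 9)},
        )
        over = overlay_rdna(ideo, patterns["P. avium"])
        for c in ideo.chromosomes:
            old = [b for b in ideo.chromosomes[c].blocks]
            kept = [b for b in over.chromosomes[c].blocks if b.source not in ("5S", "45S")]
            assert kept == old

    def test_empty_pattern_is_noop(self, nominal_genome):
        ideo = predicted_ideogram(BarcodeScheme(assignments={}), nominal_genome)
        over = overlay_rdna(ideo, RdnaSitePattern("none", 2, []))
        assert over.n_blocks == 0

    def test_unknown_chromosome_errors(self, nominal_genome):
        ideo = predicted_ideogram(BarcodeScheme(assignments={}), nominal_genome)
        bad = RdnaSitePattern("x", 2, [RdnaSite("5S", "Chr_9", "proximal")])
        with pytest.raises(KeyError):
            overlay_rdna(ideo, bad)

    def test_terminal_sits_at_arm_end(self, nominal_genome):
        ideo = predicted_ideogram(
            BarcodeScheme(assignments={}), nominal_genome,
            {f"Chr_{i}": 10_000_000 for i in range(1, 9)},  # short arm left
        )
        over = overlay_rdna(
            ideo,
            RdnaSitePattern("x", 2, [RdnaSite("45S", "Chr_4", "terminal", "short")]),
        )
        (block,) = over.chromosomes["Chr_4"].blocks
        assert block.start == 0.0 and block.end <= 0.05


class TestSignatures:
    def test_eleven_species_eight_types(self, patterns):
        assert len(patterns) == 11
        sigs = {pattern_signature(p) for p in patterns.values()}
        assert len(sigs) == 8

    def test_ploidy_independent_sharing(self, patterns):
        assert pattern_signature(patterns["P. avium"]) == pattern_signature(
            patterns["P. cerasus"]
        )  # diploid vs tetraploid, same distribution type
        assert pattern_signature(
            patterns["P. pseudocerasus"]
        ) == pattern_signature(patterns["P. yedoensis"])

    def test_distinct_types_differ(self, patterns):
        assert pattern_signature(patterns["P. humilis"]) != pattern_signature(
            patterns["P. salicina"]
        )
        assert pattern_signature(patterns["P. dulcis"]) != pattern_signature(
            patterns["P. persica"]
        )

    def test_empty_pattern_empty_signature(self):
        assert pattern_signature(RdnaSitePattern("x", 2, [])) == ""

    def test_duplicate_sites_deduplicated(self):
        s = RdnaSite("5S", "Chr_8", "proximal", "short")
        p = RdnaSitePattern("x", 4, [s, s])
        assert len(p.sites) == 1


class TestSignalPairs:
    def test_tetraploid_counts(self, patterns):
        pp = patterns["P. pseudocerasus"]
        assert expected_signal_pairs(pp, "45S") == 6
        assert expected_signal_pairs(pp, "5S") == 4

    def test_diploid_single_site(self, patterns):
        assert expected_signal_pairs(patterns["P. avium"], "5S") == 1

    def test_no_sites(self):
        assert expected_signal_pairs(RdnaSitePattern("x", 6, []), "45S") == 0

    def test_pentaploid_floors_with_warning(self, patterns):
        penta = RdnaSitePattern(
            "P. pseudocerasus", 5, patterns["P. pseudocerasus"].sites
        )
        with pytest.warns(UserWarning, match="odd ploidy"):
            assert expected_signal_pairs(penta, "45S") == 7


class TestKaryotypeMeasures:
    def test_equal_chromosomes(self):
        m = KaryotypeMeasure(
            cells=[{f"c{i}": (1.0, 1.0) for i in range(8)}]
        )
        rl = relative_lengths(m)
        assert all(v == pytest.approx(12.5) for v in rl.values())

    def test_two_chromosome_cell(self):
        m = KaryotypeMeasure(cells=[{"a": (1.0, 1.0), "b": (1.0, 2.0)}])
        rl = relative_lengths(m)
        assert rl == {"a": pytest.approx(40.0), "b": pytest.approx(60.0)}

    def test_incomplete_cell_excluded(self):
        m = KaryotypeMeasure(
            cells=[
                {"a": (1.0, 1.0), "b": (1.0, 1.0)},
                {"a": (9.0, 9.0)},
            ]
        )
        with pytest.warns(UserWarning, match="missing"):
            rl = relative_lengths(m)
        assert rl["a"] == pytest.approx(50.0)

    def test_noisy_cells_recover_truth(self):
        rng = np.random.default_rng(1)
        truth = {f"c{i}": 1.0 + 0.3 * i for i in range(8)}
        cells = []
        for _ in range(5):
            cells.append(
                {
                    c: (
                        max(0.35 * l + rng.normal(0, 0.03), 0.05),
                        max(0.65 * l + rng.normal(0, 0.03), 0.05),
                    )
                    for c, l in truth.items()
                }
            )
        rl = relative_lengths(KaryotypeMeasure(cells=cells))
        total = sum(truth.values())
        for c, l in truth.items():
            assert rl[c] == pytest.approx(100 * l / total, abs=1.0)
        assert sum(rl.values()) == pytest.approx(100.0, abs=0.01)

    @pytest.mark.parametrize(
        "short,long,expected", [(1.0, 1.0, 1.0), (1.0, 3.0, 3.0), (2.1, 1.4, 1.5)]
    )
    def test_arm_ratio(self, short, long, expected):
        assert arm_ratio(short, long) == pytest.approx(expected)

    def test_arm_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            arm_ratio(0.0, 1.0)
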