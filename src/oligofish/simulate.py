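"""Deterministic generators for toy genomes, primer sets, and the published
sublibrary table.

Toy genomes are i.i.d. uniform random sequence with planted, exactly-known
structure: tandem satellite arrays (default monomer lengths mirror the
102/149/159-bp satellites of true cherries), near-duplicate segments at an
exact mismatch count (to probe the uniqueness-filter boundary), assembly-gap
N runs, and centromere positions. Every generator is seed-deterministic and
returns truth tracks describing exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .barcode import BarcodeScheme, PatternBlock, PrimerPair, validate_primer_set
from .genome import Genome, Interval
from .selection import Sublibrary

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    chrom: int  # 0-based chromosome index
    monomer_length: int
    copies: int
    start: int

    @property
    def length(self) -> int:
        return self.monomer_length * self.copies


@dataclass(frozen=True)
class DuplicationSpec:
    src_chrom: int
    src_start: int
    length: int
    identity: float  # exact: round((1-identity)*length) substitutions
    dst_chrom: int
    dst_start: int

    @property
    def n_substitutions(self) -> int:
        return int(round((1.0 - self.identity) * self.length))


@dataclass(frozen=True)
class GapSpec:
    chrom: int
    start: int
    length: int


@dataclass
class ToyGenomeSpec:
    n_chromosomes: int
    lengths: list[int]
    seed: int
    repeats: list[RepeatSpec] = field(default_factory=list)
    duplications: list[DuplicationSpec] = field(default_factory=list)
    gaps: list[GapSpec] = field(default_factory=list)
    centromeres: list[int] | None = None
    gc: float = 0.5
    chrom_prefix: str = "Chr_"

    def __post_init__(self) -> None:
        if len(self.lengths) != self.n_chromosomes:
            raise ValueError("lengths must match n_chromosomes")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def chrom_name(self, i: int) -> str:
        return f"{self.chrom_prefix}{i + 1}"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ToyGenomeSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["repeats"] = [RepeatSpec(**r) for r in doc.get("repeats", [])]
        doc["duplications"] = [
            DuplicationSpec(**d) for d in doc.get("duplications", [])
        ]
        doc["gaps"] = [GapSpec(**g) for g in doc.get("gaps", [])]
        return cls(**doc)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def make_toy_genome(
    spec: ToyGenomeSpec,
) -> tuple[Genome, dict[str, list[Interval]]]:
    """Build the genome and exact truth tracks from a spec.

    Truth keys: ``repeats``, ``duplications`` (source and destination),
    ``gaps``, ``centromeres``. Overlapping planted features raise
    ``ValueError``; a duplication source must sit in untouched background.
    """
    rng = np.random.default_rng(spec.seed)
    arrs = [
        _random_bases(rng, n, spec.gc) for n in spec.lengths
    ]

    written: list[tuple[int, int, int]] = []  # (chrom, start, end)

    def claim(c: int, s: int, e: int, what: str) -> None:
        if not (0 <= s < e <= spec.lengths[c]):
            raise ValueError(f"{what} out of bounds on chromosome {c + 1}")
        for oc, os_, oe in written:
            if oc == c and s < oe and os_ < e:
                raise ValueError(
                    f"{what} overlaps another planted feature on "
                    f"chromosome {c + 1}"
                )
        written.append((c, s, e))

    truth: dict[str, list[Interval]] = {
        "repeats": [],
        "duplications": [],
        "gaps": [],
        "centromeres": [],
    }

    for g in spec.gaps:
        claim(g.chrom, g.start, g.start + g.length, "gap")
        arrs[g.chrom][g.start : g.start + g.length] = ord("N")
        truth["gaps"].append(
            Interval(spec.chrom_name(g.chrom), g.start, g.start + g.length, "gap")
        )

    for r in spec.repeats:
        claim(r.chrom, r.start, r.start + r.length, "repeat array")
        monomer = _random_bases(rng, r.monomer_length, spec.gc)
        arrs[r.chrom][r.start : r.start + r.length] = np.tile(monomer, r.copies)
        truth["repeats"].append(
            Interval(
                spec.chrom_name(r.chrom), r.start, r.start + r.length,
                f"sat{r.monomer_length}x{r.copies}",
            )
        )

    for i, d in enumerate(spec.duplications):
        # source is read-only but must be untouched background
        for oc, os_, oe in written:
            if oc == d.src_chrom and d.src_start < oe and os_ < d.src_start + d.length:
                raise ValueError("duplication source overlaps a planted feature")
        claim(d.dst_chrom, d.dst_start, d.dst_start + d.length, "duplication")
        seg = arrs[d.src_chrom][d.src_start : d.src_start + d.length].copy()
        n_sub = d.n_substitutions
        if n_sub:
            pos = rng.choice(d.length, size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub)
            code = np.searchsorted(BASES, seg[pos])  # ACGT is ascii-sorted
            seg[pos] = BASES[(code + shift) % 4]
        arrs[d.dst_chrom][d.dst_start : d.dst_start + d.length] = seg
        truth["duplications"].append(
            Interval(
                spec.chrom_name(d.src_chrom), d.src_start,
                d.src_start + d.length, f"dup{i}_src", d.identity,
            )
        )
        truth["duplications"].append(
            Interval(
                spec.chrom_name(d.dst_chrom), d.dst_start,
                d.dst_start + d.length, f"dup{i}_dst", d.identity,
            )
        )

    if spec.centromeres is not None:
        for c, pos in enumerate(spec.centromeres):
            truth["centromeres"].append(
                Interval(spec.chrom_name(c), pos, pos + 1, "centromere")
            )

    genome = Genome(
        (spec.chrom_name(i), a.tobytes().decode("ascii"))
        for i, a in enumerate(arrs)
    )
    return genome, truth


def centromere_map(spec: ToyGenomeSpec) -> dict[str, int]:
    if spec.centromeres is None:
        return {}
    return {spec.chrom_name(i): c for i, c in enumerate(spec.centromeres)}


# -- primers -----------------------------------------------------------------

def make_primer_set(
    seed: int,
    n_internal: int = 8,
    n_external: int = 2,
    length: int = 20,
    max_tries: int = 20_000,
) -> list[PrimerPair]:
    """Deterministic primer pairs P1..Pn then W1..Wm.

    Constraints: GC fraction in [0.4, 0.6], no homopolymer run > 4, all
    primers pairwise distinct and never a substring of one another.
    Raises ``ValueError`` when the constraint space cannot be satisfied
    (e.g. very short primers).
    """
    if n_internal < 0 or n_external < 1:
        raise ValueError("need n_internal >= 0 and n_external >= 1")
    if not (18 <= length <= 25):
        raise ValueError(
            f"primer length {length} unusable: constraint space requires "
            "18..25 nt"
        )
    rng = np.random.default_rng(seed)
    need = 2 * (n_internal + n_external)
    accepted: list[str] = []
    tries = 0
    while len(accepted) < need:
        tries += 1
        if tries > max_tries:
            raise ValueError("primer constraints unsatisfiable at this length")
        cand = _random_bases(rng, length, 0.5).tobytes().decode("ascii")
        gc = (cand.count("G") + cand.count("C")) / length
        if not (0.4 <= gc <= 0.6):
            continue
        if _max_homopolymer(cand) > 4:
            continue
        if any(cand in a or a in cand for a in accepted):
            continue
        accepted.append(cand)
    pairs = []
    names = [f"P{i + 1}" for i in range(n_internal)] + [
        f"W{i + 1}" for i in range(n_external)
    ]
    for i, name in enumerate(names):
        pairs.append(PrimerPair(name, accepted[2 * i], accepted[2 * i + 1]))
    validate_primer_set(pairs)
    return pairs


def _max_homopolymer(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# -- published sublibrary table ----------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    contig: str
    contig_length_bp: int
    oligo_count: int
    chrom: str
    region_length_bp: int
    printed_density: float
    internal_primer: str
    external_class: str


_TABLE1 = [
    ("Contig_27", 2_252_344, 6790, "Chr_1", 1_699_807, 3.99, "P1", "W1"),
    ("Contig_29", 2_199_550, 7513, "Chr_1", 2_141_321, 3.42, "P1", "W1"),
    ("Contig_25", 2_290_169, 7413, "Chr_2", 1_399_377, 5.30, "P2", "W2"),
    ("Contig_02", 5_439_059, 6568, "Chr_3", 1_594_437, 4.11, "P3", "W2"),
    ("Contig_09", 4_505_147, 6618, "Chr_3", 1_462_969, 4.41, "P3", "W2"),
    ("Contig_04", 5_080_108, 6964, "Chr_4", 1_480_858, 4.64, "P4", "W1"),
    ("Contig_01", 7_149_121, 7960, "Chr_5", 1_998_387, 3.98, "P5", "W1"),
    ("Contig_37", 1_734_690, 7162, "Chr_5", 1_676_082, 4.21, "P5", "W2"),
    ("Contig_45", 1_603_937, 7120, "Chr_6", 1_541_098, 4.45, "P6", "W2"),
    ("Contig_07", 4_762_281, 7080, "Chr_6", 1_765_125, 3.93, "P6", "W1"),
    ("Contig_34", 2_027_033, 6780, "Chr_7", 1_516_158, 4.52, "P7", "W1"),
    ("Contig_08", 4_598_159, 5407, "Chr_7", 1_598_107, 3.38, "P7", "W2"),
    ("Contig_20", 2_726_937, 5146, "Chr_8", 1_879_060, 2.71, "P8", "W1"),
    ("Contig_52", 1_520_798, 6773, "Chr_8", 1_418_134, 4.84, "P8", "W1"),
]


def table1_fixture() -> list[Table1Row]:
    """The 14 published sublibrary rows (ids, counts, lengths, primers)."""
    return [Table1Row(*r) for r in _TABLE1]


#: Illustrative per-contig arm placements (midpoint fraction, arm) under
#: which the published color vector resolves every chromosome. SYNTHETIC:
#: chosen so that color-identical chromosome pairs differ in arm or
#: position, not measured from any micrograph or figure.
FIG_LAYOUT_SYNTHETIC: dict[str, tuple[float, str]] = {
    "Contig_27": (0.20, "short"),
    "Contig_29": (0.70, "long"),
    "Contig_25": (0.30, "short"),
    "Contig_02": (0.25, "short"),
    "Contig_09": (0.70, "long"),
    "Contig_04": (0.50, "long"),
    "Contig_01": (0.20, "short"),
    "Contig_37": (0.60, "long"),
    "Contig_45": (0.20, "short"),
    "Contig_07": (0.80, "long"),
    "Contig_34": (0.02, "short"),
    "Contig_08": (0.95, "long"),
    "Contig_20": (0.15, "short"),
    "Contig_52": (0.45, "short"),
}


def table1_scheme(with_positions: bool = False) -> BarcodeScheme:
    """BarcodeScheme carrying the published primer/color assignments.

    ``with_positions=False`` leaves every block position/arm unknown (pure
    color sequences, ordered as printed); ``True`` applies the synthetic
    arm-placement layout ``FIG_LAYOUT_SYNTHETIC``.
    """
    rows = table1_fixture()
    patterns: dict[str, list[PatternBlock]] = {}
    assignments: dict[str, tuple[str, str]] = {}
    regions: dict[str, tuple[str, int, int]] = {}
    nominal = 30_000_000  # nominal chromosome length for fractional spans
    for r in rows:
        assignments[r.contig] = (r.internal_primer, r.external_class)
        if with_positions:
            frac, arm = FIG_LAYOUT_SYNTHETIC[r.contig]
            block = PatternBlock(frac, arm, r.external_class)
            start = max(int(frac * nominal) - r.region_length_bp // 2, 0)
        else:
            block = PatternBlock(None, "unknown", r.external_class)
            start = 0
        patterns.setdefault(r.chrom, []).append(block)
        regions[r.contig] = (r.chrom, start, start + r.region_length_bp)
    if with_positions:
        patterns = {
            c: sorted(bs, key=lambda b: b.position)
            for c, bs in patterns.items()
        }
    return BarcodeScheme(
        assignments=assignments,
        per_chromosome_pattern=patterns,
        regions=regions,
    )


def table1_sublibraries() -> list[Sublibrary]:
    """Sublibrary records for the published rows (regions placed at the
    synthetic layout positions on nominal 30-Mb chromosomes)."""
    scheme = table1_scheme(with_positions=True)
    out = []
    for r in table1_fixture():
        chrom, start, end = scheme.regions[r.contig]
        out.append(
            Sublibrary(
                id=r.contig,
                chrom=chrom,
                region=Interval(chrom, start, end),
                oligo_count=r.oligo_count,
                oligo_ids=[],
                internal_primer=r.internal_primer,
                external_class=r.external_class,
            )
        )
    return out


# -- the scaled demonstration genome ----------------------------------------

def demo_genome_spec(seed: int, n_chromosomes: int = 8) -> ToyGenomeSpec:
    """An 8-chromosome toy genome for the end-to-end scaled pipeline.

    Each 600-kb chromosome carries one 250-kb "clean island" of unique
    sequence at a chromosome-specific offset; the flanks emulate the
    repeat-rich, poorly assembled remainder of a draft genome as N gaps
    with embedded satellite arrays (102/149/159-bp monomers) plus one
    planted 300-bp duplication at 90% identity inside the island. Region
    selection at one-tenth the published megabase rules then lands at a
    distinct position per chromosome, which is what makes a two-color
    barcode resolvable.
    """
    clen = 600_000
    island = 250_000
    monomers = [102, 149, 159]
    lengths = [clen] * n_chromosomes
    gaps: list[GapSpec] = []
    repeats: list[RepeatSpec] = []
    dups: list[DuplicationSpec] = []
    centromeres: list[int] = []
    for i in range(n_chromosomes):
        is_start = 50_000 * i
        is_end = is_start + island
        m = monomers[i % 3]
        copies = 50
        # left flank: gap, with a satellite array wedged in when there is room
        if is_start > 0:
            arr_len = m * copies
            if is_start > arr_len + 2_000:
                arr_start = 1_000
                gaps.append(GapSpec(i, 0, arr_start - 0))
                repeats.append(RepeatSpec(i, m, copies, arr_start))
                gaps.append(
                    GapSpec(i, arr_start + arr_len, is_start - arr_start - arr_len)
                )
            else:
                gaps.append(GapSpec(i, 0, is_start))
        # right flank: satellite array then gap to the end
        if is_end < clen:
            arr_len = m * copies
            if clen - is_end > arr_len + 2_000:
                repeats.append(RepeatSpec(i, m, copies, is_end + 1_000))
                gaps.append(GapSpec(i, is_end, 1_000))
                gaps.append(
                    GapSpec(
                        i, is_end + 1_000 + arr_len,
                        clen - is_end - 1_000 - arr_len,
                    )
                )
            else:
                gaps.append(GapSpec(i, is_end, clen - is_end))
        dups.append(
            DuplicationSpec(
                src_chrom=i,
                src_start=is_start + 20_000,
                length=300,
                identity=0.90,
                dst_chrom=i,
                dst_start=is_start + island - 25_000,
            )
        )
        centromeres.append(is_start + island // 2 + (0 if i % 2 else 40_000))
    return ToyGenomeSpec(
        n_chromosomes=n_chromosomes,
        lengths=lengths,
        seed=seed,
        repeats=repeats,
        duplications=dups,
        gaps=gaps,
        centromeres=centromeres,
    )
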