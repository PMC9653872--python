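"""Dual-fluorophore chromosome barcode schemes and probe assembly.

Every synthesizable probe is a 50-nt genomic insert nested inside two
primer pairs::

    external.forward + internal.forward + insert
        + rc(internal.reverse) + rc(external.reverse)

Internal pairs (P1..P8) are chromosome-specific, so amplifying the pool
with P_k recovers exactly chromosome k's probes. External pairs (W1, W2)
carry the fluorophore class (by default W1 -> FAM/green, W2 -> TAMRA/red);
amplifying with one external pair recovers one whole label class. The
per-chromosome sequence of colored signal blocks along the chromosome — the
barcode — must differ between every chromosome pair for the scheme to
identify all chromosomes in one hybridization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

from .genome import reverse_complement
from .selection import Sublibrary

DEFAULT_COLOR_MAP = {"W1": "FAM/green", "W2": "TAMRA/red"}


@dataclass(frozen=True)
class PrimerPair:
    id: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not (18 <= len(seq) <= 25):
                raise ValueError(
                    f"primer {self.id}: length {len(seq)} outside 18..25 nt"
                )
            if set(seq) - set("ACGT"):
                raise ValueError(f"primer {self.id}: non-ACGT characters")
        if self.forward == self.reverse:
            raise ValueError(f"primer {self.id}: forward equals reverse")


def validate_primer_set(primers: list[PrimerPair]) -> None:
    """No primer may be a substring of another primer in the set."""
    seqs = [(p.id, which, s) for p in primers for which, s in
            (("F", p.forward), ("R", p.reverse))]
    ids = [f"{pid}.{w}" for pid, w, _ in seqs]
    if len(set(s for _, _, s in seqs)) != len(seqs):
        raise ValueError("duplicate primer sequences in set")
    for i, (_, _, a) in enumerate(seqs):
        for j, (_, _, b) in enumerate(seqs):
            if i != j and a in b:
                raise ValueError(
                    f"primer {ids[i]} is a substring of {ids[j]}"
                )


@dataclass(frozen=True)
class PatternBlock:
    """One signal block of a chromosome's barcode pattern."""

    position: float | None  # region midpoint as fraction of chrom length
    arm: str  # 'short' | 'long' | 'unknown'
    color: str  # external class id (e.g. 'W1')


@dataclass
class BarcodeScheme:
    assignments: dict[str, tuple[str, str]]  # sublib id -> (internal, external)
    color_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLOR_MAP))
    per_chromosome_pattern: dict[str, list[PatternBlock]] = field(default_factory=dict)
    # region spans (chrom, start, end) per sublibrary, for ideogram use
    regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def external_of(self, sublib_id: str) -> str:
        return self.assignments[sublib_id][1]

    def internal_of(self, sublib_id: str) -> str:
        return self.assignments[sublib_id][0]

    def to_yaml(self, path) -> None:
        doc = {
            "color_map": self.color_map,
            "assignments": {
                k: {"internal": v[0], "external": v[1]}
                for k, v in self.assignments.items()
            },
            "patterns": {
                c: [
                    {"position": b.position, "arm": b.arm, "color": b.color}
                    for b in blocks
                ]
                for c, blocks in self.per_chromosome_pattern.items()
            },
            "regions": {
                k: [v[0], int(v[1]), int(v[2])]
                for k, v in self.regions.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _blocks_collide(
    a: list[PatternBlock], b: list[PatternBlock], tol: float
) -> bool:
    """Two patterns collide when nothing observable separates them."""
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if x.color != y.color:
            return False
        if x.position is not None and y.position is not None:
            if abs(x.position - y.position) > tol:
                return False
        if x.arm in ("short", "long") and y.arm in ("short", "long"):
            if x.arm != y.arm:
                return False
    return True


def verify_scheme(
    scheme: BarcodeScheme, position_tolerance: float = 0.15
) -> tuple[bool, list[tuple[str, str]]]:
    """Pairwise-distinguishability check of the per-chromosome patterns."""
    chroms = list(scheme.per_chromosome_pattern)
    collisions = [
        (a, b)
        for a, b in itertools.combinations(chroms, 2)
        if _blocks_collide(
            scheme.per_chromosome_pattern[a],
            scheme.per_chromosome_pattern[b],
            position_tolerance,
        )
    ]
    return (not collisions, collisions)


def build_patterns(
    sublibraries: list[Sublibrary],
    colors: dict[str, str],
    chrom_lengths: dict[str, int] | None = None,
    centromeres: dict[str, int] | None = None,
) -> dict[str, list[PatternBlock]]:
    """Positional patterns (midpoint fraction, arm, color) per chromosome.

    Without a chromosome length the position is unknown; without a
    centromere the arm is unknown.
    """
    centromeres = centromeres or {}
    chrom_lengths = chrom_lengths or {}
    per_chrom: dict[str, list[tuple[int, PatternBlock]]] = {}
    for s in sublibraries:
        mid = (s.region.start + s.region.end) // 2
        clen = chrom_lengths.get(s.chrom)
        frac = mid / clen if clen else None
        cen = centromeres.get(s.chrom)
        if cen is None or clen is None:
            arm = "unknown"
        else:
            short_is_left = cen <= clen - cen
            on_left = mid < cen
            arm = "short" if (on_left == short_is_left) else "long"
        per_chrom.setdefault(s.chrom, []).append(
            (mid, PatternBlock(frac, arm, colors[s.id]))
        )
    return {
        c: [b for _, b in sorted(blocks, key=lambda t: t[0])]
        for c, blocks in per_chrom.items()
    }


def assign_scheme(
    sublibraries: list[Sublibrary],
    primers: list[PrimerPair],
    centromeres: dict[str, int] | None = None,
    n_colors: int = 2,
    chrom_lengths: dict[str, int] | None = None,
    position_tolerance: float = 0.15,
    color_map: dict[str, str] | None = None,
) -> BarcodeScheme:
    """Assign internal pairs by chromosome and search external colors.

    Color vectors are tried exhaustively in lexicographic order over
    sublibraries sorted by (chromosome order of appearance, region start);
    the first vector whose patterns are pairwise distinguishable wins.
    Raises ``ValueError`` listing irreducibly colliding chromosome pairs if
    no vector works.
    """
    validate_primer_set(primers)
    by_id = {p.id: p for p in primers}
    chrom_order: list[str] = []
    for s in sublibraries:
        if s.chrom not in chrom_order:
            chrom_order.append(s.chrom)

    internal_ids = [pid for pid in by_id if pid.startswith("P")]
    external_ids = [pid for pid in by_id if pid.startswith("W")][:n_colors]
    if len(external_ids) < n_colors:
        raise ValueError(
            f"need {n_colors} external primer pairs, have {len(external_ids)}"
        )
    internal_for_chrom: dict[str, str] = {}
    for k, chrom in enumerate(chrom_order, start=1):
        pid = f"P{k}"
        if pid not in by_id:
            raise ValueError(f"no internal primer pair {pid} for {chrom}")
        internal_for_chrom[chrom] = pid
    del internal_ids

    ordered = sorted(
        sublibraries,
        key=lambda s: (chrom_order.index(s.chrom), s.region.start),
    )
    for vector in itertools.product(external_ids, repeat=len(ordered)):
        colors = {s.id: c for s, c in zip(ordered, vector)}
        patterns = build_patterns(ordered, colors, chrom_lengths, centromeres)
        scheme = BarcodeScheme(
            assignments={
                s.id: (internal_for_chrom[s.chrom], colors[s.id])
                for s in ordered
            },
            color_map=dict(color_map or DEFAULT_COLOR_MAP),
            per_chromosome_pattern=patterns,
            regions={
                s.id: (s.chrom, s.region.start, s.region.end) for s in ordered
            },
        )
        ok, _ = verify_scheme(scheme, position_tolerance)
        if ok:
            for s in sublibraries:
                s.external_class = colors[s.id]
            return scheme

    # no vector works: report chromosome pairs indistinguishable by
    # position/arm alone (color cannot rescue all of them simultaneously)
    patterns = build_patterns(
        ordered, {s.id: external_ids[0] for s in ordered},
        chrom_lengths, centromeres,
    )
    probe = BarcodeScheme(assignments={}, per_chromosome_pattern=patterns)
    _, collisions = verify_scheme(probe, position_tolerance)
    raise ValueError(
        "no distinguishable color assignment exists; positionally "
        f"colliding chromosome pairs: {collisions}"
    )


# -- probe assembly and in-silico PCR ---------------------------------------

@dataclass(frozen=True)
class Probe:
    name: str
    sequence: str


def assemble_probe(
    oligo, internal: PrimerPair, external: PrimerPair
) -> str:
    """Full synthesizable probe sequence for one insert.

    ``oligo`` may be an Oligo or a plain insert string. Inserts containing
    N are rejected.
    """
    insert = oligo if isinstance(oligo, str) else oligo.sequence
    if "N" in insert:
        raise ValueError("insert contains N")
    return (
        external.forward
        + internal.forward
        + insert
        + reverse_complement(internal.reverse)
        + reverse_complement(external.reverse)
    )


def assemble_pool(
    sublibraries: list[Sublibrary],
    scheme: BarcodeScheme,
    primers: list[PrimerPair],
    inserts: dict[str, list[str]],
) -> list[Probe]:
    """Assemble every probe of every sublibrary.

    ``inserts`` maps sublibrary id -> list of 50-nt insert sequences.
    Probe names are ``<sublibrary>:<serial>``.
    """
    by_id = {p.id: p for p in primers}
    pool: list[Probe] = []
    for s in sublibraries:
        internal, external = scheme.assignments[s.id]
        for i, ins in enumerate(inserts[s.id]):
            pool.append(
                Probe(
                    f"{s.id}:{i}",
                    assemble_probe(ins, by_id[internal], by_id[external]),
                )
            )
    return pool


def amplify_in_silico(pool: list[Probe], pair: PrimerPair) -> list[Probe]:
    """Exact-match PCR: keep probes where the forward primer occurs on the
    forward strand and rc(reverse primer) occurs downstream of it."""
    rc_rev = reverse_complement(pair.reverse)
    out = []
    for p in pool:
        i = p.sequence.find(pair.forward)
        if i >= 0 and p.sequence.find(rc_rev, i + len(pair.forward)) >= 0:
            out.append(p)
    return out


def pool_to_fasta(pool: list[Probe], path) -> None:
    with open(path, "w") as fh:
        for p in pool:
            fh.write(f">{p.name}\n{p.sequence}\n")
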