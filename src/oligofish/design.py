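"""Single-copy oligo design.

Candidate oligos (default 50 nt, step 5 nt) are tiled from unmasked,
N-free sequence, then filtered on genome-wide uniqueness: an oligo is
discarded when any other equal-length window of the genome — on either
strand, its own origin window excluded — matches it at MORE than
``similarity_threshold`` (default 0.75) ungapped positionwise identity.
With 50-nt oligos the boundary is exact: 38/50 matching positions removes
an oligo, 37/50 keeps it.

Similarity is deliberately ungapped identity over equal-length windows:
it is the simplest definition consistent with a per-window threshold rule
and admits an exact brute-force oracle; gapped alignment is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from .genome import Genome, Interval, write_bed

EXACT_ENGINE_MAX_BP = 50_000


@dataclass(frozen=True)
class Oligo:
    """A candidate/retained oligo on the forward strand of its record."""

    chrom: str
    start: int
    end: int
    sequence: str
    name: str = ""
    max_offtarget_identity: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("oligo coordinates do not match sequence length")
        if "N" in self.sequence:
            raise ValueError("oligo sequence contains N")


@dataclass(frozen=True)
class DesignParams:
    """Tunable parameters of the probe-design pipeline.

    ``min_density`` (2 oligos/kb) is the working density floor for region
    selection; ``soft_min_density`` (1.5/kb) is the literature floor below
    which FISH signals become unreliable and is kept as a reference bound.
    Region lengths default to the megabase scale used for chromosome
    barcode blocks (1.3–2.2 Mb).
    """

    oligo_length: int = 50
    step: int = 5
    similarity_threshold: float = 0.75
    min_density: float = 2.0
    soft_min_density: float = 1.5
    region_length_range: tuple[int, int] = (1_300_000, 2_200_000)
    max_regions_per_chrom: int = 2
    gc_range: tuple[float, float] | None = None  # optional practical filter

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.oligo_length):
            raise ValueError("need 0 < step <= oligo_length")
        if not (0.0 < self.similarity_threshold < 1.0):
            raise ValueError("similarity_threshold must be in (0, 1)")
        if self.min_density < self.soft_min_density:
            raise ValueError("min_density must be >= soft_min_density")
        lo, hi = self.region_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid region_length_range")

    def scaled(self, factor: float) -> "DesignParams":
        """Copy with region lengths scaled (densities held fixed)."""
        lo, hi = self.region_length_range
        return replace(
            self,
            region_length_range=(int(lo * factor), int(hi * factor)),
        )

    @property
    def max_matches_kept(self) -> int:
        """Largest off-target match count that still survives the filter."""
        return math.floor(self.similarity_threshold * self.oligo_length + 1e-9)


def tile_candidates(
    genome: Genome,
    mask: list[Interval] | None = None,
    params: DesignParams = DesignParams(),
) -> list[Oligo]:
    """Tile all candidate windows at multiples of ``step`` per record.

    Windows overlapping the mask or containing any non-ACGT base are
    excluded. Output is sorted by (record order, start); names are
    ``chrom:start``.
    """
    L, step = params.oligo_length, params.step
    mask_by_chrom: dict[str, list[Interval]] = {}
    for iv in mask or []:
        mask_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Oligo] = []
    for rid, seq in genome:
        n = len(seq)
        if n < L:
            continue
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        blocked = np.zeros(n + 1, dtype=np.int32)
        isbad = ~np.isin(raw, np.frombuffer(b"ACGT", dtype=np.uint8))
        badpos = np.flatnonzero(isbad)
        np.add.at(blocked, badpos, 1)
        np.add.at(blocked, badpos + 1, -1)
        for iv in mask_by_chrom.get(rid, []):
            blocked[max(iv.start, 0)] += 1
            blocked[min(iv.end, n)] -= 1
        covered = np.cumsum(blocked[:-1]) > 0
        ccov = np.r_[0, np.cumsum(covered)]
        starts = np.arange(0, n - L + 1, step)
        clean = (ccov[starts + L] - ccov[starts]) == 0
        for s in starts[clean]:
            s = int(s)
            out.append(Oligo(rid, s, s + L, seq[s : s + L], name=f"{rid}:{s}"))
    if params.gc_range is not None:
        lo, hi = params.gc_range
        out = [
            o
            for o in out
            if lo <= (o.sequence.count("G") + o.sequence.count("C")) / len(o.sequence) <= hi
        ]
    return out


def max_offtarget_identity(
    oligo: Oligo, genome: Genome, chunk: int = 200_000
) -> float:
    """Best ungapped identity of ``oligo`` against any other equal-length
    genomic window on either strand (own origin window excluded).
    """
    L = len(oligo.sequence)
    ci = _engine.encode_concat(genome)
    valid = _engine.window_validity(ci, L)
    oenc = _engine._CODE[
        np.frombuffer(oligo.sequence.encode("ascii"), dtype=np.uint8)
    ].astype(np.int32)
    own = ci.forward_pos(oligo.chrom, oligo.start)
    T = ci.T
    nwin = len(T) - L + 1
    best = 0
    for lo in range(0, nwin, chunk):
        hi = min(lo + chunk, nwin)
        W = np.lib.stride_tricks.sliding_window_view(T[lo : hi + L - 1], L)
        m = (W == oenc[None, :]).sum(axis=1)
        v = valid[lo:hi].copy()
        if lo <= own < hi:
            v[own - lo] = False
        m = np.where(v, m, 0)
        if len(m):
            best = max(best, int(m.max()))
    return best / L


def offtarget_match_counts(
    genome: Genome,
    params: DesignParams = DesignParams(),
    engine: str = "auto",
    seed_k: int = 12,
) -> dict[str, np.ndarray]:
    """Per-record arrays of max off-target match counts for every forward
    window start (both strands folded in, own window excluded).

    ``engine='exact'`` walks all diagonals (guaranteed); ``'seeded'`` uses
    exact shared 12-mers with full verification; ``'auto'`` picks exact for
    genomes up to ~50 kb.
    """
    if engine == "auto":
        engine = "exact" if genome.total_length <= EXACT_ENGINE_MAX_BP else "seeded"
    ci = _engine.encode_concat(genome)
    L = params.oligo_length
    if engine == "exact":
        best = _engine.scan_exact(ci, L)
    elif engine == "seeded":
        best = _engine.scan_seeded(ci, L, seed_k=seed_k)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return _engine.fold_to_forward(ci, best, L)


def filter_unique(
    oligos: list[Oligo],
    genome: Genome,
    params: DesignParams = DesignParams(),
    engine: str = "auto",
    seed_k: int = 12,
) -> list[Oligo]:
    """Retain oligos whose best off-target identity is <= the threshold.

    Strictly-greater-than removal: at the default 0.75 threshold a 50-mer
    with a 38/50-match off-target is removed, 37/50 survives. Each retained
    oligo is annotated with its off-target statistic (exact under the exact
    engine; a tight lower bound under the seeded engine).
    """
    counts = offtarget_match_counts(genome, params, engine=engine, seed_k=seed_k)
    keep_max = params.max_matches_kept
    L = params.oligo_length
    out: list[Oligo] = []
    for o in oligos:
        m = int(counts[o.chrom][o.start])
        if m <= keep_max:
            out.append(replace(o, max_offtarget_identity=m / L))
    return out


# -- exports ----------------------------------------------------------------

def oligos_to_bed(oligos: list[Oligo], path) -> None:
    """BED6 of oligo positions; score = round(1000 * (1 - identity))."""
    ivs = []
    for i, o in enumerate(oligos):
        ident = o.max_offtarget_identity or 0.0
        ivs.append(
            Interval(
                o.chrom, o.start, o.end,
                name=o.name or f"oligo_{i}",
                score=round(1000 * (1.0 - ident)),
                strand="+",
            )
        )
    write_bed(ivs, path)


def oligos_to_fasta(oligos: list[Oligo], path) -> None:
    with open(path, "w") as fh:
        for i, o in enumerate(oligos):
            fh.write(f">{o.name or f'oligo_{i}'}\n{o.sequence}\n")
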