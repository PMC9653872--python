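"""K-mer frequency repeat masking.

High-copy sequence is detected by counting canonical k-mers (a k-mer and its
reverse complement share one entry) and masking every position covered by a
k-mer whose genome-wide count exceeds ``max_count``. This plays the role a
homology-based repeat masker plays in a probe-design pipeline — keeping
tiling away from high-copy DNA — while the downstream similarity filter
remains the actual correctness gate for single-copy status.

Defaults ``k=17, max_count=4`` flag any 17-mer seen five or more times;
both are configurable. Windows containing N are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, Interval, merge_intervals, reverse_complement


@dataclass
class KmerCountTable:
    """Canonical k-mer counts backed by sorted packed-integer arrays."""

    k: int
    values: np.ndarray  # sorted int64 2-bit packed canonical k-mers
    counts: np.ndarray  # int64, parallel to values

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> int:
        """Total counted windows (= positions minus N-containing windows)."""
        return int(self.counts.sum())

    def count_of(self, kmer: str) -> int:
        """Count of a k-mer given as a string (canonical form applied)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} nt")
        v = min(_pack(kmer), _pack(reverse_complement(kmer)))
        i = int(np.searchsorted(self.values, v))
        if i < len(self.values) and self.values[i] == v:
            return int(self.counts[i])
        return 0

    def as_dict(self) -> dict[str, int]:
        """Materialize as {canonical k-mer string: count} (small tables)."""
        return {
            _unpack(int(v), self.k): int(c)
            for v, c in zip(self.values, self.counts)
        }


def _pack(kmer: str) -> int:
    v = 0
    for ch in kmer:
        v = (v << 2) | "ACGT".index(ch)
    return v


def _unpack(v: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[v & 3])
        v >>= 2
    return "".join(reversed(out))


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical packed values, window starts) for N-free windows."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    c = np.where(codes >= 0, codes, 0).astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for t in range(k):
        fwd <<= 2
        fwd |= c[t : n + t]
        rev |= (3 - c[t : n + t]) << (2 * t)
    bad = codes < 0
    cb = np.cumsum(bad, dtype=np.int64)
    clean = np.empty(n, dtype=bool)
    clean[0] = cb[k - 1] == 0
    clean[1:] = (cb[k:] - cb[:-k]) == 0
    starts = np.flatnonzero(clean)
    return np.minimum(fwd, rev)[starts], starts


def count_kmers(genome: Genome, k: int) -> KmerCountTable:
    """Count canonical k-mers over every record; N windows are skipped.

    Raises ``ValueError`` if k is outside 1..31 or exceeds every record
    length.
    """
    if not (1 <= k <= 31):
        raise ValueError(f"k={k} outside the supported range 1..31")
    if k > max(genome.lengths.values()):
        raise ValueError(f"k={k} is larger than every record in the genome")
    chunks = [_kmer_values(_encode(seq), k)[0] for _, seq in genome]
    allv = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    values, counts = np.unique(allv, return_counts=True)
    return KmerCountTable(k=k, values=values, counts=counts.astype(np.int64))


def mask_repeats(
    genome: Genome,
    k: int = 17,
    max_count: int = 4,
    respect_softmask: bool = True,
    table: KmerCountTable | None = None,
) -> list[Interval]:
    """Mask every position covered by a k-mer with count > ``max_count``.

    Returns a merged, sorted interval list (a mask track). When
    ``respect_softmask`` is true, lowercase runs recorded at genome load
    (e.g. repeat-masker soft masking) are unioned into the track.
    """
    if table is None:
        table = count_kmers(genome, k)
    elif table.k != k:
        raise ValueError(f"count table k={table.k} does not match k={k}")
    intervals: list[Interval] = []
    for rid, seq in genome:
        values, starts = _kmer_values(_encode(seq), k)
        if len(values):
            idx = np.searchsorted(table.values, values)
            idx = np.clip(idx, 0, len(table.values) - 1)
            hit = (table.values[idx] == values) & (table.counts[idx] > max_count)
            cover = np.zeros(len(seq) + 1, dtype=np.int32)
            hs = starts[hit]
            np.add.at(cover, hs, 1)
            np.add.at(cover, hs + k, -1)
            covered = np.cumsum(cover[:-1]) > 0
            intervals.extend(_runs_to_intervals(rid, covered))
        if respect_softmask:
            intervals.extend(genome.softmask[rid])
    return merge_intervals(intervals)


def _runs_to_intervals(rid: str, flags: np.ndarray) -> list[Interval]:
    if not flags.any():
        return []
    padded = np.r_[False, flags, False]
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [Interval(rid, int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]
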