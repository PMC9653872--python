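"""Genome and interval primitives.

All coordinates are 0-based, half-open ``[start, end)``; BED input/output
matches this natively. Sequences are stored uppercase over the alphabet
``{A, C, G, T, N}``; lowercase input (soft-masked, e.g. RepeatMasker output)
is folded to uppercase and the lowercase runs are retained as a per-record
soft-mask track so downstream masking can honour them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    Length-preserving involution; N maps to N. Any other character raises
    ``ValueError``.
    """
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A genomic interval with 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """An ordered collection of named DNA sequences.

    Parameters
    ----------
    records
        Iterable of ``(id, sequence)`` pairs. Ids must be unique; sequences
        are folded to uppercase and validated against ``{A,C,G,T,N}``.
        Lowercase runs in the input are recorded in :attr:`softmask`.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.ids: list[str] = []
        self._seqs: dict[str, str] = {}
        self.softmask: dict[str, list[Interval]] = {}
        for rid, seq in records:
            if rid in self._seqs:
                raise ValueError(f"duplicate record id: {rid!r}")
            upper = seq.upper()
            bad = set(upper) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rid!r} contains non-DNA characters: {sorted(bad)}"
                )
            self.ids.append(rid)
            self._seqs[rid] = upper
            self.softmask[rid] = _lowercase_runs(rid, seq)
        if not self.ids:
            raise ValueError("genome has no records")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, rid: str) -> bool:
        return rid in self._seqs

    def __getitem__(self, rid: str) -> str:
        return self._seqs[rid]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for rid in self.ids:
            yield rid, self._seqs[rid]

    # -- queries ------------------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(self._seqs[rid]) for rid in self.ids}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def length(self, rid: str) -> int:
        return len(self._seqs[rid])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end]``; coordinates are validated."""
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"coordinates {start}-{end} out of bounds for "
                f"{chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(self._seqs[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds record "
                f"length {len(self._seqs[iv.chrom])}"
            )


def _lowercase_runs(rid: str, seq: str) -> list[Interval]:
    runs: list[Interval] = []
    start = None
    for i, ch in enumerate(seq):
        if ch.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append(Interval(rid, start, i))
            start = None
    if start is not None:
        runs.append(Interval(rid, start, len(seq)))
    return runs


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Record order is preserved. Duplicate ids or an empty file raise
    ``ValueError``.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in genome]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# -- BED --------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/4/6 into a list of intervals (order preserved)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 and f[5] != "." else None
            out.append(Interval(f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write BED; emits 3, 4 or 6 columns depending on populated fields."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(_fmt_score(iv.score))
                cols.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(cols) + "\n")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(score)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals per chromosome; sorted output."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged
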