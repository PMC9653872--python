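"""Cross-species transferability of a designed oligo pool.

Each oligo is mapped to its best equal-length window on a related target
genome (both strands, ungapped positionwise identity — the same similarity
notion the uniqueness filter uses). Per sublibrary the hits are summarised
into: mapped fraction, majority target chromosome, a trimmed cluster span,
and a coherence score; per genome, whether the transferred positional
patterns still form a resolvable barcode.

The mapper is seed-and-verify (exact shared 12-mers at any offset, full
verification of every implicated window) and reports at most one best hit
per oligo; ties break to the leftmost window on the lowest-indexed
chromosome, forward strand first. A hook accepts externally produced hit
tables (TSV) for users who prefer a full aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import _engine
from .barcode import BarcodeScheme, build_patterns, verify_scheme
from .design import Oligo
from .genome import Genome, Interval
from .selection import Sublibrary


@dataclass(frozen=True)
class OligoHit:
    oligo: str
    chrom: str
    start: int
    strand: str
    identity: float


def map_oligos(
    oligos: list[Oligo],
    target: Genome,
    min_identity: float = 0.88,
    seed_k: int = 12,
    chunk: int = 200_000,
) -> list[OligoHit]:
    """Best-window hits of each oligo on ``target`` (both strands).

    Only hits with identity >= ``min_identity`` are reported; at most one
    hit per oligo. Default 0.88 tolerates ~6 mismatches in a 50-mer.
    """
    if not oligos:
        return []
    L = len(oligos[0].sequence)
    if any(len(o.sequence) != L for o in oligos):
        raise ValueError("oligos must share one length")
    ci = _engine.encode_concat(target)
    T = ci.T
    N = len(T)
    valid = _engine.window_validity(ci, L)
    kv, pos = _engine.pack_kmers(ci, seed_k)
    order = np.argsort(kv, kind="stable")
    skv, spos = kv[order], pos[order]

    # oligo k-mers at every offset
    n = len(oligos)
    O = np.empty((n, L), dtype=np.int64)
    for i, o in enumerate(oligos):
        O[i] = _engine._CODE[
            np.frombuffer(o.sequence.encode("ascii"), dtype=np.uint8)
        ]
    noff = L - seed_k + 1
    okv = np.zeros((n, noff), dtype=np.int64)
    for t in range(seed_k):
        okv <<= 2
        okv |= O[:, t : noff + t]

    flat = okv.ravel()
    left = np.searchsorted(skv, flat, side="left")
    right = np.searchsorted(skv, flat, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return []
    rep = np.repeat(np.arange(len(flat)), counts)
    # index into spos for every expanded hit
    inner = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    tpos = spos[np.repeat(left, counts) + inner]
    oli = rep // noff
    off = rep % noff
    w = tpos - off
    ok = (w >= 0) & (w <= N - L)
    oli, w = oli[ok], w[ok]
    ok = valid[w]
    oli, w = oli[ok], w[ok]
    key = oli.astype(np.int64) * N + w
    key = np.unique(key)
    oli = (key // N).astype(np.int64)
    w = (key % N).astype(np.int64)

    # verify every candidate window
    matches = np.empty(len(w), dtype=np.int32)
    rel = np.arange(L, dtype=np.int64)
    for lo in range(0, len(w), chunk):
        sl = slice(lo, min(lo + chunk, len(w)))
        G = T[w[sl, None] + rel[None, :]]
        matches[sl] = (G == O[oli[sl]]).sum(axis=1)

    min_matches = int(np.ceil(min_identity * L - 1e-9))
    ok = matches >= min_matches
    oli, w, matches = oli[ok], w[ok], matches[ok]
    if len(w) == 0:
        return []

    # map windows to (record index, forward start, strand) for tie-breaks
    rec_idx, fstart, strand_bit = _locate_many(ci, w, L)
    rank = (rec_idx.astype(np.int64) * (N + 1) + fstart) * 2 + strand_bit
    order = np.lexsort((rank, -matches, oli))
    oli, w, matches, rank = oli[order], w[order], matches[order], rank[order]
    first = np.r_[True, oli[1:] != oli[:-1]]

    ids = [o.name or f"{o.chrom}:{o.start}" for o in oligos]
    out: list[OligoHit] = []
    for i in np.flatnonzero(first):
        r, s, b = int(rec_idx[order][i]), int(fstart[order][i]), int(strand_bit[order][i])
        out.append(
            OligoHit(
                oligo=ids[int(oli[i])],
                chrom=ci.ids[r],
                start=s,
                strand="+" if b == 0 else "-",
                identity=float(matches[i]) / L,
            )
        )
    return out


def _locate_many(
    ci: _engine.ConcatIndex, w: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    block_starts = []
    block_rec = []
    block_strand = []
    for r, rid in enumerate(ci.ids):
        block_starts.append(ci.f_off[rid])
        block_rec.append(r)
        block_strand.append(0)
    for r, rid in enumerate(ci.ids):
        block_starts.append(ci.r_off[rid])
        block_rec.append(r)
        block_strand.append(1)
    bs = np.array(block_starts)
    br = np.array(block_rec)
    bb = np.array(block_strand)
    idx = np.searchsorted(bs, w, side="right") - 1
    rec_idx = br[idx]
    strand_bit = bb[idx]
    lens = np.array([ci.lengths[ci.ids[r]] for r in rec_idx])
    local = w - bs[idx]
    fstart = np.where(strand_bit == 0, local, lens - local - L)
    return rec_idx, fstart, strand_bit


# -- hit table hooks --------------------------------------------------------

def write_hits_tsv(hits: list[OligoHit], path) -> None:
    pd.DataFrame([asdict(h) for h in hits]).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[OligoHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        OligoHit(str(r.oligo), str(r.chrom), int(r.start), str(r.strand),
                 float(r.identity))
        for r in df.itertuples()
    ]


# -- transfer report --------------------------------------------------------

@dataclass
class SublibraryTransfer:
    sublibrary_id: str
    source_chrom: str
    mapped_fraction: float
    assigned_chrom: str | None
    cluster_span: Interval | None
    coherence: float | None
    moved: bool | None  # assigned chromosome differs from the source one


@dataclass
class TransferReport:
    entries: list[SublibraryTransfer]
    barcode_conserved: bool
    collisions: list[tuple[str, str]]

    def to_json(self, path) -> None:
        doc = {
            "barcode_conserved": self.barcode_conserved,
            "collisions": [list(c) for c in self.collisions],
            "sublibraries": [
                {
                    **{k: v for k, v in asdict(e).items() if k != "cluster_span"},
                    "cluster_span": (
                        None
                        if e.cluster_span is None
                        else [e.cluster_span.chrom, e.cluster_span.start,
                              e.cluster_span.end]
                    ),
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    def to_tsv(self, path) -> None:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "sublibrary": e.sublibrary_id,
                    "source_chrom": e.source_chrom,
                    "mapped_fraction": round(e.mapped_fraction, 4),
                    "assigned_chrom": e.assigned_chrom or "",
                    "span_start": "" if e.cluster_span is None else e.cluster_span.start,
                    "span_end": "" if e.cluster_span is None else e.cluster_span.end,
                    "coherence": "" if e.coherence is None else round(e.coherence, 4),
                    "moved": "" if e.moved is None else e.moved,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def transfer_report(
    sublibraries: list[Sublibrary],
    hits: list[OligoHit],
    scheme: BarcodeScheme,
    target: Genome,
    min_mapped_fraction: float = 0.1,
    trim_fraction: float = 0.05,
    coherence_pad: float = 0.5,
    position_tolerance: float = 0.15,
) -> TransferReport:
    """Summarise transferability per sublibrary and for the whole barcode.

    ``cluster_span`` is the interval holding the central
    ``1 - 2*trim_fraction`` of hit positions on the majority chromosome;
    ``coherence`` is the fraction of the sublibrary's mapped oligos lying on
    that chromosome within the span dilated by ``coherence_pad`` x span
    length per side (so a tight unique-hit cluster scores 1.0 while
    paralogous strays and translocations score against it).
    """
    hits_by_oligo = {h.oligo: h for h in hits}
    chrom_rank = {c: i for i, c in enumerate(target.ids)}
    entries: list[SublibraryTransfer] = []
    transferred: list[Sublibrary] = []
    colors: dict[str, str] = {}
    for s in sublibraries:
        sub_hits = [hits_by_oligo[i] for i in s.oligo_ids if i in hits_by_oligo]
        frac = len(sub_hits) / s.oligo_count if s.oligo_count else 0.0
        if not sub_hits:
            entries.append(
                SublibraryTransfer(s.id, s.chrom, frac, None, None, None, None)
            )
            continue
        tally: dict[str, int] = {}
        for h in sub_hits:
            tally[h.chrom] = tally.get(h.chrom, 0) + 1
        assigned = min(tally, key=lambda c: (-tally[c], chrom_rank.get(c, 1 << 30)))
        pos = np.sort(
            np.array([h.start for h in sub_hits if h.chrom == assigned])
        )
        k = int(np.floor(trim_fraction * len(pos)))
        lo, hi = int(pos[k]), int(pos[len(pos) - 1 - k])
        span = Interval(assigned, lo, hi + 1)
        pad = coherence_pad * max(hi - lo, 1)
        inside = sum(
            1
            for h in sub_hits
            if h.chrom == assigned and lo - pad <= h.start <= hi + pad
        )
        coherence = inside / len(sub_hits)
        entries.append(
            SublibraryTransfer(
                s.id, s.chrom, frac, assigned, span, coherence,
                assigned != s.chrom,
            )
        )
        if frac >= min_mapped_fraction:
            transferred.append(
                Sublibrary(
                    id=s.id,
                    chrom=assigned,
                    region=Interval(assigned, lo, max(hi + 1, lo + 1)),
                    internal_primer=s.internal_primer,
                    external_class=scheme.external_of(s.id),
                )
            )
            colors[s.id] = scheme.external_of(s.id)

    patterns = build_patterns(transferred, colors, target.lengths)
    probe = BarcodeScheme(
        assignments={}, per_chromosome_pattern=patterns
    )
    conserved, collisions = verify_scheme(probe, position_tolerance)
    return TransferReport(entries, conserved, collisions)
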