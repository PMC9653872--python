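"""Shared integer-encoded sequence machinery.

Both strands of every record are laid out in one int32 array ``T``:

    [rec1] J [rec2] J ... [recR] J [rc(rec1)] J ... [rc(recR)] J

``J`` is a junction pad. A/C/G/T map to 0..3; every other position (N bases
and junction pads) gets a unique code ``>= 10`` so it never matches anything,
including other ambiguous positions. Off-target identity between two
oligo-length windows is then a count of positionwise equalities, and a
window pair on opposite strands appears as a forward-block/rc-block pair.

Two scan engines compute, for every valid window start, the maximum match
count against any other valid window (both strands):

* ``scan_exact`` walks every diagonal of T x T — O(|T|^2), guaranteed exact,
  intended for genomes up to a few tens of kb.
* ``scan_seeded`` enumerates exact shared k-mers (default k=12) at all
  offsets, then verifies every implicated window pair exhaustively. Any
  alignment with at most ``floor((50-k)/k)`` mismatches necessarily contains
  an exact k-run and is found; near-threshold alignments (e.g. 12 mismatches
  in 50) are found whenever they contain one exact k-run, which is the
  practically relevant regime for randomly diverged duplications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome

JUNCTION = 64  # pad length between blocks; > any window length in use
AMBIG_BASE = 10  # first code reserved for never-matching positions

_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_RC_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("TGCA"):
    _RC_CODE[ord(_b)] = _i


@dataclass
class ConcatIndex:
    """Both-strand concatenation of a genome with coordinate maps."""

    ids: list[str]
    lengths: dict[str, int]
    f_off: dict[str, int]  # record id -> offset of forward block in T
    r_off: dict[str, int]  # record id -> offset of reverse-complement block
    T: np.ndarray  # int32 codes
    n_forward: int  # length of the forward half (incl. junctions)

    def forward_pos(self, chrom: str, start: int) -> int:
        return self.f_off[chrom] + start

    def rc_window_pos(self, chrom: str, start: int, L: int) -> int:
        """T-position of the rc-strand window mirroring (chrom, start, L)."""
        return self.r_off[chrom] + self.lengths[chrom] - start - L

    def locate(self, tpos: int, L: int) -> tuple[str, int, str]:
        """Map a T window start back to (chrom, forward start, strand)."""
        for rid in self.ids:
            off, n = self.f_off[rid], self.lengths[rid]
            if off <= tpos <= off + n - L:
                return rid, tpos - off, "+"
        for rid in self.ids:
            off, n = self.r_off[rid], self.lengths[rid]
            if off <= tpos <= off + n - L:
                return rid, n - (tpos - off) - L, "-"
        raise ValueError(f"T position {tpos} is not a valid window start")


def encode_concat(genome: Genome) -> ConcatIndex:
    ids = list(genome.ids)
    lengths = genome.lengths
    total = sum(lengths.values())
    n_half = total + JUNCTION * len(ids)
    T = np.empty(2 * n_half, dtype=np.int32)
    f_off: dict[str, int] = {}
    r_off: dict[str, int] = {}

    pos = 0
    for rid in ids:
        f_off[rid] = pos
        raw = np.frombuffer(genome[rid].encode("ascii"), dtype=np.uint8)
        T[pos : pos + len(raw)] = _CODE[raw]
        pos += len(raw) + JUNCTION
    for rid in ids:
        r_off[rid] = pos
        raw = np.frombuffer(genome[rid].encode("ascii"), dtype=np.uint8)
        T[pos : pos + len(raw)] = _RC_CODE[raw][::-1]
        pos += len(raw) + JUNCTION

    # junction pads were skipped above; give every non-ACGT position
    # (pads and N bases alike) a unique never-matching code
    mask = np.ones(len(T), dtype=bool)
    cursor = 0
    for rid in ids + ids:  # mark real spans (fwd pass then rc pass)
        mask[cursor : cursor + lengths[rid]] = False
        cursor += lengths[rid] + JUNCTION
    T[mask] = 0  # placeholder for pads before unique coding
    ambig = mask | (T < 0)
    # N bases inside records decode to -1 via _CODE; fold them in too
    T[ambig] = AMBIG_BASE + np.arange(int(ambig.sum()), dtype=np.int32)
    return ConcatIndex(ids, lengths, f_off, r_off, T, n_half)


def window_validity(ci: ConcatIndex, L: int) -> np.ndarray:
    """Boolean array over T window starts: all L positions are real bases."""
    real = (ci.T >= 0) & (ci.T <= 3)
    c = np.cumsum(real, dtype=np.int64)
    n = len(ci.T) - L + 1
    full = np.empty(n, dtype=bool)
    full[0] = c[L - 1] == L
    full[1:] = (c[L:] - c[:-L]) == L
    out = np.zeros(len(ci.T), dtype=bool)
    out[:n] = full
    return out


def _window_sums(eq: np.ndarray, L: int) -> np.ndarray:
    c = np.cumsum(eq, dtype=np.int32)
    m = c[L - 1 :].copy()
    m[1:] -= c[:-L]
    return m


def scan_exact(ci: ConcatIndex, L: int) -> np.ndarray:
    """Max match count per valid T window vs any other valid window.

    Walks every diagonal d >= 1; the d = 0 diagonal (a window against
    itself) is excluded, which realises the own-origin exclusion rule.
    """
    T = ci.T
    N = len(T)
    valid = window_validity(ci, L)
    best = np.zeros(N, dtype=np.int16)
    for d in range(1, N - L + 1):
        eq = T[: N - d] == T[d:]
        m = _window_sums(eq, L).astype(np.int16)
        M = len(m)
        vm = valid[:M] & valid[d : d + M]
        np.multiply(m, vm, out=m)
        np.maximum(best[:M], m, out=best[:M])
        np.maximum(best[d : d + M], m, out=best[d : d + M])
    best[~valid] = 0
    return best


# -- seeded engine ----------------------------------------------------------

def pack_kmers(ci: ConcatIndex, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, positions) of all valid k-windows of T, 2-bit packed."""
    if not (1 <= k <= 31):
        raise ValueError("k must be in 1..31 for 2-bit packing")
    T = ci.T
    codes = np.where((T >= 0) & (T <= 3), T, 0).astype(np.int64)
    n = len(T) - k + 1
    kv = np.zeros(n, dtype=np.int64)
    for t in range(k):
        kv <<= 2
        kv |= codes[t : n + t]
    pos = np.flatnonzero(window_validity(ci, k)[:n])
    return kv[pos], pos


def _seed_pairs(
    kv: np.ndarray, pos: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """All position pairs sharing a k-mer value, up to max_lag apart in the
    per-value position list (caps quadratic blowup in huge repeat families)."""
    order = np.lexsort((pos, kv))
    v = kv[order]
    p = pos[order].astype(np.int64)
    same = v[1:] == v[:-1]
    p1s: list[np.ndarray] = []
    p2s: list[np.ndarray] = []
    lag = 1
    cur = same
    while lag <= max_lag and cur.any():
        idx = np.flatnonzero(cur)
        p1s.append(p[idx])
        p2s.append(p[idx + lag])
        lag += 1
        if lag > max_lag:
            break
        cur = cur[:-1] & same[lag - 1 :]
    if not p1s:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(p1s), np.concatenate(p2s)


def scan_seeded(
    ci: ConcatIndex,
    L: int,
    seed_k: int = 12,
    max_lag: int = 64,
    chunk: int = 100_000,
) -> np.ndarray:
    """Seed-and-verify variant of :func:`scan_exact`.

    Returns a per-window lower bound on the max match count; exact for any
    window pair whose best alignment contains an exact ``seed_k``-run.
    """
    T = ci.T
    N = len(T)
    valid = window_validity(ci, L)
    best = np.zeros(N, dtype=np.int16)

    kv, pos = pack_kmers(ci, seed_k)
    p1, p2 = _seed_pairs(kv, pos, max_lag)
    if len(p1) == 0:
        return best
    # drop pairs lying entirely in the rc half: they mirror forward pairs
    keep = p1 < ci.n_forward
    p1, p2 = p1[keep], p2[keep]
    d_all = p2 - p1
    keep = d_all > 0  # self pairs cannot occur (p1 < p2 by construction)
    p1, d_all = p1[keep], d_all[keep]

    span = 2 * L - 1
    rel = np.arange(span, dtype=np.int64)
    relw = np.arange(L, dtype=np.int64)
    for lo in range(0, len(p1), chunk):
        a = p1[lo : lo + chunk] - (L - 1)
        d = d_all[lo : lo + chunk]
        g1 = a[:, None] + rel[None, :]
        g2 = g1 + d[:, None]
        inb = (g1 >= 0) & (g2 < N)
        eq = (T[np.clip(g1, 0, N - 1)] == T[np.clip(g2, 0, N - 1)]) & inb
        c = np.cumsum(eq, axis=1, dtype=np.int32)
        m = c[:, L - 1 :].copy()
        m[:, 1:] -= c[:, :-L]
        w = a[:, None] + relw[None, :]
        wd = w + d[:, None]
        ok = (w >= 0) & (wd <= N - L)
        wc = np.clip(w, 0, N - L)
        wdc = np.clip(wd, 0, N - L)
        ok &= valid[wc] & valid[wdc]
        mm = np.where(ok, m, 0).astype(np.int16)
        np.maximum.at(best, wc, mm)
        np.maximum.at(best, wdc, mm)
    best[~valid] = 0
    return best


def fold_to_forward(ci: ConcatIndex, best: np.ndarray, L: int) -> dict[str, np.ndarray]:
    """Per-record forward-window max, folding in the mirrored rc windows."""
    out: dict[str, np.ndarray] = {}
    for rid in ci.ids:
        n = ci.lengths[rid]
        nw = max(n - L + 1, 0)
        if nw == 0:
            out[rid] = np.zeros(0, dtype=np.int16)
            continue
        fo, ro = ci.f_off[rid], ci.r_off[rid]
        fwd = best[fo : fo + nw]
        rev = best[ro : ro + nw][::-1]
        out[rid] = np.maximum(fwd, rev)
    return out
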