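"""Independent brute-force oracle for genome-wide off-target identity.

Formulated differently from the package engines on purpose: every window of
every record (both strands) is materialized as a code matrix and match
counts are taken through per-base indicator matrix products. A pure-python
triple loop (`oracle_best_matches_slow`) backs the matrix formulation on
tiny inputs.
"""

from __future__ import annotations

import numpy as np

from oligofish.genome import Genome, reverse_complement

_CODE = {c: i for i, c in enumerate("ACGT")}


def _all_windows(genome: Genome, L: int):
    meta: list[tuple[str, int, str]] = []
    rows: list[str] = []
    for rid, seq in genome:
        for s in range(len(seq) - L + 1):
            w = seq[s : s + L]
            if any(c not in _CODE for c in w):
                continue
            meta.append((rid, s, "+"))
            rows.append(w)
            meta.append((rid, s, "-"))
            rows.append(reverse_complement(w))
    M = np.array([[_CODE[c] for c in w] for w in rows], dtype=np.int8)
    return meta, M


def oracle_best_matches(
    genome: Genome, candidates, L: int = 50, chunk: int = 2000
) -> np.ndarray:
    """Max match count of each candidate against every other window."""
    meta, M = _all_windows(genome, L)
    index = {m: i for i, m in enumerate(meta)}
    C = np.array(
        [[_CODE[c] for c in o.sequence] for o in candidates], dtype=np.int8
    )
    out = np.empty(len(candidates), dtype=np.int32)
    for lo in range(0, len(candidates), chunk):
        hi = min(lo + chunk, len(candidates))
        counts = np.zeros((len(meta), hi - lo), dtype=np.float32)
        for b in range(4):
            counts += (M == b).astype(np.float32) @ (
                C[lo:hi] == b
            ).astype(np.float32).T
        for j in range(lo, hi):
            o = candidates[j]
            counts[index[(o.chrom, o.start, "+")], j - lo] = 0.0
        out[lo:hi] = counts.max(axis=0).astype(np.int32)
    return out


def oracle_decisions(
    genome: Genome, candidates, threshold: float = 0.75, L: int = 50
) -> list[bool]:
    """True = retained (identity <= threshold strictly enforced as 'more
    than threshold is removed')."""
    best = oracle_best_matches(genome, candidates, L)
    return [(m / L) <= threshold + 1e-12 for m in best]


def oracle_best_matches_slow(genome: Genome, candidates, L: int = 50):
    """Pure-python reference used to validate the matrix oracle."""
    wins = []
    for rid, seq in genome:
        for s in range(len(seq) - L + 1):
            w = seq[s : s + L]
            if any(c not in _CODE for c in w):
                continue
            wins.append((rid, s, "+", w))
            wins.append((rid, s, "-", reverse_complement(w)))
    out = []
    for o in candidates:
        best = 0
        for rid, s, st, w in wins:
            if rid == o.chrom and s == o.start and st == "+":
                continue
            best = max(best, sum(a == b for a, b in zip(o.sequence, w)))
        out.append(best)
    return out
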