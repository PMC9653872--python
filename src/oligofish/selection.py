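"""Megabase-scale sublibrary region selection.

Per chromosome, up to ``max_regions_per_chrom`` non-overlapping regions are
chosen whose retained-oligo density clears ``min_density`` and whose length
lies inside ``region_length_range``. The procedure is deterministic:

1. slide a window of the range floor across the chromosome (``window_step``
   grid) and keep windows with density >= the floor;
2. greedily pick the densest non-overlapping windows (ties -> leftmost);
   when a centromere is known and a second region is wanted, windows on the
   arm opposite the first pick are preferred if any qualify;
3. extend each pick outward (right, then left) in ``extend_step``
   increments while density stays above the floor and length below the
   range ceiling.

A chromosome with no qualifying window yields zero sublibraries and a
warning record, never an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .design import DesignParams, Oligo
from .genome import Interval


@dataclass
class Sublibrary:
    """A selected region with its member oligos and primer assignment."""

    id: str
    chrom: str
    region: Interval
    oligo_ids: list[str] = field(default_factory=list)
    oligo_count: int = 0
    internal_primer: str = ""
    external_class: str | None = None

    def __post_init__(self) -> None:
        if self.oligo_ids and self.oligo_count != len(self.oligo_ids):
            raise ValueError("oligo_count disagrees with oligo_ids")
        if self.region.chrom != self.chrom:
            raise ValueError("region chromosome disagrees with sublibrary chrom")

    @property
    def density(self) -> float:
        return sublibrary_density(self)


def sublibrary_density(s: Sublibrary) -> float:
    """Oligos per kb: count / (region length in bp / 1000), full precision."""
    n = len(s.region)
    if n <= 0:
        raise ValueError("zero-length region")
    return s.oligo_count / (n / 1000.0)


def display_density(value: float, ndigits: int = 2) -> float:
    """Half-up rounding used for human-readable density columns."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def density_profile(
    oligos: list[Oligo],
    chrom: str,
    window: int,
    step: int,
    chrom_length: int | None = None,
) -> list[tuple[Interval, float]]:
    """Sliding-window density (oligo starts per kb) along one chromosome."""
    if window < step:
        raise ValueError("need window >= step")
    starts = np.array(sorted(o.start for o in oligos if o.chrom == chrom))
    if chrom_length is None:
        if len(starts) == 0:
            raise KeyError(f"chromosome {chrom!r} absent and no length given")
        chrom_length = int(max(o.end for o in oligos if o.chrom == chrom))
    out: list[tuple[Interval, float]] = []
    for s in range(0, max(chrom_length - window, 0) + 1, step):
        n = int(np.searchsorted(starts, s + window) - np.searchsorted(starts, s))
        out.append((Interval(chrom, s, s + window), n / (window / 1000.0)))
    return out


def _count_in(starts: np.ndarray, lo: int, hi: int) -> int:
    """Oligo starts within [lo, hi - L]: callers pass hi already adjusted."""
    return int(np.searchsorted(starts, hi, side="right") - np.searchsorted(starts, lo))


def select_regions(
    oligos: list[Oligo],
    params: DesignParams = DesignParams(),
    centromeres: dict[str, int] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    window_step: int = 100_000,
    extend_step: int = 50_000,
) -> list[Sublibrary]:
    """Deterministic region selection; see module docstring for the rules.

    ``chrom_lengths`` fixes the chromosome set and order (recommended);
    otherwise both are inferred from the oligos. Internal primer ids
    P1..Pn follow chromosome order.
    """
    centromeres = centromeres or {}
    if chrom_lengths is None:
        chrom_lengths = {}
        for o in oligos:
            chrom_lengths[o.chrom] = max(chrom_lengths.get(o.chrom, 0), o.end)

    by_chrom: dict[str, list[Oligo]] = {c: [] for c in chrom_lengths}
    for o in oligos:
        if o.chrom in by_chrom:
            by_chrom[o.chrom].append(o)

    L = params.oligo_length
    rmin, rmax = params.region_length_range
    out: list[Sublibrary] = []
    for ci, chrom in enumerate(chrom_lengths, start=1):
        clen = chrom_lengths[chrom]
        members = sorted(by_chrom[chrom], key=lambda o: o.start)
        ostarts = np.array([o.start for o in members], dtype=np.int64)

        picked: list[tuple[int, int]] = []
        if clen >= rmin:
            wstarts = np.arange(0, clen - rmin + 1, window_step)
            counts = np.array(
                [_count_in(ostarts, s, s + rmin - L) for s in wstarts]
            )
            dens = counts / (rmin / 1000.0)
            ok = dens >= params.min_density
            order = np.lexsort((wstarts[ok], -counts[ok]))
            cand = [(int(wstarts[ok][i]), int(counts[ok][i])) for i in order]
            cen = centromeres.get(chrom)
            for s, _n in _greedy_pick(
                cand, rmin, params.max_regions_per_chrom, cen
            ):
                picked.append((s, s + rmin))

        # outward extension, right then left, density floor maintained
        extended: list[tuple[int, int]] = []
        for s, e in picked:
            others = [iv for iv in picked if (iv[0], iv[1]) != (s, e)]
            s, e = _extend(
                s, e, ostarts, L, params, rmax, clen, extend_step,
                [o for o in extended] + others,
            )
            extended.append((s, e))

        extended.sort()
        if not extended:
            warnings.warn(
                f"no qualifying region on {chrom} "
                f"(need length in [{rmin}, {rmax}] at >= "
                f"{params.min_density}/kb)",
                stacklevel=2,
            )
        for ri, (s, e) in enumerate(extended, start=1):
            ids = [o.name for o in members if o.start >= s and o.end <= e]
            out.append(
                Sublibrary(
                    id=f"{chrom}_r{ri}",
                    chrom=chrom,
                    region=Interval(chrom, s, e),
                    oligo_ids=ids,
                    oligo_count=len(ids),
                    internal_primer=f"P{ci}",
                )
            )
    return out


def _greedy_pick(
    cand: list[tuple[int, int]],
    width: int,
    max_regions: int,
    centromere: int | None,
) -> list[tuple[int, int]]:
    picked: list[tuple[int, int]] = []

    def overlaps_any(s: int) -> bool:
        return any(s < p + width and p < s + width for p, _ in picked)

    def arm(s: int) -> str:
        mid = s + width // 2
        return "left" if centromere is not None and mid < centromere else "right"

    while len(picked) < max_regions:
        pool = [c for c in cand if not overlaps_any(c[0])]
        if not pool:
            break
        if picked and centromere is not None:
            first_arm = arm(picked[0][0])
            opposite = [c for c in pool if arm(c[0]) != first_arm]
            if opposite:
                pool = opposite
        picked.append(pool[0])
    return picked


def _extend(
    s: int,
    e: int,
    ostarts: np.ndarray,
    L: int,
    params: DesignParams,
    rmax: int,
    clen: int,
    step: int,
    others: list[tuple[int, int]],
) -> tuple[int, int]:
    def ok(ns: int, ne: int) -> bool:
        if ne - ns > rmax or ns < 0 or ne > clen:
            return False
        if any(ns < oe and os_ < ne for os_, oe in others):
            return False
        dens = _count_in(ostarts, ns, ne - L) / ((ne - ns) / 1000.0)
        return dens >= params.min_density

    while ok(s, e + step):
        e += step
    while ok(s - step, e):
        s -= step
    return s, e


def sublibraries_to_tsv(subs: list[Sublibrary], path) -> None:
    """TSV mirroring the published sublibrary table's columns."""
    rows = [
        {
            "id": s.id,
            "chrom": s.chrom,
            "region_start": s.region.start,
            "region_end": s.region.end,
            "region_length_bp": len(s.region),
            "oligo_count": s.oligo_count,
            "density_per_kb": display_density(s.density),
            "internal_primer": s.internal_primer,
            "external_class": s.external_class or "",
        }
        for s in subs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
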