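"""Barcode ideograms, rDNA distribution patterns, and karyotype measures.

An ideogram is a schematic chromosome model: per chromosome, a length, a
centromere, and a sorted list of signal blocks in fractional coordinates.
Predicted ideograms place one block per sublibrary (first-round FISH);
rDNA overlays emulate a second sequential hybridization by adding 5S/45S
blocks at canonical positions for their reported position class
(terminal / proximal / centromeric), because cytogenetic reports give
classes, not coordinates.

rDNA distribution patterns are compared through a ploidy-independent
canonical signature: the deduplicated sorted set of
``(locus, chromosome, position_class)`` per basic (haploid) genome. Two
species share a distribution type exactly when their signatures are equal.

Karyotype measurements follow standard metaphase practice: short/long arm
lengths per chromosome per cell, relative length in percent
(100 x chromosome length / complement length, averaged over cells) and arm
ratio (long/short).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .barcode import BarcodeScheme
from .genome import Genome

RDNA_COLORS = {"5S": "5S/green", "45S": "45S/red"}

#: Class -> fractional window parameters (of arm length except centromeric,
#: which is +/- a fraction of chromosome length around the centromere).
CLASS_WINDOWS = {
    "terminal": (0.0, 0.05),  # distal 5% of the arm
    "proximal": (0.15, 0.25),  # 15-25% of the arm out from the centromere
    "centromeric": 0.05,  # centromere +/- 5% of chromosome length
}

#: The reported pentaploid accession lacks three 45S signals on Chr_4;
#: encoded as a signal-count observation note, not a pattern change.
SIGNAL_COUNT_NOTES = {
    ("P. pseudocerasus", 5): {"45S": "three Chr_4 signals undetected"},
}


# -- ideogram ----------------------------------------------------------------

@dataclass(frozen=True)
class SignalBlock:
    start: float  # fraction of chromosome length
    end: float
    color: str
    source: str  # sublibrary id, '5S' or '45S'

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end <= 1.0):
            raise ValueError(f"block [{self.start}, {self.end}] outside [0, 1]")


@dataclass
class ChromosomeModel:
    length: float  # bp (or um for measured karyotypes)
    centromere: float | None  # same unit as length
    blocks: list[SignalBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.centromere is not None and not (
            0 < self.centromere < self.length
        ):
            raise ValueError("centromere outside chromosome")
        self.blocks = sorted(self.blocks, key=lambda b: (b.start, b.end))


@dataclass
class Ideogram:
    chromosomes: dict[str, ChromosomeModel]

    @property
    def n_blocks(self) -> int:
        return sum(len(c.blocks) for c in self.chromosomes.values())

    def to_json(self, path) -> None:
        doc = {
            c: {
                "length": m.length,
                "centromere": m.centromere,
                "blocks": [
                    [b.start, b.end, b.color, b.source] for b in m.blocks
                ],
            }
            for c, m in self.chromosomes.items()
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def predicted_ideogram(
    scheme: BarcodeScheme,
    genome: Genome,
    centromeres: dict[str, int] | None = None,
) -> Ideogram:
    """One block per sublibrary at its region's fractional span."""
    centromeres = centromeres or {}
    chroms = {
        rid: ChromosomeModel(float(n), centromeres.get(rid))
        for rid, n in genome.lengths.items()
    }
    for sub_id, (chrom, start, end) in scheme.regions.items():
        if chrom not in chroms:
            raise KeyError(f"sublibrary {sub_id} on unknown chromosome {chrom}")
        n = chroms[chrom].length
        color = scheme.color_map.get(
            scheme.external_of(sub_id), scheme.external_of(sub_id)
        )
        chroms[chrom].blocks.append(
            SignalBlock(start / n, min(end / n, 1.0), color, sub_id)
        )
    for m in chroms.values():
        m.blocks.sort(key=lambda b: (b.start, b.end))
    return Ideogram(chroms)


# -- rDNA patterns -----------------------------------------------------------

@dataclass(frozen=True)
class RdnaSite:
    locus: str  # '5S' | '45S'
    chrom: str
    position_class: str  # 'terminal' | 'proximal' | 'centromeric'
    arm: str = "unknown"  # 'short' | 'long' | 'unknown'

    def __post_init__(self) -> None:
        if self.locus not in ("5S", "45S"):
            raise ValueError(f"unknown rDNA locus {self.locus!r}")
        if self.arm not in ("short", "long", "unknown"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.position_class not in ("terminal", "proximal", "centromeric"):
            raise ValueError(f"unknown position class {self.position_class!r}")


@dataclass
class RdnaSitePattern:
    species: str
    ploidy: int
    sites: list[RdnaSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[RdnaSite] = []
        for s in self.sites:  # deduplicate per basic genome, keep order
            if s not in seen:
                seen.append(s)
        self.sites = seen

    def of_locus(self, locus: str) -> list[RdnaSite]:
        return [s for s in self.sites if s.locus == locus]


def pattern_signature(p: RdnaSitePattern) -> str:
    """Ploidy-independent canonical form; equal signature = same type."""
    keys = sorted({(s.locus, s.chrom, s.position_class) for s in p.sites})
    return ";".join(f"{l}@{c}:{k}" for l, c, k in keys)


def expected_signal_pairs(p: RdnaSitePattern, locus: str) -> int:
    """Expected chromosome pairs carrying ``locus`` signals at metaphase:
    sites per basic genome x ploidy/2 (floored, with a warning, for odd
    ploidies such as the occasional pentaploid)."""
    n_sites = len(p.of_locus(locus))
    if p.ploidy % 2:
        warnings.warn(
            f"odd ploidy {p.ploidy} for {p.species}: signal 'pairs' are "
            "approximate (floored)",
            stacklevel=2,
        )
    return (n_sites * p.ploidy) // 2


def load_rdna_patterns(path=None) -> dict[str, RdnaSitePattern]:
    """Load per-species site tables (the shipped survey by default)."""
    if path is None:
        with resources.as_file(
            resources.files("oligofish.data") / "rdna_sites.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, RdnaSitePattern] = {}
    for species, g in df.groupby("species", sort=False):
        out[str(species)] = RdnaSitePattern(
            species=str(species),
            ploidy=int(g["ploidy"].iloc[0]),
            sites=[
                RdnaSite(r.locus, r.chrom, r.position_class, r.arm)
                for r in g.itertuples()
            ],
        )
    return out


def save_rdna_patterns(patterns: dict[str, RdnaSitePattern], path) -> None:
    rows = [
        {
            "species": p.species,
            "ploidy": p.ploidy,
            "locus": s.locus,
            "chrom": s.chrom,
            "arm": s.arm,
            "position_class": s.position_class,
        }
        for p in patterns.values()
        for s in p.sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def overlay_rdna(ideogram: Ideogram, pattern: RdnaSitePattern) -> Ideogram:
    """Sequential-FISH emulation: add one block per rDNA site.

    Existing blocks are never moved or recolored. Position classes map to
    canonical fractional windows (see ``CLASS_WINDOWS``); placement is
    arm-aware, defaulting to the short arm when the arm is unreported.
    Unknown chromosomes raise ``KeyError``.
    """
    new = {
        c: ChromosomeModel(m.length, m.centromere, list(m.blocks))
        for c, m in ideogram.chromosomes.items()
    }
    for site in pattern.sites:
        if site.chrom not in new:
            raise KeyError(
                f"rDNA site on unknown chromosome {site.chrom!r}"
            )
        m = new[site.chrom]
        c = (m.centromere / m.length) if m.centromere else 0.5
        lo, hi = _site_window(site, c)
        m.blocks.append(
            SignalBlock(lo, hi, RDNA_COLORS[site.locus], site.locus)
        )
    for m in new.values():
        m.blocks.sort(key=lambda b: (b.start, b.end))
    return Ideogram(new)


def _site_window(site: RdnaSite, c: float) -> tuple[float, float]:
    left_len, right_len = c, 1.0 - c
    short_is_left = left_len <= right_len
    arm = site.arm if site.arm != "unknown" else "short"
    on_left = (arm == "short") == short_is_left
    if site.position_class == "centromeric":
        w = CLASS_WINDOWS["centromeric"]
        return max(c - w, 0.0), min(c + w, 1.0)
    a, b = CLASS_WINDOWS[site.position_class]
    arm_len = left_len if on_left else right_len
    if site.position_class == "terminal":
        # distal a..b of the arm, measured from the telomere
        if on_left:
            return a * arm_len, b * arm_len
        return 1.0 - b * arm_len, 1.0 - a * arm_len
    # proximal: a..b of the arm, measured out from the centromere
    if on_left:
        return c - b * arm_len, c - a * arm_len
    return c + a * arm_len, c + b * arm_len


# -- karyotype measurements --------------------------------------------------

@dataclass
class KaryotypeMeasure:
    """Arm measurements: one dict per cell, chrom -> (short, long)."""

    cells: list[dict[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for cell in self.cells:
            for chrom, (s, l) in cell.items():
                if s <= 0 or l <= 0:
                    raise ValueError(f"nonpositive arm length on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for cell in self.cells:
            for c in cell:
                if c not in seen:
                    seen.append(c)
        return seen


def arm_ratio(short: float, long: float) -> float:
    """Long-arm / short-arm ratio, always >= 1 (arms swapped if needed)."""
    if short <= 0 or long <= 0:
        raise ValueError("arm lengths must be positive")
    return max(short, long) / min(short, long)


def relative_lengths(measure: KaryotypeMeasure) -> dict[str, float]:
    """Mean relative length (%) per chromosome over complete cells.

    Per cell: 100 x (short+long) / sum over the full complement; cells
    missing any chromosome are excluded with a warning. Sums to 100 per
    cell by construction.
    """
    chroms = measure.chromosomes
    per_chrom: dict[str, list[float]] = {c: [] for c in chroms}
    for i, cell in enumerate(measure.cells):
        missing = [c for c in chroms if c not in cell]
        if missing:
            warnings.warn(
                f"cell {i} missing chromosomes {missing}; excluded",
                stacklevel=2,
            )
            continue
        total = sum(s + l for s, l in cell.values())
        for c in chroms:
            s, l = cell[c]
            per_chrom[c].append(100.0 * (s + l) / total)
    return {
        c: sum(v) / len(v) for c, v in per_chrom.items() if v
    }


def arm_ratios(measure: KaryotypeMeasure) -> dict[str, float]:
    """Mean arm ratio per chromosome over cells carrying it."""
    out: dict[str, list[float]] = {}
    for cell in measure.cells:
        for c, (s, l) in cell.items():
            out.setdefault(c, []).append(arm_ratio(s, l))
    return {c: sum(v) / len(v) for c, v in out.items()}


# -- plotting ----------------------------------------------------------------

def plot_ideogram(ideogram: Ideogram, path, title: str | None = None) -> None:
    """Render chromosomes as vertical bars with signal blocks (SVG/PNG by
    file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    chroms = list(ideogram.chromosomes)
    max_len = max(m.length for m in ideogram.chromosomes.values())
    fig, ax = plt.subplots(figsize=(1.2 * len(chroms) + 1, 4))
    for x, c in enumerate(chroms):
        m = ideogram.chromosomes[c]
        h = m.length / max_len
        ax.add_patch(
            Rectangle((x - 0.18, 0), 0.36, h, fill=False, lw=1.0)
        )
        for b in m.blocks:
            ax.add_patch(
                Rectangle(
                    (x - 0.18, b.start * h),
                    0.36,
                    (b.end - b.start) * h,
                    color=_mpl_color(b.color),
                    lw=0,
                )
            )
        if m.centromere is not None:
            ax.plot(
                [x - 0.25, x + 0.25],
                [m.centromere / max_len] * 2,
                color="k",
                lw=1.2,
            )
    ax.set_xticks(range(len(chroms)))
    ax.set_xticklabels(chroms, rotation=45, ha="right")
    ax.set_ylim(1.05, -0.05)
    ax.set_yticks([])
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _mpl_color(label: str) -> str:
    low = label.lower()
    if "green" in low or "fam" in low:
        return "tab:green"
    if "red" in low or "tamra" in low:
        return "tab:red"
    return "tab:blue"
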