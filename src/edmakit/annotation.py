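"""Genomic-feature annotation of restriction fragments.

Every probe's MseI–MseI fragment receives a fixed annotation vector used for
downstream enrichment analysis:

* gene windows — distal promoter (50 kb), promoter (5 kb) and proximal
  promoter (1 kb) upstream of the TSS, plus exon and intron overlap, each
  carrying the ids of every gene whose window the fragment touches;
* CpG-island relation — ``island`` when overlapping, ``shore`` within 2 kb,
  ``shelf`` between 2 and 4 kb, ``open_sea`` beyond; overlapping fragments
  additionally inherit the island's length and density classes (bottom-20th
  / top-80th percentile cuts over the surveyed island cohort);
* repeat classes — the class labels (LINE, SINE, LTR, ...) of every
  overlapping repeat record.

Gene models arrive as BED12, islands as BED4, repeats as BED6 with the class
encoded in the name field (text before "/", RepeatMasker style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .restriction import RestrictionFragment

__all__ = [
    "GeneModel",
    "CpGIslandRecord",
    "AnnotationError",
    "PROMOTER_WINDOW_SIZES",
    "promoter_windows",
    "island_relation",
    "classify_islands",
    "compute_island_stats",
    "annotate",
    "read_bed12",
    "read_islands",
    "read_repeats",
]


class AnnotationError(ValueError):
    """Inconsistent annotation tracks (bad strand, mismatched chromosomes...)."""


#: Upstream window widths in nucleotides, 5' of the TSS.
PROMOTER_WINDOW_SIZES: dict[str, int] = {
    "proximal_promoter": 1_000,
    "promoter": 5_000,
    "distal_promoter": 50_000,
}

GENE_WINDOW_COLUMNS = (
    "distal_promoter",
    "promoter",
    "proximal_promoter",
    "exon",
    "intron",
)


@dataclass
class GeneModel:
    """A transcript model; TSS is the 5' end on the annotated strand."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons[:-1], self.exons[1:])
            if s2 > e1
        ]


@dataclass
class CpGIslandRecord:
    chrom: str
    start: int
    end: int
    name: str = ""
    cpg_count: int | None = None
    length_class: str | None = None
    density_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float | None:
        """CpG count per nucleotide of island (at most 0.5)."""
        if self.cpg_count is None:
            return None
        return self.cpg_count / self.length


def promoter_windows(
    gene: GeneModel, sizes: Mapping[str, int] = PROMOTER_WINDOW_SIZES
) -> dict[str, tuple[int, int]]:
    """The nested upstream windows 5' of the TSS, clipped at the chromosome start.

    On the + strand a window of width W is [tss − W, tss); on the − strand it
    mirrors to [tss, tss + W).
    """
    out: dict[str, tuple[int, int]] = {}
    for label, width in sizes.items():
        if gene.strand == "+":
            out[label] = (max(0, gene.tss - width), gene.tss)
        else:
            out[label] = (gene.tss, gene.tss + width)
    return out


def _gap(frag_start: int, frag_end: int, isl_start: int, isl_end: int) -> int:
    """Nucleotides between two half-open intervals; 0 when they overlap or abut."""
    if isl_start >= frag_end:
        return isl_start - frag_end
    if isl_end <= frag_start:
        return frag_start - isl_end
    return 0


def island_relation(
    frag_start: int,
    frag_end: int,
    islands: Sequence[CpGIslandRecord],
    shore_distance: int = 2_000,
    shelf_distance: int = 4_000,
) -> tuple[str, float, CpGIslandRecord | None]:
    """Classify a fragment against the islands of its chromosome.

    Returns ``(relation, distance, nearest_island)``.  Overlap gives
    ``island`` at distance 0; otherwise the minimum gap d maps to ``shore``
    (d ≤ 2000, including abutting intervals), ``shelf`` (2000 < d ≤ 4000) or
    ``open_sea`` (d > 4000).  With no island on the chromosome the relation
    is ``open_sea`` at infinite distance.  Ties between equally near islands
    go to the longer island.
    """
    if not islands:
        return "open_sea", math.inf, None
    # Rank by (distance, overlap-before-abutment, longer island wins ties).
    best: CpGIslandRecord | None = None
    best_key: tuple[float, int, int] | None = None
    best_overlap = False
    for isl in islands:
        overlaps = isl.start < frag_end and isl.end > frag_start
        d = 0.0 if overlaps else float(_gap(frag_start, frag_end, isl.start, isl.end))
        key = (d, 0 if overlaps else 1, -isl.length)
        if best_key is None or key < best_key:
            best, best_key, best_overlap = isl, key, overlaps
    assert best is not None and best_key is not None
    best_d = best_key[0]
    if best_overlap:
        return "island", 0.0, best
    if best_d <= shore_distance:
        return "shore", best_d, best
    if best_d <= shelf_distance:
        return "shelf", best_d, best
    return "open_sea", best_d, best


def classify_islands(
    islands: Sequence[CpGIslandRecord],
    lower_pct: float = 20.0,
    upper_pct: float = 80.0,
) -> list[CpGIslandRecord]:
    """Assign length and density classes from cohort percentiles.

    The cohort is every island surveyed by the array.  Thresholds are the
    linear-interpolation percentiles of length and density; values strictly
    below the lower cut are ``short``/``low``, strictly above the upper cut
    ``long``/``high``, everything else (including exact threshold hits)
    ``intermediate``.  Refuses cohorts of fewer than 5 islands.
    """
    if len(islands) < 5:
        raise AnnotationError(
            f"island cohort too small for percentile classes (n={len(islands)} < 5)"
        )
    if any(isl.cpg_count is None for isl in islands):
        raise AnnotationError(
            "island CpG counts missing; run compute_island_stats first"
        )
    lengths = np.array([isl.length for isl in islands], dtype=float)
    densities = np.array([isl.density for isl in islands], dtype=float)
    len_lo, len_hi = np.percentile(lengths, [lower_pct, upper_pct])
    den_lo, den_hi = np.percentile(densities, [lower_pct, upper_pct])

    def cut(value: float, lo: float, hi: float, low: str, high: str) -> str:
        if value < lo:
            return low
        if value > hi:
            return high
        return "intermediate"

    for isl in islands:
        isl.length_class = cut(isl.length, len_lo, len_hi, "short", "long")
        isl.density_class = cut(float(isl.density), den_lo, den_hi, "low", "high")
    return list(islands)


def compute_island_stats(
    islands: Sequence[CpGIslandRecord], genome: Mapping[str, str]
) -> list[CpGIslandRecord]:
    """Fill per-island CpG counts from the genome sequence."""
    for isl in islands:
        if isl.chrom not in genome:
            raise AnnotationError(f"island on unknown chromosome {isl.chrom!r}")
        isl.cpg_count = genome[isl.chrom][isl.start : isl.end].upper().count("CG")
    return list(islands)


def _check_chroms(
    fragments: Sequence[RestrictionFragment],
    track_name: str,
    track_chroms: set[str],
) -> None:
    frag_chroms = {f.chrom for f in fragments}
    if track_chroms and not (frag_chroms & track_chroms):
        raise AnnotationError(
            f"chromosome names of the {track_name} track ({sorted(track_chroms)}) "
            f"share nothing with the fragments ({sorted(frag_chroms)}); "
            "reconcile naming (e.g. 'chr1' vs '1') before annotating"
        )


def annotate(
    fragments: Sequence[RestrictionFragment],
    genes: Sequence[GeneModel] = (),
    islands: Sequence[CpGIslandRecord] = (),
    repeats: pd.DataFrame | None = None,
    promoter_sizes: Mapping[str, int] = PROMOTER_WINDOW_SIZES,
    shore_distance: int = 2_000,
    shelf_distance: int = 4_000,
) -> pd.DataFrame:
    """Build the full annotation vector, one row per fragment.

    Gene ids are comma-joined and sorted within each window column; a gene
    appears under every window its fragment overlaps, and a fragment may
    carry several window flags at once.  The island relation is unique per
    fragment; island classes are filled only for overlapping fragments.
    Repeats contribute the set of overlapping class labels.
    """
    if repeats is None:
        repeats = pd.DataFrame(columns=["chrom", "start", "end", "repeat_class"])
    if genes:
        _check_chroms(fragments, "gene", {g.chrom for g in genes})
    if islands:
        _check_chroms(fragments, "island", {i.chrom for i in islands})
    if len(repeats):
        _check_chroms(fragments, "repeat", set(repeats["chrom"]))

    # Interval trees per chromosome for gene windows, exons, introns, repeats.
    trees: dict[str, IntervalTree] = {}

    def add(chrom: str, start: int, end: int, payload: tuple[str, str]) -> None:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)

    for g in genes:
        for label, (ws, we) in promoter_windows(g, promoter_sizes).items():
            add(g.chrom, ws, we, (label, g.gene_id))
        for es, ee in g.exons:
            add(g.chrom, es, ee, ("exon", g.gene_id))
        for is_, ie in g.introns:
            add(g.chrom, is_, ie, ("intron", g.gene_id))
    for row in repeats.itertuples(index=False):
        add(str(row.chrom), int(row.start), int(row.end), ("repeat", str(row.repeat_class)))

    islands_by_chrom: dict[str, list[CpGIslandRecord]] = {}
    for isl in islands:
        islands_by_chrom.setdefault(isl.chrom, []).append(isl)
    for lst in islands_by_chrom.values():
        lst.sort(key=lambda i: (i.start, i.end))

    rows = []
    for idx, frag in enumerate(fragments):
        hits: dict[str, set[str]] = {c: set() for c in GENE_WINDOW_COLUMNS}
        repeat_classes: set[str] = set()
        tree = trees.get(frag.chrom)
        if tree is not None:
            for iv in tree.overlap(frag.start, frag.end):
                kind, value = iv.data
                if kind == "repeat":
                    repeat_classes.add(value)
                else:
                    hits[kind].add(value)
        relation, distance, nearest = island_relation(
            frag.start,
            frag.end,
            islands_by_chrom.get(frag.chrom, []),
            shore_distance=shore_distance,
            shelf_distance=shelf_distance,
        )
        rows.append(
            {
                "fragment_id": f"F{idx:06d}",
                "chrom": frag.chrom,
                "start": frag.start,
                "end": frag.end,
                **{c: ",".join(sorted(hits[c])) for c in GENE_WINDOW_COLUMNS},
                "island_relation": relation,
                "island_distance": distance,
                "island_length_class": (
                    nearest.length_class or ""
                    if relation == "island" and nearest is not None
                    else ""
                ),
                "island_density_class": (
                    nearest.density_class or ""
                    if relation == "island" and nearest is not None
                    else ""
                ),
                "repeat_classes": ",".join(sorted(repeat_classes)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Track readers


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"BED12 line with {len(f)} fields: {line!r}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def read_islands(path: str | Path) -> list[CpGIslandRecord]:
    islands: list[CpGIslandRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            islands.append(CpGIslandRecord(f[0], int(f[1]), int(f[2]), name))
    return islands


def read_repeats(path: str | Path) -> pd.DataFrame:
    """BED6 repeats; class is the name-field text before '/', RepeatMasker style."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "Unknown"
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "repeat_class": name.split("/", 1)[0],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])
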