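"""In silico restriction digestion and fragment-level site statistics.

The assay fragments genomic DNA with MseI (T/TAA), whose AT-rich recognition
site leaves CpG islands largely intact while cutting the bulk genome into
short fragments.  Methyl-sensitive restriction endonucleases (MSREs: HpaII
C/CGG, HinP1I GC/GC, AciI C/CGC) then cleave only *unmethylated* copies of
their sites, so an MseI–MseI fragment that carries at least one internal
MSRE site is informative: it survives to amplification only when methylated.

This module reproduces the design-time computations: locating enzyme sites,
cutting chromosomes into fragments, counting CpGs and MSRE sites per
fragment, and summarising coverage of the genome and of CpGs by
MSRE-containing ("cleavable") fragments.

Coordinates are 0-based half-open throughout; BED is used on disk.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnzymeSpec",
    "RestrictionFragment",
    "DigestSummary",
    "MSE_I",
    "HPA_II",
    "HIN_P1I",
    "ACI_I",
    "DEFAULT_MSRES",
    "ENZYMES",
    "reverse_complement",
    "find_sites",
    "digest",
    "annotate_fragment_sites",
    "digest_summary",
    "read_fasta",
    "write_fasta",
    "fragments_to_frame",
    "write_fragment_tables",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DigestError(ValueError):
    """Invalid enzyme definition or fragment/genome inconsistency."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif and cut offset.

    ``cut_offset`` is the distance in nucleotides from the motif start to the
    cut position on the top strand (MseI T/TAA cuts after the first T, so its
    offset is 1).  ``palindromic`` records whether the motif equals its own
    reverse complement; non-palindromic motifs (AciI C/CGC) must be scanned
    on both strands to find every site.
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool = True

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        if len(motif) < 4:
            raise DigestError(
                f"{self.name}: recognition motif must be at least 4 nt, got {motif!r}"
            )
        if set(motif) - set("ACGT"):
            raise DigestError(
                f"{self.name}: recognition motif may contain only A/C/G/T, got {motif!r}"
            )
        if not 0 <= self.cut_offset <= len(motif):
            raise DigestError(
                f"{self.name}: cut offset {self.cut_offset} outside motif of "
                f"length {len(motif)}"
            )
        object.__setattr__(self, "recognition", motif)
        if self.palindromic and motif != reverse_complement(motif):
            raise DigestError(f"{self.name}: motif {motif} is not palindromic")


MSE_I = EnzymeSpec("MseI", "TTAA", 1)
HPA_II = EnzymeSpec("HpaII", "CCGG", 1)
HIN_P1I = EnzymeSpec("HinP1I", "GCGC", 1)
ACI_I = EnzymeSpec("AciI", "CCGC", 1, palindromic=False)

#: The MSRE cocktail used for fragment selection.
DEFAULT_MSRES: tuple[EnzymeSpec, ...] = (HPA_II, HIN_P1I, ACI_I)

ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e for e in (MSE_I, HPA_II, HIN_P1I, ACI_I)
}


@dataclass
class RestrictionFragment:
    """An MseI–MseI genomic interval, the analysis unit targeted by probes."""

    chrom: str
    start: int
    end: int
    cpg_count: int | None = None
    msre_site_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DigestError(
                f"fragment {self.chrom}:{self.start}-{self.end} has end <= start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_msre(self) -> bool:
        """True when any MSRE site lies strictly inside the fragment."""
        return any(v > 0 for v in self.msre_site_counts.values())

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DigestSummary:
    fragment_count: int
    mean_length: float
    median_length: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    genome_fraction_covered_by_msre_fragments: float
    cpg_fraction_in_msre_fragments: float  # NaN when the genome has no CpG


def find_sites(
    sequence: str, enzyme: EnzymeSpec, both_strands: bool = False
) -> list[int]:
    """Motif start positions of ``enzyme`` on a sequence, sorted ascending.

    Overlapping occurrences are all reported.  When ``both_strands`` is set
    and the enzyme is non-palindromic, plus-strand occurrences of the
    reverse-complement motif are included as well (the site on the minus
    strand reads as the motif there).  ``N`` never matches.
    """
    if not enzyme.recognition:
        raise DigestError("enzyme has an empty recognition motif")
    seq = sequence.upper()
    motifs = [enzyme.recognition]
    if both_strands and not enzyme.palindromic:
        motifs.append(reverse_complement(enzyme.recognition))
    positions: set[int] = set()
    for motif in motifs:
        pattern = re.compile("(?=" + re.escape(motif) + ")")
        positions.update(m.start() for m in pattern.finditer(seq))
    return sorted(positions)


def digest(
    genome: Mapping[str, str], enzyme: EnzymeSpec = MSE_I
) -> list[RestrictionFragment]:
    """Cut every chromosome with a palindromic enzyme into tiling fragments.

    The cut coordinate is ``site + cut_offset``; fragments are the intervals
    between consecutive cuts plus the chromosome ends, so per chromosome the
    fragment lengths always sum to the chromosome length.  A chromosome with
    no site yields a single fragment spanning it.
    """
    if not enzyme.palindromic:
        raise DigestError(
            f"digest requires a palindromic enzyme with defined cut geometry, "
            f"got {enzyme.name}"
        )
    fragments: list[RestrictionFragment] = []
    for chrom, sequence in genome.items():
        if not sequence:
            raise DigestError(f"chromosome {chrom!r} is empty")
        n = len(sequence)
        cuts = [s + enzyme.cut_offset for s in find_sites(sequence, enzyme)]
        bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
        for start, end in zip(bounds[:-1], bounds[1:]):
            fragments.append(RestrictionFragment(chrom, start, end))
    return fragments


def annotate_fragment_sites(
    fragments: Sequence[RestrictionFragment],
    genome: Mapping[str, str],
    msre_enzymes: Iterable[EnzymeSpec] = DEFAULT_MSRES,
    both_strands: bool = True,
) -> list[RestrictionFragment]:
    """Fill ``cpg_count`` and per-enzyme ``msre_site_counts`` in place.

    CpGs are CG dinucleotides whose two bases lie within the fragment; MSRE
    sites count only when the full motif lies within the fragment interval —
    a motif straddling an MseI cut is destroyed by fragmentation and ignored.
    Counting the minus strand of non-palindromic enzymes is on by default
    (``both_strands``), matching how cleavable sites present in the assay.
    """
    enzymes = list(msre_enzymes)
    for frag in fragments:
        if frag.chrom not in genome:
            raise DigestError(f"fragment on unknown chromosome {frag.chrom!r}")
        seq = genome[frag.chrom]
        if frag.end > len(seq):
            raise DigestError(
                f"fragment {frag.name} extends past chromosome end ({len(seq)})"
            )
        sub = seq[frag.start : frag.end].upper()
        frag.cpg_count = sub.count("CG")
        frag.msre_site_counts = {
            e.name: len(find_sites(sub, e, both_strands=both_strands))
            for e in enzymes
        }
    return list(fragments)


def digest_summary(
    fragments: Sequence[RestrictionFragment],
    genome: Mapping[str, str] | None = None,
    bins: int | Sequence[float] = 20,
) -> DigestSummary:
    """Fragment-length distribution and MSRE coverage fractions.

    ``genome_fraction`` is the total length of MSRE-containing fragments over
    the genome length; ``cpg_fraction`` the CpGs in those fragments over all
    fragment CpGs.  A genome without CpGs reports ``cpg_fraction`` as NaN
    rather than failing.
    """
    if not fragments:
        raise DigestError("no fragments to summarise")
    if any(f.cpg_count is None for f in fragments):
        raise DigestError("fragments must be annotated first (annotate_fragment_sites)")
    lengths = np.array([f.length for f in fragments], dtype=float)
    if genome is not None:
        genome_length = sum(len(s) for s in genome.values())
    else:
        genome_length = int(lengths.sum())
    counts, edges = np.histogram(lengths, bins=bins)
    msre_length = sum(f.length for f in fragments if f.has_msre)
    total_cpg = sum(f.cpg_count for f in fragments)  # type: ignore[misc]
    msre_cpg = sum(f.cpg_count for f in fragments if f.has_msre)  # type: ignore[misc]
    cpg_fraction = math.nan if total_cpg == 0 else msre_cpg / total_cpg
    return DigestSummary(
        fragment_count=len(fragments),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        histogram_counts=counts,
        histogram_edges=edges,
        genome_fraction_covered_by_msre_fragments=msre_length / genome_length,
        cpg_fraction_in_msre_fragments=cpg_fraction,
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly multi-record, line-wrapped) FASTA into a dict."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fragments_to_frame(fragments: Sequence[RestrictionFragment]) -> pd.DataFrame:
    """Fragment table with one column per MSRE enzyme's site count."""
    enzyme_names = sorted({k for f in fragments for k in f.msre_site_counts})
    rows = []
    for i, f in enumerate(fragments):
        row = {
            "fragment_id": f"F{i:06d}",
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "length": f.length,
            "cpg_count": f.cpg_count if f.cpg_count is not None else -1,
        }
        for name in enzyme_names:
            row[f"sites_{name}"] = f.msre_site_counts.get(name, 0)
        row["has_msre"] = int(f.has_msre)
        rows.append(row)
    return pd.DataFrame(rows)


def write_fragment_tables(
    fragments: Sequence[RestrictionFragment], out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.bed`` (BED6, score = CpG count) and ``<prefix>.tsv``."""
    prefix = Path(out_prefix)
    table = fragments_to_frame(fragments)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    bed = table[["chrom", "start", "end", "fragment_id", "cpg_count"]].copy()
    bed["strand"] = "."
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    table.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path
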