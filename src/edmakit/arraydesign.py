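"""Array design bookkeeping: probe/control categories and control placement.

The production array (GEO platform GPL18384, "EDMA.V2") carries 414,566
probes targeting 359,738 MseI–MseI loci, surveying 20,355 genes and 34,379
CpG islands.  2.5 % of probes are controls, in three categories: vendor
proprietary spike-ins, genomic cleavage controls (probes centred on an MseI
site, tiled along the genome, used to verify fragmentation), and exogenous
methylation spike-in controls (tomato-derived template pairs carrying the
MSRE sites).  These published design constants are kept here both as
reference metadata and to drive the simulator's control layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["ControlProbeCounts", "ArrayDesign", "EDMA_V2", "tile_control_positions"]


@dataclass(frozen=True)
class ControlProbeCounts:
    """Control probes by category; the total is derived, never stored."""

    vendor_spikein: int
    genomic_cleavage: int
    methylation_spikein: int

    @property
    def total(self) -> int:
        return self.vendor_spikein + self.genomic_cleavage + self.methylation_spikein


@dataclass(frozen=True)
class ArrayDesign:
    name: str
    probes: int
    loci: int
    genes_surveyed: int
    cpg_islands_surveyed: int
    controls: ControlProbeCounts
    genomic_control_spacing: int  # nt between genomic cleavage controls

    @property
    def control_fraction(self) -> float:
        return self.controls.total / self.probes


#: Published design of the production array (GEO platform GPL18384).
EDMA_V2 = ArrayDesign(
    name="EDMA.V2",
    probes=414_566,
    loci=359_738,
    genes_surveyed=20_355,
    cpg_islands_surveyed=34_379,
    controls=ControlProbeCounts(
        vendor_spikein=5_610,
        genomic_cleavage=4_634,
        methylation_spikein=144,
    ),
    genomic_control_spacing=1_000_000,
)


def tile_control_positions(
    chrom_lengths: Mapping[str, int], spacing: int
) -> list[tuple[str, int]]:
    """Genomic-cleavage control positions, tiled every ``spacing`` nt.

    Controls sit at spacing, 2·spacing, ... along each chromosome (the
    production design tiles one per megabase over the whole genome).
    """
    if spacing <= 0:
        raise ValueError(f"control spacing must be positive, got {spacing}")
    positions = []
    for chrom, length in chrom_lengths.items():
        pos = spacing
        while pos < length:
            positions.append((chrom, pos))
            pos += spacing
    return positions
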