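"""Cleavage quality control from spike-in qPCR and array control probes.

Each sample carries one exogenous template pair per MSRE; one member is
in-vitro methylated (protected from cleavage), the other left unmethylated
(cleaved).  After digestion, the residual uncleaved fraction of the
unprotected template shows up as a qPCR threshold-cycle difference
``ΔCt = ct_unprotected − ct_protected``: with perfect per-cycle doubling,
residual = 2^(−ΔCt) and cleavage efficiency = 1 − 2^(−ΔCt).  Samples are
gated before the expensive amplification/hybridization steps; any enzyme
below the efficiency threshold (default 97 %) fails the sample, which in the
wet protocol triggers a second MSRE digestion.

On the array side, negative controls set a limit of detection (mean plus
four standard deviations) and genomic controls centred on MseI sites verify
fragmentation: their signal should sit below the LOD when digestion is
complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CleavageQCError",
    "SpikeInPair",
    "CleavageReport",
    "GateResult",
    "REQUIRED_MSRES",
    "cleavage_efficiency",
    "gate_sample",
    "limit_of_detection",
    "genomic_cleavage_check",
    "read_ct_table",
    "build_cleavage_reports",
]


class CleavageQCError(ValueError):
    """Inverted spike-in pair, incomplete report, or degenerate control set."""


#: Enzymes whose spike-in pairs a complete report must cover.
REQUIRED_MSRES: tuple[str, ...] = ("HpaII", "HinP1I", "AciI")


@dataclass(frozen=True)
class SpikeInPair:
    """One MSRE's protected/unprotected spike-in template pair."""

    enzyme: str
    ct_protected: float
    ct_unprotected: float

    def __post_init__(self) -> None:
        if self.ct_protected <= 0 or self.ct_unprotected <= 0:
            raise CleavageQCError(
                f"{self.enzyme}: Ct values must be positive "
                f"({self.ct_protected}, {self.ct_unprotected})"
            )

    @property
    def delta_ct(self) -> float:
        return self.ct_unprotected - self.ct_protected


def cleavage_efficiency(
    delta_ct: float, amplification_efficiency: float = 2.0
) -> float:
    """Fraction of unprotected template cleaved, from the pair's ΔCt.

    Assumes perfect per-cycle doubling by default: the uncleaved residue is
    amplification_efficiency^(−ΔCt), so efficiency = 1 − 2^(−ΔCt); ΔCt = 5
    corresponds to 97 % cleavage (96.875 % before rounding).  A negative ΔCt
    means the unprotected template amplified earlier than the protected one,
    which is an assay failure, not a negative efficiency.
    """
    if delta_ct < 0:
        raise CleavageQCError(
            f"inverted spike-in pair: ΔCt = {delta_ct:.3f} < 0 "
            "(unprotected template amplified before the protected one)"
        )
    if amplification_efficiency <= 1:
        raise CleavageQCError(
            f"amplification efficiency must exceed 1, got {amplification_efficiency}"
        )
    return 1.0 - amplification_efficiency ** (-delta_ct)


@dataclass
class GateResult:
    passed: bool
    threshold: float
    failing_enzymes: list[str] = field(default_factory=list)


@dataclass
class CleavageReport:
    """Per-sample cleavage QC: ΔCt and efficiency per enzyme, plus array checks."""

    sample: str
    delta_ct: dict[str, float]
    efficiency: dict[str, float]
    threshold: float = 0.97
    lod: float | None = None
    msre_control_fail_fraction: float | None = None

    @property
    def gate(self) -> GateResult:
        return gate_sample(self.efficiency, self.threshold)

    @property
    def passed(self) -> bool:
        return self.gate.passed


def gate_sample(
    efficiencies: Mapping[str, float],
    threshold: float = 0.97,
    required: Sequence[str] = REQUIRED_MSRES,
) -> GateResult:
    """Pass iff every required enzyme's efficiency strictly exceeds the threshold.

    The gate is strict ("cleaved > 97 %"), so an efficiency exactly at the
    threshold fails.  Failing enzymes are listed so the sample can be sent
    back for an additional MSRE digestion.
    """
    missing = [e for e in required if e not in efficiencies]
    if missing:
        raise CleavageQCError(f"incomplete report: missing enzymes {missing}")
    failing = [e for e in required if efficiencies[e] <= threshold]
    return GateResult(passed=not failing, threshold=threshold, failing_enzymes=failing)


def limit_of_detection(negative_control_intensities: Iterable[float]) -> float:
    """Background ceiling: mean of negative controls plus four sample sd (n−1)."""
    values = np.asarray(list(negative_control_intensities), dtype=float)
    if values.size < 2:
        raise CleavageQCError(
            f"need at least 2 negative controls to estimate a spread, got {values.size}"
        )
    return float(values.mean() + 4.0 * values.std(ddof=1))


def genomic_cleavage_check(
    msei_control_intensities: Iterable[float], lod: float
) -> float:
    """Fraction of MseI-centred control probes with signal above the LOD.

    These controls straddle an MseI site, so complete genomic fragmentation
    destroys their target and their signal drops into the background: a
    fraction near 0 indicates complete digestion.
    """
    values = np.asarray(list(msei_control_intensities), dtype=float)
    if values.size == 0:
        raise CleavageQCError("no MseI control intensities supplied")
    return float((values > lod).mean())


# ---------------------------------------------------------------------------
# Table I/O


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Spike-in qPCR table: columns sample, enzyme, template, ct.

    ``template`` is 'protected' or 'unprotected'.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "enzyme", "template", "ct"}
    if not required.issubset(df.columns):
        raise CleavageQCError(
            f"Ct table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = set(df["template"]) - {"protected", "unprotected"}
    if bad:
        raise CleavageQCError(f"unknown template labels {sorted(bad)}")
    return df


def build_cleavage_reports(
    ct_table: pd.DataFrame,
    threshold: float = 0.97,
    required: Sequence[str] = REQUIRED_MSRES,
) -> dict[str, CleavageReport]:
    """Fold a long Ct table into one CleavageReport per sample."""
    reports: dict[str, CleavageReport] = {}
    for sample, sub in ct_table.groupby("sample", sort=True):
        delta: dict[str, float] = {}
        eff: dict[str, float] = {}
        for enzyme, pair_rows in sub.groupby("enzyme", sort=True):
            by_template = pair_rows.set_index("template")["ct"]
            if not {"protected", "unprotected"}.issubset(by_template.index):
                raise CleavageQCError(
                    f"sample {sample!r}, enzyme {enzyme!r}: incomplete template pair"
                )
            pair = SpikeInPair(
                str(enzyme),
                float(by_template["protected"]),
                float(by_template["unprotected"]),
            )
            delta[str(enzyme)] = pair.delta_ct
            eff[str(enzyme)] = cleavage_efficiency(pair.delta_ct)
        missing = [e for e in required if e not in eff]
        if missing:
            raise CleavageQCError(
                f"sample {sample!r}: missing spike-in pairs for {missing}"
            )
        reports[str(sample)] = CleavageReport(
            sample=str(sample), delta_ct=delta, efficiency=eff, threshold=threshold
        )
    return reports


def reports_to_frame(reports: Mapping[str, CleavageReport]) -> pd.DataFrame:
    rows = []
    for sample, rep in reports.items():
        for enzyme, eff in sorted(rep.efficiency.items()):
            rows.append(
                {
                    "sample": sample,
                    "enzyme": enzyme,
                    "delta_ct": rep.delta_ct[enzyme],
                    "efficiency": eff,
                    "passed": rep.passed,
                }
            )
    return pd.DataFrame(rows)
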