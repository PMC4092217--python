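"""Genome-browser and Circos-ready exports, plus simple chromosome plots.

Bedgraph files use the UCSC dialect: a ``track type=bedGraph`` header line
followed by 4 tab-separated columns (chrom, start, end, value) in 0-based
half-open coordinates.  Circos consumes a karyotype file plus 2D data
tracks in its whitespace-separated text format; rendering itself is left to
Circos or any karyotype plotter — this module only emits the data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExportError",
    "export_bedgraph",
    "parse_bedgraph",
    "export_circos_karyotype",
    "export_circos_data",
    "plot_chromosome_track",
]


class ExportError(ValueError):
    pass


def _resolve_overlaps(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    prev_end: dict[str, int] = {}
    keep_rows = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        last = prev_end.get(chrom, -1)
        if start < last:
            if policy == "error":
                raise ExportError(
                    f"overlapping intervals on {chrom} at {start} < {last}"
                )
            start = last  # policy == "merge": clip to the previous end
            if start >= end:
                continue
        prev_end[chrom] = end
        keep_rows.append({"chrom": chrom, "start": start, "end": end, "value": row.value})
    return pd.DataFrame(keep_rows, columns=["chrom", "start", "end", "value"])


def export_bedgraph(
    track: pd.DataFrame,
    path: str | Path | None = None,
    name: str = "edma_track",
    value_column: str = "value",
    overlap_policy: str = "error",
) -> str:
    """Serialise a (chrom, start, end, value) table as UCSC bedgraph text.

    ``overlap_policy`` is ``error`` (default) or ``merge`` (clip overlapping
    starts to the previous interval's end).  Values are written with 6
    significant digits, enough to round-trip the tracks this package emits.
    """
    for col in ("chrom", "start", "end"):
        if col not in track.columns:
            raise ExportError(f"track missing column {col!r}")
    if value_column not in track.columns:
        raise ExportError(f"track missing value column {value_column!r}")
    if overlap_policy not in ("error", "merge"):
        raise ExportError(f"unknown overlap policy {overlap_policy!r}")
    df = track[["chrom", "start", "end", value_column]].rename(
        columns={value_column: "value"}
    )
    df = _resolve_overlaps(df, overlap_policy)
    lines = [f'track type=bedGraph name="{name}"']
    for row in df.itertuples(index=False):
        lines.append(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_bedgraph(source: str | Path) -> pd.DataFrame:
    """Read bedgraph text (or a path to it) back into a table."""
    text = (
        Path(source).read_text()
        if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists())
        else str(source)
    )
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        chrom, start, end, value = line.split("\t")
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "value": float(value),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def export_circos_karyotype(
    chrom_lengths: Mapping[str, int], path: str | Path | None = None
) -> str:
    """Circos karyotype file: one ``chr`` line per chromosome."""
    lines = [
        f"chr - {chrom} {chrom} 0 {length} grey"
        for chrom, length in chrom_lengths.items()
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def export_circos_data(
    track: pd.DataFrame,
    path: str | Path | None = None,
    value_column: str = "value",
) -> str:
    """Circos 2D data track: chrom start end value, whitespace separated.

    NaN values (empty windows) are emitted as Circos missing markers by
    skipping the line, which Circos treats as absent data.
    """
    lines = []
    for row in track.itertuples(index=False):
        value = getattr(row, value_column)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        lines.append(f"{row.chrom} {int(row.start)} {int(row.end)} {value:.6g}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def plot_chromosome_track(
    track: pd.DataFrame,
    path: str | Path,
    value_column: str = "smoothed_p",
    title: str = "",
) -> None:
    """Quick per-chromosome line plot of a positional track (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(pd.unique(track["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 2.2 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = track[track["chrom"] == chrom]
        ax.plot(sub["position"], sub[value_column], lw=0.8)
        ax.set_ylabel(value_column)
        ax.set_title(str(chrom), fontsize=9)
    axes[-1, 0].set_xlabel("position (nt)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
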