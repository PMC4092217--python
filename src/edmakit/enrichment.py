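"""DMR enrichment by genomic feature, methylation hot spots, Circos windows.

Enrichment compares, per annotation category, the number of DMRs
hypermethylated in group A against those hypermethylated in group B as a
log2 ratio (with a Haldane–Anscombe pseudocount guarding zero cells).  A
DMR contributes to *every* category its fragment belongs to.

"Methylation hot spots" smooth the differential-methylation p-values over
±100 kb around each probe: for every probe, the p-values of all probes
(itself included) within the window on the same chromosome are averaged.
The averaged values have no statistical meaning — they are an indicator
for regions of interest, not probabilities.

Circos-style windows tile each chromosome in fixed 5 Mb bins from
coordinate 0 and report the mean p per bin, alongside the top-N most
significant DMRs, for chromosome-scale overview plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentError",
    "annotation_categories",
    "enrichment_table",
    "hotspots",
    "circos_windows",
]


class EnrichmentError(ValueError):
    pass


GENE_WINDOW_CATEGORIES = (
    "distal_promoter",
    "promoter",
    "proximal_promoter",
    "exon",
    "intron",
)
ISLAND_RELATION_CATEGORIES = ("island", "shore", "shelf", "open_sea")


def annotation_categories(row: pd.Series) -> list[str]:
    """Expand one annotation record into its enrichment category labels.

    Gene windows contribute when any gene id is attached; the island
    relation always contributes one label; overlapping islands additionally
    contribute combined length/density labels (e.g. ``island_short_length``,
    ``island_high_density``); each repeat class contributes its own label.
    """
    cats: list[str] = []
    for col in GENE_WINDOW_CATEGORIES:
        if str(row.get(col, "") or "").strip():
            cats.append(col)
    relation = str(row.get("island_relation", "") or "")
    if relation:
        cats.append(relation)
    if relation == "island":
        lc = str(row.get("island_length_class", "") or "")
        dc = str(row.get("island_density_class", "") or "")
        if lc:
            cats.append(f"island_{lc}_length")
        if dc:
            cats.append(f"island_{dc}_density")
    repeats = str(row.get("repeat_classes", "") or "")
    for cls in repeats.split(","):
        cls = cls.strip()
        if cls:
            cats.append(cls)
    return cats


def enrichment_table(
    dmrs: pd.DataFrame,
    annotations: pd.DataFrame,
    pseudocount: float = 0.5,
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category hyper-in-A vs hyper-in-B DMR counts and log2 ratio.

    ``dmrs`` needs a ``direction`` column (``hyper_in_A``/``hyper_in_B``)
    and must be joinable to ``annotations`` on index or ``fragment_id``.
    log2_ratio = log2((nA + c)/(nB + c)) with pseudocount c; with c = 0 a
    zero denominator yields an infinite ratio, which is why the default
    keeps c = 0.5.  When an explicit category list is given, unknown names
    raise rather than silently reporting zeros.
    """
    if "direction" not in dmrs.columns:
        raise EnrichmentError("DMR table lacks a 'direction' column")
    ann = annotations
    if "fragment_id" in ann.columns and len(dmrs.index.intersection(ann.index)) == 0:
        ann = ann.set_index("fragment_id")
    missing = dmrs.index.difference(ann.index)
    if len(missing):
        raise EnrichmentError(
            f"{len(missing)} DMRs lack annotation records (e.g. {list(missing[:3])})"
        )
    counts: dict[str, list[int]] = {}
    for idx, direction in dmrs["direction"].items():
        for cat in annotation_categories(ann.loc[idx]):
            a, b = counts.setdefault(cat, [0, 0])
            if direction == "hyper_in_A":
                counts[cat][0] = a + 1
            else:
                counts[cat][1] = b + 1
    if categories is not None:
        unknown = set(categories) - set(counts) - set(
            GENE_WINDOW_CATEGORIES
        ) - set(ISLAND_RELATION_CATEGORIES)
        # A configured category that never occurs among annotations at all is
        # likely a typo in the config.
        if unknown:
            raise EnrichmentError(f"unknown enrichment categories: {sorted(unknown)}")
        selected = categories
    else:
        selected = sorted(counts)
    rows = []
    for cat in selected:
        n_a, n_b = counts.get(cat, [0, 0])
        rows.append(
            {
                "category": cat,
                "hyper_in_A": n_a,
                "hyper_in_B": n_b,
                "log2_ratio": float(
                    np.log2((n_a + pseudocount) / (n_b + pseudocount))
                ),
            }
        )
    return pd.DataFrame(rows, columns=["category", "hyper_in_A", "hyper_in_B", "log2_ratio"])


def hotspots(
    positions: np.ndarray | pd.Series,
    pvalues: np.ndarray | pd.Series,
    chroms: np.ndarray | pd.Series | None = None,
    window_half_width: int = 100_000,
) -> pd.DataFrame:
    """Mean p over all probes within ±window_half_width of each probe.

    ``positions`` are probe positions (fragment midpoints).  Input order is
    free; output follows genome order (chromosome, then position).  Each
    probe contributes to its own window, so the smoothed value always lies
    between the window's min and max p.  A half-width of 0 returns each
    probe's own p.
    """
    positions = np.asarray(positions, dtype=np.int64)
    pvalues = np.asarray(pvalues, dtype=float)
    if positions.shape != pvalues.shape:
        raise EnrichmentError("positions and p-values differ in length")
    if window_half_width < 0:
        raise EnrichmentError("window half-width must be nonnegative")
    if chroms is None:
        chroms = np.full(positions.shape, "chr", dtype=object)
    else:
        chroms = np.asarray(chroms, dtype=object)
    frames = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        p = pvalues[sel]
        order = np.argsort(pos, kind="stable")
        pos, p = pos[order], p[order]
        csum = np.concatenate([[0.0], np.cumsum(p)])
        left = np.searchsorted(pos, pos - window_half_width, side="left")
        right = np.searchsorted(pos, pos + window_half_width, side="right")
        smoothed = (csum[right] - csum[left]) / (right - left)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": pos,
                    "p": p,
                    "smoothed_p": smoothed,
                    "n_contributors": right - left,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def circos_windows(
    fits: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 5_000_000,
    top_n: int = 100,
    dmrs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-window mean p track plus the top-N most significant DMR table.

    ``fits`` needs columns chrom, position (probe midpoint), p, mean_m.
    Bins tile each chromosome from 0 in half-open [k·w, (k+1)·w) windows;
    empty bins are emitted with NaN mean p so tracks stay genome-complete.
    The top table ranks DMR candidates by ascending p, ties broken by
    descending |mean M|; when no separate DMR table is given the ranking is
    taken over all fits.
    """
    for col in ("chrom", "position", "p", "mean_m"):
        if col not in fits.columns:
            raise EnrichmentError(f"fits table missing column {col!r}")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / window)) if length > 0 else 0
        sub = fits[fits["chrom"] == chrom]
        bin_idx = (sub["position"] // window).astype(int)
        means = sub.groupby(bin_idx)["p"].mean()
        counts = sub.groupby(bin_idx)["p"].size()
        for k in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "start": k * window,
                    "end": min((k + 1) * window, length),
                    "mean_p": float(means.get(k, np.nan)),
                    "n_probes": int(counts.get(k, 0)),
                }
            )
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_p", "n_probes"])
    source = dmrs if dmrs is not None else fits
    ranked = source.assign(_abs_m=source["mean_m"].abs()).sort_values(
        ["p", "_abs_m"], ascending=[True, False], kind="mergesort"
    )
    top = ranked.head(top_n).drop(columns="_abs_m")
    return bins, top
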