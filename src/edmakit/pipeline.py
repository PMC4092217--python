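"""End-to-end orchestration: digest → annotate → QC → normalize/fit → export.

``run_pipeline`` wires the stage modules together over on-disk inputs,
writes every product as a text table, and enforces the cleavage QC gate: a
sample set whose spike-in efficiencies miss the threshold halts the run
before the expensive fitting stage (override with ``force``).  The resolved
configuration is serialised next to the outputs so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import restriction as dg
from . import dmr as dmr_mod
from . import enrichment as enr
from . import export as exp
from . import normalize as norm
from . import qc as qc_mod
from .config import PipelineConfig, serialize_config

__all__ = ["PipelineResult", "QCGateFailure", "run_pipeline"]

log = logging.getLogger("edmakit")


class QCGateFailure(RuntimeError):
    """Raised when the cleavage gate fails and ``force`` is off."""

    def __init__(self, failing: dict[str, list[str]]):
        self.failing = failing
        details = "; ".join(
            f"{sample}: {', '.join(enzymes)}" for sample, enzymes in failing.items()
        )
        super().__init__(
            f"cleavage QC gate failed ({details}); a second MSRE digestion is "
            "indicated, or rerun with force=True"
        )


@dataclass
class PipelineResult:
    outdir: Path
    qc_reports: dict = field(default_factory=dict)
    n_fragments: int = 0
    n_probes: int = 0
    n_dmrs: int = 0
    dmr_table: pd.DataFrame | None = None
    fit_table: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    halted_at_qc: bool = False


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.txt").write_text(serialize_config(config))
    t0 = time.time()
    from . import __version__

    log.info("edmakit %s, seed %d", __version__, config.seed)
    result = PipelineResult(outdir=out)

    # --- digestion ---------------------------------------------------------
    genome = dg.read_fasta(config.fasta)
    enzyme = dg.ENZYMES[config.fragmenting_enzyme]
    msres = [dg.ENZYMES[n] for n in config.msre_list()]
    fragments = dg.digest(genome, enzyme)
    dg.annotate_fragment_sites(
        fragments, genome, msres, both_strands=config.msre_both_strands
    )
    dg.write_fragment_tables(fragments, out / "fragments")
    result.n_fragments = len(fragments)
    log.info("digest: %d fragments", len(fragments))

    # --- annotation --------------------------------------------------------
    genes = ann.read_bed12(config.genes) if config.genes else []
    islands = ann.read_islands(config.islands) if config.islands else []
    repeats = ann.read_repeats(config.repeats) if config.repeats else None
    if islands:
        ann.compute_island_stats(islands, genome)
        if len(islands) >= 5:
            ann.classify_islands(
                islands,
                config.island_lower_percentile,
                config.island_upper_percentile,
            )
    annotations = ann.annotate(
        fragments,
        genes,
        islands,
        repeats,
        promoter_sizes={
            "proximal_promoter": config.proximal_promoter_window,
            "promoter": config.promoter_window,
            "distal_promoter": config.distal_promoter_window,
        },
        shore_distance=config.shore_distance,
        shelf_distance=config.shelf_distance,
    )
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)

    # --- cleavage QC -------------------------------------------------------
    controls = (
        pd.read_csv(config.controls, sep="\t") if config.controls else pd.DataFrame()
    )
    if config.spikein_ct:
        ct = qc_mod.read_ct_table(config.spikein_ct)
        reports = qc_mod.build_cleavage_reports(
            ct, threshold=config.cleavage_threshold
        )
        if len(controls):
            for sample, rep in reports.items():
                neg = controls.loc[
                    controls["category"] == "negative", "intensity"
                ]
                msei = controls.loc[
                    controls["category"] == "genomic_msei", "intensity"
                ]
                if len(neg) >= 2:
                    rep.lod = qc_mod.limit_of_detection(neg)
                    if len(msei):
                        rep.msre_control_fail_fraction = qc_mod.genomic_cleavage_check(
                            msei, rep.lod
                        )
        qc_mod.reports_to_frame(reports).to_csv(
            out / "qc_report.tsv", sep="\t", index=False
        )
        result.qc_reports = reports
        failing = {
            s: r.gate.failing_enzymes for s, r in reports.items() if not r.passed
        }
        if failing and not config.force:
            result.halted_at_qc = True
            log.warning("halting at QC gate: %s", failing)
            raise QCGateFailure(failing)

    # --- normalization and fitting ----------------------------------------
    intensities = pd.read_csv(config.intensities, sep="\t")
    manifest = pd.read_csv(config.manifest, sep="\t")
    M, A, dropped = norm.build_ma_matrices(intensities, manifest)
    if len(dropped):
        log.info("excluded %d probes with nonpositive intensities", len(dropped))
    M = norm.loess_normalize(
        M, A, span=config.loess_span, iterations=config.loess_iterations
    )
    if config.inter_array_method == "quantile":
        M = norm.quantile_normalize(M)
    elif config.inter_array_method == "scale":
        M = norm.scale_normalize(M)
    else:
        raise ValueError(
            f"unknown inter-array method {config.inter_array_method!r}"
        )
    M.to_csv(out / "m_matrix.tsv", sep="\t")
    result.n_probes = M.shape[0]

    fits = dmr_mod.fit_moderated(M)
    probes = pd.read_csv(config.probes, sep="\t") if config.probes else None
    if probes is not None:
        probe_info = probes.set_index("probe_id")
        fits = fits.join(probe_info, how="left")
        fits["position"] = (fits["start"] + fits["end"]) // 2
    fits.to_csv(out / "fits.tsv", sep="\t")
    result.fit_table = fits

    ann_by_fragment = annotations.set_index("fragment_id")
    dmr_annotations = None
    if probes is not None:
        dmr_annotations = (
            probes.set_index("probe_id")[["fragment_id"]]
            .join(ann_by_fragment, on="fragment_id")
        )
    dmrs = dmr_mod.call_dmrs(
        fits,
        p_threshold=config.p_threshold,
        m_threshold=config.m_threshold,
        annotations=dmr_annotations,
    )
    dmrs.to_csv(out / "dmrs.tsv", sep="\t")
    result.dmr_table = dmrs
    result.n_dmrs = len(dmrs)
    log.info("called %d DMRs", len(dmrs))

    # --- enrichment, hot spots, exports ------------------------------------
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    if dmr_annotations is not None and len(dmrs):
        enrich = enr.enrichment_table(
            dmrs, dmr_annotations, pseudocount=config.pseudocount
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        result.enrichment = enrich
    if probes is not None:
        track = enr.hotspots(
            fits["position"],
            fits["p"],
            fits["chrom"],
            window_half_width=config.hotspot_half_width,
        )
        track.to_csv(out / "hotspots.tsv", sep="\t", index=False)
        exp.export_bedgraph(
            track.assign(
                start=track["position"], end=track["position"] + 1
            ),
            out / "hotspots.bedgraph",
            name="methylation_hotspots",
            value_column="smoothed_p",
            overlap_policy="merge",
        )
        bins, top = enr.circos_windows(
            fits,
            chrom_lengths,
            window=config.circos_window,
            top_n=config.circos_top_n,
            dmrs=dmrs if len(dmrs) else None,
        )
        bins.to_csv(out / "circos_windows.tsv", sep="\t", index=False)
        top.to_csv(out / "top_dmrs.tsv", sep="\t")
        exp.export_circos_karyotype(chrom_lengths, out / "circos_karyotype.txt")
        exp.export_circos_data(
            bins, out / "circos_mean_p.txt", value_column="mean_p"
        )
        # mean-M bedgraph per probe fragment for genome browsers
        m_track = fits.reset_index()[["chrom", "start", "end", "mean_m"]].dropna()
        exp.export_bedgraph(
            m_track,
            out / "mean_m.bedgraph",
            name="mean_M",
            value_column="mean_m",
            overlap_policy="merge",
        )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return result
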