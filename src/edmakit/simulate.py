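"""Synthetic experiments with known ground truth for every pipeline stage.

The simulator emulates the data an MSRE/two-color methylation array produces,
end to end: an AT-rich genome with CpG-enriched island blocks, gene and
repeat tracks; MseI fragment structure (digestion is delegated to the real
digest module, not re-modelled); per-fragment methylation states with
planted differentially methylated regions; two-channel intensities with
multiplicative log-normal noise and a smooth intensity-dependent dye bias;
negative and genomic-cleavage control probes; and spike-in qPCR Ct values
that invert the cleavage-efficiency formula.

Everything derives from one seeded random generator, so a config plus seed
fixes every output byte-for-byte.  The defaults are the desk-scale study
conditions the package is validated under: 20,000 probes, 200 planted DMRs
of |ΔM| = 2 (85 % hypermethylated in group A), 4 dye-swap hybridization
pairs, M-noise standard deviation 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .restriction import (
    DEFAULT_MSRES,
    MSE_I,
    RestrictionFragment,
    annotate_fragment_sites,
    digest as digest_genome,
    write_fasta,
)
from .annotation import CpGIslandRecord, GeneModel
from .arraydesign import tile_control_positions

__all__ = [
    "SimConfigError",
    "SimConfig",
    "SimulatedExperiment",
    "simulate_genome",
    "simulate_methylation",
    "simulate_intensities",
    "simulate_spikein_ct",
    "simulate_experiment",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Low_complexity", "Simple_repeat")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition knobs for one synthetic experiment.

    Genome: ``at_fraction`` is the A+T share of the background composition
    (split equally), chosen AT-rich so MseI (TTAA) fragments come out short,
    the regime the assay is designed for.  Islands overwrite background
    blocks with composition whose C+G share is boosted by
    ``island_cpg_enrichment`` (factor 1 = no enrichment).

    Design: ``n_hyb_pairs`` dye-swap pairs yield 2·pairs hybridizations, all
    comparing group A against group B.  Planted DMRs shift the group-A
    channel abundance by ±``dmr_delta_m`` on the log2 scale; exactly
    ``round(n_dmrs·dmr_hyper_in_a_fraction)`` of them are hyper in A.

    Noise: per-channel log2 noise sd defaults to 0.4/√2 so the resulting M
    noise sd is 0.4; the dye bias adds ``bias_intercept + bias_slope·A``
    log2 units to Cy5, which the loess step is expected to remove.
    """

    seed: int = 42
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 3_000_000
    at_fraction: float = 0.60
    n_islands_per_chromosome: int = 60
    island_mean_length: int = 800
    island_cpg_enrichment: float = 5.0
    n_genes_per_chromosome: int = 30
    n_repeats_per_chromosome: int = 150
    # methylation baselines (means of Beta draws, concentration 20)
    island_baseline_methylation: float = 0.15
    repeat_baseline_methylation: float = 0.85
    other_baseline_methylation: float = 0.50
    # array design
    n_probes: int = 20_000
    n_hyb_pairs: int = 4
    n_dmrs: int = 200
    dmr_delta_m: float = 2.0
    dmr_hyper_in_a_fraction: float = 0.85
    # intensity model
    signal_scale: float = 2000.0
    background_level: float = 20.0
    channel_log2_noise_sd: float = 0.4 / math.sqrt(2.0)
    dye_bias_intercept: float = 0.2
    dye_bias_slope: float = 0.05
    # controls
    n_negative_controls: int = 96
    genomic_control_spacing: int = 25_000
    # spike-ins
    spikein_cleaved_fraction: dict[str, float] = field(
        default_factory=lambda: {"HpaII": 0.99, "HinP1I": 0.99, "AciI": 0.99}
    )
    spikein_ct_base: float = 22.0
    spikein_ct_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.at_fraction < 1:
            raise SimConfigError(f"at_fraction must be in (0,1), got {self.at_fraction}")
        if not 0 <= self.dmr_hyper_in_a_fraction <= 1:
            raise SimConfigError("dmr_hyper_in_a_fraction must be in [0,1]")
        for enzyme, f in self.spikein_cleaved_fraction.items():
            if not 0 <= f < 1:
                raise SimConfigError(
                    f"{enzyme}: cleaved fraction must be in [0,1), got {f} "
                    "(f = 1 would mean an infinite ΔCt)"
                )
        island_total = self.n_islands_per_chromosome * self.island_mean_length
        if island_total > self.chromosome_length:
            raise SimConfigError(
                f"islands ({island_total} nt expected) exceed chromosome length "
                f"({self.chromosome_length} nt)"
            )

    @property
    def sample_names(self) -> tuple[list[str], list[str]]:
        a = [f"A{i + 1}" for i in range(self.n_hyb_pairs)]
        b = [f"B{i + 1}" for i in range(self.n_hyb_pairs)]
        return a, b


def _base_probs(at_fraction: float, cg_boost: float = 1.0) -> np.ndarray:
    """Composition over ACGT; C/G share multiplied by sqrt(cg_boost), renormalised."""
    at = at_fraction / 2.0
    cg = (1.0 - at_fraction) / 2.0
    cg_b = cg * math.sqrt(cg_boost)
    probs = np.array([at, cg_b, cg_b, at], dtype=float)
    return probs / probs.sum()


_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return "".join(_BASES[idx])


def _place_intervals(
    rng: np.random.Generator,
    chrom_length: int,
    count: int,
    mean_length: int,
    min_length: int = 100,
) -> list[tuple[int, int]]:
    """Non-overlapping random intervals, sorted; overlapping draws are dropped."""
    lengths = np.maximum(
        min_length, rng.gamma(shape=4.0, scale=mean_length / 4.0, size=count)
    ).astype(int)
    starts = rng.integers(0, max(1, chrom_length - int(lengths.max())), size=count)
    order = np.argsort(starts, kind="stable")
    placed: list[tuple[int, int]] = []
    last_end = -1
    for i in order:
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        if s > last_end and e <= chrom_length:
            placed.append((s, e))
            last_end = e
    return placed


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[CpGIslandRecord], list[GeneModel], pd.DataFrame]:
    """Genome FASTA dict plus island/gene/repeat tracks.

    Background bases are i.i.d. with the configured AT-richness; island
    blocks are overwritten with CpG-enriched composition; gene models get
    2–8 exons within a uniform span; repeats draw labels from the five
    production repeat classes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bg_probs = _base_probs(config.at_fraction)
    isl_probs = _base_probs(config.at_fraction, config.island_cpg_enrichment)
    genome: dict[str, str] = {}
    islands: list[CpGIslandRecord] = []
    genes: list[GeneModel] = []
    repeat_rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = list(_random_sequence(rng, config.chromosome_length, bg_probs))
        isl_intervals = _place_intervals(
            rng,
            config.chromosome_length,
            config.n_islands_per_chromosome,
            config.island_mean_length,
            min_length=200,
        )
        for k, (s, e) in enumerate(isl_intervals):
            seq[s:e] = _random_sequence(rng, e - s, isl_probs)
            islands.append(CpGIslandRecord(chrom, s, e, name=f"CpG_{chrom}_{k}"))
        genome[chrom] = "".join(seq)
        for g, (s, e) in enumerate(
            _place_intervals(
                rng,
                config.chromosome_length,
                config.n_genes_per_chromosome,
                15_000,
                min_length=2_000,
            )
        ):
            n_exons = int(rng.integers(2, 9))
            cuts = np.sort(rng.choice(np.arange(s + 1, e), size=2 * n_exons - 1, replace=False))
            bounds = np.concatenate([[s], cuts, [e]])
            exons = [
                (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene_{chrom}_{g}", chrom, strand, s, e, exons))
        for s, e in _place_intervals(
            rng, config.chromosome_length, config.n_repeats_per_chromosome, 400,
            min_length=150,
        ):
            repeat_rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "repeat_class": str(rng.choice(REPEAT_CLASSES)),
                }
            )
    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "repeat_class"]
    )
    return genome, islands, genes, repeats


def _overlaps_any(
    frag: RestrictionFragment, intervals: Mapping[str, np.ndarray]
) -> bool:
    arr = intervals.get(frag.chrom)
    if arr is None or not len(arr):
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    i = np.searchsorted(starts, frag.end)
    return bool(np.any(ends[:i] > frag.start))


def simulate_methylation(
    fragments: list[RestrictionFragment],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    islands: list[CpGIslandRecord] | None = None,
    repeats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Truth table: per-fragment methylation, probe selection, planted DMRs.

    Only fragments carrying an MSRE site can be informative (a fragment
    without one is never protected and yields no signal), so probes and
    planted DMRs are drawn from those.  Baseline methylation is
    category-conditional — islands hypomethylated, repeats hypermethylated,
    everything else intermediate — via Beta draws around the configured
    means.  The planted direction split is exact by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    isl_arr: dict[str, np.ndarray] = {}
    for isl in islands or []:
        isl_arr.setdefault(isl.chrom, []).append((isl.start, isl.end))  # type: ignore[arg-type]
    isl_arr = {k: np.array(sorted(v)) for k, v in isl_arr.items()}
    rep_arr: dict[str, np.ndarray] = {}
    if repeats is not None and len(repeats):
        for chrom, sub in repeats.groupby("chrom"):
            rep_arr[str(chrom)] = sub[["start", "end"]].sort_values("start").to_numpy()

    rows = []
    conc = 20.0
    for i, frag in enumerate(fragments):
        if _overlaps_any(frag, isl_arr):
            category, mean = "island", config.island_baseline_methylation
        elif _overlaps_any(frag, rep_arr):
            category, mean = "repeat", config.repeat_baseline_methylation
        else:
            category, mean = "other", config.other_baseline_methylation
        meth = float(rng.beta(mean * conc, (1 - mean) * conc))
        rows.append(
            {
                "fragment_id": f"F{i:06d}",
                "chrom": frag.chrom,
                "start": frag.start,
                "end": frag.end,
                "has_msre": frag.has_msre,
                "category": category,
                "meth_level": meth,
            }
        )
    truth = pd.DataFrame(rows)
    eligible = truth.index[truth["has_msre"]].to_numpy()
    if config.n_probes > eligible.size:
        raise SimConfigError(
            f"requested {config.n_probes} probes but only {eligible.size} "
            "MSRE-bearing fragments are available; enlarge the genome"
        )
    probe_rows = rng.choice(eligible, size=config.n_probes, replace=False)
    probe_rows.sort()
    truth["is_probe"] = False
    truth.loc[probe_rows, "is_probe"] = True
    probe_ids = np.full(len(truth), "", dtype=object)
    probe_ids[probe_rows] = [f"P{i:06d}" for i in range(config.n_probes)]
    truth["probe_id"] = probe_ids

    truth["is_dmr"] = False
    truth["true_delta_m"] = 0.0
    if config.n_dmrs > 0:
        if config.n_dmrs > config.n_probes:
            raise SimConfigError("more planted DMRs than probes")
        dmr_rows = rng.choice(probe_rows, size=config.n_dmrs, replace=False)
        n_hyper_a = int(round(config.n_dmrs * config.dmr_hyper_in_a_fraction))
        signs = np.concatenate(
            [
                np.full(n_hyper_a, 1.0),
                np.full(config.n_dmrs - n_hyper_a, -1.0),
            ]
        )
        rng.shuffle(signs)
        truth.loc[dmr_rows, "is_dmr"] = True
        truth.loc[dmr_rows, "true_delta_m"] = signs * config.dmr_delta_m
    return truth


def simulate_intensities(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-channel intensities for every hybridization, plus control signals.

    Per probe, the expected group-B channel abundance is scale·methylated
    fraction + background; group A multiplies that by 2^ΔM for planted DMRs.
    Each measured channel gets independent multiplicative log-normal noise,
    and Cy5 additionally receives a smooth A-dependent dye bias (so the
    loess step has something real to remove).  Dye-swap pairs are emitted as
    two arrays with reversed channel assignment.

    Returns ``(intensities, manifest, controls)``: a long intensity table
    (probe_id, array_id, cy3, cy5), the array manifest (array_id, sample_a,
    sample_b, dye_swap), and single-channel control intensities (array_id,
    control_id, category, intensity) covering negative controls, MseI
    genomic-cleavage controls (digestion complete → background signal) and
    protected/unprotected methylation spike-ins.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    probes = truth[truth["is_probe"]].reset_index(drop=True)
    # The planted log2 difference is split symmetrically between the groups
    # so a probe's average intensity (A) does not encode its DMR status;
    # differential signal and intensity-dependent dye bias stay orthogonal.
    base = config.signal_scale * probes["meth_level"].to_numpy() + config.background_level
    half_shift = np.exp2(0.5 * probes["true_delta_m"].to_numpy())
    base_a = base * half_shift
    base_b = base / half_shift
    a_true = 0.5 * (np.log2(base_a) + np.log2(base_b))
    sd = config.channel_log2_noise_sd

    samples_a, samples_b = config.sample_names
    manifest_rows = []
    intensity_frames = []
    control_rows = []
    lam = math.log(2.0)
    for pair in range(config.n_hyb_pairs):
        for swap in (False, True):
            array_id = f"arr{pair + 1}{'s' if swap else 'f'}"
            manifest_rows.append(
                {
                    "array_id": array_id,
                    "sample_a": samples_a[pair],
                    "sample_b": samples_b[pair],
                    "dye_swap": swap,
                }
            )
            noise_a = np.exp(lam * rng.normal(0.0, sd, size=len(probes)))
            noise_b = np.exp(lam * rng.normal(0.0, sd, size=len(probes)))
            sig_a = base_a * noise_a
            sig_b = base_b * noise_b
            # group A sits in Cy5 on forward arrays, Cy3 on swapped ones
            cy5, cy3 = (sig_b, sig_a) if swap else (sig_a, sig_b)
            bias = np.exp2(
                config.dye_bias_intercept + config.dye_bias_slope * a_true
            )
            cy5 = cy5 * bias
            intensity_frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probes["probe_id"],
                        "array_id": array_id,
                        "cy3": cy3,
                        "cy5": cy5,
                    }
                )
            )
            # --- controls (single-channel summaries) ---
            bg = config.background_level
            neg = bg * np.exp(
                lam * rng.normal(0.0, sd, size=config.n_negative_controls)
            )
            for k, v in enumerate(neg):
                control_rows.append(
                    {
                        "array_id": array_id,
                        "control_id": f"neg{k:03d}",
                        "category": "negative",
                        "enzyme": "",
                        "intensity": float(v),
                    }
                )
            if chrom_lengths:
                tiles = tile_control_positions(
                    chrom_lengths, config.genomic_control_spacing
                )
                gen = bg * np.exp(lam * rng.normal(0.0, sd, size=len(tiles)))
                for (chrom, pos), v in zip(tiles, gen):
                    control_rows.append(
                        {
                            "array_id": array_id,
                            "control_id": f"msei_{chrom}_{pos}",
                            "category": "genomic_msei",
                            "enzyme": "",
                            "intensity": float(v),
                        }
                    )
            for enzyme, f in config.spikein_cleaved_fraction.items():
                protected = config.signal_scale * float(
                    np.exp(lam * rng.normal(0.0, sd))
                )
                unprotected = (
                    (1.0 - f) * config.signal_scale + bg
                ) * float(np.exp(lam * rng.normal(0.0, sd)))
                control_rows.append(
                    {
                        "array_id": array_id,
                        "control_id": f"spike_{enzyme}_protected",
                        "category": "spikein_protected",
                        "enzyme": enzyme,
                        "intensity": protected,
                    }
                )
                control_rows.append(
                    {
                        "array_id": array_id,
                        "control_id": f"spike_{enzyme}_unprotected",
                        "category": "spikein_unprotected",
                        "enzyme": enzyme,
                        "intensity": unprotected,
                    }
                )
    intensities = pd.concat(intensity_frames, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    controls = pd.DataFrame(
        control_rows, columns=["array_id", "control_id", "category", "enzyme", "intensity"]
    )
    return intensities, manifest, controls


def simulate_spikein_ct(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Spike-in qPCR table inverting the cleavage model: ΔCt = −log2(1 − f).

    One protected/unprotected pair per enzyme per sample; Gaussian Ct noise
    of the configured sd is added to the unprotected member.  A cleaved
    fraction of exactly 1 is rejected at config time (infinite ΔCt).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    samples_a, samples_b = config.sample_names
    rows = []
    for sample in samples_a + samples_b:
        for enzyme, f in config.spikein_cleaved_fraction.items():
            ct_prot = config.spikein_ct_base + float(rng.normal(0.0, 0.2))
            delta = -math.log2(1.0 - f)
            ct_unprot = ct_prot + delta + float(
                rng.normal(0.0, config.spikein_ct_noise_sd)
            )
            rows.append(
                {"sample": sample, "enzyme": enzyme, "template": "protected", "ct": ct_prot}
            )
            rows.append(
                {"sample": sample, "enzyme": enzyme, "template": "unprotected", "ct": ct_unprot}
            )
    return pd.DataFrame(rows, columns=["sample", "enzyme", "template", "ct"])


@dataclass
class SimulatedExperiment:
    """Everything one synthetic run produces, ready for the pipeline."""

    config: SimConfig
    genome: dict[str, str]
    islands: list[CpGIslandRecord]
    genes: list[GeneModel]
    repeats: pd.DataFrame
    fragments: list[RestrictionFragment]
    truth: pd.DataFrame
    intensities: pd.DataFrame
    manifest: pd.DataFrame
    controls: pd.DataFrame
    spikein_ct: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit exactly the text formats the pipeline consumes, plus truth."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "islands": out / "islands.bed",
            "genes": out / "genes.bed",
            "repeats": out / "repeats.bed",
            "intensities": out / "intensities.tsv",
            "manifest": out / "manifest.tsv",
            "controls": out / "controls.tsv",
            "spikein_ct": out / "spikein_ct.tsv",
            "truth": out / "truth.tsv",
            "probes": out / "probes.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        with open(paths["islands"], "w") as fh:
            for isl in self.islands:
                fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.name}\n")
        with open(paths["genes"], "w") as fh:
            for g in self.genes:
                sizes = ",".join(str(e - s) for s, e in g.exons) + ","
                offsets = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
                fh.write(
                    f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
                )
        with open(paths["repeats"], "w") as fh:
            for row in self.repeats.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.repeat_class}/sim\t0\t+\n"
                )
        self.intensities.to_csv(paths["intensities"], sep="\t", index=False)
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        self.controls.to_csv(paths["controls"], sep="\t", index=False)
        self.spikein_ct.to_csv(paths["spikein_ct"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        probes = self.truth[self.truth["is_probe"]][
            ["probe_id", "fragment_id", "chrom", "start", "end"]
        ]
        probes.to_csv(paths["probes"], sep="\t", index=False)
        return paths


def simulate_experiment(config: SimConfig | None = None) -> SimulatedExperiment:
    """Run the whole generator: genome → digest → methylation → intensities.

    Digestion and MSRE annotation use the production digest module, so the
    simulated fragment structure is exactly what the pipeline itself would
    compute from the FASTA.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genome, islands, genes, repeats = simulate_genome(config, rng)
    fragments = digest_genome(genome, MSE_I)
    annotate_fragment_sites(fragments, genome, DEFAULT_MSRES)
    truth = simulate_methylation(fragments, config, rng, islands, repeats)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    intensities, manifest, controls = simulate_intensities(
        truth, config, rng, chrom_lengths
    )
    spikein_ct = simulate_spikein_ct(config, rng)
    return SimulatedExperiment(
        config=config,
        genome=genome,
        islands=islands,
        genes=genes,
        repeats=repeats,
        fragments=fragments,
        truth=truth,
        intensities=intensities,
        manifest=manifest,
        controls=controls,
        spikein_ct=spikein_ct,
    )
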