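"""Pipeline configuration: defaults, plain-text key=value parsing, round-trip.

Every analysis constant has its production default here: cleavage gate 0.97,
DMR thresholds p < 0.05 and |log2 FC| ≥ 1.5, promoter windows 1/5/50 kb,
shore/shelf bands 2/4 kb, island percentile cuts 20/80, hot-spot half-width
100 kb, Circos window 5 Mb, enrichment pseudocount 0.5.  Config files are
plain ``key = value`` text; unknown keys are errors so threshold-name typos
cannot silently fall back to defaults.  Each pipeline run serialises its
resolved config next to the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["ConfigError", "PipelineConfig", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # input paths (empty = stage skipped or simulator-provided)
    fasta: str = ""
    genes: str = ""
    islands: str = ""
    repeats: str = ""
    intensities: str = ""
    manifest: str = ""
    probes: str = ""
    controls: str = ""
    spikein_ct: str = ""
    # enzymes
    fragmenting_enzyme: str = "MseI"
    msre_enzymes: str = "HpaII,HinP1I,AciI"
    msre_both_strands: bool = True
    # thresholds
    cleavage_threshold: float = 0.97
    p_threshold: float = 0.05
    m_threshold: float = 1.5
    # windows (nt)
    proximal_promoter_window: int = 1_000
    promoter_window: int = 5_000
    distal_promoter_window: int = 50_000
    shore_distance: int = 2_000
    shelf_distance: int = 4_000
    hotspot_half_width: int = 100_000
    circos_window: int = 5_000_000
    circos_top_n: int = 100
    # island classes
    island_lower_percentile: float = 20.0
    island_upper_percentile: float = 80.0
    # enrichment
    pseudocount: float = 0.5
    # normalization
    loess_span: float = 0.3
    loess_iterations: int = 3
    inter_array_method: str = "quantile"  # or "scale"
    # misc
    seed: int = 42
    force: bool = False  # continue past a failed QC gate

    def msre_list(self) -> list[str]:
        return [e.strip() for e in self.msre_enzymes.split(",") if e.strip()]


_BOOL_TRUE = {"true", "yes", "1", "on"}
_BOOL_FALSE = {"false", "no", "0", "off"}


def _coerce(name: str, raw: str, typ: type) -> object:
    raw = raw.strip()
    if typ is bool:
        low = raw.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ConfigError(f"{name}: cannot parse {raw!r} as a boolean")
    try:
        return typ(raw)
    except ValueError as exc:
        raise ConfigError(f"{name}: cannot parse {raw!r} as {typ.__name__}") from exc


def parse_config(source: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Read ``key = value`` text (or a path to it) into a PipelineConfig.

    Blank lines and ``#`` comments are ignored.  Unknown keys raise.
    ``overrides`` (e.g. from command-line flags) win over file values.
    """
    if isinstance(source, Path) or ("\n" not in str(source) and "=" not in str(source)):
        text = Path(source).read_text()
    else:
        text = str(source)
    schema = {f.name: f.type for f in fields(PipelineConfig)}
    # dataclass field types may arrive as strings under future annotations
    types = {
        f.name: (type(getattr(PipelineConfig(), f.name))) for f in fields(PipelineConfig)
    }
    values: dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in schema:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
        values[key] = _coerce(key, raw, types[key])
    if overrides:
        unknown = set(overrides) - set(schema)
        if unknown:
            raise ConfigError(f"unknown override keys: {sorted(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)  # type: ignore[arg-type]


def serialize_config(config: PipelineConfig) -> str:
    lines = [
        f"{f.name} = {getattr(config, f.name)}" for f in fields(PipelineConfig)
    ]
    return "\n".join(lines) + "\n"
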