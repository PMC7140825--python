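"""The single key=value configuration file driving the pipeline.

Format: one ``Name=Value`` pair per line; ``#`` starts a comment; blank
lines and whitespace around ``=`` are ignored.  Keys are grouped into
required, optional and advanced sections, but the section headers are
purely cosmetic — lookup is by key name and unknown keys are an error
(they are almost always typos).  An empty value for an optional key means
"use the default" or, for ``AdapterSeq``/``HalfLinker``/``Restriction``,
"detect automatically".
"""

from __future__ import annotations

from dataclasses import MISSING, dataclass, field, fields
from pathlib import Path

from ._seq import is_nucleotide
from .fragments import RestrictionSite
from .mapping import MappingParams
from .preprocess import AdapterParams, LinkerAlignParams

__all__ = ["Config", "ConfigError", "parse_config", "write_template"]


class ConfigError(ValueError):
    pass


@dataclass
class Config:
    # required
    data_file: str = ""
    genome_file: str = ""
    out_path: str = ""
    # optional
    adapter_seq: str = ""
    half_linker: str = ""
    restriction: str = ""
    reads_type: str = "short"
    resolutions: list[int] = field(default_factory=lambda: [1_000_000, 100_000])
    threads: int = 1
    # advanced
    match_score: int = 1
    mismatch_score: int = -1
    indel_score: int = -1
    min_score_fraction: float = 0.8
    min_tag_length: int = 10
    adapter_sample_size: int = 100
    adapter_min_base_freq: float = 0.6
    adapter_min_overlap: int = 6
    iterative: bool = False
    n_max: int = 3
    chunk_size: int = 100_000
    short_range_max: int = 5_000
    dup_window: int = 2
    detect_sample_size: int = 10_000

    def __post_init__(self) -> None:
        if self.reads_type not in ("short", "long"):
            raise ConfigError(f"ReadsType must be 'short' or 'long', got {self.reads_type!r}")
        if self.adapter_seq and not is_nucleotide(self.adapter_seq):
            raise ConfigError(f"AdapterSeq {self.adapter_seq!r} is not a nucleotide string")
        for h in self.half_linkers:
            if not is_nucleotide(h):
                raise ConfigError(f"HalfLinker {h!r} is not a nucleotide string")
        if len(self.half_linkers) > 2:
            raise ConfigError("at most two comma-separated half-linkers are supported")
        if self.restriction:
            RestrictionSite.from_string(self.restriction)  # validates caret + alphabet
        if any(r <= 0 for r in self.resolutions):
            raise ConfigError("resolutions must be positive integers")
        if self.threads <= 0:
            raise ConfigError("Threads must be a positive integer")

    @property
    def half_linkers(self) -> list[str]:
        return [h for h in self.half_linker.split(",") if h]

    @property
    def restriction_site(self) -> RestrictionSite | None:
        return RestrictionSite.from_string(self.restriction) if self.restriction else None

    def linker_align_params(self) -> LinkerAlignParams:
        return LinkerAlignParams(self.match_score, self.mismatch_score,
                                 self.indel_score, self.min_score_fraction)

    def adapter_params(self) -> AdapterParams:
        return AdapterParams(self.adapter_sample_size, self.adapter_min_base_freq,
                             self.adapter_min_overlap)

    def mapping_params(self) -> MappingParams:
        return MappingParams(
            algorithm="mem" if self.reads_type == "long" else "aln",
            iterative=self.iterative, n_max=self.n_max,
            chunk_size=self.chunk_size, threads=self.threads,
        )


# key name in file -> (attribute, parser, section, comment)
def _bool(text: str) -> bool:
    if text.lower() in ("true", "yes", "1"):
        return True
    if text.lower() in ("false", "no", "0"):
        return False
    raise ValueError(f"expected true/false, got {text!r}")


def _int_list(text: str) -> list[int]:
    return [int(x) for x in text.split(",") if x.strip()]


_KEYS: dict[str, tuple[str, object, str, str]] = {
    "DataFile": ("data_file", str, "required", "input FASTQ or FASTQ.gz (R1 only)"),
    "GenomeFile": ("genome_file", str, "required", "reference genome FASTA"),
    "OutPath": ("out_path", str, "required", "output directory"),
    "AdapterSeq": ("adapter_seq", str, "optional",
                   "sequencing adapter; empty = detect automatically"),
    "HalfLinker": ("half_linker", str, "optional",
                   "one or two comma-separated half-linkers; empty = detect"),
    "Restriction": ("restriction", str, "optional",
                    "restriction site with caret cut mark, e.g. T^TAA; empty = detect"),
    "ReadsType": ("reads_type", str, "optional", "short (bwa aln) or long (bwa mem)"),
    "Resolutions": ("resolutions", _int_list, "optional",
                    "comma-separated matrix bin sizes in bp"),
    "Threads": ("threads", int, "optional", "worker threads for mapping"),
    "MatchScore": ("match_score", int, "advanced", "linker alignment match score"),
    "MisMatchScore": ("mismatch_score", int, "advanced", "linker alignment mismatch score"),
    "InDelScore": ("indel_score", int, "advanced", "linker alignment indel score"),
    "MinScoreFraction": ("min_score_fraction", float, "advanced",
                         "accept a linker hit at this fraction of full length"),
    "MinTagLength": ("min_tag_length", int, "advanced", "discard reads with shorter tags"),
    "AdapterSampleSize": ("adapter_sample_size", int, "advanced",
                          "reads sampled for adapter consensus"),
    "AdapterMinBaseFreq": ("adapter_min_base_freq", float, "advanced",
                           "consensus base-call frequency threshold"),
    "AdapterMinOverlap": ("adapter_min_overlap", int, "advanced",
                          "minimal adapter overlap at the read end"),
    "Iterative": ("iterative", _bool, "advanced", "iterative mapping on/off"),
    "NMax": ("n_max", int, "advanced", "edit-distance cap for iterative mapping"),
    "ChunkSize": ("chunk_size", int, "advanced", "reads per mapping chunk"),
    "ShortRangeMax": ("short_range_max", int, "advanced",
                      "intra-chromosomal short-range boundary in bp"),
    "DupWindow": ("dup_window", int, "advanced", "duplicate position window in bp"),
    "DetectSampleSize": ("detect_sample_size", int, "advanced",
                         "reads sampled for linker/enzyme detection"),
}

_REQUIRED = [k for k, v in _KEYS.items() if v[2] == "required"]
_DEFAULTS = {
    f.name: (f.default_factory() if f.default_factory is not MISSING else f.default)
    for f in fields(Config)
}


def parse_config(path: str | Path) -> Config:
    """Parse and validate a configuration file."""
    values: dict[str, object] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected Name=Value, got {raw.strip()!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _KEYS:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            if key in seen:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            seen.add(key)
            attr, parser, _sec, _doc = _KEYS[key]
            if value == "" and key not in _REQUIRED:
                continue  # empty optional value = default / auto-detect
            try:
                values[attr] = parser(value)  # type: ignore[operator]
            except ConfigError:
                raise
            except Exception as exc:
                raise ConfigError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc
    missing = [k for k in _REQUIRED if _KEYS[k][0] not in values or not values[_KEYS[k][0]]]
    if missing:
        raise ConfigError(f"{path}: missing required key(s): {', '.join(missing)}")
    try:
        return Config(**values)  # type: ignore[arg-type]
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def serialize_config(cfg: Config) -> str:
    """Render a Config back to file text (round-trips through parse_config)."""
    lines = []
    for section in ("required", "optional", "advanced"):
        lines.append(f"# [{section} parameters]")
        for key, (attr, _p, sec, doc) in _KEYS.items():
            if sec != section:
                continue
            value = getattr(cfg, attr)
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            elif isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{key}={value}  # {doc}")
        lines.append("")
    return "\n".join(lines)


def write_template(path: str | Path) -> None:
    """Write a commented template with every recognized key and its default."""
    lines = []
    for section in ("required", "optional", "advanced"):
        lines.append(f"# [{section} parameters]")
        for key, (attr, _p, sec, doc) in _KEYS.items():
            if sec != section:
                continue
            default = _DEFAULTS[attr]
            if isinstance(default, list):
                default = ",".join(str(v) for v in default)
            elif isinstance(default, bool):
                default = "true" if default else "false"
            lines.append(f"# {doc}")
            lines.append(f"{key}={default}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
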