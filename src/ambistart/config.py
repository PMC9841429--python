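"""Scan configuration: anti-SD letters, window sizes, classification breakpoints.

Loaded from a small YAML mapping; every key has a default matching the
reference survey, so an empty (or absent) config reproduces it. Keys:

``asd_sequence``     9-nt anti-SD (default ACCUCCUUA, *E. coli* 16S 3' end)
``upstream_window``  SD search window upstream of the CDS, nt (default 30)
``min_sd_len``       minimum SD duplex length, nt (default 4)
``longest_only``     report only maximal-length SD matches (default true)
``include_pseudo``   keep pseudogenes in the scan (default false)
``seed``             seed for synthetic generation subcommands (default 0)
``windows``          mapping of AmbiguityWindows breakpoints (integers)
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .ambiguity import AmbiguityWindows
from .sd import AntiSD


class ConfigError(ValueError):
    """The configuration file is malformed."""


@dataclass
class ScanConfig:
    asd_sequence: str = "ACCUCCUUA"
    upstream_window: int = 30
    min_sd_len: int = 4
    longest_only: bool = True
    include_pseudo: bool = False
    seed: int = 0
    windows: AmbiguityWindows = field(default_factory=AmbiguityWindows)

    @property
    def asd(self) -> AntiSD:
        return AntiSD(self.asd_sequence)


def load_config(path: str | Path | None) -> ScanConfig:
    """Load a ScanConfig from YAML; ``None`` yields the defaults."""
    if path is None:
        return ScanConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(ScanConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    win_raw = raw.pop("windows", None)
    try:
        windows = AmbiguityWindows(**win_raw) if win_raw else AmbiguityWindows()
        cfg = ScanConfig(windows=windows, **raw)
        cfg.asd  # validates letters/length
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc
    return cfg
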