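"""Flat key-value pipeline configuration.

The config file format is one ``key = value`` pair per line; ``#`` starts a
comment.  Values are parsed as int, float, comma-separated tuple, or string
in that order of preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .spectra import SearchConfig, DEFAULT_MZ_RANGE


@dataclass
class PipelineConfig:
    """End-to-end settings shared by the command-line stages."""

    tol_ppm: float = 200.0
    tol_da: float = 0.6
    score_threshold: float = 3.0
    series_set: tuple[str, ...] = ("a", "b", "y")
    max_charge: int = 1
    mz_min: float = DEFAULT_MZ_RANGE[0]
    mz_max: float = DEFAULT_MZ_RANGE[1]
    allow_monobasic: bool = False
    min_len: int = 4
    alkylated: bool = False
    pattern_library: str = ""  # empty = packaged library
    tissue_panel: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.tol_da <= 0:
            raise ValueError("tolerances must be positive")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            tol_ppm=self.tol_ppm,
            tol_da=self.tol_da,
            score_threshold=self.score_threshold,
            series_set=tuple(self.series_set),
            max_charge=self.max_charge,
            mz_range=(self.mz_min, self.mz_max),
        )


def _parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        return tuple(_parse_value(part) for part in raw.split(",") if part.strip())
    if raw.lower() in ("true", "yes"):
        return True
    if raw.lower() in ("false", "no"):
        return False
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def read_config(path) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _parse_value(raw)
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        for f in fields(PipelineConfig):
            value = getattr(config, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{f.name} = {value}\n")
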