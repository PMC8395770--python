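"""Run configuration: the model's defaults and a key=value file loader.

All defaults are the study conventions: translation factor 0.72, %HRR
targets 60/70/80, avoided speed band 1.79–2.23 m/s, agreement bands ±10 bpm
and ±1 RPE unit.  A config file holds ``key = value`` lines (``#`` comments
allowed); values given on the command line override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    translation_factor: float = 0.72
    hrr_fractions: tuple = (0.6, 0.7, 0.8)
    avoid_band_m_s: tuple = (1.79, 2.23)
    speed_unit: str = "m/s"
    grade_resolution_pct: float = 1.0
    hr_band_bpm: float = 10.0
    rpe_band: float = 1.0
    warmup_speed_m_s: float = 1.33
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.translation_factor <= 1):
            raise ValueError("translation_factor must lie in (0, 1]")
        if not self.avoid_band_m_s[0] < self.avoid_band_m_s[1]:
            raise ValueError("avoid band lower bound must be below upper")
        if any(not (0 <= f <= 1) for f in self.hrr_fractions):
            raise ValueError("HRR fractions must lie in [0, 1]")
        if self.grade_resolution_pct not in (0.5, 1.0):
            raise ValueError("grade display resolution must be 0.5 or 1.0 percent")

    @property
    def avoid_band_m_min(self) -> tuple:
        return (self.avoid_band_m_s[0] * 60.0, self.avoid_band_m_s[1] * 60.0)

    def describe(self) -> str:
        """All resolved values as one ``key=value`` line for logging."""
        return " ".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in fields(self)
        )


def _parse_value(name: str, raw: str):
    raw = raw.strip()
    if name in ("hrr_fractions", "avoid_band_m_s"):
        return tuple(float(x) for x in raw.replace(",", " ").split())
    if name == "speed_unit":
        return raw
    if name == "seed":
        return int(raw)
    return float(raw)


def load_config(path, **overrides) -> RunConfig:
    """Read a key=value config file; keyword overrides win over the file."""
    values = {}
    names = {f.name for f in fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in names:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(key, raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def resolve_config(config_path=None, **overrides) -> RunConfig:
    """RunConfig from optional file plus non-None keyword overrides."""
    if config_path is not None:
        return load_config(config_path, **overrides)
    return replace(RunConfig(), **{k: v for k, v in overrides.items() if v is not None})
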