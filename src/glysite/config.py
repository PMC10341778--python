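"""Flat key=value run configuration with documented defaults.

Unknown keys are rejected; every field has a default, so a config file only
needs to state what differs from it. ``parse_config(write_config(cfg))``
round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Malformed or unknown configuration."""


@dataclass
class RunConfig:
    # inputs / outputs
    fasta: str = ""                      # protein FASTA path
    peaklist_dir: str = ""               # directory of <digest>.tsv peak lists
    bli_input: str = ""                  # sensorgram CSV path
    out_dir: str = "glysite_results"
    # digestion
    proteases: str = "trypsin,chymotrypsin"  # comma-separated digest list
    max_missed: int = 2
    chymotrypsin_residues: str = "FWYL"
    # glycan composition search space
    hexnac_min: int = 2
    hexnac_max: int = 8
    hex_min: int = 3
    hex_max: int = 12
    fuc_min: int = 0
    fuc_max: int = 2
    neuac_min: int = 0
    neuac_max: int = 4
    neugc_min: int = 0
    neugc_max: int = 2
    use_default_constraint: bool = True
    # matching / quantification
    tol_ppm: float = 10.0
    combine: str = "pooled"              # pooled | per_digest
    # BLI fitting
    fit_offset: bool = True
    # randomness
    seed: int = 0

    def protease_list(self) -> list[str]:
        return [p.strip() for p in self.proteases.split(",") if p.strip()]

    def composition_bounds(self) -> dict[str, tuple[int, int]]:
        return {
            "hexnac": (self.hexnac_min, self.hexnac_max),
            "hex": (self.hex_min, self.hex_max),
            "fuc": (self.fuc_min, self.fuc_max),
            "neuac": (self.neuac_min, self.neuac_max),
            "neugc": (self.neugc_min, self.neugc_max),
        }


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _convert(name: str, raw: str):
    ftype = _FIELDS[name].type
    raw = raw.strip()
    if ftype in ("int", int):
        return int(raw)
    if ftype in ("float", float):
        return float(raw)
    if ftype in ("bool", bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"{name}: expected true/false, got {raw!r}")
    return raw


def parse_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` file; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    values = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELDS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _convert(key, raw)
    return RunConfig(**values)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# glysite run configuration\n")
        for f in dataclasses.fields(RunConfig):
            v = getattr(cfg, f.name)
            if isinstance(v, bool):
                v = "true" if v else "false"
            fh.write(f"{f.name} = {v}\n")
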