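"""Run configuration: the pipeline's tunable parameters with their defaults.

Defaults are the mining thresholds of the published protocol: profile-hit
e-value cutoff 0.01, candidate size band 30-500 aa, operon intergenic window
-20..30 bp.  A flat key=value config file mirrors the CLI flags; explicit CLI
flags override file values.  Every run echoes its effective configuration to
the log so the parameters are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    evalue_cutoff: float = 0.01
    min_aa: int = 30
    max_aa: int = 500
    gap_min: int = -20
    gap_max: int = 30
    same_strand: bool = True
    fold_up: float = 2.0
    fold_down: float = 0.5
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.min_aa > self.max_aa:
            raise ValueError("min_aa > max_aa")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min > gap_max")
        return self

    def as_log_lines(self) -> list[str]:
        return [f"# {f.name}={getattr(self, f.name)}" for f in fields(self)]


_BOOLS = {"true": True, "false": False, "1": True, "0": False,
          "yes": True, "no": False}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional key=value file plus overrides."""
    values: dict = {}
    if path is not None:
        types = {f.name: f.type for f in fields(RunConfig)}
        defaults = RunConfig()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    values[key] = _BOOLS[raw.lower()]
                elif isinstance(current, int):
                    values[key] = int(raw)
                else:
                    values[key] = float(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values).validate()
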