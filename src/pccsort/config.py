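"""Run configuration: CLI parameter bundle with YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import __version__

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of the simulate/sort/equilibrium pipeline.

    Round-trips losslessly through YAML; the version stamp travels with the
    config so outputs are attributable to a code version.
    """

    n_particles: int = 1000
    binding_prob: float | None = 0.8
    formula_weights: list[float] | None = None
    eps_fn: float = 0.0
    eps_fp: float = 0.0
    seed: int = 0
    pseudocount: float = 0.0
    out: str | None = None
    truth_out: str | None = None
    version: str = __version__

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def header_lines(self) -> list[str]:
        """Provenance comment lines echoed into every output file."""
        d = asdict(self)
        return [f"pccsort {d.pop('version')}"] + [
            f"{k} = {d[k]}" for k in sorted(d) if d[k] is not None
        ]
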