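"""Run configuration and output-directory provenance."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .network import ModelDefinition
from .simulate import RTOL_DEFAULT, ATOL_DEFAULT

__all__ = ["RunConfig", "write_provenance"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run bit-for-bit."""

    command: str
    dose: float | None = None
    doses: list[float] = field(default_factory=list)
    pre_duration_h: float = 300.0
    post_duration_h: float = 300.0
    parameter_overrides: dict = field(default_factory=dict)
    knockout_target: str | None = None
    feedback_gene: str | None = None
    seed: int = 0
    rtol: float = RTOL_DEFAULT
    atol: float = ATOL_DEFAULT
    outdir: str = "."

    def validate(self, model: ModelDefinition) -> None:
        for name in self.parameter_overrides:
            if name not in model.parameters:
                raise KeyError(f"unknown parameter override {name!r}")
        if self.dose is not None and self.dose < 0:
            raise ValueError("dose must be non-negative")


def write_provenance(config: RunConfig, model: ModelDefinition) -> Path:
    """Serialize config, parameter table and package version into outdir."""
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "abagrn_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "disabled_reactions": sorted(model.disabled_reactions),
    }
    (outdir / "config.json").write_text(json.dumps(payload, indent=2))
    (outdir / "parameters.txt").write_text(model.parameters.to_text())
    return outdir
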