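"""Pipeline configuration: one flat document with per-module sections.

Every tunable has its documented default; unknown keys are rejected so
typos fail loudly.  The effective configuration can be echoed to the
output directory for provenance, and a short hash of it is stamped into
output-file headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .motifs import DEFAULT_AT_HOOK_WINDOW, DEFAULT_PPC_SPAN, DEFAULT_PSEUDOCOUNT
from .simulate import SimulationConfig


@dataclass
class ScanConfig:
    at_hook_window: int = DEFAULT_AT_HOOK_WINDOW
    ppc_span: int = DEFAULT_PPC_SPAN
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class ReconcileConfig:
    outgroup: Optional[str] = None
    clade_label: str = ""


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    scan: ScanConfig = field(default_factory=ScanConfig)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    reconcile: ReconcileConfig = field(default_factory=ReconcileConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for section, section_cls in (
            ("scan", ScanConfig),
            ("simulate", SimulationConfig),
            ("reconcile", ReconcileConfig),
        ):
            payload = data.pop(section, {}) or {}
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(payload) - known
            if unknown:
                raise ValueError(
                    f"unknown {section} config keys: {sorted(unknown)}"
                )
            kwargs[section] = section_cls(**payload)
        for key in ("seed", "log_level"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def echo(self, path: Union[str, Path]) -> None:
        """Write the effective configuration for provenance."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.simulate, seed=seed)
        return dataclasses.replace(self, seed=seed, simulate=sim)
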