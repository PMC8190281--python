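"""Run configuration: one serializable object drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths / reproducibility
    out_dir: str = "ctrlnet_run"
    seed: int = 0
    # cohort generation
    n_controls: int = 80
    n_patients: int = 24
    n_nodes: int = 374
    n_modules: int = 8
    density: float = 0.25
    amp0: float = 1.0
    amp2: float = 3.0
    spread0: float = 0.10
    spread2: float = 0.40
    noise_sd: float = 0.10
    stability_d: float = 0.0
    energy_d: float = 0.0
    gene_slope_d1: float = 0.0
    gene_slope_d2: float = 0.0
    # dynamics / solver
    stabilization: str = "spectral"
    stabilization_c: float = 1.0
    horizon: float = 1.0
    rho: float = 1.0
    nsteps: int = 1001
    # suboptimal-trajectory analysis
    sigma: float = 0.05
    n_iter: int = 200
    n_repeat: int = 10
    # toggles
    compute_impact: bool = False
    impact_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.horizon <= 0 or self.rho <= 0:
            raise ValueError("horizon and rho must be positive")
        if self.nsteps < 2:
            raise ValueError("nsteps must be at least 2")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_iter < 1 or self.n_repeat < 1:
            raise ValueError("n_iter and n_repeat must be at least 1")
        if not 0.0 < self.impact_fraction <= 1.0:
            raise ValueError("impact_fraction must be in (0, 1]")
        if self.stabilization not in ("spectral", "scaled"):
            raise ValueError("stabilization must be 'spectral' or 'scaled'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Hash of the scientific parameters (out_dir excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
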