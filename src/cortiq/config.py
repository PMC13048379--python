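"""Pipeline configuration: a validated, YAML-serialisable schema.

One ``PipelineConfig`` drives every stage; each run writes the resolved
configuration next to its outputs so results are reproducible from the
file alone (plus the seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .btensor import ProtocolConfig
from .synthetic import EffectConfig, PhantomConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class FitConfig:
    constraints: str | None = "psd"  # "psd" or null
    n_reweight: int = 2

    def validate(self) -> None:
        if self.constraints not in (None, "psd"):
            raise ValueError("fit.constraints must be 'psd' or null")


@dataclass
class GridConfig:
    n_lines: int = 50
    n_depth: int = 10
    laplace_spacing: float | None = None  # default: half the voxel size

    def validate(self) -> None:
        if self.n_lines < 2 or self.n_depth < 1:
            raise ValueError("grid needs n_lines >= 2 and n_depth >= 1")


@dataclass
class StatsConfig:
    alpha_form: float = 0.01
    alpha_cluster: float = 0.05
    n_perm: int = 5000
    connectivity: int = 4

    def validate(self) -> None:
        if not 0 < self.alpha_form < 1 or not 0 < self.alpha_cluster < 1:
            raise ValueError("stats alphas must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("stats.connectivity must be 4 or 8")
        if self.n_perm < 1:
            raise ValueError("stats.n_perm must be positive")


@dataclass
class CohortConfig:
    n_control: int = 10
    n_treated: int = 10
    snr_b0: float = 30.0  # Rician sigma = S0 / snr_b0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_treated < 2:
            raise ValueError("cohort needs >= 2 subjects per group")
        if self.snr_b0 <= 0:
            raise ValueError("cohort.snr_b0 must be positive")


@dataclass
class HistoConfig:
    sigma_window_um: float = 15.0
    pixel_size_um: float = 1.0
    threshold_method: str = "otsu"

    def validate(self) -> None:
        if self.sigma_window_um <= self.pixel_size_um:
            raise ValueError("histo.sigma_window_um must exceed the pixel size")
        if self.threshold_method != "otsu":
            raise ValueError("histo.threshold_method must be 'otsu'")


@dataclass
class PipelineConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    effect: EffectConfig = field(default_factory=EffectConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    histo: HistoConfig = field(default_factory=HistoConfig)

    def validate(self) -> None:
        for name in ("cohort", "fit", "grid", "stats", "histo"):
            getattr(self, name).validate()
        # protocol/phantom/effect validate on use; cheap sanity here
        if len(self.protocol.shells) < 2:
            raise ValueError("protocol needs >= 2 b-value shells")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "protocol": ProtocolConfig,
    "phantom": PhantomConfig,
    "effect": EffectConfig,
    "cohort": CohortConfig,
    "fit": FitConfig,
    "grid": GridConfig,
    "stats": StatsConfig,
    "histo": HistoConfig,
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown sections or keys are schema violations (fail fast rather
    than silently ignoring typos).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    kwargs = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        cls = _SECTIONS[section]
        known = {f.name for f in fields(cls)}
        payload = payload or {}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        if "shells" in payload:
            payload["shells"] = tuple(payload["shells"])
        for tup_key in ("s_range", "d_range"):
            if tup_key in payload:
                payload[tup_key] = tuple(payload[tup_key])
        kwargs[section] = cls(**payload)
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
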