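"""Run configuration: assay constants, thresholds, and reproducibility seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline with their assay defaults."""

    ksv: float = 60.0                    # Stern-Volmer coefficient (1/M)
    tl_ext: float = 0.025                # extravesicular Tl+ (M)
    window: tuple[float, float] = (0.002, 1.0)   # fit window (s)
    temperature: float = 298.15          # K
    vlip_over_vaq: float = 3.6e-5
    normrate_edges: tuple[float, float] = (1.25, 1.5)
    cc20_edges: tuple[float, float] = (10.0, 50.0)   # µM
    alogp_threshold: float = 3.0
    psa_threshold: float = 75.0          # Å²
    qed_threshold: float = 0.5
    pscore_edges: tuple[float, float] = (100.0, 300.0)
    r2_flag_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ksv", "temperature", "vlip_over_vaq", "alogp_threshold",
                     "psa_threshold", "qed_threshold", "r2_flag_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.window
        if not 0 <= lo < hi:
            raise ValueError("fit window must satisfy 0 <= t_min < t_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window", "normrate_edges", "cc20_edges", "pscore_edges"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("window", "normrate_edges", "cc20_edges", "pscore_edges"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
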