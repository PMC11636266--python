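"""Run configuration: one structured file describing a full workflow run.

Every knob of the pipeline lives here with the standard defaults (channel
geometry, molecule budget, design grids, timing parameters, detection
policy), overridable from a YAML file.  The configuration hash is embedded
in every output artifact so results can be traced back to their settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .channel import ChannelConfig, WalkerConfig
from .circuit import CircuitParams
from .period_finder import DEFAULT_ALPHA_GRID, DEFAULT_T_SHIFT_GRID
from .signals import DEFAULT_BITS, ONE_SHOT_BITS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of a design-space exploration run."""

    channel_a: ChannelConfig = field(default_factory=ChannelConfig)
    channel_b: ChannelConfig = field(
        default_factory=lambda: ChannelConfig(diffusion_um2_per_s=870.0)
    )
    circuit: CircuitParams = field(default_factory=CircuitParams)
    walker: WalkerConfig = field(default_factory=WalkerConfig)

    total_molecules: float = 3_500_000.0
    bits: str = DEFAULT_BITS
    one_shot_bits: str = ONE_SHOT_BITS
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    t_shift_grid: tuple = DEFAULT_T_SHIFT_GRID
    t_s_default: float = 1500.0
    t_s_max: float = 2000.0
    sampling_interval_s: float = 40.0
    ratio_tolerance: float = 0.02
    lambda_policy: str | float = "midpoint"
    detection_statistic: str = "max"
    points_per_symbol: int = 200

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0 or len(self.t_shift_grid) == 0:
            raise ValueError("alpha_grid and t_shift_grid must be nonempty")
        for bits_name in ("bits", "one_shot_bits"):
            bits = getattr(self, bits_name)
            if not bits or set(bits) - {"0", "1"}:
                raise ValueError(f"{bits_name} must be a nonempty string over {{0,1}}")
            if not bits.startswith("00"):
                raise ValueError(f"{bits_name} must start with the 00 warm-up symbols")
        if not (isinstance(self.lambda_policy, (int, float)) or self.lambda_policy == "midpoint"):
            raise ValueError("lambda_policy must be 'midpoint' or a numeric threshold")
        if self.detection_statistic not in ("max", "end"):
            raise ValueError("detection_statistic must be 'max' or 'end'")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_grid"] = [float(a) for a in self.alpha_grid]
        d["t_shift_grid"] = [float(t) for t in self.t_shift_grid]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for key, sub_cls in (
            ("channel_a", ChannelConfig),
            ("channel_b", ChannelConfig),
            ("circuit", CircuitParams),
            ("walker", WalkerConfig),
        ):
            if key in data:
                sub = data.pop(key)
                kwargs[key] = sub_cls(**sub) if isinstance(sub, dict) else sub
        for key in ("alpha_grid", "t_shift_grid"):
            if key in data:
                data[key] = tuple(data.pop(key))
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs, **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        try:
            return cls.from_dict(data)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        """Short stable digest of the canonicalised configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def with_(self, **changes) -> "RunConfig":
        return replace(self, **changes)
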