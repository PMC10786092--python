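"""Simulation and pipeline configuration.

The simulation config is the package's "stated world": every default below is
either taken from the experimental procedure being emulated (shock scale,
epoch window, 2x2x2 design, peak latencies) or is a fixed, documented choice
(noise level, envelope width, trait-path coefficients).  See docs/methods.md
for the rationale behind each default.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError

#: The three stimulus dimensions, in canonical order.
DIMENSIONS = ("race", "pain", "gender")

#: Category labels per dimension: race Asian/White, expression Neutral/Pain,
#: gender Female/Male.
CATEGORIES = {"race": ("A", "W"), "pain": ("N", "P"), "gender": ("F", "M")}

#: Canonical ordering of the 8 conditions: lexicographic over
#: (race, pain, gender) with the category orders above.  All RDMs and
#: condition-mean arrays in this package follow this order.
CONDITIONS = tuple(
    (r, p, g)
    for r in CATEGORIES["race"]
    for p in CATEGORIES["pain"]
    for g in CATEGORIES["gender"]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EEG + behavior generator.

    Amplitudes are in microvolts, latencies in milliseconds, shocks in mA.
    ``trait_to_race_slope`` holds the trait -> race-representation paths
    (the a-paths of the mediation structure); ``mediation_paths`` holds the
    remaining b and c' paths on standardized scales.
    """

    n_channels: int = 30
    sampling_rate_hz: float = 100.0
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    trials_per_condition: int = 64
    dimension_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"race": 2.0, "pain": 1.0, "gender": 1.0}
    )
    dimension_peak_ms: Mapping[str, float] = field(
        default_factory=lambda: {"race": 140.0, "pain": 140.0, "gender": 300.0}
    )
    dimension_width_ms: float = 30.0
    noise_variance_uv2: float = 16.0
    noise_spatial_decay: float = 3.0
    trait_to_race_slope: Mapping[str, float] = field(
        default_factory=lambda: {"EG": 0.3, "RI": -0.3}
    )
    race_modulation_depth: float = 0.5
    trait_correlation: float = 0.3
    mediation_paths: Mapping[str, float] = field(
        default_factory=lambda: {"b": 0.3, "c_prime_EG": 0.1, "c_prime_RI": -0.1}
    )
    shock_scale: tuple[float, float, float, float] = (0.8, 3.4, 1.5, 2.8)
    behavior_noise_sd: float = 0.25
    low_anchor_noise_sd: float = 0.1
    items_per_factor: Mapping[str, int] = field(
        default_factory=lambda: {"EG": 5, "RI": 4}
    )
    item_loading: float = 0.8
    item_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        start, end = self.epoch_window_ms
        if not (start < 0.0 < end):
            raise ConfigError("epoch_window_ms must satisfy start < 0 < end")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        for d in DIMENSIONS:
            if d not in self.dimension_amplitudes:
                raise ConfigError(f"dimension_amplitudes missing '{d}'")
            if self.dimension_amplitudes[d] < 0:
                raise ConfigError(f"dimension_amplitudes['{d}'] must be >= 0")
            if d not in self.dimension_peak_ms:
                raise ConfigError(f"dimension_peak_ms missing '{d}'")
            if not (start <= self.dimension_peak_ms[d] <= end):
                raise ConfigError(
                    f"dimension_peak_ms['{d}'] must lie inside epoch_window_ms"
                )
        if self.dimension_width_ms <= 0:
            raise ConfigError("dimension_width_ms must be positive")
        if self.noise_variance_uv2 < 0:
            raise ConfigError("noise_variance_uv2 must be >= 0")
        if self.noise_spatial_decay <= 0:
            raise ConfigError("noise_spatial_decay must be positive")
        for t in ("EG", "RI"):
            if t not in self.trait_to_race_slope:
                raise ConfigError(f"trait_to_race_slope missing '{t}'")
        if not -1.0 < self.trait_correlation < 1.0:
            raise ConfigError("trait_correlation must be in (-1, 1)")
        if self._race_strength_residual_var() <= 0:
            raise ConfigError(
                "trait_to_race_slope too large: latent race strength cannot "
                "be standardized (residual variance <= 0)"
            )
        for k in ("b", "c_prime_EG", "c_prime_RI"):
            if k not in self.mediation_paths:
                raise ConfigError(f"mediation_paths missing '{k}'")
        lo, hi, low_anchor, high_anchor = self.shock_scale
        if not (lo < low_anchor < hi and lo < high_anchor < hi):
            raise ConfigError("shock_scale anchors must lie strictly between min and max")
        if lo >= hi:
            raise ConfigError("shock_scale min must be below max")
        if self.behavior_noise_sd < 0 or self.low_anchor_noise_sd < 0:
            raise ConfigError("behavior noise SDs must be >= 0")
        for t in ("EG", "RI"):
            if self.items_per_factor.get(t, 0) < 2:
                raise ConfigError(f"items_per_factor['{t}'] must be >= 2")

    def _race_strength_residual_var(self) -> float:
        """Residual variance making the latent race strength unit-variance."""
        g_eg = self.trait_to_race_slope["EG"]
        g_ri = self.trait_to_race_slope["RI"]
        rho = self.trait_correlation
        explained = g_eg**2 + g_ri**2 + 2.0 * g_eg * g_ri * rho
        return 1.0 - explained

    @property
    def times_ms(self):
        import numpy as np

        start, end = self.epoch_window_ms
        step = 1000.0 / self.sampling_rate_hz
        n = int(round((end - start) / step)) + 1
        return start + step * np.arange(n)

    @property
    def channel_ids(self) -> list[str]:
        return [f"ch{i + 1:02d}" for i in range(self.n_channels)]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dimension_amplitudes"] = dict(self.dimension_amplitudes)
        d["dimension_peak_ms"] = dict(self.dimension_peak_ms)
        d["trait_to_race_slope"] = dict(self.trait_to_race_slope)
        d["mediation_paths"] = dict(self.mediation_paths)
        d["items_per_factor"] = dict(self.items_per_factor)
        d["epoch_window_ms"] = list(self.epoch_window_ms)
        d["shock_scale"] = list(self.shock_scale)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("epoch_window_ms", "shock_scale"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
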