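"""Run-wide configuration.

Collects the handful of conventions that the analysis stages share: the
gravitational constant, the inner/outer radius proportionality for
hand-measured sections, the basket tare mass added to every nominal load,
how accelerometer drift is removed, which lever arm the cantilever model
uses, and the axial slicing interval for meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal

import yaml

#: Standard gravity, m s^-2.
GRAVITY = 9.81

#: Tare mass of the wire-supported load basket hung on each pole end, kg.
BASKET_MASS = 0.480

#: Default inner/outer radius proportionality for partial-tube sections.
DEFAULT_R_RATIO = 0.73

#: Observed range of the inner/outer radius ratio across poles.
R_RATIO_RANGE = (0.69, 0.78)


@dataclass
class AnalysisConfig:
    """Shared knobs for the pole-characterisation pipeline.

    Parameters
    ----------
    g : float
        Gravitational acceleration, m s^-2.
    r_ratio : float
        Inner radius as a fraction of the outer radius for hand-measured
        sections. Must lie in the observed range [0.69, 0.78].
    basket_mass : float
        Basket + wire tare added to each nominal per-end load, kg.
    detrend : {"linear", "none"}
        Drift-removal mode applied to the displacement obtained by double
        integration of acceleration.
    x_l_convention : {"half_length", "per_end"}
        Lever arm used when turning flexural rigidity into a spring
        constant: half the pole length, or an explicitly supplied
        per-end functional-centre distance.
    slice_interval : float
        Axial spacing of mesh cross-sections, mm.
    """

    g: float = GRAVITY
    r_ratio: float = DEFAULT_R_RATIO
    basket_mass: float = BASKET_MASS
    detrend: Literal["linear", "none"] = "linear"
    x_l_convention: Literal["half_length", "per_end"] = "half_length"
    slice_interval: float = 5.0
    node_window: tuple[float, float] = field(default=(0.40, 0.60))

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be positive")
        lo, hi = R_RATIO_RANGE
        if not (lo <= self.r_ratio <= hi):
            raise ValueError(f"r_ratio must lie in [{lo}, {hi}], got {self.r_ratio}")
        if self.basket_mass < 0:
            raise ValueError("basket_mass must be nonnegative")
        if self.detrend not in ("linear", "none"):
            raise ValueError(f"unknown detrend mode {self.detrend!r}")
        if self.x_l_convention not in ("half_length", "per_end"):
            raise ValueError(f"unknown x_L convention {self.x_l_convention!r}")
        if self.slice_interval <= 0:
            raise ValueError("slice_interval must be positive")
        a, b = self.node_window
        if not (0.0 <= a < b <= 1.0):
            raise ValueError("node_window must satisfy 0 <= lo < hi <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a YAML key-value file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "node_window" in raw:
            raw["node_window"] = tuple(raw["node_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["node_window"] = list(data["node_window"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
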