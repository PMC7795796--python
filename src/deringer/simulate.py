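"""Detector-defect (ring-artifact) simulation with known ground truth.

Two artifact classes are injected as fixed-pattern, full-column sinogram
deviations:

* **HRA** (high-level ring artifacts) — dead detector pixels saturated
  at the top of the dynamic range, and "hot" pixels carrying a large
  constant offset (10-60% of the sinogram maximum).
* **LRA** (low-level ring artifacts) — miscalibrated pixels with a small
  constant offset within +-1% of the sinogram maximum.

The default spec reproduces an extreme defect scenario: 25% of detector
columns affected, split 5% HRA / 20% LRA, with one fifth of the HRA
columns dead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RingSimulationSpec",
    "GroundTruthArtifacts",
    "simulate_ring_artifacts",
    "to_dynamic_range",
]


@dataclass
class RingSimulationSpec:
    """Parameters governing the simulated detector defects.

    Fractions refer to the detector width; deviation intervals are
    expressed as fractions of the maximum sinogram intensity.
    """

    frac_total: float = 0.25
    frac_hra: float = 0.05
    frac_lra: float = 0.20
    dead_fraction_of_hra: float = 0.2
    hra_deviation_interval: tuple[float, float] = (0.10, 0.60)
    lra_deviation_interval: tuple[float, float] = (-0.01, 0.01)
    dynamic_range_max: float = 2.0**16 - 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_total", "frac_hra", "frac_lra", "dead_fraction_of_hra"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isclose(self.frac_hra + self.frac_lra, self.frac_total):
            raise ValueError("frac_hra + frac_lra must equal frac_total")
        for name in ("hra_deviation_interval", "lra_deviation_interval"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be an ordered interval")
        if self.dynamic_range_max <= 0:
            raise ValueError("dynamic_range_max must be positive")

    def with_seed(self, seed: int) -> "RingSimulationSpec":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruthArtifacts:
    """Injected artifact layout: column indices, labels and offsets.

    ``hra_columns`` maps column index to ``"dead"`` or ``"hot"``;
    ``deviation_per_column`` stores the signed additive offset for hot
    and LRA columns (dead columns are saturated, not offset, and are
    recorded as NaN).
    """

    hra_columns: dict[int, str] = field(default_factory=dict)
    lra_columns: set[int] = field(default_factory=set)
    deviation_per_column: dict[int, float] = field(default_factory=dict)

    @property
    def hra_set(self) -> set[int]:
        return set(self.hra_columns)

    @property
    def dead_columns(self) -> set[int]:
        return {c for c, lab in self.hra_columns.items() if lab == "dead"}

    @property
    def hot_columns(self) -> set[int]:
        return {c for c, lab in self.hra_columns.items() if lab == "hot"}

    @property
    def all_columns(self) -> set[int]:
        return self.hra_set | self.lra_columns

    def to_dict(self) -> dict:
        return {
            "hra_columns": {str(c): lab for c, lab in sorted(self.hra_columns.items())},
            "lra_columns": sorted(self.lra_columns),
            "deviation_per_column": {
                str(c): (None if np.isnan(v) else float(v))
                for c, v in sorted(self.deviation_per_column.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthArtifacts":
        return cls(
            hra_columns={int(c): lab for c, lab in d["hra_columns"].items()},
            lra_columns=set(int(c) for c in d["lra_columns"]),
            deviation_per_column={
                int(c): (np.nan if v is None else float(v))
                for c, v in d["deviation_per_column"].items()
            },
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthArtifacts":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def to_dynamic_range(sino: np.ndarray, max_value: float = 2.0**16 - 1) -> np.ndarray:
    """Min-max stretch a sinogram to [0, max_value] (detector counts)."""
    sino = np.asarray(sino, dtype=float)
    lo, hi = sino.min(), sino.max()
    if hi == lo:
        raise ValueError("constant sinogram cannot be stretched to a dynamic range")
    return (sino - lo) / (hi - lo) * max_value


def simulate_ring_artifacts(
    sino: np.ndarray, spec: RingSimulationSpec
) -> tuple[np.ndarray, GroundTruthArtifacts]:
    """Inject simulated ring artifacts into a sinogram.

    Columns are drawn uniformly at random without replacement.  Dead
    columns are set to ``spec.dynamic_range_max`` in every row; hot HRA
    columns receive a per-column constant offset drawn from the HRA
    deviation interval (scaled by the sinogram maximum) with a random
    sign; LRA columns receive a per-column constant offset from the LRA
    interval.  All other columns are returned bit-identical.

    The RNG stream order is fixed (columns, then types via the already
    random column permutation, then offsets) so a seed fully determines
    the layout.
    """
    sino = np.asarray(sino, dtype=float)
    if not np.all(np.isfinite(sino)):
        raise ValueError("sinogram contains non-finite values")
    n_cols = sino.shape[1]
    out = sino.copy()
    truth = GroundTruthArtifacts()
    if spec.frac_total == 0:
        return out, truth

    n_hra = int(np.floor(spec.frac_hra * n_cols))
    n_lra = int(np.floor(spec.frac_lra * n_cols))
    if spec.frac_hra > 0 and n_hra < 1:
        raise ValueError("frac_hra yields < 1 column at this detector width")
    if spec.frac_lra > 0 and n_lra < 1:
        raise ValueError("frac_lra yields < 1 column at this detector width")
    if n_hra + n_lra < 1:
        raise ValueError("frac_total yields < 1 affected column")

    rng = np.random.default_rng(spec.seed)
    columns = rng.choice(n_cols, size=n_hra + n_lra, replace=False)
    hra_cols = columns[:n_hra]
    lra_cols = columns[n_hra:]
    # The permutation is already uniformly random, so taking its head as
    # the dead subset is an unbiased type assignment.
    n_dead = int(np.floor(n_hra * spec.dead_fraction_of_hra))
    dead_cols = hra_cols[:n_dead]
    hot_cols = hra_cols[n_dead:]

    smax = sino.max()
    lo, hi = spec.hra_deviation_interval
    hot_mags = rng.uniform(lo, hi, size=hot_cols.size) * smax
    hot_signs = rng.choice([-1.0, 1.0], size=hot_cols.size)
    lra_lo, lra_hi = spec.lra_deviation_interval
    lra_devs = rng.uniform(lra_lo, lra_hi, size=lra_cols.size) * smax

    out[:, dead_cols] = spec.dynamic_range_max
    out[:, hot_cols] += hot_signs * hot_mags
    out[:, lra_cols] += lra_devs

    for c in dead_cols:
        truth.hra_columns[int(c)] = "dead"
        truth.deviation_per_column[int(c)] = np.nan
    for c, s, m in zip(hot_cols, hot_signs, hot_mags):
        truth.hra_columns[int(c)] = "hot"
        truth.deviation_per_column[int(c)] = float(s * m)
    for c, d in zip(lra_cols, lra_devs):
        truth.lra_columns.add(int(c))
        truth.deviation_per_column[int(c)] = float(d)
    return out, truth
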