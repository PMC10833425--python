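"""Core containers and configuration for steered phase retrieval.

Conventions used throughout the package:

* All images live on an even ``m x m`` pixel grid.
* Diffraction patterns are zero-frequency centered: the DC pixel sits at
  ``(m/2, m/2)`` and the Friedel mate of pixel ``(r, c)`` is
  ``((m - r) % m, (m - c) % m)``.
* Support masks are plain boolean arrays of the same shape as the map they
  constrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DensityMap",
    "DiffractionPattern",
    "PhantomSpec",
    "PhasingConfig",
    "SteeringConfig",
    "as_values",
]


def as_values(obj) -> np.ndarray:
    """Return the pixel array of a :class:`DensityMap` or pass an array through."""
    if isinstance(obj, DensityMap):
        return obj.values
    return np.asarray(obj, dtype=float)


@dataclass
class DensityMap:
    """A real-valued 2D image of projected electron density.

    Parameters
    ----------
    values
        ``m x m`` array of densities (arbitrary electron-density units).
        Phantoms are non-negative; reconstruction states may carry negative
        excursions outside the support.
    pixel_size
        Optional physical edge length of one pixel, in nanometres.
    """

    values: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density map contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass
class DiffractionPattern:
    """An oversampled far-field amplitude pattern with a validity mask.

    ``amplitude`` holds |F| (photon-count-derived units) and ``valid`` marks
    pixels that carry usable data; beamstop, detector-gap and saturated
    pixels are ``False`` and are left unconstrained during phase retrieval.
    Zero frequency is at pixel ``(m/2, m/2)``.
    """

    amplitude: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be 2D")
        if self.amplitude.shape != self.valid.shape:
            raise ValueError(
                f"amplitude shape {self.amplitude.shape} does not match "
                f"valid-mask shape {self.valid.shape}"
            )
        if not self.valid.any():
            raise ValueError("pattern has no valid pixels")
        bad = self.amplitude[self.valid] < 0
        if bad.any():
            idx = np.argwhere(self.valid)[bad][0]
            raise ValueError(
                f"negative amplitude at valid pixel ({idx[0]}, {idx[1]})"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.amplitude.shape

    @property
    def intensity(self) -> np.ndarray:
        return self.amplitude**2


@dataclass
class PhantomSpec:
    """Parameters of a synthetic specimen.

    ``disk_aggregate`` emulates aggregates of electron-dense colloidal
    particles of a known diameter; ``ellipsoid`` emulates a low-contrast
    projected ellipsoid (e.g. a cell nucleus) with mild internal texture.
    """

    kind: str = "disk_aggregate"
    n_particles: int = 3
    diameter_px: int = 10
    axes_px: Tuple[int, int] = (17, 21)
    contrast: float = 1.0
    texture_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("disk_aggregate", "ellipsoid"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass
class PhasingConfig:
    """Schedule constants of a single phase-retrieval trial.

    Defaults follow the production protocol for colloidal-gold patterns:
    HIO feedback ``beta = 0.9``, 10000 cycles, shrink-wrap every 100 cycles
    with the blur width starting at 2 px and bottoming out at 0.9 px, and a
    support threshold of 4% of the blurred-map maximum.
    """

    beta: float = 0.9
    n_cycles: int = 10000
    sw_period: int = 100
    support_threshold_frac: float = 0.04
    zeta_init: float = 2.0
    zeta_low: float = 0.9
    zeta_decay: float = 0.99
    delta_os_threshold: float = 2.0
    autocorr_threshold_frac: float = 0.04

    def __post_init__(self):
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if not 0 < self.support_threshold_frac < 1:
            raise ValueError("support_threshold_frac must be in (0, 1)")
        if self.sw_period <= 0:
            raise ValueError("sw_period must be positive")


@dataclass
class SteeringConfig:
    """Constants of the ensemble steering schedule.

    The consensus weight ``w`` climbs a ladder from ``w0`` in steps of
    ``dw`` up to ``w_max``; map modification happens every ``mod_period``
    cycles after the trigger and stops after ``mod_stop_cycle``.
    """

    t_threshold: float = 0.2
    w0: float = 0.05
    dw: float = 0.05
    w_max: float = 0.50
    mod_period: int = 500
    mod_stop_cycle: int = 9000
    post_trigger_cycles: int = 100
    search_radius: int = 5
    terminate_patience: int = 3
    terminate_early: bool = False

    def __post_init__(self):
        if not 0 < self.w0 <= self.w_max <= 1:
            raise ValueError("need 0 < w0 <= w_max <= 1")
        if not 0 < self.t_threshold < 1:
            raise ValueError("t_threshold must be in (0, 1)")


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
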