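"""Single-trial iterative phase retrieval: HIO, shrink-wrap and OSS.

The engine iterates between reciprocal space (amplitudes replaced by the
measured ones wherever the detector recorded valid data, invalid pixels
left completely unconstrained) and real space (Fienup's hybrid input-output
feedback with support and non-negativity constraints).  The support is
re-estimated periodically by shrink-wrap: threshold a Gaussian-blurred
current map at a fixed fraction of its maximum.

Two shrink-wrap blur schedules are provided.  The *ordinary* schedule
decays the blur width geometrically from 2 px down to a floor of 0.9 px.
The *adaptive* schedule watches the oversampling ratio (grid area /
support area): while successive shrink-wrap updates still change the OS
ratio by more than 2 the blur stays wide (2 px) so that the ensemble keeps
exploring; once the support stabilizes the width drops to 0.9 px and
latches there for the rest of the run.  The latch event is what triggers
ensemble steering.

The OSS variant replaces the density outside the support by a low-pass
filtered copy (Gaussian frequency window of width eta shrinking from m to
1/m), which suppresses high-frequency noise in the unconstrained region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import DensityMap, DiffractionPattern, PhasingConfig, as_values

__all__ = [
    "initial_support_from_autocorrelation",
    "autocorrelation",
    "reciprocal_constraint",
    "hio_update",
    "gaussian_lowpass",
    "shrinkwrap_update",
    "zeta_schedule_ordinary",
    "zeta_adaptive",
    "os_ratio",
    "oss_update",
    "oss_eta_schedule",
    "fourier_residual",
    "Trial",
    "TrialHistory",
    "run_trial",
]


# -- Fourier conventions ----------------------------------------------------
# Patterns are stored zero-frequency centered.  fft_forward/fft_inverse map a
# real-space array to/from the centered reciprocal grid; they are exact
# inverses of each other.

def fft_forward(rho: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(rho))


def fft_inverse(G: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(G))


def autocorrelation(pattern: DiffractionPattern) -> np.ndarray:
    """Autocorrelation of the specimen from the measured intensities.

    Invalid pixels are treated as zero intensity for this step.  The result
    is centered (zero lag at ``(m/2, m/2)``) and real up to round-off.
    """
    I = np.where(pattern.valid, pattern.intensity, 0.0)
    ac = np.fft.ifft2(np.fft.ifftshift(I))
    return np.fft.fftshift(ac.real)


def initial_support_from_autocorrelation(
    pattern: DiffractionPattern, threshold_frac: float = 0.04
) -> np.ndarray:
    """Initial support: pixels where |autocorrelation| exceeds a fraction
    of its maximum (default 4%)."""
    ac = np.abs(autocorrelation(pattern))
    peak = ac.max()
    if peak <= 0:
        raise ValueError("all-zero pattern: autocorrelation support undefined")
    support = ac > threshold_frac * peak
    if not support.any():
        raise ValueError("autocorrelation threshold left an empty support")
    return support


def reciprocal_constraint(G: np.ndarray, pattern: DiffractionPattern) -> np.ndarray:
    """Replace |G| by the observed amplitude on valid pixels, keep phases.

    Invalid pixels (beamstop, gaps, saturation) float completely freely.
    Where a valid pixel has |G| = 0 the phase is undefined; the convention
    is phase 0, i.e. the output is the observed amplitude itself.
    """
    if G.shape != pattern.shape:
        raise ValueError("field and pattern shapes disagree")
    mod = np.abs(G)
    phase = np.where(mod > 0, G, 1.0) / np.where(mod > 0, mod, 1.0)
    out = np.where(pattern.valid, pattern.amplitude * phase, G)
    return out


def hio_update(
    rho_k: np.ndarray, rho_prime: np.ndarray, support: np.ndarray, beta: float
) -> np.ndarray:
    """Fienup HIO real-space update.

    Pixels satisfying the constraints (inside the support with non-negative
    density) take the Fourier-consistent value ``rho_prime``; everywhere
    else negative feedback ``rho_k - beta * rho_prime`` pushes the estimate
    toward constraint satisfaction.
    """
    good = support & (rho_prime >= 0)
    return np.where(good, rho_prime, rho_k - beta * rho_prime)


def gaussian_lowpass(dmap, zeta: float) -> np.ndarray:
    """Periodic convolution with a unit-mass Gaussian of std ``zeta`` px."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    return ndimage.gaussian_filter(as_values(dmap), sigma=zeta, mode="wrap")


def shrinkwrap_update(
    dmap, zeta: float, threshold_frac: float = 0.04
) -> np.ndarray:
    """Shrink-wrap support: threshold the blurred map at a fraction of its
    (blurred) maximum."""
    blurred = gaussian_lowpass(dmap, zeta)
    peak = blurred.max()
    if peak <= 0:
        raise ValueError("map maximum is not positive: support undefined")
    return blurred >= threshold_frac * peak


def zeta_schedule_ordinary(h: int, config: PhasingConfig) -> float:
    """Blur width for the h-th shrink-wrap update (h >= 1): geometric decay
    from ``zeta_init`` floored at ``zeta_low``."""
    if h < 1:
        raise ValueError("shrink-wrap update index starts at 1")
    return max(config.zeta_init * config.zeta_decay ** (h - 1), config.zeta_low)


def zeta_adaptive(
    zeta_latched: bool,
    os_ratio_prev: Optional[float],
    os_ratio_now: float,
    config: PhasingConfig,
) -> tuple[float, bool]:
    """OS-ratio-adaptive blur width with a one-way latch.

    Returns ``(zeta, latched)``.  While the support is still changing fast
    (|delta OS ratio| > 2, or no previous ratio yet) the width stays at
    ``zeta_init``; once the change drops below the threshold the width
    falls to ``zeta_low`` and stays there for the rest of the trial.
    Only a change strictly below the threshold switches: a change of
    exactly the threshold keeps the wide width.
    """
    if zeta_latched:
        return config.zeta_low, True
    if os_ratio_prev is None:
        return config.zeta_init, False
    if abs(os_ratio_now - os_ratio_prev) >= config.delta_os_threshold:
        return config.zeta_init, False
    return config.zeta_low, True


def os_ratio(support: np.ndarray) -> float:
    """Oversampling ratio: total grid area / support area (>= 1)."""
    n = int(np.count_nonzero(support))
    if n == 0:
        raise ValueError("empty support has no OS ratio")
    return support.size / n


def _freq_radius_sq(m: int) -> np.ndarray:
    rr, cc = np.indices((m, m))
    return (rr - m // 2) ** 2.0 + (cc - m // 2) ** 2.0


def oss_update(
    rho_k: np.ndarray,
    rho_prime: np.ndarray,
    support: np.ndarray,
    beta: float,
    eta: float,
) -> np.ndarray:
    """Oversampling-smoothness real-space update.

    Inside the support this is plain HIO; outside, the HIO output is
    replaced by its Gaussian low-pass filtered version (frequency-domain
    window ``exp(-k^2 / (2 eta^2))``), damping high-frequency density in
    the unconstrained region.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    H = hio_update(rho_k, rho_prime, support, beta)
    m = H.shape[0]
    W = np.exp(-_freq_radius_sq(m) / (2.0 * eta**2))
    smooth = fft_inverse(W * fft_forward(H)).real
    return np.where(support, H, smooth)


def oss_eta_schedule(cycle: int, total_cycles: int, m: int,
                     block: int = 1000) -> float:
    """Piecewise-constant filter width: ``total_cycles/block`` blocks with
    values linearly spaced from ``m`` (first block) to ``1/m`` (last)."""
    if total_cycles < block:
        raise ValueError(f"OSS schedule needs at least {block} cycles")
    n_blocks = total_cycles // block
    values = np.linspace(m, 1.0 / m, n_blocks)
    idx = min(cycle // block, n_blocks - 1)
    return float(values[idx])


def fourier_residual(rho: np.ndarray, pattern: DiffractionPattern) -> float:
    """Relative amplitude misfit on the valid pixels."""
    G = fft_forward(rho)
    v = pattern.valid
    num = np.sqrt(((np.abs(G)[v] - pattern.amplitude[v]) ** 2).sum())
    den = np.sqrt((pattern.amplitude[v] ** 2).sum())
    return float(num / den)


# -- trial driver -----------------------------------------------------------

@dataclass
class TrialHistory:
    """Outcome of one phase-retrieval trial."""

    final_map: np.ndarray
    final_support: np.ndarray
    snapshots: Dict[int, np.ndarray]
    cycle: int
    zeta: float
    zeta_latched: bool
    failed: bool
    seed: int
    residuals: Dict[int, float] = field(default_factory=dict)


class Trial:
    """Incremental single-trial engine, steppable from outside.

    The ensemble orchestrator advances many trials in lock-step between
    barrier points; this class therefore exposes ``run_cycles`` and
    ``sw_update`` separately instead of one opaque loop.  All randomness
    comes from the trial's own seeded generator, so a trial is bit
    reproducible given (pattern, config, mode, seed).
    """

    MODES = ("ordinary", "steered_local", "oss")

    def __init__(
        self,
        pattern: DiffractionPattern,
        config: PhasingConfig,
        mode: str = "ordinary",
        seed: int = 0,
        initial_support: Optional[np.ndarray] = None,
    ):
        if mode not in self.MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.pattern = pattern
        self.config = config
        self.mode = mode
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        if initial_support is None:
            if mode == "oss":
                raise ValueError("mode='oss' requires a starting support")
            initial_support = initial_support_from_autocorrelation(
                pattern, config.autocorr_threshold_frac
            )
        self.support = initial_support.astype(bool).copy()
        # random non-negative start inside the initial support
        rho = np.zeros(pattern.shape)
        rho[self.support] = self.rng.random(int(self.support.sum()))
        self.rho = rho
        # Fourier-consistent map of the latest cycle; shrink-wrap and all
        # reported maps are based on it (the raw HIO state carries
        # oscillating feedback residue that would bloat the support)
        self.rho_prime = rho.copy()
        self.cycle = 0
        self.sw_count = 0
        self.zeta = config.zeta_init
        self.zeta_latched = False
        self.os_ratio_prev: Optional[float] = None
        self.failed = False
        # unshifted copies for the inner loop (avoids per-cycle fftshifts)
        self._amp_u = np.fft.ifftshift(pattern.amplitude)
        self._valid_u = np.fft.ifftshift(pattern.valid)

    def _one_cycle(self) -> None:
        G = np.fft.fft2(self.rho)
        mod = np.abs(G)
        phase = np.where(mod > 0, G, 1.0) / np.where(mod > 0, mod, 1.0)
        Gp = np.where(self._valid_u, self._amp_u * phase, G)
        rho_prime = np.fft.ifft2(Gp).real
        self.rho_prime = rho_prime
        if self.mode == "oss":
            eta = oss_eta_schedule(self.cycle, self.config.n_cycles,
                                   self.rho.shape[0])
            self.rho = oss_update(self.rho, rho_prime, self.support,
                                  self.config.beta, eta)
        else:
            self.rho = hio_update(self.rho, rho_prime, self.support,
                                  self.config.beta)
        self.cycle += 1

    def run_cycles(self, n: int) -> None:
        if self.failed:
            self.cycle += n
            return
        for _ in range(n):
            self._one_cycle()

    def sw_update(self) -> None:
        """One shrink-wrap event under the trial's blur schedule.

        OSS trials keep their externally supplied support fixed.
        An empty or degenerate support marks the trial failed (recorded,
        not fatal to an ensemble).
        """
        if self.failed or self.mode == "oss":
            return
        self.sw_count += 1
        if self.mode == "ordinary":
            zeta = zeta_schedule_ordinary(self.sw_count, self.config)
        else:  # steered_local: adaptive rule on the pre-update support
            now = os_ratio(self.support)
            zeta, self.zeta_latched = zeta_adaptive(
                self.zeta_latched, self.os_ratio_prev, now, self.config
            )
            self.os_ratio_prev = now
        self.zeta = zeta
        # blur the Fourier-consistent reconstruction, not the raw HIO
        # state: the state's out-of-support feedback residue oscillates at
        # a noise-dependent level and never decays on noisy data, so a
        # support thresholded from it churns instead of shrinking onto
        # the particle
        basis = np.clip(self.rho_prime, 0.0, None)
        try:
            self.support = shrinkwrap_update(
                basis, zeta, self.config.support_threshold_frac
            )
        except ValueError:
            self.failed = True
            return
        if not self.support.any():
            self.failed = True

    def output_map(self) -> np.ndarray:
        """Current reconstruction as reported: the Fourier-consistent
        density inside the support, negatives clipped.

        The raw HIO state carries feedback residue outside the support
        (that is how the algorithm escapes local minima); the physically
        meaningful electron density is the non-negative part of the
        constrained map inside the support, and that is what scoring,
        steering and analysis see.
        """
        return np.where(self.support, np.clip(self.rho_prime, 0.0, None), 0.0)


def run_trial(
    pattern: DiffractionPattern,
    config: PhasingConfig,
    mode: str = "ordinary",
    seed: int = 0,
    snapshot_cycles: Sequence[int] = (),
    initial_support: Optional[np.ndarray] = None,
    track_residuals: bool = False,
) -> TrialHistory:
    """Run one full phase-retrieval trial.

    The cycle loop is: Fourier transform, reciprocal-space constraint,
    inverse transform, real-space update — with a shrink-wrap support
    update after every ``config.sw_period`` cycles (ordinary or adaptive
    blur schedule depending on ``mode``; OSS trials keep their given
    support).  Snapshots of the clipped density are recorded at the
    requested cycle numbers, and the run is deterministic given
    (pattern, config, mode, seed).
    """
    trial = Trial(pattern, config, mode, seed, initial_support)
    snapshots: Dict[int, np.ndarray] = {}
    residuals: Dict[int, float] = {}
    wanted = sorted(set(int(c) for c in snapshot_cycles))
    if 0 in wanted:
        snapshots[0] = trial.output_map()
    for stop in range(config.sw_period, config.n_cycles + 1, config.sw_period):
        start = trial.cycle
        marks = [c for c in wanted if start < c <= stop]
        for c in marks:
            trial.run_cycles(c - trial.cycle)
            snapshots[c] = trial.output_map()
            if track_residuals and not trial.failed:
                residuals[c] = fourier_residual(trial.rho, pattern)
        trial.run_cycles(stop - trial.cycle)
        if stop < config.n_cycles or config.n_cycles % config.sw_period == 0:
            trial.sw_update()
    # trailing cycles if n_cycles is not a multiple of sw_period
    if trial.cycle < config.n_cycles:
        for c in [c for c in wanted if trial.cycle < c <= config.n_cycles]:
            trial.run_cycles(c - trial.cycle)
            snapshots[c] = trial.output_map()
        trial.run_cycles(config.n_cycles - trial.cycle)
    return TrialHistory(
        final_map=trial.output_map(),
        final_support=trial.support.copy(),
        snapshots=snapshots,
        cycle=trial.cycle,
        zeta=trial.zeta,
        zeta_latched=trial.zeta_latched,
        failed=trial.failed,
        seed=seed,
        residuals=residuals,
    )
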