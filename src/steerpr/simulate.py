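"""Synthetic specimens, forward diffraction and pattern-quality metrics.

The simulator produces the kind of data a single-particle coherent
diffraction experiment delivers after detector merging: an oversampled
far-field amplitude pattern degraded by Poisson photon noise, a central
beamstop, detector-gap stripes and saturated pixels, together with a
validity mask marking the unusable regions.

Two phantom families are provided. ``disk_aggregate`` mimics aggregates of
electron-dense colloidal particles of known diameter — a high-contrast
benchmark whose reality is easy to judge. ``ellipsoid`` mimics a
low-contrast biological particle (a projected ellipsoid with weak internal
texture), the regime where phase retrieval struggles most.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import DensityMap, DiffractionPattern, PhantomSpec, as_values

__all__ = [
    "make_disk_aggregate",
    "make_ellipsoid_phantom",
    "make_phantom",
    "embed_map",
    "forward_diffract",
    "degrade_pattern",
    "centrosymmetry_score",
    "shell_snr",
]

_MAX_PLACEMENT_TRIES = 10_000


def _disk_mask(m: int, center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:m, :m]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_disk_aggregate(spec: PhantomSpec, field: int) -> DensityMap:
    """Rasterize an aggregate of equal-diameter disks on an ``m x m`` field.

    Disk centers are drawn on the integer grid inside a central window, by
    rejection sampling so that no two disks overlap (touching is allowed).
    Density is ``spec.contrast`` inside each disk (plus optional seeded
    texture) and exactly zero outside.
    """
    if spec.kind != "disk_aggregate":
        raise ValueError("spec.kind must be 'disk_aggregate'")
    if spec.n_particles < 1:
        raise ValueError("need at least one particle")
    m = int(field)
    d = int(spec.diameter_px)
    radius = d / 2.0
    # Central placement window: keeps the aggregate compact and away from
    # the field edge so every disk is fully inside the field.
    margin = int(np.ceil(radius)) + 1
    half = m // 4
    lo = max(margin, m // 2 - half)
    hi = min(m - margin, m // 2 + half)
    if hi <= lo:
        raise ValueError(f"field of size {m} too small for diameter {d} disks")

    rng = np.random.default_rng(spec.seed)
    centers: list[Tuple[int, int]] = []
    tries = 0
    while len(centers) < spec.n_particles:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise ValueError(
                f"could not place {spec.n_particles} non-overlapping disks of "
                f"diameter {d} in a {m}x{m} field"
            )
        tries += 1
        cand = (int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
        ok = all(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= d**2 for c in centers
        )
        if ok and cand not in centers:
            centers.append(cand)

    values = np.zeros((m, m))
    for c in centers:
        mask = _disk_mask(m, c, radius)
        disk = np.full(mask.sum(), spec.contrast)
        if spec.texture_sd > 0:
            disk = disk + spec.texture_sd * rng.standard_normal(disk.size)
        values[mask] += np.clip(disk, 0.0, None)
    return DensityMap(values)


def make_ellipsoid_phantom(
    spec: PhantomSpec, field: int, pixel_size: Optional[float] = None
) -> DensityMap:
    """Projected density of a homogeneous triaxial ellipsoid plus texture.

    The ellipsoid has full axes ``axes_px = (short, long)`` in the image
    plane; the axis along the projection direction equals the short axis.
    The projection of a homogeneous ellipsoid is its chord length, so the
    profile is ``contrast * 2c * sqrt(1 - x^2/a^2 - y^2/b^2)`` with
    ``a = c = short/2`` and ``b = long/2`` (short axis along rows).
    ``texture_sd`` adds seeded Gaussian density fluctuation (absolute
    units) inside the particle, clipped to keep the map non-negative.
    """
    if spec.kind != "ellipsoid":
        raise ValueError("spec.kind must be 'ellipsoid'")
    short, long_ = spec.axes_px
    if short <= 0 or long_ <= 0:
        raise ValueError("ellipsoid axes must be positive")
    m = int(field)
    if short > m or long_ > m:
        raise ValueError("ellipsoid does not fit inside the field")
    a = short / 2.0  # semi-axis along rows
    b = long_ / 2.0  # semi-axis along columns
    c = a  # projection-direction semi-axis
    rr, cc = np.ogrid[:m, :m]
    x = rr - m / 2.0
    y = cc - m / 2.0
    arg = 1.0 - (x / a) ** 2 - (y / b) ** 2
    values = spec.contrast * 2.0 * c * np.sqrt(np.clip(arg, 0.0, None))
    if spec.texture_sd > 0:
        rng = np.random.default_rng(spec.seed)
        inside = arg > 0
        noise = spec.texture_sd * rng.standard_normal((m, m))
        values = values + np.where(inside, noise, 0.0)
        values = np.clip(values, 0.0, None)
    return DensityMap(values, pixel_size=pixel_size)


def make_phantom(spec: PhantomSpec, field: int) -> DensityMap:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "disk_aggregate":
        return make_disk_aggregate(spec, field)
    return make_ellipsoid_phantom(spec, field)


def embed_map(dmap, pad_factor: int) -> DensityMap:
    """Embed an ``m x m`` map centered in a ``pad_factor*m`` field.

    This is the real-space grid on which reconstructions of the
    corresponding oversampled pattern live; use it to compare retrieved
    maps against the ground-truth phantom.
    """
    values = as_values(dmap)
    m = values.shape[0]
    L = int(pad_factor) * m
    out = np.zeros((L, L))
    off = (L - m) // 2
    out[off : off + m, off : off + m] = values
    return DensityMap(out)


def forward_diffract(dmap, pad_factor: int = 2) -> DiffractionPattern:
    """Noiseless oversampled amplitude of a real map.

    The map is zero-padded by ``pad_factor`` (the oversampling), discretely
    Fourier transformed and centered.  Amplitudes obey Friedel symmetry
    |F(S)| = |F(-S)| exactly for real input, and Parseval's identity holds
    as ``sum(intensity) / L**2 == sum(map**2)`` on the padded ``L x L``
    grid (numpy's unnormalized forward DFT convention).
    """
    if pad_factor < 2:
        raise ValueError("oversampling requires pad_factor >= 2")
    padded = embed_map(dmap, pad_factor).values
    F = np.fft.fftshift(np.fft.fft2(padded))
    amplitude = np.abs(F)
    return DiffractionPattern(amplitude, np.ones_like(amplitude, dtype=bool))


def degrade_pattern(
    pattern: DiffractionPattern,
    photon_budget: float,
    beamstop_radius_px: int = 0,
    gap_rows: Sequence[int] = (),
    saturation_level: float = np.inf,
    seed: int = 0,
) -> DiffractionPattern:
    """Apply Poisson photon statistics and detector pathologies.

    Intensities are scaled so the expected total photon count over the full
    detector equals ``photon_budget``, then Poisson-sampled per pixel; the
    recorded amplitude is ``sqrt(counts)``.  Pixels inside the central
    beamstop disk, in the listed gap rows, or whose counts reach
    ``saturation_level`` are marked invalid (saturation is invalidation,
    not clipping: saturated regions are discarded from the constraint).
    """
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    I = pattern.intensity
    total = I.sum()
    if total <= 0:
        raise ValueError("input pattern carries no intensity")
    scale = photon_budget / total
    rng = np.random.default_rng(seed)
    counts = rng.poisson(scale * I).astype(float)
    amplitude = np.sqrt(counts)

    m = pattern.shape[0]
    valid = pattern.valid.copy()
    if beamstop_radius_px > 0:
        valid &= ~_disk_mask(m, (m // 2, m // 2), beamstop_radius_px)
    for row in gap_rows:
        valid[int(row), :] = False
    valid &= counts < saturation_level
    if not valid.any():
        raise ValueError("beamstop/gaps/saturation removed every pixel")
    return DiffractionPattern(amplitude, valid)


def _mate(arr: np.ndarray) -> np.ndarray:
    """Centrosymmetric mate: pixel (r, c) -> ((m-r) % m, (m-c) % m)."""
    return np.roll(arr[::-1, ::-1], shift=(1, 1), axis=(0, 1))


def centrosymmetry_score(pattern: DiffractionPattern) -> float:
    """Centrosymmetry metric C_sym of a diffraction pattern.

    Pearson-style normalized cross-correlation between the intensity
    ``I(S)`` and its point-reflected mate ``I(-S)`` over pixels where both
    mates are valid.  Exactly centrosymmetric intensities (e.g. any
    noiseless pattern of a real specimen, by Friedel symmetry) score 1;
    asymmetric degradation lowers the score.
    """
    I = pattern.intensity
    both = pattern.valid & _mate(pattern.valid)
    if both.sum() < 2:
        raise ValueError("no valid centrosymmetric pixel pairs")
    x = I[both]
    y = _mate(I)[both]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("centrosymmetry score undefined for constant intensity")
    return float((xc * yc).sum() / denom)


def shell_snr(pattern: DiffractionPattern, snr_threshold: float = 2.0,
              min_pixels: int = 200) -> Tuple[pd.DataFrame, Optional[int]]:
    """Per-shell Poisson signal-to-noise table and the max-resolution shell.

    Shells are integer-radius annuli about the pattern center; the
    per-pixel SNR of a Poisson count ``n`` is ``n / sqrt(n) = sqrt(n)``.
    The max-resolution shell is the outermost shell in which more than
    ``min_pixels`` valid pixels exceed ``snr_threshold`` — the selection
    rule used to grade experimental patterns.  All-invalid shells are
    simply absent from the table.

    Returns
    -------
    table : pandas.DataFrame
        Columns ``shell``, ``n_valid``, ``n_above``, ``mean_snr``.
    max_shell : int or None
        Outermost qualifying shell radius, or None if no shell qualifies.
    """
    m = pattern.shape[0]
    rr, cc = np.indices(pattern.shape)
    radius = np.rint(
        np.hypot(rr - m // 2, cc - m // 2)
    ).astype(int)
    counts = pattern.intensity
    snr = np.sqrt(np.clip(counts, 0.0, None))
    rows = []
    for shell in range(radius.max() + 1):
        sel = (radius == shell) & pattern.valid
        n_valid = int(sel.sum())
        if n_valid == 0:
            continue
        above = int((snr[sel] > snr_threshold).sum())
        rows.append(
            {
                "shell": shell,
                "n_valid": n_valid,
                "n_above": above,
                "mean_snr": float(snr[sel].mean()),
            }
        )
    table = pd.DataFrame(rows, columns=["shell", "n_valid", "n_above", "mean_snr"])
    qualifying = table[table["n_above"] > min_pixels]["shell"]
    max_shell = int(qualifying.max()) if len(qualifying) else None
    return table, max_shell
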