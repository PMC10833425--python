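"""Map alignment, similarity scoring and the consensus modification.

Retrieved maps from independent trials differ by arbitrary translations
and by the pi-rotation ambiguity (a map and its point reflection have
identical diffraction amplitudes), so every comparison first aligns the
maps: coarse center-of-gravity shift, then an exhaustive integer-pixel
search over a small window for both the map and its point reflection.
Sub-pixel registration is deliberately avoided so that scores are exactly
reproducible.

The similarity score between two non-negative maps is the normalized L1
difference

    T_ij = sum |rho_i - rho_j| / sum (rho_i + rho_j)

which is 0 for identical maps, 1 for maps with disjoint supports, and
empirically below 0.2 for pairs that both approximate the true specimen.

Steering builds a consensus map as the *unweighted* mean of all
reference-aligned maps scoring below the threshold against the reference
(similarity-weighted averaging such as (1 - T_ij) is deliberately not
used), and blends it into every trial with a weight w that climbs from
0.05 to 0.50 across modification stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import as_values

__all__ = [
    "AlignmentTransform",
    "PairScores",
    "center_of_gravity",
    "pi_rotate",
    "similarity_score",
    "align_to",
    "apply_transform",
    "invert_transform",
    "pairwise_scores",
    "select_reference",
    "build_steering_map",
    "modify_map",
    "w_schedule",
]


@dataclass(frozen=True)
class AlignmentTransform:
    """Integer cyclic shift (dy, dx) plus optional point reflection.

    Applied as: reflect first (if ``pi_rotated``), then roll by ``shift``.
    """

    shift: Tuple[int, int] = (0, 0)
    pi_rotated: bool = False


def pi_rotate(values: np.ndarray) -> np.ndarray:
    """Point reflection through the grid center: index i -> (m - i) % m."""
    return np.roll(values[::-1, ::-1], shift=(1, 1), axis=(0, 1))


def apply_transform(dmap, t: AlignmentTransform) -> np.ndarray:
    values = as_values(dmap)
    if t.pi_rotated:
        values = pi_rotate(values)
    return np.roll(values, t.shift, axis=(0, 1))


def invert_transform(dmap, t: AlignmentTransform) -> np.ndarray:
    """Undo :func:`apply_transform` (reflection is an involution)."""
    values = np.roll(as_values(dmap), (-t.shift[0], -t.shift[1]), axis=(0, 1))
    if t.pi_rotated:
        values = pi_rotate(values)
    return values


def center_of_gravity(dmap) -> Tuple[float, float]:
    """Intensity-weighted centroid (negatives clipped for the weights)."""
    values = np.clip(as_values(dmap), 0.0, None)
    total = values.sum()
    if total <= 0:
        raise ValueError("zero-mass map has no center of gravity")
    rr, cc = np.indices(values.shape)
    return (
        float((rr * values).sum() / total),
        float((cc * values).sum() / total),
    )


def similarity_score(rho_i, rho_j) -> float:
    """Normalized L1 dissimilarity of two non-negative maps (no alignment).

    Negative excursions are clipped before scoring; 0 means identical,
    1 means disjoint supports.
    """
    a = np.clip(as_values(rho_i), 0.0, None)
    b = np.clip(as_values(rho_j), 0.0, None)
    if a.shape != b.shape:
        raise ValueError("maps must share one grid")
    denom = (a + b).sum()
    if denom <= 0:
        raise ValueError("similarity undefined for two zero maps")
    return float(np.abs(a - b).sum() / denom)


def _cog_shift(moving: np.ndarray, reference: np.ndarray) -> Tuple[int, int]:
    cr, cc = center_of_gravity(reference)
    mr, mc = center_of_gravity(moving)
    return (int(round(cr - mr)), int(round(cc - mc)))


def align_to(
    dmap,
    reference,
    search_radius: int = 5,
) -> Tuple[np.ndarray, AlignmentTransform, float]:
    """Optimally align a map to a reference map.

    Coarse center-of-gravity shift, then exhaustive integer-shift search
    within ``+-search_radius`` for both the map and its point reflection;
    the candidate minimizing the similarity score wins.  Ties are broken
    by smaller total shift magnitude, then by the un-rotated orientation.

    Returns ``(aligned_values, transform, score)``.
    """
    ref = np.clip(as_values(reference), 0.0, None)
    moving = np.clip(as_values(dmap), 0.0, None)
    best: Optional[Tuple[float, int, int, np.ndarray, AlignmentTransform]] = None
    for rotated in (False, True):
        cand = pi_rotate(moving) if rotated else moving
        base = _cog_shift(cand, ref)
        for dy in range(-search_radius, search_radius + 1):
            for dx in range(-search_radius, search_radius + 1):
                shift = (base[0] + dy, base[1] + dx)
                shifted = np.roll(cand, shift, axis=(0, 1))
                T = similarity_score(shifted, ref)
                mag = shift[0] ** 2 + shift[1] ** 2
                key = (T, mag, int(rotated))
                if best is None or key < best[0]:
                    best = (key, shift, rotated, shifted)
    key, shift, rotated, shifted = best
    t = AlignmentTransform(shift=tuple(shift), pi_rotated=bool(rotated))
    return shifted, t, key[0]


@dataclass
class PairScores:
    """All-pairs similarity scores of an ensemble of maps.

    ``T`` is symmetric with a zero diagonal.  After reference selection,
    ``reference_index`` names the lower-index member of the minimal pair,
    ``scores_vs_reference`` holds the re-aligned scores of every map
    against it, and ``transforms`` the per-map alignment into the
    reference frame (identity for the reference itself).
    """

    T: np.ndarray
    reference_index: Optional[int] = None
    scores_vs_reference: Optional[np.ndarray] = None
    transforms: Optional[List[AlignmentTransform]] = None


def pairwise_scores(maps: Sequence) -> PairScores:
    """Similarity scores for all pairs after center-of-gravity alignment
    (taking the better of the two pi-rotation orientations)."""
    arrays = [np.clip(as_values(m), 0.0, None) for m in maps]
    n = len(arrays)
    if n < 2:
        raise ValueError("need at least two maps")
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ref = arrays[i]
            scores = []
            for rotated in (False, True):
                cand = pi_rotate(arrays[j]) if rotated else arrays[j]
                shift = _cog_shift(cand, ref)
                scores.append(
                    similarity_score(np.roll(cand, shift, axis=(0, 1)), ref)
                )
            T[i, j] = T[j, i] = min(scores)
    return PairScores(T=T)


def select_reference(
    scores: PairScores, maps: Sequence, search_radius: int = 5
) -> PairScores:
    """Pick the reference map and re-align everything to it.

    The pair with the smallest score is found; its lower-index member
    becomes the reference.  All other maps are then optimally re-aligned
    to the reference (translation + pi-rotation) and their scores
    recomputed.
    """
    T = scores.T
    n = T.shape[0]
    iu = np.triu_indices(n, k=1)
    k = int(np.argmin(T[iu]))
    i, j = int(iu[0][k]), int(iu[1][k])
    ref_idx = min(i, j)
    ref = np.clip(as_values(maps[ref_idx]), 0.0, None)
    svr = np.zeros(n)
    transforms: List[AlignmentTransform] = []
    for q in range(n):
        if q == ref_idx:
            transforms.append(AlignmentTransform())
            continue
        _, t, score = align_to(maps[q], ref, search_radius)
        svr[q] = score
        transforms.append(t)
    return PairScores(
        T=T,
        reference_index=ref_idx,
        scores_vs_reference=svr,
        transforms=transforms,
    )


def build_steering_map(
    maps: Sequence,
    scores: PairScores,
    t_threshold: float = 0.2,
) -> np.ndarray:
    """Consensus map: unweighted mean of the reference-aligned maps whose
    score against the reference is below the threshold.

    The reference itself (score 0) always contributes, so the consensus is
    never empty.  The output is rescaled to the mean total mass of the
    contributing maps.
    """
    if scores.reference_index is None:
        raise ValueError("select_reference must run before steering")
    aligned = []
    for q, m in enumerate(maps):
        if scores.scores_vs_reference[q] < t_threshold:
            a = np.clip(apply_transform(m, scores.transforms[q]), 0.0, None)
            aligned.append(a)
    stack = np.stack(aligned)
    rho_bar = stack.mean(axis=0)
    target_mass = stack.sum(axis=(1, 2)).mean()
    mass = rho_bar.sum()
    if mass > 0:
        rho_bar = rho_bar * (target_mass / mass)
    return rho_bar


def modify_map(rho, rho_bar, w: float) -> np.ndarray:
    """Convex blend of a trial map with the consensus map.

    Both maps must already be in the reference frame; the caller maps the
    result back to the trial's own frame.  The blend is affine in w:
    ``(1 - w) * rho + w * rho_bar``.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    return (1.0 - w) * as_values(rho) + w * as_values(rho_bar)


def w_schedule(stage: int, w0: float = 0.05, dw: float = 0.05,
               w_max: float = 0.50) -> float:
    """Consensus weight at a modification stage (stage >= 1): w0, w0+dw,
    ... clamped at w_max."""
    if stage < 1:
        raise ValueError("modification stages start at 1")
    return min(w0 + dw * (stage - 1), w_max)
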