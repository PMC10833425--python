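"""Post-hoc ensemble analytics: PCA plane, trajectories, clustering.

A retrieved map of J pixels is a point in a J-dimensional image space.
The ensemble's final maps, once mutually aligned (translation +
pi-rotation), define a PCA plane spanned by the first two principal
components; projecting every trial's snapshot trajectory onto that plane
shows how reconstructions wander between basins, and a 2D visit-frequency
histogram shows where they dwell.  K-means over the final-map projections
counts the distinct basins.  In synthetic mode, where the ground-truth
phantom is known, the fraction of final maps scoring below the similarity
threshold against the truth replaces manual inspection of which basin is
the realistic one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datatypes import as_values
from .steering import align_to, similarity_score

__all__ = [
    "AlignedStack",
    "PCAPlane",
    "stack_aligned_finals",
    "pca_plane",
    "project_trajectories",
    "visit_frequency_map",
    "kmeans_regions",
    "realistic_fraction",
]


@dataclass
class AlignedStack:
    """Aligned, flattened, mean-centered final maps.

    ``data`` has one row per retained map; ``mean`` is the subtracted mean
    row; ``reference`` is the (clipped) first map, the common alignment
    frame for later snapshot projection; ``retained`` lists the indices of
    the maps that survived (degenerate zero-mass maps are dropped).
    """

    data: np.ndarray
    mean: np.ndarray
    reference: np.ndarray
    retained: List[int]
    shape: Tuple[int, int]


@dataclass
class PCAPlane:
    """Top-2 principal components over map pixels (orthonormal rows)."""

    components: np.ndarray  # (2, J)
    explained_variance: np.ndarray  # (2,)


def stack_aligned_finals(maps: Sequence, search_radius: int = 5) -> AlignedStack:
    """Align all final maps to the first one and build the data matrix."""
    if len(maps) < 3:
        raise ValueError("need at least three maps for a PCA plane")
    reference = np.clip(as_values(maps[0]), 0.0, None)
    if reference.sum() <= 0:
        raise ValueError("first map is degenerate; cannot define a frame")
    rows = [reference.ravel()]
    retained = [0]
    for i, m in enumerate(maps[1:], start=1):
        values = np.clip(as_values(m), 0.0, None)
        if values.sum() <= 0:
            warnings.warn(f"dropping degenerate map {i} from the stack")
            continue
        aligned, _, _ = align_to(values, reference, search_radius)
        rows.append(aligned.ravel())
        retained.append(i)
    data = np.stack(rows)
    mean = data.mean(axis=0)
    return AlignedStack(
        data=data - mean,
        mean=mean,
        reference=reference,
        retained=retained,
        shape=reference.shape,
    )


def pca_plane(stack: AlignedStack) -> PCAPlane:
    """First two principal components of the aligned final maps.

    Deterministic sign convention: within each component the coordinate of
    largest magnitude is made positive (scikit-learn's ``svd_flip``).
    """
    if stack.data.shape[0] < 3:
        raise ValueError("need at least three rows")
    if not np.any(stack.data):
        raise ValueError("zero variance: no plane is defined")
    n_comp = min(2, stack.data.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(stack.data)
    components = pca.components_
    variance = pca.explained_variance_
    if n_comp < 2:
        # degenerate 1-D cloud: pad an arbitrary orthonormal second axis
        components = np.vstack([components, np.zeros_like(components[0])])
        variance = np.append(variance, 0.0)
    return PCAPlane(components=components, explained_variance=variance)


def project_trajectories(
    snapshots: Sequence, plane: PCAPlane, stack: AlignedStack,
    align: bool = True, search_radius: int = 5,
) -> np.ndarray:
    """Project maps (e.g. one trial's snapshot trajectory) onto the plane.

    Each map is aligned to the stack's reference frame (unless ``align``
    is False, for maps already in that frame), mean-centered with the
    stack's mean row, and dotted with the two components.  Maps from a
    steered run may be projected onto an ordinary run's plane to compare
    trajectories in one coordinate system.
    """
    coords = np.zeros((len(snapshots), 2))
    for k, m in enumerate(snapshots):
        values = np.clip(as_values(m), 0.0, None)
        if values.shape != stack.shape:
            raise ValueError("snapshot shape does not match the plane's grid")
        if align and values.sum() > 0:
            values, _, _ = align_to(values, stack.reference, search_radius)
        row = values.ravel() - stack.mean
        coords[k] = plane.components @ row
    return coords


def visit_frequency_map(
    coordinates: np.ndarray, grid_size: int = 128,
    extent: Optional[Tuple[float, float, float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D visit-count histogram over the bounding box of the coordinates."""
    coordinates = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coordinates.size == 0:
        raise ValueError("need at least one coordinate")
    if extent is None:
        x0, x1 = coordinates[:, 0].min(), coordinates[:, 0].max()
        y0, y1 = coordinates[:, 1].min(), coordinates[:, 1].max()
    else:
        x0, x1, y0, y1 = extent
    # degenerate (single-point) boxes get a token width so the histogram
    # still counts every snapshot
    if x1 <= x0:
        x0, x1 = x0 - 0.5, x0 + 0.5
    if y1 <= y0:
        y0, y1 = y0 - 0.5, y0 + 0.5
    grid, xe, ye = np.histogram2d(
        coordinates[:, 0], coordinates[:, 1], bins=grid_size,
        range=[[x0, x1], [y0, y1]],
    )
    return grid, xe, ye


def kmeans_regions(
    projections: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded K-means over final-map projections.

    Returns (labels, cluster sizes); deterministic for a fixed seed.
    """
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > projections.shape[0]:
        raise ValueError("more clusters than points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(projections)
    sizes = np.bincount(labels, minlength=k)
    return labels, sizes


def realistic_fraction(
    final_maps: Sequence,
    ground_truth,
    t_threshold: float = 0.2,
    search_radius: int = 5,
    normalize: bool = True,
) -> float:
    """Fraction of final maps that approximate the known phantom.

    A map counts as realistic when its similarity score against the
    ground truth, after optimal alignment, is below the threshold — the
    synthetic-mode surrogate for manual inspection.  Monotone
    non-decreasing in ``t_threshold``.

    Reconstructions carry an arbitrary global scale (the photon-count
    units of the measured amplitudes), so by default both map and truth
    are normalized to unit total mass before scoring; disable only when
    the maps share the phantom's density units.
    """
    if ground_truth is None:
        raise ValueError("realistic_fraction needs a ground-truth map")
    truth = np.clip(as_values(ground_truth), 0.0, None)
    if truth.sum() <= 0:
        raise ValueError("ground truth has no mass")
    if len(final_maps) == 0:
        raise ValueError("no final maps")
    if normalize:
        truth = truth / truth.sum()
    hits = 0
    for m in final_maps:
        values = np.clip(as_values(m), 0.0, None)
        if values.sum() <= 0:
            continue
        if normalize:
            values = values / values.sum()
        _, _, score = align_to(values, truth, search_radius)
        if score < t_threshold:
            hits += 1
    return hits / len(final_maps)
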