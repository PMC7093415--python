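"""Three-component phasor unmixing via variance-scaled center augmentation.

The algorithm attributes each pixel's phasor to one endogenous and two
exogenous reference clusters in three steps:

1. *Role assignment.*  Among the three cluster centers the one with the
   largest S is "topmost"; of the remaining two, the smaller G is "leftmost"
   and the larger G "rightmost".

2. *Center augmentation.*  Each center is pushed outward along its role axis
   by 25% of its cluster's fraction of the total scalar variance:

       y_new = y_orig * (1 + 0.25 * var_frac)        (topmost, S axis)
       x_new = x_orig * (1 - 0.25 * var_frac)        (leftmost, G axis)
       x_new = x_orig * (1 + 0.25 * var_frac)        (rightmost, G axis)

   This expands the triangle spanned by the centers and down-weights
   high-variance clusters (typically the broad autofluorescence cloud) in
   the subsequent distance-based attribution.

3. *Inverse-distance contributions.*  For a phasor point P, the Euclidean
   distances D_i to the augmented centers define contributions C_i = 1/D_i,
   normalized by C_tot = sum_i C_i.  A point coinciding with a center
   (D < 1e-12) is attributed entirely to that component.

Contribution maps are rendered to RGB by scaling each component's display
color by its normalized contribution; the conventional legend is yellow for
autofluorescence, cyan for tazarotene and magenta for minocycline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flim_io import PhasorImage
from .reference_clusters import ReferenceCluster

__all__ = [
    "AugmentedCenters",
    "ContributionMap",
    "assign_roles",
    "augment_centers",
    "contributions",
    "contribution_image",
    "colorize",
    "phasor_colormap",
]

logger = logging.getLogger(__name__)

AUGMENTATION_GAIN = 0.25
_COINCIDENCE = 1e-12

# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def assign_roles(centers: Sequence[Sequence[float]]) -> dict[int, str]:
    """Map each of three cluster centers to its geometric role.

    Topmost is the center with the largest S (ties broken by smaller G, then
    input order, and logged); of the remaining two, leftmost has the smaller
    G (tie broken by input order).
    """
    c = np.asarray(centers, dtype=float)
    if c.shape != (3, 2):
        raise ValueError("exactly three (g, s) centers required")
    if len({tuple(row) for row in c.tolist()}) != 3:
        raise ValueError("centers must be distinct")
    s = c[:, 1]
    top_candidates = np.flatnonzero(s == s.max())
    if len(top_candidates) > 1:
        logger.warning(
            "topmost tie between centers %s; breaking by smaller g", top_candidates
        )
        top = int(top_candidates[np.argmin(c[top_candidates, 0])])
    else:
        top = int(top_candidates[0])
    rest = [i for i in range(3) if i != top]
    if c[rest[0], 0] == c[rest[1], 0]:
        logger.warning("left/right tie between centers %s; keeping input order", rest)
        left, right = rest
    elif c[rest[0], 0] < c[rest[1], 0]:
        left, right = rest
    else:
        right, left = rest
    return {top: "topmost", left: "leftmost", right: "rightmost"}


# ---------------------------------------------------------------------------
# Center augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentedCenters:
    """Original and variance-augmented cluster centers with roles and colors."""

    original_centers: np.ndarray
    variance_fractions: np.ndarray
    augmented_centers: np.ndarray
    roles: dict[int, str]
    colors: tuple[tuple[int, int, int], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.original_centers = np.asarray(self.original_centers, dtype=float)
        self.augmented_centers = np.asarray(self.augmented_centers, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if self.original_centers.shape != (3, 2) or self.augmented_centers.shape != (3, 2):
            raise ValueError("exactly three (g, s) centers required")
        total = self.variance_fractions.sum()
        if not (abs(total - 1.0) < 1e-9 or total == 0.0):
            raise ValueError("variance fractions must sum to 1 (or all be 0)")

    @classmethod
    def from_points(
        cls,
        centers: Sequence[Sequence[float]],
        labels: Sequence[str],
        colors: Sequence[tuple[int, int, int]],
    ) -> "AugmentedCenters":
        """Wrap bare points that are already variance-adjusted centers.

        Used when the three anchor points carry no cluster scatter of their
        own (zero variance), e.g. the synthetic benchmark, where the chosen
        simulation centers *are* the variance-adjusted centers; augmentation
        is then the identity.
        """
        c = np.asarray(centers, dtype=float)
        return cls(
            original_centers=c,
            variance_fractions=np.zeros(3),
            augmented_centers=c.copy(),
            roles=assign_roles(c),
            colors=tuple(tuple(int(v) for v in col) for col in colors),
            labels=tuple(labels),
        )


def augment_centers(clusters: Sequence[ReferenceCluster]) -> AugmentedCenters:
    """Expand three cluster centers outward by variance-scaled shifts.

    Each cluster's scalar variance is normalized into a fraction of the total
    variance; the topmost center's S, the leftmost center's G and the
    rightmost center's G are then scaled by ``(1 +/- 0.25 * fraction)``.
    When the total variance is zero the centers are returned unmodified with
    a warning (the augmentation is a no-op on scatter-free references).
    """
    if len(clusters) != 3:
        raise ValueError("exactly three reference clusters required")
    centers = np.asarray([cl.center for cl in clusters], dtype=float)
    roles = assign_roles(centers)
    variances = np.asarray([cl.variance for cl in clusters], dtype=float)
    total = variances.sum()
    labels = tuple(cl.label for cl in clusters)
    colors = tuple(tuple(int(v) for v in cl.color) for cl in clusters)
    if total == 0:
        warnings.warn("total cluster variance is zero; augmentation is a no-op")
        return AugmentedCenters(
            original_centers=centers,
            variance_fractions=np.zeros(3),
            augmented_centers=centers.copy(),
            roles=roles,
            colors=colors,
            labels=labels,
        )
    fractions = variances / total
    augmented = centers.copy()
    for i, role in roles.items():
        if role == "topmost":
            augmented[i, 1] = centers[i, 1] * (1.0 + AUGMENTATION_GAIN * fractions[i])
        elif role == "leftmost":
            augmented[i, 0] = centers[i, 0] * (1.0 - AUGMENTATION_GAIN * fractions[i])
        else:  # rightmost
            augmented[i, 0] = centers[i, 0] * (1.0 + AUGMENTATION_GAIN * fractions[i])
    return AugmentedCenters(
        original_centers=centers,
        variance_fractions=fractions,
        augmented_centers=augmented,
        roles=roles,
        colors=colors,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Inverse-distance contributions
# ---------------------------------------------------------------------------

def _contributions_array(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Normalized 1/D contributions for an (..., 2) array of phasor points."""
    d = np.linalg.norm(points[..., None, :] - centers, axis=-1)
    at_center = d < _COINCIDENCE
    inv = 1.0 / np.where(at_center, 1.0, d)
    c = inv / inv.sum(axis=-1, keepdims=True)
    hit = at_center.any(axis=-1)
    if np.any(hit):
        # point-at-center rule: the coincident component takes everything
        pure = at_center.astype(float)
        denom = pure.sum(axis=-1, keepdims=True)
        pure = pure / np.where(denom > 0, denom, 1.0)
        c = np.where(hit[..., None], pure, c)
    return c


def contributions(point: Sequence[float], centers: AugmentedCenters) -> np.ndarray:
    """Normalized contributions of the three components to one phasor point."""
    p = np.asarray(point, dtype=float)
    if p.shape != (2,):
        raise ValueError("point must be a (g, s) pair")
    return _contributions_array(p[None], centers.augmented_centers)[0]


@dataclass
class ContributionMap:
    """Per-pixel normalized component contributions (channels sum to 1)."""

    contributions: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...]
    colors: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.contributions.ndim != 3 or self.contributions.shape[2] != len(self.labels):
            raise ValueError("contributions must be (H, W, n_components)")
        if self.contributions.shape[:2] != self.mask.shape:
            raise ValueError("contributions and mask must share image shape")
        vals = self.contributions[self.mask]
        if vals.size:
            if vals.min() < -1e-9:
                raise ValueError("contributions must be non-negative")
            if np.abs(vals.sum(axis=-1) - 1.0).max() > 1e-6:
                raise ValueError("unmasked contributions must sum to 1")


def contribution_image(sample: PhasorImage, centers: AugmentedCenters) -> ContributionMap:
    """Apply the inverse-distance attribution to every unmasked pixel."""
    pts = np.stack([sample.g, sample.s], axis=-1)
    c = _contributions_array(pts, centers.augmented_centers)
    c[~sample.mask] = 0.0
    return ContributionMap(
        contributions=c,
        mask=sample.mask.copy(),
        labels=centers.labels,
        colors=centers.colors,
    )


# ---------------------------------------------------------------------------
# Colorization
# ---------------------------------------------------------------------------

def _blend(contrib: np.ndarray, colors: np.ndarray) -> np.ndarray:
    rgb = contrib @ colors
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)  # half-up rounding


def colorize(cm: ContributionMap) -> np.ndarray:
    """Blend component colors by contribution into an 8-bit RGB image.

    Each RGB channel is ``round(sum_i contribution_i * color_i)`` (half-up,
    clamped); masked pixels are black.  The identical blend applied to
    phasor-plot points (see :func:`phasor_colormap`) guarantees the 1:1
    correspondence between the colored phasor plot and the tissue image.
    """
    colors = np.asarray(cm.colors, dtype=float)
    rgb = _blend(cm.contributions, colors)
    rgb[~cm.mask] = 0
    return rgb


def phasor_colormap(points: np.ndarray, centers: AugmentedCenters) -> np.ndarray:
    """Color arbitrary (g, s) points by the same contribution blend as pixels."""
    c = _contributions_array(np.asarray(points, dtype=float), centers.augmented_centers)
    return _blend(c, np.asarray(centers.colors, dtype=float))
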