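"""Statistical models of reference phasor clusters and Mahalanobis distances.

A reference cluster is the phasor population of a designated reference image:
vehicle-treated tissue for endogenous autofluorescence, or a dried
single-drug sample for an exogenous reference.  The cluster is summarized by
its center (mean G, S), its 2x2 sample covariance, and a scalar variance —
the mean squared Euclidean distance of the points to the center, which
equals the trace of the population (denominator N) covariance.  The mean
convention keeps variance fractions independent of how many pixels each
reference image contributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .flim_io import PhasorImage

__all__ = ["ReferenceCluster", "build_cluster", "mahalanobis"]

# Diagonal loading applied when the covariance is (near-)singular, e.g. for
# collinear or degenerate reference points.
_EIG_FLOOR = 1e-12
_RIDGE = 1e-9


@dataclass
class ReferenceCluster:
    """A labeled phasor population with center, covariance and scalar variance."""

    label: str
    points: np.ndarray
    center: tuple[float, float] = field(init=False)
    covariance: np.ndarray = field(init=False)
    variance: float = field(init=False)
    color: tuple[int, int, int] = (255, 255, 255)
    role: str | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("points must be (N, 2) (g, s) pairs")
        if pts.shape[0] < 2:
            raise ValueError("insufficient reference data: need >= 2 points")
        self.points = pts
        c = pts.mean(axis=0)
        self.center = (float(c[0]), float(c[1]))
        d = pts - c
        n = pts.shape[0]
        self.covariance = d.T @ d / (n - 1)
        # mean squared distance to center == trace of population covariance
        self.variance = float(np.mean(np.einsum("ij,ij->i", d, d)))
        if self.role not in (None, "topmost", "leftmost", "rightmost"):
            raise ValueError(f"unknown role: {self.role!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "center": list(self.center),
            "covariance": self.covariance.tolist(),
            "variance": self.variance,
            "color": list(self.color),
            "role": self.role,
            "points": self.points.tolist(),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceCluster":
        d = json.loads(Path(path).read_text())
        return cls(
            label=d["label"],
            points=np.asarray(d["points"], dtype=float),
            color=tuple(d.get("color", (255, 255, 255))),
            role=d.get("role"),
        )

    def regularized_covariance(self) -> np.ndarray:
        """Covariance with diagonal loading when the smallest eigenvalue is ~0."""
        cov = self.covariance
        if np.linalg.eigvalsh(cov)[0] < _EIG_FLOOR:
            cov = cov + _RIDGE * np.eye(2)
        return cov


def build_cluster(
    p: PhasorImage,
    label: str,
    color: tuple[int, int, int] = (255, 255, 255),
    role: str | None = None,
) -> ReferenceCluster:
    """Build a reference cluster from all unmasked pixels of a phasor image."""
    pts = p.points()
    if pts.shape[0] < 2:
        raise ValueError("insufficient reference data: need >= 2 unmasked pixels")
    return ReferenceCluster(label=label, points=pts, color=color, role=role)


def mahalanobis(point, cluster: ReferenceCluster) -> np.ndarray | float:
    """Mahalanobis distance from phasor point(s) to a reference cluster.

    ``D = sqrt((p - c)^T Sigma^{-1} (p - c))`` with the cluster's sample
    covariance (diagonally loaded if singular).  Accepts a single (g, s)
    pair or an ``(..., 2)`` array; with an identity covariance this reduces
    to the Euclidean distance.
    """
    p = np.asarray(point, dtype=float)
    scalar = p.ndim == 1
    d = np.atleast_2d(p) - np.asarray(cluster.center)
    cov = cluster.regularized_covariance()
    sol = np.linalg.solve(cov, d.reshape(-1, 2).T).T.reshape(d.shape)
    d2 = np.einsum("...i,...i->...", d, sol)
    out = np.sqrt(np.clip(d2, 0.0, None))
    return float(out[0]) if scalar else out
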