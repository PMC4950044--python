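"""Pairwise community dissimilarity, great-circle distance, and PCoA.

Bray-Curtis dissimilarity is computed on row-normalized (relative)
abundances, so it is invariant to library size.  Principal coordinates
analysis uses Gower double-centering with no negative-eigenvalue
correction: negative eigenvalues are reported, but proportions explained
are taken over the positive eigenvalues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import OtuTable

__all__ = ["DistanceMatrix", "OrdinationResult", "bray_curtis", "haversine_km", "pcoa"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Labelled square symmetric (dis)similarity matrix."""

    labels: list
    values: np.ndarray
    kind: str = "dissimilarity"  # or "similarity"
    metric_name: str = ""

    def __post_init__(self):
        self.labels = list(map(str, self.labels))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        diag = 0.0 if self.kind == "dissimilarity" else 1.0
        if not np.allclose(np.diag(self.values), diag, atol=1e-12):
            raise ValueError(f"{self.kind} matrix must have a constant {diag} diagonal")

    def to_similarity(self) -> "DistanceMatrix":
        if self.kind == "similarity":
            return self
        return DistanceMatrix(self.labels, 1.0 - self.values, "similarity", self.metric_name)

    def submatrix(self, keep) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in keep]
        return DistanceMatrix(
            list(keep), self.values[np.ix_(idx, idx)], self.kind, self.metric_name
        )

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class OrdinationResult:
    """Eigenvalues, scores and proportions explained of an ordination."""

    eigenvalues: np.ndarray
    prop_explained: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray = None
    constraint_scores: np.ndarray = None
    extras: dict = field(default_factory=dict)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) on relative rows."""
    rel = table.relative() if table.mode == "counts" else table
    zero = rel.values.sum(axis=1) == 0
    if np.any(zero):
        i = int(np.argmax(zero))
        raise ValueError(f"all-zero sample {rel.sample_ids[i]!r}")
    x = rel.values
    # |x_i - y_i| summed / (x_i + y_i) summed; rows sum to 1 so denominator = 2
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(x - x[i]).sum(axis=1) / (x + x[i]).sum(axis=1)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(rel.sample_ids, d, "dissimilarity", "bray-curtis")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError(f"latitude {lat} out of [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical MDS).

    Gower-centers -0.5 * d^2 and eigendecomposes.  Axes are ordered by
    decreasing eigenvalue; coordinates are eigenvectors scaled by
    sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean input) are kept
    in ``eigenvalues`` but excluded from coordinates, and ``prop_explained``
    divides by the sum of positive eigenvalues.
    """
    if d.kind != "dissimilarity":
        raise ValueError("pcoa requires a dissimilarity matrix")
    dm = d.values
    n = dm.shape[0]
    a = -0.5 * dm**2
    ctr = np.eye(n) - np.ones((n, n)) / n
    b = ctr @ a @ ctr
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10 if evals.size else np.array([], bool)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(
        eigenvalues=evals,
        prop_explained=prop,
        site_scores=coords,
        extras={"labels": d.labels, "n_negative_eigenvalues": int((evals < 0).sum())},
    )
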