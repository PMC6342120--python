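"""Multidimensional trait space: Gower dissimilarity, PCoA, and FRic.

Entities are embedded by principal coordinates analysis (PCoA) of their
pairwise Gower dissimilarities. Because Gower dissimilarities on
categorical data are generally non-Euclidean, a Cailliez additive
constant is applied when the doubly-centered Gram matrix has negative
eigenvalues, making the configuration embeddable without imaginary
axes. Functional richness (FRic) of an assemblage is the volume of the
convex hull of its entities on the retained axes, expressed as a
percentage of the pooled hull volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel

from .errors import DegenerateHullError, ValidationError
from .schema import EntityTable, TraitSchema

__all__ = [
    "TraitSpace",
    "QualityRecord",
    "FRicResult",
    "gower_matrix",
    "cailliez_constant",
    "pcoa_cailliez",
    "space_quality",
    "fric",
    "plot_trait_space",
]

#: Relative tolerance below which an eigenvalue is treated as zero.
EIG_TOL = 1e-8


def _trait_tuples(entities) -> list[tuple[str, ...]]:
    if isinstance(entities, EntityTable):
        return entities.trait_tuples
    return [tuple(t) for t in entities]


def gower_matrix(entities, schema: TraitSchema) -> np.ndarray:
    """Pairwise Gower dissimilarities between functional entities.

    Nominal traits contribute a 0/1 mismatch; ordered traits contribute
    the absolute rank difference normalized by the trait's declared rank
    range (number of levels minus one). The per-pair dissimilarity is the
    unweighted mean over traits, so it lies in [0, 1].

    `entities` may be an :class:`EntityTable` or a plain sequence of
    trait-value tuples.
    """
    tuples = _trait_tuples(entities)
    n = len(tuples)
    if n < 2:
        raise ValidationError("Gower matrix needs at least 2 entities")
    parts = np.zeros((n, n))
    for j, trait in enumerate(schema.traits):
        ranks = np.array([trait.rank(t[j]) for t in tuples], dtype=float)
        if trait.ordered and trait.n_levels > 1:
            rng = trait.n_levels - 1
            contrib = np.abs(ranks[:, None] - ranks[None, :]) / rng
        else:
            contrib = (ranks[:, None] != ranks[None, :]).astype(float)
        parts += contrib
    return parts / len(schema.traits)


@dataclass
class QualityRecord:
    """Quality diagnostics of a reduced-dimension trait space."""

    msd: float
    mantel_r: float
    mantel_r2: float
    mantel_p: float
    permutations: int
    low_permutations: bool = False

    def to_dict(self) -> dict:
        return {
            "mSD": self.msd,
            "mantel_r": self.mantel_r,
            "mantel_r2": self.mantel_r2,
            "mantel_p": self.mantel_p,
            "permutations": self.permutations,
            "low_permutations": self.low_permutations,
        }


@dataclass
class TraitSpace:
    """Coordinates of functional entities on the retained PCoA axes.

    Attributes
    ----------
    coordinates:
        Entities x m array of axis scores, ordered by decreasing
        eigenvalue; columns are centered.
    eigenvalues:
        All positive eigenvalues of the (corrected) configuration.
    m:
        Number of retained axes.
    cailliez_constant:
        Additive constant applied to off-diagonal dissimilarities
        (0.0 when the input was already Euclidean).
    quality:
        Optional :class:`QualityRecord`, filled by :func:`space_quality`.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    m: int
    cailliez_constant: float = 0.0
    quality: QualityRecord | None = field(default=None)

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]


def _gram(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean.

    Computed as the largest real eigenvalue of the 2n x 2n companion
    matrix of Cailliez (1983); returns 0 for an already-Euclidean D.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D ** 2) @ J
    d2 = -0.5 * J @ D @ J
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bottom = np.hstack([-np.eye(n), -4.0 * d2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    c = float(np.max(eigs.real))
    return max(c, 0.0)


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    return D


def pcoa_cailliez(D: np.ndarray, m: int = 4) -> TraitSpace:
    """Principal coordinates analysis with a Cailliez correction.

    The correction constant is applied only when the uncorrected Gram
    matrix has an eigenvalue below ``-EIG_TOL * max(eigenvalue)``. The
    first `m` axes (by decreasing eigenvalue) are returned; requesting
    more axes than there are positive eigenvalues is an error.
    """
    D = _check_dissimilarity(D)
    if m < 2:
        raise ValidationError("at least 2 axes are required (m >= 2)")
    eigvals = np.linalg.eigvalsh(_gram(D))
    tol = EIG_TOL * max(eigvals.max(), 1.0)
    constant = 0.0
    if eigvals.min() < -tol:
        constant = cailliez_constant(D)
        D = D + constant * (1 - np.eye(D.shape[0]))
    vals, vecs = np.linalg.eigh(_gram(D))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = EIG_TOL * max(vals.max(), 1.0)
    positive = vals > tol
    n_pos = int(positive.sum())
    if m > n_pos:
        raise ValidationError(
            f"requested {m} axes but only {n_pos} positive axes are available"
        )
    coords = vecs[:, :m] * np.sqrt(vals[:m])
    return TraitSpace(
        coordinates=coords,
        eigenvalues=vals[positive],
        m=m,
        cailliez_constant=constant,
    )


def space_quality(
    D: np.ndarray,
    space: TraitSpace,
    permutations: int = 999,
    seed: int | None = None,
) -> QualityRecord:
    """Quality of the reduced space relative to the input dissimilarities.

    mSD is the mean squared deviation between the input dissimilarities
    and the Euclidean distances in the retained space, both standardized
    by their maximum so the two are on a common scale. The Mantel
    statistic is the Pearson matrix correlation, with a one-sided
    (positive association) permutation p-value.
    """
    D = _check_dissimilarity(D)
    if space.n_points != D.shape[0]:
        raise ValidationError("trait space and dissimilarity matrix sizes differ")
    d_in = squareform(D, checks=False)
    d_sp = pdist(space.coordinates)
    s_in = d_in / d_in.max()
    s_sp = d_sp / d_sp.max()
    msd = float(np.mean((s_in - s_sp) ** 2))
    r, p, _ = mantel(
        DistanceMatrix(D),
        DistanceMatrix(squareform(d_sp, checks=False)),
        method="pearson",
        permutations=permutations,
        alternative="greater",
        seed=seed,
    )
    record = QualityRecord(
        msd=msd,
        mantel_r=float(r),
        mantel_r2=float(r) ** 2,
        mantel_p=float(p),
        permutations=permutations,
        low_permutations=permutations < 99,
    )
    space.quality = record
    return record


@dataclass
class FRicResult:
    """Convex-hull functional richness of one assemblage."""

    assemblage: str
    hull_volume: float
    pool_volume: float
    fric_percent: float


def _hull_volume(points: np.ndarray, context: str) -> float:
    m = points.shape[1]
    if points.shape[0] < m + 1:
        raise DegenerateHullError(
            f"{context}: {points.shape[0]} points cannot span {m} dimensions"
        )
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateHullError(
            f"{context}: points are affinely dependent in {m} dimensions"
        ) from exc


def fric(
    space: TraitSpace,
    subset: Sequence[int],
    pool: Sequence[int] | None = None,
    assemblage: str = "",
) -> FRicResult:
    """Functional richness of `subset` as a percentage of `pool`'s hull volume.

    Raises :class:`DegenerateHullError` (never a silent zero) when the
    subset is affinely dependent on the retained axes.
    """
    pool_idx = np.arange(space.n_points) if pool is None else np.asarray(sorted(pool))
    sub_idx = np.asarray(sorted(subset))
    if not np.isin(sub_idx, pool_idx).all():
        raise ValidationError("subset must be contained in the pool")
    pool_vol = _hull_volume(space.coordinates[pool_idx], "pool")
    sub_vol = _hull_volume(space.coordinates[sub_idx], f"assemblage {assemblage!r}")
    return FRicResult(
        assemblage=assemblage,
        hull_volume=sub_vol,
        pool_volume=pool_vol,
        fric_percent=100.0 * sub_vol / pool_vol,
    )


def plot_trait_space(space: TraitSpace, highlight=None, ax=None, **scatter_kw):
    """Basic scatter of entities on the first two trait-space axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = space.coordinates[:, :2]
    ax.scatter(xy[:, 0], xy[:, 1], color="0.6", s=12, **scatter_kw)
    if highlight is not None:
        idx = np.asarray(list(highlight))
        ax.scatter(xy[idx, 0], xy[idx, 1], color="C3", s=18)
    ax.set_xlabel("PCoA axis 1")
    ax.set_ylabel("PCoA axis 2")
    return ax
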