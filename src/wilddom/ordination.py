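"""Ordination: PCoA, non-metric MDS with Kruskal stress-1, axis orientation.

NMDS axes carry no intrinsic sign, so every directional statistic in the
pipeline is defined relative to an explicit orientation rule. The default
(``anchor_group_positive``) flips axis 1 so that the mean coordinate of the
domesticated samples minus the mean of the wild samples is nonnegative;
"rightward" shifts are therefore shifts toward the domesticated side by
construction, and the arbitrary sign of the embedding can never silently
invert a result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .datasets import NA, CountTable, RunConfig, ValidationError

logger = logging.getLogger("wilddom")

EIG_TOL = 1e-9


@dataclass
class OrdinationResult:
    """Low-dimensional sample configuration plus fit diagnostics."""

    sample_ids: list[str]
    coordinates: np.ndarray  # n x k, column-centered
    stress: float | None = None  # Kruskal stress-1 (NMDS only)
    eigenvalues: np.ndarray | None = None  # PCoA only, includes negatives
    converged: bool = True
    n_starts_used: int = 1
    orientation_rule: str = "none"
    method: str = "nmds"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 1:
            raise ValidationError("coordinates must be an n x k matrix with k >= 1")

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        frame = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"axis{i + 1}" for i in range(k)],
        )
        return frame

    def axis(self, index: int = 0) -> pd.Series:
        return self.to_frame().iloc[:, index]


def stress1(coordinates: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Fitted inter-point distances are monotonically regressed on the observed
    dissimilarities (weak / primary tie treatment, as in isotonic regression
    with ties averaged); stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    delta = squareform(dm.data, checks=False)
    d = pdist(np.asarray(coordinates, dtype=float))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dhat = iso.fit_transform(delta, d)
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal-coordinates analysis keeping only positive-eigenvalue axes.

    Eigendecomposition of the Gower-centered squared-distance matrix.
    Negative eigenvalues (non-Euclidean dissimilarities such as Bray-Curtis)
    are reported signed in ``eigenvalues`` but their axes are excluded;
    ``k`` is truncated with a warning when fewer positive axes exist.
    """
    n = len(dm.ids)
    a = -0.5 * dm.data.astype(float) ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    g = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_positive = int((eigvals > EIG_TOL).sum())
    if (eigvals < -EIG_TOL).any():
        logger.warning(
            "pcoa: %d negative eigenvalues (min %.3g); their axes are excluded",
            int((eigvals < -EIG_TOL).sum()),
            float(eigvals.min()),
        )
    if k > n_positive:
        logger.warning("pcoa: k=%d truncated to %d positive axes", k, n_positive)
        k = max(n_positive, 1)
    k = min(k, n_positive) if n_positive else 1
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(
        sample_ids=[str(i) for i in dm.ids],
        coordinates=coords,
        eigenvalues=eigvals,
        method="pcoa",
    )


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    One start from the PCoA configuration plus ``n_starts - 1`` random
    starts; the lowest-stress solution is returned (the PCoA start itself is
    a candidate, so the returned stress never exceeds the start's stress).
    """
    n = len(dm.ids)
    if n < k + 2:
        raise ValidationError(f"NMDS with k={k} needs at least {k + 2} samples, got {n}")
    start = pcoa(dm, k=k)
    init = start.coordinates
    if init.shape[1] < k:  # degenerate: pad with zeros
        init = np.hstack([init, np.zeros((n, k - init.shape[1]))])

    candidates: list[tuple[float, np.ndarray, bool]] = [(stress1(init, dm), init, True)]
    rng = np.random.default_rng(seed)
    inits: list[np.ndarray | None] = [init] + [None] * max(0, n_starts - 1)
    for start_init in inits:
        state = int(rng.integers(0, 2**31 - 1))
        coords, _, n_iter = smacof(
            dm.data,
            metric=False,
            n_components=k,
            init=start_init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=state,
            normalized_stress=True,
            return_n_iter=True,
        )
        candidates.append((stress1(coords, dm), coords, n_iter < max_iter))
    best_stress, best_coords, best_converged = min(candidates, key=lambda c: c[0])
    if not best_converged:
        logger.warning("nmds: best start did not converge within %d iterations", max_iter)
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    # rotate to principal axes so axis 1 is the max-variance direction
    _, _, vt = np.linalg.svd(best_coords, full_matrices=False)
    best_coords = best_coords @ vt.T
    return OrdinationResult(
        sample_ids=[str(i) for i in dm.ids],
        coordinates=best_coords,
        stress=best_stress,
        converged=best_converged,
        n_starts_used=n_starts,
        method="nmds",
        seed=seed,
    )


def nmds_from_config(dm: DistanceMatrix, config: RunConfig) -> OrdinationResult:
    return nmds(
        dm,
        k=config.nmds_dimensions,
        n_starts=config.nmds_starts,
        max_iter=config.nmds_max_iter,
        tol=config.nmds_tol,
        seed=config.random_seed,
    )


def orient(
    result: OrdinationResult,
    metadata: pd.DataFrame,
    rule: str = "anchor_group_positive",
    anchor_column: str = "status",
    positive_level: str = "domesticated",
    negative_level: str = "wild",
) -> OrdinationResult:
    """Fix axis signs deterministically (sign flips only; distances unchanged).

    ``anchor_group_positive`` flips axis 1 so mean(positive_level) -
    mean(negative_level) >= 0; higher axes are flipped so their largest-
    magnitude coordinate is positive. Idempotent.
    """
    if rule == "none":
        return replace(result, orientation_rule="none")
    if rule != "anchor_group_positive":
        raise ValidationError(f"unknown orientation rule {rule!r}")
    frame = result.to_frame()
    labels = metadata.reindex(frame.index)[anchor_column]
    pos = frame[labels == positive_level]
    neg = frame[labels == negative_level]
    if pos.empty or neg.empty:
        raise ValidationError(
            f"orientation anchor groups {positive_level!r}/{negative_level!r} absent"
        )
    coords = result.coordinates.copy()
    if pos.iloc[:, 0].mean() - neg.iloc[:, 0].mean() < 0:
        coords[:, 0] = -coords[:, 0]
    for j in range(1, coords.shape[1]):
        extreme = np.argmax(np.abs(coords[:, j]))
        if coords[extreme, j] < 0:
            coords[:, j] = -coords[:, j]
    return replace(result, coordinates=coords, orientation_rule=rule)


@dataclass
class ProcrustesResult:
    aligned: OrdinationResult
    m_squared: float
    n_shared: int


def procrustes(target: OrdinationResult, query: OrdinationResult) -> ProcrustesResult:
    """Align ``query`` onto ``target`` by translation/rotation/scaling.

    The transform is estimated on the shared samples (>= 3 required) and the
    symmetric Procrustes statistic m² in [0, 1] is reported; the transform
    is then applied to all query samples.
    """
    shared = [s for s in target.sample_ids if s in set(query.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("procrustes needs at least 3 shared samples")
    tf = target.to_frame().loc[shared].to_numpy()
    qf = query.to_frame().loc[shared].to_numpy()
    mu_t, mu_q = tf.mean(axis=0), qf.mean(axis=0)
    a = tf - mu_t
    b = qf - mu_q
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0 or norm_b == 0:
        raise ValidationError("degenerate configuration (all points coincide)")
    a /= norm_a
    b /= norm_b
    u, s, vt = np.linalg.svd(b.T @ a)
    rotation = u @ vt
    scale = s.sum()
    m_squared = float(max(0.0, 1.0 - scale**2))
    full = (query.coordinates - mu_q) / norm_b
    aligned_coords = scale * full @ rotation
    aligned = replace(query, coordinates=aligned_coords, orientation_rule="procrustes_reference")
    return ProcrustesResult(aligned=aligned, m_squared=m_squared, n_shared=len(shared))


def joint_ordination(
    tables: list[CountTable],
    metric: str = "braycurtis",
    config: RunConfig | None = None,
    tree=None,
) -> tuple[OrdinationResult, DistanceMatrix]:
    """Merge cohorts on their taxon union and embed them in one NMDS space."""
    from .diversity import distance_matrix  # local import avoids a cycle

    merged = CountTable.merge(tables)
    universes = [set(t.taxon_ids) for t in tables]
    if len(universes) > 1 and not set.intersection(*universes):
        logger.warning("joint_ordination: cohorts share no taxa; distances will saturate")
    dm = distance_matrix(merged, metric=metric, tree=tree)
    config = config or RunConfig()
    return nmds_from_config(dm, config), dm
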