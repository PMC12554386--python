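"""Alpha diversity, Bray-Curtis ordination and ANOSIM group testing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from assemblage.io_tables import CommunityTable, register_result


@register_result
@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling coordinates with eigenvalues sorted descending.

    ``proportion_explained`` is computed over positive eigenvalues only;
    negative eigenvalues are reported as-is (no correction applied).
    """

    coordinates: tuple  # samples x axes
    eigenvalues: tuple
    proportion_explained: tuple
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "coordinates", tuple(map(tuple, self.coordinates)))
        object.__setattr__(self, "eigenvalues", tuple(self.eigenvalues))
        object.__setattr__(
            self, "proportion_explained", tuple(self.proportion_explained)
        )

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)


@register_result
@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int
    seed: int | None = None

    def __post_init__(self):
        if not -1.0 <= self.R <= 1.0:
            raise ValueError(f"R out of range: {self.R}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")


def shannon(counts) -> float:
    """Shannon diversity in nats: ``H = -sum p ln p`` over positive counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: CommunityTable) -> dict[str, float]:
    return {
        s: shannon(table.counts[:, j]) for j, s in enumerate(table.sample_ids)
    }


def bray_curtis(table: CommunityTable) -> np.ndarray:
    """Bray-Curtis dissimilarity on raw counts (no rarefaction)."""
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if (table.library_sizes == 0).any():
        raise ValueError("zero-total sample column")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    return squareform(condensed)


def pcoa(
    d: np.ndarray,
    n_axes: int | None = None,
    sample_ids: tuple[str, ...] = (),
) -> OrdinationResult:
    """Principal coordinate analysis by classical scaling.

    Double-centers ``-d**2 / 2``, eigendecomposes, and returns coordinates
    ``eigvec * sqrt(eigval)`` for positive eigenvalues (up to ``n_axes``).
    Negative eigenvalues are reported unchanged.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    positive = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    n_pos = int(positive.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[positive].sum()
    proportion = tuple(
        float(v / pos_sum) if pos else 0.0
        for v, pos in zip(eigvals, positive)
    )
    return OrdinationResult(
        coordinates=tuple(map(tuple, coords)),
        eigenvalues=tuple(float(v) for v in eigvals),
        proportion_explained=proportion,
        sample_ids=tuple(sample_ids),
    )


def pcoa_table(table: CommunityTable, n_axes: int | None = None) -> OrdinationResult:
    return pcoa(bray_curtis(table), n_axes=n_axes, sample_ids=table.sample_ids)


def _anosim_r(ranks: np.ndarray, between: np.ndarray, n: int) -> float:
    r_between = ranks[between].mean()
    r_within = ranks[~between].mean()
    m = n * (n - 1) / 2
    return (r_between - r_within) / (m / 2)


def anosim(
    d: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    mid-ranked ties over all M pairs; the permutation p-value carries the
    +1 correction and never reaches 0.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    codes = np.searchsorted(uniq, labels)
    between_obs = codes[iu[0]] != codes[iu[1]]
    r_obs = _anosim_r(ranks, between_obs, n)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        between = perm[iu[0]] != perm[iu[1]]
        if _anosim_r(ranks, between, n) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p=float(p), n_perm=n_perm, seed=seed)
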